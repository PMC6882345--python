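# Ensembl VEP consequence terms with impact rating HIGH (Ensembl release 98).
# One term per line; matching is case-insensitive. Override with the
# high_impact_terms option in the configuration file.
transcript_ablation
splice_acceptor_variant
splice_donor_variant
stop_gained
frameshift_variant
stop_lost
start_lost
transcript_amplification
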