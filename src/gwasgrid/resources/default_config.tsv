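# Default cell-classification rules and global parameters.
# Rules: two count tiers (1 and >=2) crossed with the low-MAF and
# high-impact flags; report=TRUE rows get a numbered bubble when the
# cell lies beyond the significance boundary.
idx	min_count	maf	conseq	colour	report
1	1	FALSE	FALSE	black	FALSE
2	1	FALSE	TRUE	light pink	TRUE
3	1	TRUE	FALSE	green	FALSE
4	1	TRUE	TRUE	dark magenta	TRUE
5	2	FALSE	FALSE	blue	FALSE
6	2	FALSE	TRUE	pink	TRUE
7	2	TRUE	FALSE	red	FALSE
8	2	TRUE	TRUE	cyan	TRUE
[options]
chunk_bp=3000000
pbin=0.125
cap_nlp=20
maf_threshold=0.05
fdr_q=0.05
annotation_mode=table
output_format=pdf
table_capacity=130
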