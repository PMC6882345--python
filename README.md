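# gwasgrid

Binned, transposed Manhattan plots for genome-wide association (GWAS)
summary statistics.

## The problem

A conventional Manhattan plot draws one point per variant, −log10(p)
against genomic position. With modern meta-analyses reporting tens of
millions of variants and hundreds of associated loci, the plot becomes
both unwieldy (annotating gene names by hand) and uninformative (a
single very significant variant is indistinguishable from a dense
haplotype block of equally significant variants hiding behind one dot).

`gwasgrid` addresses both problems for analysts preparing
publication-quality association figures:

- The genome is divided into chunks of `c` bp (default `c` = 3 Mbp) and
  the significance axis into chunks of width `w` in −log10(p) units
  (default `w` = 0.125), capped at −log10(p) = 20: a variant with
  chromosome position `x` and p-value `p` increments the count
  `N[⌊(x−1)/c⌋, ⌊min(−log10 p, 20)/w⌋]` of a genome × significance
  matrix. One streaming pass suffices, so memory is governed by the
  matrix (about 1031 × 160 cells genome-wide at the defaults), not by
  the number of variants.
- Each non-empty cell is classified by its variant count and two
  annotation flags — does it contain at least one low-frequency variant
  (MAF < 5%), at least one variant with a high-impact (VEP `HIGH`)
  consequence — against a configurable eight-rule colour scheme.
- Significance is gated by a Benjamini–Hochberg false-discovery-rate
  boundary at level `q` (default 5%): with order statistics
  p(1) ≤ … ≤ p(m) over all variants, the boundary is
  p\* = p(k), k = max{i : p(i) ≤ iq/m}. Cells entirely beyond the
  boundary are drawn in their rule's colour, with numbered bubbles
  marking cells whose rule requests reporting; everything else is shaded
  in alternating greys by chromosome parity. A fixed −log10(p) cut
  (e.g. genome-wide 5·10⁻⁸) can be used instead.
- The plot is transposed — genome down the page, significance across —
  which frees the right-hand panel for locus annotations: a table of up
  to 130 loci (sentinel variant, gene, odds ratio, effect-allele
  frequency, p-value, novel/known), or repelled gene-name labels when
  there are more.

## Worked example

Everything below is synthetic — the package ships a simulator so no
download is needed:

```python
from gwasgrid import (simulate_gwas, default_config, read_summary_stats, read_loci_table,
                      build_layout, accumulate, significance_boundary, classify_matrix,
                      key_counts, PlotSpec, render_figure, render_key)

rules, opts = default_config()
summary, loci_path, truth = simulate_gwas(100_000, 12, seed=42, out_dir="example")
layout = build_layout(read_summary_stats(summary), opts.chunk_bp)
matrix = accumulate(read_summary_stats(summary), layout, opts)
boundary = significance_boundary(matrix.pvalues, opts)
cells = classify_matrix(matrix, rules, boundary)
key = key_counts(cells, matrix, rules)

print(f"genome bins: {layout.n_rows}, significance bins: {matrix.n_cols}")
print(f"BH 5% FDR boundary: p* = {boundary.p_star:.3e} (-log10 p = {boundary.nlp_star:.2f})")
print(f"non-empty cells: {len(cells)}, significant: {sum(c.significant for c in cells)}, "
      f"bubbles: {sum(c.bubble for c in cells)}")
for row in render_key(key, rules):
    print(f"  key {row.idx}: count {row.count_range:>7}  {row.annotation:<22} {row.n_cells} cells")

spec = PlotSpec(layout=layout, matrix=matrix, cells=cells, boundary=boundary, key=key,
                rules=rules, loci=read_loci_table(loci_path), mode="table", options=opts)
render_figure(spec, "example/figure.pdf")
```

prints

```
genome bins: 965, significance bins: 160
BH 5% FDR boundary: p* = 1.463e-04 (-log10 p = 3.83)
non-empty cells: 13556, significant: 236, bubbles: 12
  key 1: count       1  -                      3126 cells
  key 2: count       1  high impact            29 cells
  key 3: count       1  low MAF                344 cells
  key 4: count       1  low MAF + high impact  8 cells
  key 5: count    2-42  -                      4462 cells
  key 6: count    2-42  high impact            252 cells
  key 7: count    2-42  low MAF                4677 cells
  key 8: count    2-42  low MAF + high impact  658 cells
```

The 100,000 variants collapse into 13,556 occupied cells; 236 cells lie
beyond the 5% FDR boundary and 12 of them carry a numbered bubble
because their rule (low-MAF and/or high-impact content) asks for
reporting. The key's count ranges end at the data-driven maximum cell
count (42 variants here). `example/figure.pdf` is the two-panel A4
figure: the transposed heatmap on the left, the 12-locus annotation
table and the key on the right.

The same pipeline is available as a console script:

```sh
gwasgrid simulate --n-variants 100000 --n-loci 12 --seed 42 --out-dir example
gwasgrid --summary example/sim_summary.tsv.gz --loci example/sim_loci.tsv \
         --config default --out example/figure.pdf
```

which also writes `example/figure.manifest.json` (input checksums,
resolved options, row counts, the boundary) for reproducibility.

## Configuration

`write_default_config("config.tsv")` emits the shipped scheme: a
tab-separated rule table (index, minimum count, MAF flag, consequence
flag, colour, report flag — eight rows covering {1, ≥2} counts crossed
with both flags) followed by an `[options]` block (`chunk_bp`, `pbin`,
`cap_nlp`, `maf_threshold`, `fdr_q` or `threshold_nlp`,
`high_impact_terms`, `annotation_mode`, `output_format`,
`table_capacity`). User configs with more count tiers are supported;
rule sets are validated for exhaustive, non-overlapping coverage at
load time.

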