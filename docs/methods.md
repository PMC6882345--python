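# Methods

## Binning model

The plot is a 2-D histogram of association results. Genome bins are
half-open intervals `[k·c + 1, (k+1)·c]` of width `c = chunk_bp`
(default 3,000,000 bp) in 1-based coordinates, laid out chromosome by
chromosome (1..22 numerically, then X, Y, MT, then other labels
lexicographically); a chromosome of length L owns `⌈L/c⌉` consecutive
matrix rows. Significance bins are half-open intervals
`[j·w, (j+1)·w)` in −log10(p) with `w = pbin` (default 0.125), up to a
ceiling `cap_nlp` (default 20). P-values below `10^-cap_nlp` — and
p = 0 from numeric underflow in the source file, with a warning — are
assigned to the last bin, so extreme signals stay on the page at the
cost of resolution beyond the cap; under the defaults the matrix has
160 significance columns and the capped bin is column 159.

Accumulation is a single streaming pass: each variant increments one
cell, sets the cell's low-MAF flag if its MAF is below `maf_threshold`
(default 0.05) and the high-impact flag if its consequence term is in
the high-impact set. Memory is therefore the matrix plus the retained
p-value vector (needed for the FDR boundary), independent of variant
count. Chromosome lengths are taken from an optional two-column lengths
file; otherwise they are inferred as the maximum observed position per
chromosome, which costs a second pass over the input but no memory.
Variants on chromosomes unknown to the layout, or beyond the stated
length, are skipped with a warning and counted (`--strict` makes the
first such record fatal); silent misplacement is never an option.

## Input handling

Summary statistics and loci tables are delimited text (tab or comma,
auto-detected from the header; gzip sniffed from magic bytes). Headers
are matched case-insensitively against a synonym list (`P`, `PVAL`,
`P_VALUE` → p-value, etc.) before an explicit column map is required.
Rows with unparsable numeric fields are skipped with a logged warning
and counted, since real summary files contain `NA` rows; accepted +
skipped always equals the number of data rows. Allele frequencies above
0.5 are folded to `1 − f` with a warning — files labelled MAF
frequently carry effect-allele frequencies.

The high-impact set defaults to the Ensembl VEP HIGH-impact consequence
terms (release-pinned in `resources/high_impact_terms.txt`) and can be
overridden with the `high_impact_terms` option; matching is
case-insensitive.

## Cell classification

A rule is (index, `min_count`, MAF flag, consequence flag, colour,
report). The distinct `min_count` values define count tiers; a valid
rule set covers every (tier, MAF, consequence) combination exactly once
and its lowest tier starts at 1, which is checked at load time. A cell
with count n and flags (m, c) matches the rule with the largest
`min_count ≤ n` whose flags equal (m, c) — this generalises the shipped
two-tier {1, ≥2} scheme to user configurations with more tiers. The
shipped scheme colours singleton cells black/light pink/green/dark
magenta and multi-variant cells blue/pink/red/cyan as the flags switch
on, with reporting (bubbles) on the four flag-carrying rule indices 2,
4, 6 and 8.

## Significance boundary

Benjamini–Hochberg step-up over the full vector of accepted p-values at
level `fdr_q` (default 0.05): p\* is the largest p(k) with
p(k) ≤ k·q/m. A cell is significant iff the lower edge of its
significance bin is ≥ −log10(p\*): a bin straddling the boundary stays
grey, so no bin is ever half grey and half coloured; an exact tie
between the boundary and a bin edge counts as significant. When p\* is
at or beyond the cap, the capped column itself is the boundary column,
so capped variants are never excluded by rounding. If nothing is
rejected, no cell is significant. A fixed cut (`threshold_nlp`, e.g.
7.301 for the conventional genome-wide 5·10⁻⁸) replaces BH when set,
covering user-defined significance conventions.

## Rendering

Portrait A4, two panels. The left panel is the matrix drawn as an RGBA
raster (one pixel per cell, nearest-neighbour interpolation) with
chromosome 1 at the top; empty cells are not painted at all.
Non-significant cells alternate dark grey (odd chromosomes) and light
grey (even); significant cells take their rule colour; bubble cells get
a circle with the rule index as text, enlarged to a legible minimum.
The boundary is a dashed vertical line. The right panel is either a
table of loci (capacity `table_capacity`, default 130 — beyond it the
renderer raises a capacity error naming label mode, or switches
automatically under `--auto-mode`) or repelled name labels. The key is
generated from the classified matrix: one row per rule with its colour,
count range (tier start to the next tier minus one; the top tier ends
at the data-driven maximum cell count), flag description and the number
of cells carrying that index.

PDF output is vector and byte-deterministic (the embedded creation
timestamp is stripped); TIFF defaults to 300 dpi.

### Label layout

Labels are placed by a short repulsion phase (overlapping boxes push
each other apart vertically, 40 sweeps) followed by an exact resolution
sweep: labels are visited in anchor order and moved to the nearest free
vertical slot, computed from the merged forbidden intervals induced by
already-placed boxes. The result is guaranteed overlap-free, is a pure
function of the input and the seed, and never raises on dense inputs —
labels displaced beyond the configured maximum only log a warning.
Leader lines connect anchors to labels displaced by more than their own
box size. Coincident anchors receive a small seeded jitter so the
layout has a direction to separate them.

## Synthetic data

The simulator emulates a single-trait case/control GWAS over 22
synthetic autosomes whose lengths follow the human karyotype shape
(longest 249 Mbp), stored as a constant so tests never need a reference
genome. Null variants receive p ~ U(0,1), positions uniform
length-weighted across the genome, MAF ~ U(0.001, 0.5), and consequence
terms drawn from a mixed list with ~1% high-impact. Each spiked locus
is a cluster (default up to 25 variants within ±400 kb) whose
−log10(p) decays log-linearly from the sentinel over a 500 kb horizon;
sentinel significance spans 10⁻³⁰ (exercising the cap) down to 10⁻¹⁰,
and loci cycle through the four (low-MAF, high-impact) designations so
every shipped rule index is realised in practice. The loci table lists
one sentinel per spiked locus with plausible odds ratio, effect-allele
frequency and alternating novel/known status. Every simulated variant
is recorded in a `SimulationTruth`, whose vectorised oracle re-bins
them independently of the streaming accumulator; same-seed runs are
byte-identical (gzip written with mtime 0).

What the simulator does not emulate: linkage-disequilibrium-driven
correlation among null p-values, genomic inflation, allosome and
mitochondrial variants, missingness patterns, or effect sizes tied to
allele frequency. Passing tests therefore demonstrate correctness of
binning, classification, thresholding and rendering — not calibration
of the FDR boundary under realistic LD.

## Problem sizes and numerical choices

The test suite runs the full pipeline at 10⁴–10⁶ simulated variants
(the end-to-end check uses 10⁶ variants and 20 loci, about 40 s total);
the acceptance script probes table capacity on a 10⁵-variant dataset
with 131 spiked loci. Equality with the naive two-pass binning oracle
is exact (integer counts); BH agreement with the brute-force step-up
scan is exact float equality, both sides selecting an element of the
same input vector. The boundary-column computation subtracts 1e-9
before the ceiling so a −log10(p\*) landing within one part in 10⁹ of a
bin edge counts as that edge, guarding against decimal-to-binary
rounding of bin widths like 0.125·k.

## Known limitations

- The annotation table at its 130-locus capacity uses a very small font;
  that matches its intended use as a full-page journal figure, but
  on-screen reading at 100% zoom is uncomfortable.
- FDR is computed over all variants in the file; filtering (e.g. by
  INFO score) must happen upstream.
- The label layout moves labels only vertically during exact
  resolution; extremely dense label sets therefore grow the occupied
  vertical band rather than spreading horizontally.
- Genome builds are the caller's responsibility: positions are binned
  as given, with no liftover.
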