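"""Reproducible synthetic GWAS fixtures with known ground truth.

Simulates a genome-wide summary-statistics file over 22 synthetic
autosomes (lengths scaled from the human karyotype, longest ~249 Mbp),
a matching loci-of-interest table and, on request, a configuration file.
Null variants carry uniform p-values; each spiked locus contributes a
cluster whose -log10(p) decays log-linearly away from the sentinel, with
sentinel p-values reaching 1e-30 so the significance cap is exercised.
Designated loci carry low-MAF and/or high-impact variants so every
default classification rule is realised.  Everything generated is
recorded in a :class:`SimulationTruth` so tests can recompute expected
per-cell counts with an independent oracle.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .io_formats import GlobalOptions

#: synthetic autosome lengths in bp (human karyotype shape, rounded to Mbp)
CHROM_LENGTHS_BP: dict[str, int] = {
    "1": 249_000_000, "2": 243_000_000, "3": 198_000_000, "4": 191_000_000,
    "5": 181_000_000, "6": 171_000_000, "7": 159_000_000, "8": 146_000_000,
    "9": 141_000_000, "10": 136_000_000, "11": 135_000_000, "12": 134_000_000,
    "13": 115_000_000, "14": 107_000_000, "15": 102_000_000, "16": 90_000_000,
    "17": 83_000_000, "18": 80_000_000, "19": 59_000_000, "20": 63_000_000,
    "21": 48_000_000, "22": 51_000_000,
}

BENIGN_TERMS = (
    "intergenic_variant",
    "intron_variant",
    "synonymous_variant",
    "missense_variant",
    "upstream_gene_variant",
    "3_prime_UTR_variant",
)
HIGH_TERMS = ("stop_gained", "frameshift_variant", "splice_donor_variant")

#: half-width of a spiked locus in bp and the sentinel decay horizon
SPIKE_HALF_WIDTH_BP = 400_000
SPIKE_DECAY_BP = 500_000


@dataclass(frozen=True)
class SpikedLocus:
    """Ground truth for one simulated association signal."""

    chrom: str
    centre: int
    min_p: float
    n_variants: int
    low_maf: bool
    high_impact: bool
    sentinel_name: str
    gene: str


@dataclass
class SimulationTruth:
    """Everything needed to recompute the expected matrix independently."""

    seed: int
    n_variants: int
    spiked_loci: list[SpikedLocus]
    options: GlobalOptions
    variants: pd.DataFrame = field(repr=False)  # name, chrom, pos, pvalue, maf, consequence

    def expected_cell_counts(self, layout) -> np.ndarray:
        """Vectorised oracle: re-bin every simulated variant from the truth
        table (independent of the streaming accumulator)."""
        from .binning import n_significance_bins

        opts = self.options
        n_cols = n_significance_bins(opts.pbin, opts.cap_nlp)
        counts = np.zeros((layout.n_rows, n_cols), dtype=np.int64)
        offsets = np.array([layout.row_offset[c] for c in self.variants["chrom"]])
        rows = offsets + (self.variants["pos"].to_numpy() - 1) // layout.chunk_bp
        p = self.variants["pvalue"].to_numpy()
        nlp = np.where(p > 0, -np.log10(np.where(p > 0, p, 1.0)), opts.cap_nlp)
        nlp = np.minimum(nlp, opts.cap_nlp)
        cols = np.minimum((nlp / opts.pbin).astype(np.int64), n_cols - 1)
        np.add.at(counts, (rows, cols), 1)
        return counts


def _write_table(df: pd.DataFrame, path: Path, compress: bool) -> Path:
    text = df.to_csv(sep="\t", index=False)
    if compress:
        path = path if path.suffix == ".gz" else path.with_suffix(path.suffix + ".gz")
        # mtime=0 keeps output byte-identical across reruns of the same seed
        path.write_bytes(gzip.compress(text.encode("utf-8"), mtime=0))
    else:
        path.write_text(text, encoding="utf-8")
    return path


def simulate_gwas(
    n_variants: int,
    n_loci: int,
    seed: int,
    options: GlobalOptions | None = None,
    out_dir: str | Path = ".",
    *,
    prefix: str = "sim",
    compress: bool = True,
) -> tuple[Path, Path, SimulationTruth]:
    """Simulate a summary-statistics file and a loci table.

    Returns ``(summary_path, loci_path, truth)``.  Reruns with the same
    arguments produce byte-identical files.
    """
    if n_variants < 0 or n_loci < 0 or n_variants < n_loci:
        raise InputError(f"need n_variants >= n_loci >= 0, got {n_variants}, {n_loci}")
    if options is None:
        options = GlobalOptions()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    chroms = list(CHROM_LENGTHS_BP)
    lengths = np.array([CHROM_LENGTHS_BP[c] for c in chroms], dtype=np.float64)
    weights = lengths / lengths.sum()

    per_locus = max(1, min(25, n_variants // n_loci)) if n_loci else 0
    n_spiked = per_locus * n_loci
    n_null = n_variants - n_spiked

    frames: list[pd.DataFrame] = []
    spiked: list[SpikedLocus] = []
    loci_rows: list[dict] = []

    if n_loci:
        # sentinel significance from 1e-30 (cap exercised) down to 1e-10
        exps = np.linspace(30.0, 10.0, n_loci) if n_loci > 1 else np.array([30.0])
        for i in range(n_loci):
            chrom = chroms[i % len(chroms)]
            clen = CHROM_LENGTHS_BP[chrom]
            centre = int(rng.integers(5_000_000, clen - 5_000_000))
            low_maf = bool(i % 4 in (1, 3))
            high_impact = bool(i % 4 in (2, 3))
            offs = np.concatenate(
                [[0], rng.integers(-SPIKE_HALF_WIDTH_BP, SPIKE_HALF_WIDTH_BP + 1, per_locus - 1)]
            ) if per_locus > 1 else np.array([0])
            pos = np.clip(centre + offs, 1, clen)
            nlp = np.maximum(exps[i] * (1.0 - np.abs(offs) / SPIKE_DECAY_BP), 2.0)
            pvals = 10.0 ** (-nlp)
            maf = rng.uniform(options.maf_threshold + 0.01, 0.5, per_locus)
            if low_maf:
                k = max(1, per_locus // 2)
                maf[:k] = rng.uniform(0.005, options.maf_threshold * 0.9, k)
            csq = rng.choice(BENIGN_TERMS, per_locus)
            if high_impact:
                k = min(2, per_locus)
                csq[:k] = rng.choice(HIGH_TERMS, k)
            names = [f"rs9{i:03d}{j:04d}" for j in range(per_locus)]
            frames.append(
                pd.DataFrame(
                    {
                        "name": names,
                        "chrom": chrom,
                        "pos": pos.astype(np.int64),
                        "pvalue": pvals,
                        "maf": maf,
                        "consequence": csq,
                    }
                )
            )
            spiked.append(
                SpikedLocus(
                    chrom=chrom,
                    centre=centre,
                    min_p=float(pvals.min()),
                    n_variants=per_locus,
                    low_maf=low_maf,
                    high_impact=high_impact,
                    sentinel_name=names[0],
                    gene=f"GENE{i + 1}",
                )
            )
            loci_rows.append(
                {
                    "name": names[0],
                    "chrom": chrom,
                    "pos": centre,
                    "eaf": round(float(rng.uniform(0.01, 0.05) if low_maf else rng.uniform(0.10, 0.90)), 4),
                    "odds_ratio": round(float(np.exp(rng.normal(0.1, 0.08))), 3),
                    "pvalue": float(pvals.min()),
                    "novelty": "novel" if i % 2 == 0 else "known",
                    "gene": f"GENE{i + 1}",
                }
            )

    if n_null:
        ci = rng.choice(len(chroms), n_null, p=weights)
        null_pos = (rng.random(n_null) * lengths[ci]).astype(np.int64) + 1
        is_high = rng.random(n_null) < 0.01
        csq = np.where(
            is_high,
            rng.choice(HIGH_TERMS, n_null),
            rng.choice(BENIGN_TERMS, n_null),
        )
        frames.append(
            pd.DataFrame(
                {
                    "name": [f"rs{j}" for j in range(n_null)],
                    "chrom": np.array(chroms, dtype=object)[ci],
                    "pos": null_pos,
                    "pvalue": rng.uniform(0.0, 1.0, n_null).clip(min=1e-12),
                    "maf": rng.uniform(0.001, 0.5, n_null),
                    "consequence": csq,
                }
            )
        )

    if frames:
        variants = pd.concat(frames, ignore_index=True)
        order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].map(chroms.index).to_numpy()))
        variants = variants.iloc[order].reset_index(drop=True)
    else:
        variants = pd.DataFrame(columns=["name", "chrom", "pos", "pvalue", "maf", "consequence"])

    summary_path = _write_table(variants, out_dir / f"{prefix}_summary.tsv", compress)
    loci_df = pd.DataFrame(
        loci_rows, columns=["name", "chrom", "pos", "eaf", "odds_ratio", "pvalue", "novelty", "gene"]
    )
    loci_path = _write_table(loci_df, out_dir / f"{prefix}_loci.tsv", compress=False)

    truth = SimulationTruth(
        seed=seed,
        n_variants=n_variants,
        spiked_loci=spiked,
        options=options,
        variants=variants,
    )
    return summary_path, loci_path, truth


def make_index_coverage_fixture(
    seed: int = 0, out_dir: str | Path = "."
) -> tuple[Path, dict[tuple[int, int], int]]:
    """A minimal constructive dataset realising all 8 default rule indices.

    Eight cells are placed in consecutive 3-Mbp bins of chromosome 1, all
    at p = 1e-8 (significance column 64 under defaults); cell k is built
    to classify as rule index k.  Returns the summary file path and the
    expected ``{(row, col): idx}`` map computed at construction time.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    opts = GlobalOptions()
    p = 1e-8
    col = int(min(-np.log10(p), opts.cap_nlp) / opts.pbin)
    low, high = 0.01, 0.30  # below / above the 5% MAF threshold
    rows = []
    expected: dict[tuple[int, int], int] = {}

    def add(bin_idx: int, maf: float, consequence: str, tag: int) -> None:
        pos = bin_idx * opts.chunk_bp + int(rng.integers(1, opts.chunk_bp // 2))
        rows.append(
            {"name": f"fx{tag}", "chrom": "1", "pos": pos, "pvalue": p,
             "maf": maf, "consequence": consequence}
        )

    specs = [
        (1, [(high, "intron_variant")]),
        (2, [(high, "stop_gained")]),
        (3, [(low, "intron_variant")]),
        (4, [(low, "stop_gained")]),
        (5, [(high, "intron_variant"), (high, "synonymous_variant")]),
        (6, [(high, "stop_gained"), (high, "intron_variant")]),
        (7, [(low, "intron_variant"), (high, "intron_variant")]),
        (8, [(low, "intron_variant"), (high, "stop_gained")]),
    ]
    tag = 0
    for idx, members in specs:
        bin_idx = idx - 1
        for maf, csq in members:
            add(bin_idx, maf, csq, tag)
            tag += 1
        expected[(bin_idx, col)] = idx

    df = pd.DataFrame(rows, columns=["name", "chrom", "pos", "pvalue", "maf", "consequence"])
    path = _write_table(df, out_dir / "index_coverage.tsv", compress=False)
    return path, expected
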