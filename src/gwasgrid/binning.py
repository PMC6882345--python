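"""Genome layout and 2-D count-matrix accumulation.

The genome is split into fixed-width chunks (default 3 Mbp) and the
significance axis into -log10(p) chunks (default 0.125, capped at 20).
A single streaming pass over the summary statistics increments one
counter per variant, so memory is governed by the matrix dimensions and
the retained p-values, not by the number of variants.  Each cell also
carries two booleans: whether any variant in it is low-frequency
(MAF < threshold) and whether any has a high-impact consequence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import InputError, ValidationError
from .io_formats import GlobalOptions, VariantRecord

log = logging.getLogger(__name__)


def chrom_sort_key(label: str) -> tuple[int, float, str]:
    """Canonical chromosome order: 1..22 numerically, then X, Y, MT,
    then anything else lexicographically."""
    s = label.strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.isdigit():
        return (0, int(s), "")
    special = {"x": 23, "y": 24, "mt": 25, "m": 25}
    if s.lower() in special:
        return (0, special[s.lower()], "")
    return (1, 0, s.lower())


@dataclass(frozen=True)
class GenomeLayout:
    """Maps (chromosome, position) to a row of the count matrix.

    Rows are ordered by chromosome (canonical order) and then by
    ascending position bin; ``row_offset[c]`` is the first row of
    chromosome ``c`` and chromosome ``c`` owns
    ``ceil(chrom_length[c] / chunk_bp)`` consecutive rows.
    """

    chrom_order: tuple[str, ...]
    chrom_length: Mapping[str, int]
    chunk_bp: int
    row_offset: Mapping[str, int]
    n_rows: int

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_length[chrom] // self.chunk_bp)

    def row_chrom_index(self) -> np.ndarray:
        """Per-row index into chrom_order (used for parity shading)."""
        out = np.empty(self.n_rows, dtype=np.int32)
        for ci, c in enumerate(self.chrom_order):
            start = self.row_offset[c]
            out[start : start + self.n_bins(c)] = ci
        return out


def build_layout(
    records_or_lengths: Mapping[str, int] | Iterable[VariantRecord],
    chunk_bp: int = 3_000_000,
) -> GenomeLayout:
    """Build a :class:`GenomeLayout` from explicit chromosome lengths or by
    scanning a record stream (length = maximum observed position)."""
    if chunk_bp < 1:
        raise ValidationError(f"chunk_bp must be >= 1, got {chunk_bp}")
    if isinstance(records_or_lengths, Mapping):
        lengths = dict(records_or_lengths)
    else:
        lengths = {}
        for rec in records_or_lengths:
            if rec.pos > lengths.get(rec.chrom, 0):
                lengths[rec.chrom] = rec.pos
    if not lengths:
        raise InputError("cannot build genome layout: no chromosomes")
    for c, ln in lengths.items():
        if ln < 1:
            raise ValidationError(f"chromosome {c!r} has non-positive length {ln}")
    order = tuple(sorted(lengths, key=chrom_sort_key))
    offsets: dict[str, int] = {}
    row = 0
    for c in order:
        offsets[c] = row
        row += -(-lengths[c] // chunk_bp)
    return GenomeLayout(
        chrom_order=order,
        chrom_length=lengths,
        chunk_bp=chunk_bp,
        row_offset=offsets,
        n_rows=row,
    )


def position_to_row(chrom: str, pos: int, layout: GenomeLayout) -> int:
    """Row index for a 1-based position; genome bins are half-open
    ``[k*chunk_bp + 1, (k+1)*chunk_bp]`` in 1-based coordinates."""
    if chrom not in layout.row_offset:
        raise ValidationError(f"chromosome {chrom!r} not in layout")
    if pos < 1 or pos > layout.chrom_length[chrom]:
        raise ValidationError(
            f"position {pos} outside chromosome {chrom} (length {layout.chrom_length[chrom]})"
        )
    return layout.row_offset[chrom] + (pos - 1) // layout.chunk_bp


def n_significance_bins(pbin: float, cap_nlp: float) -> int:
    return int(math.ceil(cap_nlp / pbin))


def pvalue_to_col(
    pvalue: float, pbin: float = 0.125, cap_nlp: float = 20.0, *, strict: bool = False
) -> int:
    """Column index for a p-value: ``floor(min(-log10 p, cap) / pbin)``,
    clipped into the last bin so everything at or below the cap lands there.

    p = 0 (underflow in the source file) is treated as below the cap and
    assigned the last column with a warning; ``strict`` makes it fatal.
    """
    if pvalue < 0 or pvalue > 1:
        raise ValidationError(f"p-value must be in [0,1], got {pvalue}")
    n_cols = n_significance_bins(pbin, cap_nlp)
    if pvalue == 0:
        if strict:
            raise ValidationError("p-value of exactly 0 (numeric underflow)")
        log.warning("p-value of 0 assigned to the capped bin (numeric underflow)")
        return n_cols - 1
    nlp = min(-math.log10(pvalue), cap_nlp)
    return min(int(nlp / pbin), n_cols - 1)


def is_high_impact(consequence: str, high_impact_terms: frozenset[str] | set[str]) -> bool:
    """Case-insensitive membership of a consequence term in the
    high-impact set (default: the Ensembl VEP HIGH terms)."""
    return consequence.strip().lower() in high_impact_terms


@dataclass
class CountMatrix:
    """The (genome bin x significance bin) accumulator.

    ``count`` holds the per-cell variant tally; ``maf_any`` /
    ``conseq_any`` record whether any variant in the cell was low-MAF /
    high-impact.  ``pvalues`` keeps every accepted p-value for the FDR
    boundary computation.
    """

    count: np.ndarray  # (n_rows, n_cols) int64
    maf_any: np.ndarray  # (n_rows, n_cols) bool
    conseq_any: np.ndarray  # (n_rows, n_cols) bool
    total_variants: int
    pvalues: np.ndarray  # (total_variants,) float64
    pbin: float
    cap_nlp: float
    n_unmapped: int = 0  # records skipped: unknown chromosome / out-of-range pos

    @property
    def n_rows(self) -> int:
        return self.count.shape[0]

    @property
    def n_cols(self) -> int:
        return self.count.shape[1]


def accumulate(
    records: Iterable[VariantRecord],
    layout: GenomeLayout,
    options: GlobalOptions | None = None,
    *,
    strict: bool = False,
) -> CountMatrix:
    """Stream variants into a :class:`CountMatrix` in a single pass.

    Records on chromosomes absent from the layout, or with positions
    beyond the chromosome length, are skipped with a warning and counted
    in ``n_unmapped`` (robustness over silent misplacement).
    """
    if options is None:
        options = GlobalOptions()
    n_cols = n_significance_bins(options.pbin, options.cap_nlp)
    count = np.zeros((layout.n_rows, n_cols), dtype=np.int64)
    maf_any = np.zeros((layout.n_rows, n_cols), dtype=bool)
    conseq_any = np.zeros((layout.n_rows, n_cols), dtype=bool)
    pvals: list[float] = []
    n_unmapped = 0
    total = 0

    offsets = layout.row_offset
    lengths = layout.chrom_length
    chunk_bp = layout.chunk_bp
    pbin = options.pbin
    cap_nlp = options.cap_nlp
    maf_thr = options.maf_threshold
    terms = options.high_impact_terms
    zero_warned = False

    for rec in records:
        off = offsets.get(rec.chrom)
        if off is None or rec.pos > lengths[rec.chrom] or rec.pos < 1:
            if strict:
                raise ValidationError(
                    f"variant {rec.name}: ({rec.chrom}:{rec.pos}) not mappable to the layout"
                )
            if n_unmapped < 5:
                log.warning("variant %s (%s:%d) not mappable; skipped", rec.name, rec.chrom, rec.pos)
            n_unmapped += 1
            continue
        row = off + (rec.pos - 1) // chunk_bp
        p = rec.pvalue
        if p == 0:
            if strict:
                raise ValidationError(f"variant {rec.name}: p-value of exactly 0")
            if not zero_warned:
                log.warning("p-values of 0 assigned to the capped bin (numeric underflow)")
                zero_warned = True
            col = n_cols - 1
        else:
            nlp = -math.log10(p)
            if nlp >= cap_nlp:
                col = n_cols - 1
            else:
                col = min(int(nlp / pbin), n_cols - 1)
        count[row, col] += 1
        if rec.maf < maf_thr:
            maf_any[row, col] = True
        if rec.consequence.strip().lower() in terms:
            conseq_any[row, col] = True
        pvals.append(p)
        total += 1

    return CountMatrix(
        count=count,
        maf_any=maf_any,
        conseq_any=conseq_any,
        total_variants=total,
        pvalues=np.asarray(pvals, dtype=np.float64),
        pbin=pbin,
        cap_nlp=cap_nlp,
        n_unmapped=n_unmapped,
    )
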