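"""Cell classification, FDR boundary and key summarisation.

Every non-empty cell of the count matrix is matched to exactly one
configuration rule by its (count tier, low-MAF flag, high-impact flag)
combination.  The significance boundary is computed with the
Benjamini-Hochberg step-up procedure over all accepted p-values (or a
fixed -log10 p cut when configured), and cells whose significance bin
lies entirely at or beyond the boundary are drawn in the rule's colour;
bubble markers are added where the matched rule asks for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .binning import CountMatrix, n_significance_bins
from .errors import ClassificationError, InputError
from .io_formats import CellConfig, GlobalOptions


@dataclass(frozen=True)
class SignificanceBoundary:
    """The grey/coloured split of the significance axis.

    ``p_star`` is the largest rejected p-value (None when nothing is
    rejected); ``boundary_col`` is the first matrix column counted as
    significant: a cell is significant iff its column's lower edge is at
    or beyond ``nlp_star``, so a bin straddling the threshold stays grey.
    """

    q: float
    p_star: float | None
    nlp_star: float | None
    boundary_col: int | None


@dataclass(frozen=True)
class ClassifiedCell:
    row: int
    col: int
    count: int
    idx: int
    significant: bool
    bubble: bool


@dataclass(frozen=True)
class KeySummary:
    """Per-rule cell tallies for the plot key, plus the data-driven
    maximum cell count used to print the top tier's count range."""

    per_idx: dict[int, int]
    max_cell_count: int


def fdr_threshold(
    pvalues: Sequence[float] | np.ndarray,
    q: float = 0.05,
    *,
    pbin: float = 0.125,
    cap_nlp: float = 20.0,
) -> SignificanceBoundary:
    """Benjamini-Hochberg step-up over the full set of accepted p-values.

    With order statistics p(1) <= ... <= p(m), the largest k with
    p(k) <= k*q/m is found; p_star = p(k).  When no p-value is rejected,
    ``p_star`` is None and no cell is significant.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        raise InputError("FDR threshold requires at least one p-value")
    m = p.size
    ps = np.sort(p)
    crit = q * np.arange(1, m + 1) / m
    passing = np.nonzero(ps <= crit)[0]
    if passing.size == 0:
        return SignificanceBoundary(q=q, p_star=None, nlp_star=None, boundary_col=None)
    p_star = float(ps[passing[-1]])
    return _boundary_from_pstar(p_star, q, pbin, cap_nlp)


def fixed_threshold(
    threshold_nlp: float, *, pbin: float = 0.125, cap_nlp: float = 20.0, q: float = 0.05
) -> SignificanceBoundary:
    """A fixed -log10(p) significance cut (e.g. 7.3 for genome-wide 5e-8)."""
    return _boundary_from_pstar(10.0 ** (-threshold_nlp), q, pbin, cap_nlp)


def _boundary_from_pstar(
    p_star: float, q: float, pbin: float, cap_nlp: float
) -> SignificanceBoundary:
    nlp_star = -math.log10(p_star) if p_star > 0 else cap_nlp
    n_cols = n_significance_bins(pbin, cap_nlp)
    # first column whose lower edge >= nlp_star; exact ties are significant
    col = int(math.ceil(nlp_star / pbin - 1e-9))
    col = max(0, min(col, n_cols - 1))
    return SignificanceBoundary(q=q, p_star=p_star, nlp_star=nlp_star, boundary_col=col)


def significance_boundary(
    pvalues: Sequence[float] | np.ndarray, options: GlobalOptions
) -> SignificanceBoundary:
    """Dispatch to the configured procedure: fixed cut if ``threshold_nlp``
    is set, Benjamini-Hochberg at ``fdr_q`` otherwise."""
    if options.threshold_nlp is not None:
        return fixed_threshold(
            options.threshold_nlp, pbin=options.pbin, cap_nlp=options.cap_nlp, q=options.fdr_q
        )
    return fdr_threshold(pvalues, options.fdr_q, pbin=options.pbin, cap_nlp=options.cap_nlp)


def _tier_lookup(rules: Sequence[CellConfig]) -> dict[tuple[bool, bool], list[CellConfig]]:
    """Rules grouped by flag pair, sorted by descending min_count so the
    first tier whose min_count <= count wins."""
    table: dict[tuple[bool, bool], list[CellConfig]] = {}
    for r in rules:
        table.setdefault((r.maf_flag, r.conseq_flag), []).append(r)
    for group in table.values():
        group.sort(key=lambda r: -r.min_count)
    return table


def classify_cell(
    count: int, maf_any: bool, conseq_any: bool, rules: Sequence[CellConfig]
) -> CellConfig:
    """The unique rule with the largest ``min_count <= count`` whose flags
    equal the cell's flags."""
    for r in sorted(
        (r for r in rules if r.maf_flag == maf_any and r.conseq_flag == conseq_any),
        key=lambda r: -r.min_count,
    ):
        if r.min_count <= count:
            return r
    raise ClassificationError(
        f"no rule matches cell (count={count}, maf={maf_any}, conseq={conseq_any})"
    )


def classify_matrix(
    matrix: CountMatrix,
    rules: Sequence[CellConfig],
    boundary: SignificanceBoundary,
) -> list[ClassifiedCell]:
    """One :class:`ClassifiedCell` per non-empty cell, in row-major order.

    ``bubble`` is set only on significant cells whose rule has
    ``report=True``.
    """
    lookup = _tier_lookup(rules)
    bcol = boundary.boundary_col
    cells: list[ClassifiedCell] = []
    rows, cols = np.nonzero(matrix.count)
    counts = matrix.count[rows, cols]
    mafs = matrix.maf_any[rows, cols]
    csqs = matrix.conseq_any[rows, cols]
    for row, col, count, maf, csq in zip(
        rows.tolist(), cols.tolist(), counts.tolist(), mafs.tolist(), csqs.tolist()
    ):
        group = lookup.get((maf, csq))
        rule = None
        if group is not None:
            for r in group:
                if r.min_count <= count:
                    rule = r
                    break
        if rule is None:
            raise ClassificationError(
                f"no rule matches cell (count={count}, maf={maf}, conseq={csq})"
            )
        significant = bcol is not None and col >= bcol
        cells.append(
            ClassifiedCell(
                row=row,
                col=col,
                count=int(count),
                idx=rule.idx,
                significant=significant,
                bubble=significant and rule.report,
            )
        )
    return cells


def key_counts(
    cells: Sequence[ClassifiedCell],
    matrix: CountMatrix,
    rules: Sequence[CellConfig] | None = None,
) -> KeySummary:
    """Per-rule-index cell tallies and the matrix-wide maximum cell count.

    Indices with zero cells are reported as 0 when ``rules`` supplies the
    index universe.
    """
    per_idx: dict[int, int] = {r.idx: 0 for r in rules} if rules else {}
    for cell in cells:
        per_idx[cell.idx] = per_idx.get(cell.idx, 0) + 1
    max_count = int(matrix.count.max()) if matrix.count.size else 0
    return KeySummary(per_idx=per_idx, max_cell_count=max_count)
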