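"""Two-panel figure rendering.

The left panel is the transposed association heatmap: genome bins run
down the vertical axis (chromosome 1 at the top), significance bins run
along the horizontal -log10(p) axis.  Non-significant cells are shaded
in alternating dark/light grey by chromosome parity; significant cells
take the matched rule's colour and, where the rule asks for reporting, a
numbered bubble.  The right panel carries either a tabular summary of
the loci of interest (up to a configurable capacity, default 130) or
repelled gene-name labels, plus an auto-generated key.  Output is vector
PDF or high-resolution TIFF.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from matplotlib.figure import Figure
from matplotlib.patches import Rectangle

from .binning import CountMatrix, GenomeLayout
from .classify import ClassifiedCell, KeySummary, SignificanceBoundary
from .errors import CapacityError, RenderError
from .io_formats import CellConfig, GlobalOptions, LocusAnnotation, resolve_colour

log = logging.getLogger(__name__)

DARK_GREY = (0.30, 0.30, 0.30, 1.0)  # odd chromosomes (1, 3, ...)
LIGHT_GREY = (0.72, 0.72, 0.72, 1.0)  # even chromosomes


@dataclass(frozen=True)
class PageSettings:
    """Output page geometry: portrait A4 by default, 300 dpi for TIFF."""

    width_in: float = 8.27
    height_in: float = 11.69
    dpi: int = 300


@dataclass
class PlotSpec:
    """Everything the renderer needs, already computed and validated."""

    layout: GenomeLayout
    matrix: CountMatrix
    cells: Sequence[ClassifiedCell]
    boundary: SignificanceBoundary
    key: KeySummary
    rules: Sequence[CellConfig]
    loci: Sequence[LocusAnnotation]
    mode: str = "table"  # "table" | "labels"
    options: GlobalOptions = field(default_factory=GlobalOptions)
    page: PageSettings = field(default_factory=PageSettings)


def resolve_cell_style(
    cell: ClassifiedCell, rules: Sequence[CellConfig], chrom_parity: str
) -> tuple[tuple[float, float, float, float], str | None]:
    """Colour (RGBA) and bubble glyph for one classified cell.

    Non-significant cells are grey by chromosome parity ("odd" -> dark,
    "even" -> light); significant cells take the matched rule's colour;
    bubble cells additionally carry the rule index as glyph text.
    """
    if not cell.significant:
        return (DARK_GREY if chrom_parity == "odd" else LIGHT_GREY), None
    rule = next(r for r in rules if r.idx == cell.idx)
    glyph = str(rule.idx) if cell.bubble else None
    return resolve_colour(rule.colour), glyph


# ---------------------------------------------------------------------------
# label layout


@dataclass
class LabelBox:
    """A text label: anchor point, measured extent, and final position."""

    text: str
    anchor: tuple[float, float]
    width: float
    height: float
    placed: tuple[float, float] | None = None


def boxes_overlap(a: LabelBox, b: LabelBox, pad: float = 0.0) -> bool:
    ax, ay = a.placed if a.placed else a.anchor
    bx, by = b.placed if b.placed else b.anchor
    return abs(ax - bx) < (a.width + b.width) / 2 + pad - 1e-12 and abs(ay - by) < (
        a.height + b.height
    ) / 2 + pad - 1e-12


def layout_labels(
    labels: Sequence[LabelBox],
    seed: int = 0,
    *,
    max_displacement: float | None = None,
    pad: float = 0.0,
) -> list[LabelBox]:
    """Repel overlapping labels until no two extents intersect.

    A short force phase pushes overlapping boxes apart vertically; a
    deterministic sweep then resolves every remaining conflict exactly by
    moving each label to the nearest free vertical slot, so the result is
    guaranteed overlap-free and identical for identical seeds.  Labels
    displaced beyond ``max_displacement`` trigger a warning (best-effort
    layout, never an exception).
    """
    out = [replace(b, placed=b.placed or b.anchor) for b in labels]
    n = len(out)
    if n == 0:
        return out
    rng = np.random.default_rng(seed)
    # jitter exactly coincident anchors so the force phase has a direction
    seen: dict[tuple[float, float], int] = {}
    for b in out:
        key = (round(b.placed[0], 9), round(b.placed[1], 9))
        if key in seen:
            dx = float(rng.uniform(-0.25, 0.25)) * b.width
            dy = float(rng.uniform(0.3, 0.8)) * b.height * (1 + seen[key])
            b.placed = (b.placed[0] + dx, b.placed[1] + dy)
            seen[key] += 1
        else:
            seen[key] = 0

    for _ in range(40):
        moved = False
        for i in range(n):
            for j in range(i + 1, n):
                a, b = out[i], out[j]
                if boxes_overlap(a, b, pad):
                    need = (a.height + b.height) / 2 + pad
                    dy = b.placed[1] - a.placed[1]
                    sign = 1.0 if dy >= 0 else -1.0
                    push = (need - abs(dy)) / 2 + 1e-6
                    a.placed = (a.placed[0], a.placed[1] - sign * push)
                    b.placed = (b.placed[0], b.placed[1] + sign * push)
                    moved = True
        if not moved:
            break

    # exact resolution sweep: nearest free vertical slot per label
    order = sorted(range(n), key=lambda i: (out[i].anchor[1], out[i].anchor[0], out[i].text))
    placed_idx: list[int] = []
    warned = False
    for i in order:
        b = out[i]
        x, y0 = b.placed
        forbidden: list[tuple[float, float]] = []
        for j in placed_idx:
            o = out[j]
            if abs(o.placed[0] - x) < (o.width + b.width) / 2 + pad - 1e-12:
                half = (o.height + b.height) / 2 + pad
                forbidden.append((o.placed[1] - half, o.placed[1] + half))
        y = _nearest_free(y0, forbidden)
        b.placed = (x, y)
        placed_idx.append(i)
        if max_displacement is not None and not warned:
            disp = math.hypot(b.placed[0] - b.anchor[0], b.placed[1] - b.anchor[1])
            if disp > max_displacement:
                log.warning(
                    "label %r displaced %.3g beyond the configured maximum %.3g "
                    "(best-effort layout)",
                    b.text,
                    disp,
                    max_displacement,
                )
                warned = True
    return out


def _nearest_free(y0: float, forbidden: list[tuple[float, float]]) -> float:
    """Nearest y not strictly inside any (merged) forbidden open interval."""
    if not forbidden:
        return y0
    ivs = sorted(forbidden)
    merged: list[list[float]] = [list(ivs[0])]
    for lo, hi in ivs[1:]:
        if lo < merged[-1][1] - 1e-12:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    for lo, hi in merged:
        if lo + 1e-12 < y0 < hi - 1e-12:
            # inside a blocked run: snap to the closer edge
            return lo if (y0 - lo) <= (hi - y0) else hi
    return y0


# ---------------------------------------------------------------------------
# key


@dataclass(frozen=True)
class KeyRow:
    """One legend entry: rule index, swatch colour, count range covered by
    the tier, flag description, and the per-index cell counter."""

    idx: int
    colour: str
    count_range: str
    annotation: str
    n_cells: int


def render_key(key: KeySummary, rules: Sequence[CellConfig]) -> list[KeyRow]:
    """Legend content: one row per rule, with the count tier printed as a
    range whose top value is the matrix-wide maximum cell count."""
    tiers = sorted({r.min_count for r in rules})
    rows: list[KeyRow] = []
    for r in sorted(rules, key=lambda r: r.idx):
        nxt = next((t for t in tiers if t > r.min_count), None)
        upper = (nxt - 1) if nxt is not None else max(key.max_cell_count, r.min_count)
        count_range = str(r.min_count) if upper <= r.min_count else f"{r.min_count}-{upper}"
        if r.maf_flag and r.conseq_flag:
            annotation = "low MAF + high impact"
        elif r.maf_flag:
            annotation = "low MAF"
        elif r.conseq_flag:
            annotation = "high impact"
        else:
            annotation = "-"
        rows.append(
            KeyRow(
                idx=r.idx,
                colour=r.colour,
                count_range=count_range,
                annotation=annotation,
                n_cells=key.per_idx.get(r.idx, 0),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# figure


def _heatmap_image(spec: PlotSpec) -> np.ndarray:
    """RGBA raster of the matrix; empty cells stay transparent."""
    img = np.zeros((spec.matrix.n_rows, spec.matrix.n_cols, 4), dtype=np.float64)
    chrom_of_row = spec.layout.row_chrom_index()
    for cell in spec.cells:
        parity = "odd" if chrom_of_row[cell.row] % 2 == 0 else "even"
        colour, _ = resolve_cell_style(cell, spec.rules, parity)
        img[cell.row, cell.col] = colour
    return img


def _draw_heatmap(ax, spec: PlotSpec) -> None:
    pbin = spec.matrix.pbin
    x_max = spec.matrix.n_cols * pbin
    img = _heatmap_image(spec)
    ax.imshow(
        img,
        origin="upper",
        aspect="auto",
        interpolation="nearest",
        extent=(0.0, x_max, spec.matrix.n_rows, 0.0),
        zorder=1,
    )
    ax.set_xlim(0.0, x_max)
    ax.set_ylim(spec.matrix.n_rows, 0.0)
    ax.set_xlabel(r"$-\log_{10}(p)$", fontsize=7)
    ticks, tick_labels = [], []
    for c in spec.layout.chrom_order:
        start = spec.layout.row_offset[c]
        ticks.append(start + spec.layout.n_bins(c) / 2)
        tick_labels.append(c)
    ax.set_yticks(ticks)
    ax.set_yticklabels(tick_labels, fontsize=5)
    ax.set_ylabel("chromosome", fontsize=7)
    ax.tick_params(axis="x", labelsize=6)
    if spec.boundary.nlp_star is not None:
        ax.axvline(
            min(spec.boundary.nlp_star, spec.matrix.cap_nlp),
            linestyle="--",
            linewidth=0.6,
            color="0.25",
            zorder=3,
        )
    for cell in spec.cells:
        if cell.bubble:
            x = (cell.col + 0.5) * pbin
            y = cell.row + 0.5
            ax.scatter(
                [x], [y], s=48, facecolors="white", edgecolors="black",
                linewidths=0.5, zorder=4, alpha=0.85,
            )
            ax.text(x, y, str(cell.idx), fontsize=3.5, ha="center", va="center", zorder=5)


def _draw_table(ax, loci: Sequence[LocusAnnotation]) -> None:
    ax.axis("off")
    if not loci:
        return
    header = ["variant", "gene", "OR", "EAF", "p-value", "novelty"]
    rows = [
        [l.name, l.gene, f"{l.odds_ratio:.2f}", f"{l.eaf:.2f}", f"{l.pvalue:.2e}", l.novelty]
        for l in loci
    ]
    table = ax.table(cellText=rows, colLabels=header, loc="center", bbox=[0.0, 0.0, 1.0, 1.0])
    table.auto_set_font_size(False)
    n = len(rows)
    fs = 6 if n <= 40 else (4 if n <= 90 else 3)
    table.set_fontsize(fs)
    for cell in table.get_celld().values():
        cell.set_linewidth(0.2)


def _draw_labels(ax, spec: PlotSpec, fig: Figure, seed: int) -> None:
    """Repelled gene-name labels drawn on the heatmap axes."""
    pbin = spec.matrix.pbin
    cap = spec.matrix.cap_nlp
    fontsize = 4.0
    bbox = ax.get_position()
    ax_w_in = bbox.width * fig.get_figwidth()
    ax_h_in = bbox.height * fig.get_figheight()
    x_upp = (spec.matrix.n_cols * pbin) / (ax_w_in * 72.0)  # x data units per point
    y_upp = spec.matrix.n_rows / (ax_h_in * 72.0)
    labels: list[LabelBox] = []
    for locus in spec.loci:
        if locus.chrom not in spec.layout.row_offset:
            log.warning("locus %s on unknown chromosome %s; label skipped", locus.name, locus.chrom)
            continue
        row = spec.layout.row_offset[locus.chrom] + (locus.pos - 1) // spec.layout.chunk_bp
        nlp = min(-math.log10(locus.pvalue), cap) if locus.pvalue > 0 else cap
        text = locus.gene or locus.name
        labels.append(
            LabelBox(
                text=text,
                anchor=(nlp, row + 0.5),
                width=(0.62 * fontsize * max(len(text), 1) + 4) * x_upp,
                height=1.6 * fontsize * y_upp,
            )
        )
    placed = layout_labels(labels, seed=seed, pad=0.3 * fontsize * y_upp)
    for b in placed:
        if math.hypot(b.placed[0] - b.anchor[0], b.placed[1] - b.anchor[1]) > max(b.width, b.height):
            ax.plot(
                [b.anchor[0], b.placed[0]], [b.anchor[1], b.placed[1]],
                linewidth=0.3, color="0.35", zorder=6,
            )
        ax.text(
            b.placed[0], b.placed[1], b.text,
            fontsize=fontsize, ha="center", va="center", zorder=7,
            bbox=dict(boxstyle="round,pad=0.15", facecolor="white", edgecolor="0.4", linewidth=0.3),
        )


def _draw_key(ax, key_rows: Sequence[KeyRow]) -> None:
    ax.axis("off")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    n = len(key_rows)
    if n == 0:
        return
    ax.text(0.0, 1.0, "Key", fontsize=7, va="top", fontweight="bold")
    row_h = 0.9 / max(n, 1)
    for i, kr in enumerate(key_rows):
        y = 0.92 - (i + 0.5) * row_h
        ax.add_patch(
            Rectangle(
                (0.0, y - 0.3 * row_h), 0.05, 0.6 * row_h,
                facecolor=resolve_colour(kr.colour), edgecolor="black", linewidth=0.3,
            )
        )
        ax.text(0.08, y, str(kr.idx), fontsize=5, va="center")
        ax.text(0.16, y, kr.count_range, fontsize=5, va="center")
        ax.text(0.40, y, kr.annotation, fontsize=5, va="center")
        ax.text(0.88, y, str(kr.n_cells), fontsize=5, va="center", ha="right")


def render_figure(
    spec: PlotSpec,
    out_path: str | Path,
    *,
    fmt: str | None = None,
    auto_mode: bool = False,
    seed: int = 0,
) -> Path:
    """Render and save the two-panel figure.

    Table mode with more loci than ``options.table_capacity`` raises
    :class:`CapacityError` naming label mode, unless ``auto_mode`` is set
    in which case the renderer switches to labels with a warning.
    """
    out_path = Path(out_path)
    mode = spec.mode
    capacity = spec.options.table_capacity
    if mode == "table" and len(spec.loci) > capacity:
        if auto_mode:
            log.warning(
                "%d loci exceed the table capacity (%d); switching to label mode",
                len(spec.loci),
                capacity,
            )
            mode = "labels"
        else:
            raise CapacityError(
                f"{len(spec.loci)} loci exceed the annotation-table capacity ({capacity}); "
                f"use label mode (annotation_mode=labels) or raise table_capacity"
            )
    fig = Figure(figsize=(spec.page.width_in, spec.page.height_in))
    heat_ax = fig.add_axes([0.07, 0.05, 0.50, 0.92])
    right_ax = fig.add_axes([0.62, 0.32, 0.36, 0.64])
    key_ax = fig.add_axes([0.62, 0.04, 0.36, 0.24])

    _draw_heatmap(heat_ax, spec)
    if mode == "table":
        _draw_table(right_ax, spec.loci)
    else:
        right_ax.axis("off")
        _draw_labels(heat_ax, spec, fig, seed)
    _draw_key(key_ax, render_key(spec.key, spec.rules))

    fmt = (fmt or out_path.suffix.lstrip(".") or spec.options.output_format).lower()
    if fmt == "tif":
        fmt = "tiff"
    if fmt not in ("pdf", "tiff"):
        raise RenderError(f"unsupported output format {fmt!r} (pdf or tiff)")
    try:
        if fmt == "pdf":
            # drop the timestamp so identical specs give identical bytes
            fig.savefig(out_path, format="pdf", metadata={"CreationDate": None})
        else:
            fig.savefig(out_path, format="tiff", dpi=spec.page.dpi)
    except OSError as exc:
        raise RenderError(f"cannot write figure to {out_path}: {exc}")
    return out_path
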