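"""Readers and writers for the three delimited text inputs.

The tool consumes (1) a genome-wide summary-statistics table, (2) a
loci-of-interest table used for the annotation panel, and (3) a
configuration file holding the cell-classification rules and global
parameters.  All three are plain delimited text; the summary statistics
may additionally be gzip-compressed.  Column headers in the summary and
loci tables are matched case-insensitively against a synonym list so
files from different association pipelines load without renaming.
"""

from __future__ import annotations

import csv
import gzip
import logging
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import IO, Iterator, Mapping, Sequence

import matplotlib.colors as mcolors

from .errors import ConfigurationError, InputError, ValidationError

log = logging.getLogger(__name__)

SUMMARY_COLUMNS = ("name", "chrom", "pos", "pvalue", "maf", "consequence")
LOCI_COLUMNS = ("name", "chrom", "pos", "eaf", "odds_ratio", "pvalue", "novelty", "gene")
CONFIG_COLUMNS = ("idx", "min_count", "maf", "conseq", "colour", "report")

#: case-insensitive header synonyms accepted without an explicit column_map
SUMMARY_SYNONYMS: dict[str, frozenset[str]] = {
    "name": frozenset({"name", "snp", "rsid", "variant", "variant_id", "markername", "snpid", "id"}),
    "chrom": frozenset({"chrom", "chr", "chromosome", "#chrom", "#chr"}),
    "pos": frozenset({"pos", "bp", "position", "base_pair_location", "pos_bp"}),
    "pvalue": frozenset({"pvalue", "p", "pval", "p_value", "p-value", "p.value"}),
    "maf": frozenset({"maf", "minor_allele_frequency", "freq", "af", "allele_frequency", "frq"}),
    "consequence": frozenset(
        {"consequence", "conseq", "annotation", "func", "most_severe_consequence", "effect"}
    ),
}

LOCI_SYNONYMS: dict[str, frozenset[str]] = {
    "name": frozenset({"name", "snp", "rsid", "variant", "variant_id", "markername", "sentinel"}),
    "chrom": frozenset({"chrom", "chr", "chromosome"}),
    "pos": frozenset({"pos", "bp", "position"}),
    "eaf": frozenset({"eaf", "effect_allele_frequency", "freq", "af"}),
    "odds_ratio": frozenset({"odds_ratio", "or", "oddsratio"}),
    "pvalue": frozenset({"pvalue", "p", "pval", "p_value", "p-value"}),
    "novelty": frozenset({"novelty", "novel", "novel_known", "status"}),
    "gene": frozenset({"gene", "gene_name", "genename", "symbol", "nearest_gene"}),
}


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One summary-statistics row: a variant with its association result."""

    name: str
    chrom: str
    pos: int
    pvalue: float
    maf: float
    consequence: str


@dataclass(frozen=True, slots=True)
class LocusAnnotation:
    """One loci-of-interest row (sentinel variant) for the annotation panel."""

    name: str
    chrom: str
    pos: int
    eaf: float
    odds_ratio: float
    pvalue: float
    novelty: str  # "novel" or "known", normalised to lower case
    gene: str


@dataclass(frozen=True, slots=True)
class CellConfig:
    """One classification rule: which cells it matches and how to draw them.

    ``min_count`` is the lower edge of the rule's count tier; ``maf_flag``
    / ``conseq_flag`` say whether the cell must contain at least one
    low-MAF / high-impact variant; ``report`` asks for a numbered bubble
    when the cell is significant.
    """

    idx: int
    min_count: int
    maf_flag: bool
    conseq_flag: bool
    colour: str
    report: bool


def _default_high_impact_terms() -> frozenset[str]:
    text = resources.files("gwasgrid.resources").joinpath("high_impact_terms.txt").read_text()
    terms = [ln.strip().lower() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return frozenset(terms)


@dataclass(frozen=True)
class GlobalOptions:
    """Global plotting/binning parameters (the key=value block of the config).

    chunk_bp
        genome bin width in base pairs (default 3 Mbp).
    pbin
        significance bin width in -log10(p) units (default 0.125).
    cap_nlp
        -log10(p) ceiling; smaller p-values are assigned the capped value
        so extreme signals stay on the page (default 20, i.e. p = 1e-20).
    maf_threshold
        minor-allele-frequency cutoff below which a variant is flagged as
        low frequency (default 0.05).
    fdr_q
        Benjamini-Hochberg false-discovery-rate level for the significance
        boundary (default 0.05).
    threshold_nlp
        optional fixed -log10(p) significance cut used instead of FDR.
    """

    chunk_bp: int = 3_000_000
    pbin: float = 0.125
    cap_nlp: float = 20.0
    maf_threshold: float = 0.05
    fdr_q: float = 0.05
    threshold_nlp: float | None = None
    high_impact_terms: frozenset[str] = field(default_factory=_default_high_impact_terms)
    annotation_mode: str = "table"  # "table" | "labels"
    output_format: str = "pdf"  # "pdf" | "tiff"
    table_capacity: int = 130

    def __post_init__(self) -> None:
        if self.chunk_bp < 1:
            raise ConfigurationError(f"chunk_bp must be >= 1, got {self.chunk_bp}")
        if self.pbin <= 0:
            raise ConfigurationError(f"pbin must be > 0, got {self.pbin}")
        if self.cap_nlp <= 0:
            raise ConfigurationError(f"cap_nlp must be > 0, got {self.cap_nlp}")
        if not 0 < self.fdr_q < 1:
            raise ConfigurationError(f"fdr_q must be in (0,1), got {self.fdr_q}")
        if not 0 < self.maf_threshold < 0.5:
            raise ConfigurationError(f"maf_threshold must be in (0,0.5), got {self.maf_threshold}")
        if self.annotation_mode not in ("table", "labels"):
            raise ConfigurationError(f"annotation_mode must be 'table' or 'labels', got {self.annotation_mode!r}")
        if self.output_format not in ("pdf", "tiff"):
            raise ConfigurationError(f"output_format must be 'pdf' or 'tiff', got {self.output_format!r}")


#: the shipped default classification scheme: 8 rules over two count tiers
#: ({1} and {>= 2}) crossed with the low-MAF and high-impact flags.
DEFAULT_RULES: tuple[CellConfig, ...] = (
    CellConfig(1, 1, False, False, "black", False),
    CellConfig(2, 1, False, True, "light pink", True),
    CellConfig(3, 1, True, False, "green", False),
    CellConfig(4, 1, True, True, "dark magenta", True),
    CellConfig(5, 2, False, False, "blue", False),
    CellConfig(6, 2, False, True, "pink", True),
    CellConfig(7, 2, True, False, "red", False),
    CellConfig(8, 2, True, True, "cyan", True),
)


@dataclass
class ReadStats:
    """Row bookkeeping for a streamed read (conservation invariant:
    accepted + skipped == total_rows)."""

    total_rows: int = 0
    accepted: int = 0
    skipped: int = 0


# ---------------------------------------------------------------------------
# low-level helpers


def _open_text(path: str | Path) -> IO[str]:
    """Open plain or gzip text transparently (sniffs the gzip magic bytes)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file does not exist: {path}")
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt", encoding="utf-8", newline="")
    return open(path, "rt", encoding="utf-8", newline="")


def _detect_delimiter(header_line: str) -> str:
    """Tab vs comma, decided from the header line; tab wins a tie."""
    if header_line.count("\t") >= header_line.count(","):
        return "\t" if "\t" in header_line else ("," if "," in header_line else "\t")
    return ","


def _map_header(
    header: Sequence[str],
    required: Sequence[str],
    synonyms: Mapping[str, frozenset[str]],
    column_map: Mapping[str, str] | None,
    path: str | Path,
) -> dict[str, int]:
    """Resolve each required field to a header column index.

    An explicit ``column_map`` entry takes precedence; otherwise the
    synonym list is searched case-insensitively.
    """
    lower = [h.strip().lower() for h in header]
    out: dict[str, int] = {}
    missing: list[str] = []
    for fieldname in required:
        target = None
        if column_map and fieldname in column_map:
            target = column_map[fieldname].strip().lower()
            if target in lower:
                out[fieldname] = lower.index(target)
                continue
            missing.append(fieldname)
            continue
        for i, h in enumerate(lower):
            if h in synonyms[fieldname]:
                target = h
                out[fieldname] = i
                break
        if target is None:
            missing.append(fieldname)
    if missing:
        raise ConfigurationError(
            f"{path}: required column(s) not found in header: {', '.join(missing)}; "
            f"header was {list(header)!r}. Provide a column_map entry for each."
        )
    return out


def _fold_maf(value: float) -> float:
    """Fold an allele frequency > 0.5 to the minor allele (1 - value)."""
    if value > 0.5:
        return 1.0 - value
    return value


# ---------------------------------------------------------------------------
# summary statistics


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    strict: bool = False,
    stats: ReadStats | None = None,
) -> Iterator[VariantRecord]:
    """Stream :class:`VariantRecord` rows from a summary-statistics file.

    Rows with unparsable numeric fields (``NA`` p-values and the like) are
    skipped with a logged warning unless ``strict`` is set, in which case
    the first such row raises :class:`ValidationError`.  MAF values above
    0.5 are folded to ``1 - value`` (allele frequency vs minor-allele
    frequency confusion is common in real files).  Pass a
    :class:`ReadStats` to recover the accepted/skipped row counts.
    """
    if stats is None:
        stats = ReadStats()
    with _open_text(path) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise InputError(f"{path}: empty file (no header line)")
        delim = _detect_delimiter(header_line)
        header = next(csv.reader([header_line], delimiter=delim))
        colmap = _map_header(header, SUMMARY_COLUMNS, SUMMARY_SYNONYMS, column_map, path)
        reader = csv.reader(fh, delimiter=delim)
        i_name = colmap["name"]
        i_chrom = colmap["chrom"]
        i_pos = colmap["pos"]
        i_p = colmap["pvalue"]
        i_maf = colmap["maf"]
        i_csq = colmap["consequence"]
        folded_warned = False
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            stats.total_rows += 1
            try:
                pos = int(row[i_pos])
                pvalue = float(row[i_p])
                maf = float(row[i_maf])
            except (ValueError, IndexError) as exc:
                if strict:
                    raise ValidationError(f"{path}: row {rownum}: unparsable numeric field ({exc})")
                log.warning("%s: row %d skipped: unparsable numeric field", path, rownum)
                stats.skipped += 1
                continue
            if maf > 0.5:
                if maf > 1.0:
                    if strict:
                        raise ValidationError(f"{path}: row {rownum}: MAF {maf} outside [0,1]")
                    log.warning("%s: row %d skipped: MAF %g outside [0,1]", path, rownum, maf)
                    stats.skipped += 1
                    continue
                if not folded_warned:
                    log.warning("%s: allele frequencies > 0.5 folded to minor-allele frequency", path)
                    folded_warned = True
                maf = _fold_maf(maf)
            if pos < 1 or maf < 0 or pvalue < 0 or pvalue > 1:
                if strict:
                    raise ValidationError(f"{path}: row {rownum}: value out of range")
                log.warning("%s: row %d skipped: value out of range", path, rownum)
                stats.skipped += 1
                continue
            stats.accepted += 1
            yield VariantRecord(
                name=row[i_name],
                chrom=row[i_chrom].strip(),
                pos=pos,
                pvalue=pvalue,
                maf=maf,
                consequence=row[i_csq].strip(),
            )


# ---------------------------------------------------------------------------
# loci table


def read_loci_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[LocusAnnotation]:
    """Read the loci-of-interest table, preserving file order.

    Every row is validated: odds ratio must be positive, the p-value in
    (0, 1], the effect-allele frequency in (0, 1) and novelty one of
    ``novel``/``known`` (case-insensitive).  Violations raise
    :class:`ValidationError` citing the row number.
    """
    with _open_text(path) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise InputError(f"{path}: empty file (no header line)")
        delim = _detect_delimiter(header_line)
        header = next(csv.reader([header_line], delimiter=delim))
        colmap = _map_header(header, LOCI_COLUMNS, LOCI_SYNONYMS, column_map, path)
        out: list[LocusAnnotation] = []
        for rownum, row in enumerate(csv.reader(fh, delimiter=delim), start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                pos = int(row[colmap["pos"]])
                eaf = float(row[colmap["eaf"]])
                odds_ratio = float(row[colmap["odds_ratio"]])
                pvalue = float(row[colmap["pvalue"]])
            except (ValueError, IndexError) as exc:
                raise ValidationError(f"{path}: row {rownum}: unparsable field ({exc})")
            novelty = row[colmap["novelty"]].strip().lower()
            if novelty not in ("novel", "known"):
                raise ValidationError(
                    f"{path}: row {rownum}: novelty must be 'novel' or 'known', got {novelty!r}"
                )
            if odds_ratio <= 0:
                raise ValidationError(f"{path}: row {rownum}: odds_ratio must be > 0, got {odds_ratio}")
            if not 0 < pvalue <= 1:
                raise ValidationError(f"{path}: row {rownum}: p-value must be in (0,1], got {pvalue}")
            if not 0 < eaf < 1:
                raise ValidationError(f"{path}: row {rownum}: eaf must be in (0,1), got {eaf}")
            if pos < 1:
                raise ValidationError(f"{path}: row {rownum}: position must be >= 1, got {pos}")
            out.append(
                LocusAnnotation(
                    name=row[colmap["name"]],
                    chrom=row[colmap["chrom"]].strip(),
                    pos=pos,
                    eaf=eaf,
                    odds_ratio=odds_ratio,
                    pvalue=pvalue,
                    novelty=novelty,
                    gene=row[colmap["gene"]].strip(),
                )
            )
    return out


# ---------------------------------------------------------------------------
# configuration


def resolve_colour(name: str) -> tuple[float, float, float, float]:
    """Resolve a colour name ('dark magenta', hex, ...) to RGBA.

    Spaces are stripped so the human-readable names used in configuration
    files ('light pink') match the matplotlib named colours."""
    candidates = (name, name.replace(" ", ""), name.replace(" ", "").lower())
    for cand in candidates:
        try:
            return mcolors.to_rgba(cand)
        except ValueError:
            continue
    raise ConfigurationError(f"unresolvable colour name: {name!r}")


def _parse_bool(s: str, where: str) -> bool:
    v = s.strip().lower()
    if v in ("true", "t", "1", "yes"):
        return True
    if v in ("false", "f", "0", "no"):
        return False
    raise ConfigurationError(f"{where}: expected TRUE/FALSE, got {s!r}")


_OPTION_PARSERS = {
    "chunk_bp": int,
    "pbin": float,
    "cap_nlp": float,
    "maf_threshold": float,
    "fdr_q": float,
    "threshold_nlp": float,
    "annotation_mode": str,
    "output_format": str,
    "table_capacity": int,
    "high_impact_terms": lambda s: frozenset(t.strip().lower() for t in s.split(",") if t.strip()),
}


def validate_rules(rules: Sequence[CellConfig]) -> None:
    """Check the rule set is usable: unique indices, resolvable colours,
    and exhaustive, non-overlapping coverage of (count tier, maf, conseq).

    The count tiers are the distinct ``min_count`` values; every tier must
    be crossed with all four flag combinations exactly once, and the
    lowest tier must start at count 1 so singleton cells classify.
    """
    if not rules:
        raise ConfigurationError("configuration contains no classification rules")
    seen_idx: set[int] = set()
    for r in rules:
        if r.idx in seen_idx:
            raise ConfigurationError(f"duplicate rule idx {r.idx}")
        seen_idx.add(r.idx)
        if r.min_count < 1:
            raise ConfigurationError(f"rule idx {r.idx}: min_count must be >= 1, got {r.min_count}")
        resolve_colour(r.colour)
    tiers = sorted({r.min_count for r in rules})
    if tiers[0] != 1:
        raise ConfigurationError(
            f"no rule tier covers cells with a single variant (smallest min_count is {tiers[0]})"
        )
    combos: dict[tuple[int, bool, bool], int] = {}
    for r in rules:
        key = (r.min_count, r.maf_flag, r.conseq_flag)
        if key in combos:
            raise ConfigurationError(
                f"overlapping rules idx {combos[key]} and idx {r.idx} both cover "
                f"(min_count={key[0]}, maf={key[1]}, conseq={key[2]})"
            )
        combos[key] = r.idx
    missing = [
        (mc, m, c)
        for mc in tiers
        for m in (False, True)
        for c in (False, True)
        if (mc, m, c) not in combos
    ]
    if missing:
        desc = ", ".join(f"(min_count={mc}, maf={m}, conseq={c})" for mc, m, c in missing)
        raise ConfigurationError(f"non-exhaustive rule coverage; uncovered combination(s): {desc}")


def read_config(path: str | Path) -> tuple[list[CellConfig], GlobalOptions]:
    """Parse a configuration file: a delimited rule table followed by an
    ``[options]`` key=value block.  Returns the validated rules and options."""
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    rule_lines: list[str] = []
    option_lines: list[str] = []
    in_options = False
    for ln in lines:
        stripped = ln.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if stripped.lower() == "[options]":
            in_options = True
            continue
        (option_lines if in_options else rule_lines).append(ln)
    if not rule_lines:
        raise ConfigurationError(f"{path}: no rule table found")

    delim = _detect_delimiter(rule_lines[0])
    header = [h.strip().lower() for h in next(csv.reader([rule_lines[0]], delimiter=delim))]
    missing = [c for c in CONFIG_COLUMNS if c not in header]
    if missing:
        raise ConfigurationError(f"{path}: rule table missing column(s): {', '.join(missing)}")
    idxs = {c: header.index(c) for c in CONFIG_COLUMNS}
    rules: list[CellConfig] = []
    for rownum, row in enumerate(csv.reader(rule_lines[1:], delimiter=delim), start=2):
        where = f"{path}: rule row {rownum}"
        try:
            rules.append(
                CellConfig(
                    idx=int(row[idxs["idx"]]),
                    min_count=int(row[idxs["min_count"]]),
                    maf_flag=_parse_bool(row[idxs["maf"]], where),
                    conseq_flag=_parse_bool(row[idxs["conseq"]], where),
                    colour=row[idxs["colour"]].strip(),
                    report=_parse_bool(row[idxs["report"]], where),
                )
            )
        except (ValueError, IndexError) as exc:
            raise ConfigurationError(f"{where}: unparsable rule ({exc})")
    validate_rules(rules)

    kwargs: dict = {}
    for ln in option_lines:
        if "=" not in ln:
            raise ConfigurationError(f"{path}: malformed option line {ln!r} (expected key=value)")
        key, _, value = ln.partition("=")
        key = key.strip().lower()
        if key not in _OPTION_PARSERS:
            raise ConfigurationError(f"{path}: unknown option {key!r}")
        try:
            kwargs[key] = _OPTION_PARSERS[key](value.strip())
        except ValueError as exc:
            raise ConfigurationError(f"{path}: option {key}: {exc}")
    options = GlobalOptions(**kwargs)
    return rules, options


_DEFAULT_CONFIG_TEXT = """\
# Default cell-classification rules and global parameters.
# Rules: two count tiers (1 and >=2) crossed with the low-MAF and
# high-impact flags; report=TRUE rows get a numbered bubble when the
# cell lies beyond the significance boundary.
idx\tmin_count\tmaf\tconseq\tcolour\treport
1\t1\tFALSE\tFALSE\tblack\tFALSE
2\t1\tFALSE\tTRUE\tlight pink\tTRUE
3\t1\tTRUE\tFALSE\tgreen\tFALSE
4\t1\tTRUE\tTRUE\tdark magenta\tTRUE
5\t2\tFALSE\tFALSE\tblue\tFALSE
6\t2\tFALSE\tTRUE\tpink\tTRUE
7\t2\tTRUE\tFALSE\tred\tFALSE
8\t2\tTRUE\tTRUE\tcyan\tTRUE
[options]
chunk_bp=3000000
pbin=0.125
cap_nlp=20
maf_threshold=0.05
fdr_q=0.05
annotation_mode=table
output_format=pdf
table_capacity=130
"""


def write_default_config(path: str | Path) -> Path:
    """Write the shipped default configuration; round-trips through
    :func:`read_config` to the in-memory defaults."""
    path = Path(path)
    try:
        path.write_text(_DEFAULT_CONFIG_TEXT, encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot write configuration to {path}: {exc}")
    return path


def default_config() -> tuple[list[CellConfig], GlobalOptions]:
    """The shipped default rules and options (Table-style 8-rule scheme)."""
    return list(DEFAULT_RULES), GlobalOptions()


def read_lengths_file(path: str | Path) -> dict[str, int]:
    """Read a two-column (chromosome, length-in-bp) delimited file."""
    lengths: dict[str, int] = {}
    with _open_text(path) as fh:
        for rownum, ln in enumerate(fh, start=1):
            stripped = ln.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.replace(",", "\t").split()
            if len(parts) < 2:
                raise ValidationError(f"{path}: row {rownum}: expected 'chrom length'")
            try:
                lengths[parts[0]] = int(parts[1])
            except ValueError:
                raise ValidationError(f"{path}: row {rownum}: length must be an integer")
    if not lengths:
        raise InputError(f"{path}: no chromosome lengths found")
    return lengths
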