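"""Readers and writers for the tabular and sequence formats the pipeline touches.

Tabular files are tab-delimited by default (BioGRID-tab heritage); pass
``dialect="csv"`` to any reader for comma-separated input. Well identifiers
follow the 384-well convention: row letter A-P, column number 1-24, with or
without zero padding ("A1" == "A01").
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Default control siRNA label (fluorescent cyclophilin-B control).
CONTROL_LABEL = "siGLO"

#: Screen arm labels. Controls occupy their own pseudo-arm.
ARMS = ("Group1", "Group1B", "Group2", "Group3", "control")

#: Morphology features reported per segmented cell, in canonical order.
MORPHOLOGY_FEATURES = (
    "cell_area",
    "nuclear_area",
    "cell_elongation",
    "nuclear_elongation",
    "cell_roundness",
    "nuclear_roundness",
)

#: Optional per-cell marker channels.
MARKER_CHANNELS = ("p16", "p21", "brdu")

LAYOUT_COLUMNS = ("plate", "well", "sirna", "dose_nM", "arm", "replicate")
CELL_COLUMNS = ("plate", "well", "cell_index") + MORPHOLOGY_FEATURES

_WELL_RE = re.compile(r"^([A-P])0?([1-9]|1[0-9]|2[0-4])$")

_DNA_RE = re.compile(r"^[ACGTN]+$")


class FormatError(ValueError):
    """Malformed input file."""


def _sep(dialect: str) -> str:
    if dialect in ("tsv", "tab"):
        return "\t"
    if dialect in ("csv", "comma"):
        return ","
    raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")


def normalize_well(well: str) -> str:
    """Canonicalise a 384-well id ('A01' -> 'A1'); raise on out-of-range ids."""
    m = _WELL_RE.match(str(well).strip().upper())
    if not m:
        raise FormatError(
            f"well id {well!r} is not a valid 384-well position (A1-P24)"
        )
    return f"{m.group(1)}{int(m.group(2))}"


# ---------------------------------------------------------------------------
# Plate layout
# ---------------------------------------------------------------------------

def read_plate_map(
    path, dialect: str = "tsv", control_label: str = CONTROL_LABEL
) -> pd.DataFrame:
    """Read a well -> treatment map for a 384-well screen.

    Required columns: plate, well, sirna, dose_nM, arm, replicate. Unknown
    columns are preserved untouched. Every plate must contain at least one
    well whose siRNA equals *control_label*.
    """
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str)
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"plate map {path} lacks required columns: {missing}")
    df["well"] = df["well"].map(normalize_well)
    df["dose_nM"] = pd.to_numeric(df["dose_nM"])
    df["replicate"] = pd.to_numeric(df["replicate"], downcast="integer")
    bad_arms = sorted(set(df["arm"]) - set(ARMS))
    if bad_arms:
        raise FormatError(f"unknown arm labels {bad_arms}; expected one of {ARMS}")
    return validate_layout(df, control_label=control_label)


def validate_layout(
    layout: pd.DataFrame, control_label: str = CONTROL_LABEL
) -> pd.DataFrame:
    """Check well uniqueness and per-plate control presence; return the layout."""
    dup = layout.duplicated(subset=["plate", "well"], keep=False)
    if dup.any():
        offenders = layout.loc[dup, ["plate", "well"]].drop_duplicates()
        pairs = [f"{p}:{w}" for p, w in offenders.itertuples(index=False)]
        raise FormatError(f"duplicate (plate, well) entries: {', '.join(pairs)}")
    for plate, grp in layout.groupby("plate"):
        if not (grp["sirna"] == control_label).any():
            raise FormatError(
                f"plate {plate!r} has no {control_label!r} control wells"
            )
    return layout.reset_index(drop=True)


def write_plate_map(layout: pd.DataFrame, path, dialect: str = "tsv") -> None:
    layout.to_csv(path, sep=_sep(dialect), index=False)


# ---------------------------------------------------------------------------
# Per-cell feature table
# ---------------------------------------------------------------------------

def read_cell_table(path, layout: pd.DataFrame, dialect: str = "tsv") -> pd.DataFrame:
    """Read per-cell morphology/intensity records keyed by (plate, well).

    Rows referencing wells absent from *layout* are dropped with a warning
    reporting how many; a non-numeric morphology value raises with the
    offending line number.
    """
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cell table {path} lacks required columns: {missing}")
    if df.empty:
        warnings.warn(f"cell table {path} contains a header but no rows")
    df["well"] = df["well"].map(normalize_well)
    numeric = [c for c in df.columns if c not in ("plate", "well")]
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
            raise FormatError(
                f"non-numeric value {df.loc[line - 2, col]!r} in column "
                f"{col!r} at line {line} of {path}"
            ) from None
    for col in MORPHOLOGY_FEATURES:
        if not df.empty and not df[col].apply(pd.notna).all():
            raise FormatError(f"missing morphology values in column {col!r}")
    known = set(zip(layout["plate"], layout["well"]))
    in_layout = [pw in known for pw in zip(df["plate"], df["well"])]
    n_reject = len(df) - sum(in_layout)
    if n_reject:
        warnings.warn(
            f"{n_reject} cell rows reference wells absent from the layout; dropped"
        )
    return df.loc[in_layout].reset_index(drop=True)


def write_cell_table(cells: pd.DataFrame, path, dialect: str = "tsv") -> None:
    cells.to_csv(path, sep=_sep(dialect), index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, upper-case sequence) pairs.

    Ids are the first whitespace-delimited header token. Sequences must be
    non-empty and drawn from ACGTN (case-insensitive).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"record {rec.id!r} has an empty sequence")
        if not _DNA_RE.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise FormatError(
                f"record {rec.id!r} contains non-ACGTN characters: {bad}"
            )
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# Interaction edge list
# ---------------------------------------------------------------------------

def read_edge_list(path, dialect: str = "tsv") -> list[frozenset]:
    """Read a two-column gene-pair file into undirected, de-duplicated edges.

    Self-loops are dropped (count reported via warning); "A B" and "B A"
    collapse to one edge. Returns edges sorted for determinism.
    """
    sep = _sep(dialect)
    edges: set[frozenset] = set()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(sep)
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise FormatError(
                    f"line {lineno} of {path} does not have two gene columns"
                )
            a, b = parts[0].strip(), parts[1].strip()
            if a == b:
                n_self += 1
                continue
            edges.add(frozenset((a, b)))
    if n_self:
        warnings.warn(f"dropped {n_self} self-loop edges from {path}")
    return sorted(edges, key=lambda e: tuple(sorted(e)))


def write_edge_list(edges: Iterable[frozenset], path, dialect: str = "tsv") -> None:
    sep = _sep(dialect)
    rows = sorted(tuple(sorted(e)) for e in edges)
    with open(path, "w") as fh:
        for a, b in rows:
            fh.write(f"{a}{sep}{b}\n")


def read_annotation(path, dialect: str = "tsv") -> dict[str, str]:
    """Read a gene -> functional-category table (columns: gene, category)."""
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str)
    if "gene" not in df.columns or "category" not in df.columns:
        raise FormatError(f"annotation {path} needs 'gene' and 'category' columns")
    return dict(zip(df["gene"], df["category"]))


def write_annotation(annotation: dict[str, str], path, dialect: str = "tsv") -> None:
    df = pd.DataFrame(
        sorted(annotation.items()), columns=["gene", "category"]
    )
    df.to_csv(path, sep=_sep(dialect), index=False)


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

def write_expression(expr, path, dialect: str = "tsv") -> None:
    """Write a gene x sample matrix; sample ids follow COND_rep (e.g. DS_2)."""
    expr.values.rename_axis("gene").to_csv(
        path, sep=_sep(dialect), float_format="%.6f"
    )


def read_expression(path, dialect: str = "tsv"):
    """Read a gene x sample matrix whose sample ids encode the condition as
    the token before the first underscore (EP_1, DS_2, R_3, ...)."""
    from .expression import ExpressionMatrix

    df = pd.read_csv(path, sep=_sep(dialect), index_col="gene")
    conditions = pd.Series({c: c.split("_")[0] for c in df.columns})
    bad = sorted(set(conditions) - {"EP", "DS", "R"})
    if bad:
        raise FormatError(f"sample ids with unknown condition prefixes: {bad}")
    return ExpressionMatrix(df, conditions)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def _write_sorted(df: pd.DataFrame, sort_cols: Sequence[str], path, dialect: str):
    out = df.sort_values(list(sort_cols), kind="mergesort").reset_index(drop=True)
    out.to_csv(path, sep=_sep(dialect), index=False, float_format="%.4f")


def write_hit_table(hits: pd.DataFrame, path, dialect: str = "tsv") -> None:
    """Write hit calls: stable column order, siRNA-lexicographic rows, 4 dp."""
    cols = [c for c in ("sirna", "arm") if c in hits.columns]
    cols += [c for c in hits.columns if c not in cols]
    _write_sorted(hits[cols], [c for c in ("sirna", "arm") if c in cols], path, dialect)


def write_zscore_matrix(z: pd.DataFrame, path, dialect: str = "tsv") -> None:
    """Write a siRNA (x arm) by feature Z matrix, deterministically ordered."""
    out = z.reset_index()
    sort_cols = [c for c in ("sirna", "arm") if c in out.columns]
    _write_sorted(out, sort_cols or [out.columns[0]], path, dialect)


def read_zscore_matrix(path, dialect: str = "tsv") -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(dialect))
    idx = [c for c in ("sirna", "arm") if c in df.columns]
    return df.set_index(idx)
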