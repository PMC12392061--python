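"""Reading and writing Cq matrices, sample sheets and mapping tables.

Raw quantification-cycle (Cq) exports use an "Undetermined" sentinel for
reactions that never crossed the fluorescence threshold.  Non-detection is
kept categorical throughout the package (stored as NaN, written back as the
sentinel token) rather than imputed to a ceiling cycle such as 40, so that
detection logic and group means stay exact.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical sentinel token written for non-detected reactions.
NOT_DETECTED_TOKEN = "Undetermined"

#: Tokens recognised as non-detection on input.
DEFAULT_SENTINEL_TOKENS = (NOT_DETECTED_TOKEN, "NA", "")

#: Instrument ceiling: a numeric Cq above this many cycles is not a real
#: quantification and is mapped to non-detection.
CQ_CEILING = 40.0

CELL_TYPES = ("PSC", "NSC", "FPP")
COMPARTMENTS = ("IN", "EV")


class CqIOError(ValueError):
    """Raised on malformed Cq matrices, sample sheets or mapping tables."""


@dataclass
class CqMatrix:
    """Rectangular matrix of Cq values, assays in rows, samples in columns.

    Non-detected cells are NaN.  Every numeric entry satisfies
    ``0 < Cq <= CQ_CEILING``.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise CqIOError(f"duplicate assay ids: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise CqIOError(f"duplicate sample ids: {dups}")
        arr = df.to_numpy(dtype=float, copy=False)
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite <= 0).any():
            raise CqIOError("Cq values must be positive")
        # values above the instrument ceiling are categorical non-detections
        over = arr > CQ_CEILING
        if over.any():
            df = df.mask(pd.DataFrame(over, index=df.index, columns=df.columns))
            object.__setattr__(self, "values", df)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def detected_mask(self, lower_cq: float, upper_cq: float) -> pd.DataFrame:
        """Boolean mask: numeric and within ``[lower_cq, upper_cq]`` (inclusive)."""
        v = self.values
        return v.notna() & (v >= lower_cq) & (v <= upper_cq)

    def equals(self, other: "CqMatrix") -> bool:
        return self.values.equals(other.values)


@dataclass
class SampleSheet:
    """Per-sample annotations: donor, cell type and compartment.

    Groups are the (cell_type, compartment) pairs, labelled ``"PSC:IN"`` etc.
    """

    table: pd.DataFrame  # columns: sample_id, donor, cell_type, compartment
    _by_sample: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_id", "donor", "cell_type", "compartment"}
        missing = required - set(t.columns)
        if missing:
            raise CqIOError(f"sample sheet missing columns: {sorted(missing)}")
        if t["sample_id"].duplicated().any():
            raise CqIOError("duplicate sample_id in sample sheet")
        t = t.copy()
        t["cell_type"] = t["cell_type"].astype(str).str.strip().str.upper()
        t["compartment"] = t["compartment"].astype(str).str.strip().str.upper()
        bad_ct = sorted(set(t["cell_type"]) - set(CELL_TYPES))
        if bad_ct:
            raise CqIOError(f"unknown cell_type values: {bad_ct}")
        bad_cp = sorted(set(t["compartment"]) - set(COMPARTMENTS))
        if bad_cp:
            raise CqIOError(f"unknown compartment values: {bad_cp}")
        object.__setattr__(self, "table", t)
        object.__setattr__(
            self, "_by_sample", t.set_index("sample_id").to_dict("index")
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def group_label(self, sample_id: str) -> str:
        row = self._by_sample[sample_id]
        return f"{row['cell_type']}:{row['compartment']}"

    def group_members(self, group: str) -> list[str]:
        """Samples in a ``"CELLTYPE:COMPARTMENT"`` group, in sheet order."""
        cell_type, compartment = parse_group_label(group)
        t = self.table
        sel = (t["cell_type"] == cell_type) & (t["compartment"] == compartment)
        return list(t.loc[sel, "sample_id"])

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.group_label(s), None)
        return list(seen)

    def validate_against(self, cq: CqMatrix) -> None:
        """Every matrix sample must be annotated (hard error on orphans)."""
        orphans = [s for s in cq.sample_ids if s not in self._by_sample]
        if orphans:
            raise CqIOError(f"samples missing from sample sheet: {orphans}")


def parse_group_label(group: str) -> tuple[str, str]:
    """Split and canonicalize ``"FPP:IN"``-style group labels."""
    try:
        cell_type, compartment = group.split(":")
    except ValueError as exc:
        raise CqIOError(
            f"group label {group!r} is not of the form CELLTYPE:COMPARTMENT"
        ) from exc
    cell_type = cell_type.strip().upper()
    compartment = compartment.strip().upper()
    if cell_type not in CELL_TYPES:
        raise CqIOError(f"unknown cell_type {cell_type!r}")
    if compartment not in COMPARTMENTS:
        raise CqIOError(f"unknown compartment {compartment!r}")
    return cell_type, compartment


def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_cq_matrix(path, sentinel_tokens=DEFAULT_SENTINEL_TOKENS) -> CqMatrix:
    """Read a delimited Cq matrix: first column assay id, one column per sample.

    Tokens in ``sentinel_tokens`` map to non-detection; any other non-numeric
    cell is a hard error naming its row and column.  Delimiter is
    auto-detected from {tab, comma}; ragged rows are rejected.
    """
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if raw.index.hasnans or any(a == "" for a in raw.index):
        raise CqIOError("empty assay id")
    sentinels = set(sentinel_tokens)

    def parse_cell(token: str, assay: str, sample: str) -> float:
        token = token.strip()
        if token in sentinels:
            return np.nan
        try:
            return float(token)
        except ValueError:
            raise CqIOError(
                f"non-numeric Cq {token!r} at assay {assay!r}, sample {sample!r}"
            ) from None

    parsed = pd.DataFrame(
        {
            sample: [parse_cell(v, a, sample) for a, v in col.items()]
            for sample, col in raw.items()
        },
        index=raw.index,
    )
    parsed.index.name = "assay_id"
    return CqMatrix(parsed)


def write_cq_matrix(cq: CqMatrix, path, sep: str = "\t") -> None:
    """Write a Cq matrix; non-detected cells become the canonical sentinel."""
    out = cq.values.astype(object).where(cq.values.notna(), NOT_DETECTED_TOKEN)
    out.index.name = "assay_id"
    out.to_csv(path, sep=sep)


def read_sample_sheet(path) -> SampleSheet:
    """Read a delimited sample sheet with sample_id/donor/cell_type/compartment."""
    sep = _sniff_sep(path)
    table = pd.read_csv(path, sep=sep, dtype=str)
    return SampleSheet(table)


def read_mapping_table(path, columns: tuple[str, str] | None = None) -> pd.DataFrame:
    """Read a two-or-more-column TSV mapping table (miRNA→gene or gene→pathway).

    Duplicate pairs on the first two columns are rejected; empty identifiers
    are rejected.  Extra columns (e.g. an interaction score) are preserved.
    """
    sep = _sniff_sep(path)
    table = pd.read_csv(path, sep=sep, dtype={0: str, 1: str})
    if table.shape[1] < 2:
        raise CqIOError("mapping table needs at least two columns")
    if columns is not None:
        table = table.rename(
            columns=dict(zip(table.columns[:2], columns, strict=False))
        )
    key = table.columns[:2].tolist()
    pairs = table[key].astype(str)
    if pairs.duplicated().any():
        raise CqIOError("duplicate pairs in mapping table")
    if (pairs == "").any().any() or pairs.isna().any().any():
        raise CqIOError("empty identifier in mapping table")
    return table


def cq_matrix_from_arrays(assay_ids, sample_ids, values) -> CqMatrix:
    """Build a :class:`CqMatrix` from plain arrays (NaN = non-detected)."""
    df = pd.DataFrame(np.asarray(values, dtype=float), index=list(assay_ids),
                      columns=list(sample_ids))
    df.index.name = "assay_id"
    return CqMatrix(df)


def round_trip_string(cq: CqMatrix) -> str:
    """Serialize to the TSV dialect (mainly for tests and logs)."""
    buf = _io.StringIO()
    write_cq_matrix(cq, buf)
    return buf.getvalue()
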