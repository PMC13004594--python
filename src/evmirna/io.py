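"""Reading and writing the canonical delimited tables.

The canonical well table is long-format, one qPCR well per row, with columns
``sample_id, assay_id, card, cq, amp_score, cq_conf``.  ``cq`` is the
quantification cycle; an undetermined reaction is stored as NaN in memory and
written back as ``Undetermined``.  The sample sheet maps every sample to a
receptor experiment, a condition (``media_control`` / ``vehicle_control`` /
``agonist``) and, for treated samples, the pair/block id linking one vehicle
replicate to one agonist replicate.

Instrument exports differ in column naming and missing-value spelling, so
:class:`DialectConfig` maps vendor headers onto the canonical schema.  Assay
names are opaque identifiers; no miRBase normalization is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, DuplicateWellError, SchemaError

WELL_COLUMNS = ["sample_id", "assay_id", "card", "cq", "amp_score", "cq_conf"]
SHEET_COLUMNS = ["sample_id", "receptor", "condition", "pair_id", "run_batch"]

CARDS = ("A", "B")
CONDITIONS = ("media_control", "vehicle_control", "agonist")
RECEPTORS = ("ADORA1", "HRH1", "FZD4", "ACKR3", "other")

#: Accepted spellings of a missing / undetermined Cq (case-insensitive).
MISSING_SENTINELS = ("", "undetermined", "na", "nan")


@dataclass
class DialectConfig:
    """Maps a vendor export onto the canonical well-table schema.

    Parameters
    ----------
    column_aliases
        canonical column name -> accepted header spellings (case-insensitive).
        The canonical name itself is always accepted.
    missing_sentinels
        strings (case-insensitive, stripped) treated as a missing Cq.
    decimal
        decimal mark used in the file.
    delimiter
        field delimiter; ``None`` infers ``\\t`` for ``.tsv``/``.tab``
        files and ``,`` otherwise.
    """

    column_aliases: Mapping[str, Sequence[str]] = field(default_factory=dict)
    missing_sentinels: Sequence[str] = MISSING_SENTINELS
    decimal: str = "."
    delimiter: str | None = None


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def _canonicalize_columns(df: pd.DataFrame, required: Sequence[str],
                          dialect: DialectConfig) -> pd.DataFrame:
    lookup: dict[str, str] = {}
    for canonical in required:
        lookup[canonical.lower()] = canonical
        for alias in dialect.column_aliases.get(canonical, ()):
            lookup[alias.lower()] = canonical
    rename = {c: lookup[c.strip().lower()]
              for c in df.columns if c.strip().lower() in lookup}
    df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s): {', '.join(missing)}; "
            f"found columns: {', '.join(map(str, df.columns))}")
    return df


def _parse_numeric(series: pd.Series, sentinels: Iterable[str],
                   decimal: str, what: str) -> pd.Series:
    s = series.astype("string").str.strip()
    sentinel_set = {x.lower() for x in sentinels}
    is_missing = s.isna() | s.str.lower().isin(sentinel_set)
    if decimal != ".":
        s = s.str.replace(decimal, ".", regex=False)
    out = pd.to_numeric(s.mask(is_missing), errors="coerce")
    bad = (~is_missing) & out.isna()
    if bad.any():
        rows = list(series.index[bad][:5])
        raise SchemaError(f"unparseable {what} value(s) at row(s) {rows}")
    return out.astype(float)


def read_well_table(path: str | Path,
                    dialect: DialectConfig | None = None) -> pd.DataFrame:
    """Read a long-format well table into the canonical schema.

    Row order is preserved; ``Undetermined`` / empty Cq become NaN.
    Raises :class:`SchemaError` on missing columns or malformed values and
    :class:`DuplicateWellError` when a (sample, assay) pair repeats.
    """
    path = Path(path)
    dialect = dialect or DialectConfig()
    raw = pd.read_csv(path, sep=_infer_delimiter(path, dialect.delimiter),
                      dtype=str, keep_default_na=False)
    raw = _canonicalize_columns(raw, WELL_COLUMNS, dialect)
    df = pd.DataFrame({
        "sample_id": raw["sample_id"].str.strip(),
        "assay_id": raw["assay_id"].str.strip(),
        "card": raw["card"].str.strip().str.upper(),
        "cq": _parse_numeric(raw["cq"], dialect.missing_sentinels,
                             dialect.decimal, "cq"),
        "amp_score": _parse_numeric(raw["amp_score"], dialect.missing_sentinels,
                                    dialect.decimal, "amp_score"),
        "cq_conf": _parse_numeric(raw["cq_conf"], dialect.missing_sentinels,
                                  dialect.decimal, "cq_conf"),
    })
    bad_card = ~df["card"].isin(CARDS)
    if bad_card.any():
        raise SchemaError(
            f"card must be one of {CARDS}; offending rows: "
            f"{list(df.index[bad_card][:5])}")
    present = df["cq"].notna()
    if (present & (df["cq"] <= 0)).any() or not np.isfinite(
            df.loc[present, "cq"]).all():
        raise SchemaError("cq values must be finite and > 0 when present")
    conf = df["cq_conf"].dropna()
    if ((conf < 0) | (conf > 1)).any():
        raise SchemaError("cq_conf values must lie in [0, 1]")
    dup = df.duplicated(["sample_id", "assay_id"], keep=False)
    if dup.any():
        offenders = (df.loc[dup, ["sample_id", "assay_id"]]
                     .drop_duplicates().itertuples(index=False))
        listing = ", ".join(f"({s}, {a})" for s, a in list(offenders)[:10])
        raise DuplicateWellError(
            f"duplicate (sample_id, assay_id) entries: {listing}")
    return df


def write_well_table(wells: pd.DataFrame, path: str | Path,
                     delimiter: str | None = None) -> None:
    """Write a canonical well table; missing Cq is spelled ``Undetermined``."""
    path = Path(path)
    out = wells[WELL_COLUMNS].copy()
    out["cq"] = out["cq"].map(
        lambda v: "Undetermined" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, sep=_infer_delimiter(path, delimiter), index=False)


def read_sample_sheet(path: str | Path,
                      dialect: DialectConfig | None = None) -> pd.DataFrame:
    """Read and validate a sample sheet.

    Validates the pairing structure: each pair_id occurs exactly once as
    vehicle_control and once as agonist; media_control samples carry none.
    """
    path = Path(path)
    dialect = dialect or DialectConfig()
    raw = pd.read_csv(path, sep=_infer_delimiter(path, dialect.delimiter),
                      dtype=str, keep_default_na=False)
    raw = _canonicalize_columns(raw, SHEET_COLUMNS[:3], dialect)
    for optional in ("pair_id", "run_batch"):
        if optional not in raw.columns:
            raw[optional] = ""
    sheet = pd.DataFrame({
        "sample_id": raw["sample_id"].str.strip(),
        "receptor": raw["receptor"].str.strip(),
        "condition": raw["condition"].str.strip(),
        "pair_id": raw["pair_id"].str.strip().replace("", pd.NA),
        "run_batch": raw["run_batch"].str.strip().replace("", pd.NA),
    })
    return validate_sample_sheet(sheet)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    if sheet["sample_id"].duplicated().any():
        raise SchemaError("duplicate sample_id in sample sheet")
    bad = ~sheet["condition"].isin(CONDITIONS)
    if bad.any():
        raise SchemaError(
            f"unknown condition(s): {sorted(sheet.loc[bad, 'condition'].unique())}")
    mc = sheet["condition"] == "media_control"
    if sheet.loc[mc, "pair_id"].notna().any():
        raise SchemaError("media_control samples must not carry a pair_id")
    for cond in ("vehicle_control", "agonist"):
        sub = sheet[sheet["condition"] == cond]
        if sub["pair_id"].isna().any():
            raise SchemaError(f"{cond} samples must carry a pair_id")
        counts = sub["pair_id"].value_counts()
        if (counts != 1).any():
            raise SchemaError(
                f"pair_id must occur exactly once per condition; offenders in "
                f"{cond}: {sorted(counts.index[counts != 1])}")
    veh = set(sheet.loc[sheet["condition"] == "vehicle_control", "pair_id"])
    ago = set(sheet.loc[sheet["condition"] == "agonist", "pair_id"])
    if veh != ago:
        raise SchemaError(
            f"pair_ids differ between vehicle_control and agonist: "
            f"{sorted(veh ^ ago)}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path,
                       delimiter: str | None = None) -> None:
    path = Path(path)
    sheet[SHEET_COLUMNS].to_csv(path, sep=_infer_delimiter(path, delimiter),
                                index=False)


def pivot_to_matrix(wells: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long well table into an assays x samples Cq matrix.

    Assays are ordered lexicographically; sample columns follow sheet order.
    Cells with no record, or with a missing Cq, are NaN.  Raises
    :class:`ConsistencyError` for samples absent from the sheet.
    """
    unknown = set(wells["sample_id"]) - set(sheet["sample_id"])
    if unknown:
        raise ConsistencyError(
            f"sample(s) in well table absent from sample sheet: "
            f"{sorted(unknown)}")
    assays = sorted(wells["assay_id"].unique())
    samples = list(sheet["sample_id"])
    matrix = pd.DataFrame(np.nan, index=pd.Index(assays, name="assay_id"),
                          columns=pd.Index(samples, name="sample_id"))
    if len(wells):
        pv = wells.pivot(index="assay_id", columns="sample_id", values="cq")
        matrix.update(pv)
    return matrix


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(Path(path))


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), index_col=0)
    df.index.name = "assay_id"
    df.columns.name = "sample_id"
    return df


def results_table(effects: pd.DataFrame,
                  selection: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble the canonical results table with stable column order."""
    out = effects.copy()
    if selection is not None:
        keep = [c for c in ("assay_id", "rank_by_effect", "selected_p02",
                            "selected_fc15", "significant_p05")
                if c in selection.columns]
        out = out.merge(selection[keep], on="assay_id", how="left")
    lead = ["assay_id", "log2_fc", "sd_log2_fc", "n_pairs",
            "p_skillings_mack"]
    alt = sorted(c for c in out.columns if c.startswith("p_")
                 and c not in lead)
    tail = [c for c in ("rank_by_effect", "selected_p02", "selected_fc15",
                        "significant_p05") if c in out.columns]
    rest = [c for c in out.columns if c not in lead + alt + tail]
    return out[[c for c in lead if c in out.columns] + alt + rest + tail]


def write_results(effects: pd.DataFrame, selection: pd.DataFrame | None,
                  path: str | Path, delimiter: str | None = None) -> None:
    """Write the merged effects/selection table as delimited text."""
    path = Path(path)
    results_table(effects, selection).to_csv(
        path, sep=_infer_delimiter(path, delimiter), index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
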