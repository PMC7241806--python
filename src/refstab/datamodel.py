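"""Core data types and delimited-text I/O for quantification-cycle (Cq) data.

The package works on long ("tidy") tables, one qPCR well per row, as exported
by plate readers after manual annotation:

    sample,group,plate,run,gene,replicate,cq
    S1,control,P1,R1,ACTB,1,19.8

Three tabular artefacts flow through an analysis:

* **replicate table** -- raw well-level Cq measurements with sample, treatment
  group, plate, run and gene metadata (one row per well);
* **Cq table** -- per (sample, gene) aggregated mean Cq with QC flags;
* **efficiency table** -- per (gene, plate) amplification efficiency ``E``
  (amplification factor per cycle, in (1, 2]), optional quantification
  threshold ``nq`` and optional plate correction factor ``factor``.

Relative quantities live in :class:`RQMatrix`, a thin wrapper around a
samples x genes :class:`pandas.DataFrame` carrying group/plate metadata and
provenance flags.

Missing Cq values are represented as NaN and are never silently dropped or
replaced by a sentinel cycle number; downstream modules decide how to treat
them (the mixed-model stability measure tolerates randomly missing data).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "REPLICATE_COLUMNS",
    "EFFICIENCY_COLUMNS",
    "QC_FLAGS",
    "RQMatrix",
    "read_replicate_table",
    "write_replicate_table",
    "validate_replicate_table",
    "read_efficiency_table",
    "validate_efficiency_table",
    "to_jsonable",
    "write_json",
]

#: Required columns of a replicate (well-level) table.
REPLICATE_COLUMNS = ("sample", "group", "plate", "run", "gene", "replicate", "cq")

#: Columns of an efficiency table; ``nq`` and ``factor`` are optional.
EFFICIENCY_COLUMNS = ("gene", "plate", "efficiency")

#: QC outcome per (sample, gene) after replicate aggregation.
QC_FLAGS = ("pass", "spread_exceeded", "missing_replicate", "above_max_cq")


class ValidationError(ValueError):
    """Raised when an input table violates the data-model contract."""


# ---------------------------------------------------------------------------
# replicate tables
# ---------------------------------------------------------------------------

def read_replicate_table(
    path: str | Path,
    sep: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate a long-format replicate table.

    Parameters
    ----------
    path
        Delimited text file (comma or tab; UTF-8) with a header row.
    sep
        Field delimiter; ``None`` sniffs comma vs tab.
    column_map
        Optional mapping from the file's column names to the canonical names
        in :data:`REPLICATE_COLUMNS` (e.g. ``{"Sample Name": "sample"}``).

    Returns
    -------
    pandas.DataFrame
        Validated table with columns :data:`REPLICATE_COLUMNS`.  Empty Cq
        cells are preserved as NaN.

    Raises
    ------
    ValidationError
        On missing columns, duplicate (run, sample, gene, replicate) keys, or
        non-numeric Cq values (reported with row numbers).
    """
    df = pd.read_csv(path, sep=sep, engine="python", dtype=object, skipinitialspace=True)
    if column_map:
        df = df.rename(columns=dict(column_map))
    return validate_replicate_table(df, source=str(path))


def validate_replicate_table(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    """Validate a raw replicate table and coerce column dtypes.

    Validation is total: every malformed input yields a
    :class:`ValidationError` naming the offending rows or keys, never a
    silently coerced value.
    """
    missing = [c for c in REPLICATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{source}: missing required column(s) {missing}; "
            f"expected {list(REPLICATE_COLUMNS)} (use column_map to rename)"
        )
    out = df.loc[:, list(REPLICATE_COLUMNS)].copy()
    for col in ("sample", "group", "plate", "run", "gene"):
        out[col] = out[col].astype(str).str.strip()

    out["replicate"] = _numeric_column(out["replicate"], "replicate", source, allow_missing=False)
    if (out["replicate"] <= 0).any() or (out["replicate"] % 1 != 0).any():
        bad = out.index[(out["replicate"] <= 0) | (out["replicate"] % 1 != 0)].tolist()
        raise ValidationError(f"{source}: replicate must be a positive integer (rows {bad})")
    out["replicate"] = out["replicate"].astype(int)

    out["cq"] = _numeric_column(out["cq"], "cq", source, allow_missing=True)
    bad_cq = out["cq"].notna() & ((out["cq"] <= 0) | ~np.isfinite(out["cq"]))
    if bad_cq.any():
        raise ValidationError(
            f"{source}: cq must be finite and > 0 when present (rows {out.index[bad_cq].tolist()})"
        )

    keys = out[["run", "sample", "gene", "replicate"]]
    dup = keys.duplicated(keep=False)
    if dup.any():
        offending = keys[dup].drop_duplicates().apply(tuple, axis=1).tolist()
        raise ValidationError(
            f"{source}: duplicate (run, sample, gene, replicate) key(s): {offending}"
        )
    return out.reset_index(drop=True)


def _numeric_column(col: pd.Series, name: str, source: str, allow_missing: bool) -> pd.Series:
    raw = col.astype(object)
    blank = raw.isna() | (raw.astype(str).str.strip() == "")
    converted = pd.to_numeric(raw.where(~blank), errors="coerce")
    bad = converted.isna() & ~blank
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # 1-based + header
        raise ValidationError(f"{source}: non-numeric {name} value(s) at file row(s) {rows}")
    if not allow_missing and blank.any():
        rows = (np.flatnonzero(blank.to_numpy()) + 2).tolist()
        raise ValidationError(f"{source}: missing {name} value(s) at file row(s) {rows}")
    return converted.astype(float)


def write_replicate_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a replicate table as CSV (Cq to 6 decimals, labels verbatim)."""
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# efficiency tables
# ---------------------------------------------------------------------------

def read_efficiency_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a per-(gene, plate) amplification-efficiency table.

    Required columns: ``gene``, ``plate``, ``efficiency``; optional columns
    ``nq`` (quantification-threshold fluorescence, > 0) and ``factor``
    (plate correction factor, > 0).
    """
    df = pd.read_csv(path, sep=sep, engine="python", skipinitialspace=True)
    return validate_efficiency_table(df, source=str(path))


def validate_efficiency_table(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    missing = [c for c in EFFICIENCY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{source}: missing required column(s) {missing}")
    out = df.copy()
    out["gene"] = out["gene"].astype(str).str.strip()
    out["plate"] = out["plate"].astype(str).str.strip()
    out["efficiency"] = pd.to_numeric(out["efficiency"], errors="raise").astype(float)
    e = out["efficiency"]
    bad = (e <= 1.0) | (e > 2.0) | ~np.isfinite(e)
    if bad.any():
        raise ValidationError(
            f"{source}: efficiency must lie in (1, 2] (amplification factor per cycle); "
            f"offending rows: {out.loc[bad, ['gene', 'plate', 'efficiency']].to_dict('records')}"
        )
    for opt in ("nq", "factor"):
        if opt in out.columns:
            out[opt] = pd.to_numeric(out[opt], errors="raise").astype(float)
            neg = out[opt].notna() & (out[opt] <= 0)
            if neg.any():
                raise ValidationError(f"{source}: {opt} must be > 0 where present")
        else:
            out[opt] = np.nan
    dup = out[["gene", "plate"]].duplicated(keep=False)
    if dup.any():
        raise ValidationError(
            f"{source}: duplicate (gene, plate) efficiency record(s): "
            f"{out.loc[dup, ['gene', 'plate']].drop_duplicates().apply(tuple, axis=1).tolist()}"
        )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# relative-quantity matrix
# ---------------------------------------------------------------------------

@dataclass
class RQMatrix:
    """Samples x genes matrix of relative quantities with sample metadata.

    Attributes
    ----------
    values
        DataFrame indexed by sample, one column per gene; entries are
        positive relative quantities or NaN for explicitly missing cells.
    groups
        Treatment-group label per sample (aligned with ``values.index``).
    plates
        Plate label per sample, if known (required for plate correction).
    plate_corrected
        Whether inter-plate factor correction has been applied.
    rq_mode
        ``"calibrator"`` (per-gene max RQ = 1) or ``"nq"``
        (RQ = N_q / E^Cq, absolute per plate).
    """

    values: pd.DataFrame
    groups: pd.Series
    plates: pd.Series | None = None
    plate_corrected: bool = False
    rq_mode: str = "calibrator"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.groups = self.groups.reindex(self.values.index)
        if self.plates is not None:
            self.plates = self.plates.reindex(self.values.index)
        self.validate()

    def validate(self) -> None:
        vals = self.values.to_numpy()
        with np.errstate(invalid="ignore"):
            if np.any(vals[~np.isnan(vals)] <= 0):
                raise ValidationError("RQMatrix entries must be > 0 or missing (NaN)")
        if self.groups.isna().any():
            raise ValidationError(
                f"missing group label for sample(s) {self.groups.index[self.groups.isna()].tolist()}"
            )
        if self.rq_mode not in ("calibrator", "nq"):
            raise ValidationError(f"unknown rq_mode {self.rq_mode!r}")

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.values.columns]

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.values.index]

    def log2(self) -> pd.DataFrame:
        """log2-transformed RQ values (NaN preserved)."""
        return np.log2(self.values)

    def subset(self, genes: Sequence[str]) -> "RQMatrix":
        return RQMatrix(
            values=self.values.loc[:, list(genes)],
            groups=self.groups,
            plates=self.plates,
            plate_corrected=self.plate_corrected,
            rq_mode=self.rq_mode,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: sample, group, plate, gene, rq."""
        long = self.values.stack(future_stack=True).rename("rq").reset_index()
        long.columns = ["sample", "gene", "rq"]
        long["group"] = long["sample"].map(self.groups)
        if self.plates is not None:
            long["plate"] = long["sample"].map(self.plates)
        return long

    @classmethod
    def from_frame(cls, long: pd.DataFrame, **kwargs) -> "RQMatrix":
        """Build from a long table with columns sample, group, gene, rq
        (and optionally plate)."""
        values = long.pivot(index="sample", columns="gene", values="rq")
        groups = long.drop_duplicates("sample").set_index("sample")["group"]
        plates = None
        if "plate" in long.columns:
            plates = long.drop_duplicates("sample").set_index("sample")["plate"]
        return cls(values=values, groups=groups, plates=plates, **kwargs)


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------

def to_jsonable(obj):
    """Recursively convert results (dataclasses, pandas, numpy) to plain
    JSON-serializable Python objects."""
    if obj is None or isinstance(obj, (bool, int, str)):
        return obj
    if isinstance(obj, float):
        return obj if np.isfinite(obj) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return to_jsonable(float(obj))
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [to_jsonable(x) for x in obj.tolist()]
    if isinstance(obj, pd.Series):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return {
            "columns": [str(c) for c in obj.columns],
            "index": [str(i) for i in obj.index],
            "data": [[to_jsonable(v) for v in row] for row in obj.to_numpy().tolist()],
        }
    if hasattr(obj, "__dataclass_fields__"):
        return {k: to_jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, Mapping):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [to_jsonable(x) for x in obj]
    return str(obj)


def write_json(obj, path: str | Path) -> None:
    """Serialize a result object to a structured JSON document."""
    Path(path).write_text(json.dumps(to_jsonable(obj), indent=2) + "\n")
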