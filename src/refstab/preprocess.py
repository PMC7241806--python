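"""Replicate QC, efficiency-corrected relative quantification and inter-plate
factor correction.

The preprocessing chain turns well-level Cq measurements into the positive
relative-quantity (RQ) matrix consumed by every stability algorithm:

1. :func:`aggregate_replicates` -- average technical replicates per
   (sample, gene) and attach QC flags.  Wet-lab practice is to re-assay
   triplicates whose Cq spread exceeds one cycle; software cannot re-assay,
   so flagged records are excluded from stability input by default (the
   exclusion set is configurable).
2. :func:`relative_quantity` -- convert mean Cq to RQ using per-(gene, plate)
   amplification efficiencies, either against the per-gene calibrator sample
   (``RQ = E**(Cq_min - Cq)``, max RQ = 1 per gene) or absolutely from the
   quantification threshold (``RQ = N_q / E**Cq``).
3. :func:`plate_factor_correction` -- remove the multiplicative between-plate
   session effect with per-(gene, plate) factors constrained to geometric
   mean 1 across plates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import RQMatrix, ValidationError

__all__ = [
    "QcPolicy",
    "aggregate_replicates",
    "relative_quantity",
    "plate_factor_correction",
    "replicate_rse",
]

#: QC flags that exclude a (sample, gene) record from stability input.
DEFAULT_EXCLUDE_FLAGS = ("spread_exceeded", "missing_replicate", "above_max_cq")


@dataclass
class QcPolicy:
    """Replicate quality-control thresholds.

    Attributes
    ----------
    max_spread
        Maximum tolerated max-min Cq difference within a replicate set
        (cycles); wider sets are flagged ``spread_exceeded``.
    max_cq
        Maximum mean Cq for a reference gene (cycles); later quantification
        cycles sit in the stochastic single-template regime and are flagged
        ``above_max_cq``.
    min_replicates
        Minimum number of non-missing replicates for a ``pass``.
    """

    max_spread: float = 1.0
    max_cq: float = 34.0
    min_replicates: int = 2

    def __post_init__(self) -> None:
        if self.max_spread <= 0 or self.max_cq <= 0 or self.min_replicates <= 0:
            raise ValidationError("QcPolicy fields must be strictly positive")


def aggregate_replicates(reps: pd.DataFrame, policy: QcPolicy | None = None) -> pd.DataFrame:
    """Aggregate well-level replicates into a per-(sample, gene) Cq table.

    Parameters
    ----------
    reps
        Validated replicate table (see :mod:`refstab.datamodel`).
    policy
        QC thresholds; defaults to :class:`QcPolicy` defaults.

    Returns
    -------
    pandas.DataFrame
        One row per (run, sample, gene) with columns ``sample, group, plate,
        run, gene, mean_cq, sd_cq, spread, n_replicates, qc_flag``.
        ``mean_cq`` is the arithmetic mean of the non-missing replicate Cq
        (equivalently the geometric mean of quantities).  Flag precedence:
        ``missing_replicate`` > ``spread_exceeded`` > ``above_max_cq``.
        A (sample, gene) with no usable wells yields ``missing_replicate``
        with NaN mean, not a hard error.
    """
    policy = policy or QcPolicy()
    keys = ["run", "sample", "gene"]
    agg = (
        reps.groupby(keys, sort=False)
        .agg(
            group=("group", "first"),
            plate=("plate", "first"),
            mean_cq=("cq", "mean"),
            sd_cq=("cq", lambda c: c.std(ddof=1) if c.notna().sum() > 1 else (0.0 if c.notna().sum() == 1 else np.nan)),
            min_cq=("cq", "min"),
            max_cq=("cq", "max"),
            n_replicates=("cq", "count"),
        )
        .reset_index()
    )
    agg["spread"] = agg["max_cq"] - agg["min_cq"]
    flag = np.full(len(agg), "pass", dtype=object)
    flag[agg["mean_cq"].to_numpy() > policy.max_cq] = "above_max_cq"
    flag[agg["spread"].to_numpy() > policy.max_spread] = "spread_exceeded"
    flag[agg["n_replicates"].to_numpy() < policy.min_replicates] = "missing_replicate"
    agg["qc_flag"] = flag
    cols = ["sample", "group", "plate", "run", "gene", "mean_cq", "sd_cq",
            "spread", "n_replicates", "qc_flag"]
    return agg[cols]


def relative_quantity(
    cq: pd.DataFrame,
    eff: pd.DataFrame,
    mode: str = "calibrator",
    exclude_flags: tuple[str, ...] = DEFAULT_EXCLUDE_FLAGS,
) -> RQMatrix:
    """Efficiency-corrected relative quantification of a Cq table.

    Parameters
    ----------
    cq
        Aggregated Cq table from :func:`aggregate_replicates`.
    eff
        Efficiency table with one record per (gene, plate).
    mode
        ``"calibrator"``: per gene, ``RQ_s = E_s**(Cq_min - Cq_s)`` with
        ``Cq_min`` the smallest mean Cq for that gene, so the calibrator
        sample has RQ = 1 and every other RQ <= 1.
        ``"nq"``: ``RQ_s = N_q / E_s**Cq_s`` with the plate-matched
        efficiency and quantification threshold -- absolute per plate, which
        composes naturally with inter-plate factor correction.
    exclude_flags
        QC flags whose records are dropped before quantification.

    Raises
    ------
    ValidationError
        If a (gene, plate) present in ``cq`` has no efficiency record, or if
        nq mode is requested without ``nq`` values.
    """
    if mode not in ("calibrator", "nq"):
        raise ValidationError(f"unknown RQ mode {mode!r}")
    keep = cq[~cq["qc_flag"].isin(exclude_flags) & cq["mean_cq"].notna()].copy()
    if keep.empty:
        raise ValidationError(
            "no records left after QC exclusion "
            f"(flags excluded: {list(exclude_flags)}; observed: {cq['qc_flag'].value_counts().to_dict()})"
        )

    emap = eff.set_index(["gene", "plate"])
    need = set(zip(keep["gene"], keep["plate"]))
    missing = sorted(k for k in need if k not in emap.index)
    if missing:
        raise ValidationError(f"no efficiency record for (gene, plate): {missing}")

    e = np.array([emap.loc[(g, p), "efficiency"] for g, p in zip(keep["gene"], keep["plate"])])
    if mode == "nq":
        nq = np.array([emap.loc[(g, p), "nq"] for g, p in zip(keep["gene"], keep["plate"])])
        if np.isnan(nq).any():
            bad = sorted(
                {(g, p) for g, p, v in zip(keep["gene"], keep["plate"], nq) if np.isnan(v)}
            )
            raise ValidationError(f"nq mode requires a quantification threshold; missing for {bad}")
        # log-space evaluation: E**Cq overflows float64 beyond ~Cq 700
        keep["rq"] = np.exp(np.log(nq) - keep["mean_cq"].to_numpy() * np.log(e))
    else:
        keep["_loge"] = np.log(e)
        parts = []
        for gene, grp in keep.groupby("gene", sort=False):
            cq_min = grp["mean_cq"].min()
            rq = np.exp((cq_min - grp["mean_cq"].to_numpy()) * grp["_loge"].to_numpy())
            parts.append(pd.Series(rq, index=grp.index))
        keep["rq"] = pd.concat(parts)
        keep = keep.drop(columns="_loge")

    return RQMatrix.from_frame(
        keep[["sample", "group", "plate", "gene", "rq"]], rq_mode=mode
    )


def plate_factor_correction(rq: RQMatrix) -> tuple[RQMatrix, pd.DataFrame]:
    """Fit and apply multiplicative inter-plate correction factors.

    Per gene, the factor for plate *p* is the ratio of the overall geometric
    mean RQ to the plate-*p* geometric mean, renormalized so the geometric
    mean of the factors across plates is exactly 1 (least-squares solution
    for a multiplicative session effect on the log-RQ scale).  Corrected RQ
    for a sample is its RQ times the factor of its plate.

    Returns
    -------
    (RQMatrix, pandas.DataFrame)
        The corrected matrix (``plate_corrected=True``) and the factor set,
        one row per (gene, plate) with column ``factor`` (NaN and flagged
        where a plate has no observation for the gene).

    Notes
    -----
    With plates of equal size the correction also preserves each gene's
    overall geometric mean exactly; with unbalanced plate composition the
    geometric-mean-1 constraint on the factors takes precedence.
    """
    if rq.plates is None:
        raise ValidationError("plate_factor_correction requires per-sample plate labels")
    plates = rq.plates
    plate_levels = sorted(plates.dropna().unique().tolist())
    if len(plate_levels) < 2:
        warnings.warn("single plate: factors are identically 1", stacklevel=2)
        factors = pd.DataFrame(
            [(g, p, 1.0, "single_plate") for g in rq.genes for p in plate_levels],
            columns=["gene", "plate", "factor", "flag"],
        )
        out = RQMatrix(rq.values.copy(), rq.groups, rq.plates, True, rq.rq_mode)
        return out, factors

    log2rq = rq.log2()
    corrected = log2rq.copy()
    records = []
    for gene in rq.genes:
        col = log2rq[gene]
        plate_means = col.groupby(plates).mean()
        f = -(plate_means - plate_means.mean())  # log2 factors, sum 0 over plates
        for p in plate_levels:
            if p not in plate_means.index or np.isnan(plate_means.get(p, np.nan)):
                records.append((gene, p, np.nan, "no_observations"))
            else:
                records.append((gene, p, float(2.0 ** f[p]), "ok"))
        shift = plates.map(f).astype(float)
        corrected[gene] = col + shift
    factors = pd.DataFrame(records, columns=["gene", "plate", "factor", "flag"])
    out = RQMatrix(2.0 ** corrected, rq.groups, rq.plates, True, rq.rq_mode)
    return out, factors


def replicate_rse(cq: pd.DataFrame, eff: pd.DataFrame) -> pd.Series:
    """Per-(sample, gene) relative standard error of RQ from replicate spread.

    The SD of the replicate Cq maps to the natural-log quantity scale via
    ln(E); the standard error of the replicate mean divides by sqrt(n).
    Returned as a Series aligned with ``cq``'s rows.
    """
    emap = eff.set_index(["gene", "plate"])["efficiency"]
    loge = np.array(
        [np.log(emap.get((g, p), np.nan)) for g, p in zip(cq["gene"], cq["plate"])]
    )
    n = cq["n_replicates"].to_numpy().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rse = loge * cq["sd_cq"].to_numpy() / np.sqrt(np.maximum(n, 1.0))
    return pd.Series(rse, index=cq.index, name="rse")
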