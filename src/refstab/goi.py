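"""Normalization of genes of interest to a reference-gene combination.

The normalized relative quantity (NRQ) of a gene of interest (GOI) in a
sample is its relative quantity divided by the geometric mean of the
reference combination's relative quantities in that sample (the per-sample
normalisation factor).  Uncertainty is propagated by first-order
(delta-method) quadrature of relative standard errors on the log scale:

    rSE(NRQ)^2 = rSE(GOI)^2 + (1/k^2) * sum_g rSE(ref_g)^2

for k reference genes, so a k = 1 reference reduces to simple division with
``rSE = sqrt(rSE_goi^2 + rSE_ref^2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import RQMatrix, ValidationError

__all__ = ["NRQResult", "nrq"]


@dataclass
class NRQResult:
    """Per-sample normalized relative quantities for one GOI.

    ``table`` has columns ``nrq``, ``rse`` (relative standard error, NaN
    when no input errors were supplied) and ``ref_nf`` (the per-sample
    geometric-mean reference quantity).
    """

    goi: str
    reference_combination: tuple[str, ...]
    table: pd.DataFrame


def nrq(
    goi_rq: pd.Series,
    refs: RQMatrix | pd.DataFrame,
    ref_genes: list[str] | None = None,
    goi_rse: pd.Series | None = None,
    ref_rse: pd.DataFrame | None = None,
    goi_name: str = "GOI",
) -> NRQResult:
    """Normalize a GOI's relative quantities to a reference combination.

    Parameters
    ----------
    goi_rq
        Per-sample RQ of the gene of interest (index = samples, all > 0).
    refs
        Reference RQ matrix; ``ref_genes`` selects the combination columns
        (default: all columns).
    goi_rse, ref_rse
        Optional per-sample relative standard errors of the GOI and of each
        reference gene (same shape as the corresponding RQ input).

    Samples missing any reference value get a missing NRQ with a warning;
    zero or negative quantities are a hard error.
    """
    ref_frame = refs.values if isinstance(refs, RQMatrix) else refs
    if ref_genes is not None:
        missing = [g for g in ref_genes if g not in ref_frame.columns]
        if missing:
            raise ValidationError(f"reference genes not present: {missing}")
        ref_frame = ref_frame.loc[:, list(ref_genes)]
    combo = tuple(str(g) for g in ref_frame.columns)
    k = len(combo)
    if k == 0:
        raise ValidationError("at least one reference gene required")

    common = goi_rq.index.intersection(ref_frame.index)
    if len(common) < len(goi_rq.index):
        raise ValidationError("GOI and reference matrices must cover the same samples")
    goi_rq = goi_rq.loc[common]
    ref_frame = ref_frame.loc[common]

    if (goi_rq.dropna() <= 0).any():
        raise ValidationError("GOI relative quantities must be > 0")
    vals = ref_frame.to_numpy(float)
    if np.any(vals[~np.isnan(vals)] <= 0):
        raise ValidationError("reference relative quantities must be > 0")

    incomplete = ref_frame.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"missing reference value(s); NRQ set missing for sample(s) "
            f"{ref_frame.index[incomplete].tolist()}",
            stacklevel=2,
        )
    nf = pd.Series(np.nan, index=common, name="ref_nf", dtype=float)
    ok = ~incomplete
    nf[ok] = stats.gmean(ref_frame[ok].to_numpy(float), axis=1)
    out = pd.DataFrame(index=common)
    out["nrq"] = goi_rq / nf
    out["ref_nf"] = nf

    if goi_rse is not None or ref_rse is not None:
        g2 = (goi_rse.loc[common] ** 2) if goi_rse is not None else 0.0
        if ref_rse is not None:
            r2 = (ref_rse.loc[common, list(combo)] ** 2).sum(axis=1) / (k * k)
        else:
            r2 = 0.0
        out["rse"] = np.sqrt(g2 + r2)
    else:
        out["rse"] = np.nan
    return NRQResult(goi=goi_name, reference_combination=combo, table=out)
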