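"""Classic reference-gene stability algorithms.

Four published algorithms are implemented against a common interface:

* :func:`genorm` -- pairwise-ratio variation ``M`` with stepwise elimination
  and the pairwise variation ``V_n`` of successive normalisation factors
  (the qBase+ heuristic flags ``V_n < 0.15`` as "no benefit from gene n+1");
* :func:`normfinder` -- model-based decomposition into intergroup difference
  and intragroup variance with shrinkage of group differences;
* :func:`bestkeeper` -- descriptive Cq dispersion (mean absolute deviation)
  plus correlation of each gene with the geometric-mean BestKeeper index;
* :func:`comparative_delta_cq` -- mean SD of pairwise Cq differences.

All logarithms are base 2 (the natural scale of quantification cycles).
Rankings are permutations of the gene set; ties are broken by input gene
order so results are deterministic.  Missing values are handled pairwise
(geNorm, delta-Cq), by complete-sample restriction (BestKeeper index), and
by per-group omission (NormFinder).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import RQMatrix, ValidationError

__all__ = [
    "StabilityScores",
    "GenormResult",
    "NormFinderResult",
    "BestKeeperResult",
    "genorm",
    "normfinder",
    "bestkeeper",
    "comparative_delta_cq",
    "run_all",
]

#: qBase+ cutoff below which adding the (n+1)-th gene is deemed unnecessary.
GENORM_V_CUTOFF = 0.15


@dataclass
class StabilityScores:
    """Per-gene stability scores of one algorithm.

    ``ranking`` lists genes from most stable (rank 1) to least stable and is
    always consistent with ``scores`` under ``orientation``.
    """

    algorithm: str
    scores: pd.Series
    orientation: str  # "lower_better" | "higher_better"
    ranking: list[str]

    def __post_init__(self) -> None:
        if self.orientation not in ("lower_better", "higher_better"):
            raise ValidationError(f"bad orientation {self.orientation!r}")
        if sorted(self.ranking) != sorted(str(g) for g in self.scores.index):
            raise ValidationError("ranking is not a permutation of the scored genes")


def _rank_genes(scores: pd.Series, orientation: str) -> list[str]:
    """Order genes by score; ties keep input order (stable sort)."""
    asc = orientation == "lower_better"
    s = scores if asc else -scores
    order = np.argsort(s.to_numpy(), kind="stable")
    return [str(scores.index[i]) for i in order]


def _as_rq_frame(rq: RQMatrix | pd.DataFrame) -> pd.DataFrame:
    return rq.values if isinstance(rq, RQMatrix) else rq


def _as_cq_wide(cq: pd.DataFrame) -> pd.DataFrame:
    """Accept an aggregated Cq table (long) or a samples x genes wide frame."""
    if {"sample", "gene", "mean_cq"}.issubset(cq.columns):
        if "qc_flag" in cq.columns:
            cq = cq[cq["qc_flag"] == "pass"]
        return cq.pivot(index="sample", columns="gene", values="mean_cq")
    return cq


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

@dataclass
class GenormResult:
    """Stepwise geNorm output.

    ``m_values`` holds the first-pass (all genes) M values -- the single
    summary column conventionally reported.  ``steps`` records the M values
    recomputed at each elimination round; ``pairwise_variation`` maps
    n -> V_n for n = 2..G-1 using the final ranking.
    """

    m_values: pd.Series
    elimination_order: list[str]
    final_pair: tuple[str, str]
    ranking: list[str]
    pairwise_variation: pd.Series
    v_below_cutoff: pd.Series
    steps: list[pd.Series] = field(default_factory=list)

    def scores(self) -> StabilityScores:
        return StabilityScores("genorm", self.m_values, "lower_better", self.ranking)


def _genorm_m(log2rq: pd.DataFrame) -> pd.Series:
    """M_j = mean over k != j of SD(log2 RQ_j - log2 RQ_k), pairwise-complete."""
    genes = list(log2rq.columns)
    m = {}
    for j in genes:
        sds = []
        for k in genes:
            if k == j:
                continue
            ratio = (log2rq[j] - log2rq[k]).dropna()
            sds.append(ratio.std(ddof=1) if len(ratio) > 1 else np.nan)
        m[j] = float(np.nanmean(sds))
    return pd.Series(m, name="M")


def genorm(rq: RQMatrix | pd.DataFrame) -> GenormResult:
    """geNorm stability analysis on a relative-quantity matrix.

    Requires >= 3 genes.  The gene with the largest M is removed and M is
    recomputed until two genes remain; the ranking is the elimination order
    reversed, with the final pair occupying ranks 1-2 (ordered by first-pass
    M, ties by input order).
    """
    values = _as_rq_frame(rq)
    genes = [str(g) for g in values.columns]
    if len(genes) < 3:
        raise ValidationError("genorm requires at least 3 genes")
    log2rq = np.log2(values)

    first_pass = _genorm_m(log2rq)
    steps = [first_pass]
    remaining = list(genes)
    eliminated: list[str] = []
    current = first_pass
    while len(remaining) > 2:
        worst = current.idxmax()
        eliminated.append(str(worst))
        remaining.remove(str(worst))
        current = _genorm_m(log2rq[remaining])
        steps.append(current)

    # final pair ordered by first-pass M (their last-step Ms are identical)
    pair = sorted(remaining, key=lambda g: (first_pass[g], genes.index(g)))
    ranking = pair + eliminated[::-1]

    # pairwise variation V_n between successive normalisation factors
    v = {}
    for n in range(2, len(genes)):
        nf_n = log2rq[ranking[:n]].mean(axis=1)
        nf_n1 = log2rq[ranking[: n + 1]].mean(axis=1)
        diff = (nf_n - nf_n1).dropna()
        v[n] = float(diff.std(ddof=1)) if len(diff) > 1 else np.nan
    v_series = pd.Series(v, name="V")
    return GenormResult(
        m_values=first_pass,
        elimination_order=eliminated,
        final_pair=(pair[0], pair[1]),
        ranking=ranking,
        pairwise_variation=v_series,
        v_below_cutoff=v_series < GENORM_V_CUTOFF,
        steps=steps,
    )


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

@dataclass
class NormFinderResult:
    """Model-based stability decomposition.

    ``group_differences`` and ``group_variances`` are genes x groups frames
    of the intergroup difference estimates (log2 units) and bias-corrected
    intragroup variances; ``shrunken_differences`` applies the empirical
    shrinkage factor gamma2/(gamma2 + Var(d)).  ``stability`` is the
    per-gene score (lower = more stable); ``best_pair`` minimizes the
    combination stability over all gene pairs.
    """

    stability: pd.Series
    ranking: list[str]
    group_differences: pd.DataFrame | None
    group_variances: pd.DataFrame
    shrunken_differences: pd.DataFrame | None
    difference_variances: pd.DataFrame | None
    gamma2: float
    best_pair: tuple[str, str] | None
    best_pair_stability: float | None
    single_group: bool

    def scores(self) -> StabilityScores:
        return StabilityScores("normfinder", self.stability, "lower_better", self.ranking)


_EPS_VAR = 1e-12


def normfinder(rq: RQMatrix | pd.DataFrame, groups: pd.Series | Sequence[str] | None = None) -> NormFinderResult:
    """NormFinder stability of candidate genes, with or without groups.

    The algorithm works on ``y = log2 RQ``:

    1. center each sample across genes: ``z = y - sample mean``;
    2. per group i and gene g, intergroup difference
       ``d_ig = mean_{s in i}(z_gs) - mean_all(z_gs)``;
    3. intragroup sample variances of z, bias-corrected by subtracting
       ``mean_g(s2_ig)/G`` (floored at a tiny epsilon);
    4. between-group variance ``gamma2`` estimated by moments and used to
       shrink d toward 0;
    5. per-gene stability = mean over groups of ``|d~_ig| + sqrt(Var(d_ig))``.

    With a single group the score reduces to the square root of the
    bias-corrected within-sample-centered variance.  Groups with fewer than
    two samples are excluded with a warning.
    """
    values = _as_rq_frame(rq)
    genes = [str(g) for g in values.columns]
    G = len(genes)
    if G < 3:
        raise ValidationError("normfinder requires at least 3 genes")
    if isinstance(rq, RQMatrix) and groups is None:
        groups = rq.groups
    y = np.log2(values)
    z = y.sub(y.mean(axis=1), axis=0)

    if groups is None:
        grp = pd.Series("all", index=values.index)
    else:
        grp = pd.Series(list(groups), index=values.index).astype(str)

    sizes = grp.value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small and len(sizes) > 1:
        import warnings

        warnings.warn(f"excluding group(s) with a single sample: {small}", stacklevel=2)
        keep = ~grp.isin(small)
        z, grp = z[keep], grp[keep]
    levels = [g for g in pd.unique(grp)]
    single_group = len(levels) < 2

    s2 = z.groupby(grp).var(ddof=1).reindex(levels)  # groups x genes
    sigma2 = (s2.sub(s2.mean(axis=1) / G, axis=0)).clip(lower=_EPS_VAR)

    if single_group:
        stab = np.sqrt(sigma2.iloc[0])
        stab.name = "stability"
        ranking = _rank_genes(stab, "lower_better")
        return NormFinderResult(
            stability=stab,
            ranking=ranking,
            group_differences=None,
            group_variances=sigma2.T,
            shrunken_differences=None,
            difference_variances=None,
            gamma2=0.0,
            best_pair=None,
            best_pair_stability=None,
            single_group=True,
        )

    n_i = grp.value_counts().reindex(levels)
    zbar_all = z.mean(axis=0)
    d = z.groupby(grp).mean().reindex(levels).sub(zbar_all, axis=1)  # groups x genes
    var_d = sigma2.div(n_i, axis=0)
    gamma2 = max(
        0.0,
        float((d**2).to_numpy().mean() * G / (G - 1) - var_d.to_numpy().mean()),
    )
    d_shrunk = d * (gamma2 / (gamma2 + var_d))
    stab = (d_shrunk.abs() + np.sqrt(var_d)).mean(axis=0)
    stab.name = "stability"
    ranking = _rank_genes(stab, "lower_better")

    result = NormFinderResult(
        stability=stab,
        ranking=ranking,
        group_differences=d.T,
        group_variances=sigma2.T,
        shrunken_differences=d_shrunk.T,
        difference_variances=var_d.T,
        gamma2=gamma2,
        best_pair=None,
        best_pair_stability=None,
        single_group=False,
    )
    best_pair, best_val = None, np.inf
    for pair in combinations(genes, 2):
        rho = combination_stability(result, pair)
        if rho < best_val:
            best_pair, best_val = pair, rho
    result.best_pair = best_pair
    result.best_pair_stability = best_val
    return result


def combination_stability(result: NormFinderResult, combo: Sequence[str]) -> float:
    """NormFinder stability of a gene-set normalisation factor.

    Per group: |mean over the set of shrunken differences| plus
    sqrt(sum of Var(d))/|set|, averaged over groups.  Multi-group fits only.
    """
    if result.single_group:
        raise ValidationError("combination stability requires a multi-group fit")
    combo = list(combo)
    k = len(combo)
    d = result.shrunken_differences.loc[combo]  # genes x groups
    var_d = result.difference_variances.loc[combo]
    per_group = d.mean(axis=0).abs() + np.sqrt(var_d.sum(axis=0)) / k
    return float(per_group.mean())


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

@dataclass
class BestKeeperResult:
    """Descriptive dispersion and index correlation per gene.

    ``summary`` has one row per gene: geometric/arithmetic mean Cq, min,
    max, SD (mean absolute deviation from the arithmetic mean, in cycles),
    CV (percent), Pearson r vs the BestKeeper index and its two-sided
    p-value, and a reliability flag (SD <= 1 cycle).  ``index`` is the
    per-sample geometric mean Cq over all genes (complete samples only).
    """

    summary: pd.DataFrame
    index: pd.Series
    ranking: list[str]
    dropped_samples: list[str] = field(default_factory=list)

    def scores(self) -> StabilityScores:
        return StabilityScores(
            "bestkeeper", self.summary["r"], "higher_better", self.ranking
        )


def bestkeeper(cq: pd.DataFrame, remove_outliers: bool = False) -> BestKeeperResult:
    """BestKeeper analysis of an aggregated Cq table.

    Samples missing any gene are excluded from the index.  With
    ``remove_outliers`` set, samples whose index deviates from the median
    index by more than 3x the median absolute deviation are dropped before
    correlation (no outlier removal by default).
    """
    wide = _as_cq_wide(cq)
    genes = [str(g) for g in wide.columns]
    if len(genes) < 2:
        raise ValidationError("bestkeeper requires at least 2 genes")
    complete = wide.dropna()
    if len(complete) < 3:
        raise ValidationError("bestkeeper requires >= 3 complete samples for correlations")

    index = pd.Series(
        stats.gmean(complete.to_numpy(), axis=1), index=complete.index, name="bk_index"
    )
    dropped: list[str] = []
    if remove_outliers:
        resid = (index - index.median()).abs()
        mad = float(np.median(resid))
        if mad > 0:
            keep = resid <= 3 * mad
            dropped = [str(s) for s in index.index[~keep]]
            complete, index = complete[keep], index[keep]

    rows = []
    for g in genes:
        col = wide[g].dropna()
        am = col.mean()
        sd = float((col - am).abs().mean())  # BestKeeper convention: MAD about the mean
        r, p = stats.pearsonr(complete[g], index)
        rows.append(
            {
                "gene": g,
                "geo_mean_cq": float(stats.gmean(col)),
                "arith_mean_cq": float(am),
                "min_cq": float(col.min()),
                "max_cq": float(col.max()),
                "sd_cq": sd,
                "cv_pct": 100.0 * sd / float(am),
                "r": float(r),
                "p_value": float(p),
                "reliable": bool(sd <= 1.0),
            }
        )
    summary = pd.DataFrame(rows).set_index("gene")
    ranking = _rank_genes(summary["r"], "higher_better")
    return BestKeeperResult(summary=summary, index=index, ranking=ranking, dropped_samples=dropped)


# ---------------------------------------------------------------------------
# comparative delta-Cq
# ---------------------------------------------------------------------------

def comparative_delta_cq(cq: pd.DataFrame) -> StabilityScores:
    """Comparative delta-Cq stability: mean over gene pairs of the sample SD
    (n-1 denominator) of the pairwise Cq difference; lower = more stable.

    Pairs with fewer than two complete samples are skipped with a warning.
    """
    wide = _as_cq_wide(cq)
    genes = [str(g) for g in wide.columns]
    if len(genes) < 3:
        raise ValidationError("comparative_delta_cq requires at least 3 genes")
    sums = {g: [] for g in genes}
    for a, b in combinations(genes, 2):
        diff = (wide[a] - wide[b]).dropna()
        if len(diff) < 2:
            import warnings

            warnings.warn(f"pair ({a}, {b}) has < 2 complete samples; skipped", stacklevel=2)
            continue
        sd = float(diff.std(ddof=1))
        sums[a].append(sd)
        sums[b].append(sd)
    scores = pd.Series({g: float(np.mean(v)) if v else np.nan for g, v in sums.items()}, name="delta_cq")
    return StabilityScores("delta_cq", scores, "lower_better", _rank_genes(scores, "lower_better"))


# ---------------------------------------------------------------------------
# convenience driver
# ---------------------------------------------------------------------------

def run_all(
    rq: RQMatrix,
    cq: pd.DataFrame | None = None,
    algorithms: Sequence[str] = ("genorm", "normfinder", "bestkeeper", "delta_cq"),
) -> dict:
    """Run the requested algorithms and return ``{name: result}``.

    geNorm and NormFinder consume the RQ matrix; BestKeeper and the
    comparative delta-Cq consume Cq values.  When no Cq table is given,
    ``-log2 RQ`` is used as a Cq surrogate (identical up to the per-gene
    efficiency scaling and an additive constant, which the two algorithms'
    dispersion statistics treat transparently).
    """
    if cq is None:
        cq_wide = -rq.log2()
    else:
        cq_wide = _as_cq_wide(cq)
    out: dict = {}
    for alg in algorithms:
        if alg == "genorm":
            out[alg] = genorm(rq)
        elif alg == "normfinder":
            out[alg] = normfinder(rq, rq.groups)
        elif alg == "bestkeeper":
            out[alg] = bestkeeper(cq_wide)
        elif alg in ("delta_cq", "deltacq"):
            out["delta_cq"] = comparative_delta_cq(cq_wide)
        else:
            raise ValidationError(f"unknown algorithm {alg!r}")
    return out
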