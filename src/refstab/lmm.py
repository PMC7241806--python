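"""ICC-based stability of reference-gene combinations from a 3-way linear
mixed-effects model.

A combination of k reference genes is treated as k repeated measurements
("raters") of each sample.  On the log2 expression scale the model is

    y_{g,s} = mu + gene_g + group_i(s) + (gene x group)_{g,i(s)} + b_s + e_{g,s}

with a random intercept ``b_s ~ N(0, sigma2_sample)`` for samples nested in
treatment groups and residual ``e ~ N(0, sigma2_error)``.  The stability
measure is the intraclass correlation

    rho = sigma2_sample / (sigma2_sample + sigma2_error),

i.e. the agreement of the combination's genes within a sample after all
systematic (gene, group, interaction) effects are removed: a stable
combination tracks the sample-to-sample input variation and nothing else.

Variance components are estimated by REML through a profile likelihood in
the single variance ratio ``lambda = sigma2_sample / sigma2_error`` (the
random-intercept structure makes the generalized least squares whitening
closed-form per sample block, so each likelihood evaluation is one ordinary
least squares solve; missing gene measurements simply shrink a block).

Confidence intervals: for complete data (every retained sample measured on
all combination genes) the F-based consistency interval on
``F = MS_samples / MS_error`` is used; otherwise a seeded parametric
bootstrap.  Systematic (group and gene x group) effects are tested with a
likelihood-ratio test of maximum-likelihood fits against a chi-square with
``(n_groups - 1) * k`` degrees of freedom; a small p-value means the
"reference" genes move with treatment and the combination is unsuitable.

Sample-size planning uses Bonett's closed-form approximation for the number
of samples needed to pin the ICC's confidence interval to a target width.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations as iter_combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import RQMatrix, ValidationError

__all__ = [
    "LmmSpec",
    "IccResult",
    "CombinationSearchResult",
    "SampleSizeSpec",
    "MomentSet",
    "fit_combination",
    "search_combinations",
    "classify_reliability",
    "bonett_sample_size",
    "sample_size_table",
    "variance_of_product",
]


@dataclass
class LmmSpec:
    """Model and estimation settings.

    ``response_scale``: ``"log2_rq"`` (default) models log2 relative
    quantities; ``"neg_cq"`` models the negated quantification cycle
    directly (an efficiency-1 convention).  ``ci_method``: ``"auto"`` picks
    the F-based interval for complete data and the parametric bootstrap
    otherwise; ``"fband"`` / ``"bootstrap"`` force one.

    ``lrt_correction``: ``"bartlett"`` (default) scales the likelihood-ratio
    statistic by ``(N - p_full) / N`` before the chi-square comparison -- the
    classical Bartlett-type degrees-of-freedom correction, near-exact for
    fixed-effect tests in the linear-model limit; ``"none"`` uses the raw
    asymptotic statistic, which is measurably anticonservative at study-sized
    n (a few dozen samples against ~k x g estimated cell means).
    """

    response_scale: str = "log2_rq"
    ci_method: str = "auto"
    alpha: float = 0.05
    n_boot: int = 1000
    lrt_correction: str = "bartlett"

    def __post_init__(self) -> None:
        if self.response_scale not in ("log2_rq", "neg_cq"):
            raise ValidationError(f"unknown response scale {self.response_scale!r}")
        if self.ci_method not in ("auto", "fband", "bootstrap"):
            raise ValidationError(f"unknown ci_method {self.ci_method!r}")
        if self.lrt_correction not in ("bartlett", "none"):
            raise ValidationError(f"unknown lrt_correction {self.lrt_correction!r}")


@dataclass
class IccResult:
    """REML variance components and ICC of one gene combination."""

    combination: tuple[str, ...]
    sigma2_sample: float
    sigma2_error: float
    icc: float
    ci_lower: float
    ci_upper: float
    lrt_stat: float | None
    lrt_p: float | None
    ci_method: str
    n_samples: int
    n_groups: int
    flags: list[str] = field(default_factory=list)

    @property
    def width(self) -> float:
        return self.ci_upper - self.ci_lower

    @property
    def systematic_effects(self) -> bool | None:
        """True when the LRT flags group / gene-by-group effects (p <= 0.05)."""
        return None if self.lrt_p is None else bool(self.lrt_p <= 0.05)


@dataclass
class CombinationSearchResult:
    results: list[IccResult]
    selected: IccResult
    stop_reason: str  # "lower_bound_no_increase" | "max_size_reached"
    best_lower_by_size: dict[int, float]

    def ranking(self) -> list[IccResult]:
        """Combinations ranked by lower CI bound (desc), then narrower CI."""
        order = sorted(
            range(len(self.results)),
            key=lambda i: (-self.results[i].ci_lower, self.results[i].width, i),
        )
        return [self.results[i] for i in order]


# ---------------------------------------------------------------------------
# profile-likelihood engine for the random-intercept model
# ---------------------------------------------------------------------------

@dataclass
class _Fit:
    lam: float
    sigma2_error: float
    sigma2_sample: float
    neg2ll: float
    beta: np.ndarray
    rank: int


def _whiten(lam: float, y: np.ndarray, X: np.ndarray, s: np.ndarray, counts: np.ndarray):
    """GLS whitening for V = I + lam * (block of ones) per sample block."""
    if lam <= 0:
        return y, X
    a = 1.0 - 1.0 / np.sqrt(1.0 + counts * lam)  # per-sample shrink of the block mean
    ymean = np.bincount(s, weights=y) / counts
    ytil = y - a[s] * ymean[s]
    Xmean = np.empty((len(counts), X.shape[1]))
    for j in range(X.shape[1]):
        Xmean[:, j] = np.bincount(s, weights=X[:, j]) / counts
    Xtil = X - a[s, None] * Xmean[s]
    return ytil, Xtil


def _neg2ll(lam: float, y: np.ndarray, X: np.ndarray, s: np.ndarray,
            counts: np.ndarray, reml: bool) -> tuple[float, float, np.ndarray, int]:
    ytil, Xtil = _whiten(lam, y, X, s, counts)
    beta, _, rank, _ = np.linalg.lstsq(Xtil, ytil, rcond=None)
    resid = ytil - Xtil @ beta
    rss = float(resid @ resid)
    N = len(y)
    ld_v = float(np.sum(np.log1p(counts * lam)))
    if reml:
        dof = N - rank
        s2 = max(rss / dof, 1e-300)
        sign, ld_x = np.linalg.slogdet(Xtil.T @ Xtil)
        val = dof * (math.log(2 * math.pi * s2) + 1.0) + ld_v + ld_x
    else:
        s2 = max(rss / N, 1e-300)
        val = N * (math.log(2 * math.pi * s2) + 1.0) + ld_v
    return val, s2, beta, rank


def _fit_variance_ratio(y: np.ndarray, X: np.ndarray, s: np.ndarray, reml: bool = True) -> _Fit:
    """Profile the (-2) log-likelihood over lambda = sigma2_s / sigma2_e >= 0."""
    counts = np.bincount(s)
    if (counts == 0).any():
        keep = counts > 0
        remap = np.cumsum(keep) - 1
        s = remap[s]
        counts = counts[keep]

    def f(t: float) -> float:
        return _neg2ll(math.exp(t), y, X, s, counts, reml)[0]

    res = optimize.minimize_scalar(f, bounds=(-18.0, 18.0), method="bounded",
                                   options={"xatol": 1e-8})
    candidates = [(f(-30.0), 0.0), (res.fun, math.exp(res.x))]
    # lambda ~ e^-30 is numerically the boundary fit sigma2_sample = 0
    best_val, lam = min(candidates, key=lambda t: t[0])
    val, s2e, beta, rank = _neg2ll(lam, y, X, s, counts, reml)
    if lam * s2e < 1e-12 * max(s2e, 1e-300):
        lam = 0.0
        val, s2e, beta, rank = _neg2ll(0.0, y, X, s, counts, reml)
    return _Fit(lam=lam, sigma2_error=s2e, sigma2_sample=lam * s2e,
                neg2ll=val, beta=beta, rank=rank)


def _designs(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full (gene x group cell means) and reduced (gene means) design
    matrices, plus sample codes."""
    gene_codes, _ = pd.factorize(df["gene"], sort=True)
    group_codes, _ = pd.factorize(df["group"], sort=True)
    cell = gene_codes * (group_codes.max() + 1) + group_codes
    X_full = pd.get_dummies(pd.Series(cell)).to_numpy(float)
    X_red = pd.get_dummies(pd.Series(gene_codes)).to_numpy(float)
    sample_codes, _ = pd.factorize(df["sample"], sort=True)
    return X_full, X_red, sample_codes


def _long_response(expr: RQMatrix | pd.DataFrame, groups, combo: Sequence[str],
                   spec: LmmSpec) -> pd.DataFrame:
    if isinstance(expr, RQMatrix):
        frame = expr.values
        if groups is None:
            groups = expr.groups
    else:
        frame = expr
    combo = [str(g) for g in combo]
    missing = [g for g in combo if g not in map(str, frame.columns)]
    if missing:
        raise ValidationError(f"combination genes not in expression matrix: {missing}")
    sub = frame.loc[:, combo]
    y = np.log2(sub) if spec.response_scale == "log2_rq" else -sub
    long = y.stack(future_stack=True).rename("y").reset_index()
    long.columns = ["sample", "gene", "y"]
    gmap = pd.Series(list(groups), index=frame.index).astype(str)
    long["group"] = long["sample"].map(gmap)
    long = long.dropna(subset=["y"])
    long = long[np.isfinite(long["y"])]
    return long.reset_index(drop=True)


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------

def _fband_ci(df: pd.DataFrame, k: int, alpha: float) -> tuple[float, float, dict]:
    """F-based consistency interval for complete per-sample data.

    MS_samples and MS_error come from the least-squares decomposition with
    the gene x group fixed cells and sample indicators; degrees of freedom
    are rank-based so unbalanced group sizes are handled.
    """
    X_full, _, s = _designs(df)
    y = df["y"].to_numpy(float)
    n = int(s.max()) + 1
    S = np.zeros((len(y), n))
    S[np.arange(len(y)), s] = 1.0
    X2 = np.hstack([X_full, S])
    b1, _, rank1, _ = np.linalg.lstsq(X_full, y, rcond=None)
    rss1 = float(np.sum((y - X_full @ b1) ** 2))
    b2, _, rank2, _ = np.linalg.lstsq(X2, y, rcond=None)
    rss2 = float(np.sum((y - X2 @ b2) ** 2))
    df_s = rank2 - rank1
    df_e = len(y) - rank2
    if df_s <= 0 or df_e <= 0:
        raise ValidationError("not enough replication for the F-based interval")
    ms_s = max(rss1 - rss2, 0.0) / df_s
    ms_e = rss2 / df_e
    if ms_e <= 0:
        return 1.0, 1.0, {"df_samples": df_s, "df_error": df_e, "F": math.inf}
    F = ms_s / ms_e
    fl = F / stats.f.ppf(1 - alpha / 2, df_s, df_e)
    fu = F * stats.f.ppf(1 - alpha / 2, df_e, df_s)
    lo = (fl - 1.0) / (fl + k - 1.0)
    hi = (fu - 1.0) / (fu + k - 1.0)
    return (
        float(np.clip(lo, 0.0, 1.0)),
        float(np.clip(hi, 0.0, 1.0)),
        {"df_samples": df_s, "df_error": df_e, "F": F},
    )


def _bootstrap_ci(df: pd.DataFrame, fit: _Fit, X_full: np.ndarray, s: np.ndarray,
                  alpha: float, n_boot: int, seed: int | None) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    n = int(s.max()) + 1
    mu = X_full @ fit.beta
    sd_b = math.sqrt(max(fit.sigma2_sample, 0.0))
    sd_e = math.sqrt(max(fit.sigma2_error, 0.0))
    iccs = np.empty(n_boot)
    for i in range(n_boot):
        b = rng.normal(0.0, sd_b, size=n)
        ystar = mu + b[s] + rng.normal(0.0, sd_e, size=len(mu))
        f = _fit_variance_ratio(ystar, X_full, s, reml=True)
        tot = f.sigma2_sample + f.sigma2_error
        iccs[i] = f.sigma2_sample / tot if tot > 0 else 0.0
    lo, hi = np.quantile(iccs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def fit_combination(
    expr: RQMatrix | pd.DataFrame,
    groups: Sequence[str] | pd.Series | None,
    combo: Sequence[str],
    spec: LmmSpec | None = None,
    seed: int | None = None,
) -> IccResult:
    """Fit the 3-way mixed model for one gene combination and return its ICC.

    Parameters
    ----------
    expr
        RQ matrix (or plain samples x genes frame of relative quantities).
    groups
        Treatment-group label per sample (taken from the RQMatrix if None).
    combo
        Gene set of size >= 2 acting as the raters of each sample.
    spec
        Estimation settings (:class:`LmmSpec`).
    seed
        Seed for the parametric bootstrap (required only when it is used).
    """
    spec = spec or LmmSpec()
    combo = tuple(str(g) for g in combo)
    if len(combo) < 2:
        raise ValidationError("a combination needs at least 2 genes")
    df = _long_response(expr, groups, combo, spec)
    if df.empty:
        raise ValidationError("no usable observations for this combination")
    k = len(combo)
    n = df["sample"].nunique()
    g = df["group"].nunique()
    per_group = df.drop_duplicates("sample").groupby("group").size()
    if (per_group < 2).any():
        raise ValidationError(
            f"groups with fewer than 2 samples after omission: "
            f"{per_group[per_group < 2].index.tolist()}"
        )

    X_full, X_red, s = _designs(df)
    y = df["y"].to_numpy(float)
    flags: list[str] = []

    fit = _fit_variance_ratio(y, X_full, s, reml=True)
    tot = fit.sigma2_sample + fit.sigma2_error
    degenerate = tot <= 1e-12 * max(float(np.var(y)), 1e-30)
    if degenerate:
        flags.append("degenerate_fit_zero_variance")
        icc = 1.0  # all genes agree exactly: perfect within-sample agreement
    else:
        icc = fit.sigma2_sample / tot
        if fit.lam == 0.0:
            flags.append("boundary_sigma2_sample_zero")

    complete = bool((df.groupby("sample")["gene"].nunique() == k).all())
    method = spec.ci_method
    if method == "auto":
        method = "fband" if complete else "bootstrap"
    if method == "fband" and not complete:
        warnings.warn("incomplete data: falling back to bootstrap CI", stacklevel=2)
        method = "bootstrap"

    if degenerate:
        lo, hi = icc, icc
    elif method == "fband":
        lo, hi, _ = _fband_ci(df, k, spec.alpha)
    else:
        lo, hi = _bootstrap_ci(df, fit, X_full, s, spec.alpha, spec.n_boot, seed)
    if not (lo <= icc <= hi):
        flags.append("ci_truncated_to_contain_point")
        lo, hi = min(lo, icc), max(hi, icc)

    lrt_stat = lrt_p = None
    if g >= 2:
        full_ml = _fit_variance_ratio(y, X_full, s, reml=False)
        red_ml = _fit_variance_ratio(y, X_red, s, reml=False)
        lrt_stat = max(red_ml.neg2ll - full_ml.neg2ll, 0.0)
        if spec.lrt_correction == "bartlett":
            lrt_stat *= (len(y) - full_ml.rank) / len(y)
        lrt_p = float(stats.chi2.sf(lrt_stat, df=(g - 1) * k))

    return IccResult(
        combination=combo,
        sigma2_sample=fit.sigma2_sample,
        sigma2_error=fit.sigma2_error,
        icc=float(icc),
        ci_lower=float(lo),
        ci_upper=float(hi),
        lrt_stat=lrt_stat,
        lrt_p=lrt_p,
        ci_method=method,
        n_samples=n,
        n_groups=g,
        flags=flags,
    )


def search_combinations(
    expr: RQMatrix | pd.DataFrame,
    groups: Sequence[str] | pd.Series | None,
    candidates: Sequence[str] | None = None,
    max_k: int = 5,
    spec: LmmSpec | None = None,
    seed: int | None = None,
) -> CombinationSearchResult:
    """Exhaustive per-size search for the most stable gene combination.

    All size-2 combinations are evaluated, then size-3, and so on; the
    search stops as soon as the best lower 95% CI bound at size k+1 fails to
    exceed the best at size k (using the lower bound guards against
    selecting an imprecisely estimated ICC).  Failed fits are skipped with
    a warning rather than aborting the search.
    """
    spec = spec or LmmSpec()
    if candidates is None:
        candidates = expr.genes if isinstance(expr, RQMatrix) else list(map(str, expr.columns))
    candidates = [str(g) for g in candidates]
    if len(candidates) < 3:
        raise ValidationError("combination search needs at least 3 candidate genes")
    max_k = min(max_k, len(candidates))

    results: list[IccResult] = []
    best_lower_by_size: dict[int, float] = {}
    stop_reason = "max_size_reached"
    prev_best = -np.inf
    for size in range(2, max_k + 1):
        best_this = -np.inf
        for combo in iter_combinations(candidates, size):
            try:
                res = fit_combination(expr, groups, combo, spec, seed=seed)
            except (ValidationError, np.linalg.LinAlgError) as err:
                warnings.warn(f"fit failed for {combo}: {err}", stacklevel=2)
                continue
            results.append(res)
            best_this = max(best_this, res.ci_lower)
        best_lower_by_size[size] = best_this
        if size > 2 and best_this <= prev_best:
            stop_reason = "lower_bound_no_increase"
            break
        prev_best = max(prev_best, best_this)
    if not results:
        raise ValidationError("every combination fit failed")
    ordered = sorted(
        range(len(results)),
        key=lambda i: (-results[i].ci_lower, results[i].width, i),
    )
    selected = results[ordered[0]]
    return CombinationSearchResult(
        results=results,
        selected=selected,
        stop_reason=stop_reason,
        best_lower_by_size=best_lower_by_size,
    )


#: Reliability bands on the ICC scale (left-closed).
_BANDS = ((0.9, "excellent"), (0.75, "good"), (0.5, "moderate"), (-np.inf, "poor"))


def _band(x: float) -> str:
    for cut, name in _BANDS:
        if x >= cut:
            return name
    return "poor"


def classify_reliability(res: IccResult) -> str:
    """Qualitative reliability from the CI lower bound and point estimate.

    Bands: < 0.5 poor; [0.5, 0.75) moderate; [0.75, 0.9) good; >= 0.9
    excellent.  When lower bound and point estimate fall in different bands
    the label spans them, e.g. ``"moderate to good"``.
    """
    lo_band = _band(res.ci_lower)
    pt_band = _band(res.icc)
    return lo_band if lo_band == pt_band else f"{lo_band} to {pt_band}"


# ---------------------------------------------------------------------------
# sample-size planning (Bonett)
# ---------------------------------------------------------------------------

@dataclass
class SampleSizeSpec:
    """Planning inputs: target ICC, raters (genes) k, CI width and level."""

    rho: float
    k: int
    width: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValidationError("rho must lie in [0, 1]")
        if self.k < 2:
            raise ValidationError("at least 2 raters (genes) required")
        if not (0.0 < self.width <= 1.0):
            raise ValidationError("width must lie in (0, 1]")
        if not (0.0 < self.level < 1.0):
            raise ValidationError("level must lie in (0, 1)")


def bonett_sample_size(rho: float, k: int, width: float, level: float = 0.95) -> int:
    """Minimum samples for a two-sided ICC confidence interval of given width.

    Bonett's approximation::

        n = ceil( 8 z^2 (1 - rho)^2 (1 + (k-1) rho)^2 / (k (k-1) w^2) + 1 )

    with z the two-sided normal quantile of the confidence level.  The
    result is non-increasing in ``width`` everywhere and in ``rho`` over the
    planning range (rho >= 0.5; for k >= 3 the (1-rho)(1+(k-1)rho) factor
    peaks at small rho); at ``rho = 1`` the numerator vanishes and the
    formula returns 1.  ICC values are conventionally entered at two-decimal
    precision.
    """
    spec = SampleSizeSpec(rho=rho, k=k, width=width, level=level)
    z = stats.norm.ppf(1.0 - (1.0 - spec.level) / 2.0)
    num = 8.0 * z * z * (1.0 - spec.rho) ** 2 * (1.0 + (spec.k - 1) * spec.rho) ** 2
    den = spec.k * (spec.k - 1) * spec.width**2
    return int(math.ceil(num / den + 1.0))


def sample_size_table(
    rhos: Sequence[float] | None = None,
    ks: Sequence[int] | None = None,
    ws: Sequence[float] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Cross-product table of Bonett minimum sample sizes.

    Default grid: k = 2..5 reference genes, ICC 0.70..0.90 in steps of 0.01
    and CI widths 0.1 and 0.2 -- the planning ranges relevant to selecting
    "true reference genes" at moderate-to-excellent reliability.
    """
    if rhos is None:
        rhos = np.round(np.arange(0.70, 0.901, 0.01), 2).tolist()
    if ks is None:
        ks = [2, 3, 4, 5]
    if ws is None:
        ws = [0.1, 0.2]
    if not rhos or not list(ks) or not list(ws):
        raise ValidationError("empty planning grid")
    rows = [
        {"rho": float(r), "k": int(k), "width": float(w),
         "n": bonett_sample_size(float(r), int(k), float(w), level)}
        for r in rhos for k in ks for w in ws
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# variance of a product
# ---------------------------------------------------------------------------

@dataclass
class MomentSet:
    """First/second moments of two random quantities X and Y."""

    var_x: float
    var_y: float
    mu_x: float
    mu_y: float
    cov_xy: float | None = None
    cov_x2y2: float | None = None

    def __post_init__(self) -> None:
        if self.var_x < 0 or self.var_y < 0:
            raise ValidationError("variances must be non-negative")


def variance_of_product(m: MomentSet, independent: bool = True) -> float:
    """Variance of the product X*Y from moments.

    Independent mode::

        Var(XY) = Var(X) Var(Y) + Var(X) mu_y^2 + Var(Y) mu_x^2

    Dependent mode (requires both covariance fields) is the exact identity
    ``Var(XY) = E[X^2 Y^2] - (E[XY])^2`` written in terms of the moments::

        Var(XY) = Cov(X^2, Y^2) + (Var(X) + mu_x^2)(Var(Y) + mu_y^2)
                  - (Cov(X, Y) + mu_x mu_y)^2

    since ``E[X^2 Y^2] = Cov(X^2, Y^2) + E[X^2] E[Y^2]`` and
    ``E[XY] = Cov(X, Y) + mu_x mu_y``.  It reduces to the independent form
    when both covariances vanish.

    In normalisation terms X is the gene of interest and Y the reciprocal of
    the reference-combination normalisation factor: any covariance between
    them inflates the variance of the normalized quotient, which is why an
    unstable (treatment-coupled) reference combination costs statistical
    power downstream.  Both modes are cross-checked by Monte Carlo in the
    test suite.
    """
    if independent:
        return m.var_x * m.var_y + m.var_x * m.mu_y**2 + m.var_y * m.mu_x**2
    if m.cov_xy is None or m.cov_x2y2 is None:
        raise ValidationError("dependent mode requires cov_xy and cov_x2y2")
    return (
        m.cov_x2y2
        + (m.var_x + m.mu_x**2) * (m.var_y + m.mu_y**2)
        - (m.cov_xy + m.mu_x * m.mu_y) ** 2
    )
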