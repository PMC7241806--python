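"""Consensus ranking of stability algorithms by weighted Spearman footrule.

Given K rankings of the same G genes (one per stability algorithm), the
consensus is the permutation minimizing the (optionally weighted) Spearman
footrule objective.  Two solvers are provided:

* :func:`brute_force_aggregate` -- exact.  Both the unweighted and the
  weighted footrule objectives decompose into per-(gene, position) costs, so
  the global minimum is found as a linear assignment problem; full
  enumeration over permutations is retained in the test suite as an
  independent oracle.
* :func:`ce_aggregate` -- cross-entropy Monte Carlo over permutations,
  maintaining a position-probability matrix tilted toward elite samples.
  Useful beyond the enumeration guard and as a stochastic cross-check.

Weighted dialect: each list's stability scores are oriented so that smaller
means more stable (correlation-type scores are negated), min-max normalized
to [0, 1] within the list, and the distance contribution of gene g in list i
is ``|W_i(candidate position) - W_i(observed position)|`` where ``W_i`` is
the normalized score at a position of list i.  The unweighted objective uses
raw rank positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .datamodel import ValidationError

__all__ = [
    "RankingEnsemble",
    "ConsensusRanking",
    "footrule_objective",
    "brute_force_aggregate",
    "ce_aggregate",
    "CEParams",
]

BRUTE_FORCE_MAX_ITEMS = 10


@dataclass
class RankingEnsemble:
    """K ranked lists over a common gene set, with optional score vectors.

    ``rankings`` lists genes from most to least stable.  ``scores`` (if
    given) maps each list to its per-gene stability values and
    ``orientations`` states whether smaller or larger values mean more
    stable for that list.
    """

    rankings: list[list[str]]
    scores: list[pd.Series] | None = None
    orientations: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.rankings:
            raise ValidationError("ensemble needs at least one ranking")
        base = sorted(self.rankings[0])
        for r in self.rankings:
            if sorted(r) != base:
                raise ValidationError("all rankings must be permutations of the same gene set")
        if self.scores is not None:
            if self.orientations is None or len(self.scores) != len(self.rankings):
                raise ValidationError("scores require one orientation per list")

    @property
    def genes(self) -> list[str]:
        return sorted(self.rankings[0])

    @property
    def n_items(self) -> int:
        return len(self.rankings[0])

    @classmethod
    def from_stability(cls, results: dict) -> "RankingEnsemble":
        """Build an ensemble from ``refstab.stability`` results
        (objects exposing ``.scores()`` or already ``StabilityScores``)."""
        rankings, scores, orientations = [], [], []
        for res in results.values():
            sc = res.scores() if hasattr(res, "scores") and callable(res.scores) else res
            rankings.append(list(sc.ranking))
            scores.append(sc.scores)
            orientations.append(sc.orientation)
        return cls(rankings=rankings, scores=scores, orientations=orientations)

    def position_weights(self) -> np.ndarray | None:
        """K x G matrix of orientation-normalized scores by list position.

        Row i holds the scores of list i's items in rank order, oriented so
        that 0 = most stable and min-max scaled to [0, 1]; None when the
        ensemble carries no scores.
        """
        if self.scores is None:
            return None
        W = np.empty((len(self.rankings), self.n_items))
        for i, (ranking, sc, orient) in enumerate(
            zip(self.rankings, self.scores, self.orientations)
        ):
            v = np.array([float(sc[g]) for g in ranking])
            if orient == "higher_better":
                v = -v
            lo, hi = v.min(), v.max()
            W[i] = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
        return W


@dataclass
class ConsensusRanking:
    """An aggregated ordering with its recomputed objective value."""

    ordering: list[str]
    objective: float
    method: str  # "brute_force" | "cross_entropy"
    weighted: bool
    seed: int | None = None
    n_iterations: int | None = None


def _positions(ranking: Sequence[str]) -> dict[str, int]:
    return {g: i for i, g in enumerate(ranking)}


def _cost_matrix(ensemble: RankingEnsemble, weighted: bool) -> tuple[np.ndarray, list[str]]:
    """cost[g, p]: footrule contribution of placing gene g at position p."""
    genes = ensemble.genes
    G = len(genes)
    pos = np.array(
        [[_positions(r)[g] for g in genes] for r in ensemble.rankings]
    )  # K x G observed positions
    p_grid = np.arange(G)
    if weighted:
        W = ensemble.position_weights()
        if W is None:
            raise ValidationError("weighted aggregation requires per-list scores")
        # |W_i(p) - W_i(pos_i(g))| summed over lists
        cost = np.abs(W[:, None, :] - W[np.arange(len(W))[:, None], pos][:, :, None]).sum(axis=0)
    else:
        cost = np.abs(p_grid[None, None, :] - pos[:, :, None]).sum(axis=0).astype(float)
    return cost, genes


def footrule_objective(
    candidate: Sequence[str], ensemble: RankingEnsemble, weighted: bool = False
) -> float:
    """Spearman footrule distance of a candidate permutation to the ensemble.

    Unweighted: sum over lists and genes of |candidate position - list
    position| (1-based or 0-based is immaterial).  Weighted: positions are
    replaced by each list's normalized stability score at that position.
    """
    genes = ensemble.genes
    if sorted(candidate) != genes:
        raise ValidationError("candidate is not a permutation of the ensemble's gene set")
    cost, gene_order = _cost_matrix(ensemble, weighted)
    gidx = {g: i for i, g in enumerate(gene_order)}
    return float(sum(cost[gidx[g], p] for p, g in enumerate(candidate)))


def brute_force_aggregate(ensemble: RankingEnsemble, weighted: bool = False) -> ConsensusRanking:
    """Exact footrule-minimizing consensus via linear assignment.

    The footrule objective is a sum of independent (gene, position) costs,
    so the minimizing permutation is an optimal assignment of genes to
    positions -- identical to full enumeration but polynomial.  Ties between
    optimal assignments are broken toward lexicographic gene order.  Refuses
    more than 10 items (the enumeration-equivalent regime this solver is
    specified for); use :func:`ce_aggregate` beyond that.
    """
    G = ensemble.n_items
    if G > BRUTE_FORCE_MAX_ITEMS:
        raise ValidationError(
            f"brute-force aggregation is limited to {BRUTE_FORCE_MAX_ITEMS} items "
            f"(got {G}); use ce_aggregate for larger ensembles"
        )
    cost, genes = _cost_matrix(ensemble, weighted)
    # deterministic tie-break: prefer lexicographically earlier gene earlier
    # (rearrangement: minimizing -sum(rank * position) pairs small ranks with
    # small positions); perturbation kept below a quarter of the smallest
    # nonzero cost gap so true optima are never displaced
    uniq = np.unique(cost)
    gap = float(np.min(np.diff(uniq))) if len(uniq) > 1 else 1.0
    eps = gap / (4.0 * G * G * G)
    tie = -eps * np.outer(np.arange(G), np.arange(G))
    rows, cols = linear_sum_assignment(cost + tie)
    ordering = [None] * G
    for r, c in zip(rows, cols):
        ordering[c] = genes[r]
    obj = footrule_objective(ordering, ensemble, weighted)
    return ConsensusRanking(ordering=ordering, objective=obj, method="brute_force", weighted=weighted)


@dataclass
class CEParams:
    """Cross-entropy sampler settings."""

    samples_per_iter: int = 2000
    elite_fraction: float = 0.1
    smoothing: float = 0.7
    patience: int = 5
    max_iter: int = 200


def ce_aggregate(
    ensemble: RankingEnsemble,
    seed: int,
    weighted: bool = False,
    params: CEParams | None = None,
) -> ConsensusRanking:
    """Cross-entropy Monte Carlo consensus search over permutations.

    A G x G position-probability matrix (rows: genes, columns: positions)
    is sampled sequentially position by position; the elite fraction of each
    batch re-estimates the matrix with multiplicative smoothing.  The search
    stops when the best objective has not improved for ``patience``
    iterations.  Fully reproducible for a fixed seed.
    """
    params = params or CEParams()
    if ensemble.n_items < 2:
        raise ValidationError("ce_aggregate needs at least 2 items")
    rng = np.random.default_rng(seed)
    cost, genes = _cost_matrix(ensemble, weighted)
    G = len(genes)
    P = np.full((G, G), 1.0 / G)
    n_elite = max(1, int(np.ceil(params.elite_fraction * params.samples_per_iter)))

    best_obj = np.inf
    best_perm: np.ndarray | None = None
    stale = 0
    reinitialized = False
    it = 0
    for it in range(1, params.max_iter + 1):
        perms = _sample_permutations(P, params.samples_per_iter, rng)
        objs = cost[perms, np.arange(G)[None, :]].sum(axis=1)
        order = np.argsort(objs, kind="stable")
        elite = perms[order[:n_elite]]
        if objs[order[0]] < best_obj - 1e-12:
            best_obj = float(objs[order[0]])
            best_perm = perms[order[0]].copy()
            stale = 0
        else:
            stale += 1
        P_hat = np.zeros_like(P)
        np.add.at(P_hat, (elite, np.arange(G)[None, :]), 1.0)
        P_hat /= n_elite
        P = params.smoothing * P_hat + (1.0 - params.smoothing) * P
        col_sums = P.sum(axis=0)
        if np.any(col_sums <= 0) or np.any(~np.isfinite(P)):
            if reinitialized:
                raise RuntimeError("cross-entropy probability matrix degenerated twice")
            warnings.warn("degenerate probability matrix; re-initializing once", stacklevel=2)
            P = np.full((G, G), 1.0 / G)
            reinitialized = True
        if stale >= params.patience:
            break

    ordering = [genes[i] for i in best_perm]
    return ConsensusRanking(
        ordering=ordering,
        objective=float(best_obj),
        method="cross_entropy",
        weighted=weighted,
        seed=seed,
        n_iterations=it,
    )


def _sample_permutations(P: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample n permutations; result[i, p] = gene index at position p."""
    G = P.shape[0]
    out = np.empty((n, G), dtype=np.intp)
    used = np.zeros((n, G), dtype=bool)
    rows = np.arange(n)
    for p in range(G):
        probs = np.where(used, 0.0, P[:, p][None, :].repeat(n, axis=0))
        totals = probs.sum(axis=1, keepdims=True)
        flat = totals[:, 0] <= 0
        if flat.any():  # column mass exhausted by earlier picks: fall back to uniform
            probs[flat] = (~used[flat]).astype(float)
            totals = probs.sum(axis=1, keepdims=True)
        probs /= totals
        cum = np.cumsum(probs, axis=1)
        u = rng.random((n, 1))
        pick = (cum < u).sum(axis=1)
        pick = np.minimum(pick, G - 1)
        out[:, p] = pick
        used[rows, pick] = True
    return out
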