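"""Full-pipeline orchestration and report assembly.

:func:`run_full_analysis` wires the stages together:
replicate QC -> relative quantification -> inter-plate correction ->
classic stability algorithms -> consensus ranking -> mixed-model ICC
combination search, and assembles an :class:`AnalysisReport` whose every
number is recomputable from the serialized intermediate artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .aggregate import RankingEnsemble, brute_force_aggregate, ce_aggregate
from .datamodel import to_jsonable, write_json
from .lmm import LmmSpec, classify_reliability, search_combinations
from .preprocess import QcPolicy, aggregate_replicates, plate_factor_correction, relative_quantity
from .stability import run_all

log = logging.getLogger("refstab")

__all__ = ["AnalysisReport", "run_full_analysis", "descriptive_statistics"]


@dataclass
class AnalysisReport:
    """Machine-readable analysis report with provenance."""

    qc_summary: dict
    descriptives: pd.DataFrame
    algorithm_rankings: dict
    consensus: dict
    top_combinations: list[dict]
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_json(self, out / "report.json")
        self.descriptives.to_csv(out / "descriptives.csv")
        pd.DataFrame(self.top_combinations).to_csv(out / "combinations.csv", index=False)


def descriptive_statistics(cq: pd.DataFrame) -> pd.DataFrame:
    """Per-gene descriptive statistics of aggregated Cq values.

    One column per gene; rows: number of values, minimum, maximum,
    arithmetic mean, standard deviation (n-1), geometric mean, and the
    D'Agostino-Pearson omnibus normality p-value (NaN below n = 8, the
    test's validity floor).
    """
    wide = cq.pivot(index="sample", columns="gene", values="mean_cq")
    rows = {}
    for g in wide.columns:
        col = wide[g].dropna()
        if len(col) >= 8:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p_norm = float(stats.normaltest(col).pvalue)
        else:
            p_norm = np.nan
        rows[str(g)] = {
            "n": int(len(col)),
            "min_cq": float(col.min()) if len(col) else np.nan,
            "max_cq": float(col.max()) if len(col) else np.nan,
            "mean_cq": float(col.mean()) if len(col) else np.nan,
            "sd_cq": float(col.std(ddof=1)) if len(col) > 1 else 0.0,
            "geo_mean_cq": float(stats.gmean(col)) if len(col) else np.nan,
            "dagostino_p": p_norm,
        }
    return pd.DataFrame(rows)


def run_full_analysis(
    reps: pd.DataFrame,
    eff: pd.DataFrame,
    qc: QcPolicy | None = None,
    rq_mode: str = "nq",
    correct_plates: bool = True,
    weighted_consensus: bool = True,
    consensus_method: str = "brute",
    max_k: int = 5,
    lmm_spec: LmmSpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> AnalysisReport:
    """Run the complete stability workflow on a replicate-level dataset.

    Stage failures raise with the failing stage named; artifacts produced
    before the failure are retained when ``out_dir`` is set.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args, **kwargs):
        log.info("stage %s: start", name)
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err

    cq = _stage("preprocess.aggregate", aggregate_replicates, reps, qc)
    if rq_mode == "nq" and eff["nq"].isna().all():
        rq_mode = "calibrator"
    rq = _stage("preprocess.rq", relative_quantity, cq, eff, rq_mode)
    factors = None
    if correct_plates and rq.plates is not None and rq.plates.nunique() > 1:
        rq, factors = _stage("preprocess.plates", plate_factor_correction, rq)
    if out is not None:
        cq.to_csv(out / "cq_table.csv", index=False)
        rq.to_frame().to_csv(out / "rq.csv", index=False)
        if factors is not None:
            factors.to_csv(out / "plate_factors.csv", index=False)

    cq_pass = cq[cq["qc_flag"] == "pass"]
    descriptives = _stage("descriptives", descriptive_statistics, cq_pass)
    stability = _stage("stability", run_all, rq, cq_pass)

    ensemble = RankingEnsemble.from_stability(stability)
    if consensus_method == "ce":
        consensus = _stage("aggregate", ce_aggregate, ensemble, seed, weighted_consensus)
    else:
        consensus = _stage("aggregate", brute_force_aggregate, ensemble, weighted_consensus)

    search = _stage(
        "lmm", search_combinations, rq, rq.groups, None, max_k, lmm_spec, seed
    )
    top = [
        {
            "combination": " x ".join(r.combination),
            "icc": r.icc,
            "ci_lower": r.ci_lower,
            "ci_upper": r.ci_upper,
            "width": r.width,
            "lrt_p": r.lrt_p,
            "reliability": classify_reliability(r),
            "systematic_effects": r.systematic_effects,
        }
        for r in search.ranking()[:10]
    ]

    config_repr = json.dumps(
        to_jsonable(
            {
                "qc": qc or QcPolicy(),
                "rq_mode": rq_mode,
                "correct_plates": correct_plates,
                "weighted_consensus": weighted_consensus,
                "consensus_method": consensus_method,
                "max_k": max_k,
                "lmm": lmm_spec or LmmSpec(),
                "seed": seed,
            }
        ),
        sort_keys=True,
    )
    report = AnalysisReport(
        qc_summary=cq["qc_flag"].value_counts().to_dict(),
        descriptives=descriptives,
        algorithm_rankings={
            name: {
                "ranking": res.scores().ranking if hasattr(res, "scores") and callable(res.scores) else res.ranking,
                "scores": (res.scores().scores if hasattr(res, "scores") and callable(res.scores) else res.scores).round(6).to_dict(),
            }
            for name, res in stability.items()
        },
        consensus={
            "ordering": consensus.ordering,
            "objective": consensus.objective,
            "method": consensus.method,
            "weighted": consensus.weighted,
        },
        top_combinations=top,
        provenance={
            "version": __version__,
            "seed": seed,
            "config_sha256": hashlib.sha256(config_repr.encode()).hexdigest(),
            "stop_reason": search.stop_reason,
        },
    )
    if out is not None:
        report.write(out)
    return report
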