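"""Synthetic replicate-level Cq datasets with known ground truth.

The generator emulates a multi-group RT-qPCR reference-gene study: ~54-56
kidney samples in 7 treatment groups, 10 candidate reference genes measured
in triplicate wells, samples split over 2 plates per run, and gene-specific
amplification efficiencies in (1.85, 2.0].

The latent log2 expression of gene g in sample s (group i) is

    x_{g,s} = shift_{g,i} + b_s + e_{g,s},
    b_s ~ N(0, sigma_b^2),   e_{g,s} ~ N(0, sigma_{e,g}^2),

i.e. a shared sample effect (RNA input / extraction efficiency -- what a
reference gene should track) plus gene-specific biological/technical noise
(what makes a reference gene unstable).  The well-level quantification
cycle maps through each gene's own efficiency,

    Cq = baseline_g - (x + plate_offset_log2) * log(2)/log(E_g) + well noise,

so pipelines that assume perfect doubling (E = 2) diverge measurably from
efficiency-corrected ones on these data.  Plate offsets are additive on the
log2-quantity scale (multiplicative on quantities), matching the
inter-plate factor-correction model.

Ground truth: the ICC of a gene combination under this generator is
``sigma_b^2 / (sigma_b^2 + mean_g sigma_{e,g}^2)`` (:func:`truth_icc`),
which parameter-recovery tests compare against fitted values.

Default noise levels are calibrated so the default dataset behaves like the
emulated study: with ``sigma_b = 1`` the two most stable genes (gene noise
SD 0.4 log2 units) give a pair ICC near 0.86, while ribosomal 18S and GAPDH
(gene noise SD 1.5-1.8) are unambiguously unstable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import ValidationError

__all__ = ["GeneSpec", "SimConfig", "SimTruth", "simulate_dataset", "truth_icc", "default_genes"]

_LOG2 = np.log(2.0)


@dataclass(frozen=True)
class GeneSpec:
    """One simulated gene: baseline Cq, amplification efficiency and
    gene-specific residual SD (log2 units)."""

    name: str
    baseline_cq: float
    efficiency: float
    sigma_e: float

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency <= 2.0):
            raise ValidationError(f"{self.name}: efficiency must be in (1, 2]")
        if self.sigma_e < 0 or self.baseline_cq <= 0:
            raise ValidationError(f"{self.name}: invalid baseline or sigma_e")


def default_genes() -> list[GeneSpec]:
    """Ten candidate reference genes shaped like a rat-kidney panel.

    Baseline Cq values follow typical abundances (ribosomal 18S most
    abundant, YWHAG least); efficiencies lie in (1.85, 2.0]; per-gene noise
    SDs make ACTB/PABPN1/HMBS stable and 18S/GAPDH unstable.
    """
    return [
        GeneSpec("18S", 15.5, 1.88, 1.80),
        GeneSpec("GAPDH", 26.5, 2.00, 1.50),
        GeneSpec("ACTB", 19.7, 1.94, 0.40),
        GeneSpec("HMBS", 21.0, 1.97, 0.45),
        GeneSpec("HPRT", 22.8, 1.97, 0.70),
        GeneSpec("PABPN1", 20.0, 1.86, 0.40),
        GeneSpec("SDHA", 17.7, 1.98, 0.90),
        GeneSpec("TBP", 26.4, 2.00, 0.60),
        GeneSpec("YWHAG", 27.9, 2.00, 0.50),
        GeneSpec("YWHAZ", 20.3, 1.93, 0.55),
    ]


@dataclass
class SimConfig:
    """Study-design and noise configuration of the generator.

    Attributes
    ----------
    n_groups, samples_per_group
        7 treatment groups of 8 samples by default (56 total).
    genes
        Per-gene baseline/efficiency/noise settings.
    sigma_b
        SD of the shared per-sample random effect (log2 units).
    group_shifts
        Optional mapping gene -> per-group log2 shifts (systematic effects);
        default none (stable references).
    plate_log2_offsets
        Additive log2-quantity offset per plate (2 plates by default).
    replicate_sd
        Well-to-well technical noise on the Cq scale (cycles).
    n_replicates, missing_rate, seed
        Triplicates, no missing wells, and a fixed seed by default.
    """

    n_groups: int = 7
    samples_per_group: int = 8
    genes: list[GeneSpec] = field(default_factory=default_genes)
    sigma_b: float = 1.0
    group_shifts: Mapping[str, Sequence[float]] | None = None
    plate_log2_offsets: tuple[float, ...] = (0.25, -0.25)
    replicate_sd: float = 0.1
    n_replicates: int = 3
    missing_rate: float = 0.0
    run_id: str = "R1"
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.sigma_b < 0 or self.replicate_sd < 0:
            raise ValidationError("SDs must be >= 0")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValidationError("missing_rate must be in [0, 1]")
        if self.n_groups < 1 or self.samples_per_group < 1 or self.n_replicates < 1:
            raise ValidationError("design counts must be >= 1")
        if self.group_shifts:
            names = {g.name for g in self.genes}
            for gene, shifts in self.group_shifts.items():
                if gene not in names:
                    raise ValidationError(f"group_shifts references unknown gene {gene!r}")
                if len(shifts) != self.n_groups:
                    raise ValidationError(f"group_shifts[{gene!r}] must list {self.n_groups} values")

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "genes" in raw:
            raw["genes"] = [GeneSpec(**g) for g in raw["genes"]]
        if "plate_log2_offsets" in raw:
            raw["plate_log2_offsets"] = tuple(raw["plate_log2_offsets"])
        return cls(**raw)


@dataclass
class SimTruth:
    """Realized latent quantities and generating parameters."""

    sample_effects: pd.Series
    group_shifts: pd.DataFrame  # genes x groups, log2 units
    plate_factors: pd.Series  # log2-quantity offset per plate
    config: SimConfig


def simulate_dataset(
    cfg: SimConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate a replicate table, efficiency table and ground truth.

    ``seed`` overrides ``cfg.seed``; identical seed + config give
    bit-identical tables.  Samples alternate between plates within each
    group so plates stay balanced; wells are dropped independently at
    ``missing_rate`` (Cq set missing, row retained).
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genes = cfg.genes
    groups = [f"G{i + 1}" for i in range(cfg.n_groups)]
    n = cfg.n_groups * cfg.samples_per_group
    samples = [f"S{i + 1:03d}" for i in range(n)]
    sample_group = {s: groups[i // cfg.samples_per_group] for i, s in enumerate(samples)}
    n_plates = len(cfg.plate_log2_offsets)
    plates = [f"P{p + 1}" for p in range(n_plates)]
    sample_plate = {s: plates[i % n_plates] for i, s in enumerate(samples)}

    shifts = pd.DataFrame(0.0, index=cfg.gene_names, columns=groups)
    if cfg.group_shifts:
        for gene, vals in cfg.group_shifts.items():
            shifts.loc[gene] = list(vals)

    b = pd.Series(rng.normal(0.0, cfg.sigma_b, size=n), index=samples, name="b")
    plate_off = pd.Series(list(cfg.plate_log2_offsets), index=plates, name="plate_log2")

    rows = []
    for s in samples:
        grp, plate = sample_group[s], sample_plate[s]
        for g in genes:
            eps = rng.normal(0.0, g.sigma_e)
            x = shifts.loc[g.name, grp] + b[s] + eps
            slope = _LOG2 / np.log(g.efficiency)
            cq_center = g.baseline_cq - (x + plate_off[plate]) * slope
            for rep in range(1, cfg.n_replicates + 1):
                cq = cq_center + rng.normal(0.0, cfg.replicate_sd)
                if cfg.missing_rate > 0 and rng.random() < cfg.missing_rate:
                    cq = np.nan
                rows.append((s, grp, plate, cfg.run_id, g.name, rep, cq))
    reps = pd.DataFrame(
        rows, columns=["sample", "group", "plate", "run", "gene", "replicate", "cq"]
    )

    eff = pd.DataFrame(
        [
            {
                "gene": g.name,
                "plate": p,
                "efficiency": g.efficiency,
                # a plausible threshold: fluorescence at the gene's baseline cycle
                "nq": 50.0,
                "factor": np.nan,
            }
            for g in genes
            for p in plates
        ]
    )
    truth = SimTruth(sample_effects=b, group_shifts=shifts, plate_factors=plate_off, config=cfg)
    return reps, eff, truth


def truth_icc(cfg: SimConfig, combo: Sequence[str]) -> float:
    """Closed-form generating ICC of a gene combination:
    ``sigma_b^2 / (sigma_b^2 + mean_g sigma_{e,g}^2)``."""
    by_name = {g.name: g for g in cfg.genes}
    missing = [g for g in combo if g not in by_name]
    if missing:
        raise ValidationError(f"combo genes not in config: {missing}")
    s2e = float(np.mean([by_name[g].sigma_e ** 2 for g in combo]))
    s2b = cfg.sigma_b**2
    if s2b + s2e == 0:
        return 1.0
    return s2b / (s2b + s2e)
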