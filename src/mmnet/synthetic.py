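"""Synthetic-data generators emulating the study's experimental readouts.

Every pipeline stage is testable without wet-lab data: the generators run
the network model (or the 4PL curve) and overlay a declared noise model —
multiplicative lognormal for abundance readouts (qPCR ratios, western
densitometry are positive, ratio-scaled quantities), additive Gaussian on
the percent scale for viability.  All generators are pure functions of
(configuration, seed).

The lognormal multiplier is parameterized to have mean 1 and the requested
coefficient of variation: sigma^2 = ln(1 + CV^2), mu = -sigma^2/2.

Default study conditions: treatment time courses sampled at
0/4/8/24/48/72 h with 3 replicates and CV 10%; chase series at
0/8/24/48/72 h (sub-hour points added when short-lived proteins are the
object of interest); viability as triplicate percent-survival points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discrepancy import ExperimentalSeries
from .dose_response import DoseResponseCurve, four_param_logistic
from .network import DrugPerturbation, NetworkParameters, simulate, simulate_chase

__all__ = [
    "NoiseModel",
    "TREATMENT_TIMEPOINTS",
    "CHASE_TIMEPOINTS",
    "gen_treatment_dataset",
    "gen_chase_dataset",
    "gen_viability",
]

#: Treatment sampling grid: drug exposures read out at 4-72 h plus t = 0.
TREATMENT_TIMEPOINTS = (0.0, 4.0, 8.0, 24.0, 48.0, 72.0)

#: Default chase sampling grid ("up to 72 h").
CHASE_TIMEPOINTS = (0.0, 8.0, 24.0, 48.0, 72.0)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal replicate noise.

    ``cv`` is the coefficient of variation of the mean-one multiplier;
    generation is bit-reproducible for a fixed seed.
    """

    cv: float = 0.1
    n_replicates: int = 3
    seed: int = 0
    kind: str = "multiplicative-lognormal"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError(f"CV must be >= 0, got {self.cv}")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.kind != "multiplicative-lognormal":
            raise ValueError(f"unsupported noise kind {self.kind!r}")

    def multipliers(self, rng: np.random.Generator, shape) -> np.ndarray:
        if self.cv == 0:
            return np.ones(shape)
        sigma = math.sqrt(math.log(1.0 + self.cv**2))
        return np.exp(rng.normal(-0.5 * sigma**2, sigma, shape))


def gen_treatment_dataset(
    params: NetworkParameters,
    perturbation: DrugPerturbation | None,
    noise: NoiseModel,
    timepoints=TREATMENT_TIMEPOINTS,
    *,
    cell_line: str = "synthetic",
    drug: str = "synthetic-drug",
) -> list[ExperimentalSeries]:
    """Simulate a drug treatment and emit noisy replicate time courses for
    all six species/analyte combinations (raw, pre-normalization: noise is
    applied at every timepoint including t = 0)."""
    grid = np.asarray(timepoints, dtype=float)
    traj = simulate(params, perturbation, t_max=float(grid[-1]))
    rng = np.random.default_rng(noise.seed)
    out = []
    for species in ("MYC", "IRF4", "PRDM1"):
        for analyte in ("mRNA", "protein"):
            truth = traj.series_at(species, analyte, grid)
            mult = noise.multipliers(rng, (noise.n_replicates, grid.size))
            out.append(ExperimentalSeries(
                cell_line=cell_line, drug=drug, species=species,
                analyte=analyte, timepoints=grid, values=truth[None, :] * mult,
            ))
    return out


def gen_chase_dataset(
    params: NetworkParameters,
    noise: NoiseModel,
    timepoints=CHASE_TIMEPOINTS,
) -> pd.DataFrame:
    """Simulate a cycloheximide chase and emit a noisy protein decay table
    (columns: species, replicate, time_h, signal)."""
    grid = np.asarray(timepoints, dtype=float)
    traj = simulate_chase(params, t_max=float(grid[-1]))
    rng = np.random.default_rng(noise.seed)
    rows = []
    for species in ("MYC", "IRF4", "PRDM1"):
        truth = traj.series_at(species, "protein", grid)
        mult = noise.multipliers(rng, (noise.n_replicates, grid.size))
        signal = truth[None, :] * mult
        for r in range(noise.n_replicates):
            for j, t in enumerate(grid):
                rows.append({"species": species, "replicate": r,
                             "time_h": t, "signal": signal[r, j]})
    return pd.DataFrame(rows, columns=["species", "replicate", "time_h", "signal"])


def gen_viability(
    ic50_uM: float,
    doses_uM,
    *,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    noise_sd_pct: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    drug: str = "synthetic-drug",
    cell_line: str = "synthetic",
) -> DoseResponseCurve:
    """Evaluate a 4PL at the given doses and add Gaussian noise on the
    percent-survival scale."""
    d = np.asarray(doses_uM, dtype=float)
    truth = four_param_logistic(d, ic50_uM, hill, top, bottom)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd_pct, (n_replicates, d.size)) if noise_sd_pct > 0 \
        else np.zeros((n_replicates, d.size))
    return DoseResponseCurve(drug=drug, cell_line=cell_line, doses_uM=d,
                             responses=truth[None, :] + noise)


def viability_to_frame(curve: DoseResponseCurve) -> pd.DataFrame:
    rows = []
    for r in range(curve.responses.shape[0]):
        for j, d in enumerate(curve.doses_uM):
            rows.append({"drug": curve.drug, "cell_line": curve.cell_line,
                         "replicate": r, "dose_uM": d,
                         "survival_pct": curve.responses[r, j]})
    return pd.DataFrame(rows, columns=["drug", "cell_line", "replicate", "dose_uM", "survival_pct"])
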