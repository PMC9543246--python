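"""Model-data comparison: fold-change normalization, replicate summaries,
per-timepoint squared distances and drug-target scenario ranking.

Experimental readouts (qPCR ratios, western densitometry) arrive in
arbitrary positive units; each replicate is divided by its own first
timepoint so every series starts at 1, matching the model's fold-change
units.  The goodness-of-fit readout is the squared distance
``(model_t - mean_data_t)^2`` per timepoint, summed per species/analyte,
and — for ranking the drug-target hypotheses (MYC transcription, IRF4
transcription, or both) — summed with equal weights into a grand total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .network import (
    SPECIES,
    DrugPerturbation,
    NetworkParameters,
    Trajectory,
    simulate,
)

__all__ = [
    "ExperimentalSeries",
    "DiscrepancyEntry",
    "DiscrepancyReport",
    "SCENARIOS",
    "fold_change_normalize",
    "summarize_replicates",
    "squared_distance",
    "compare_scenarios",
    "read_dataset",
    "write_dataset",
]

#: Drug-target scenarios; label -> targeted transcription reactions.
SCENARIOS: dict[str, tuple[str, ...]] = {
    "MYC": ("MYC",),
    "IRF4": ("IRF4",),
    "MYC+IRF4": ("MYC", "IRF4"),
}


@dataclass(frozen=True)
class ExperimentalSeries:
    """Replicate measurements of one analyte/species over timepoints.

    ``values`` is a (replicate x timepoint) matrix in arbitrary positive
    units (or fold units once normalized).
    """

    cell_line: str
    drug: str
    species: str
    analyte: str  # "mRNA" | "protein"
    timepoints: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.analyte not in ("mRNA", "protein"):
            raise ValueError(f"analyte must be 'mRNA' or 'protein', got {self.analyte!r}")
        if v.shape[0] < 1 or v.shape[1] != t.size:
            raise ValueError("values must be (n_replicates, n_timepoints) matching the grid")
        if not np.all(np.diff(t) > 0):
            raise ValueError("timepoints must be strictly increasing")
        object.__setattr__(self, "timepoints", t)
        object.__setattr__(self, "values", v)

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]


def fold_change_normalize(series: ExperimentalSeries) -> ExperimentalSeries:
    """Divide each replicate by its own first-timepoint value.

    After normalization the first timepoint is exactly 1 in every
    replicate.  Idempotent on already-normalized data.
    """
    first = series.values[:, 0]
    bad = np.flatnonzero(first <= 0)
    if bad.size:
        raise ValueError(
            f"cannot fold-change normalize {series.species} {series.analyte}: "
            f"replicate(s) {bad.tolist()} have nonpositive first-timepoint value"
        )
    return replace(series, values=series.values / first[:, None])


def summarize_replicates(series: ExperimentalSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-timepoint arithmetic mean and sample SD (n-1 denominator).

    A single-replicate series yields SD 0 with a warning.
    """
    mean = series.values.mean(axis=0)
    if series.n_replicates < 2:
        warnings.warn(
            f"{series.species} {series.analyte}: single replicate, SD reported as 0",
            UserWarning, stacklevel=2,
        )
        sd = np.zeros_like(mean)
    else:
        sd = series.values.std(axis=0, ddof=1)
    return mean, sd


@dataclass(frozen=True)
class DiscrepancyEntry:
    """Squared distances for one (species, analyte) series."""

    species: str
    analyte: str
    timepoints: np.ndarray
    sq_dist: np.ndarray

    @property
    def total(self) -> float:
        return float(self.sq_dist.sum())


@dataclass
class DiscrepancyReport:
    """Per-series squared distances plus their grand total, for one scenario."""

    scenario: str
    entries: list[DiscrepancyEntry] = field(default_factory=list)

    @property
    def grand_total(self) -> float:
        return float(sum(e.total for e in self.entries))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            for t, d in zip(e.timepoints, e.sq_dist):
                rows.append({"scenario": self.scenario, "species": e.species,
                             "analyte": e.analyte, "time_h": t, "sq_dist": d})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "grand_total": self.grand_total,
            "entries": [
                {"species": e.species, "analyte": e.analyte,
                 "time_h": e.timepoints.tolist(), "sq_dist": e.sq_dist.tolist(),
                 "total": e.total}
                for e in self.entries
            ],
        }


def squared_distance(model: Trajectory, data_mean, timepoints,
                     species: str, analyte: str) -> DiscrepancyEntry:
    """Per-timepoint ``(model - mean data)^2`` for one species/analyte.

    Model values at data timepoints come from the solver's dense output;
    timepoints outside the simulated span raise (no extrapolation).
    """
    t = np.asarray(timepoints, dtype=float)
    mean = np.asarray(data_mean, dtype=float)
    if t.shape != mean.shape:
        raise ValueError("data mean and timepoints must have the same length")
    model_vals = model.series_at(species, analyte, t)
    return DiscrepancyEntry(species=species, analyte=analyte, timepoints=t,
                            sq_dist=(model_vals - mean) ** 2)


def compare_scenarios(
    params: NetworkParameters,
    dataset: list[ExperimentalSeries],
    *,
    epsilon: float = 0.8,
    scenarios: dict[str, tuple[str, ...]] | None = None,
    normalize: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> list[DiscrepancyReport]:
    """Score each drug-target scenario against a dataset and rank them.

    Each scenario is simulated once over the dataset's timepoint span with
    the given inhibition fraction, compared with the replicate mean of
    every (normalized) series, and the reports are returned sorted by
    grand total ascending; ties break by lexicographic scenario label.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    scenarios = scenarios if scenarios is not None else SCENARIOS
    t_max = max(float(s.timepoints[-1]) for s in dataset)
    prepared = []
    for s in dataset:
        ns = fold_change_normalize(s) if normalize else s
        mean = ns.values.mean(axis=0)
        prepared.append((ns, mean))

    reports = []
    for label, targets in scenarios.items():
        if targets:
            pert = DrugPerturbation(targets=targets, epsilon=epsilon)
        else:
            pert = None
        traj = simulate(params, pert, t_max=t_max, rtol=rtol, atol=atol)
        report = DiscrepancyReport(scenario=label)
        for ns, mean in prepared:
            report.entries.append(
                squared_distance(traj, mean, ns.timepoints, ns.species, ns.analyte)
            )
        reports.append(report)
    reports.sort(key=lambda r: (r.grand_total, r.scenario))
    return reports


# ---------------------------------------------------------------------------
# dataset CSV I/O (columns: cell_line, drug, species, analyte, replicate,
# time_h, value)

DATASET_COLUMNS = ["cell_line", "drug", "species", "analyte", "replicate", "time_h", "value"]


def read_dataset(path) -> list[ExperimentalSeries]:
    df = pd.read_csv(path, comment="#")
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dataset missing columns: {sorted(missing)}")
    out = []
    for (cell, drug, sp, an), grp in df.groupby(
            ["cell_line", "drug", "species", "analyte"], sort=True):
        wide = grp.pivot_table(index="replicate", columns="time_h",
                               values="value", sort=True)
        if wide.isna().any().any():
            raise ValueError(
                f"replicates of {sp} {an} ({cell}, {drug}) do not share a timepoint grid"
            )
        out.append(ExperimentalSeries(
            cell_line=cell, drug=drug, species=sp, analyte=an,
            timepoints=wide.columns.to_numpy(dtype=float),
            values=wide.to_numpy(dtype=float),
        ))
    return out


def write_dataset(dataset: list[ExperimentalSeries], path) -> None:
    rows = []
    for s in dataset:
        for r in range(s.n_replicates):
            for j, t in enumerate(s.timepoints):
                rows.append({"cell_line": s.cell_line, "drug": s.drug,
                             "species": s.species, "analyte": s.analyte,
                             "replicate": r, "time_h": t,
                             "value": s.values[r, j]})
    pd.DataFrame(rows, columns=DATASET_COLUMNS).to_csv(path, index=False)
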