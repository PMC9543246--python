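"""ODE model of the IRF4-MYC-PRDM1 regulatory network in multiple myeloma.

The model tracks six state variables — mRNA and protein for each of MYC,
IRF4 and PRDM1 — in dimensionless fold units, normalized so that the
unperturbed steady state is exactly 1 for every variable.  Kinetics are
two-stage (transcription then translation) with first-order turnover:

    d(mRNA_X)/dt    = k_m,X * drug_X(t) * prod_e g_e(protein_source(e))
                      - gamma_m,X * mRNA_X
    d(protein_X)/dt = k_p,X * mRNA_X - gamma_p,X * protein_X

Degradation rates derive from half-lives (gamma = ln2 / t_half) and the
synthesis constants are fixed by the fold-change normalization
(k_m = gamma_m, k_p = gamma_p), so with every regulator at 1 and no drug
the all-ones state is an exact fixed point.

Regulatory edges (IRF4 and MYC transactivate each other, IRF4 activates
itself and PRDM1, PRDM1 represses MYC) enter as multiplicative Hill-type
factors on the target's transcription rate, each normalized so that
g(1) = 1.  For an edge with threshold ``K``, Hill coefficient ``h`` and
maximum fold effect ``w``:

* activation:  g(x) = (1 - a) + a * x^h (1 + K^h) / (x^h + K^h),
  with a = (w - 1) / K^h, so g(0) = 1 - a (basal floor), g(1) = 1 and
  g(inf) = w.  Requires w <= 1 + K^h.
* repression:  g(x) = (1 - b) + b * (1 + K^h) / (K^h + x^h),
  with b = (w - 1) * K^h, so g(0) = w, g(1) = 1 and g(inf) = 1 - b.
  Requires w <= 1 + K^(-h).

With the default K = 1, h = 1, w = 2 these reduce to the fully-scaled
Hill forms 2x/(1+x) and 2/(1+x).

A drug acting on the transcription of MYC, IRF4 or both multiplies the
targeted synthesis term by (1 - epsilon) from its onset time onward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "SPECIES",
    "STATE_COLUMNS",
    "PRESETS",
    "RegulationEdge",
    "NetworkParameters",
    "DrugPerturbation",
    "Trajectory",
    "build_parameters",
    "default_edges",
    "regulation_factor",
    "simulate",
    "simulate_chase",
]

LN2 = math.log(2.0)

#: The three modeled species, in canonical (state-vector and CSV) order.
SPECIES = ("MYC", "IRF4", "PRDM1")

#: Column order of the 6-dimensional state: mRNA then protein per species.
STATE_COLUMNS = (
    "MYC_mRNA", "MYC_protein",
    "IRF4_mRNA", "IRF4_protein",
    "PRDM1_mRNA", "PRDM1_protein",
)

#: Protein half-lives (hours) per documented preset.  MYC values of 22 and
#: 30 min are stored as exact rational hours.  mRNA half-lives and the
#: PRDM1 protein half-life are model assumptions (see docs/methods.md).
PRESETS: dict[str, dict[str, float]] = {
    "initial_model": {"MYC": 0.5, "IRF4": 7.0, "PRDM1": 7.0},
    "updated_model": {"MYC": 0.5, "IRF4": 48.0, "PRDM1": 7.0},
    "KMS-12-BM": {"MYC": 1.0, "IRF4": 61.0, "PRDM1": 7.0},
    "NCI-H929": {"MYC": 22.0 / 60.0, "IRF4": 52.0, "PRDM1": 7.0},
    "SKMM-1": {"MYC": 0.5, "IRF4": 33.0, "PRDM1": 7.0},
}

DEFAULT_MRNA_HALF_LIFE = {"MYC": 0.5, "IRF4": 2.0, "PRDM1": 2.0}


def minutes_to_hours(minutes: float) -> float:
    """Convert minutes to hours (exact up to float division)."""
    return minutes / 60.0


def hours_to_minutes(hours: float) -> float:
    return hours * 60.0


@dataclass(frozen=True)
class RegulationEdge:
    """One regulatory interaction: source protein acts on target transcription.

    Parameters
    ----------
    source, target : str
        Species names; the *protein* of ``source`` regulates transcription
        of ``target``.
    sign : {"activation", "repression"}
    K : float
        Half-effect threshold in fold units (> 0).
    h : float
        Hill coefficient (> 0).
    w : float
        Maximum fold effect of the edge (>= 1); bounded above by
        ``1 + K**h`` (activation) or ``1 + K**-h`` (repression) so the
        normalized form stays a convex combination.
    """

    source: str
    target: str
    sign: str
    K: float = 1.0
    h: float = 1.0
    w: float = 2.0

    def __post_init__(self) -> None:
        if self.source not in SPECIES or self.target not in SPECIES:
            raise ValueError(
                f"edge {self.source}->{self.target}: species must be one of {SPECIES}"
            )
        if self.sign not in ("activation", "repression"):
            raise ValueError(f"edge sign must be 'activation' or 'repression', got {self.sign!r}")
        if not (self.K > 0 and math.isfinite(self.K)):
            raise ValueError(f"edge {self.source}->{self.target}: K must be positive, got {self.K}")
        if not (self.h > 0 and math.isfinite(self.h)):
            raise ValueError(f"edge {self.source}->{self.target}: h must be positive, got {self.h}")
        if self.w < 1:
            raise ValueError(f"edge {self.source}->{self.target}: fold strength w must be >= 1, got {self.w}")
        w_max = 1.0 + (self.K ** self.h if self.sign == "activation" else self.K ** -self.h)
        if self.w > w_max + 1e-12:
            raise ValueError(
                f"edge {self.source}->{self.target}: w={self.w} exceeds the admissible "
                f"maximum {w_max} for sign={self.sign}, K={self.K}, h={self.h}"
            )


def default_edges() -> tuple[RegulationEdge, ...]:
    """The documented network topology.

    MYC and IRF4 transactivate each other, IRF4 activates its own promoter
    and PRDM1, and PRDM1 protein represses MYC transcription.
    """
    return (
        RegulationEdge("MYC", "IRF4", "activation"),
        RegulationEdge("IRF4", "MYC", "activation"),
        RegulationEdge("IRF4", "IRF4", "activation"),
        RegulationEdge("IRF4", "PRDM1", "activation"),
        RegulationEdge("PRDM1", "MYC", "repression"),
    )


def regulation_factor(edge: RegulationEdge, regulator_level: float) -> float:
    """Multiplicative factor an edge applies to its target's transcription.

    Normalized so the factor is exactly 1 when the regulator sits at its
    unperturbed steady-state level of 1 (see module docstring for the
    algebra).  Activation is non-decreasing in the regulator, repression
    non-increasing.
    """
    x = regulator_level
    if x < 0:
        raise ValueError(f"regulator level must be >= 0, got {x}")
    Kh = edge.K ** edge.h
    xh = x ** edge.h
    if edge.sign == "activation":
        a = (edge.w - 1.0) / Kh
        base = xh * (1.0 + Kh) / (xh + Kh)
        return (1.0 - a) + a * base
    b = (edge.w - 1.0) * Kh
    base = (1.0 + Kh) / (Kh + xh)
    return (1.0 - b) + b * base


@dataclass(frozen=True)
class NetworkParameters:
    """Kinetic constants and topology of the network model.

    Half-lives are in hours.  Degradation rates are derived exactly as
    gamma = ln2 / t_half; synthesis constants equal the matching
    degradation rate (fold-unit normalization), so they are not stored.
    """

    protein_half_life: dict[str, float]
    mrna_half_life: dict[str, float]
    edges: tuple[RegulationEdge, ...] = field(default_factory=default_edges)
    preset: str | None = None

    def __post_init__(self) -> None:
        for tier, table in (("protein", self.protein_half_life), ("mRNA", self.mrna_half_life)):
            for s in SPECIES:
                if s not in table:
                    raise ValueError(f"missing {tier} half-life for {s}")
                t = table[s]
                if not (isinstance(t, (int, float)) and math.isfinite(t) and t > 0):
                    raise ValueError(f"{tier} half-life for {s} must be a positive finite number, got {t!r}")
        for e in self.edges:
            if e.source not in SPECIES or e.target not in SPECIES:
                raise ValueError(f"edge references undefined species: {e.source}->{e.target}")

    @property
    def gamma_p(self) -> dict[str, float]:
        """Protein degradation rates, per hour."""
        return {s: LN2 / self.protein_half_life[s] for s in SPECIES}

    @property
    def gamma_m(self) -> dict[str, float]:
        """mRNA degradation rates, per hour."""
        return {s: LN2 / self.mrna_half_life[s] for s in SPECIES}

    # synthesis constants fixed by the steady-state normalization
    @property
    def k_m(self) -> dict[str, float]:
        return self.gamma_m

    @property
    def k_p(self) -> dict[str, float]:
        return self.gamma_p

    def with_protein_half_life(self, species: str, hours: float) -> "NetworkParameters":
        table = dict(self.protein_half_life)
        table[species] = hours
        return replace(self, protein_half_life=table, preset=None)


def build_parameters(
    preset: str | None = None,
    *,
    protein_half_life: dict[str, float] | None = None,
    mrna_half_life: dict[str, float] | None = None,
    edges: tuple[RegulationEdge, ...] | None = None,
) -> NetworkParameters:
    """Assemble :class:`NetworkParameters` from a preset and/or overrides.

    Explicit half-lives override the preset; unspecified values fall back
    to the preset (protein) or the documented defaults (mRNA).

    Raises
    ------
    ValueError
        For an unknown preset (the message lists valid presets) or a
        nonpositive/missing half-life (the message names the field).
    """
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; valid presets: {sorted(PRESETS)}")
        protein = dict(PRESETS[preset])
    else:
        protein = dict(PRESETS["updated_model"])
    if protein_half_life:
        protein.update(protein_half_life)
    mrna = dict(DEFAULT_MRNA_HALF_LIFE)
    if mrna_half_life:
        mrna.update(mrna_half_life)
    return NetworkParameters(
        protein_half_life=protein,
        mrna_half_life=mrna,
        edges=tuple(edges) if edges is not None else default_edges(),
        preset=preset,
    )


@dataclass(frozen=True)
class DrugPerturbation:
    """A drug inhibiting transcription of MYC, IRF4 or both.

    ``epsilon`` is the inhibition fraction in [0, 1] applied per target
    (0 = no effect, 1 = complete transcriptional block); the targeted
    synthesis terms are multiplied by (1 - epsilon) from ``onset_h``
    onward.
    """

    targets: tuple[str, ...]
    epsilon: float = 0.8
    onset_h: float = 0.0

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("perturbation must target at least one transcription reaction")
        for t in self.targets:
            if t not in ("MYC", "IRF4"):
                raise ValueError(f"drug targets must be in ('MYC', 'IRF4'), got {t!r}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"inhibition fraction must lie in [0, 1], got {self.epsilon}")
        if self.onset_h < 0:
            raise ValueError(f"onset time must be >= 0, got {self.onset_h}")

    @classmethod
    def myc(cls, epsilon: float = 0.8, onset_h: float = 0.0) -> "DrugPerturbation":
        return cls(("MYC",), epsilon, onset_h)

    @classmethod
    def irf4(cls, epsilon: float = 0.8, onset_h: float = 0.0) -> "DrugPerturbation":
        return cls(("IRF4",), epsilon, onset_h)

    @classmethod
    def both(cls, epsilon: float = 0.8, onset_h: float = 0.0) -> "DrugPerturbation":
        return cls(("MYC", "IRF4"), epsilon, onset_h)


@dataclass
class Trajectory:
    """A simulated time course of all six state variables, in fold units.

    ``values`` has one row per grid time and one column per entry of
    :data:`STATE_COLUMNS`.  ``at(t)`` evaluates the solver's dense output
    (no extrapolation outside the simulated span).
    """

    time: np.ndarray
    values: np.ndarray
    params: NetworkParameters
    perturbation: DrugPerturbation | None = None
    _interp: object = None  # callable t -> state vector(s)

    @property
    def columns(self) -> tuple[str, ...]:
        return STATE_COLUMNS

    def at(self, t) -> np.ndarray:
        """Dense-output state at arbitrary time(s) within the simulated span."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.time[0], self.time[-1]
        if np.any(t < lo - 1e-12) or np.any(t > hi + 1e-12):
            raise ValueError(f"requested time outside simulated range [{lo}, {hi}]")
        if self._interp is None:
            raise ValueError("trajectory carries no dense interpolant")
        out = np.stack([np.clip(self._interp(ti), 0.0, None) for ti in t])
        return out

    def series(self, species: str, analyte: str) -> np.ndarray:
        """One state variable's grid values; analyte is 'mRNA' or 'protein'."""
        return self.values[:, STATE_COLUMNS.index(f"{species}_{analyte}")]

    def series_at(self, species: str, analyte: str, t) -> np.ndarray:
        return self.at(t)[:, STATE_COLUMNS.index(f"{species}_{analyte}")]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(STATE_COLUMNS))
        df.insert(0, "time_h", self.time)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _validate_grid(time_grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(time_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("time grid must be a 1-D array with at least two points")
    if grid[0] != 0.0:
        raise ValueError(f"time grid must start at 0, got {grid[0]}")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("time grid must be strictly increasing")
    return grid


def _make_rhs(params: NetworkParameters, drug_factor: dict[str, float]):
    gm = np.array([params.gamma_m[s] for s in SPECIES])
    gp = np.array([params.gamma_p[s] for s in SPECIES])
    dvec = np.array([drug_factor.get(s, 1.0) for s in SPECIES])
    edges_by_target = [
        [(STATE_COLUMNS.index(f"{e.source}_protein"), e) for e in params.edges if e.target == s]
        for s in SPECIES
    ]

    def rhs(t, y):
        dy = np.empty(6)
        for i in range(3):
            reg = 1.0
            for idx, e in edges_by_target[i]:
                # transient tiny negatives from the solver are clamped for
                # evaluation only; state itself is never clipped in-solver
                reg *= regulation_factor(e, y[idx] if y[idx] > 0.0 else 0.0)
            mi, pi = 2 * i, 2 * i + 1
            dy[mi] = gm[i] * dvec[i] * reg - gm[i] * y[mi]
            dy[pi] = gp[i] * y[mi] - gp[i] * y[pi]
        return dy

    return rhs


def _integrate(rhs, t0, t1, y0, rtol, atol):
    sol = solve_ivp(
        rhs, (t0, t1), y0, method="LSODA",
        rtol=rtol, atol=atol, dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed on [{t0}, {t1}]: {sol.message}")
    return sol


def simulate(
    params: NetworkParameters,
    perturbation: DrugPerturbation | None = None,
    time_grid=None,
    *,
    t_max: float = 72.0,
    n_points: int = 289,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the network ODEs from the all-ones steady state.

    With no perturbation the trajectory stays at the fixed point; with a
    drug, targeted transcription is multiplied by (1 - epsilon) from the
    onset time (a hard switch; the integrator is restarted there).
    Solution is reported on ``time_grid`` (default: uniform grid on
    [0, t_max]) with a dense interpolant retained for off-grid queries.
    """
    grid = _validate_grid(time_grid if time_grid is not None else np.linspace(0.0, t_max, n_points))
    y0 = np.ones(6)
    t_end = float(grid[-1])

    if perturbation is None or perturbation.epsilon == 0.0:
        segments = [(0.0, t_end, {})]
    else:
        factor = {t: 1.0 - perturbation.epsilon for t in perturbation.targets}
        onset = perturbation.onset_h
        if onset <= 0.0:
            segments = [(0.0, t_end, factor)]
        elif onset >= t_end:
            segments = [(0.0, t_end, {})]
        else:
            segments = [(0.0, onset, {}), (onset, t_end, factor)]

    sols = []
    y = y0
    for t0, t1, factor in segments:
        sol = _integrate(_make_rhs(params, factor), t0, t1, y, rtol, atol)
        sols.append(sol)
        y = sol.y[:, -1]

    def interp(t: float) -> np.ndarray:
        for sol in sols:
            if t <= sol.t[-1] + 1e-12:
                return sol.sol(min(t, sol.t[-1]))
        return sols[-1].sol(sols[-1].t[-1])

    values = np.clip(np.stack([interp(t) for t in grid]), 0.0, None)
    return Trajectory(time=grid, values=values, params=params,
                      perturbation=perturbation, _interp=interp)


def simulate_chase(
    params: NetworkParameters,
    time_grid=None,
    *,
    t_max: float = 72.0,
    n_points: int = 289,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Simulate a cycloheximide chase: translation arrested from t = 0.

    With all translation rates k_p set to 0, each protein obeys
    dp/dt = -gamma_p p and so decays as exp(-gamma_p t) exactly; protein
    values are therefore taken from the closed form.  mRNA dynamics
    continue unchanged, driven by the decaying regulator proteins, and
    are integrated numerically.
    """
    grid = _validate_grid(time_grid if time_grid is not None else np.linspace(0.0, t_max, n_points))
    gp = np.array([params.gamma_p[s] for s in SPECIES])
    gm = np.array([params.gamma_m[s] for s in SPECIES])
    edges_by_target = [
        [(SPECIES.index(e.source), e) for e in params.edges if e.target == s]
        for s in SPECIES
    ]

    def rhs(t, m):
        dm = np.empty(3)
        prot = np.exp(-gp * t)
        for i in range(3):
            reg = 1.0
            for src, e in edges_by_target[i]:
                reg *= regulation_factor(e, prot[src])
            dm[i] = gm[i] * reg - gm[i] * m[i]
        return dm

    sol = _integrate(rhs, 0.0, float(grid[-1]), np.ones(3), rtol, atol)

    def interp(t: float) -> np.ndarray:
        y = np.empty(6)
        m = sol.sol(min(t, sol.t[-1]))
        y[0::2] = m
        y[1::2] = np.exp(-gp * t)
        return y

    values = np.clip(np.stack([interp(t) for t in grid]), 0.0, None)
    return Trajectory(time=grid, values=values, params=params,
                      perturbation=None, _interp=interp)
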