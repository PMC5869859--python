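"""Stochastic update rules and the simulation time loop.

One time unit is one day. At each time unit every cell is visited once (by
default in a fresh random order) and the rule matching its state *at visit
time* is applied, in place:

1. R  → PS on a successful induction draw (mode-dependent, see below);
2. PS → its timer advances; after ``t_i`` time units in PS it becomes S;
3. S  → each currently-resting Moore neighbour independently becomes PS
        with probability ``p_bys`` (the SASP bystander effect);
4. S  → if at least ``S_n`` neighbours are senescent, the cell is cleared to
        E with probability ``p_clr`` (quorum-gated immune clearance);
5. E  → repopulated to R with probability ``p_new``.

Rules 3 and 4 are both evaluated on a senescent cell's visit, bystander
conversion first; the quorum count uses the lattice state at evaluation
time. Updates are asynchronous: a conversion made earlier in a time unit is
visible to cells visited later in the same unit.

Induction modes: ``irradiation_day1`` draws induction once for every resting
cell at time unit 1 (an acute irradiation protocol); ``stochastic_entry``
gives every resting cell an independent chance ``p_trigger`` per time unit
of experiencing a damage event that triggers an induction draw; ``none``
disables induction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .induction import InductionSpec, draw_induction
from .lattice import (
    BOUNDARY_FIXED,
    CellState,
    Lattice,
    SN_PER_CELL_HALF,
    build_lattice,
    quorum_array,
)

__all__ = [
    "SimulationParams",
    "Trajectory",
    "EnsembleResult",
    "ConfigError",
    "StepStats",
    "step",
    "run",
    "run_ensemble",
    "replicate_seed",
]

INDUCTION_IRRADIATION_DAY1 = "irradiation_day1"
INDUCTION_STOCHASTIC_ENTRY = "stochastic_entry"
INDUCTION_NONE = "none"

ORDER_RANDOM_PERMUTATION = "random_permutation"
ORDER_RASTER = "raster"

_R = int(CellState.RESTING)
_PS = int(CellState.PRE_SENESCENT)
_S = int(CellState.SENESCENT)
_E = int(CellState.EMPTY)


class ConfigError(ValueError):
    """Raised for invalid or mutually inconsistent simulation parameters."""


@dataclass
class SimulationParams:
    """Everything that defines one simulation run.

    Probabilities are per time unit (per exposure for ``p_bys``); defaults
    are the reference parameterisation used throughout: ``p_new`` = 0.5,
    ``p_clr`` = 0.4, ``p_bys`` = 0.2, ``t_i`` = 10 days, stochastic-entry
    trigger 0.02.
    """

    dims: tuple[int, ...] = (10, 10)
    n_steps: int = 250
    p_bys: float = 0.2
    p_clr: float = 0.4
    p_new: float = 0.5
    t_i: int = 10
    induction_mode: str = INDUCTION_IRRADIATION_DAY1
    p_trigger: float = 0.02
    induction: InductionSpec = field(default_factory=InductionSpec)
    s_n_policy: str = SN_PER_CELL_HALF
    boundary: str = BOUNDARY_FIXED
    update_order: str = ORDER_RANDOM_PERMUTATION
    seed: int = 0

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)
        for name in ("p_bys", "p_clr", "p_new", "p_trigger"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.t_i < 1:
            raise ConfigError(f"t_i must be >= 1, got {self.t_i}")
        if self.n_steps < 1:
            raise ConfigError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.induction_mode not in (
            INDUCTION_IRRADIATION_DAY1,
            INDUCTION_STOCHASTIC_ENTRY,
            INDUCTION_NONE,
        ):
            raise ConfigError(f"unknown induction_mode {self.induction_mode!r}")
        if self.update_order not in (ORDER_RANDOM_PERMUTATION, ORDER_RASTER):
            raise ConfigError(f"unknown update_order {self.update_order!r}")


@dataclass
class StepStats:
    """Counters accumulated across steps (induction-rate diagnostics).

    ``resting_exposures`` counts resting cells that were eligible for a
    stochastic-entry damage event; ``induction_triggers`` counts the events
    that fired (whether or not the induction draw then committed the cell).
    """

    resting_exposures: int = 0
    induction_triggers: int = 0
    induction_draws: int = 0
    induction_commits: int = 0


@dataclass
class Trajectory:
    """Per-time-unit state counts for one run, including t = 0."""

    times: np.ndarray
    counts: np.ndarray  # shape (n_steps + 1, 4), columns R, PS, S, E
    seed: int
    params: SimulationParams
    stats: StepStats = field(default_factory=StepStats)

    @property
    def n_sites(self) -> int:
        return int(self.counts[0].sum())

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.n_sites

    def fraction_of(self, state: CellState) -> np.ndarray:
        return self.fractions[:, int(state)]

    def to_dataframe(self) -> pd.DataFrame:
        frac = self.fractions
        return pd.DataFrame(
            {
                "t": self.times,
                "R": self.counts[:, _R],
                "PS": self.counts[:, _PS],
                "S": self.counts[:, _S],
                "E": self.counts[:, _E],
                "frac_R": frac[:, _R],
                "frac_PS": frac[:, _PS],
                "frac_S": frac[:, _S],
                "frac_E": frac[:, _E],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")


@dataclass
class EnsembleResult:
    """Replicate trajectories plus per-time mean/SD of state fractions."""

    trajectories: list[Trajectory]
    mean_fractions: np.ndarray  # (n_steps + 1, 4)
    sd_fractions: np.ndarray  # zeros when n_replicates == 1
    base_seed: int

    @property
    def n_replicates(self) -> int:
        return len(self.trajectories)

    @property
    def times(self) -> np.ndarray:
        return self.trajectories[0].times

    def mean_fraction_of(self, state: CellState) -> np.ndarray:
        return self.mean_fractions[:, int(state)]

    def summary_dataframe(self) -> pd.DataFrame:
        cols = {"t": self.times}
        for state, name in zip(CellState, ("R", "PS", "S", "E")):
            cols[f"mean_frac_{name}"] = self.mean_fractions[:, int(state)]
            cols[f"sd_frac_{name}"] = self.sd_fractions[:, int(state)]
        return pd.DataFrame(cols)

    def write_summary_csv(self, path: str | Path) -> None:
        self.summary_dataframe().to_csv(path, index=False, float_format="%.10g")


def step(
    lattice: Lattice,
    params: SimulationParams,
    rng: np.random.Generator,
    t: int = 1,
    stats: StepStats | None = None,
    _quorum: np.ndarray | None = None,
) -> Lattice:
    """Advance the lattice by one time unit, mutating it in place.

    ``t`` is the time unit this step produces; irradiation-day-1 induction
    fires only when ``t == 1``. Returns the (mutated) lattice.
    """
    if tuple(lattice.dims) != params.dims:
        raise ConfigError(
            f"lattice dims {lattice.dims} do not match params dims {params.dims}"
        )
    n = lattice.n_sites
    states = lattice.states.reshape(-1)
    timers = lattice.ps_timer.reshape(-1)
    neighbors = lattice.neighbor_flat_indices()
    quorum = _quorum if _quorum is not None else quorum_array(lattice, params.s_n_policy)

    if params.update_order == ORDER_RANDOM_PERMUTATION:
        order = rng.permutation(n)
    else:
        order = np.arange(n)

    irradiating = (
        params.induction_mode == INDUCTION_IRRADIATION_DAY1 and t == 1
    )
    stochastic = params.induction_mode == INDUCTION_STOCHASTIC_ENTRY

    for i in order:
        s = states[i]
        if s == _R:
            if irradiating:
                if stats is not None:
                    stats.induction_draws += 1
                if draw_induction(params.induction, rng):
                    states[i] = _PS
                    timers[i] = 0
                    if stats is not None:
                        stats.induction_commits += 1
            elif stochastic:
                if stats is not None:
                    stats.resting_exposures += 1
                if rng.random() < params.p_trigger:
                    if stats is not None:
                        stats.induction_triggers += 1
                        stats.induction_draws += 1
                    if draw_induction(params.induction, rng):
                        states[i] = _PS
                        timers[i] = 0
                        if stats is not None:
                            stats.induction_commits += 1
        elif s == _PS:
            timers[i] += 1
            if timers[i] >= params.t_i:
                states[i] = _S
                timers[i] = 0
        elif s == _S:
            nb = neighbors[i]
            if params.p_bys > 0.0 and nb.size:
                nb_states = states[nb]
                resting = nb[nb_states == _R]
                if resting.size:
                    converted = resting[rng.random(resting.size) < params.p_bys]
                    if converted.size:
                        states[converted] = _PS
                        timers[converted] = 0
            n_sen = int(np.count_nonzero(states[nb] == _S))
            if n_sen >= quorum[i] and params.p_clr > 0.0:
                if rng.random() < params.p_clr:
                    states[i] = _E
        else:  # EMPTY
            if params.p_new > 0.0 and rng.random() < params.p_new:
                states[i] = _R
    return lattice


def run(
    params: SimulationParams,
    initial_lattice: Lattice | None = None,
    snapshot_times: Sequence[int] | None = None,
) -> Trajectory | tuple[Trajectory, list[tuple[int, Lattice]]]:
    """Run a full simulation from an all-resting lattice (or a caller-supplied
    one) and record state counts at every time unit including t = 0.

    Deterministic given ``params.seed``. When ``snapshot_times`` is given,
    copies of the lattice at those times are returned alongside the
    trajectory.
    """
    rng = np.random.default_rng(params.seed)
    if (
        params.induction_mode != INDUCTION_NONE
        and params.induction.mode == "marker_surrogate"
        and params.induction.thresholds is None
    ):
        # Self-calibrate once per run, from a dedicated reference population,
        # so that P_ind is homogeneous across the lattice.
        params.induction.calibrate(rng)
    if initial_lattice is None:
        lattice = build_lattice(params.dims, CellState.RESTING, params.boundary)
    else:
        if tuple(initial_lattice.dims) != params.dims:
            raise ConfigError(
                f"initial lattice dims {initial_lattice.dims} do not match "
                f"params dims {params.dims}"
            )
        lattice = initial_lattice
    quorum = quorum_array(lattice, params.s_n_policy)
    stats = StepStats()

    n_states = 4
    counts = np.zeros((params.n_steps + 1, n_states), dtype=np.int64)
    counts[0] = np.bincount(lattice.states.reshape(-1), minlength=n_states)
    snaps: list[tuple[int, Lattice]] = []
    want = set(snapshot_times) if snapshot_times is not None else set()
    if 0 in want:
        snaps.append((0, lattice.copy()))
    for t in range(1, params.n_steps + 1):
        step(lattice, params, rng, t=t, stats=stats, _quorum=quorum)
        counts[t] = np.bincount(lattice.states.reshape(-1), minlength=n_states)
        if t in want:
            snaps.append((t, lattice.copy()))
    traj = Trajectory(
        times=np.arange(params.n_steps + 1),
        counts=counts,
        seed=params.seed,
        params=params,
        stats=stats,
    )
    if snapshot_times is not None:
        return traj, snaps
    return traj


def replicate_seed(base_seed: int, replicate: int) -> int:
    """Deterministic counter-based mix of (base seed, replicate index)."""
    return int((int(base_seed) * 1_000_003 + 7919 * int(replicate) + 1) % 2**31)


def run_ensemble(
    params: SimulationParams, n_replicates: int, base_seed: int
) -> EnsembleResult:
    """Run replicate simulations with seeds derived from ``base_seed`` and
    summarise per-time mean and SD of the state fractions.

    With a single replicate the SD is zero by convention.
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    trajectories = []
    for r in range(n_replicates):
        p = replace(params, seed=replicate_seed(base_seed, r))
        trajectories.append(run(p))
    fracs = np.stack([t.fractions for t in trajectories])
    mean = fracs.mean(axis=0)
    sd = fracs.std(axis=0, ddof=1) if n_replicates > 1 else np.zeros_like(mean)
    return EnsembleResult(
        trajectories=trajectories,
        mean_fractions=mean,
        sd_fractions=sd,
        base_seed=base_seed,
    )
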