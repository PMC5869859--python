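"""Synthetic fixtures: marker populations and in-vitro time series.

Two generators make every stage of the pipeline testable without external
data. ``generate_marker_population`` produces irradiated-population marker
trajectories for the induction layer's threshold classifier (with defaults
under which roughly 10% of cells exceed all four self-calibrated
thresholds). ``generate_invitro_series`` produces an observed
senescent-fraction time course by running the simulator itself in in-vitro
mode at a known true ``p_bys`` and adding Gaussian measurement noise — the
ground truth for parameter-recovery tests of the calibration scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import ObservedSeries, in_vitro_params, write_observed_csv
from .engine import (
    INDUCTION_IRRADIATION_DAY1,
    ConfigError,
    SimulationParams,
    run_ensemble,
)
from .induction import (
    InductionSpec,
    SurrogateParams,
    simulate_marker_population,
    write_marker_csv,
)
from .lattice import CellState

__all__ = ["SyntheticSpec", "generate_invitro_series", "generate_marker_population"]

KIND_MARKER_POPULATION = "marker_population"
KIND_INVITRO_SERIES = "invitro_series"

#: Plausible in-vitro sampling days for a month-long senescence time course.
DEFAULT_OBS_DAYS = (1, 5, 10, 15, 20, 25, 30)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic fixture.

    For ``invitro_series``: a 2D lattice is simulated in in-vitro mode
    (``p_clr = p_new = 0``) under day-1 irradiation induction with Bernoulli
    probability ``p_ind`` and the given true ``p_bys``; the ensemble-mean
    senescent fraction at ``days`` is observed with Gaussian noise of SD
    ``noise_sd`` (truncated to [0, 1]).

    For ``marker_population``: ``n_cells`` marker trajectories from the
    induction surrogate through day ``n_days``.
    """

    kind: str = KIND_INVITRO_SERIES
    seed: int = 0
    # in-vitro series parameters
    dims: tuple[int, int] = (10, 10)
    true_p_bys: float = 0.2
    p_ind: float = 0.1
    t_i: int = 10
    days: tuple[int, ...] = DEFAULT_OBS_DAYS
    noise_sd: float = 0.01
    n_replicates: int = 100
    # marker-population parameters
    n_cells: int = 1000
    n_days: int = 21
    surrogate_params: SurrogateParams = field(default_factory=SurrogateParams)

    def __post_init__(self) -> None:
        if self.kind not in (KIND_MARKER_POPULATION, KIND_INVITRO_SERIES):
            raise ConfigError(f"unknown synthetic fixture kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if len(self.days) == 0:
            raise ConfigError("days must be non-empty")
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")


def generate_invitro_series(spec: SyntheticSpec) -> ObservedSeries:
    """Simulate an observed in-vitro senescent-fraction time course.

    The emitted ``sd`` column equals ``noise_sd`` (omitted when the noise is
    zero, since a zero SD would make a weighted objective ill-defined).
    """
    if spec.kind != KIND_INVITRO_SERIES:
        raise ConfigError(f"spec kind is {spec.kind!r}, expected invitro_series")
    days = np.asarray(spec.days, dtype=int)
    base = SimulationParams(
        dims=spec.dims,
        n_steps=int(days.max()),
        p_bys=spec.true_p_bys,
        t_i=spec.t_i,
        induction_mode=INDUCTION_IRRADIATION_DAY1,
        induction=InductionSpec(mode="bernoulli", p_ind=spec.p_ind),
        seed=spec.seed,
    )
    params = in_vitro_params(base)
    ens = run_ensemble(params, spec.n_replicates, base_seed=spec.seed)
    mean_s = ens.mean_fractions[days, int(CellState.SENESCENT)]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 777_000_001)
        noisy = mean_s + rng.normal(0.0, spec.noise_sd, size=mean_s.size)
        observed = np.clip(noisy, 0.0, 1.0)
        sd = np.full(days.size, spec.noise_sd)
    else:
        observed = mean_s
        sd = None
    return ObservedSeries(days=days, senescent_fraction=observed, sd=sd)


def generate_marker_population(spec: SyntheticSpec) -> pd.DataFrame:
    """Simulate a marker-trajectory population (long-format frame)."""
    if spec.kind != KIND_MARKER_POPULATION:
        raise ConfigError(f"spec kind is {spec.kind!r}, expected marker_population")
    rng = np.random.default_rng(spec.seed)
    return simulate_marker_population(
        spec.surrogate_params, spec.n_cells, rng, n_days=spec.n_days
    )


def materialise_fixtures(spec_series: SyntheticSpec, spec_markers: SyntheticSpec,
                         out_dir: str | Path) -> dict[str, Path]:
    """Write both fixture kinds into a directory (CLI helper)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series_path = out_dir / "invitro_series.csv"
    markers_path = out_dir / "marker_population.csv"
    write_observed_csv(generate_invitro_series(spec_series), series_path)
    write_marker_csv(generate_marker_population(spec_markers), markers_path)
    return {"invitro_series": series_path, "marker_population": markers_path}
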