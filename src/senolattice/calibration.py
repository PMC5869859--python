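"""Chi-squared calibration of the bystander-effect probability.

The bystander probability ``p_bys`` is estimated by scanning a grid of
candidate values, simulating each candidate in *in-vitro mode* — a 2D
monolayer with immune clearance and repopulation switched off
(``p_clr = p_new = 0``), matching cultured cells with no immune system —
and scoring the ensemble-mean senescent fraction against an observed time
series with a chi-squared objective.

The scan deliberately reports the whole objective landscape, not just the
argmin: with data sampled near the population plateau, many values of
``p_bys`` fit almost equally well (the parameter is only weakly
identifiable from such data), and the landscape's flatness ratio makes that
visible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import ConfigError, SimulationParams, replicate_seed, run_ensemble
from .lattice import CellState

__all__ = [
    "ObservedSeries",
    "FitLandscape",
    "chi_squared",
    "in_vitro_params",
    "scan_pbys",
    "read_observed_csv",
    "write_observed_csv",
    "check_physiological_plausibility",
]

logger = logging.getLogger(__name__)

DEFAULT_PBYS_GRID = np.round(np.arange(0.0, 1.0001, 0.05), 10)


@dataclass
class ObservedSeries:
    """Observed senescent-fraction time course, optionally with per-day SD."""

    days: np.ndarray
    senescent_fraction: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.senescent_fraction = np.asarray(self.senescent_fraction, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if self.days.ndim != 1 or len(self.days) == 0:
            raise ValueError("days must be a non-empty 1D sequence")
        if len(self.senescent_fraction) != len(self.days):
            raise ValueError("days and senescent_fraction must have equal length")
        if self.sd is not None and len(self.sd) != len(self.days):
            raise ValueError("sd must match days in length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any((self.senescent_fraction < 0) | (self.senescent_fraction > 1)):
            raise ValueError("senescent fractions must lie in [0, 1]")
        if self.sd is not None and np.any(self.sd <= 0):
            raise ValueError("all sd values must be positive")


@dataclass
class FitLandscape:
    """Chi-squared objective over a grid of candidate ``p_bys`` values.

    ``chisq_mean`` is the objective evaluated on the ensemble-mean senescent
    fraction for each candidate (the quantity the argmin is taken over);
    ``chisq_sd`` is the spread of single-replicate objective values, an
    identifiability diagnostic. ``flatness`` is (max - min) / min of the
    objective across the grid — near zero means the data barely distinguish
    the candidates.
    """

    pbys_grid: np.ndarray
    chisq_mean: np.ndarray
    chisq_sd: np.ndarray
    n_replicates: int

    def __post_init__(self) -> None:
        self.pbys_grid = np.asarray(self.pbys_grid, dtype=float)
        self.chisq_mean = np.asarray(self.chisq_mean, dtype=float)
        self.chisq_sd = np.asarray(self.chisq_sd, dtype=float)

    @property
    def argmin(self) -> float:
        return float(self.pbys_grid[int(np.argmin(self.chisq_mean))])

    @property
    def flatness(self) -> float:
        lo = float(self.chisq_mean.min())
        hi = float(self.chisq_mean.max())
        if lo == 0.0:
            return 0.0 if hi == 0.0 else float("inf")
        return (hi - lo) / lo

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "p_bys": self.pbys_grid,
                "chisq_mean": self.chisq_mean,
                "chisq_sd": self.chisq_sd,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")

    def write_summary_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "argmin_p_bys": self.argmin,
                    "min_chisq": float(self.chisq_mean.min()),
                    "flatness": self.flatness,
                    "n_replicates": self.n_replicates,
                    "grid": self.pbys_grid.tolist(),
                },
                indent=2,
            )
            + "\n"
        )


def chi_squared(obs: ObservedSeries, sim: Sequence[float]) -> float:
    """Chi-squared discrepancy between observed and simulated fractions.

    With SDs: sum of ((obs - sim) / sd)^2. Without SDs the unweighted sum of
    squared residuals is used as a fallback (and logged, since it changes
    the objective's scale).
    """
    sim = np.asarray(sim, dtype=float)
    if sim.shape != obs.senescent_fraction.shape:
        raise ValueError(
            f"sim shape {sim.shape} does not match observed shape "
            f"{obs.senescent_fraction.shape}"
        )
    resid = obs.senescent_fraction - sim
    if obs.sd is not None:
        return float(np.sum((resid / obs.sd) ** 2))
    logger.info("no SDs supplied; using unweighted sum-of-squares objective")
    return float(np.sum(resid**2))


def in_vitro_params(
    base: SimulationParams, strict: bool = False
) -> SimulationParams:
    """Derive in-vitro-mode parameters: ``p_clr = p_new = 0``, 2D geometry.

    Cultured monolayers have neither immune clearance nor repopulation of
    cleared sites. A 3D base geometry is flattened to its first two
    dimensions with a warning (or rejected when ``strict``). Idempotent.
    """
    dims = base.dims
    if len(dims) == 3:
        if strict:
            raise ConfigError(
                "in-vitro mode requires a 2D monolayer; got 3D dims "
                f"{dims} with strict=True"
            )
        warnings.warn(
            f"in-vitro mode forces a 2D monolayer; flattening dims {dims} "
            f"to {dims[:2]}",
            stacklevel=2,
        )
        dims = dims[:2]
    return replace(base, dims=dims, p_clr=0.0, p_new=0.0)


def scan_pbys(
    obs: ObservedSeries,
    base: SimulationParams,
    pbys_grid: Sequence[float] | None = None,
    n_replicates: int = 50,
    base_seed: int = 0,
) -> FitLandscape:
    """Scan candidate ``p_bys`` values against an observed series.

    Each candidate is simulated as an in-vitro-mode ensemble; the objective
    compares the observed fractions to the ensemble-mean senescent fraction
    at the observed days. Deterministic given ``base_seed``.
    """
    grid = (
        np.asarray(DEFAULT_PBYS_GRID, dtype=float)
        if pbys_grid is None
        else np.asarray(pbys_grid, dtype=float)
    )
    if grid.size == 0:
        raise ValueError("pbys_grid must be non-empty")
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("pbys_grid values must lie in [0, 1]")
    base = in_vitro_params(base)
    if obs.days.max() > base.n_steps:
        raise ConfigError(
            f"observed days extend to {obs.days.max()} but the simulation "
            f"only runs {base.n_steps} steps"
        )
    s_col = int(CellState.SENESCENT)
    chisq_mean = np.empty(grid.size)
    chisq_sd = np.empty(grid.size)
    for k, cand in enumerate(grid):
        params = replace(base, p_bys=float(cand))
        ens = run_ensemble(params, n_replicates, replicate_seed(base_seed, 100_000 + k))
        mean_s = ens.mean_fractions[obs.days, s_col]
        chisq_mean[k] = chi_squared(obs, mean_s)
        per_rep = [
            chi_squared(obs, t.fractions[obs.days, s_col])
            for t in ens.trajectories
        ]
        chisq_sd[k] = float(np.std(per_rep, ddof=1)) if n_replicates > 1 else 0.0
    return FitLandscape(
        pbys_grid=grid,
        chisq_mean=chisq_mean,
        chisq_sd=chisq_sd,
        n_replicates=n_replicates,
    )


def check_physiological_plausibility(params: SimulationParams) -> bool:
    """Warn when ``p_bys > p_clr``.

    In a physiologically healthy tissue the bystander probability is assumed
    not to exceed the clearance probability — otherwise a single senescent
    cell arising early in life could drive runaway accumulation. This is a
    plausibility warning, not a hard constraint.
    """
    if params.p_bys > params.p_clr:
        warnings.warn(
            f"p_bys ({params.p_bys}) exceeds p_clr ({params.p_clr}): outside "
            "the physiologically plausible regime p_bys <= p_clr",
            stacklevel=2,
        )
        return False
    return True


def read_observed_csv(path: str | Path) -> ObservedSeries:
    """Read ``day,frac_senescent[,sd]`` into an ObservedSeries."""
    df = pd.read_csv(path)
    if "day" not in df.columns or "frac_senescent" not in df.columns:
        raise ValueError("observed CSV needs columns day,frac_senescent[,sd]")
    sd = df["sd"].to_numpy() if "sd" in df.columns else None
    return ObservedSeries(
        days=df["day"].to_numpy(),
        senescent_fraction=df["frac_senescent"].to_numpy(),
        sd=sd,
    )


def write_observed_csv(obs: ObservedSeries, path: str | Path) -> None:
    cols = {"day": obs.days, "frac_senescent": obs.senescent_fraction}
    if obs.sd is not None:
        cols["sd"] = obs.sd
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")
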