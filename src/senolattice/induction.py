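"""Per-cell senescence-induction layer.

Whether a resting cell commits to the senescence programme on an induction
event is a binary outcome with probability ``P_ind``. Two interchangeable
modes supply that outcome:

* ``bernoulli`` — a direct coin flip with probability ``p_ind``
  (default 0.1, matching the ~10% of cells that become senescent after
  irradiation in the experimental protocol the model emulates);
* ``marker_surrogate`` — one stochastic run of a reduced marker-trajectory
  model: four senescence markers (p21, SA-β-Gal, ROS, DNA damage) rise along
  saturating curves toward per-cell random plateaus, and the cell is classed
  pre-senescent iff at a reference day (21) ALL four markers strictly exceed
  thresholds set to the population-mean marker levels of a reference
  irradiated population at that day.

The surrogate is a deliberately simple stochastic stand-in with the
population heterogeneity the classifier needs; it is not an intracellular
network model. Its default parameters are tuned so that roughly 10% of a
self-calibrated population classifies as pre-senescent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MARKERS",
    "MarkerPanel",
    "ThresholdSet",
    "SurrogateParams",
    "InductionSpec",
    "CalibrationError",
    "compute_thresholds",
    "classify_presenescent",
    "draw_induction",
    "simulate_marker_population",
    "simulate_marker_cell",
    "read_marker_csv",
    "write_marker_csv",
]

MARKERS = ("p21", "sa_b_gal", "ros", "dna_damage")

MODE_BERNOULLI = "bernoulli"
MODE_MARKER_SURROGATE = "marker_surrogate"


class CalibrationError(ValueError):
    """Raised when thresholds are missing or cannot be computed."""


@dataclass(frozen=True)
class MarkerPanel:
    """Levels of the four senescence markers for one cell, arbitrary units."""

    p21: float
    sa_b_gal: float
    ros: float
    dna_damage: float

    def __post_init__(self) -> None:
        for m in MARKERS:
            if getattr(self, m) < 0:
                raise ValueError(f"marker level {m} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, m) for m in MARKERS], dtype=float)


@dataclass(frozen=True)
class ThresholdSet:
    """One classification threshold per marker, plus the reference day."""

    p21: float
    sa_b_gal: float
    ros: float
    dna_damage: float
    reference_day: int = 21

    def __post_init__(self) -> None:
        for m in MARKERS:
            if getattr(self, m) < 0:
                raise ValueError(f"threshold {m} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, m) for m in MARKERS], dtype=float)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {m: getattr(self, m) for m in MARKERS}
                | {"reference_day": self.reference_day},
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdSet":
        raw = json.loads(Path(path).read_text())
        return cls(**raw)


@dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the stochastic marker-trajectory surrogate.

    Each cell draws a shared damage factor ``exp(cell_sd * Z)`` (log-normal,
    median 1) expressing how strongly it responds to the damage stimulus, and
    a per-marker factor ``exp(marker_sd * Z_m)`` on top. Marker ``m`` then
    follows ``base_m * factors * (1 - exp(-rise_rate * day))`` with
    day-to-day multiplicative observation noise ``exp(day_sd * Z_{m,day})``.
    The shared factor correlates the four markers within a cell, which is
    what lets an all-four-markers threshold rule pass an appreciable
    fraction of cells.

    Defaults are tuned so that ~10% of a population strictly exceeds its own
    day-21 mean on all four markers.
    """

    base_levels: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    rise_rate: float = 0.25  # per day; plateau is >99% reached by day 21
    cell_sd: float = 2.5  # shared per-cell log-scale heterogeneity
    marker_sd: float = 0.15  # marker-specific per-cell heterogeneity
    day_sd: float = 0.05  # observation noise per marker per day

    def __post_init__(self) -> None:
        if self.rise_rate <= 0:
            raise ValueError("rise_rate must be positive")
        for name in ("cell_sd", "marker_sd", "day_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class InductionSpec:
    """Configuration of the induction layer handed to the engine.

    In ``bernoulli`` mode only ``p_ind`` matters. In ``marker_surrogate``
    mode a ``ThresholdSet`` must be present before any induction draw; call
    :meth:`calibrate` to derive thresholds from a dedicated reference
    population (kept separate from the lattice's own cells so that P_ind is
    homogeneous across the lattice).
    """

    mode: str = MODE_BERNOULLI
    p_ind: float = 0.1
    surrogate_params: SurrogateParams = field(default_factory=SurrogateParams)
    thresholds: ThresholdSet | None = None
    reference_population_size: int = 1000

    def __post_init__(self) -> None:
        if self.mode not in (MODE_BERNOULLI, MODE_MARKER_SURROGATE):
            raise ValueError(f"unknown induction mode {self.mode!r}")
        if not 0.0 <= self.p_ind <= 1.0:
            raise ValueError(f"p_ind must be in [0, 1], got {self.p_ind}")
        if self.reference_population_size < 1:
            raise ValueError("reference_population_size must be >= 1")

    def calibrate(self, rng: np.random.Generator) -> "InductionSpec":
        """Self-calibrate thresholds from a fresh reference population."""
        ref_day = (
            self.thresholds.reference_day if self.thresholds is not None else 21
        )
        pop = simulate_marker_population(
            self.surrogate_params,
            self.reference_population_size,
            rng,
            n_days=ref_day,
        )
        panels = panels_at_day(pop, ref_day)
        self.thresholds = compute_thresholds(panels, reference_day=ref_day)
        return self


def compute_thresholds(
    population: Iterable[MarkerPanel], reference_day: int = 21
) -> ThresholdSet:
    """Per-marker thresholds: the arithmetic mean over the reference
    population at the reference day."""
    panels = list(population)
    if not panels:
        raise CalibrationError("cannot compute thresholds from an empty population")
    levels = np.array([p.as_array() for p in panels])
    means = levels.mean(axis=0)
    return ThresholdSet(*map(float, means), reference_day=reference_day)


def classify_presenescent(panel: MarkerPanel, thresholds: ThresholdSet) -> bool:
    """True iff every marker level strictly exceeds its threshold.

    The all-of-four policy with strict inequality is a stated convention: a
    marker exactly at threshold does not count as exceeding it.
    """
    return bool(np.all(panel.as_array() > thresholds.as_array()))


def draw_induction(spec: InductionSpec, rng: np.random.Generator) -> bool:
    """One binary induction outcome for one resting cell.

    ``bernoulli``: True with probability ``p_ind``. ``marker_surrogate``:
    simulate a single stochastic marker trajectory to the reference day and
    classify it against the calibrated thresholds.
    """
    if spec.mode == MODE_BERNOULLI:
        return bool(rng.random() < spec.p_ind)
    if spec.thresholds is None:
        raise CalibrationError(
            "marker_surrogate induction requires calibrated thresholds; "
            "call InductionSpec.calibrate() first"
        )
    ref_day = spec.thresholds.reference_day
    traj = simulate_marker_cell(spec.surrogate_params, rng, n_days=ref_day)
    panel = MarkerPanel(*traj[ref_day])
    return classify_presenescent(panel, spec.thresholds)


# ---------------------------------------------------------------------------
# The marker-trajectory surrogate.

def simulate_marker_cell(
    params: SurrogateParams, rng: np.random.Generator, n_days: int = 21
) -> np.ndarray:
    """One cell's marker levels for days 0..n_days, shape (n_days+1, 4)."""
    base = np.asarray(params.base_levels, dtype=float)
    cell_factor = np.exp(params.cell_sd * rng.standard_normal())
    marker_factor = np.exp(params.marker_sd * rng.standard_normal(4))
    plateau = base * cell_factor * marker_factor
    days = np.arange(n_days + 1)
    kinetic = 1.0 - np.exp(-params.rise_rate * days)
    noise = np.exp(params.day_sd * rng.standard_normal((n_days + 1, 4)))
    return plateau[None, :] * kinetic[:, None] * noise


def simulate_marker_population(
    params: SurrogateParams,
    n_cells: int,
    rng: np.random.Generator,
    n_days: int = 21,
) -> pd.DataFrame:
    """Stochastic marker trajectories for a population of cells.

    Returns a long-format frame with columns
    ``cell_id, day, p21, sa_b_gal, ros, dna_damage`` covering days
    0..n_days for each cell.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    frames = []
    for cid in range(n_cells):
        levels = simulate_marker_cell(params, rng, n_days=n_days)
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": cid,
                    "day": np.arange(n_days + 1),
                    **{m: levels[:, j] for j, m in enumerate(MARKERS)},
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def panels_at_day(population: pd.DataFrame, day: int) -> list[MarkerPanel]:
    """Extract one MarkerPanel per cell at the given day from a long frame."""
    sub = population[population["day"] == day]
    if sub.empty:
        raise CalibrationError(f"population has no measurements at day {day}")
    return [
        MarkerPanel(*(float(row[m]) for m in MARKERS))
        for _, row in sub.iterrows()
    ]


def classified_fraction(
    population: pd.DataFrame, thresholds: ThresholdSet
) -> float:
    """Fraction of cells classified pre-senescent at the reference day."""
    panels = panels_at_day(population, thresholds.reference_day)
    flags = [classify_presenescent(p, thresholds) for p in panels]
    return float(np.mean(flags))


def write_marker_csv(population: pd.DataFrame, path: str | Path) -> None:
    cols = ["cell_id", "day", *MARKERS]
    population[cols].to_csv(path, index=False, float_format="%.10g")


def read_marker_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"cell_id", "day", *MARKERS}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"marker CSV missing columns: {sorted(missing)}")
    return df
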