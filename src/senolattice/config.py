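"""Run configuration: a single YAML file with documented defaults.

Every field has a default matching the reference parameterisation
(``p_new`` 0.5, ``p_clr`` 0.4, ``p_bys`` 0.2, ``t_i`` 10, ``p_trigger``
0.02, 10x10 lattice), so an empty config file is a valid, complete run.
Unknown keys are rejected rather than silently ignored; loading also emits
the physiological-plausibility warning when ``p_bys > p_clr``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .calibration import check_physiological_plausibility
from .engine import ConfigError, SimulationParams
from .induction import InductionSpec, SurrogateParams

__all__ = ["RunConfig", "load_config", "save_config"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full run configuration: simulation + induction + output toggles."""

    # lattice / engine
    dims: tuple[int, ...] = (10, 10)
    n_steps: int = 250
    p_bys: float = 0.2
    p_clr: float = 0.4
    p_new: float = 0.5
    t_i: int = 10
    induction_mode: str = "irradiation_day1"
    p_trigger: float = 0.02
    s_n_policy: str = "per_cell_half"
    boundary: str = "fixed"
    update_order: str = "random_permutation"
    seed: int = 0
    # induction layer
    induction_kind: str = "bernoulli"  # or "marker_surrogate"
    p_ind: float = 0.1
    reference_population_size: int = 1000
    surrogate: dict[str, Any] = field(default_factory=dict)
    # outputs
    out_dir: str = "senolattice_out"
    write_trajectory: bool = True
    write_snapshots: bool = False
    write_ensemble_summary: bool = True
    n_replicates: int = 50
    log_level: str = "INFO"

    def to_params(self) -> SimulationParams:
        induction = InductionSpec(
            mode=self.induction_kind,
            p_ind=self.p_ind,
            surrogate_params=SurrogateParams(**self.surrogate),
            reference_population_size=self.reference_population_size,
        )
        return SimulationParams(
            dims=tuple(self.dims),
            n_steps=self.n_steps,
            p_bys=self.p_bys,
            p_clr=self.p_clr,
            p_new=self.p_new,
            t_i=self.t_i,
            induction_mode=self.induction_mode,
            p_trigger=self.p_trigger,
            induction=induction,
            s_n_policy=self.s_n_policy,
            boundary=self.boundary,
            update_order=self.update_order,
            seed=self.seed,
        )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["dims"] = list(self.dims)
        return d


def load_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    """Load a RunConfig from YAML, applying keyword overrides on top.

    Missing keys take the documented defaults; unknown keys raise a
    ConfigError naming the offending key. Validation (probability ranges
    etc.) is delegated to the parameter dataclasses, which also name the
    offending field.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must be a YAML mapping")
        raw.update(loaded)
    raw.update({k: v for k, v in overrides.items() if v is not None})

    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "dims" in raw:
        raw["dims"] = tuple(int(d) for d in raw["dims"])
    cfg = RunConfig(**raw)
    params = cfg.to_params()  # runs range validation, names offending field
    check_physiological_plausibility(params)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
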