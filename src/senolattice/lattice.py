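"""Lattice geometry, Moore neighbourhoods and the immune-clearance quorum.

The tissue is a regular 2D or 3D grid of cell agents. Each site holds one of
four discrete states; pre-senescent sites additionally carry a timer counting
the time units spent in that state. Neighbourhoods are Moore neighbourhoods
(all sites within one coordinate unit in every dimension: 8 neighbours for an
interior site in 2D, 26 in 3D).

The immune-clearance rule removes a senescent cell only when a minimum number
``S_n`` of its neighbours are also senescent — immune effectors are assumed
to be recruited to groups of senescent cells rather than isolated ones. The
quorum is half the neighbourhood size: 4 for an interior 2D site, 13 for an
interior 3D site. At lattice edges the neighbourhood is truncated; the
default policy rescales the quorum to half the actual neighbour count
(rounded up), while a fixed policy always uses the interior value.
"""

from __future__ import annotations

import csv
import itertools
import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CellState",
    "Lattice",
    "InvalidGeometryError",
    "build_lattice",
    "moore_neighbors",
    "min_senescent_neighbors",
    "state_counts",
    "write_snapshot",
    "write_long_csv",
]


class CellState(IntEnum):
    """The four discrete states a lattice site can hold.

    RESTING (R) — healthy cell; PRE_SENESCENT (PS) — committed to senescence
    but not yet senescent; SENESCENT (S) — fully senescent, secreting SASP;
    EMPTY (E) — vacated by immune clearance, available for repopulation.
    """

    RESTING = 0
    PRE_SENESCENT = 1
    SENESCENT = 2
    EMPTY = 3


class InvalidGeometryError(ValueError):
    """Raised for lattice dimensions that are not 2 or 3 positive integers."""


BOUNDARY_FIXED = "fixed"
BOUNDARY_PERIODIC = "periodic"

SN_PER_CELL_HALF = "per_cell_half"
SN_FIXED = "fixed"

#: Interior Moore-neighbourhood size is 3^d - 1; the fixed quorum is half of it.
FIXED_QUORUM = {2: 4, 3: 13}


@dataclass
class Lattice:
    """Dense grid of cell states with per-site pre-senescence timers.

    ``ps_timer`` is meaningful only where ``states == PRE_SENESCENT`` and is
    zero everywhere else. Neighbour flat-index arrays are cached per lattice
    because geometry never changes after construction.
    """

    dims: tuple[int, ...]
    states: np.ndarray
    ps_timer: np.ndarray
    boundary: str = BOUNDARY_FIXED
    _neighbor_cache: list[np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_sites(self) -> int:
        return int(np.prod(self.dims))

    @property
    def ndim(self) -> int:
        return len(self.dims)

    def neighbor_flat_indices(self) -> list[np.ndarray]:
        """Flat neighbour indices for every site, in site (row-major) order.

        Built lazily and cached; used by the simulation engine's inner loop.
        """
        if self._neighbor_cache is None:
            self._neighbor_cache = [
                np.array(
                    [_ravel(c, self.dims) for c in moore_neighbors(self, coord)],
                    dtype=np.intp,
                )
                for coord in itertools.product(*(range(d) for d in self.dims))
            ]
        return self._neighbor_cache

    def copy(self) -> "Lattice":
        lat = Lattice(
            dims=self.dims,
            states=self.states.copy(),
            ps_timer=self.ps_timer.copy(),
            boundary=self.boundary,
        )
        lat._neighbor_cache = self._neighbor_cache
        return lat


def _ravel(coord: tuple[int, ...], dims: tuple[int, ...]) -> int:
    return int(np.ravel_multi_index(coord, dims))


def build_lattice(
    dims: Sequence[int],
    initial_state: CellState = CellState.RESTING,
    boundary: str = BOUNDARY_FIXED,
) -> Lattice:
    """Create a lattice with every site in ``initial_state`` and timers at 0."""
    dims = tuple(int(d) for d in dims)
    if len(dims) not in (2, 3):
        raise InvalidGeometryError(
            f"lattice must be 2D or 3D, got {len(dims)} dimensions"
        )
    if any(d < 1 for d in dims):
        raise InvalidGeometryError(f"all dimensions must be >= 1, got {dims}")
    if boundary not in (BOUNDARY_FIXED, BOUNDARY_PERIODIC):
        raise InvalidGeometryError(f"unknown boundary policy {boundary!r}")
    states = np.full(dims, int(initial_state), dtype=np.int8)
    timers = np.zeros(dims, dtype=np.int32)
    return Lattice(dims=dims, states=states, ps_timer=timers, boundary=boundary)


def _check_coord(lattice: Lattice, coord: Sequence[int]) -> tuple[int, ...]:
    coord = tuple(int(c) for c in coord)
    if len(coord) != lattice.ndim:
        raise IndexError(f"coordinate {coord} has wrong arity for dims {lattice.dims}")
    for c, d in zip(coord, lattice.dims):
        if not 0 <= c < d:
            raise IndexError(f"coordinate {coord} outside lattice bounds {lattice.dims}")
    return coord


def moore_neighbors(lattice: Lattice, coord: Sequence[int]) -> list[tuple[int, ...]]:
    """All in-bounds sites within one coordinate unit of ``coord`` in every
    dimension, excluding ``coord`` itself, in lexicographic order.

    With fixed boundaries edge sites have truncated neighbourhoods; with
    periodic boundaries coordinates wrap (duplicates from wrapping on very
    small lattices are removed).
    """
    coord = _check_coord(lattice, coord)
    out: set[tuple[int, ...]] = set()
    for offset in itertools.product((-1, 0, 1), repeat=lattice.ndim):
        if all(o == 0 for o in offset):
            continue
        cand = tuple(c + o for c, o in zip(coord, offset))
        if lattice.boundary == BOUNDARY_PERIODIC:
            cand = tuple(c % d for c, d in zip(cand, lattice.dims))
            if cand == coord:
                continue
            out.add(cand)
        else:
            if all(0 <= c < d for c, d in zip(cand, lattice.dims)):
                out.add(cand)
    return sorted(out)


def min_senescent_neighbors(
    lattice: Lattice, coord: Sequence[int], policy: str = SN_PER_CELL_HALF
) -> int:
    """Clearance quorum S_n at ``coord``.

    ``per_cell_half``: ceil(half of the actual neighbour count) — 4 for an
    interior 2D site, 13 for an interior 3D site, smaller at truncated edges.
    ``fixed``: always the interior value (4 in 2D, 13 in 3D).
    """
    coord = _check_coord(lattice, coord)
    if policy == SN_FIXED:
        return FIXED_QUORUM[lattice.ndim]
    if policy == SN_PER_CELL_HALF:
        return math.ceil(len(moore_neighbors(lattice, coord)) / 2)
    raise ValueError(f"unknown S_n policy {policy!r}")


def quorum_array(lattice: Lattice, policy: str = SN_PER_CELL_HALF) -> np.ndarray:
    """Per-site quorum thresholds as a flat array (engine helper)."""
    if policy == SN_FIXED:
        return np.full(lattice.n_sites, FIXED_QUORUM[lattice.ndim], dtype=np.intp)
    return np.array(
        [
            math.ceil(len(nb) / 2)
            for nb in (
                moore_neighbors(lattice, coord)
                for coord in itertools.product(*(range(d) for d in lattice.dims))
            )
        ],
        dtype=np.intp,
    )


def state_counts(lattice: Lattice) -> dict[CellState, int]:
    """Number of sites in each of the four states; always sums to n_sites."""
    counts = np.bincount(lattice.states.reshape(-1), minlength=4)
    return {state: int(counts[state.value]) for state in CellState}


# ---------------------------------------------------------------------------
# Snapshot I/O: integer-coded text grids and a long-format CSV.

def write_snapshot(lattice: Lattice, path: str | Path) -> None:
    """Write the state grid as integer codes (0=R, 1=PS, 2=S, 3=E).

    2D: one row of space-separated codes per lattice row. 3D: one 2D slab per
    leading index, slabs separated by a blank line.
    """
    path = Path(path)
    with path.open("w") as fh:
        if lattice.ndim == 2:
            _write_slab(fh, lattice.states)
        else:
            for k, slab in enumerate(lattice.states):
                if k:
                    fh.write("\n")
                _write_slab(fh, slab)


def _write_slab(fh, slab: np.ndarray) -> None:
    for row in slab:
        fh.write(" ".join(str(int(v)) for v in row) + "\n")


def write_long_csv(
    snapshots: Iterable[tuple[int, Lattice]], path: str | Path
) -> None:
    """Long-format snapshot CSV: one row per (time, site) with the state code."""
    snapshots = list(snapshots)
    if not snapshots:
        raise ValueError("no snapshots to write")
    ndim = snapshots[0][1].ndim
    header = ["t", "x", "y"] + (["z"] if ndim == 3 else []) + ["state_code"]
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for t, lat in snapshots:
            for coord in itertools.product(*(range(d) for d in lat.dims)):
                writer.writerow([t, *coord, int(lat.states[coord])])
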