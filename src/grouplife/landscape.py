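"""Patch lattice generation and neighborhood queries.

The world is a rectangular lattice of patches (default 33x33) representing
exploitable land, with absorbing edges: boundary patches simply have fewer
than four von Neumann neighbours (no wrap-around, no reflection).  Each
patch carries one of two productivity levels, which fixes its carrying
capacity and annual population growth rate for the whole run.  Landscapes
are generated either by scattering high-productivity patches uniformly at
random or by aggregating them into square blocks of at least 9, 49 or 81
patches, the habitat layouts used in the sensitivity experiments.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

Coord = tuple[int, int]


class ConfigurationError(ValueError):
    """A parameter combination that cannot produce a valid model state."""


class Productivity(enum.Enum):
    HIGH = "H"
    LOW = "L"


class AggregationMode(enum.Enum):
    RANDOM = "random"
    BLOCK9 = "block9"
    BLOCK49 = "block49"
    BLOCK81 = "block81"


#: Side length of the square high-productivity blocks placed in each mode.
_BLOCK_SIDE = {
    AggregationMode.BLOCK9: 3,
    AggregationMode.BLOCK49: 7,
    AggregationMode.BLOCK81: 9,
}


def as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    """Coerce an int seed (or None) into a numpy Generator.

    Any object exposing the Generator draw interface is passed through
    unchanged, so tests can inject scripted random sources.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        return np.random.default_rng(rng)
    return rng


@dataclass(frozen=True)
class Patch:
    """One immutable lattice site."""

    coord: Coord
    productivity: Productivity
    carrying_capacity: float
    growth_rate: float


@dataclass
class Landscape:
    """The full lattice: productivity layout plus demographic constants.

    ``high_mask[row, col]`` is True where the patch is high-productivity.
    Carrying capacities and growth rates are derived arrays kept in sync
    with the mask; the layout never changes after generation.
    """

    width: int
    height: int
    aggregation_mode: AggregationMode
    lp_hp_ratio: tuple[int, int]
    high_mask: np.ndarray
    K_H: float = 100.0
    K_L: float = 50.0
    r_H: float = 0.03
    r_L: float = 0.01
    _K: np.ndarray = field(init=False, repr=False)
    _r: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.high_mask = np.asarray(self.high_mask, dtype=bool)
        if self.high_mask.shape != (self.height, self.width):
            raise ConfigurationError(
                f"high_mask shape {self.high_mask.shape} does not match "
                f"(height, width)=({self.height}, {self.width})"
            )
        self._K = np.where(self.high_mask, self.K_H, self.K_L)
        self._r = np.where(self.high_mask, self.r_H, self.r_L)

    # -- queries ---------------------------------------------------------

    def in_bounds(self, coord: Coord) -> bool:
        r, c = coord
        return 0 <= r < self.height and 0 <= c < self.width

    def _check_bounds(self, coord: Coord) -> None:
        if not self.in_bounds(coord):
            raise IndexError(f"coordinate {coord} outside {self.height}x{self.width} lattice")

    def is_high(self, coord: Coord) -> bool:
        self._check_bounds(coord)
        return bool(self.high_mask[coord])

    def carrying_capacity(self, coord: Coord) -> float:
        return float(self._K[coord])

    def growth_rate(self, coord: Coord) -> float:
        return float(self._r[coord])

    def patch(self, coord: Coord) -> Patch:
        self._check_bounds(coord)
        high = bool(self.high_mask[coord])
        return Patch(
            coord=coord,
            productivity=Productivity.HIGH if high else Productivity.LOW,
            carrying_capacity=self.K_H if high else self.K_L,
            growth_rate=self.r_H if high else self.r_L,
        )

    def __getitem__(self, coord: Coord) -> Patch:
        return self.patch(coord)

    @property
    def n_patches(self) -> int:
        return self.width * self.height

    @property
    def n_high(self) -> int:
        return int(self.high_mask.sum())

    @property
    def n_low(self) -> int:
        return self.n_patches - self.n_high

    def coords(self) -> Iterator[Coord]:
        """All coordinates in row-major order."""
        for r in range(self.height):
            for c in range(self.width):
                yield (r, c)

    def high_coords(self) -> list[Coord]:
        return [tuple(x) for x in np.argwhere(self.high_mask)]

    def low_coords(self) -> list[Coord]:
        return [tuple(x) for x in np.argwhere(~self.high_mask)]

    def neighbors(self, coord: Coord) -> list[Coord]:
        """Existing von Neumann neighbours, in deterministic row-major order."""
        self._check_bounds(coord)
        r, c = coord
        cand = ((r - 1, c), (r, c - 1), (r, c + 1), (r + 1, c))
        return [p for p in cand if self.in_bounds(p)]

    # -- export ----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Grid snapshot: one row per patch with columns row, col, productivity."""
        rows = [
            {"row": r, "col": c, "productivity": "H" if self.high_mask[r, c] else "L"}
            for r, c in self.coords()
        ]
        return pd.DataFrame(rows, columns=["row", "col", "productivity"])


def neighbors(landscape: Landscape, coord: Coord) -> list[Coord]:
    """Module-level alias for :meth:`Landscape.neighbors`."""
    return landscape.neighbors(coord)


def low_high_quota(width: int, height: int, lp_hp_ratio: tuple[int, int]) -> tuple[int, int]:
    """Split ``width*height`` patches into (n_low, n_high) under a LP:HP ratio.

    The low-productivity share is rounded half-up, so LOW absorbs the
    remainder when the split is not exact (e.g. 1:1 on 1089 patches gives
    545 low and 544 high).
    """
    lp, hp = lp_hp_ratio
    if lp < 0 or hp < 0 or lp + hp == 0:
        raise ConfigurationError(f"invalid lp_hp_ratio {lp_hp_ratio}: parts must be >=0, not both 0")
    total = width * height
    n_low = int(np.floor(total * lp / (lp + hp) + 0.5))
    return n_low, total - n_low


def generate_landscape(
    width: int = 33,
    height: int = 33,
    lp_hp_ratio: tuple[int, int] = (1, 1),
    aggregation_mode: AggregationMode | str = AggregationMode.RANDOM,
    rng: np.random.Generator | int | None = None,
    *,
    K_H: float = 100.0,
    K_L: float = 50.0,
    r_H: float = 0.03,
    r_L: float = 0.01,
) -> Landscape:
    """Generate a productivity layout under the declared ratio and mode.

    RANDOM mode scatters the high-productivity quota uniformly over the
    lattice.  BLOCKk modes tile non-overlapping square blocks (3x3, 7x7 or
    9x9) of high-productivity patches at uniformly random positions until
    fewer than k high patches remain, then attach the residual one patch at
    a time to the boundary of existing high clusters, so every high patch
    ends up in a 4-connected cluster of at least k patches.
    """
    if width < 1 or height < 1:
        raise ConfigurationError(f"lattice dimensions must be >=1, got {width}x{height}")
    mode = AggregationMode(aggregation_mode)
    rng = as_rng(rng)
    n_low, n_high = low_high_quota(width, height, tuple(lp_hp_ratio))

    mask = np.zeros((height, width), dtype=bool)
    if mode is AggregationMode.RANDOM:
        flat = rng.permutation(width * height)[:n_high]
        mask.flat[flat] = True
    else:
        side = _BLOCK_SIDE[mode]
        block = side * side
        if n_high < block:
            raise ConfigurationError(
                f"aggregation_mode={mode.value} requires at least {block} high-productivity "
                f"patches, but lp_hp_ratio={lp_hp_ratio} on {width}x{height} yields only {n_high}"
            )
        if side > min(width, height):
            raise ConfigurationError(
                f"aggregation_mode={mode.value} block side {side} exceeds lattice "
                f"dimensions {width}x{height}"
            )
        remaining = n_high
        while remaining >= block:
            placed = False
            # uniform rejection sampling of non-overlapping block positions
            for _ in range(1000):
                r = int(rng.integers(height - side + 1))
                c = int(rng.integers(width - side + 1))
                if not mask[r : r + side, c : c + side].any():
                    mask[r : r + side, c : c + side] = True
                    remaining -= block
                    placed = True
                    break
            if not placed:
                # crowded lattice: enumerate the remaining legal positions
                cand = [
                    (r, c)
                    for r in range(height - side + 1)
                    for c in range(width - side + 1)
                    if not mask[r : r + side, c : c + side].any()
                ]
                if not cand:
                    break
                r, c = cand[int(rng.integers(len(cand)))]
                mask[r : r + side, c : c + side] = True
                remaining -= block
        # residual high patches grow contiguously out of existing blocks
        while remaining > 0:
            frontier = sorted(
                (r, c)
                for r in range(height)
                for c in range(width)
                if not mask[r, c]
                and any(
                    mask[nr, nc]
                    for nr, nc in ((r - 1, c), (r, c - 1), (r, c + 1), (r + 1, c))
                    if 0 <= nr < height and 0 <= nc < width
                )
            )
            if not frontier:
                raise ConfigurationError(
                    f"cannot place residual high-productivity patches for mode {mode.value}"
                )
            coord = frontier[int(rng.integers(len(frontier)))]
            mask[coord] = True
            remaining -= 1

    return Landscape(
        width=width,
        height=height,
        aggregation_mode=mode,
        lp_hp_ratio=tuple(lp_hp_ratio),
        high_mask=mask,
        K_H=K_H,
        K_L=K_L,
        r_H=r_H,
        r_L=r_L,
    )
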