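"""Mutable simulation state: cells, groups and demography.

A *cell* is the occupancy of one patch by one group: a real-valued
population count tied to a patch coordinate.  A *group* is either a
single-celled group (SCG, exactly one cell) or a multicellular group
(MCG, two or more cells at birth, possibly fewer later — an MCG split or
shrunk by war keeps its identity).  Group aggression ("redness") derives
from the productivity of occupied patches: a cell on a low-productivity
patch contributes redness 1, on a high-productivity patch 0, and a group's
redness is the unweighted mean over its member cells.

Growth is discrete annual compounding with a hard carrying-capacity gate:
a cell grows by its patch rate while at or below the patch capacity K, so
it can overshoot K by at most one multiplicative step and then freezes.
That single-step overshoot is what later triggers expansion decisions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .landscape import ConfigurationError, Coord, Landscape, Patch, Productivity, as_rng


class StateError(RuntimeError):
    """The world state violates a structural invariant."""


class GroupKind(enum.Enum):
    SCG = "SCG"
    MCG = "MCG"


@dataclass
class Cell:
    coord: Coord
    population: float
    group_id: int


@dataclass
class Group:
    """A registered group.

    ``id`` is the unique registry key; ``marker`` is the heritable identity
    label on the 0..n scale.  SCG daughters born by budding get a fresh id
    but inherit the parent's marker (a lineage), while each new MCG gets a
    fresh marker of its own, allocated above all prior ids.
    """

    id: int
    marker: int
    kind: GroupKind
    member_coords: set[Coord]


class World:
    """Landscape + cells + group registry + year counter + RNG state."""

    def __init__(self, landscape: Landscape, rng: np.random.Generator | int | None = None):
        self.landscape = landscape
        self.cells: dict[Coord, Cell] = {}
        self.groups: dict[int, Group] = {}
        self.year: int = 0
        self.rng = as_rng(rng)
        self._next_id: int = 0

    # -- registry management --------------------------------------------

    def new_group_id(self) -> int:
        gid = self._next_id
        self._next_id += 1
        return gid

    def add_group(self, group: Group) -> Group:
        if group.id in self.groups:
            raise StateError(f"group id {group.id} already registered")
        self.groups[group.id] = group
        self._next_id = max(self._next_id, group.id + 1)
        return group

    def add_cell(self, coord: Coord, population: float, group_id: int) -> Cell:
        if coord in self.cells:
            raise StateError(f"patch {coord} is already occupied")
        if group_id not in self.groups:
            raise StateError(f"group {group_id} is not registered")
        cell = Cell(coord, population, group_id)
        self.cells[coord] = cell
        self.groups[group_id].member_coords.add(coord)
        return cell

    def remove_cell(self, coord: Coord) -> int | None:
        """Remove the cell at ``coord``; return the id of a group this
        extinguished (its last cell), else None."""
        cell = self.cells.pop(coord, None)
        if cell is None:
            raise StateError(f"no cell at {coord}")
        group = self.groups[cell.group_id]
        group.member_coords.discard(coord)
        if not group.member_coords:
            del self.groups[group.id]
            return group.id
        return None

    # -- audits ----------------------------------------------------------

    def audit(self) -> None:
        """Raise StateError unless cells and groups are mutually consistent."""
        seen: set[Coord] = set()
        for gid, group in self.groups.items():
            if gid != group.id:
                raise StateError(f"registry key {gid} != group id {group.id}")
            if not group.member_coords:
                raise StateError(f"group {gid} has no cells but is registered")
            if group.kind is GroupKind.SCG and len(group.member_coords) != 1:
                raise StateError(f"SCG {gid} has {len(group.member_coords)} cells")
            for coord in group.member_coords:
                if coord in seen:
                    raise StateError(f"patch {coord} claimed by two groups")
                seen.add(coord)
                cell = self.cells.get(coord)
                if cell is None:
                    raise StateError(f"group {gid} claims empty patch {coord}")
                if cell.group_id != gid:
                    raise StateError(
                        f"cell at {coord} belongs to {cell.group_id}, claimed by {gid}"
                    )
        if seen != set(self.cells):
            orphans = set(self.cells) - seen
            raise StateError(f"cells unclaimed by any group: {sorted(orphans)}")
        for coord, cell in self.cells.items():
            if cell.coord != coord:
                raise StateError(f"cell keyed {coord} carries coord {cell.coord}")
            if not self.landscape.in_bounds(coord):
                raise StateError(f"cell at {coord} is outside the lattice")
            if cell.population <= 0:
                raise StateError(f"cell at {coord} has population {cell.population}")

    # -- export ----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Occupancy snapshot with one row per occupied patch."""
        rows = []
        for coord in sorted(self.cells):
            cell = self.cells[coord]
            group = self.groups[cell.group_id]
            rows.append(
                {
                    "row": coord[0],
                    "col": coord[1],
                    "productivity": "H" if self.landscape.is_high(coord) else "L",
                    "group_id": group.id,
                    "group_kind": group.kind.value,
                    "population": cell.population,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["row", "col", "productivity", "group_id", "group_kind", "population"],
        )


# -- construction --------------------------------------------------------


def place_initial_groups(
    landscape: Landscape,
    n_blue: int = 10,
    n_red: int = 10,
    init_pop: float = 30.0,
    rng: np.random.Generator | int | None = None,
) -> World:
    """Seed the world at year 0 with SCGs on random patches.

    ``n_blue`` SCGs land on distinct high-productivity patches and
    ``n_red`` on distinct low-productivity patches, each with population
    ``init_pop``.  Groups receive ids (and markers) 0..n_blue+n_red-1,
    blue first.
    """
    rng = as_rng(rng)
    world = World(landscape, rng)
    highs = landscape.high_coords()
    lows = landscape.low_coords()
    if n_blue > len(highs):
        raise ConfigurationError(
            f"cannot place {n_blue} blue SCGs on {len(highs)} high-productivity patches"
        )
    if n_red > len(lows):
        raise ConfigurationError(
            f"cannot place {n_red} red SCGs on {len(lows)} low-productivity patches"
        )
    chosen: list[Coord] = []
    if n_blue:
        idx = rng.choice(len(highs), size=n_blue, replace=False)
        chosen += [highs[i] for i in idx]
    if n_red:
        idx = rng.choice(len(lows), size=n_red, replace=False)
        chosen += [lows[i] for i in idx]
    for gid, coord in enumerate(chosen):
        world.add_group(Group(id=gid, marker=gid, kind=GroupKind.SCG, member_coords=set()))
        world.add_cell(coord, float(init_pop), gid)
    return world


# -- demography ----------------------------------------------------------


def grow_cell(cell: Cell, patch: Patch) -> Cell:
    """One year of growth for one cell (pure version).

    The cell compounds by its patch growth rate while population <= K;
    once above K (after a single overshooting step) it stays frozen.
    """
    if cell.population <= 0:
        raise StateError(f"cell at {cell.coord} has non-positive population")
    if cell.population <= patch.carrying_capacity:
        return replace(cell, population=cell.population * (1.0 + patch.growth_rate))
    return cell


def grow_all(world: World) -> None:
    """In-place growth phase over every cell in the world."""
    ls = world.landscape
    K = ls._K
    r = ls._r
    for cell in world.cells.values():
        if cell.population <= K[cell.coord]:
            cell.population *= 1.0 + r[cell.coord]


# -- redness and aggregates ---------------------------------------------


def cell_redness(patch: Patch) -> float:
    """Aggression contribution of one patch: 1 on LOW, 0 on HIGH."""
    return 1.0 if patch.productivity is Productivity.LOW else 0.0


def group_redness(group: Group, world: World) -> float:
    """Unweighted mean of member-cell rednesses, in [0, 1]."""
    if not group.member_coords:
        raise StateError(f"group {group.id} has no cells")
    high = world.landscape.high_mask
    reds = sum(0.0 if high[coord] else 1.0 for coord in group.member_coords)
    return reds / len(group.member_coords)


def group_population(group: Group, world: World) -> float:
    """Total persons across the group's member cells."""
    return sum(world.cells[coord].population for coord in group.member_coords)


def group_size(group: Group) -> int:
    """Number of member cells (patches occupied)."""
    return len(group.member_coords)
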