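"""Birth of multicellular groups by fusion of adjacent blue SCGs.

The transition from single-celled to multicellular groups happens under
population pressure: once at least T blue SCGs (SCGs on high-productivity
patches) sit strictly above a fraction of their carrying capacity
(default: 4 groups above 90% of K), one eligible group is drawn uniformly
at random as the reference.  If at least T-1 of the reference's von
Neumann neighbours hold eligible blue SCGs, the reference and *all* its
adjacent eligible SCGs merge into one new MCG with a fresh identity
marker; member cells keep their populations and patches, so fusion
conserves population and occupancy exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .actions import _event
from .world import Group, GroupKind, World


@dataclass
class FusionParams:
    """Threshold T: minimum number of blue SCGs that fuse (reference plus
    T-1 adjacent).  cc_fraction: eligibility cut as a fraction of carrying
    capacity, strict inequality."""

    threshold: int = 4
    cc_fraction: float = 0.90

    def __post_init__(self) -> None:
        if self.threshold < 2:
            raise ValueError(f"fusion threshold must be >=2, got {self.threshold}")
        if not 0.0 < self.cc_fraction < 1.0:
            raise ValueError(f"cc_fraction must lie in (0, 1), got {self.cc_fraction}")


def eligible_blue_scgs(world: World, cc_fraction: float = 0.90) -> list[Group]:
    """All SCGs on high-productivity patches strictly above cc_fraction of
    their carrying capacity, ordered by group id."""
    out = []
    for gid in sorted(world.groups):
        group = world.groups[gid]
        if group.kind is not GroupKind.SCG:
            continue
        (coord,) = group.member_coords
        if not world.landscape.is_high(coord):
            continue
        if world.cells[coord].population > cc_fraction * world.landscape.carrying_capacity(coord):
            out.append(group)
    return out


def attempt_fusion(world: World, params: FusionParams) -> dict | None:
    """Run one fusion check; return the FUSION event if a merge happened.

    No-op unless at least ``threshold`` eligible blue SCGs exist anywhere.
    The reference is drawn uniformly from the eligible groups; it fuses
    with all adjacent eligible groups only if there are at least
    ``threshold - 1`` of them.
    """
    eligible = eligible_blue_scgs(world, params.cc_fraction)
    if len(eligible) < params.threshold:
        return None
    reference = eligible[int(world.rng.integers(len(eligible)))]
    (ref_coord,) = reference.member_coords
    by_coord = {next(iter(g.member_coords)): g for g in eligible}
    adjacent = [
        by_coord[c] for c in world.landscape.neighbors(ref_coord) if c in by_coord
    ]
    if len(adjacent) < params.threshold - 1:
        return None
    founders = [reference] + adjacent
    gid = world.new_group_id()
    coords = set()
    for g in founders:
        coords |= g.member_coords
        del world.groups[g.id]
    world.add_group(Group(id=gid, marker=gid, kind=GroupKind.MCG, member_coords=coords))
    for coord in coords:
        world.cells[coord].group_id = gid
    return _event(
        "FUSION",
        world.year,
        actor_id=gid,
        coord=ref_coord,
        pop_after=sum(world.cells[c].population for c in coords),
        members=";".join(str(g.id) for g in founders),
    )
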