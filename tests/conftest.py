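"""Shared fixtures and scenario builders for hand-crafted world states."""

from __future__ import annotations

import numpy as np
import pytest

from grouplife.landscape import AggregationMode, Landscape
from grouplife.world import Cell, Group, GroupKind, World


class ScriptedRng:
    """Random source replaying queued draws, for forcing stochastic branches.

    ``integers`` values are returned verbatim (they must be legal for the
    requested range); ``random`` values come from their own queue.  Raises
    when a queue runs dry so tests fail loudly on unexpected draws.
    """

    def __init__(self, integers=(), randoms=()):
        self._integers = list(integers)
        self._randoms = list(randoms)

    def integers(self, low, high=None, size=None):
        if size is not None:
            raise NotImplementedError("scripted draws are scalar")
        value = self._integers.pop(0)
        lo, hi = (0, low) if high is None else (low, high)
        assert lo <= value < hi, f"scripted integer {value} outside [{lo}, {hi})"
        return value

    def random(self):
        return self._randoms.pop(0)


def make_landscape(
    width: int = 7,
    height: int = 7,
    high: str | list | None = "all",
    **kwargs,
) -> Landscape:
    """Build a landscape with an explicit productivity layout.

    ``high`` is "all", "none", or a list of HIGH coordinates.
    """
    mask = np.zeros((height, width), dtype=bool)
    if high == "all":
        mask[:] = True
    elif high and high != "none":
        for coord in high:
            mask[coord] = True
    return Landscape(
        width=width,
        height=height,
        aggregation_mode=AggregationMode.RANDOM,
        lp_hp_ratio=(1, 1),
        high_mask=mask,
        **kwargs,
    )


def make_world(landscape: Landscape, groups, rng=None) -> World:
    """Populate a world from a list of (kind, [(coord, population), ...]).

    Groups receive ids (and markers) 0, 1, ... in list order.
    """
    world = World(landscape, rng if rng is not None else 0)
    for gid, (kind, cells) in enumerate(groups):
        world.add_group(
            Group(id=gid, marker=gid, kind=GroupKind(kind), member_coords=set())
        )
        for coord, pop in cells:
            world.add_cell(coord, float(pop), gid)
    world.audit()
    return world


@pytest.fixture
def all_high_7x7() -> Landscape:
    return make_landscape(7, 7, "all")


@pytest.fixture
def all_low_7x7() -> Landscape:
    return make_landscape(7, 7, "none")
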