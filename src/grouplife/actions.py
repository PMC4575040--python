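"""Per-cell expansion decisions and warfare resolution.

A cell only acts in the year(s) it sits above its patch carrying capacity
(the single-step growth overshoot).  When chosen to act it inspects one
uniformly random neighbouring patch: an empty patch invites budding, a
patch held by a foreign group invites war with a probability that rises
with the acting group's redness and total population, and a patch held by
the cell's own group (or a declined war) leaves the cell static.

Warfare follows a linear (Lanchester) law on total group populations: the
probability that the attacker's group wins is N_A / (N_A + N_B).  A
squared law, under which large groups are disproportionately favoured, is
available as an alternative kernel but is not the default.  The winner of
a war captures (attacker) or holds (defender) the contested patch; as with
budding, an SCG that captures a patch proliferates — the new cell founds a
fresh SCG in the same lineage — while a capturing MCG absorbs it.  The
losing group additionally pays an attrition cost scaled by the winning
group's total population and its victory odds, spread proportionally
across the loser's remaining cells; cells falling below one person are
removed, and a group losing its last cell goes extinct.  Group-scaled
attrition is what lets a single lost war strip a large group of hundreds
of cells at once (an engaged-cell-scaled variant, under which wars only
ever nibble, is available for comparison).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .landscape import Coord
from .world import GroupKind, Group, StateError, World, group_population, group_redness


class ActionKind(enum.Enum):
    STATIC = "static"
    BUD = "bud"
    WAR = "war"


@dataclass(frozen=True)
class Action:
    kind: ActionKind
    target: Coord | None = None


STATIC = Action(ActionKind.STATIC)


@dataclass
class WarParams:
    """Constants of the warfare functions.

    c scales how strongly a group's total population raises its propensity
    to attack (per person); c1 scales the attrition cost paid by the
    losing side.  victory_law selects the combat kernel: "linear" (default)
    or "squared".
    """

    c: float = 0.001
    c1: float = 1.0
    victory_law: str = "linear"
    attrition_scale: str = "winner_group"

    def __post_init__(self) -> None:
        if self.c < 0 or self.c1 < 0:
            raise ValueError(f"war constants must be non-negative, got c={self.c}, c1={self.c1}")
        if self.victory_law not in ("linear", "squared"):
            raise ValueError(f"unknown victory_law {self.victory_law!r}")
        if self.attrition_scale not in ("winner_group", "engaged_cell"):
            raise ValueError(f"unknown attrition_scale {self.attrition_scale!r}")


def war_probability(group: Group, world: World, params: WarParams) -> float:
    """Probability that the group attacks a foreign neighbour when given
    the chance: min(1, redness + c * total population)."""
    p = group_redness(group, world) + params.c * group_population(group, world)
    return min(1.0, p)


def victory_probability(
    attacker: Group, defender: Group, world: World, law: str = "linear"
) -> float:
    """Attacker's chance of winning, from total group populations.

    Linear law: N_A / (N_A + N_B).  Squared law: N_A^2 / (N_A^2 + N_B^2).
    Complementary by construction: P(A beats B) + P(B beats A) = 1.
    """
    n_a = group_population(attacker, world)
    n_b = group_population(defender, world)
    if n_a <= 0 and n_b <= 0:
        raise StateError("victory probability undefined for two empty groups")
    if law == "squared":
        n_a, n_b = n_a * n_a, n_b * n_b
    return n_a / (n_a + n_b)


def choose_action(coord: Coord, world: World, params: WarParams) -> Action:
    """Decide what the cell at ``coord`` does this decision slot.

    A cell at or below its carrying capacity stays static.  Otherwise one
    neighbouring patch is drawn uniformly: empty -> bud there; foreign ->
    war there with probability :func:`war_probability`, else static; own
    group -> static.
    """
    cell = world.cells[coord]
    if cell.population <= world.landscape.carrying_capacity(coord):
        return STATIC
    nbrs = world.landscape.neighbors(coord)
    target = nbrs[int(world.rng.integers(len(nbrs)))]
    occupant = world.cells.get(target)
    if occupant is None:
        return Action(ActionKind.BUD, target)
    if occupant.group_id == cell.group_id:
        return STATIC
    p = war_probability(world.groups[cell.group_id], world, params)
    if world.rng.random() < p:
        return Action(ActionKind.WAR, target)
    return STATIC


def _event(
    type_: str,
    year: int,
    *,
    actor_id: int | None = None,
    target_id: int | None = None,
    coord: Coord | None = None,
    pop_before: float | None = None,
    pop_after: float | None = None,
    winner_id: int | None = None,
    members: str | None = None,
) -> dict:
    row, col = coord if coord is not None else (None, None)
    return {
        "year": year,
        "type": type_,
        "actor_id": actor_id,
        "target_id": target_id,
        "row": row,
        "col": col,
        "pop_before": pop_before,
        "pop_after": pop_after,
        "winner_id": winner_id,
        "members": members,
    }


EVENT_COLUMNS = list(_event("", 0).keys())


def bud(
    coord: Coord, target: Coord, world: World, seed_size: float | None = None
) -> list[dict]:
    """Split the cell at ``coord`` into an adjacent empty patch.

    By default the parent's population halves and the other half founds
    the daughter cell (``seed_size`` instead fixes the daughter size).  An
    SCG parent spawns a *new* SCG that inherits the parent's heritable
    marker; an MCG parent simply gains a cell.  Total population is
    conserved exactly.
    """
    if target in world.cells:
        raise StateError(f"bud target {target} is occupied")
    if target not in world.landscape.neighbors(coord):
        raise StateError(f"bud target {target} is not adjacent to {coord}")
    parent = world.cells[coord]
    group = world.groups[parent.group_id]
    before = parent.population
    if seed_size is None:
        daughter_pop = parent.population / 2.0
    else:
        if not 0 < seed_size < parent.population:
            raise StateError(
                f"seed size {seed_size} must lie strictly inside (0, {parent.population})"
            )
        daughter_pop = float(seed_size)
    parent.population -= daughter_pop
    if group.kind is GroupKind.SCG:
        gid = world.new_group_id()
        world.add_group(
            Group(id=gid, marker=group.marker, kind=GroupKind.SCG, member_coords=set())
        )
        world.add_cell(target, daughter_pop, gid)
        daughter_group = gid
    else:
        world.add_cell(target, daughter_pop, group.id)
        daughter_group = group.id
    return [
        _event(
            "BUD",
            world.year,
            actor_id=group.id,
            target_id=daughter_group,
            coord=target,
            pop_before=before,
            pop_after=parent.population,
        )
    ]


def resolve_war(
    attacker_coord: Coord, defender_coord: Coord, world: World, params: WarParams
) -> list[dict]:
    """Fight one war between the cells on two adjacent patches.

    The winner is drawn by :func:`victory_probability` on total group
    populations.  If the attacker's group wins, the defender's engaged
    cell is destroyed and the attacker's engaged cell splits half of its
    population onto the captured patch — joining the attacker's group if
    it is an MCG, or founding a new SCG of the attacker's lineage if the
    attacker is an SCG (which must keep exactly one cell).  If the
    defender's group wins, the
    attacker's engaged cell is destroyed and the patch stays empty (no
    territorial gain for defenders).  Either way the losing group pays an
    attrition cost c1 * p_winner * N_winner, removed proportionally across
    its remaining cells, where N_winner is the winning group's total
    population (default) or its engaged cell's population, per
    ``params.attrition_scale``; cells below one person are culled and
    emptied groups are deleted (extinctions logged).
    """
    attacker = world.cells[attacker_coord]
    defender = world.cells[defender_coord]
    if attacker.group_id == defender.group_id:
        raise StateError("a group cannot war with itself")
    if defender_coord not in world.landscape.neighbors(attacker_coord):
        raise StateError(f"{attacker_coord} and {defender_coord} are not adjacent")
    group_a = world.groups[attacker.group_id]
    group_b = world.groups[defender.group_id]
    p_attacker = victory_probability(group_a, group_b, world, params.victory_law)
    attacker_wins = world.rng.random() < p_attacker

    events = [
        _event(
            "WAR",
            world.year,
            actor_id=group_a.id,
            target_id=group_b.id,
            coord=defender_coord,
            pop_before=group_population(group_a, world) + group_population(group_b, world),
            winner_id=group_a.id if attacker_wins else group_b.id,
        )
    ]

    if attacker_wins:
        p_win = p_attacker
        attrition_base = (
            group_population(group_a, world)
            if params.attrition_scale == "winner_group"
            else attacker.population
        )
        extinct = world.remove_cell(defender_coord)
        half = attacker.population / 2.0
        attacker.population = half
        if group_a.kind is GroupKind.SCG:
            gid = world.new_group_id()
            world.add_group(
                Group(id=gid, marker=group_a.marker, kind=GroupKind.SCG, member_coords=set())
            )
            world.add_cell(defender_coord, half, gid)
        else:
            world.add_cell(defender_coord, half, group_a.id)
        loser = group_b
    else:
        p_win = 1.0 - p_attacker
        attrition_base = (
            group_population(group_b, world)
            if params.attrition_scale == "winner_group"
            else defender.population
        )
        extinct = world.remove_cell(attacker_coord)
        loser = group_a
    if extinct is not None:
        events.append(_event("EXTINCTION", world.year, actor_id=extinct))

    # attrition on the losing group's surviving cells
    if loser.id in world.groups:
        delta = params.c1 * p_win * attrition_base
        total = group_population(loser, world)
        if delta > 0 and total > 0:
            keep = max(0.0, 1.0 - delta / total)
            for coord in loser.member_coords:
                world.cells[coord].population *= keep
        for coord in sorted(loser.member_coords):
            if world.cells[coord].population < 1.0:
                extinct = world.remove_cell(coord)
                if extinct is not None:
                    events.append(_event("EXTINCTION", world.year, actor_id=extinct))

    events[0]["pop_after"] = sum(
        group_population(world.groups[g], world)
        for g in (group_a.id, group_b.id)
        if g in world.groups
    )
    return events
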