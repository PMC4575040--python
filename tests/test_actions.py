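"""Decision policy, war propensity, combat law and war/bud resolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grouplife.actions import (
    ActionKind,
    WarParams,
    bud,
    choose_action,
    resolve_war,
    victory_probability,
    war_probability,
)
from grouplife.world import GroupKind, StateError, group_population

from conftest import ScriptedRng, make_landscape, make_world

PARAMS = WarParams()


class TestWarProbability:
    def test_peaceful_group_scales_with_population(self, all_high_7x7):
        world = make_world(all_high_7x7, [("SCG", [((2, 2), 100)])])
        assert war_probability(world.groups[0], world, PARAMS) == pytest.approx(0.1)

    def test_red_group_always_fights(self, all_low_7x7):
        world = make_world(all_low_7x7, [("SCG", [((2, 2), 37)])])
        assert war_probability(world.groups[0], world, PARAMS) == 1.0

    def test_capped_at_one(self, all_high_7x7):
        world = make_world(all_high_7x7, [("MCG", [((2, 2), 900), ((2, 3), 900)])])
        assert war_probability(world.groups[0], world, PARAMS) == 1.0


class TestVictoryProbability:
    def test_symmetry_at_equal_strength(self, all_high_7x7):
        world = make_world(
            all_high_7x7, [("SCG", [((0, 0), 80)]), ("SCG", [((3, 3), 80)])]
        )
        assert victory_probability(world.groups[0], world.groups[1], world) == 0.5

    def test_linear_law_two_to_one(self, all_high_7x7):
        world = make_world(
            all_high_7x7,
            [("MCG", [((0, 0), 100), ((0, 1), 100)]), ("SCG", [((3, 3), 100)])],
        )
        assert victory_probability(world.groups[0], world.groups[1], world) == pytest.approx(
            2 / 3
        )

    def test_squared_law_favours_the_large(self, all_high_7x7):
        world = make_world(
            all_high_7x7,
            [("MCG", [((0, 0), 100), ((0, 1), 100)]), ("SCG", [((3, 3), 100)])],
        )
        assert victory_probability(
            world.groups[0], world.groups[1], world, law="squared"
        ) == pytest.approx(0.8)

    def test_empty_opponent_is_certain_defeat(self, all_high_7x7):
        world = make_world(
            all_high_7x7, [("SCG", [((0, 0), 80)]), ("SCG", [((3, 3), 80)])]
        )
        world.cells[(3, 3)].population = 0.0
        assert victory_probability(world.groups[0], world.groups[1], world) == 1.0

    @given(
        n_a=st.floats(min_value=0.1, max_value=1e6),
        n_b=st.floats(min_value=0.1, max_value=1e6),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_complementarity(self, n_a, n_b):
        ls = make_landscape(7, 7, "all")
        world = make_world(ls, [("SCG", [((0, 0), n_a)]), ("SCG", [((3, 3), n_b)])])
        p = victory_probability(world.groups[0], world.groups[1], world)
        q = victory_probability(world.groups[1], world.groups[0], world)
        assert p + q == pytest.approx(1.0)
        assert 0.0 <= p <= 1.0


class TestChooseAction:
    def test_below_capacity_is_static(self, all_high_7x7):
        world = make_world(all_high_7x7, [("SCG", [((3, 3), 90)])])
        assert choose_action((3, 3), world, PARAMS).kind is ActionKind.STATIC

    def test_empty_neighbor_means_bud(self, all_high_7x7):
        world = make_world(
            all_high_7x7, [("SCG", [((3, 3), 103)])], rng=ScriptedRng(integers=[0])
        )
        action = choose_action((3, 3), world, PARAMS)
        assert action.kind is ActionKind.BUD
        assert action.target == (2, 3)  # first neighbor in row-major order

    def test_foreign_neighbor_war_when_draw_below_propensity(self, all_high_7x7):
        world = make_world(
            all_high_7x7,
            [("SCG", [((3, 3), 103)]), ("SCG", [((2, 3), 80)])],
            rng=ScriptedRng(integers=[0], randoms=[0.05]),
        )
        action = choose_action((3, 3), world, PARAMS)  # p_war = 0.103 > 0.05
        assert action.kind is ActionKind.WAR and action.target == (2, 3)

    def test_foreign_neighbor_static_when_draw_above_propensity(self, all_high_7x7):
        world = make_world(
            all_high_7x7,
            [("SCG", [((3, 3), 103)]), ("SCG", [((2, 3), 80)])],
            rng=ScriptedRng(integers=[0], randoms=[0.5]),
        )
        assert choose_action((3, 3), world, PARAMS).kind is ActionKind.STATIC

    def test_own_group_neighbor_is_static(self, all_high_7x7):
        world = make_world(
            all_high_7x7,
            [("MCG", [((3, 3), 103), ((2, 3), 50)])],
            rng=ScriptedRng(integers=[0]),
        )
        assert choose_action((3, 3), world, PARAMS).kind is ActionKind.STATIC


class TestBud:
    def test_scg_bud_founds_new_lineage_member(self, all_high_7x7):
        world = make_world(all_high_7x7, [("SCG", [((3, 3), 103)])])
        world.groups[0].marker = 7
        bud((3, 3), (3, 4), world)
        world.audit()
        assert len(world.groups) == 2
        daughter = world.groups[world.cells[(3, 4)].group_id]
        assert daughter.kind is GroupKind.SCG
        assert daughter.marker == 7  # heritable lineage marker
        assert world.cells[(3, 3)].population == pytest.approx(51.5)
        assert world.cells[(3, 4)].population == pytest.approx(51.5)

    def test_bud_daughter_colour_follows_patch(self):
        ls = make_landscape(5, 5, [(2, 2)])  # parent HIGH, all targets LOW
        world = make_world(ls, [("SCG", [((2, 2), 103)])])
        bud((2, 2), (2, 3), world)
        daughter = world.groups[world.cells[(2, 3)].group_id]
        assert not ls.is_high((2, 3))  # a red SCG by patch colour

    def test_mcg_bud_extends_group(self, all_high_7x7):
        world = make_world(all_high_7x7, [("MCG", [((3, 3), 103), ((3, 2), 60)])])
        bud((3, 3), (3, 4), world)
        world.audit()
        assert len(world.groups) == 1
        assert len(world.groups[0].member_coords) == 3

    def test_bud_conserves_population(self, all_high_7x7):
        world = make_world(all_high_7x7, [("SCG", [((3, 3), 103)])])
        before = sum(c.population for c in world.cells.values())
        bud((3, 3), (3, 4), world)
        after = sum(c.population for c in world.cells.values())
        assert after == pytest.approx(before)
        assert len(world.cells) == 2

    def test_bud_rejects_occupied_target(self, all_high_7x7):
        world = make_world(
            all_high_7x7, [("SCG", [((3, 3), 103)]), ("SCG", [((3, 4), 30)])]
        )
        with pytest.raises(StateError):
            bud((3, 3), (3, 4), world)


def two_group_world(rng):
    """Attacker MCG (103 + 97 = 200 persons) adjacent to a blue SCG of 50."""
    ls = make_landscape(7, 7, "all")
    return make_world(
        ls,
        [("MCG", [((3, 3), 103), ((3, 2), 97)]), ("SCG", [((3, 4), 50)])],
        rng=rng,
    )


class TestResolveWar:
    def test_attacker_victory_captures_and_splits(self):
        world = two_group_world(ScriptedRng(randoms=[0.0]))  # 0.0 < 0.8 -> attacker wins
        events = resolve_war((3, 3), (3, 4), world, PARAMS)
        world.audit()
        assert 1 not in world.groups  # defender SCG extinct
        assert world.cells[(3, 4)].population == pytest.approx(51.5)
        assert world.cells[(3, 3)].population == pytest.approx(51.5)
        assert world.cells[(3, 4)].group_id == 0  # captured by the MCG
        assert {e["type"] for e in events} == {"WAR", "EXTINCTION"}

    def test_defender_victory_attrition_formula(self):
        world = two_group_world(ScriptedRng(randoms=[0.99]))  # 0.99 >= 0.8 -> defender wins
        resolve_war((3, 3), (3, 4), world, PARAMS)
        world.audit()
        assert (3, 3) not in world.cells  # engaged attacker cell destroyed
        # attrition = c1 * (50/250) * 50 = 10 persons off the remaining 97
        assert group_population(world.groups[0], world) == pytest.approx(87.0)
        assert world.cells[(3, 4)].population == 50  # defender untouched

    def test_scg_attacker_capture_founds_new_scg(self, all_high_7x7):
        world = make_world(
            all_high_7x7,
            [("SCG", [((3, 3), 103)]), ("SCG", [((3, 4), 50)])],
            rng=ScriptedRng(randoms=[0.0]),
        )
        world.groups[0].marker = 3
        resolve_war((3, 3), (3, 4), world, PARAMS)
        world.audit()
        winner_daughter = world.groups[world.cells[(3, 4)].group_id]
        assert winner_daughter.kind is GroupKind.SCG
        assert winner_daughter.id != 0 and winner_daughter.marker == 3

    def test_war_never_increases_population(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            world = two_group_world(np.random.default_rng(int(rng.integers(2**31))))
            before = sum(c.population for c in world.cells.values())
            resolve_war((3, 3), (3, 4), world, PARAMS)
            after = sum(c.population for c in world.cells.values())
            assert after <= before + 1e-9
            world.audit()

    def test_same_group_war_rejected(self, all_high_7x7):
        world = make_world(all_high_7x7, [("MCG", [((3, 3), 103), ((3, 4), 50)])])
        with pytest.raises(StateError):
            resolve_war((3, 3), (3, 4), world, PARAMS)

    def test_empirical_win_rate_two_to_one(self):
        """Monte-Carlo check of the linear law: 200 vs 100 -> 2/3 +- 0.01."""
        rng = np.random.default_rng(12345)
        ls = make_landscape(5, 5, "all")
        wins = 0
        n = 10_000
        for _ in range(n):
            world = make_world(
                ls,
                [("MCG", [((2, 2), 100), ((2, 1), 100)]), ("SCG", [((2, 3), 100)])],
                rng=rng,
            )
            events = resolve_war((2, 2), (2, 3), world, PARAMS)
            wins += events[0]["winner_id"] == 0
        assert wins / n == pytest.approx(2 / 3, abs=0.01)
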