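"""Yearly scheduler, full-run driver and replicate-ensemble runner.

One simulated year is: a growth phase over every cell, then a batch of
``decisions_per_year`` cells sampled uniformly without replacement (all
cells if fewer exist), each executing its expansion decision in sampled
order with a fusion check immediately after each decision, then the year
counter advances.  Cells created mid-year (buds, captured patches) are not
eligible for that year's remaining slots, and a slot whose sampled cell
was destroyed earlier in the year is skipped.

Runs are fully determined by (params, seed); replicate ensembles derive
per-replicate seeds additively from a base seed so they are reproducible
across platforms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .actions import EVENT_COLUMNS, ActionKind, WarParams, bud, choose_action, resolve_war
from .fusion import FusionParams, attempt_fusion
from .landscape import AggregationMode, ConfigurationError, generate_landscape
from .metrics import YearCensus, census, census_frame, size_histogram
from .world import World, grow_all, place_initial_groups


@dataclass
class SimulationParams:
    """Full configuration of one numerical experiment.

    The defaults are the baseline condition: a 33x33 lattice with a 1:1
    LP:HP random patch layout, carrying capacities 50/100 and growth rates
    0.01/0.03 on low/high patches, 10 red and 10 blue initial SCGs of 30
    persons, war constants c=0.001 and c1=1, fusion of >=4 blue SCGs above
    90% of capacity, 20 decisions per year, and a 600-year horizon.
    """

    width: int = 33
    height: int = 33
    lp_hp_ratio: tuple[int, int] = (1, 1)
    aggregation_mode: AggregationMode = AggregationMode.RANDOM
    K_H: float = 100.0
    K_L: float = 50.0
    r_H: float = 0.03
    r_L: float = 0.01
    n_blue: int = 10
    n_red: int = 10
    init_pop: float = 30.0
    c: float = 0.001
    c1: float = 1.0
    fusion_threshold: int = 4
    cc_fraction: float = 0.90
    decisions_per_year: int = 20
    years: int = 600
    seed: int = 0
    n_reps: int = 15
    # engineering switches (not part of the baseline experiment design)
    sample_with_replacement: bool = False
    bud_seed_size: float | None = None
    victory_law: str = "linear"
    attrition_scale: str = "winner_group"
    histogram_every: int = 100

    def __post_init__(self) -> None:
        self.lp_hp_ratio = tuple(self.lp_hp_ratio)
        self.aggregation_mode = AggregationMode(self.aggregation_mode)

    def validate(self) -> None:
        if self.years < 1:
            raise ConfigurationError(f"years must be >=1, got {self.years}")
        if self.decisions_per_year < 0:
            raise ConfigurationError(
                f"decisions_per_year must be >=0, got {self.decisions_per_year}"
            )
        if self.n_reps < 1:
            raise ConfigurationError(f"n_reps must be >=1, got {self.n_reps}")
        # delegate range checks to the component parameter types
        self.war_params()
        self.fusion_params()

    def war_params(self) -> WarParams:
        return WarParams(
            c=self.c,
            c1=self.c1,
            victory_law=self.victory_law,
            attrition_scale=self.attrition_scale,
        )

    def fusion_params(self) -> FusionParams:
        return FusionParams(threshold=self.fusion_threshold, cc_fraction=self.cc_fraction)


@dataclass
class SimulationResult:
    """Everything one run produced.

    ``census`` has one row per simulated year (years 0..years-1, each
    recorded at the start of the year, i.e. the state reached after that
    many completed years); the state after the final year lives in
    ``final_world``.  ``histograms`` holds MCG size histograms sampled
    every ``histogram_every`` years and at the final year.
    """

    params: SimulationParams
    seed: int
    census: pd.DataFrame
    events: pd.DataFrame
    final_world: World
    histograms: dict[int, pd.Series] = field(default_factory=dict)

    def final_census(self) -> YearCensus:
        return census(self.final_world)


def step_year(world: World, params: SimulationParams, events: list | None = None) -> World:
    """Advance the world by one year in place (also returns it)."""
    if events is None:
        events = []
    world.year += 1
    grow_all(world)
    n = len(world.cells)
    d = params.decisions_per_year
    if d > 0 and n > 0:
        coords = sorted(world.cells)
        if params.sample_with_replacement:
            idx = world.rng.integers(0, n, size=d)
        else:
            idx = world.rng.choice(n, size=min(d, n), replace=False)
        war_params = params.war_params()
        fusion_params = params.fusion_params()
        slots = [(coords[i], world.cells[coords[i]].group_id) for i in idx]
        for coord, gid in slots:
            cell = world.cells.get(coord)
            if cell is None or cell.group_id != gid:
                continue  # destroyed earlier this year
            action = choose_action(coord, world, war_params)
            if action.kind is ActionKind.BUD:
                events.extend(bud(coord, action.target, world, params.bud_seed_size))
            elif action.kind is ActionKind.WAR:
                events.extend(resolve_war(coord, action.target, world, war_params))
            fusion_event = attempt_fusion(world, fusion_params)
            if fusion_event is not None:
                events.append(fusion_event)
    return world


def run_simulation(params: SimulationParams) -> SimulationResult:
    """Initialise the world and iterate ``params.years`` yearly steps.

    The census records the state at the start of each year (year 0 is the
    initial placement), giving exactly ``years`` rows; the final state is
    kept as ``final_world``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    landscape = generate_landscape(
        params.width,
        params.height,
        params.lp_hp_ratio,
        params.aggregation_mode,
        rng,
        K_H=params.K_H,
        K_L=params.K_L,
        r_H=params.r_H,
        r_L=params.r_L,
    )
    world = place_initial_groups(landscape, params.n_blue, params.n_red, params.init_pop, rng)
    events: list[dict] = []
    censuses: list[YearCensus] = []
    histograms: dict[int, pd.Series] = {}
    for _ in range(params.years):
        censuses.append(census(world))
        if params.histogram_every and world.year % params.histogram_every == 0:
            histograms[world.year] = size_histogram(world)
        step_year(world, params, events)
    histograms[world.year] = size_histogram(world)
    events_df = pd.DataFrame(events, columns=EVENT_COLUMNS)
    return SimulationResult(
        params=params,
        seed=params.seed,
        census=census_frame(censuses),
        events=events_df,
        final_world=world,
        histograms=histograms,
    )


def run_replicates(
    params: SimulationParams, n_reps: int | None = None, base_seed: int | None = None
) -> list[SimulationResult]:
    """Independent replicate runs with seeds base_seed, base_seed+1, ..."""
    if n_reps is None:
        n_reps = params.n_reps
    if n_reps < 1:
        raise ConfigurationError(f"n_reps must be >=1, got {n_reps}")
    if base_seed is None:
        base_seed = params.seed
    return [
        run_simulation(dataclasses.replace(params, seed=base_seed + i)) for i in range(n_reps)
    ]
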