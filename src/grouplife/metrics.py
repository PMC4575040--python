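"""Census, size-distribution, emergence and dominance statistics.

Per-year censuses count groups by kind and colour (a red SCG sits on a
low-productivity patch, a blue SCG on a high-productivity one) along with
cells belonging to MCGs and the footprint of the largest MCG.  MCG size
distributions use the fixed binning 2-10, 11-20, ..., 91-100, 101-200,
..., 401-500, >500 cells.  Ensemble summaries are per-year sample means
and standard deviations (n-1 denominator) over replicate runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .landscape import Landscape
from .world import Group, GroupKind, World

#: (low, high) inclusive cell-count edges of the MCG size bins; None = open.
SIZE_BIN_EDGES: tuple[tuple[int, int | None], ...] = tuple(
    [(2, 10)]
    + [(lo, lo + 9) for lo in range(11, 100, 10)]
    + [(lo, lo + 99) for lo in range(101, 500, 100)]
    + [(501, None)]
)

SIZE_BIN_LABELS: tuple[str, ...] = tuple(
    f"{lo}-{hi}" if hi is not None else f">{lo - 1}" for lo, hi in SIZE_BIN_EDGES
)


@dataclass
class YearCensus:
    year: int
    n_red_scg: int
    n_blue_scg: int
    n_mcg: int
    n_mcg_cells: int
    n_cells_total: int
    largest_mcg_cells: int
    largest_mcg_occupancy_fraction: float


def census(world: World) -> YearCensus:
    """Count groups by kind and colour in the current world state."""
    n_red = n_blue = n_mcg = n_mcg_cells = largest = 0
    for group in world.groups.values():
        if group.kind is GroupKind.SCG:
            (coord,) = group.member_coords
            if world.landscape.is_high(coord):
                n_blue += 1
            else:
                n_red += 1
        else:
            n_mcg += 1
            size = len(group.member_coords)
            n_mcg_cells += size
            largest = max(largest, size)
    return YearCensus(
        year=world.year,
        n_red_scg=n_red,
        n_blue_scg=n_blue,
        n_mcg=n_mcg,
        n_mcg_cells=n_mcg_cells,
        n_cells_total=len(world.cells),
        largest_mcg_cells=largest,
        largest_mcg_occupancy_fraction=largest / world.landscape.n_patches,
    )


def census_frame(censuses: Iterable[YearCensus]) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in censuses])


def size_histogram(world: World) -> pd.Series:
    """MCG cell counts binned on the fixed edges; sums to the MCG count."""
    counts = np.zeros(len(SIZE_BIN_EDGES), dtype=int)
    for group in world.groups.values():
        if group.kind is not GroupKind.MCG:
            continue
        size = len(group.member_coords)
        for i, (lo, hi) in enumerate(SIZE_BIN_EDGES):
            if size >= lo and (hi is None or size <= hi):
                counts[i] += 1
                break
    return pd.Series(counts, index=list(SIZE_BIN_LABELS), name="n_mcg")


def first_mcg_emergence_year(result) -> int | None:
    """Year of the earliest fusion event in a run, or None if none occurred."""
    events = result.events
    if events is None or len(events) == 0:
        return None
    fusions = events[events["type"] == "FUSION"]
    if fusions.empty:
        return None
    return int(fusions["year"].min())


def mcgs_formed(result) -> int:
    """Cumulative number of MCGs formed during a run (fusion events)."""
    events = result.events
    if events is None or len(events) == 0:
        return 0
    return int((events["type"] == "FUSION").sum())


def occupancy_fraction(group: Group, landscape: Landscape) -> float:
    """Fraction of lattice patches occupied by the group's cells."""
    return len(group.member_coords) / landscape.n_patches


@dataclass
class EnsembleSummary:
    """Per-year means/SDs over replicates, plus run-level aggregates.

    ``per_year`` is long-format with columns year, field, mean, sd.  With a
    single replicate SDs are reported as 0 and ``single_replicate`` flags
    that they are not estimates.
    """

    per_year: pd.DataFrame
    mcgs_formed_mean: float
    mcgs_formed_sd: float
    final_histogram_mean: pd.Series
    final_histogram_sd: pd.Series
    n_replicates: int
    single_replicate: bool


def _sd(values: np.ndarray, axis: int = 0) -> np.ndarray:
    if values.shape[axis] < 2:
        return np.zeros_like(values.mean(axis=axis), dtype=float)
    return values.std(axis=axis, ddof=1)


def ensemble_summary(results: Sequence) -> EnsembleSummary:
    """Summarise replicate runs with matched horizons."""
    if not results:
        raise ValueError("ensemble_summary needs at least one result")
    horizons = {len(r.census) for r in results}
    if len(horizons) != 1:
        raise ValueError(f"replicates have mismatched horizons: {sorted(horizons)}")
    single = len(results) == 1

    fields = [c for c in results[0].census.columns if c != "year"]
    stacked = np.stack([r.census[fields].to_numpy(dtype=float) for r in results])
    years = results[0].census["year"].to_numpy()
    mean = stacked.mean(axis=0)
    sd = _sd(stacked, axis=0)
    per_year = pd.DataFrame(
        {
            "year": np.repeat(years, len(fields)),
            "field": np.tile(fields, len(years)),
            "mean": mean.ravel(),
            "sd": sd.ravel(),
        }
    )

    formed = np.array([mcgs_formed(r) for r in results], dtype=float)
    hists = np.stack([size_histogram(r.final_world).to_numpy(dtype=float) for r in results])
    labels = list(SIZE_BIN_LABELS)
    return EnsembleSummary(
        per_year=per_year,
        mcgs_formed_mean=float(formed.mean()),
        mcgs_formed_sd=float(_sd(formed)),
        final_histogram_mean=pd.Series(hists.mean(axis=0), index=labels, name="mean"),
        final_histogram_sd=pd.Series(_sd(hists, axis=0), index=labels, name="sd"),
        n_replicates=len(results),
        single_replicate=single,
    )
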