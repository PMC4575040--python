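# Model description and methods

## Overview

`grouplife` simulates the demography and territorial dynamics of human
sociocultural groups on a square lattice of land patches. The unit of
state is the *cell*: the population of one group on one patch. Groups are
either single-celled (SCG) — small, autonomous communities — or
multicellular (MCG) — large, structured polities born by the fusion of
several near-capacity SCGs. The model's purpose is to study when the
SCG→MCG transition happens, how MCGs subsequently spread by budding and
warfare, and what distribution of group sizes the competition settles
into.

## State and parameters

A patch is high-productivity (HP) or low-productivity (LP); productivity
is fixed at generation time and sets the patch's carrying capacity and
growth rate. The lattice has absorbing edges: border patches simply have
2 or 3 von Neumann neighbours instead of 4.

| Parameter | Default | Meaning |
|---|---|---|
| `width × height` | 33 × 33 | lattice size (patches) |
| `lp_hp_ratio` | 1:1 | LP:HP patch ratio; the LP share is rounded half-up |
| `aggregation_mode` | random | HP layout: uniform random, or 3×3 / 7×7 / 9×9 HP blocks |
| `K_H`, `K_L` | 100, 50 | carrying capacities (persons per patch) |
| `r_H`, `r_L` | 0.03, 0.01 | annual growth rates |
| `n_blue`, `n_red` | 10, 10 | initial SCGs on HP / LP patches |
| `init_pop` | 30 | initial persons per SCG |
| `c` | 0.001 | population weight in the war-propensity function (per person) |
| `c1` | 1 | attrition cost scale |
| `fusion_threshold` | 4 | minimum number of blue SCGs that fuse |
| `cc_fraction` | 0.90 | fusion eligibility cut as a fraction of K (strict >) |
| `decisions_per_year` | 20 | cells sampled for decisions each year |
| `years` | 600 | run horizon |
| `n_reps` | 15 | replicates per ensemble |

A group's *redness* (aggression) is the unweighted mean over its member
cells of the patch indicator (LP cell → 1, HP cell → 0). An SCG on an LP
patch ("red SCG") has redness 1; on an HP patch ("blue SCG") redness 0.
Group identity markers are heritable: an SCG daughter born by budding or
by capturing a patch keeps its parent's marker, while every new MCG
receives a fresh marker above all prior ids.

## The yearly cycle

1. **Growth.** Every cell with `N ≤ K` grows to `N(1+r)`. Growth may
   overshoot `K` by one multiplicative step and then freezes. The
   overshoot is deliberate: a cell strictly above its capacity is exactly
   the condition for it to act, so without it nothing would ever expand.
2. **Decisions.** `decisions_per_year` cells are drawn uniformly without
   replacement (all cells when fewer exist). In sampled order, each cell
   above its capacity inspects *one* uniformly drawn neighbouring patch:
   - empty → **bud**: the cell splits half its population onto the patch.
     An SCG parent founds a new, independent SCG of its lineage; an MCG
     parent gains a cell.
   - foreign group → **war** with probability
     `min(1, redness + c · N_group)`, else static.
   - own group, or a declined war → static.
   Cells created during the year are not eligible for the year's remaining
   slots; a slot whose cell was destroyed earlier that year is skipped.
3. **Fusion check** after every decision: if at least `fusion_threshold`
   blue SCGs sit strictly above `cc_fraction · K_H`, one eligible group is
   drawn uniformly as reference; if at least `fusion_threshold − 1` of its
   von Neumann neighbours hold eligible blue SCGs, the reference and *all*
   its adjacent eligible SCGs merge into one new MCG. Fusion conserves
   population and occupancy exactly.

Wars resolve on total group populations with the linear (Lanchester) law
`P(attacker wins) = N_A / (N_A + N_B)`. A winning attacker destroys the
defending cell and splits its engaged cell onto the captured patch; a
winning defender destroys the attacking cell and the patch stays empty
(defenders do not gain territory). The losing group then pays an attrition
cost `c1 · p_win · N_winner-group`, removed proportionally across its
remaining cells; cells that fall below one person are culled, and a group
with no cells left is extinct. MCGs fragmented by war keep their identity
(an MCG split into disconnected parts, or reduced to a single cell,
remains one MCG).

## Design choices made where the design was open

- **Real-valued populations.** Integer truncation would distort the low
  growth rates (0.5 %/year); populations are floats throughout.
- **Attrition scale.** The cost paid by the losing side scales with the
  *winning group's total population* (`attrition_scale="winner_group"`).
  This is what lets a single lost war strip a large polity of hundreds of
  cells at once — the catastrophic, recoverable losses that dominant
  groups display. An engaged-cell-scaled variant
  (`attrition_scale="engaged_cell"`), under which a war can remove at most
  about one cell's worth of people, is kept for comparison.
- **Victory law.** Linear by default; the squared law
  (`victory_law="squared"`), which favours large groups
  disproportionately and better fits modern warfare, is available but is
  not used in the baseline experiments.
- **Capture by an SCG.** A patch captured by an SCG founds a new SCG of
  the same lineage (SCGs have exactly one cell by definition, and MCGs
  are born only by fusion, so the captured cell cannot simply join).
- **Budding split.** 50/50 between parent and daughter; a fixed daughter
  size is available as `bud_seed_size`.
- **Fusion adjacency** is reference-centric: the reference's direct von
  Neumann neighbours, not a connected cluster of eligible groups.
- **Quota rounding.** The LP patch count is `round_half_up(total ·
  LP/(LP+HP))`; LP absorbs the remainder, so 1:1 on 1089 patches gives
  545 LP / 544 HP.
- **Seeding.** One integer seed drives landscape, placement and all
  within-run draws; replicate *i* of an ensemble uses `base_seed + i`.

## Numerical and degenerate-input conventions

Eligibility and decision cuts are strict inequalities (`N > 0.9 K`,
`N > K`). A war between two empty groups is a state error rather than a
coin flip. Ensemble standard deviations use the n−1 denominator; a
single-replicate ensemble reports SD 0 and sets a `single_replicate`
flag. Census rows record the state at the start of each year (year 0 is
the initial placement), giving exactly `years` rows; the state after the
final year is kept as the run's final-world snapshot. Histogram bins for
MCG sizes are 2–10, 11–20, …, 91–100, 101–200, …, 401–500, > 500 cells.

## What the simulations show — and what they cannot

The generator *is* the study system: there is no external data, and the
baseline parameter set above defines the experimental conditions. Under
it, the model reproduces the qualitative regularities robustly across
seeds: MCGs first emerge after roughly a century of SCG demography
(later when growth rates are halved); lowering the fusion threshold
makes MCGs earlier and more numerous; LP-dominated landscapes (3:1)
produce few, highly variable MCGs while HP-dominated ones (1:3) produce
many; SCG counts rise and then decline as MCG territory expands; and over
long horizons group sizes concentrate, with the number of MCGs falling
while the largest keeps growing.

Absolute event counts are sensitive to the exact functional forms of the
war-propensity, victory and cost equations and to the per-decision fusion
kernel, which are only partially constrained by the sources this model is
built from. With the forms above, cumulative MCG formation runs higher
(≈ 20–30 per 600 years at threshold 4) than the headline counts this
model family is known for (≈ 8), which also thins the extreme right tail
of the size distribution at year 600 and delays single-group dominance
past the 600-year mark (a peak single-MCG share of ~35–55 % of the
lattice by year 1660, varying by seed). The acceptance suite asserts the
published absolute values at their stated tolerances, so those checks
fail under this implementation while every ordering and structural
property passes; the module boundaries keep the combat and fusion kernels
swappable should the original equations become available.

The model is a deliberately minimal abstraction: no within-patch
age/sex structure, no migration between a group's own cells, no resource
depletion, no fragmentation of over-extended polities (scalar stress), no
cultural mutation of identity markers, and no rational decision-making —
expansion choices are random. Conclusions about real sociopolitical
history should rest on the qualitative, not the numeric, behaviour.

## Problem sizes used in the test and acceptance runs

Unit and property tests use small lattices (5×5 to 9×9) and short
horizons. Ensemble checks use the full baseline design — 15 replicates ×
600 years per condition — and the long-horizon dominance check uses 3
replicates × 1660 years; a full acceptance recomputation takes a few
minutes on one CPU.
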