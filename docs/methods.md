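# Methods

## The model

`reefrisk` implements a discrete Bayesian network for the probability of
hard-coral-cover decline on a mid-shelf, mid-latitude reef over a ten-year
horizon. Nodes come in four kinds:

* **input** — observed per-reef stressor categories (temperature anomaly,
  cyclone exposure, flood-plume exposure, nutrient/sediment/pollutant loads,
  irradiance, fishing effort), each with three ordered states
  `below < average < above` on an increasing-adversity order;
* **composite** — deterministic weighted indices. `water_quality` combines
  plume, nutrient, sediment and pollutant categories; `anthro_stress`
  combines fishing and water quality. The weighted mean of normalized parent
  ordinals is cut at 1/3 and 2/3 into `low/medium/high` (both thresholds and
  weights configurable; defaults are equal weights);
* **event** — latent stress events (`bleaching`, `disease`, `cots`) with
  states `decreased < unchanged < increased` frequency;
* **outcome** — binary `coral_decline` (`no_decline` / `decline`).

The default wiring is temperature + irradiance + water quality → bleaching;
temperature + water quality → disease; water quality → CoTS; and all three
events + cyclones + anthropogenic stress → outcome. Published descriptions
of networks of this kind are schematic about exact parent sets, so this
wiring is explicitly an assumption: it ships as an editable YAML structure
file and every routine accepts a custom structure. Cyclones act on the
outcome directly rather than through `anthro_stress` because cyclone
exposure is not anthropogenic. Larval connectivity between reefs is
deliberately absent.

Inference is exact variable elimination over the CPT factors, eliminating
hidden nodes in topological order — appropriate because the network has a
dozen nodes and at most ~3⁵ outcome rows. Results agree with full-joint
enumeration to 1e-12 (tested on 100 random networks), and no approximate
machinery exists in the package.

## Elicitation and parameterization

Experts answer with the 4-point method: lowest possible value, best
estimate, highest possible value, and confidence (a credible level in
percent) for each required probability. Confidence handling is not pinned
down by the method itself; the package linearly rescales the interval
half-widths by `target_level / confidence` (default target 90 %), clamped to
[0, 1], leaving the best estimate untouched. This is the standard treatment
for 4-point data, and since only pooled *best estimates* feed the
parameterizations (standardized intervals are retained for diagnostics
only), the choice cannot silently change headline outputs.

For each elicited node, experts state the distribution over its states at
the two parent extremes only ("all stressors low", "all stressors high");
the full CPT is filled by linear interpolation between those endpoint rows.
The interpolation coordinate is the mean normalized parent ordinal
(`ordinal_score`): 0 iff all parents are least adverse, 1 iff all are most
adverse. This is the simplest coordinate consistent with endpoint
interpolation; rows at the endpoints reproduce the elicited distributions
bit-for-bit, and interior rows are renormalized convex combinations, so when
the high endpoint stochastically dominates the low one, every
single-parent adversity increase weakly increases the decline probability.

Pooling uses equal expert weights. Percentiles use linear interpolation
between order statistics (numpy's default), configurable only in the sense
that the convention is documented here and isolated in one function. Three
parameterizations are built:

* `mean` — group mean per quantity;
* `pessimistic` / `optimistic` — 25th/75th percentiles with an
  **orientation map**: a quantity whose state sits above the middle of the
  adversity order is adverse (pessimistic takes its 75th percentile), below
  the middle beneficial (25th), the middle state neutral (mean). This makes
  "pessimistic" mean *higher adverse probabilities* for every quantity. A
  `literal` mode (pessimistic = 25th percentile of everything) is provided
  because elicitation reports sometimes use the percentile label directly;
  the default is the orientation-consistent mode, and after per-entry
  pooling each endpoint distribution is renormalized. Under this
  construction the pessimistic endpoint distributions stochastically
  dominate the optimistic ones, hence pessimistic decline ≥ optimistic
  decline for every evidence assignment (asserted exhaustively in the test
  suite).

## Layers, effort and zoning

Continuous layers are re-coded as `above` iff value ≥ mean + SD, `below` iff
value ≤ mean − SD ("one standard deviation **or more**" — boundaries belong
to the extreme categories); temperature uses the fixed ±1 °C anomaly rule
with *strict* inequalities (the boundary is `average`). Layer statistics are
computed table-wide over mid-shelf reefs by default; a stats file can
override them, since whether the original statistics were fleet-wide or
climatological per reef is not recoverable.

Fishing effort reported on a coarse confidentiality-limited grid is
reapportioned onto fine cells proportionally to the fine-scale weight
distribution within each block; per-block mass is conserved exactly, and a
block with positive effort but all-zero weights is an error rather than a
silent drop. Reefs flagged no-take are assigned zero effort before
discretization. Evidence is taken at reef centroids as given in the input
table; polygon-to-centroid reduction and all raster/GIS preprocessing are
upstream of this package.

## Scenarios

A scenario is a per-variable categorical shift (−1/0/+1), a temperature
delta, and a cyclone multiplier. The four shipped scenarios: baseline
(no change); climate (+0.2 °C, cyclones ×1.3, disease and bleaching up one
state); climate + management (as climate, plus nutrients, sediment,
pollution and fishing down one state); management only (the reductions
alone). The ~30 % management reductions are encoded as a −1 category shift
because the model only sees categories; the cyclone increase defaults to the
multiplier on the continuous exposure applied *before* discretization, with
the categorical `+1` shift available as an alternative mechanism. Flood-plume
exposure stays at baseline in all four scenarios.

Shifts on the latent event nodes cannot be evidence (events are never
observed); they are implemented as a clamped state-shift of the event CPT's
rows — mass at state *i* moves to state *i + shift*, clamped at the ends.
This preserves row normalization and stochastic ordering, so scenario
monotonicity (climate ≥ baseline ≥ management, per reef) follows from the
same dominance argument as above.

Change maps divide the between-scenario difference by the first scenario's
value, per reef; a reef with a zero first-scenario probability yields an
explicit undefined flag, never a number. Zone summaries are arithmetic means
over reefs (overall, no-take, open) with `difference = mean_open −
mean_no_take`; an empty zone is flagged undefined.

## Synthetic data

The generator emulates the study conditions: 775 mid-shelf reefs spanning
15.77–22.31 °S with a 0.33 no-take fraction, and 21 experts. Layer
distribution families (normal for temperature anomaly and irradiance,
Poisson for cyclone and CoTS counts, lognormal for fishing effort, gamma for
the load indices) are chosen for qualitative realism only — they are
synthetic stand-ins, not estimates of Great Barrier Reef conditions, and
carry no spatial autocorrelation, cyclone-track structure or bathymetry.
Passing tests therefore demonstrate correctness of the machinery under
known truths, not fidelity to real reef data.

Expert noise is symmetric additive on the probability scale with clamping to
[0, 1] (a logit-scale option exists for boundary-heavy truths). The default
"true" endpoint probabilities are kept within [0.1, 0.9]: at truth 0.9 and
noise SD 0.1 the clamp bias of the pooled mean is ≈ 0.008, comfortably
inside the 0.02 recovery tolerance the tests assert at n = 10,000 experts,
so recovery tests measure estimator behaviour rather than boundary
artefacts. High endpoints stochastically dominate low endpoints in the
default truth, which is what licenses the monotonicity assertions.

## Numerical choices and limitations

* CPT rows must sum to 1 within 1e-9; interpolated interior rows are
  renormalized, endpoint rows are copied verbatim.
* Posterior normalization guards against zero-probability evidence with an
  explicit error.
* Composite thresholds use ≥ comparisons, so an index exactly at 1/3 or 2/3
  takes the higher state; ties among expert best estimates need no special
  handling under linear-interpolation percentiles.
* All file formats round-trip bit-exactly (floats written with `repr`);
  the CPT file is a long-format CSV (node, parent combo, state,
  probability) because nodes have heterogeneous parent sets.
* Problem sizes in the test and acceptance runs (60–775 reefs, 100 random
  oracle networks, 10,000 simulated experts) were chosen to make every
  statistical assertion sharp at interactive runtimes.
* The model assumes uniform susceptibility across reefs of the modelled
  type, elicits one CPT set for all of them, and has no temporal dynamics:
  the ten-year horizon is semantic (the CPTs are elicited for it), not a
  discretized time axis. Conclusions about management effectiveness are
  conditional on the assumed wiring; alternative structures should be run
  through the same pipeline via the structure file.
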