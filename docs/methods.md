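# Methods

## Model structure and assumptions

The regulatory cascade is modelled at single-molecule, single-promoter
resolution. A cell's state is the vector of free monomer counts per species
plus one occupancy slot per promoter copy. Promoters have no DNA-sequence
representation; each is an operator that is either free or bound by exactly
one activator oligomer. Where two activators target the same promoter (BisR
and BisDC at P_alpA), occupancy is mutually exclusive — the minimal
single-operator logic. BisDC is one species; its heteromeric composition is
below the model's resolution. Transcription and translation are collapsed
into a single zero-order production step per bound promoter. There is no
cell growth, division, or partitioning: each simulated cell is an
independent closed reaction volume observed over 100 time units.

Key kinetic assumptions:

- **Oligomeric binding.** An activator binds as an n-mer assembled on the
  fly: the binding propensity is A1·C(x, n), the number of distinct n-mers
  that can form from x free monomers, times a per-oligomer rate. Default
  n = 2 for every node (typical transcription-factor dimerization);
  configurable per activator config.
- **Sequestration with protection.** Binding removes n monomers from the
  free pool; they cannot degrade while bound and return intact on
  unbinding. Protection is the simpler convention and matters only at very
  low copy numbers; it is configurable in the sense that a degradation
  channel for bound complexes can be added as an explicit promoter config.
- **Continuous time.** "Time steps" are continuous simulated time in an
  arbitrary unit; the horizon is t_end = 100 with endpoint observation at
  t = 100, not 100 discrete updates or SSA events. Rates are per the same
  arbitrary unit, so only rate ratios are meaningful.
- **Exact SSA.** The direct method (exponential waiting times from the
  total propensity, channel chosen proportionally) is used rather than
  tau-leaping: molecule numbers are O(10–100) and exactness is cheap at
  this scale. Counts are right-continuous at event times.

The zero state — all regulator counts and occupancies zero — is absorbing
in every preset because no promoter has basal activity. That absorption is
the mechanistic origin of the zero mode in all bimodal outputs.

## Parameters

All rates are per arbitrary time unit. A-prefixed rates belong to the
BisDC/P_alpA feedback node, B-prefixed to BisR acting on P_alpA, T-prefixed
to TciR acting on P_bisR (with production rate C5), L-prefixed to the late
node.

| rate | meaning | default |
|------|---------|---------|
| A1 | BisDC dimer binding to P_alpA | 0.01 |
| A2 | unbinding | 1.0 |
| A3 | BisDC production while P_alpA bound (either activator) | 10.0 |
| A4 | BisDC degradation | 0.1 |
| B1, B2 | BisR binding/unbinding at P_alpA | 0.01, 1.0 |
| B4 | BisR degradation | 0.02 |
| T1, T2 | TciR binding/unbinding at P_bisR | 0.0008, 1.0 |
| T4 | TciR degradation | 0.3 |
| C5 | BisR production while P_bisR bound | 40.0 |
| L1, L2, L3 | late-node binding/unbinding/production | 0.01, 1.0, 10.0 |
| L4 | late-protein degradation, stable / unstable | 0.02 / 0.1 |

The production rate while P_alpA is bound is A3 regardless of which
activator sits there: the bound promoter drives the same gene, so the
cascade-specific rate C5 is assigned to the P_bisR node only.

With these values the bare loop's positive state sits near A3/A4 times the
bound fraction (~98 molecules), with an unstable threshold around 3–4
molecules. Defaults were fixed once by the two documented anchors in
`analysis/00_calibrate.py`: (i) the bare feedback loop from a binomial
(mean 8) start must produce a clearly bimodal output with a separated
positive mode, and (ii) the default full cascade must place the
positive-state share inside the empirically observed 3–5% tc-cell band.
The cascade timescales (fast TciR pulse, large BisR bursts of mean C5
per binding, slow BisR decay) additionally keep every activated cell's
BisR visible inside the conventional [10, 20] integration window, so the
structural reading "no early BisR ⇒ no BisDC" holds per cell in practice;
with exponential lifetimes its converse cannot be literally impossible,
but under the defaults a counterexample occurs at the ~10⁻⁶ per cell
level (none in the shipped fixed-seed ensembles).

Default per-cell inputs (initial copy numbers; cells are i.i.d.): binomial
(16, 0.5), i.e. mean 8, for the feedback-only preset; uniform-integer
{0..16} (mean 8) for the kickstart and cascade presets. The uniform and
binomial mean-8 variants are both implemented because the two descriptions
of the feedback-loop input disagree at this level of detail; the binomial
form is the shipped default there. Dose–response sweeps use uniform
{0..2m} grids with m ∈ {1, 2, 4, 8, 16, 32}, within the copy-number range
typical of transcription factors; the zero-inflated ("bimodal") input is a
0/Poisson mixture. The `scale_multiplier` dose knob multiplies draws and
rounds half-up.

## Randomness and reproducibility

One root seed drives an ensemble. It spawns (via `numpy` `SeedSequence`)
one stream for input sampling and one child per cell, whose first 32-bit
word seeds that cell's jit-compiled Mersenne-Twister SSA stream. Records
are therefore reproducible bit-for-bit from (config, seed) and independent
of execution order; a run's JSON/YAML sidecar re-executes to identical
per-cell records.

## Readout definitions

- **Zero/positive partition.** A cell is "positive" iff its readout is
  > 0 — endpoint count at t = 100 for BisDC and the late protein, exact
  count-path integral over [10, 20] for the transient BisR node. No
  threshold above zero is applied anywhere.
- **Uncertainty.** Fractions carry normal-approximation standard errors;
  positive-state medians carry seeded percentile-bootstrap 95% intervals
  (1,000 resamples).
- **Histograms.** Integer-aligned bins with the zero state in its own
  [-0.5, 0.5) bin; the positive bin width (recorded in the summary) is an
  integer chosen so the range spans ≤ ~50 bins.

## Synthetic fluorescence and the qq estimator

The generator emulates the statistical structure of single-cell reporter
microscopy, not its optics: intensities are a two-component log-normal
mixture (background autofluorescence; activated cells, default 10× median
separation), or, bridging from simulation, background + gain × endpoint
count. Log-normal components reflect the strong right skew of real reporter
distributions — the same skew that motivates the 75th-percentile summary
(`percentile_summary`, numpy's linear/type-7 interpolation) over means.

The activated fraction is estimated by quantile–quantile comparison: sort
the intensities; fit the reference family (log-normal by default) to the
lower half of ranks by regressing log-values on standard-normal
plotting-position quantiles; flag values above the fitted quantile plus
k·sigma (k = 2 by default); take the lowest rank above which ≥ 95% of all
higher ranks are flagged, and report the flagged share above that
breakpoint. Counting only flagged cells (rather than the whole tail)
removes the upward bias the 5% persistence tolerance would otherwise
introduce. The fit window, k, and the persistence level are repository
calibrations chosen by the error tables in `analysis/00_calibrate.py`
(median |error| ≤ 0.01 across true fractions 1–20% at n = 1,000 and 10×
separation), not published constants. The estimator assumes activated
cells are a minority-to-half of the sample; beyond that the background fit
absorbs the activated mode and the estimate collapses — visible in the
readout script when doses are pushed high.

What passing tests on synthetic data do *not* show: robustness to
segmentation artifacts, spatial illumination gradients, day effects, or
background families departing from log-normal. The generator draws i.i.d.
cells from clean parametric components; real micrographs do not.

## Numerical choices and degenerate inputs

- Binomial coefficients in propensities are computed in floating point
  (exact for the relevant x ≲ 10⁴).
- An all-zero propensity vector ends the simulation; the state is held
  constant to t_end and window integrals are completed analytically.
- Event logs grow by doubling and replay deterministically from the same
  seed, so recorded and summary-only runs realize identical paths.
- `classify_states` on an all-zero population reports the positive median
  and IQR as absent rather than NaN-propagating.
- Empty grids, non-increasing dose levels, mismatched ablation ensembles,
  out-of-range windows, negative rates and non-integer oligomer orders are
  rejected with explicit messages; `validate` returns diagnostics without
  raising.

## Problem sizes

Shipped defaults: 10,000-cell ensembles for headline readouts (zero
fractions of a few percent are then resolved to ±0.2%), 5,000 cells per
sweep/dose grid point, 100 replicates per estimator calibration point.
The jit-compiled direct method runs all of these in seconds, so the sizes
match the resolution the claims need rather than any runtime ceiling.

## Known limitations

- No repressive branches, chromatin-free instantaneous binding, and a
  single promoter copy per node: the model is the minimal architecture
  that produces the bistable phenomenology, not a parametric fit.
- Absolute time and rate units are arbitrary; only ratios are calibrated,
  and only through the two anchors above.
- The positive state is metastable, not permanent: at infinite time every
  finite loop is absorbed at zero. The claims concern the t = 100 horizon.
- The qq estimator degrades gracefully but systematically once the
  activated fraction approaches the background-fit window (see above).
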