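# Methods

## The cross-scale estimation problem

Census-derived migration matrices are typically published at a coarse
administrative level (tens of units), while mobility-dependent applications
need flows between fine units (hundreds to thousands). Fitting a gravity
model at the coarse level and disaggregating is the usual workaround; this
package instead parameterises the model at the fine level and carries the
aggregation inside the likelihood, so the coarse observations constrain the
fine-scale coefficients directly. The broad-scale (single-level) model is
the degenerate case in which every coarse unit contains exactly one fine
unit, and the code paths coincide exactly there (this equality is tested).

## Model and likelihood

For each ordered fine pair (i, j), i ≠ j, the proportion of origin i's
population migrating to j over the study window is
`v_ij = logit⁻¹(β0 + β·x_ij)`, with the covariate vector x_ij assembled
from unit attributes (populations, urban fractions, per-capita economic
product, population-percentile indicators) and pair attributes (centroid
distance in km, binary contiguity). Coarse-pair proportions are the
population-weighted average over origins of the total proportion moving to
any unit of the destination group:

    P_IJ = Σ_{i∈I} N_i (Σ_{j∈J} v_ij) / Σ_{i∈I} N_i .

As printed in some accounts, the denominator of this aggregation carries an
extra factor of the number of destination units; under that reading P_IJ is
the mean sub-pair proportion rather than a proportion of I's population.
The origin-population denominator is the default because only it makes
`M_IJ ~ Binomial(N_I, P_IJ)` coherent; the per-destination-unit variant
remains available as `denominator="literal"` and is precisely the
population-weighted sub-pair mean that inverts uniform disaggregation.

Counts for distinct destinations from a common origin are treated as
independent binomials, not as one multinomial — Σ_J P_IJ is unconstrained.
The log-likelihood sums `M_IJ ln P_IJ + (N_I − M_IJ) ln(1 − P_IJ)` over
ordered coarse pairs I ≠ J; the combinatorial constant `ln C(N_I, M_IJ)` is
computed via log-gamma on request and omitted from MCMC, where it cancels.
N_I is the number of *sampled* persons at origin I (the motivating data are
a 10% census sample), and the synthetic generator draws counts at the same
sampling fraction so that generator and likelihood agree. Within-group
fine-pair proportions are produced by the aggregation but never enter the
likelihood or validation comparisons.

## Covariate standardization

Continuous covariates are scaled to mean 0 and sample sd 0.5 (division by
twice the sd, n−1 denominator) and binary covariates centred to mean 0 with
range 1, so that a coefficient of 1 corresponds to a substantively large
effect under the Cauchy(0, 2.5) slope priors (intercept: Cauchy(0, 10)).
Standardization is fitted on the pair-level design rows — where the
regression sees the data — not on the unit table; each transform is stored
in a `Scaler` and replayed bit-identically at prediction time. Population
percentiles use average ranks mapped to [0, 1]; the TINY/MAJCEN thresholds
are the linear-interpolation 10th/90th percentiles with strict
inequalities, so ties produce no flags. Populations enter untransformed
(standardized raw values, not logs).

## Posterior computation

The sampler is a Gaussian random-walk Metropolis with per-parameter
proposal scales. During burn-in, every `adapt_window` (default 100) steps
the scales adapt in the Haario spirit — each parameter's scale tracks
2.4/√p times the spread of its recent draws, and a common multiplier is
nudged multiplicatively until the window acceptance rate sits in the target
band (default 0.15–0.45). Adaptation freezes at the end of burn-in, so
retained draws come from a fixed-kernel chain. The full protocol is 5
chains × 150 000 steps, first half discarded, thinning every 10 (7 500
retained draws per chain); study-sized problems in the tests use 3 chains ×
20 000 steps, which the recovery results below justify.

Chain initialisation: each chain starts from the L-BFGS posterior mode plus
prior-distributed jitter (Cauchy draws truncated to |offset| ≤ 5, scaled by
`init_dispersion`, default 0.25), rejecting starts with non-finite
posterior (aggregated proportions can exceed 1 for implausible
coefficients, and the likelihood is −∞ there). Pure prior-tail starts were
observed to strand random-walk chains in a secondary posterior mode at
short chain lengths — R-hat flags it, but model selection then sees inflated
DICs — so mode-anchored dispersion is the default; it keeps chains distinct
enough for the Gelman–Rubin diagnostic to detect genuine non-mixing.

Convergence uses the classic (non-split) Gelman–Rubin PSRF,
`sqrt(((n−1)/n·W + B/n)/W)`; model comparison uses the Spiegelhalter DIC,
`Dbar + pD` with `pD = Dbar − D(posterior mean)`, computed from the
constant-free deviance (the constant would cancel in DIC differences).
Summaries report medians and central 95% intervals by linear-interpolation
quantiles.

## Forward selection

Selection starts from the basic gravity specification
{DIST_ij, POP_j, POP_i}; each iteration fits every remaining candidate
added singly and adopts the lowest-DIC candidate if it improves the
incumbent by more than the stop threshold (default 2, the conventional
"substantial" DIC difference; no threshold is prescribed by the procedure
this mirrors, so it is configurable). Failed candidate fits are skipped
with a warning; exact ties break by candidate order. Search fits may use
shortened chains, with the selected model refit at full settings.

## Synthetic landscapes

The generator emulates the statistical structure of the motivating inputs
without any geometry I/O: coarse units tile a planar grid of square cells
(default 100 km side), fine-unit seed points fall uniformly within their
cell, populations are log-normal (default median 15 000 persons, σ = 1 —
heavy-tailed like municipality sizes), urban fractions Beta(2, 2),
per-capita economic values log-normal (median 6, σ = 0.5, in thousands of
PPP dollars). Contiguity joins Delaunay neighbours of the seed points
(units are "contiguous" when their tessellation cells share a boundary),
augmented with each coarse cell's internal minimum spanning tree so every
coarse unit is internally connected — required for building contiguous
intermediate-level groupings by random merging. Default generative
coefficients (−6.0 intercept, −2.0 distance, +0.16 origin population,
−0.12 destination population on the standardized scale) reproduce the
qualitative sign pattern of fitted fine-scale models — strong distance
decay, mild opposing population effects — and give realistic five-year
outmigration totals of roughly 10% per origin.

What the generator does not emulate: real administrative geometry and
shared polygon boundaries, spatial autocorrelation of covariates,
multi-department intermediate units, overdispersion or zero-inflation
relative to the binomial, and within-origin dependence between
destinations. Passing recovery tests therefore show the estimator is
correct when the model is correctly specified; they do not certify
performance under real-data misspecification (a multinomial sampling
toggle exists for one such robustness probe).

## Numerical choices

- Linear predictors are clipped to |η| ≤ 35 before the inverse logit so
  v never rounds to exactly 0 or 1 in double precision.
- Aggregation inside MCMC is a precomputed sparse matrix–vector product;
  a proposal whose aggregated proportions leave (0, 1) gets log-posterior
  −∞ and is rejected.
- Raster imputation fills each missing cell with the mean of its
  non-missing Moore neighbours (truncated at borders), sweeping repeatedly
  so values propagate into interior holes; it terminates whenever at least
  one cell is known, and is idempotent on complete grids.
- Resampling is integer block replication (nearest neighbour, no
  smoothing); zonal statistics are unweighted over a zone's cells (how
  cells straddling zone boundaries should be weighted is unspecified in
  the motivating workflow, so the simple mean is used).
- Coordinates are planar kilometres throughout; map projections and
  geodesic distances are out of scope.
- Master seeds derive chain seeds and replicate seeds via
  `numpy.random.SeedSequence.spawn`, so every run is reproducible from one
  integer and no derived seed exceeds 2³¹.

## Problem sizes in the shipped studies

The parameter-recovery study uses 20 replicates of 8 coarse × 6 fine units
(2 256 ordered fine pairs) at sampling fraction 0.1 with 3 chains × 20 000
steps; the selection study uses 6 coarse × 5 fine landscapes with one
active candidate (URBANPROP_j, +0.9) among three. These sizes give tight
posteriors (worst-case median error ≈ 0.1 on the standardized scale) while
keeping the full suite fast; the acceptance script runs 5 replicates of
each study.

## Known limitations

- The sampler is a random-walk Metropolis; for strongly correlated or
  high-dimensional posteriors gradient-based samplers would mix better.
- DIC from heavily shortened chains is noisy; the selector's stop
  threshold of 2 assumes DIC Monte-Carlo error below that, which the
  mode-anchored initialisation and multi-chain averaging provide at the
  shipped settings but which should be rechecked for harder problems.
- The independent-binomial likelihood ignores the constraint
  Σ_J M_IJ ≤ N_I (enforced in data validation, not in the model).
- `coarsen_partition` only merges within coarse units; intermediate units
  spanning several coarse units are not representable.
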