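# Methods

This note records the modelling assumptions, parameter choices, numerical
decisions and known limitations behind the package. It documents how the
code behaves and why; every empirical statement here is one the test suite
or `scripts/acceptance.py` computes.

## Data model

A *yield panel* is a stations × years matrix of annual crop yields
(kg ha⁻¹), years strictly contiguous, missing entries carried as NaN.
Contiguity is required because lagged pairs are built positionally; a
panel with a hole in its year axis would silently misalign W_{t−1} with
W_t. Missing *values* (as opposed to missing years) are recovered by
per-station mean imputation: each gap is replaced by the mean of that
station's observed values, mirroring the recovery used for gap years in
national yield archives. The operation is idempotent and refuses stations
with fewer than two observations.

Min–max normalization maps W → (W − W_min)/(W_max − W_min). Bounds are
taken from the pooled *training* stations by default (`bounds_scope="train"`),
so test inputs may legitimately fall outside [0, 1]; they are mapped
linearly, never clipped, which keeps the transform exactly invertible and
evaluation in original units exact. A `bounds_scope="all"` variant uses the
whole panel; which scope a published experiment used is generally not
recoverable from a paper, so both exist and reports carry the choice.

## Synthetic panels

The generator draws, per station i, a stationary AR(1) process
z_t = φ z_{t−1} + √(1−φ²) ε_t whose innovation vectors are correlated
across stations through a Cholesky factor of the target correlation
matrix, then rescales to requested means and standard deviations.
Skewness targets, when given, are matched best-effort by a monotone
exponential tilt T_h(z) = (exp(hz) − 1)/h with h found by bracketed root
finding and the result re-standardized. Exact joint control of mean, SD,
skewness, kurtosis *and* cross-correlation is over-determined, so
mean/SD/correlation take priority — they are what drive the learners.
Positivity is enforced by flooring at 1 % of the station mean (floor
events are counted in `panel.attrs`), preserving the correlation structure
rather than re-sampling.

The default 27-station × 33-year specification carries published
per-district yield statistics, a uniform cross-station correlation of 0.6
(published pairwise correlations span roughly 0.18–0.95) and φ = 0.3 —
annual yields show weak serial persistence compared to their strong
spatial co-movement. What the generator deliberately does *not* emulate:
climate covariates, spatially structured (distance-decaying) correlation,
technology trends, or heteroscedastic measurement error. Passing tests on
these panels therefore demonstrate algorithmic correctness and the stated
statistical properties, not real-world predictive skill.

## Phase 1: ant-colony station selection

Settings follow the published study: 10 ants, 20 iterations, initial
pheromone τ₀ = 1, exponents α = β = 1. Two pieces the study leaves open
are fixed here as package choices:

- **Cost functional.** The wrapper only has to *rank* subsets, so the
  default cost model is a deterministic lag-1 ordinary-least-squares fit
  on the pooled subset, scored by RMSE on the target's own lag pairs in
  original units. A small fixed-seed ELM cost model is available
  (`cost_model="elm"`) for a nonlinear wrapper.
- **Pheromone update.** Classic Ant System: τᵢ ← (1−ρ)τᵢ + Σ Q/cost over
  ants whose subset contains i, with evaporation ρ = 0.1 and deposit scale
  Q defaulting to the mean target yield so deposits are O(1) against
  τ₀ = 1 regardless of the panel's units.

Subsets are built without replacement by sequential roulette draws;
identical subsets within a run are costed once (cache). The number of
stations to select, `n_features`, is an input, as in the published per-
station counts (22/20/19/17/12/14 for the six preset targets); no selection
rule for it is derivable. The best-ever subset and per-iteration best cost
are reported, so the trace is non-increasing by construction, and the
best-ever cost can never undercut the exhaustive minimum — the property
the acceptance oracle checks on an enumerable 6-candidate toy.

## Phase 2: lags and learners

**PACF.** Durbin–Levinson on the biased sample autocorrelations
(statsmodels' `ldb` method; an independent Yule–Walker/Toeplitz solve is
the test oracle). Significance uses the large-sample 95 % band ±1.96/√n.
The modelling default is lag {1} when significant — consistent with the
finding that adding W_{t−2} degrades annual-yield accuracy — falling back
to the first significant lag, or to {1} when nothing clears the band.
In the detection-power checks, the AR(1) "lag 1 and only lag 1" criterion
is evaluated at max_lag = 2: each null lag carries a ~5 % false-positive
rate by construction, so demanding *no* false positive among 19 null lags
would fail ~62 % of the time for any correct implementation; lag 2 is the
theoretically relevant null for an AR(1).

**ELM.** Hidden parameters are drawn once from a seeded generator:
aᵢ ~ U(−1,1) per input dimension and bᵢ ~ U(−1,1) for additive neurons
(sig/sin/hardlim/tanh); for rbf neurons aᵢ are centres ~ U(−1,1) and
bᵢ ~ U(0.05, 1) are widths (kept positive). Inputs are not
bias-augmented. Output weights solve min ‖Hρ − T‖² via SVD pseudoinverse
(`np.linalg.pinv`), with optional Tikhonov ridge for conditioning.

**OSELM.** Initialization P₀ = (H₀ᵀH₀)⁻¹, ρ₀ = P₀H₀ᵀT₀ on the first
chunk (the "block size 100" of the published configuration is read as
chunk size; the init chunk is enlarged to n_hidden when the block is
smaller). Updates are the Woodbury/RLS block form, which avoids
re-inversion and makes the final weights equal the batch solution for any
chunk schedule — verified to < 10⁻⁶ relative over 50 random
configurations in the acceptance checks.

Two numerical realities shape the implementation:

- **Rank/conditioning gate.** The explicit inverse seeding the recursion
  is meaningless once cond(H₀ᵀH₀) exceeds ~10¹⁰; such initializations
  raise a hard error rather than propagate garbage. With a *single* lag
  feature the hidden columns are smooth functions of one scalar and
  become numerically collinear beyond only a handful of neurons, so
  unridged sequential fitting on 1-D inputs is limited to small widths.
- **Ridge-seeded recursion.** `fit_oselm(..., ridge=ε)` seeds
  P₀ = (H₀ᵀH₀ + εI)⁻¹. Because RLS accumulates Gram blocks exactly, the
  final weights then coincide with the batch ridge solution over all
  absorbed data — the equivalence survives, shifted to the ridge
  problem. The pipeline uses ε = 10⁻⁶ by default (targets live in [0, 1],
  so the bias is negligible while the recursion's condition number stays
  bounded); the pure pseudoinverse path is `ridge=0`.

The sequential/batch equivalence suite draws input pools of 400–750
samples with 2–6 input dimensions on U(−3, 3) — wide enough that hidden
arguments spread across the activations' nonlinear range and the
least-squares problem is well posed; configurations violating the
initialization rank condition are redrawn, per the property's own
precondition, as are configurations whose full-pool Gram condition
exceeds 10⁸ — beyond that, roundoff amplification (~cond · ε) leaves the
weights themselves undetermined at the precision being compared. With
1-D inputs or narrow input ranges the comparison would measure Gram
conditioning, not the RLS algebra.

**Random forest.** Wrapped from scikit-learn with the published
parameters (10,000 trees, 2 split predictors, capped at the input
dimension); the study defines no bespoke tree mechanics, so re-implementing
bagged trees would add nothing but risk.

## Evaluation

The eight measures follow their standard definitions; all are checked
against plain-loop (non-vectorized) oracles to 10⁻¹⁰. Decisions:

- **NSE denominator.** The conventional form sums squared deviations of
  observations from the observed mean. A variant deviating from the
  *predicted* mean exists behind `nse_denominator="pred_mean"` because
  that form circulates in some applied papers; reports record which was
  used.
- **Rating boundaries.** The published band definitions use strict
  inequalities on both sides, leaving 10/20/30 % unassigned; boundaries
  fall into the *better* band here.
- **Degenerate inputs.** Constant observations make r/NSE/LM undefined:
  they come back NaN with their names listed in `report.undefined`, never
  silently 0. Any observation equal to 0 makes RMAE undefined and is a
  hard error.

## Experimental protocol and its caveat

Following the published design, the target station's *full* series is
predicted while training pools other stations' series over the same
years: a station-wise holdout, not a temporal one, so train and test
overlap in time. This measures how well structure transfers across
stations; it is not a forecasting benchmark. An optional `holdout_years`
mode withholds the final years of the target's pairs for honest
forecasting. Model selection is scored on training-pool RMSE;
cross-validation is deliberately absent because shuffling annual series
destroys their temporal structure.

The bookkeeping distinguishes *raw records* (n_selected × n_years — the
published dataset-size arithmetic, e.g. 22 × 33 = 726) from *usable
pairs* (n_selected × (n_years − max lag), since lag pairing consumes the
first max-lag years of each station and no pair straddles a station
boundary). Both counts are reported in `provenance`.

## Problem sizes in the checks

The acceptance script and test suite run: 50 random configurations for
the equivalence sweep (pools of 400–750 samples); 30 colony seeds against
a 20-subset exhaustive enumeration; 1000 random metric cases; 100 seeds
each for the PACF power and false-positive checks (n = 500 series); and a
single-target demonstration experiment on the default 27 × 33 panel with
a thinned hidden-neuron grid (step 4) and a 200-tree forest. The preset
configuration for real use retains the full published settings.

## Known limitations

- With one lag feature the ELM hidden map is severely rank-deficient for
  widths beyond ~5 neurons; wide published configurations (up to 35) are
  reachable only through the pseudoinverse (batch) or the ridge-seeded
  recursion, and different widths then differ mostly in the null space.
- The ant colony provides no optimality guarantee; the acceptance check
  calibrates it only on a small enumerable instance.
- Synthetic panels share one uniform cross-correlation; real districts
  show distance- and zone-structured correlation.
- The rating bands and relative errors presume strictly positive
  observations; series with zeros need rescaling before evaluation.
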