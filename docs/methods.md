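# Methods

## Model and procedure

The selector addresses sparse linear regression: given `n` samples of `p`
features and a numeric response, find the subset `Q` of features whose
ridge fit generalizes best.  Rows are split into a training part (used to
fit coefficients) and a validation part (used to choose the subset); the
final model size is chosen by an information criterion, so validation data
are *not* spent on picking `K` — they pick the best subset *of* size `K`.

For each `K` the subset search is exact.  With `a = X'_train y_train` and
`C = X'_train X_train` on the intercept-augmented design, the ridge
inner-problem optimum on a subset satisfies `a_Q = (C + δI*)_Q β_Q`, where
`I*` is the identity with a zero in the intercept slot.  The search is a
mixed-integer quadratic program over support binaries `z` (with
`Σ z_i = K`) and grid binaries `y_t` (with `Σ y_t = 1`) selecting one
penalty from a δ grid; the objective is the validation SSE.  Deselected
features have both their coefficient and their stationarity row switched
off — by indicator semantics (the default) or by big-M bounds with a
data-scaled constant.

### The native exact solver

The binaries are the only combinatorial content: at any complete
assignment the continuous block is a square linear system.  The solver is
therefore a depth-first branch-and-bound over feature inclusion:

* **Branching order** — features sorted by absolute correlation with the
  validation response, include-branch first, which finds strong incumbents
  early.
* **Admissible bound** — the residual of the unconstrained least-squares
  projection of `y_val` onto the intercept plus every still-allowed
  column.  Any feasible completion's coefficients are supported on those
  columns, so no completion can beat this bound; it is recomputed only on
  exclusion branches (the allowed set is unchanged on inclusion).
* **Leaves** — for each grid δ, solve the restricted stationarity system
  directly from `(a, C)` and score the validation SSE.  In big-M mode the
  relaxed rows and coefficient bounds are checked against `M` and
  violating candidates rejected; indicator mode needs no check.
* **Tolerances** — incumbent updates and pruning use a relative gap of
  1e-6; a search that completes is reported `optimal`, one interrupted by
  the per-solve time limit (default 60 s) returns the incumbent as
  `feasible_time_limit`.  A greedy top-`K` incumbent is evaluated before
  the search starts so a time-limited solve always returns something
  feasible.

The exhaustive enumerator in `baselines` solves the same problem through
an entirely separate code path (`ridge_fit` per subset) and is used in the
tests as the solver's independent oracle.

### Model-size selection

After the MIQP picks `(Q, δ)` for a given `K`, the criterion is computed
from a ridge refit at that `(Q, δ)` on the concatenated training +
validation rows — the combined rows are also what the final reported model
is refitted on, since the criterion itself is defined on them.  Complexity
enters as the ridge effective degrees of freedom
`df(δ) = Σ d_i²/(d_i²+δ)` (the hat-matrix trace; exactly `K` at `δ = 0`),
with `K_eff = ⌈df⌉` in the eBIC model-space term `2·g·log C(p, K_eff)`,
`g = 0.5` when `p > n` and 0 otherwise.  The binomial coefficient is
evaluated through log-gamma so `p` in the thousands is safe.  The sweep
starts at `K = 0` (intercept-only baseline, so the criterion may reject
every feature) and stops after `stop_patience` consecutive non-improving
values (default 1 — "no longer improving" taken literally).  The sweep is
capped at `K = n_train − 1`; beyond that the training system is purely
interpolating and the criterion has already turned.

### Random-block decomposition

When `p` exceeds the block length `L` (default 10), features are shuffled
into blocks of `L`, the sweep runs inside each block, survivors are pooled
and re-blocked (fresh shuffle each round) until the survivor set repeats
or drops to ≤ `L`, with a safety cap of 20 rounds; a final sweep over the
survivors produces the phase's model.  With eBIC this whole phase runs
twice: stage 1 under BIC with an `m = 10` δ grid, stage 2 on the stage-1
survivors under eBIC with a finer grid (`m = 50` when at most 100
survivors remain, `m = 100` otherwise — the "low setting" cutoff is not
pinned anywhere, so the survivor count is used).  When AIC or BIC is
requested there is a single stage under that criterion; routing stage 1
through BIC regardless would make AIC unreachable.  Stage-2 candidates are
by construction a subset of stage-1 survivors.

Inside a block, eBIC's `p` is taken to be the *full* feature count of the
problem, not the block width: the model-space penalty describes the whole
search space the procedure ranges over.

### δ grid and standardization

Feature columns are z-scored and the response centered before
optimization (constant columns pass through unscaled and can never be
selected over the intercept); coefficients are back-transformed for
reporting.  The δ grid spans the lasso-to-ridge penalty range of the
standardized problem: `λ_max = max_j |x̃_j'ỹ|/n`, grid endpoints
`δ_min = 1e-4·λ_max·n` and `δ_max = λ_max·n/1e-3`, log-equally spaced.
The rule is homogeneous of degree 1 in `y`, so rescaling the response
rescales the grid.

## Synthetic benchmark

The generator draws rows i.i.d. from `N(0, Σ)` with AR(1) covariance
`Σ_ij = ρ^|i−j|`, applies one of four sparse coefficient patterns
(type 1: `s` ones at approximately equally spaced indices; type 2: `s`
adjacent ones; type 3: linear decay 10 → 0.5 at spaced indices; type 5:
unit head with geometric `0.5^(j−s)` tail) and adds Gaussian noise with
`σ² = β'Σβ / SNR`, so the population signal-to-noise ratio is met exactly
by construction.  Spaced indices use `round(1 + (j−1)(p−1)/(s−1))` with
collisions shifted right — deterministic and symmetric.  Presets: low
(100, 10, 5), medium (500, 100, 5), high-5 (50, 1000, 5), high-10
(100, 1000, 10); ten SNR levels from 0.05 to 6.00 on a log grid; default
autocorrelation levels {0, 0.35, 0.70} with 0.35 the headline scenario;
10 replicates with seeds 1..10 by default.

Scoring is on supports (precision, recall, F1, FP, FN, non-zero count,
intercept excluded) plus the relative test error
`RTE = ((β̂−β)'Σ(β̂−β) + σ²)/σ²`, which is 1 for exact recovery and
`SNR + 1` for the all-zero model.

What the generator does *not* emulate: heavy-tailed or heteroscedastic
noise, non-Gaussian predictors, batch structure, and measurement error in
the response — all present in real expression/IC50 data.  Passing the
simulation suite therefore demonstrates correctness of the algorithm and
its selection behavior under the stated model, not performance claims on
any particular omics dataset.

## Comparators

Forward stepwise (greedy training-RSS additions, path length chosen by
validation SSE), lasso (coordinate-descent path over 100 log-spaced
penalties, chosen by validation SSE) and relaxed lasso (per-support blend
`γ·β_lasso + (1−γ)·β_LS` over a γ grid, jointly tuned with λ on
validation SSE) are tuned on the same validation data the selector uses —
deliberately, so comparisons isolate the selection strategy rather than
the tuning protocol.  The lasso path itself comes from scikit-learn; the
stepwise search and the relaxation blend are implemented here.

## Numerical and design choices

* **Intercept** — always active, never penalized, never counted in `K`,
  `df` or the cardinality constraint.  Penalizing or deselecting the
  intercept is statistically incoherent even though a formulation summing
  over all `p+1` indices is expressible.
* **df formula** — implemented as the standard ridge hat-matrix trace
  `trace(X(X'X+δI)⁻¹X')`, the form consistent with the `df(0) = K` limit.
* **Ceiling with tolerance** — `K_eff = ⌈df − 1e-9⌉` so floating noise
  just above an integer does not inflate the model-space term.
* **Ties** — the enumerator returns the lexicographically smallest subset
  (then the smallest δ) among equal objectives; the branch-and-bound keeps
  its first incumbent within the 1e-6 gap, so tied supports may
  legitimately differ between the two while objectives agree.
* **Degenerate inputs** — constant responses are rejected when building a
  δ grid; rank-deficient designs raise at `δ = 0` and are handled by the
  penalty otherwise; duplicated columns are resolved arbitrarily by the
  solver (exactly one of the pair is selected).
* **Splits** — benchmark runs use a uniform 50/50 train/validation split;
  the omics pipeline uses quantile-stratified 40/40/20 splits (5 bins) so
  each part sees a homogeneous response distribution, with small strata
  merged into their neighbor.
* **Randomness** — every entry point takes one seed; ensembles spawn
  per-run seeds through `SeedSequence([seed, i])`, so each run is
  individually reproducible.

## Problem sizes in the shipped checks

The test suite and the acceptance script run the solver-vs-enumeration
comparison on instances with `p ∈ {4..10}` and 30+30 rows across every
cardinality, the recovery and trend statistics on 10 replicates of the
low setting and of a reduced high-dimensional scenario (n=50, p=100,
s=5, SNR=3 — chosen so exhaustive verification and repeated full fits
remain cheap on one CPU), and the block-invariance comparison at p=30.

## Known limitations

* Exact search inside blocks scales exponentially in the worst case; the
  per-solve time limit converts pathological instances into incumbent
  (`feasible_time_limit`) results rather than failures.
* The information criteria assume independent predictors; under strong
  autocorrelation the selected support may swap a true feature for a
  correlated neighbor, and the criterion's MSE — computed on rows that
  also chose the subset — can admit an extra feature or two in
  single-block runs.  Consequently the random-block and single-block
  routes agree on the exact support only in a majority, not all, of
  seeded replicates at p=30.
* The block decomposition cannot recover a feature discarded in an early
  round (survivor sets only shrink across stages).
* No cross-validated δ selection: δ is chosen inside the MIQP by
  validation error, by design.
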