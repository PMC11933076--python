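# Methods

`fiberopt` re-implements, as a tested pipeline, a literature-mining machine-
learning analysis of doxorubicin (DOX)-loaded electrospun nanofibers: a
formulation table with 12 features (3 machine settings, 7 material
properties, 2 study durations) and 4 labels (average fiber diameter,
encapsulation efficiency, drug release percentage, anticancer activity) is
cleaned, feature importance is ranked, one ε-SVR surrogate is trained per
label, and particle-swarm optimization inverts the surrogates to propose
optimal fabrication parameters. This note records the model choices, the
defaults and their rationale, and what the synthetic stand-in data can and
cannot show.

## The data model

The mined table behind the original analysis was never deposited; what
survives are per-column five-number summaries (min, quartiles, max), the
count of missing cells (126), the final hyperparameters, and the result
tables. The package therefore treats the column schema as the single source
of truth (fixed snake_case headers, units, roles, inclusive bounds anchored
at the published min/max) and ships a generator that emulates the published
marginals.

One wrinkle: the published statistics table lists 11 feature columns, not
12 — it omits drug release time. The generator borrows the anticancer
study-time anchors for that column (both are study durations on comparable
day scales). Units are stored exactly as published and unit inconsistencies
in the source tables (e.g. molecular weights whose magnitudes suggest Da
rather than kDa, and a release time printed in hours against a schema in
days) are deliberately not reconciled.

## Synthetic data generator

**Marginals.** Each feature column is drawn independently through the
piecewise-linear inverse CDF interpolating (0, min), (0.25, q1), (0.5, q2),
(0.75, q3), (1, max). Draws never leave [min, max] and empirical quartiles
converge to the anchors. Only marginals are published, so no feature-feature
dependence is modelled — a deliberate refusal to invent correlations. This
is the generator's main departure from real formulation data, where e.g.
polymer concentration and density co-vary; passing tests therefore certify
the machinery, not the field's covariance structure.

**Planted surfaces.** In surface mode each label is an axis-aligned
quadratic around a known optimum x\*: a bowl (minimized) for diameter, peaks
(maximized) for the other three. The three "active" features per label carry
large curvature and echo the optima the original analysis reported (diameter
bowl at distance 15 cm, density 1.529 g/cm³, concentration 9 wt%;
anticancer peak at density 1.2 g/cm³, concentration 8 wt%, DOX 3.182 wt%;
and so on); every other feature in the label's feature set carries weak
curvature (12 label units over the full range) centred at the column median,
so the global optimum is exactly x\* in every dimension while the signal is
dominated by the active features. Curvature amplitudes were chosen so label
values span the published label ranges and the optima are identifiable from
a few thousand rows. Labels are clipped to the published label min/max and
Gaussian noise (sd 40 nm for diameter, 4 percentage points for the others,
roughly 5 % of each label's range) is added before clipping.

**Missingness.** Exactly `n_missing` (default 126, the published count)
distinct cells of the 10 fixed-feature columns are masked uniformly at
random (MCAR); labels and study-time features are never masked. A default
dataset has 200 rows — the row count was never published; 200 gives ≈ 6 %
missingness over the 2 000 fixed-feature cells, a plausible literature-mining
scale. One global seed drives three independent substreams (features, label
noise, missingness), so changing the missingness count never perturbs the
feature draws.

## Preprocessing chain

Order: per-column two-parameter Box-Cox → SoftImpute on the feature matrix →
min-max scaling to [0, 1]. The source describes the three steps in that
order without stating it explicitly; the order is fixed here as a design
choice and recorded in the report provenance. Details:

- **Box-Cox.** shift = 0 for strictly positive columns, otherwise
  `1e-6 − min` (several columns have zero minima); λ maximizes the profile
  log-likelihood (`scipy.stats.boxcox_normmax`). The transform is strictly
  monotone, so ranks — and hence every Spearman statistic — are invariant to
  the chain. The inverse floors the power argument at 1e-12 so slightly
  out-of-range surrogate predictions stay finite.
- **SoftImpute.** Missing cells start at column means; each sweep
  soft-thresholds the singular values of the current completion by λ\_nuc
  (default 10 % of the mean-filled matrix's largest singular value,
  tol 1e-5, max 500 sweeps) and overwrites only the missing cells. The
  regularized objective ½‖P\_obs(X−Z)‖²\_F + λ‖Z‖\_\* is recorded per sweep
  and is non-increasing. Note the λ→0 limit is the *minimal-nuclear-norm*
  completion, which coincides with the low-rank "true" value only when the
  observed pattern identifies it — a 2×2 matrix with one masked corner does
  not (the tests verify against a dense 1-D oracle scan).
- **Labels are never imputed.** Rows missing a label are dropped only for
  that label's surrogate, avoiding target leakage.
- **Scaling anchors** are the min/max of each transformed column *after*
  completion, so every output column spans exactly [0, 1]. Because imputed
  values can fall outside the observed support, the inverse map of an
  optimizer result is clipped to the schema bounds.

## Feature importance

Spearman's ρ between each feature and label on their observed overlap,
average ranks for ties (the simple 1 − 6Σd²/n(n²−1) form is used when ranks
are distinct and equals the rank-Pearson form there). Relative importance is
100·|ρᵢ|/maxⱼ|ρⱼ| — the only normalization consistent with the original
report that its top feature "scores 100 %". Signed ρ is reported alongside;
exact ties for the maximum are resolved by schema order. Per-label feature
sets: the 10 fixed features for diameter and encapsulation, plus the
matching study-time feature (11 total) for release and anticancer activity.

A caveat the tests make explicit: rank correlation is blind to response
surfaces whose optimum sits inside the data mass (a centred bowl has ρ ≈ 0),
so importance recovery is only a fair probe when the planted effect is
monotone over the sampled range.

## Surrogates

One ε-SVR (radial-basis kernel exp(−γ‖x−x′‖²)) per label on the scaled
cube, restricted to the label's feature set. The kernel family is inferred:
the published hyperparameter table has a γ column, which only exists for the
RBF family, and its ε values (down to 6.4·10⁻⁵) only make sense on the
compressed [0, 1] scale. Defaults are the published per-label (γ, C, ε);
the 80/20 split uses a configurable seed (default 42). Fitting goes through
scikit-learn, but the fitted model is reduced to explicit support vectors,
dual coefficients and bias, so prediction is a closed form that serializes
to JSON and round-trips bit-identically.

Evaluation inverse-transforms predictions to original label units before
computing MAE, MSE and RMSE, so metrics carry physical units. RMSE = √MSE
and MAE ≤ RMSE hold by construction; the published anticancer metric row
violates the latter (MAE 13.14 > RMSE 9.98), is mathematically impossible
for a single evaluation set, and is excluded from consistency checks.

## Inverse design

Canonical PSO (velocity = ω·v + c₁r₁(pbest−x) + c₂r₂(gbest−x)) on the
scaled cube with boundary clipping, velocities initialized to zero,
50 particles × 200 iterations (unstated in the source; fixed here as
defaults). Coefficients default to the published c₁ = 0.4862, c₂ = 2.5067,
ω = −0.2887; the negative inertia is accepted as-is. Diameter is minimized,
the other three labels maximized via negation. The reported label value at
the optimum is clipped to the scaled training range before
inverse-transforming, since RBF extrapolation beyond the data can otherwise
produce unphysical values (e.g. activity above 100 %).

Per-feature optimal ranges are the strict min/max across the four per-label
optima, study-time features excluded. Applied to the *published* optima this
rule reproduces the published range table for 9 of 10 features; the
additive-molecular-weight row disagrees (printed max 250.71 versus 493.06 in
the optima table) and is flagged rather than matched.

## Recovery experiment

The end-to-end check: over 10 seeds, draw 2 000 noiseless surface-mode rows
(no missingness), run the full chain, and measure |recovered − planted| per
active dimension as a fraction of the feature's bounded range; the bar is a
median ≤ 0.05 per label. Two experiment-specific choices: surrogates are
trained on all rows (the experiment probes the optimizer, not held-out
error), and they use surface-fit hyperparameters (γ 4, C 100, ε 10⁻³;
ε 0.01 for anticancer) rather than the published defaults, which were tuned
to the original table, not to these quadratics. The wider tube for the
anticancer label regularizes away spurious interpolation bumps in its
strongly compressed label distribution. 2 000 rows are needed because some
planted optima (DOX 3.18 wt%, dielectric constant 40) sit above the third
quartile of their marginals, where sampling is sparse.

## Numerical notes and limitations

- Everything downstream of the seeds is deterministic: SVD-based impute,
  libsvm fits, and the seeded swarm; re-running a config reproduces the
  report byte-for-byte.
- SoftImpute's per-sweep movement is O(λ\_nuc), so tiny λ with a loose
  tolerance stalls; the λ→0 tests run thousands of sweeps with tol = 0.
- `boxcox_normmax` can return large |λ| for heavily skewed shifted columns;
  the inverse guards the power argument, and degenerate (constant) columns
  are rejected with a named error.
- Surrogate-based optimum localization is limited by interpolation error:
  with ~2 000 points in a 10-D cube the surrogate's argmax wobbles by a few
  percent of the range even at training R² ≈ 1. Worst-case single-dimension
  errors of 0.1–0.2 occur at some seeds; only the median is controlled.
- Published optima for some features lie outside the published data support
  (e.g. polymer Mw optima of 80–475 against a column minimum of 1 750);
  these values are stored verbatim and only used for internal-consistency
  checks, never as bounds.
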