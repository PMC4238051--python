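# Methods

## Model and assumptions

The package works on constraint-based metabolic models at steady state:
fluxes `v` satisfy `S·v = 0` with per-reaction bounds `v_min ≤ v ≤ v_max`,
growth is the flux of a designated biomass reaction, and cells are
assumed to maximize it.  Exchange reactions carry one metabolite each;
uptake is negative flux on unsplit models.  Gene-reaction associations
are flattened to plain gene sets for expression mapping — a reaction's
expression is the arithmetic mean over its catalyzing enzymes — while the
boolean AND/OR rule text is retained but never evaluated.  Expression is
used on whatever scale the caller provides (no internal log transform):
the per-reaction min–max normalization is invariant to affine rescaling
and the association step is rank-based, so only the monotone scale choice
matters and it is deliberately left to the caller.

The central assumption of the bound-mapping step is that, within a
suitable flux window, the *ordering* of a growth-associated reaction's
expression across samples carries information about the ordering of its
attainable flux — with the direction of that relation determined
empirically from the sign of the expression–phenotype correlation, not
assumed positive.

## Pipeline and numerical choices

**Reversible splitting.** Each reaction with `lb < 0` becomes a forward
copy `[max(0, lb), max(0, ub)]` and a backward copy with negated
stoichiometry and bounds `[max(0, −ub), −lb]`; split models have only
nonnegative fluxes.  Both split directions share the gene set, so a
selected reversible reaction receives its normalized bound on both
copies; symmetric application avoids directional bias where no evidence
distinguishes the directions.

**Global tightening.** A common cap `U` is scanned downward from the
model's largest upper bound in steps of 0.1 flux units; the kept value is
the smallest grid point whose capped model (`ub_i = min(ub_i, U)` — caps
never raise a bound, which keeps media limits intact) still reaches the
unconstrained optimum within `ε = 1e-4`.  Because optimal biomass is
monotone non-decreasing in `U`, the scan grid is searched by bisection,
which returns exactly the linear scan's result at a logarithmic number of
LP solves; the scan floors one step above zero.  Step and ε are in the
model's flux units and configurable — toy models may want finer steps.

**Association.** Spearman with average ranks, two-sided p, BH step-up
across all tested (mapped, non-constant) reactions, selection at
`q ≤ α = 0.05`.  Constant expression rows are excluded with a warning; a
constant phenotype is an error.  A selected correlation of exactly zero
cannot occur (its p-value would be ~1), so the sign in the mapping is
always defined; this is asserted anyway.

**Normalization range.** `minNormVal`: knock out each reaction, call it
essential if growth drops by more than 90% of the optimum, take each
essential reaction's FVA minimum at `biomass ≥ 0.9·B0`, return the
largest.  The 0.9 FVA fraction mirrors the 90% essentiality cut; it is a
parameter because the two thresholds need not coincide.  `maxNormVal`: a
common bound on the associated set sweeps upward from `minNormVal` in
0.1 steps; the first-segment slope is estimated from the first two sweep
points, and the segment ends when the marginal biomass gain per step
falls below that slope by more than a relative tolerance of 1e-3 — a
robust discrete proxy for the breakpoint of the piecewise-linear
biomass-versus-bound curve.  A flat curve (associated reactions never
limiting) is an error rather than a silent degenerate range.

**Bound mapping.** `E = sign(ρ)·GE` per selected reaction, min–max
rescaled per reaction across the cohort into `[minNormVal, maxNormVal]`.
A constant `E` row carries no ordering information and receives the range
midpoint with a warning.  In transfer mode (an external association set,
e.g. learned on one cohort and applied to a new one without phenotype
data) the rescaling is re-anchored across the *new* cohort's samples; in
cross-validation the test fold is likewise normalized over test samples
only.

**Solvers.** LPs (FBA, FVA, sampling, tightening, sweeps) use HiGHS via
`scipy.optimize.linprog` on a sparse constraint matrix; feasibility is
asserted post hoc at `τ_feas = 1e-7` (scaled).  The MOMA quadratic
program `min ‖v − v_wt‖²` is strictly convex in the fluxes, hence has a
unique minimizer; it is solved with `trust-constr` (exact Hessian `2I`,
gradient tolerance 1e-10) and then polished by solving the
equality-constrained KKT system exactly on the active set the
interior-point solution identifies, falling back to the unpolished
iterate if the polish is infeasible or worse.  This brings toy-model MOMA
solutions to ~1e-9 accuracy against analytic KKT solutions.

**Wild-type sampling.** Alternate optimal flux distributions are drawn by
fixing biomass at its optimum and optimizing a random linear secondary
objective with coefficients uniform on [−1, 1], seeded.  This is a cheap,
reproducible spanner of the optimal face, not a uniform (hit-and-run)
sampler of the flux polytope; distributional statements downstream
(e.g. flux-shift rank-sum tests) are therefore statements about alternate
optima under random secondary objectives.

**Knockdown screens.** Per sample and target: the target's maximal
attainable flux `tmax` is computed; the wild-type reference forces the
target to carry `0.5·tmax` (so a later inhibition has something to act
on) and maximizes growth; the perturbed model caps the target at
`(1 − inhibition)·tmax` with the forcing removed.  Growth survival `Gs`
is the perturbed-to-reference growth ratio, clipped to [0, 1] after LP
noise; `Gi = 1 − Gs`.  Gene targets expand to the reactions catalyzed
solely by that gene (isoenzyme-backed reactions survive).  The
differential-target ranking filters to single-gene reactions whose gene
catalyzes at most three reactions, excluding exchange and
cross-compartment transport reactions, and ranks by cross-sample variance
of post-knockdown growth.

**Selectivity.** Selective: `Gi < 0.20` in every normal sample,
`Gi > 0.30` in every cancer sample, and the worst-case cancer–normal gap
exceeds 0.20.  Non-selective: `Gi > 0.50` everywhere in both cohorts.
The score `(Gi_cancer − Gi_normal)·Gs_normal` uses cohort means by
default; the summary is configurable to worst-case and recorded in
provenance, since a single point per target is compatible with either
choice.

**Statistics.** Empiric permutation p-values are `(n + 1)/(N + 1)` with
`n` the count of null statistics at least as extreme as the observed one
in the stated direction; the floor at `N = 1000` is `1/1001 ≈ 9.99e-4`.
Cross-validation partitions samples into k folds per repeat; folds whose
train split selects no reaction are reported as NA and excluded from the
mean — silent imputation would bias the summary.  The flux-shift analysis
runs one-sided rank-sum tests in both directions per reaction and
BH-adjusts across reactions at `α = 0.05`, reporting the direction with
the smaller adjusted p or "unchanged".

## Synthetic data: what it emulates, what it does not

The cohort generator reproduces the statistical regime the method is
designed for: samples with near-identical transcriptomes (decoy genes get
i.i.d. jitter, sd 1 on a baseline of ~50–150, shared across samples;
pairwise inter-sample Spearman correlation stays above 0.9) and a subtle
growth-linked signal in a designated gene set (expression affine in the
designed growth rate, 10 expression units per unit growth, plus Gaussian
noise σ, default 0).  Default cohort size is 40 samples with 1 true and
19 decoy genes on a chain network extended with 19 decoy side reactions,
so the association test faces a genuine multiple-testing null.  Designed
growth rates default to an even spread across the network's feasible
window [9, 10].

What passing tests on these cohorts show: the pipeline's selection,
sign handling, normalization and prediction machinery are correct and
recover a known ground truth through the full train/transfer/CV path.
What they do not show: performance under realistic transcriptome
covariance, noisy phenotypes, genome-scale networks with thousands of
coupled reactions, or model-misspecification (e.g. the true
expression–flux link being non-monotone).  The affine expression–growth
link was chosen (over a rank-only link) so that both the rank-based
selection and the linear normalization are exercised nontrivially.

The expression-proportional baseline bound-setter scales every mapped
reaction's bound by its expression relative to the reaction's cohort
maximum on the tightened model, with no reaction selection and no sign
handling — a deliberately simple comparator that inverts the growth
ranking on cohorts whose binding reaction is negatively
growth-correlated, which is precisely the failure mode the sign-aware
mapping corrects.

The engineered selectivity cohorts hard-code the mechanism of a
selective target (a bypass present in normal models and absent in cancer
models) instead of deriving it from expression, because on toy networks
the normalization window keeps every mapped bound near the binding
optimum and cannot create the >30%-vs-<20% inhibition contrast the
classifier is specified against.

## Problem sizes and defaults used in validation

The shipped validation runs use toy networks of 3–25 reactions, cohorts
of 40 samples, 20 CV repeats of 5 folds, 1000 permutations, and 5–30
wild-type samples per MOMA average; these sizes make every documented
quantity exactly reproducible in seconds while exercising each code path
at full depth.  All randomness flows through explicit integer seeds via
`numpy.random.default_rng`; identical inputs, parameters and seeds give
identical outputs, including the full CV and permutation distributions.

## Known limitations

* No thermodynamic/loopless constraints, no GPR boolean evaluation, no
  integer-programming methods; the tightening step only damps, not
  eliminates, futile cycles.
* The wild-type sampler spans alternate optima, not the whole flux space.
* Whether bounds should be tightened before or after media application
  is not canonically defined; the pipeline applies media first, then
  splits, then tightens.
* Cohort-level selectivity summaries (mean vs worst-case) change scores
  but not the class assignments on the shipped designs; both are exposed.
* Transfer-mode normalization anchors to the new cohort's expression
  extremes, so a cohort with a compressed expression range still spans
  the full bound window; this matches the per-cohort normalization
  semantics but can overstate between-cohort contrasts.
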