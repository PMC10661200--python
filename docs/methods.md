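# Methods

This note documents the models, conventions and numerical choices behind
`gmcausal`, in the order the pipeline runs them.

## Synthetic cohort generator

**Model.** The generator is a structural causal model (SCM) over nine
variables: age, sex (1 = male), smoking (1 = ever-smoker), WHR, BMI, BFP,
PA, SBP and GMV. Continuous nodes follow

    x = intercept + Σ_parents w·parent + ε,   ε ~ N(0, σ²),

binary nodes are Bernoulli with a logistic link on the same linear
predictor, and sampling proceeds in topological order (ancestral
sampling) from one seeded generator per call — no global RNG state.

**Edge set and weights.** GMV's parents are exactly age, sex, smoking,
BMI and BFP with weights −0.58, −0.33, −0.12, −0.10 and −0.07: the
magnitudes are the reported standardized effect sizes for these five
causal factors, and all signs are set negative — the atrophy direction —
because the study reports magnitudes only. Male sex is also given a
negative sign, since females show higher normalized GMV throughout the
reference marginals. SBP's parents are age (+0.40), sex (+0.30) and BMI
(+0.30); WHR, BMI, BFP and PA are connected as sex → {WHR, BMI, BFP, PA},
WHR → {BMI, BFP}, BFP → PA. Only edges explicitly described in the source
analysis are included; the remaining weights (sex→WHR 0.90, sex→BMI 0.15,
WHR→BMI 0.50, sex→BFP −1.20, WHR→BFP 0.40, sex→PA 0.20, BFP→PA −0.30)
were chosen once so that (a) each continuous node has variance ≈ 1 on the
generator's standardized scale, (b) the strong sex-dimorphism of WHR/BFP
visible in the published per-sex marginals is qualitatively reproduced,
and (c) every effect is detectable at cohort sample sizes. Noise scales
(0.75–1.0) complete the roughly unit-variance design. Binary intercepts
are the logits of the published male fraction (11,046/22,793) and
ever-smoker fraction (8,059/22,793).

Key structural property, preserved by construction: SBP and GMV share the
parents age, sex and BMI but have no edge between them, so GMV ⟂ SBP
given {age, sex, BMI} by d-separation — correlated but causally
independent.

**What the generator does and does not emulate.** It reproduces the
dependency skeleton, effect magnitudes, per-sex marginal state counts and
the confounding pattern of the reference cohort. It does not emulate
real-data features such as non-Gaussian skew, heteroscedasticity,
nonlinear dose-response, measurement error, or missing-data mechanisms;
passing tests therefore demonstrate correctness of the algorithms under
the stated SCM, not robustness to those real-data complications.

**Calibration to published marginals.** `calibrate_to_marginals`
rank-transforms each variable within sex strata: rows are stably sorted
by value, target-count blocks are assigned to states 0–3, and values are
rewritten to evenly spaced points inside each state's bin interval
(open-ended extreme bins get a synthetic width equal to the neighbouring
bin's). This preserves within-stratum rank order and makes the
discretized per-sex counts exact. Binary variables are calibrated by
minimal deterministic flipping (existing ones kept first). Exact per-sex
totals are achieved by drawing sex as a seeded permutation with a fixed
count of ones (`simulate(..., exact_binary={"sex": 11046})`).

## Preprocessing

Derived variables: WHR = waist/hip; PA = moderate + vigorous duration;
SBP = mean of two readings; smoking binarized to 1 for current/previous
smokers. Missing values propagate through derivations; complete-case
filtering requires BMI, WHR, BFP and smoking by default (configurable),
and the pipeline additionally drops rows missing any modeled variable,
logging row counts at every filter.

Standardization is the z-score (population SD, ddof = 0); it is
idempotent and invertible via the returned means/SDs, and refuses
zero-variance columns by name. Binary columns are never standardized.

Discretization uses three edges per variable (25th/50th/75th percentiles
under the linear-interpolation convention, recorded in the
`DiscretizationMap` for reproducibility). Bins are half-open,
left-closed: state 0 is (−∞, e₀) and a value equal to a printed edge
falls in the upper bin, which resolves the overlapping range labels of
the published table deterministically. Tied percentile edges (e.g.
constant columns) are a hard error suggesting explicit edges. Quartiles
are computed pooled across sexes, consistent with a single shared set of
bin edges against per-sex counts.

## Structure discovery

The NOTEARS program is solved with an augmented-Lagrangian outer loop
(penalty ρ starts at 1, ×10 whenever h fails to shrink by 4×, multiplier
α ← α + ρh each round, ρ_max = 10¹⁶, at most 100 rounds) around an
L-BFGS-B inner solver (gradient tolerance 10⁻⁶) over the positive/negative
split W = W⁺ − W⁻ so the L1 term stays smooth. The acyclicity gradient is
the closed form ∇h = (e^{W∘W})ᵀ ∘ 2W. Initialization is W = 0, making
runs deterministic without seeds. Masked entries are held at zero through
(0, 0) bounds, so prior constraints are satisfied bit-exactly.
Non-convergence (h above tolerance, default 10⁻⁸, at ρ_max) raises an
error carrying the final h.

All columns are centered internally. The loss has no intercept, so
uncentered columns (binary indicators with means ≈ 0.35–0.48) would
otherwise force spurious mean-explaining edges between them; centering
removes this without rescaling the Bernoulli variance. Binary columns
enter otherwise untouched as 0/1 — standardizing them would distort their
natural effect scale.

**Hyperparameters.** Function defaults are λ = 0.05 (L1) and pruning
floor 0.01. The synthetic-cohort analysis configuration (pipeline default
and acceptance runs) uses λ = 0.01 and floor 0.03, chosen by a-priori
arithmetic rather than tuning: a 0/1 column has variance ≈ 0.25, so the
effective lasso shrinkage on binary-parent edges is ≈ 4λ, and λ = 0.05
would annihilate the true 0.12–0.15 binary-parent effects; λ = 0.01
shrinks the smallest true effect (0.07) to ≈ 0.06 fitted, which sits more
than three standard errors above the 0.03 floor at n = 20,000, while null
entries (SE ≈ 0.01 after soft-thresholding) sit more than three SEs below
it.

**Pruning.** Entries below the floor are zeroed, then while any directed
cycle remains the smallest-|weight| edge inside a strongly connected
component is removed, ties broken lexicographically by (parent, child).
This greedy per-cycle rule is deterministic and only ever removes edges
that lie on cycles, but it is a heuristic: it does not guarantee the
minimum total removed weight (minimum feedback arc set is NP-hard), and
small counterexamples exist. The test suite asserts the guaranteed
properties plus brute-force agreement on the canonical 3-cycle instance.

**Known identifiability limits.** With every column scaled to unit
variance, a two-variable linear-Gaussian pair is score-symmetric and the
edge direction is not identifiable; direction recovery relies on
equal-noise asymmetries and, in the nine-variable model, mostly on the
role constraints (12 of the 15 true edges touch age, sex or GMV and are
therefore oriented by the mask). The WHR–BFP edge, constrained by
neither, is recovered in the skeleton but its orientation can flip —
skeleton precision/recall are the robust recovery metrics, and both
reach 1.0 at n = 20,000 in the shipped configuration (directed SHD 1).

## Bayesian network

CPTs are Dirichlet posterior means, (count + α) / (row total + K·α) with
symmetric pseudocount α = 1 (Laplace) by default — the prior is named in
the source analysis but its hyperparameter is not, so the least
informative symmetric choice is used and exposed as a parameter.
Cardinalities are 4 for discretized continuous nodes and 2 for binary
nodes.

Queries are answered by variable elimination over CPT factors (evidence
restriction, then summing out hidden variables in reverse declaration
order — exact at this scale, d ≤ 9 with ≤ 4 states). Conditioning on
evidence with zero probability raises `ZeroEvidenceError` rather than
silently renormalizing. Tests verify elimination against brute-force
joint enumeration to 10⁻¹⁰ on 200 random networks.

d-separation is delegated to `networkx.is_d_separator` behind the module
surface, and is cross-checked in tests against vanishing partial
correlation in large-sample synthetic data.

Validation: per child node, stratified seeded 10-fold cross-validation;
each held-out subject is scored with p(state | observed parents) from the
training-fold CPTs, and ROC-AUC is macro-averaged one-vs-rest over the
states present in the fold (one-vs-rest is insensitive to the class
imbalance that quartile states avoid anyway; states missing from a fold
are excluded and logged). Root nodes are skipped. After validation the
network used for inference is refitted on the full table.

## Interventions

do(X = x) is graph mutilation: incoming edges of X are severed and its
CPT replaced by a point mass, all other CPTs untouched; the operation is
idempotent. Interventional queries then run ordinary inference on the
mutilated network; on confounded triples this equals the backdoor
adjustment Σ_c p(Y | X, c) p(c), verified to 10⁻¹⁰ against enumeration.
The stratified report supports mixing do-assignments with passive
conditioning per stratum and records the flavor (interventional vs
observational) on every row; unmentioned parents are marginalized over,
not fixed. The default pipeline report intervenes on sex and age
(optionally BMI/BFP within the oldest age group), mirroring the
sex-stratified atrophy analyses.

## Confounder adjustment

"Adjusting for confounders" is residualization: x and y are each
regressed on the confounder set by OLS with intercept and the residuals
are correlated — the partial correlation, equal to the recursive
closed-form formula (verified to 10⁻¹⁰) and to `pingouin.partial_corr` in
tests. Collinear confounder designs are rejected. Raw correlations use
pairwise-complete observations; slopes of both the raw and residualized
simple regressions are returned for plotting. On default-model cohorts
the SBP–GMV pair shows |r| ≈ 0.31 raw and ≤ 0.05 after adjusting for
{age, sex, BMI} (the pipeline default adjusts for age and BMI, the
displayed confounder pair in the reference analysis; adding sex makes the
adjusted correlation vanish within sampling error, as d-separation
requires).

## Problem sizes and determinism

Shipped analyses use cohorts of 8,000–22,793 subjects; recovery and
adjustment benchmarks use n = 20,000 and CPT recovery n = 100,000,
sizes at which every asserted bound holds with ≥ 3-standard-error
margins. Every stochastic step takes an explicit integer seed
(`numpy.random.default_rng`); structure learning is deterministic by
construction. Identical configurations reproduce byte-identical
artifacts, which the test suite asserts.

## Known limitations

* Linear-Gaussian/logistic SCM only; no nonlinear or nonparametric
  structure discovery, no bootstrap stability selection.
* Observational d-separation claims transfer to real cohorts only under
  causal sufficiency (no unmeasured confounders) — the same assumption
  the reference analysis makes and discusses.
* No counterfactual (unit-level) queries; interventions are
  population-level.
* Discretization to quartile states loses resolution by design; CPT-based
  AUCs are correspondingly moderate even under the true graph.
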