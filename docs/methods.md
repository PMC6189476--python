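# Methods

## Models

All four families are restricted latent-class models for binary item
responses. An examinee is characterized by a mastery pattern
α ∈ {0,1}^K over K attributes; given the latent class, responses are
independent Bernoulli draws with

    P(X_j = 1 | α) = logistic( λ_{j0} + Σ_t λ_{jt} d_t(α) ),

where each effect term t owns a set of attributes and its indicator
d_t(α) is 1 when α masters all of them. The families differ only in the
term set of each item (determined by its Q-matrix row q_j):

* **LCDM** — every main effect and every interaction among the item's
  required attributes: 2^m − 1 terms for an m-attribute item.
* **HDCM** — the LCDM constrained by a prerequisite DAG ("hierarchy")
  over the attributes. The hierarchy shrinks the latent space to the
  patterns whose mastered attributes include all their transitive
  prerequisites, and collapses item terms that can no longer be
  distinguished. We generate the terms constructively: project the
  permissible patterns onto the item's required attributes, deduplicate,
  and create one term per non-null distinct reduced pattern, with the
  term's attribute set equal to the pattern's support. Two classes get
  the same predictor iff they have the same reduced pattern, the map
  from coefficients to distinct predictors is unitriangular (hence full
  rank), and the item's parameter count equals its number of distinct
  reduced patterns. Under an empty hierarchy this reduces exactly to the
  LCDM. This construction reproduces all nine published
  degrees-of-freedom values on the two shipped Q-matrices, which is the
  strongest validation available for the general rule.
* **DINA** — intercept plus a single conjunction term over all required
  attributes; equivalently guessing g = logistic(λ_0) and slip
  1 − s = logistic(λ_0 + λ_1).
* **C-RUM** — intercept plus one main effect per required attribute.

The structural model is a saturated categorical distribution ν over the
C permissible patterns (C − 1 free parameters, softmax with a reference
class). The free-parameter count is k = Σ_j (1 + T_j) + (C − 1); this
choice is required to reproduce the published df values. Monotonicity
(response probabilities non-decreasing in mastery) can be checked post
hoc (`check_monotonicity`) or enforced during fitting
(`monotone=True`, a zero lower bound on effect coefficients); it is not
enforced by default so that boundary behaviour remains visible.

Linear predictors are clipped at ±35 before exponentiation and
coefficients box-bounded at ±30: real-data fits of boundary items reach
|λ| ≈ 21, so overflow is a live code path, and nothing beyond ±30 is
practically identified.

## Estimation

Marginal maximum likelihood by EM over the permissible classes. The
E-step computes posterior class memberships from ν and the
class-conditional likelihoods (log space throughout; response patterns
are deduplicated so the E-step scales with the number of distinct
patterns). The M-step solves one weighted logistic regression per item
on its C × (1 + T_j) class design matrix — Newton steps with
step-halving, warm-started from the current coefficients — and updates
ν as the posterior mean. Plain EM steps are interleaved with SQUAREM
extrapolation jumps accepted only when they do not lower the observed
log-likelihood, so the log-likelihood is non-decreasing while the slow
geometric tail typical of many-class mixtures is short-circuited.

Defaults: relative log-likelihood tolerance 1e-7, at most 2000 steps,
3 starts (first neutral — intercepts −1, effects +1, uniform ν — the
rest jittered). The simulation harness instead uses a single neutral
start with tolerance 1e-9 and a 30000-step cap: multistart changes
nothing in the well-identified generating regime, while the 32-class
DINA mixture converges slowly enough that at 1e-7 the fit statistic is
still moving by several points, and its asymptotics assume the MLE.

Class proportions are floored at 1e-12. DINA fitted to hierarchical
data legitimately drives many proportions toward zero; the floor only
guards logarithms.

## The M2 statistic

Full-information chi-square tests are unusable for J = 20–28 items
(the 2^J table is almost empty), so absolute fit is tested on the
first- and second-order margins: d = J + J(J−1)/2 proportions
(every item, every item pair). With observed margins p2, model margins
π̂2, residuals r2 = p2 − π̂2 and

    W2 = Ξ2⁻¹ − Ξ2⁻¹ Δ2 (Δ2′ Ξ2⁻¹ Δ2)⁻¹ Δ2′ Ξ2⁻¹,

the statistic M2 = N·r2′W2 r2 is asymptotically chi-square with
df = d − k at the MLE. Everything is assembled from class-mixture
moments of at most four items (local independence within class):
Ξ2 entries are π_{a∪b} − π_a π_b; Δ2 is analytic — the derivative of a
margin in an item coefficient is Σ_c ν_c p_jc(1−p_jc) D_j[c,t] ·
(partner probability), and the structural block follows the softmax
Jacobian ∂ν_c/∂η_b = ν_c(1[c=b] − ν_b). A dense oracle (materialized
selector matrix, full 2^J table, explicit inverses) is part of the test
suite for small J, as is a finite-difference check of Δ2.

Numerically, M2 is computed by Cholesky-whitening r2 and Δ2 and
projecting out the column span of the whitened Jacobian
(M2 = N‖(I−P)e‖²), never by explicit inversion. Two deliberate
conventions:

* **Column equilibration.** The projection depends only on the span, so
  Jacobian columns are normalized before rank detection. Structural
  columns scale with ν_b; for near-empty classes they are tiny but
  remain genuine tangent directions (the limit of interior softmax
  estimates), and dropping them by a magnitude cut would inflate M2
  far above its published behaviour when DINA is fitted to
  hierarchical data. After equilibration only exact linear dependences
  fall below the cut (1e-8 relative).
* **df stays d − k.** The linear-hierarchy HDCM has an *exact* rank-1
  deficiency of the margins Jacobian at every parameter point (one
  parameter combination is identified only by margins of order ≥ 3);
  the two-class single-attribute model similarly hides its mixing
  weight from pairwise moments. The statistic then behaves as
  chi-square(d − rank) while the conventional df = d − k is reported,
  matching published practice: for the 20-item linear HDCM the
  replication mean sits near 146 against df = 145, exactly as printed
  in the original calibration table. `M2Result.rank_deficient` flags
  the situation.

RMSEA2 = sqrt(max(M2 − df, 0)/(N·df)); its 90% CI inverts the
noncentral chi-square: the bound λ solves
P(χ²(df, λ) ≤ M2) = 0.95 (lower) or 0.05 (upper), and the RMSEA bound
is sqrt(λ/(N·df)). p-values are reported at machine precision.

## Synthetic data

Attribute profiles: a latent normal Z ~ N(μ, R) with exchangeable
correlation R (single coefficient ρ; the structure is not stated in the
study designs, compound symmetry is the natural exchangeable choice) is
thresholded at 0; draws violating the hierarchy are rejected and
redrawn, i.e. profiles follow the threshold distribution truncated to
the permissible set. Truncation was chosen over deterministic downward
projection after a head-to-head calibration: the truncated generator
reproduces the published null mean and rejection rate of the linear
cell (146.2 / 0.070 vs printed 146.50 / 0.068 at N = 1000), projection
runs visibly high (147.9 / 0.080).

Item parameters follow the fixed-value rule: main effects
(single-attribute terms) 2, interactions 1, intercept −0.5 × (sum of
the item's effects), so full masters and full non-masters sit at p and
1 − p. Responses are Bernoulli given the profile's class.

Study conditions:

* **Calibration (type1):** μ redrawn per replication from U(−0.5, 0.5)
  per attribute; ρ redrawn from U(0.5, 0.8). N ∈ {1000, 2000, 4000},
  J = 20.
* **Power (DINA or Q-matrix misfit):** ρ fixed per condition
  (0.3 / 0.5 / 0.8) and μ fixed at 0. The zero mean is our resolution
  of an ambiguity in the stated design: with redrawn means the
  unstructured/DINA cell shows mean M2 ≈ 146 and SD ≈ 22, with zero
  means ≈ 136 and SD ≈ 16, against published 133.6 and 16.3 — the
  published dispersion is only consistent with fixed means.
* **Q-matrix misspecification:** random balance design, budget
  round(0.20·J·K) cells; items drawn without replacement; a one-attribute
  item gains an attribute, a two-attribute item loses one, a
  three-attribute item does both. The corrupted matrix is redrawn each
  replication, so the fitted df can vary across replications.

What the generator does **not** emulate: real response data with
guessing contamination, missingness, polytomous items, non-exchangeable
attribute dependence, or Q-matrices whose rows exceed three attributes.
Passing simulations therefore validate the machinery under the study's
own idealized conditions, not robustness to those features.

## Study harness and problem sizes

Each (hierarchy, ρ, N) cell derives its seed from the base seed and
cell index; each replication from the cell seed and replication index,
so any cell or replication can be reproduced in isolation and full
reruns are byte-identical. Failed replications are dropped and counted,
never retried. Default replication counts are 200 (calibration) and
100 (power) — at 200 replications the binomial SE of a 0.05 rejection
rate is ±0.015, enough to check calibration — with `--reps 500`
restoring the full published scale. The test suite runs the linear
calibration cell at 300 replications (N = 1000) and the power cells at
100; these sizes are the package's desk-scale defaults.

The parameter-recovery check fits one N = 4000 linear-hierarchy dataset
at μ = 0, ρ = 0.75 — the representative point of the calibration band
where the posterior-mode classification target (90%) is attainable even
with the true parameters. Coefficient recovery in that regime is
limited by the thin intermediate chain classes (2–5% mass each at high
ρ): the root-mean-square error of the maximum-likelihood estimates
plateaus near 0.2 on the logit scale at this sample size, concentrated
in the nested interaction terms, while classification and response
probabilities recover well. This is a property of the design, not of
the optimizer: deeper convergence, multistart, and the monotone
constraint all leave it unchanged.

## Known limitations

* Dichotomous responses only; no missing data.
* The random balance misspecification is defined for items measuring at
  most three attributes.
* M2 here is the order-2 member of the limited-information family;
  higher-order variants and item-level diagnostics are out of scope.
* The ECPE analysis ships as a workflow (`run_empirical`) with the
  published Q-matrix and hierarchy; the response matrix itself is an
  external input the user must supply.
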