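# Methods

## Model

condde assumes the steady-state joint distribution of the expression
levels `x_g, g ∈ V` of `p` genes follows a Gaussian Bayesian network
over a known DAG `G = (V, E)`: the joint density factorizes into one
linear regression per gene on its parents,

    f(X) = ∏_{g ∈ V} f(x_g | x_{pa(g)}),
    x_g | x_{pa(g)} ~ N(μ_g + Σ_{u ∈ pa(g)} β_{u→g} x_u, σ_g²).

A discrete treatment variable `T` with `k ≥ 2` levels is added as a
node with edges `T → g` into a subset `V_T ⊆ V` of directly affected
genes; the augmented graph is a hybrid (discrete + Gaussian) network
and is acyclic by construction because `T` has no incoming edges. The
treatment enters each affected gene's regression as an additive shift
per non-reference level — the treatment may move conditional means but
not covariances (no treatment-by-parent interactions). The marginal
term `f(x_T)` is excluded from all likelihoods: the analysis conditions
on `T` and the term cancels from every model comparison of interest.
Users comparing totals with joint-likelihood software should add their
own `f(x_T)` term.

## The conditional test

The object of inference is `V_T`. Removing the edge `T → g` changes
only the factor for `g`, so each edge supports its own test, regardless
of which other treatment edges are in the model: the test of

    H_g : x_g ⊥ x_T | x_{pa(g)}

is the classical F-test that all `k−1` treatment-indicator coefficients
vanish in the OLS regression of `x_g` on intercept + parents +
treatment,

    F = [(RSS_S − RSS_{S∪T}) / (k−1)] / [RSS_{S∪T} / (N − |S| − k)],

with `S = pa(g)`. For binary `T` this is the squared two-sample
t-statistic adjusted for the parents; it is exact in small samples
under the Gaussian assumption. Conventional per-gene differential
expression (one-way ANOVA / t-test) is recovered exactly as the special
case of the edgeless network `G = (V, ∅)`.

Conditioning changes what is measured: the conditional test sees the
*direct* effect of treatment on `g` against residual noise, while the
marginal test sees the *net* effect (direct plus everything transmitted
through the parents) against the full variance of `g`. Two consequences
drive the package's simulations:

* **Direct effects** — regressing out parents removes explained
  variance, so a direct effect of given size is detected with higher
  power.
* **Indirect effects** — if treatment reaches `g` only through its
  parents, the conditional null is *true*: the conditional test rejects
  at the nominal α while the marginal test's rejection rate is inflated
  by the transmitted signal.

For data where the Gaussian assumption is untenable, a permutation
fallback recomputes the same F statistic under random relabelings of
the raw treatment vector and reports
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`. Permuting raw labels (not
residuals) is the simplest scheme consistent with the null; residual
permutation would be a reasonable alternative but is not implemented.

## Model likelihoods and deviance

Maximum likelihood decomposes into independent per-node OLS fits.
Inside log-likelihoods the residual variance uses the MLE divisor `N`
(not `N − q`), so twice a difference of maximized log-likelihoods is an
exact likelihood-ratio statistic; for a single added regressor it
reduces to `N·ln(RSS_reduced / RSS_full)`. Nested augmented models are
compared by the deviance `2(l̂₁ − l̂₀)`, asymptotically χ² with df = the
difference in regression-parameter counts. The F-tests themselves use
the unbiased divisor `N − q`, the small-sample-valid classical form.
A deviance more negative than `1e-8` (relative) raises a numerical
error; smaller negatives are clamped to zero as floating-point noise
from nested fits.

## Multiplicity

Per-gene p-values form one family. Holm's step-down adjustment
controls the family-wise error rate irrespective of which hypotheses
are true; Benjamini–Hochberg step-up controls the FDR (appropriate for
large networks). Rejection uses strict inequality (adjusted < α).
Genes skipped as untestable — constant expression, or residual df < 1
because `|pa(g)| > N − k − 1` — are excluded from the family and
reported with a reason: including never-rejectable hypotheses would
distort the step-down adjustment. Both adjustments are computed by
statsmodels and cross-checked in the test suite against direct
implementations of the step-down/step-up formulas.

## DAG-ification of cyclic networks

Database-derived TF→target networks contain cycles among TFs. The
construction mirrors the global-network workflow: (1) take the subgraph
induced by the TFs (all cycles live there, since non-TF nodes have no
outgoing edges); (2) score each edge by the two-sided t-test p-value of
its coefficient in the regression of the target on *all* its in-network
parents (treatment excluded — the network describes steady-state
structure); (3) starting from the null graph, insert edges in order of
increasing p-value, skipping any edge that would close a directed cycle
(incremental DFS reachability check); (4) re-attach the TF→non-TF
fringe unchanged. The result is acyclic and greedily maximal: every
excluded edge would close a cycle if re-added. This is a greedy,
evidence-ordered heuristic, deliberately not a minimum-feedback-arc-set
optimization. Ties in p-value are broken lexicographically on
(source, target) so the result is a deterministic function of the
inputs. Edge scoring uses the TF-subgraph parent sets (scoring precedes
DAG-ification). When a target has more parents than `N − 2` the full
scoring regression is rank deficient; those parents are scored by
single-parent simple regressions instead, with a warning.

## Synthetic data

`simulate.sample` draws datasets by exact ancestral sampling of the
linear-Gaussian structural equations in topological order; the implied
joint covariance is `(I−B)⁻ᵀ D (I−B)⁻¹` and is verified against this
closed form in the tests. Default study conditions for the two-gene
scenarios: unit chain coefficient `β(g1→g2) = 1`, unit noise SD, shifts
of magnitude 1, and 20 samples per group — sizes typical of small
two-arm microarray comparisons.

The two scenario templates contrast the tests at the target gene `g2`
of the chain `g1 → g2`:

* **indirect-effect**: treatment shifts only the regulator `g1`. The
  conditional null at `g2` is true; the marginal test is dragged along
  by the transmitted signal.
* **direct-effect**: treatment additionally shifts `g2` directly. By
  default the `g1` shift is `−1`, opposite in sign to the direct `+1`
  shift on `g2` — an incoherent feed-forward loop, the motif in which
  the two analyses separate most sharply. This choice is deliberate:
  the conditional test's distribution at `g2` does not depend on the
  `g1` shift at all (`g1` is conditioned on), whereas the marginal
  test's noncentrality is `(shift + β·shift_g1)/√(1+β²)` — with an
  *aligned* `g1` shift the marginal test would receive more net signal
  than the conditional test and the power comparison would invert.
  The opposite-signed default isolates the phenomenon the comparison
  is about: the conditional test measures the direct effect, the
  marginal test the net effect.

What the generator does *not* emulate: non-Gaussian noise and heavy
tails, probe-level measurement error, correlated batch structure,
network misspecification (the testing DAG is the generating DAG), and
unmeasured confounding genes. Passing simulations therefore certify
the statistical machinery under the model's own assumptions, not
robustness to their violation; the permutation fallback addresses
non-Gaussianity only.

`rejection_rates` estimates per-gene rejection rates at *raw* level α
(the harness characterizes per-gene operating characteristics, not
family-level error). Replicate `r` draws from the substream seeded by
`(seed, r)`, so reports are bit-reproducible and shardable.

## Numerical and interface choices

* Treatment levels are encoded as `k−1` indicators against the first
  level in sorted order — deterministic and independent of file row
  order.
* Missing expression values are rejected at load time; no imputation.
* Unmeasured network genes are dropped with their incident edges and no
  transitive bypass edges are added; bypassing would silently change
  the conditional-independence structure. A regulatory chain broken by
  an unmeasured mediator therefore contributes no conditioning
  information.
* Node identifiers are case-sensitive opaque strings; matching between
  network and matrix is exact.
* Self-loops in network files are dropped with a warning (common in
  public pathway exports) rather than raising.
* Result tables are TSV with `#`-prefixed provenance headers (tool
  version, config hash, seed); identical configurations hash
  identically, so runs are auditable.
* Output row order is the lexicographic topological order of the
  (restricted) DAG.

## Problem sizes in the validation suite

Monte-Carlo checks run at sizes chosen to make their targets sharp at
desk scale: 2000 replicates for rejection-rate calibration (99%
binomial band around α = 0.05 is ±0.013), 2000 null deviances at
N = 200 for the χ²₁ KS check, 2000 families of m = 100 for FWER/FDR
control, 500 random 10-node graphs for DAG-ification properties, and
200 replicates at N = 5000 for coefficient recovery (3-SE coverage
≥ 99% aggregated over coefficients × replicates). The acceptance
script recomputes the same quantities at 1000 replicates.

## Known limitations

* The network is taken as given and correct; errors in it propagate to
  the conditioning sets and hence to the tests.
* Additive treatment effects only; treatment-by-parent interactions
  are out of scope.
* Gaussian node models only; count models (Poisson/negative-binomial)
  are not provided — use the permutation test for clearly non-Gaussian
  continuous data.
* Genes with many parents relative to N are skipped rather than
  regularized; a shrinkage variant would require a different testing
  theory.
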