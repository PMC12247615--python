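# Methods

## The statistic

For node *v* with subject-by-subject ISC matrix **B**⁽ᵛ⁾ and a behavioral
similarity matrix **M** built from scores *b* (AnnaK: mean(bᵢ, bⱼ); NN:
−|bᵢ − bⱼ|; combined: |bᵢ − bⱼ|·mean(bᵢ, bⱼ)), both matrices are
vectorized over the n(n−1)/2 unordered pairs in a fixed lexicographic
order. A nuisance design **X** — sex match, AnnaK and NN age, AnnaK and
NN motion, the elementwise products of each age column with the sex-match
column, and an intercept — is regressed out of both pair-vectors by least
squares, and the node's fit is

ρᵥ = Spearman( resid(vec **B**⁽ᵛ⁾), resid(vec **M**) ),

with average-tie ranks taken *after* residualization. "Spearman partial
correlation" is thus operationalized as residualize-both-then-rank-
correlate; ranking before projection would not leave the residuals
orthogonal to the controls.

### Permutation inference

The permutation unit is the subject: scores are shuffled over subjects,
the behavioral matrix rebuilt and re-residualized against the *same*
design, and re-correlated against the same residualized brain vector.
Nuisance covariates stay attached to their subjects, so the behavioral
residualization is redone per shuffle while each brain residual is
computed once per node. The two-tailed p uses the add-one estimator
p = (1 + #{|ρ_null| ≥ |ρ_obs|}) / (n_perm + 1), which cannot return zero;
default n_perm = 10,000 and α = .05, both configurable. One shared
permutation stream serves all nodes and models within an iteration —
cheaper than independent streams and required for the model-comparison
null to be coherent.

### Corrections and whole-brain tests

- **Holm–Bonferroni** step-down across nodes, per model:
  p̃₍ₖ₎ = max_{j≤k} min(1, (m−j+1)·p₍ⱼ₎) in ascending order.
- **Familywise count test**: each null rep draws one Uniform(0,1) p per
  node and counts those < α; the whole-brain p is the add-one fraction of
  null counts ≥ the observed count, over the whole sample (not split
  halves). The simulation is kept (rather than substituting the exact
  Binomial(n_nodes, α) tail) so the analytic tail can serve as an
  *independent* oracle in the tests.
- **Model comparison**: mean over nodes of atanh(ρ_annak) − atanh(ρ_nn),
  reported after tanh back-transform; the null is the per-permutation
  analog from the shared streams, two-sided on the absolute difference.
  |ρ| = 1 is clipped to 1 − 10⁻¹² before atanh.
- **Split-half**: an unstratified random split into halves differing by at
  most one subject; ISC and the control design are recomputed within each
  cohort, and consistency is the Pearson r across nodes of the two ρ
  vectors. This measures replication of the *spatial profile* of fit —
  it is only informative when the true effect varies across nodes; a
  cohort where every node carries identical coupling has no profile to
  replicate and its consistency hovers near zero by construction.
- **Network enrichment**: for a network of size m with k significant nodes
  among K significant of N total, expected = m·K/N and p is the exact
  hypergeometric upper tail P(X ≥ k). The choice of an exact
  hypergeometric null is an interpretation; "expected by chance" admits
  other nulls.

## The synthetic generator

Scores are drawn from a configurable distribution (standard normal by
default) and min-max normalized to w̃ ∈ [0,1] within the generated sample,
which makes the per-node coupling κ interpretable as the maximum
attainable shared-signal weight. Per node:

- **annak**: xᵢ(t) = wᵢ·s(t) + √(1−wᵢ²)·εᵢ(t) with wᵢ = κ·w̃ᵢ, giving
  population ISC(i,j) = κ²·w̃ᵢ·w̃ⱼ.
- **nn**: xᵢ(t) = κ·[cos θᵢ·s₁(t) + sin θᵢ·s₂(t)] + √(1−κ²)·εᵢ(t) with
  θᵢ = (π/2)·w̃ᵢ, giving ISC(i,j) = κ²·cos(θᵢ−θⱼ).
- **null**: pure noise, ISC = 0.

These are the minimal generative processes whose population ISC matches
each similarity model; they are validation scaffolding, not a claim about
any real dataset. All signals are unit-variance white noise so the closed
forms are exact (an optional AR(1) smoothing parameter exists, default
off, since the correlation-based inference is agnostic to
autocorrelation). Shared signals are independent across nodes, isolating
per-node inference. Sex has no effect on time courses by default (pure
nuisance); an optional per-sex offset exists to exercise the control
machinery.

Nuisance covariates: age uniform on [6, 22] years; sex a fair binary
draw; motion (mean framewise displacement) an affine function of age plus
independent Gaussian noise, calibrated to mean 0.096 mm, s.d. 0.026 mm
and a population age–motion correlation of −0.35 by default — motion
falls with age in developmental cohorts, and this coupling is what makes
the motion controls non-trivial.

What the generator does **not** emulate: hemodynamics, temporal
autocorrelation (by default), spatial correlation between nodes,
motion-censoring artifacts, or multi-session structure. Passing tests
therefore demonstrate the correctness and calibration of the statistics
under the planted model, not robustness to fMRI confounds.

## Numerical and design choices

- Pair order is lexicographic (i, j), i < j; vectorize/devectorize
  round-trip exactly.
- z-scoring uses population (1/T) normalization; Pearson r is invariant
  to the choice. ISC matrices are exactly symmetrized and the diagonal
  (stored as 1.0) is excluded from all downstream computation. Mean ISC
  is a plain average of pair values, no Fisher-Z.
- Residualization uses a thin QR of the design; residuals are orthogonal
  to every design column to ~1e−10.
- Exactly constant and exactly duplicated control columns are dropped
  with a warning rather than an error, so degenerate samples (e.g.
  single-sex cohorts, where sex match is constant *and* both interaction
  columns collapse onto the age columns) still run; rank deficiency among
  the remaining columns raises a collinear-controls error naming the
  offenders. In cohorts so small that there are fewer pairs than columns
  the design is saturated by construction and no error is raised.
- "Interaction of the age and sex matrices" is ambiguous when two age
  matrices exist; both products (age-AnnaK × sex-match, age-NN ×
  sex-match) are included, and degenerate ones are pruned automatically.
- QC thresholds are strict: a subject at exactly the mean-FD cutoff is
  excluded. Whether higher scores mean "better" is the caller's
  responsibility; scores are never reoriented.
- Subject alignment between time-course files and the behavioral table is
  by exact ID match; unmatched subjects are an error, never a silent
  drop. All result files are reproducible bit-for-bit from
  (config, seed, inputs); only the run log carries wall-clock timings.

## Problem sizes

The validation suite runs at desk scale: exhaustive-oracle comparisons at
n = 5 subjects (120 relabelings vs 10,000 sampled); null calibration over
200 single-node cohorts (n = 30, T = 300, 999 permutations); planted-model
recovery over 20 seeded runs per structure (κ = 0.8, n = 60, T = 600, 30
nodes, 1,000 permutations); generator-fidelity checks at T = 50,000.
`scripts/acceptance.py` reports each measured value together with the
problem size used.

## Known limitations

- The permutation scheme shuffles scores only; Freedman–Lane-style
  full-model schemes and spatial-autocorrelation-preserving nulls are out
  of scope, as are parametric Mantel variance approximations.
- Pair observations within a Mantel test are not independent; all
  validity here rests on the permutation null, and the familywise test
  assumes independent nodes under the null (conservative or not depending
  on the true inter-node dependence).
- No leave-one-out or windowed ISC variants, no volumetric IO, no
  session averaging: multi-session data are analyzed one run per session.
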