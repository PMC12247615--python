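# isrsa — intersubject representational similarity analysis

When a cohort watches the same movie in the scanner, the correlation
between two subjects' BOLD time courses in a brain region — their
**intersubject correlation (ISC)** — is a pairwise measure of neural
synchrony. Intersubject representational similarity analysis (**IS-RSA**)
asks whether that synchrony tracks behavior: it relates the
subject-by-subject brain-similarity matrix of each parcellated node to a
subject-by-subject *behavioral*-similarity matrix, under two competing
operationalizations of "behaviorally similar":

- **AnnaK model** — similarity(i, j) = (bᵢ + bⱼ)/2. High scorers are all
  alike; low scorers are each idiosyncratic, so synchrony rises with the
  pair's mean score.
- **Nearest Neighbors (NN) model** — similarity(i, j) = −|bᵢ − bⱼ|.
  Adjacency on the behavioral scale predicts synchrony at every score
  level.

For each node, both pair matrices are vectorized (lower triangle),
nuisance pair-vectors are regressed out of brain and behavior alike — sex
match, AnnaK/NN age, AnnaK/NN motion (mean framewise displacement), and
age-by-sex interactions — and the fit is the Spearman ρ of the residuals.
Inference is a Mantel-style permutation test (subject labels of the
behavioral matrix shuffled, default 10,000 permutations, two-tailed on
|ρ|), with Holm–Bonferroni correction across nodes, a simulated
familywise count test for whole-brain significance, split-half
consistency of the per-node ρ profile, and a direct whole-brain model
comparison: the node-averaged difference of Fisher-Z transformed ρ values,
tanh-inverted back to the correlation scale, with a permutation p from the
same shared shuffle stream.

Because real parcellated fMRI carries no ground truth, the package ships a
synthetic cohort generator whose *population* ISC is a known closed form
of the behavioral scores (planted AnnaK, NN, or null structure per node,
plus age/sex/motion nuisance covariates with a configurable age–motion
correlation), so every inference stage can be validated against a planted
truth. It is aimed at researchers analyzing naturalistic-viewing fMRI who
want a tested, reproducible IS-RSA pipeline — or a sandbox for its
statistics.

## Worked example

`examples/compare_models.py` plants AnnaK coupling (κ = 0.8) in all 30
nodes of a 60-subject cohort and runs the full two-model analysis:

```
[annak] median rho +0.877; 30/30 nodes p<.05, familywise p = 9.999e-05; 30 survive Holm
[   nn] median rho +0.206; 30/30 nodes p<.05, familywise p = 9.999e-05; 30 survive Holm
mean Fisher-Z diff (annak - nn): +1.148 (rho scale +0.817), p = 0.000999
```

Both models pick up *some* signal (an AnnaK cohort is not orthogonal to
the NN construction), but the matched model fits far better at every node,
and the whole-brain Fisher-Z comparison decides for AnnaK decisively — a
node-averaged advantage of 0.82 on the correlation scale at the
permutation floor p = 1/1001. The other scripts in `examples/` walk
through cohort simulation, single-node inference, split-half consistency
and network enrichment.

The same workflow is scriptable from a shell:

```sh
isrsa simulate --config examples/toy_simulation.yaml --output-dir toy_data
isrsa run --config examples/toy_run.yaml
isrsa report --results toy_results
```

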