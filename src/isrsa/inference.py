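"""Residualized Mantel-style inference for intersubject RSA.

The primary statistic per node is the Spearman correlation between the
residualized, vectorized lower triangles of the brain-similarity matrix
(pairwise ISC) and a behavioral-similarity matrix (AnnaK, Nearest
Neighbors, or the combined form).  Nuisance pair-vectors (sex match,
AnnaK/NN age, AnnaK/NN motion, age-by-sex interactions, intercept) are
regressed out of *both* vectors first; ranks are taken on the residuals.

Significance is assessed non-parametrically: subject labels of the
behavioral scores are shuffled, the behavioral similarity matrix rebuilt
and re-residualized against the same design, and re-correlated against
the same residualized brain vector, yielding a permutation null of rho
per node.  The two-tailed p uses the add-one estimator on |rho|::

    p = (1 + #{|rho_null| >= |rho_obs|}) / (n_perm + 1)

so no p is ever exactly zero.  One shared permutation stream is used
across all nodes and all models within an iteration; this makes the
node-averaged Fisher-Z model-comparison null coherent.

Beyond the per-node test the module provides Holm-Bonferroni step-down
correction across nodes, a simulated familywise count test for
whole-brain significance, split-half consistency of per-node effects,
the direct AnnaK-vs-NN comparison, the across-node correlation of mean
ISC with model fit, and hypergeometric network enrichment of significant
nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .isc import pairwise_isc, vectorize_lower
from .similarity import ControlDesign, behavior_matrix, control_design
from .synthetic import TimecourseSet

__all__ = [
    "residualize",
    "spearman",
    "NodeResult",
    "isrsa_node",
    "RunResult",
    "run_all_nodes",
    "holm_bonferroni",
    "FamilywiseResult",
    "familywise_count_test",
    "SplitHalfResult",
    "split_half",
    "rho_vector",
    "ModelComparisonResult",
    "model_comparison",
    "isc_fit_correlation",
    "network_enrichment",
]

_ATANH_CLIP = 1.0 - 1e-12


def residualize(v: np.ndarray, design: ControlDesign) -> np.ndarray:
    """Remove the least-squares projection of ``v`` onto the design columns.

    The returned residual is orthogonal to every design column (to
    numerical precision); with an intercept present it is mean-zero.
    """
    v = np.asarray(v, dtype=float)
    if v.shape[0] != design.matrix.shape[0]:
        raise ValueError(
            f"pair-vector length {v.shape[0]} != design rows {design.matrix.shape[0]}"
        )
    q = _design_q(design)
    return v - q @ (q.T @ v)


def _design_q(design: ControlDesign) -> np.ndarray:
    # thin QR; cached on the design object since permutation loops reuse it
    q = getattr(design, "_q", None)
    if q is None or q.shape[0] != design.matrix.shape[0]:
        q, _ = np.linalg.qr(design.matrix)
        design._q = q
    return q


def _rank_standardize(v: np.ndarray) -> np.ndarray:
    """Average-tie ranks, centered and scaled to unit norm."""
    r = stats.rankdata(v)
    r = r - r.mean()
    nrm = np.linalg.norm(r)
    if nrm == 0:
        raise ValueError("undefined correlation: input is constant after ranking")
    return r / nrm


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of average-tie ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    return float(_rank_standardize(x) @ _rank_standardize(y))


@dataclass
class NodeResult:
    """Per-node IS-RSA outcome for one behavioral-similarity model."""

    node_id: str
    model: str
    rho: float
    p_perm: float
    p_holm: float
    sig_uncorrected: bool
    sig_corrected: bool


@dataclass
class RunResult:
    """All-node IS-RSA output: tidy table plus the permutation null streams.

    ``null_rho[model]`` has shape (n_perm, n_nodes), built from one
    subject-permutation stream shared by every node and model, which is
    what makes :func:`model_comparison` on this object exact.
    """

    table: pd.DataFrame
    null_rho: dict[str, np.ndarray]
    alpha: float
    n_perm: int

    def rho(self, model: str) -> np.ndarray:
        sub = self.table[self.table["model"] == model]
        return sub["rho"].to_numpy()


def _prepare_brain(brain_vecs: np.ndarray, design: ControlDesign) -> np.ndarray:
    out = np.empty_like(brain_vecs)
    for i, v in enumerate(brain_vecs):
        out[i] = _rank_standardize(residualize(v, design))
    return out


def _behavior_standardized(scores: np.ndarray, model: str, design: ControlDesign) -> np.ndarray:
    v = vectorize_lower(behavior_matrix(scores, model))
    return _rank_standardize(residualize(v, design))


def _core(
    brain_vecs: np.ndarray,
    scores: np.ndarray,
    models: Sequence[str],
    design: ControlDesign,
    n_perm: int,
    rng: np.random.Generator,
    permutations: Sequence[np.ndarray] | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Observed rho and null rho streams, shared permutations across models/nodes.

    ``permutations`` overrides the sampled stream with an explicit list of
    subject index arrays (e.g. an exhaustive enumeration at tiny n).
    """
    scores = np.asarray(scores, dtype=float)
    if np.ptp(scores) == 0:
        raise ValueError("degenerate scores: zero variance")
    if permutations is None:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        permutations = (rng.permutation(len(scores)) for _ in range(n_perm))
    else:
        n_perm = len(permutations)
    b = _prepare_brain(brain_vecs, design)
    obs = {m: b @ _behavior_standardized(scores, m, design) for m in models}
    null = {m: np.empty((n_perm, b.shape[0])) for m in models}
    for k, perm in enumerate(permutations):
        sp = scores[perm]
        for m in models:
            null[m][k] = b @ _behavior_standardized(sp, m, design)
    return obs, null


def _perm_p(obs: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Add-one two-tailed permutation p on |rho|, per node."""
    exceed = (np.abs(null) >= np.abs(obs)[None, :]).sum(axis=0)
    return (1.0 + exceed) / (null.shape[0] + 1.0)


def isrsa_node(
    brain: np.ndarray,
    scores: np.ndarray,
    model: str,
    design: ControlDesign,
    n_perm: int,
    rng: np.random.Generator,
    alpha: float = 0.05,
    node_id: str = "node",
) -> NodeResult:
    """Single-node IS-RSA with permutation inference.

    ``brain`` is the node's subject-by-subject ISC matrix.  With a single
    test there is nothing to correct, so ``p_holm == p_perm``.
    """
    vec = vectorize_lower(brain)[None, :]
    obs, null = _core(vec, scores, [model], design, n_perm, rng)
    rho = float(obs[model][0])
    p = float(_perm_p(obs[model], null[model])[0])
    return NodeResult(
        node_id=node_id,
        model=model,
        rho=rho,
        p_perm=p,
        p_holm=p,
        sig_uncorrected=p < alpha,
        sig_corrected=p < alpha,
    )


def run_all_nodes(
    isc_matrices: np.ndarray,
    node_ids: Sequence[str],
    scores: np.ndarray,
    models: Sequence[str],
    design: ControlDesign,
    n_perm: int,
    rng: np.random.Generator,
    alpha: float = 0.05,
    permutations: Sequence[np.ndarray] | None = None,
) -> RunResult:
    """IS-RSA over all nodes and models with one shared permutation stream.

    Per model, Holm-Bonferroni correction is applied across nodes.
    Returns a :class:`RunResult` whose table has one row per
    (node, model) and whose null streams feed :func:`model_comparison`.
    An explicit ``permutations`` list replaces the sampled stream.
    """
    isc_matrices = np.asarray(isc_matrices, dtype=float)
    if isc_matrices.ndim != 3 or len(node_ids) != isc_matrices.shape[0]:
        raise ValueError("expected (n_nodes, n, n) matrices matching node_ids")
    try:
        brain_vecs = np.stack([vectorize_lower(m) for m in isc_matrices])
        obs, null = _core(brain_vecs, scores, models, design, n_perm, rng,
                          permutations=permutations)
        n_perm = next(iter(null.values())).shape[0]
    except ValueError as err:
        raise ValueError(f"IS-RSA failed: {err}") from err

    rows = []
    for m in models:
        p_perm = _perm_p(obs[m], null[m])
        p_holm = holm_bonferroni(p_perm)
        for i, node in enumerate(node_ids):
            rows.append(
                {
                    "node_id": node,
                    "model": m,
                    "rho": obs[m][i],
                    "p_perm": p_perm[i],
                    "p_holm": p_holm[i],
                    "sig_uncorrected": p_perm[i] < alpha,
                    "sig_corrected": p_holm[i] < alpha,
                }
            )
    return RunResult(table=pd.DataFrame(rows), null_rho=null, alpha=alpha, n_perm=n_perm)


def holm_bonferroni(pvalues: Sequence[float]) -> np.ndarray:
    """Step-down Holm-Bonferroni adjusted p-values, in the input order.

    At ascending rank k (1-based, m tests), the adjusted value is
    ``max_{j<=k} min(1, (m - j + 1) * p_(j))``, which enforces
    monotonicity of the step-down procedure.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need a non-empty 1-D vector of p-values")
    if np.any(~((p > 0) & (p <= 1))):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@dataclass
class FamilywiseResult:
    """Whole-brain significance of the count of nominally significant nodes."""

    observed_count: int
    alpha: float
    n_null_reps: int
    p_familywise: float


def familywise_count_test(
    observed_count: int,
    n_nodes: int,
    alpha: float,
    n_reps: int,
    rng: np.random.Generator,
) -> FamilywiseResult:
    """Simulated null for the number of nodes passing the nominal threshold.

    Each rep draws ``n_nodes`` independent Uniform(0, 1) p-values and
    counts those below ``alpha``; the whole-brain p is the add-one
    fraction of null counts at least as large as the observed count.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if not 0 <= observed_count <= n_nodes:
        raise ValueError(f"observed_count must lie in [0, {n_nodes}], got {observed_count}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    counts = (rng.random((n_reps, n_nodes)) < alpha).sum(axis=1)
    p = (1.0 + np.sum(counts >= observed_count)) / (n_reps + 1.0)
    return FamilywiseResult(
        observed_count=int(observed_count),
        alpha=alpha,
        n_null_reps=n_reps,
        p_familywise=float(p),
    )


def rho_vector(
    tc: TimecourseSet,
    behavior: pd.DataFrame,
    model: str,
    design_builder=control_design,
) -> np.ndarray:
    """Per-node observed IS-RSA rho for one cohort (no permutations).

    Recomputes ISC and the control design within the given cohort; used
    by :func:`split_half` per half and directly wherever only the
    observed fit is needed.
    """
    isc_m = pairwise_isc(tc)
    design = design_builder(behavior)
    brain = np.stack([vectorize_lower(m) for m in isc_m])
    b = _prepare_brain(brain, design)
    scores = behavior["score"].to_numpy(dtype=float)
    return b @ _behavior_standardized(scores, model, design)


@dataclass
class SplitHalfResult:
    """Consistency of per-node effects across two random disjoint cohorts."""

    cohort_assignment: pd.Series
    rho_cohort1: np.ndarray
    rho_cohort2: np.ndarray
    consistency_r: float


def split_half(
    tc: TimecourseSet,
    behavior: pd.DataFrame,
    model: str,
    rng: np.random.Generator,
    design_builder=control_design,
) -> SplitHalfResult:
    """Random disjoint halves; full IS-RSA per half; across-node Pearson r.

    ISC and the nuisance design are recomputed within each cohort.  The
    consistency r correlates the two per-node rho vectors, so it measures
    whether the *spatial pattern* of model fit replicates across halves.
    """
    n = tc.n_subjects
    if n < 8:
        raise ValueError(f"need at least 8 subjects for a split-half analysis, got {n}")
    order = rng.permutation(n)
    half = n // 2
    labels = np.empty(n, dtype=int)
    labels[order[:half]] = 1
    labels[order[half:]] = 2
    assignment = pd.Series(labels, index=list(tc.subject_ids), name="cohort")

    rhos = []
    for cohort in (1, 2):
        ids = [s for s, c in assignment.items() if c == cohort]
        beh = behavior.set_index("subject_id").loc[ids].reset_index()
        rhos.append(rho_vector(tc.subset(ids), beh, model, design_builder))
    r = isc_fit_correlation(rhos[0], rhos[1])
    return SplitHalfResult(assignment, rhos[0], rhos[1], r)


@dataclass
class ModelComparisonResult:
    """Whole-brain AnnaK-vs-NN contrast on the Fisher-Z scale."""

    mean_z_diff: float
    rho_scale_diff: float
    p_two_sided: float
    model_a: str = "annak"
    model_b: str = "nn"


def _mean_z_diff(rho_a: np.ndarray, rho_b: np.ndarray) -> float:
    za = np.arctanh(np.clip(rho_a, -_ATANH_CLIP, _ATANH_CLIP))
    zb = np.arctanh(np.clip(rho_b, -_ATANH_CLIP, _ATANH_CLIP))
    return float(np.mean(za - zb))


def model_comparison(
    result: RunResult,
    model_a: str = "annak",
    model_b: str = "nn",
) -> ModelComparisonResult:
    """Direct two-model contrast averaged across nodes.

    The observed statistic is mean over nodes of
    ``atanh(rho_a) - atanh(rho_b)``; the reported effect is its inverse
    Fisher-Z (``tanh``), back on the correlation scale.  The null uses
    the per-permutation analog from the shared streams (same subject
    shuffle for both models within an iteration), two-sided on the
    absolute difference.  Perfect correlations are clipped to
    ``+/-(1 - 1e-12)`` before ``atanh``.
    """
    for m in (model_a, model_b):
        if m not in result.null_rho:
            raise ValueError(f"model {m!r} was not run; available: {list(result.null_rho)}")
    obs = _mean_z_diff(result.rho(model_a), result.rho(model_b))
    za = np.arctanh(np.clip(result.null_rho[model_a], -_ATANH_CLIP, _ATANH_CLIP))
    zb = np.arctanh(np.clip(result.null_rho[model_b], -_ATANH_CLIP, _ATANH_CLIP))
    null = (za - zb).mean(axis=1)
    p = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (result.n_perm + 1.0)
    return ModelComparisonResult(
        mean_z_diff=obs,
        rho_scale_diff=float(np.tanh(obs)),
        p_two_sided=float(p),
        model_a=model_a,
        model_b=model_b,
    )


def isc_fit_correlation(mean_isc_values: np.ndarray, rho: np.ndarray) -> float:
    """Pearson correlation across nodes of mean ISC with IS-RSA fit."""
    x = np.asarray(mean_isc_values, dtype=float)
    y = np.asarray(rho, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of at least 3 nodes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def network_enrichment(
    sig_flags: Mapping[str, bool] | pd.Series,
    node_network: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Hypergeometric over-representation of significant nodes per network.

    For a network of size m with k significant nodes out of K significant
    among N total, expected = m * K / N and p is the upper tail
    P(X >= k) of Hypergeometric(N, K, m).
    """
    sig = pd.Series(sig_flags).astype(bool)
    net = pd.Series(node_network)
    unmapped = sig.index.difference(net.index)
    if len(unmapped) > 0:
        raise ValueError(f"nodes without a network mapping: {list(unmapped)[:5]}")
    net = net.loc[sig.index]
    n_total = len(sig)
    n_sig = int(sig.sum())
    rows = []
    for network, members in sig.groupby(net):
        m = len(members)
        k = int(members.sum())
        rows.append(
            {
                "network": network,
                "n_nodes": m,
                "n_significant": k,
                "expected": m * n_sig / n_total,
                "p": float(stats.hypergeom.sf(k - 1, n_total, n_sig, m)),
            }
        )
    return pd.DataFrame(rows).sort_values("network", ignore_index=True)
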