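"""Node-wise pairwise intersubject correlation (ISC).

For every node, each subject's time course is z-scored within subject and
Pearson-correlated with every other subject's, yielding one symmetric
subject-by-subject brain-similarity matrix per node.  Downstream analyses
use only the strictly-lower/upper triangle, vectorized in a fixed
lexicographic pair order.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .synthetic import TimecourseSet

__all__ = [
    "pairwise_isc",
    "mean_isc",
    "vectorize_lower",
    "devectorize",
    "pair_index",
]


def pairwise_isc(tc: TimecourseSet) -> np.ndarray:
    """Per-node subject-by-subject Pearson correlation matrices.

    Returns an array of shape ``(n_nodes, n_subjects, n_subjects)``;
    matrices are exactly symmetric with unit diagonal (the diagonal is
    never used downstream).

    Raises
    ------
    ValueError
        If any (subject, node) series has zero variance, naming the
        offending subject and node, or if fewer than 3 timepoints.
    """
    x = tc.values
    n_subj, n_nodes, t = x.shape
    if t < 3:
        raise ValueError(f"need at least 3 timepoints for correlation, got {t}")
    sd = x.std(axis=2)
    if np.any(sd == 0):
        i, j = np.argwhere(sd == 0)[0]
        raise ValueError(
            f"degenerate series: subject {tc.subject_ids[i]!r} has zero variance "
            f"at node {tc.node_ids[j]!r}"
        )
    # z-score within subject (population 1/T normalization; Pearson r is
    # invariant to the choice) then correlate via one matmul per node
    z = (x - x.mean(axis=2, keepdims=True)) / sd[:, :, None]
    out = np.empty((n_nodes, n_subj, n_subj))
    for j in range(n_nodes):
        c = z[:, j, :] @ z[:, j, :].T / t
        c = (c + c.T) / 2.0
        np.fill_diagonal(c, 1.0)
        out[j] = np.clip(c, -1.0, 1.0)
    return out


def mean_isc(m: np.ndarray) -> float:
    """Arithmetic mean of the n(n-1)/2 off-diagonal pairs of one matrix."""
    m = np.asarray(m, dtype=float)
    n = m.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 subjects, got {n}")
    iu = np.triu_indices(n, k=1)
    return float(m[iu].mean())


def pair_index(n: int) -> list[tuple[int, int]]:
    """Canonical pair ordering: (i, j) with i < j, lexicographic."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def vectorize_lower(m: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Vectorize the strict lower triangle of a symmetric matrix.

    Entries are returned in the canonical order of :func:`pair_index`
    (equivalently the row-major upper triangle — identical for a
    symmetric matrix).
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    if np.max(np.abs(m - m.T)) > tol:
        raise ValueError(f"matrix asymmetric beyond tolerance {tol}")
    return m[np.triu_indices(m.shape[0], k=1)].copy()


def devectorize(v: np.ndarray, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_lower` (diagonal filled with ``diagonal``)."""
    v = np.asarray(v, dtype=float)
    # length n(n-1)/2 -> n
    n = int(round((1 + np.sqrt(1 + 8 * len(v))) / 2))
    if n * (n - 1) // 2 != len(v):
        raise ValueError(f"vector length {len(v)} is not n(n-1)/2 for any integer n")
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = v
    m = m + m.T
    np.fill_diagonal(m, diagonal)
    return m


def mean_isc_table(isc_matrices: np.ndarray, node_ids: Sequence[str]):
    """Two-column per-node mean ISC table (node_id, mean_isc)."""
    import pandas as pd

    return pd.DataFrame(
        {"node_id": list(node_ids), "mean_isc": [mean_isc(m) for m in isc_matrices]}
    )
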