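"""Behavioral and nuisance similarity matrices.

Two competing operationalizations of "behaviorally similar" are the heart
of the analysis:

* **AnnaK**: similarity(i, j) = mean(b_i, b_j).  High scorers are all
  alike (mutually similar); low scorers are each idiosyncratic.
* **Nearest Neighbors (NN)**: similarity(i, j) = -|b_i - b_j|.  Adjacency
  on the behavioral scale predicts similarity at every level of the score.

A combined form |b_i - b_j| * mean(b_i, b_j) and a categorical match
matrix (1 if same category) round out the constructions.  The control
design stacks the nuisance pair-vectors — sex match, AnnaK/NN age, AnnaK/NN
motion, the age-by-sex-match interactions, and an intercept — that are
regressed out of both the brain and behavioral pair-vectors before rank
correlation.

Whether higher scores mean "better" is the caller's concern; nothing here
reorients a score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .isc import vectorize_lower

__all__ = [
    "annak_matrix",
    "nn_matrix",
    "combined_matrix",
    "match_matrix",
    "behavior_matrix",
    "ControlDesign",
    "control_design",
]

logger = logging.getLogger(__name__)

MODELS = ("annak", "nn", "combined")


def _check_scores(scores) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or len(scores) < 2:
        raise ValueError("need a 1-D vector of at least 2 scores")
    if np.any(~np.isfinite(scores)):
        i = int(np.flatnonzero(~np.isfinite(scores))[0])
        raise ValueError(f"missing or non-finite score for subject index {i}")
    return scores


def annak_matrix(scores) -> np.ndarray:
    """AnnaK similarity: entry (i, j) = (b_i + b_j) / 2."""
    b = _check_scores(scores)
    return (b[:, None] + b[None, :]) / 2.0


def nn_matrix(scores) -> np.ndarray:
    """Nearest Neighbors similarity: entry (i, j) = -|b_i - b_j|."""
    b = _check_scores(scores)
    return -np.abs(b[:, None] - b[None, :])


def combined_matrix(scores) -> np.ndarray:
    """Combined form: entry (i, j) = |b_i - b_j| * (b_i + b_j) / 2."""
    b = _check_scores(scores)
    return np.abs(b[:, None] - b[None, :]) * (b[:, None] + b[None, :]) / 2.0


def behavior_matrix(scores, model: str) -> np.ndarray:
    """Dispatch on model label in {"annak", "nn", "combined"}."""
    if model == "annak":
        return annak_matrix(scores)
    if model == "nn":
        return nn_matrix(scores)
    if model == "combined":
        return combined_matrix(scores)
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def match_matrix(categories) -> np.ndarray:
    """Categorical match: entry (i, j) = 1 if categories equal, else 0."""
    cats = np.asarray(categories)
    if len(cats) < 2:
        raise ValueError("need at least 2 subjects")
    if pd.isna(cats).any():
        i = int(np.flatnonzero(pd.isna(cats))[0])
        raise ValueError(f"missing category for subject index {i}")
    return (cats[:, None] == cats[None, :]).astype(float)


@dataclass
class ControlDesign:
    """Stacked nuisance pair-vectors with intercept, pairs x columns."""

    names: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("matrix must be (n_pairs, n_columns) matching names")

    @property
    def n_pairs(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def intercept_only(cls, n_pairs: int) -> "ControlDesign":
        return cls(["intercept"], np.ones((n_pairs, 1)))


def control_design(behavior: pd.DataFrame) -> ControlDesign:
    """Assemble the nuisance design from a behavioral table.

    Columns (before degeneracy pruning): sex_match, age_annak, age_nn,
    motion_annak, motion_nn, age_annak_x_sex, age_nn_x_sex, intercept.
    The interaction terms are the elementwise products of each age
    pair-vector with the sex-match pair-vector.  Exactly-constant and
    exactly-duplicated non-intercept columns are dropped with a warning
    (in a single-sex cohort sex_match is constant and both interactions
    collapse onto the age columns); any *remaining* rank deficiency is a
    data problem and raises a collinear-controls error.
    """
    for col in ("age", "sex", "motion"):
        if col not in behavior.columns:
            raise ValueError(f"behavioral table lacks required column {col!r}")
    sex_match = vectorize_lower(match_matrix(behavior["sex"].to_numpy()))
    age_ak = vectorize_lower(annak_matrix(behavior["age"].to_numpy()))
    age_nn = vectorize_lower(nn_matrix(behavior["age"].to_numpy()))
    mot_ak = vectorize_lower(annak_matrix(behavior["motion"].to_numpy()))
    mot_nn = vectorize_lower(nn_matrix(behavior["motion"].to_numpy()))

    columns = {
        "sex_match": sex_match,
        "age_annak": age_ak,
        "age_nn": age_nn,
        "motion_annak": mot_ak,
        "motion_nn": mot_nn,
        "age_annak_x_sex": age_ak * sex_match,
        "age_nn_x_sex": age_nn * sex_match,
    }
    kept_names, kept_cols = [], []
    for name, col in columns.items():
        if np.ptp(col) == 0.0:
            logger.warning("dropping constant control column %r", name)
            continue
        dup = next((n for n, c in zip(kept_names, kept_cols) if np.array_equal(c, col)), None)
        if dup is not None:
            logger.warning("dropping control column %r (duplicates %r)", name, dup)
            continue
        kept_names.append(name)
        kept_cols.append(col)
    kept_names.append("intercept")
    kept_cols.append(np.ones_like(sex_match))
    design = np.column_stack(kept_cols)

    # in tiny cohorts n_pairs can be smaller than the column count; the
    # design is then saturated by construction, which is not a data problem
    rank = np.linalg.matrix_rank(design)
    if rank < min(design.shape):
        # identify offending columns: those whose removal restores full rank
        offenders = [
            kept_names[k]
            for k in range(design.shape[1])
            if np.linalg.matrix_rank(np.delete(design, k, axis=1)) == rank
        ]
        raise ValueError(f"collinear control columns: {offenders}")
    return ControlDesign(kept_names, design)
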