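"""Synthetic cohorts with planted brain-behavior coupling.

Movie-watching ISC studies relate a subject-by-subject brain-similarity
matrix to a behavioral-similarity matrix, but real parcellated BOLD data
carry no ground truth about which nodes are coupled to behavior.  This
module generates per-subject node time courses whose *population*
intersubject correlation is a known closed form of the behavioral scores,
so every inference stage downstream can be validated against a planted
truth.

Two generative structures are provided, one per behavioral-similarity
model:

``annak``
    Each subject carries the node's shared stimulus signal with a weight
    monotone in their (min-max normalized) behavioral score::

        x_i(t) = w_i * s(t) + sqrt(1 - w_i^2) * eps_i(t),   w_i = kappa * w~_i

    giving population ISC(i, j) = kappa^2 * w~_i * w~_j — high scorers are
    all synchronized alike, low scorers idiosyncratic.

``nn``
    Each subject mixes two orthogonal shared signals at a phase set by
    their score::

        x_i(t) = kappa * [cos(th_i) s1(t) + sin(th_i) s2(t)]
                 + sqrt(1 - kappa^2) * eps_i(t),   th_i = (pi/2) * w~_i

    giving population ISC(i, j) = kappa^2 * cos(th_i - th_j) — synchrony
    decays with score distance regardless of score level.

``null``
    Pure white noise; population ISC is zero.

All signals are unit-variance white noise by default (an optional AR(1)
smoothing exists but is off), so the closed forms above are exact and are
exposed as :func:`expected_isc`.  Shared signals are drawn independently
per node.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimSpec",
    "TimecourseSet",
    "generate_behavior",
    "generate_timecourses",
    "expected_isc",
    "write_behavior",
    "write_timecourses",
]

NODE_MODELS = ("annak", "nn", "null")

# Motion scale calibrated to typical mean framewise displacement in a
# well-scrubbed developmental movie-watching sample (~0.096 +/- 0.026 mm).
_MOTION_MEAN = 0.096
_MOTION_SD = 0.026


@dataclass(frozen=True)
class SimSpec:
    """Full parameterization of one synthetic cohort.

    Parameters
    ----------
    n_subjects, n_nodes, n_timepoints
        Cohort and series dimensions; ``n_timepoints`` must be >= 10.
    node_models
        Per-node label in ``{"annak", "nn", "null"}``, length ``n_nodes``.
    coupling
        Per-node coupling kappa in [0, 1]; forced to 0 for null nodes.
    score_distribution
        ``(name, params)`` with name in ``{"normal", "uniform", "lognormal"}``.
    age_range
        ``(low, high)`` in years; ages drawn uniformly.
    age_motion_corr
        Target population Pearson correlation between age and mean
        framewise displacement, in (-1, 1).  Head motion decreases with
        age in developmental samples, hence the negative default.
    seed
        Seed for all randomness; identical specs produce bit-identical
        outputs.
    ar1
        Optional AR(1) coefficient applied to every signal (0 disables;
        nonzero values break the exactness of :func:`expected_isc`).
    sex_offset
        Optional additive offset applied to every male subject's series;
        exists to exercise the nuisance-control machinery, default 0.
    """

    n_subjects: int
    n_nodes: int
    n_timepoints: int
    node_models: tuple[str, ...] = ()
    coupling: tuple[float, ...] = ()
    score_distribution: tuple[str, dict] = ("normal", {"loc": 0.0, "scale": 1.0})
    age_range: tuple[float, float] = (6.0, 22.0)
    age_motion_corr: float = -0.35
    seed: int = 0
    ar1: float = 0.0
    sex_offset: float = 0.0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.n_timepoints < 10:
            raise ValueError("n_timepoints must be >= 10")
        if not abs(self.age_motion_corr) < 1:
            raise ValueError(
                f"age_motion_corr must lie strictly in (-1, 1), got {self.age_motion_corr}"
            )
        models = tuple(self.node_models) or ("null",) * self.n_nodes
        if len(models) != self.n_nodes:
            raise ValueError("node_models must have length n_nodes")
        for m in models:
            if m not in NODE_MODELS:
                raise ValueError(f"unknown node model {m!r}; expected one of {NODE_MODELS}")
        coupling = tuple(self.coupling) or (0.0,) * self.n_nodes
        if len(coupling) != self.n_nodes:
            raise ValueError("coupling must have length n_nodes")
        # Null nodes carry no shared signal by definition.
        coupling = tuple(
            0.0 if m == "null" else float(k) for m, k in zip(models, coupling)
        )
        for k in coupling:
            if not 0.0 <= k <= 1.0:
                raise ValueError(f"coupling must lie in [0, 1], got {k}")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be (low, high) with low < high")
        object.__setattr__(self, "node_models", models)
        object.__setattr__(self, "coupling", coupling)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["node_models"] = list(self.node_models)
        d["coupling"] = list(self.coupling)
        d["score_distribution"] = [self.score_distribution[0], dict(self.score_distribution[1])]
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class TimecourseSet:
    """Per-subject node time courses, indexed (subject, node, timepoint)."""

    subject_ids: list[str]
    node_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.node_ids), self.values.shape[2]):
            raise ValueError("values must have shape (n_subjects, n_nodes, n_timepoints)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time courses contain non-finite values")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]

    def subset(self, subject_ids: Sequence[str]) -> "TimecourseSet":
        """Restrict to the given subjects, preserving the given order."""
        index = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in index]
        if missing:
            raise KeyError(f"subjects not in time-course set: {missing}")
        rows = [index[s] for s in subject_ids]
        return TimecourseSet(list(subject_ids), list(self.node_ids), self.values[rows])


def _draw_scores(rng: np.random.Generator, dist: tuple[str, dict], n: int) -> np.ndarray:
    name, params = dist
    if name == "normal":
        return rng.normal(params.get("loc", 0.0), params.get("scale", 1.0), size=n)
    if name == "uniform":
        return rng.uniform(params.get("low", 0.0), params.get("high", 1.0), size=n)
    if name == "lognormal":
        return rng.lognormal(params.get("mean", 0.0), params.get("sigma", 1.0), size=n)
    raise ValueError(f"unknown score distribution {name!r}")


def generate_behavior(spec: SimSpec) -> pd.DataFrame:
    """Draw the behavioral table for a cohort.

    Scores come from ``spec.score_distribution``, ages uniformly from
    ``spec.age_range``, sex as a fair binary draw, and motion (mean
    framewise displacement, mm) as an affine function of age plus
    independent Gaussian noise calibrated so the *population* Pearson
    correlation of age and motion equals ``spec.age_motion_corr``.

    Returns a DataFrame with columns
    ``subject_id, score, age, sex, motion``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    score = _draw_scores(rng, spec.score_distribution, n)
    lo, hi = spec.age_range
    age = rng.uniform(lo, hi, size=n)
    sex = np.where(rng.random(n) < 0.5, "F", "M")

    r = spec.age_motion_corr
    sd_age = (hi - lo) / math.sqrt(12.0)  # population sd of Uniform(lo, hi)
    beta = r * _MOTION_SD / sd_age
    sigma = _MOTION_SD * math.sqrt(1.0 - r * r)
    motion = _MOTION_MEAN + beta * (age - (lo + hi) / 2.0) + sigma * rng.standard_normal(n)
    # FD is nonnegative by construction of the measure; at the calibrated
    # scale (mean ~4 sd above zero) this clip essentially never fires.
    motion = np.clip(motion, 0.0, None)

    width = len(str(n))
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:0{width}d}" for i in range(n)],
            "score": score,
            "age": age,
            "sex": sex,
            "motion": motion,
        }
    )


def _normalize_scores(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    span = scores.max() - scores.min()
    if span == 0:
        raise ValueError("degenerate scores: zero variance, cannot place coupling weights")
    return (scores - scores.min()) / span


def _ar1_filter(x: np.ndarray, phi: float) -> np.ndarray:
    """In-place AR(1) smoothing along the last axis, renormalized to unit variance."""
    out = np.empty_like(x)
    out[..., 0] = x[..., 0]
    for t in range(1, x.shape[-1]):
        out[..., t] = phi * out[..., t - 1] + x[..., t]
    return out * math.sqrt(1.0 - phi * phi)


def generate_timecourses(behavior: pd.DataFrame, spec: SimSpec) -> TimecourseSet:
    """Emit node time courses whose population ISC follows the planted model.

    The RNG is seeded from ``spec.seed`` (offset from the behavioral
    stream) so behavior and time courses are jointly reproducible.
    """
    if len(behavior) != spec.n_subjects:
        raise ValueError(
            f"behavior has {len(behavior)} rows but spec.n_subjects = {spec.n_subjects}"
        )
    rng = np.random.default_rng((spec.seed, 1))
    n, t = spec.n_subjects, spec.n_timepoints
    needs_scores = any(m in ("annak", "nn") for m in spec.node_models)
    wtil = _normalize_scores(behavior["score"].to_numpy()) if needs_scores else None

    values = np.empty((n, spec.n_nodes, t))
    for j, (model, kappa) in enumerate(zip(spec.node_models, spec.coupling)):
        eps = rng.standard_normal((n, t))
        if model == "null":
            series = eps
        elif model == "annak":
            s = rng.standard_normal(t)
            w = kappa * wtil
            series = w[:, None] * s[None, :] + np.sqrt(1.0 - w**2)[:, None] * eps
        else:  # nn
            s1 = rng.standard_normal(t)
            s2 = rng.standard_normal(t)
            theta = (math.pi / 2.0) * wtil
            shared = np.cos(theta)[:, None] * s1[None, :] + np.sin(theta)[:, None] * s2[None, :]
            series = kappa * shared + math.sqrt(1.0 - kappa * kappa) * eps
        values[:, j, :] = series

    if spec.ar1:
        values = _ar1_filter(values, spec.ar1)
    if spec.sex_offset:
        male = (behavior["sex"].to_numpy() == "M")
        values[male] += spec.sex_offset

    node_width = len(str(spec.n_nodes))
    return TimecourseSet(
        subject_ids=list(behavior["subject_id"]),
        node_ids=[f"node{j + 1:0{node_width}d}" for j in range(spec.n_nodes)],
        values=values,
    )


def expected_isc(
    model: str,
    coupling: float,
    score_i: float,
    score_j: float,
    score_bounds: tuple[float, float],
) -> float:
    """Closed-form population ISC of the generative process for one pair.

    ``score_bounds`` are the (min, max) used for min-max normalization;
    scores outside them are rejected.
    """
    if model not in NODE_MODELS:
        raise ValueError(f"unknown node model {model!r}")
    lo, hi = score_bounds
    if lo >= hi:
        raise ValueError("score_bounds must satisfy min < max")
    for s in (score_i, score_j):
        if not lo <= s <= hi:
            raise ValueError(f"score {s} outside bounds [{lo}, {hi}]")
    if model == "null":
        return 0.0
    wi = (score_i - lo) / (hi - lo)
    wj = (score_j - lo) / (hi - lo)
    k2 = coupling * coupling
    if model == "annak":
        return k2 * wi * wj
    return k2 * math.cos((math.pi / 2.0) * (wi - wj))


def write_behavior(behavior: pd.DataFrame, path: str | Path) -> None:
    behavior.to_csv(path, sep="\t", index=False)


def write_timecourses(tc: TimecourseSet, outdir: str | Path, spec: SimSpec | None = None) -> None:
    """One TSV per subject (rows = timepoints, columns = node IDs, header row).

    If a spec is given it is echoed, seed included, to ``simspec.json``
    alongside the data so a run is reproducible from its output directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, sid in enumerate(tc.subject_ids):
        df = pd.DataFrame(tc.values[i].T, columns=tc.node_ids)
        df.to_csv(outdir / f"{sid}_timecourses.tsv", sep="\t", index=False)
    if spec is not None:
        (outdir / "simspec.json").write_text(spec.to_json() + "\n")
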