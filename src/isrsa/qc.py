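"""Motion quality control on the behavioral table.

Subjects are retained only if strictly below every requested motion
threshold; the conventional cutoffs for movie-watching data are mean
framewise displacement < 0.15 mm and maximum head displacement < 3 mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["QCReport", "qc_filter"]


@dataclass
class QCReport:
    """Per-subject pass/fail with reasons, plus retained/excluded counts."""

    table: pd.DataFrame  # subject_id, passed, reason
    n_retained: int
    n_excluded: int


def qc_filter(
    behavior: pd.DataFrame,
    mean_fd: float | None = 0.15,
    max_displacement: float | None = None,
    motion_col: str = "motion",
    max_disp_col: str = "max_displacement",
) -> tuple[pd.DataFrame, QCReport]:
    """Exclude subjects at or above any motion threshold (strict ``<`` to pass).

    A threshold set to ``None`` is not applied.  Requesting a threshold
    whose column is absent is a configuration error.
    """
    checks = []
    if mean_fd is not None:
        if motion_col not in behavior.columns:
            raise ValueError(f"mean-FD threshold requested but column {motion_col!r} absent")
        checks.append((motion_col, mean_fd, "mean FD"))
    if max_displacement is not None:
        if max_disp_col not in behavior.columns:
            raise ValueError(
                f"max-displacement threshold requested but column {max_disp_col!r} absent"
            )
        checks.append((max_disp_col, max_displacement, "max displacement"))

    passed = pd.Series(True, index=behavior.index)
    reasons = pd.Series("", index=behavior.index, dtype=object)
    for col, thr, label in checks:
        fail = ~(behavior[col] < thr)
        passed &= ~fail
        for i in behavior.index[fail]:
            sep = "; " if reasons[i] else ""
            reasons[i] = f"{reasons[i]}{sep}{label} {behavior.at[i, col]:.4g} >= {thr:g} mm"
    reasons[passed] = "ok"

    report = QCReport(
        table=pd.DataFrame(
            {
                "subject_id": behavior["subject_id"].to_numpy(),
                "passed": passed.to_numpy(),
                "reason": reasons.to_numpy(),
            }
        ),
        n_retained=int(passed.sum()),
        n_excluded=int((~passed).sum()),
    )
    return behavior[passed].reset_index(drop=True), report
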