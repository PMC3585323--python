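"""Auxiliary contingency statistics and human-readable table rendering.

Contingency tests follow the convention of applying the Yates continuity
correction exactly on 2x2 tables (the correction has no standard extension
beyond 2x2), with an override for either policy.  Table renderers mirror
the layout of the published worked example: the 10 linkage classes as
rows, one expected-count column per accommodated constraint with the
per-class chi-squared cell in parentheses, and a totals matrix with one
row per network pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .linkage import canonical_classes
from .maxent import FitTrajectory


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
            raise ValueError("contingency table needs at least 2 rows and 2 columns")
        if np.any(c < 0):
            raise ValueError("negative count")
        if c.sum() <= 0:
            raise ValueError("empty contingency table")
        self.counts = c
        if self.row_labels is None:
            self.row_labels = tuple(f"r{i}" for i in range(c.shape[0]))
        if self.col_labels is None:
            self.col_labels = tuple(f"c{j}" for j in range(c.shape[1]))


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    correction: str  # "none" | "yates"


def pearson_chisq(
    table: ContingencyTable | np.ndarray, correction_policy: str = "auto"
) -> TestResult:
    """Pearson chi-squared test of independence on an r x c table.

    ``correction_policy``: ``auto`` applies the Yates continuity
    correction exactly on 2x2 tables, ``force-on`` / ``force-off``
    override.  The statistic is sum of (|O - E| - c)^2 / E with c = 0.5
    when corrected.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(counts=np.asarray(table))
    obs = table.counts
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero marginal row or column")
    is_2x2 = obs.shape == (2, 2)
    if correction_policy == "auto":
        correct = is_2x2
    elif correction_policy == "force-on":
        if not is_2x2:
            raise ValueError("Yates correction is defined for 2x2 tables only")
        correct = True
    elif correction_policy == "force-off":
        correct = False
    else:
        raise ValueError(f"unknown correction policy {correction_policy!r}")
    statistic, p, df, _ = stats.chi2_contingency(obs, correction=correct)
    return TestResult(
        statistic=float(statistic),
        df=int(df),
        p_value=float(p),
        correction="yates" if correct else "none",
    )


def proportion_comparison(
    successes_1: int,
    total_1: int,
    successes_2: int,
    total_2: int,
    correction_policy: str = "auto",
) -> tuple[TestResult, float, float]:
    """Compare two proportions via the implied 2x2 chi-squared test.

    Returns (test result, proportion 1, proportion 2).  Under the auto
    policy the 2x2 test is Yates-corrected.
    """
    if total_1 <= 0 or total_2 <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= successes_1 <= total_1 and 0 <= successes_2 <= total_2):
        raise ValueError("successes must lie in [0, total]")
    table = np.array(
        [
            [successes_1, total_1 - successes_1],
            [successes_2, total_2 - successes_2],
        ]
    )
    result = pearson_chisq(table, correction_policy)
    return result, successes_1 / total_1, successes_2 / total_2


def trajectory_frame(trajectory: FitTrajectory) -> pd.DataFrame:
    """Expected counts and chi cells per class and step, as a DataFrame.

    Columns come in pairs ``<step>`` / ``<step>_chisq`` after the observed
    column; rows follow the reference class order.
    """
    classes = canonical_classes()
    data: dict[str, list[float]] = {
        "class": [cl.label for cl in classes],
        "observed": [trajectory.observed[cl.representative] for cl in classes],
    }
    for step in trajectory.steps:
        data[step.label] = [step.expected[cl.representative] for cl in classes]
        data[f"{step.label}_chisq"] = [
            step.chisq_cells.get(cl.representative, float("nan")) for cl in classes
        ]
    return pd.DataFrame(data)


def render_table1(trajectory: FitTrajectory) -> str:
    """Fixed-width text table in the worked-example layout.

    One row per linkage class; per model column the expected count with the
    chi-squared cell in parentheses, both to 2 decimals; a totals row with
    the 4-to-7-significant-digit totals.
    """
    classes = canonical_classes()
    header = ["A B", "observed"] + [s.label for s in trajectory.steps]
    rows = []
    for cl in classes:
        bits = " ".join(str(b) for b in cl.representative)
        row = [bits, str(trajectory.observed[cl.representative])]
        for step in trajectory.steps:
            e = step.expected[cl.representative]
            chi = step.chisq_cells.get(cl.representative)
            cell = f"{e:.2f}" + (f" ({chi:.2f})" if chi is not None else " (—)")
            row.append(cell)
        rows.append(row)
    totals = ["total", ""] + [f"{step.total_chisq:.7g}" for step in trajectory.steps]
    rows.append(totals)
    widths = [max(len(r[i]) for r in [header] + rows) for i in range(len(header))]
    lines = ["  ".join(h.ljust(w) for h, w in zip(header, widths)).rstrip()]
    for r in rows:
        lines.append("  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip())
    return "\n".join(lines)


def summarize_trajectory(
    trajectories: Mapping[str, FitTrajectory]
) -> pd.DataFrame:
    """Totals matrix: one row per network pair, one column per step."""
    rows = {}
    columns: list[str] = []
    for label, traj in trajectories.items():
        rows[label] = {s.label: s.total_chisq for s in traj.steps}
        for s in traj.steps:
            if s.label not in columns:
                columns.append(s.label)
    frame = pd.DataFrame.from_dict(rows, orient="index")
    if len(columns) == 0:
        return frame
    return frame.reindex(columns=columns)
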