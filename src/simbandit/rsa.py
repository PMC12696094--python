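"""Representational similarity machinery for person x run activity patterns.

The hypothesis matrix codes pattern pairs from different functional runs as
+1 when they feature the same person and -1 when they feature different
persons from the same reward condition; same-run pairs and cross-condition
pairs are excluded by the mask, so that the contrast is not confounded by
run effects or condition (value) differences. Data RSMs are Kendall tau
similarities between pattern vectors, and model-data agreement is the
Kendall tau-a rank correlation over the included lower-triangle cells —
tau-a because the model matrix is heavily tied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RSM", "build_model_rsm", "neural_rsm", "rsm_agreement", "kendall_tau_a"]


@dataclass
class RSM:
    """A similarity matrix over labeled patterns with an inclusion mask.

    ``labels`` has one row per pattern with columns person_id, run,
    condition; ``include_mask`` selects the off-diagonal cells that enter any
    comparison (always symmetric, diagonal excluded).
    """

    values: np.ndarray
    include_mask: np.ndarray
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n) or self.include_mask.shape != (n, n):
            raise ValueError("values/mask shape must match label count")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("values must be symmetric")
        if not np.array_equal(self.include_mask, self.include_mask.T):
            raise ValueError("mask must be symmetric")
        if np.any(np.diag(self.include_mask)):
            raise ValueError("diagonal cells must be excluded")

    def included_lower_triangle(self) -> np.ndarray:
        """Included cell values from the lower triangle, row-major order."""
        n = len(self.labels)
        il, jl = np.tril_indices(n, k=-1)
        keep = self.include_mask[il, jl]
        return self.values[il[keep], jl[keep]]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        names = [f"{r.person_id}_run{r.run}" for r in self.labels.itertuples()]
        return (pd.DataFrame(self.values, index=names, columns=names),
                pd.DataFrame(self.include_mask.astype(int), index=names,
                             columns=names))


def _check_design(labels: pd.DataFrame) -> None:
    required = {"person_id", "run", "condition"}
    if required - set(labels.columns):
        raise ValueError(f"labels need columns {sorted(required)}")
    persons = labels.groupby("person_id")["condition"].first()
    if len(persons) != 4 or labels["run"].nunique() != 4 or len(labels) != 16:
        raise ValueError("expected 4 persons x 4 runs (16 patterns)")
    counts = persons.value_counts()
    if not (counts.get("HR", 0) == 2 and counts.get("LR", 0) == 2):
        raise ValueError("expected 2 HR and 2 LR persons")


def build_model_rsm(labels: pd.DataFrame) -> RSM:
    """Hypothesis RSM: +1 same person across runs, -1 different persons of
    the same condition across runs; everything else excluded."""
    _check_design(labels)
    n = len(labels)
    values = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    rows = list(labels.itertuples())
    for i, j in combinations(range(n), 2):
        a, b = rows[i], rows[j]
        if a.run == b.run:
            continue
        if a.person_id == b.person_id:
            code = 1.0
        elif a.condition == b.condition:
            code = -1.0
        else:
            continue
        values[i, j] = values[j, i] = code
        mask[i, j] = mask[j, i] = True
    return RSM(values=values, include_mask=mask, labels=labels.reset_index(drop=True))


def neural_rsm(patterns: np.ndarray, labels: pd.DataFrame) -> RSM:
    """Data RSM: Kendall tau similarity between every pair of patterns,
    carrying the same mask and labels as the hypothesis RSM."""
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2 or patterns.shape[0] != len(labels):
        raise ValueError("patterns must be (n_patterns, n_voxels)")
    if patterns.shape[1] < 2:
        raise ValueError("need at least 2 voxels")
    if np.any(patterns.std(axis=1) == 0):
        raise ValueError("constant pattern: Kendall tau undefined")
    n = patterns.shape[0]
    values = np.eye(n)
    for i, j in combinations(range(n), 2):
        tau = stats.kendalltau(patterns[i], patterns[j]).statistic
        values[i, j] = values[j, i] = tau
    template = build_model_rsm(labels)
    return RSM(values=values, include_mask=template.include_mask,
               labels=template.labels)


def kendall_tau_a(x, y) -> float:
    """Kendall tau-a: (concordant - discordant) / all pairs, no tie
    adjustment in the denominator."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D arrays, n >= 2")
    n = x.size
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    num = float(np.sum(np.tril(sx * sy, k=-1)))
    return num / (n * (n - 1) / 2)


def rsm_agreement(model: RSM, neural: RSM) -> float:
    """Kendall tau-a between model and data RSMs over included cells.

    Positive agreement means same-person pattern pairs are more similar than
    different-person pairs of the same condition.
    """
    if not np.array_equal(model.include_mask, neural.include_mask):
        raise ValueError("RSMs have different inclusion masks")
    if not model.labels[["person_id", "run"]].equals(
            neural.labels[["person_id", "run"]]):
        raise ValueError("RSMs have different labels")
    return kendall_tau_a(model.included_lower_triangle(),
                         neural.included_lower_triangle())
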