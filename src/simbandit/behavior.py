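"""Behavioral statistics: acquired preference, nonparametric tests with
effect sizes, baseline-corrected liking updates, and robust (skipped)
Spearman correlation.

The acquired-preference measure p(HR) is a subject's probability of choosing
the high-reward person over the session, missed trials excluded. The
one-tailed Wilcoxon signed-rank test against 0.5 uses the normal
approximation with continuity and tie corrections, reporting the rank-based
effect size r = z / sqrt(n). The skipped Spearman correlation removes
bivariate outliers (projection distances from a median center exceeding a
MAD-based cutoff) before correlating, with a percentile-bootstrap confidence
interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .task import Session

__all__ = ["prob_hr", "wilcoxon_signed_rank", "WilcoxonResult",
           "liking_change", "skipped_spearman", "SkippedCorrResult"]


def prob_hr(session: Session) -> float:
    """Probability of choosing the HR person across valid trials."""
    valid = session.valid_trials
    if not valid:
        raise ValueError("session has no valid trials")
    return float(np.mean([tr.chose_hr for tr in valid]))


@dataclass(frozen=True)
class WilcoxonResult:
    W: float
    z: float
    p: float
    r_effect: float
    n: int

    def summary(self) -> str:
        return (f"Wilcoxon signed-rank (one-tailed): W = {self.W:.0f}, "
                f"z = {self.z:.3f}, p = {self.p:.3g}, r = {self.r_effect:.2f} "
                f"(n = {self.n})")


def wilcoxon_signed_rank(values, mu: float = 0.0,
                         alternative: str = "greater") -> WilcoxonResult:
    """One-sample Wilcoxon signed-rank test by normal approximation.

    Differences equal to ``mu`` are dropped; W sums the ranks (of absolute
    differences, average ranks on ties) of the positive differences. The z
    statistic applies a 0.5 continuity correction and the standard tie
    correction to the variance; r = z / sqrt(n) with n the retained sample
    size.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    d = np.asarray(values, dtype=float) - mu
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all values equal mu; test undefined")
    if n < 6:
        raise ValueError("need at least 6 non-zero differences")
    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    W = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    _, counts = np.unique(absd, return_counts=True)
    tie_term = float(((counts**3 - counts) / 48.0).sum())
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var_w <= 0:
        raise ValueError("degenerate variance (all values tied)")
    if alternative == "greater":
        z = (W - mean_w - 0.5) / np.sqrt(var_w)
        p = float(stats.norm.sf(z))
    else:
        z = (W - mean_w + 0.5) / np.sqrt(var_w)
        p = float(stats.norm.cdf(z))
    return WilcoxonResult(W=W, z=float(z), p=p,
                          r_effect=float(z / np.sqrt(n)), n=n)


def liking_change(persons: pd.DataFrame) -> pd.DataFrame:
    """Baseline-corrected liking change per subject.

    ``persons`` is a long table with columns subject_id, condition,
    liking_pre, liking_post (two persons per condition). Per condition the
    change is mean(post - pre); the HR and LR changes are corrected by
    subtracting the baseline change, and the HR-vs-LR contrast is
    delta_HR - delta_LR.
    """
    required = {"subject_id", "condition", "liking_pre", "liking_post"}
    missing = required - set(persons.columns)
    if missing:
        raise ValueError(f"persons table missing columns: {sorted(missing)}")
    persons = persons.assign(change=persons["liking_post"] - persons["liking_pre"])
    wide = (persons.groupby(["subject_id", "condition"])["change"].mean()
            .unstack("condition"))
    for cond in ("HR", "LR", "BASELINE"):
        if cond not in wide.columns or wide[cond].isna().any():
            raise ValueError(f"missing {cond} persons for some subject")
    out = pd.DataFrame({
        "delta_hr": wide["HR"],
        "delta_lr": wide["LR"],
        "delta_baseline": wide["BASELINE"],
        "hr_corrected": wide["HR"] - wide["BASELINE"],
        "lr_corrected": wide["LR"] - wide["BASELINE"],
        "hr_vs_lr": wide["HR"] - wide["LR"],
    })
    return out.reset_index()


@dataclass(frozen=True)
class SkippedCorrResult:
    r_s: float
    ci: tuple[float, float]
    outlier_flags: np.ndarray
    n_retained: int

    def summary(self) -> str:
        lo, hi = self.ci
        return (f"Skipped Spearman: r_s = {self.r_s:.2f}, "
                f"95% CI = [{lo:.2f}, {hi:.2f}] "
                f"({int(self.outlier_flags.sum())} outliers removed, "
                f"n = {self.n_retained})")


def _projection_outliers(xy: np.ndarray, cutoff: float) -> np.ndarray:
    """Bivariate outliers by the projection method: a point is flagged when,
    on some projection through the coordinatewise-median center, its
    MAD-standardized distance from the projected median exceeds ``cutoff``."""
    center = np.median(xy, axis=0)
    centered = xy - center
    flags = np.zeros(len(xy), dtype=bool)
    for d in centered:
        norm = np.hypot(*d)
        if norm == 0:
            continue
        proj = centered @ (d / norm)
        med = np.median(proj)
        mad = np.median(np.abs(proj - med)) * 1.4826
        if mad == 0:
            continue
        flags |= np.abs(proj - med) / mad > cutoff
    return flags


def skipped_spearman(x, y, n_boot: int = 1000, seed: int = 0,
                     cutoff: float | None = None,
                     outlier_fn=None) -> SkippedCorrResult:
    """Robust Spearman correlation after removal of bivariate outliers.

    ``outlier_fn(xy) -> bool array`` can replace the default projection/MAD
    rule (default cutoff: sqrt of the chi-square 97.5th percentile with 2
    degrees of freedom). The CI is a seeded percentile bootstrap of the
    Spearman correlation over the retained pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 10:
        raise ValueError("need at least 10 paired observations")
    xy = np.column_stack([x, y])
    if outlier_fn is None:
        if cutoff is None:
            cutoff = float(np.sqrt(stats.chi2.ppf(0.975, df=2)))
        flags = _projection_outliers(xy, cutoff)
    else:
        flags = np.asarray(outlier_fn(xy), dtype=bool)
    keep = ~flags
    if keep.sum() < 3:
        raise ValueError("fewer than 3 pairs retained after outlier removal")
    xr, yr = x[keep], y[keep]
    r_s = float(stats.spearmanr(xr, yr).statistic)
    rng = np.random.default_rng(seed)
    n = xr.size
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b] = stats.spearmanr(xr[idx], yr[idx]).statistic
    boots = boots[np.isfinite(boots)]
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return SkippedCorrResult(r_s=r_s, ci=ci, outlier_flags=flags,
                             n_retained=int(keep.sum()))
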