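"""Fixed- and random-effects model selection across subjects.

``delta_bic`` and ``count_favoring`` summarize per-subject BIC tables.
``bms`` implements random-effects (group-level) Bayesian model selection: it
treats the model identity of each subject as drawn from a population
distribution with a Dirichlet prior and estimates, by variational Bayes, the
expected frequency of each model and its exceedance probability — the
posterior probability that the model is the most frequent one in the
population. Per-subject log model evidence is approximated as -BIC/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, logsumexp

from .task import MODEL_ORDER

__all__ = ["delta_bic", "count_favoring", "bms", "BMSResult",
           "log_evidence_from_bic"]


def _pivot_bic(fit_table: pd.DataFrame) -> pd.DataFrame:
    wide = fit_table.pivot(index="subject_id", columns="model", values="bic")
    cols = [m for m in MODEL_ORDER if m in wide.columns]
    cols += [m for m in wide.columns if m not in cols]
    return wide[cols]


def delta_bic(fit_table: pd.DataFrame, reference_model: str = "RW") -> pd.DataFrame:
    """Per-subject BIC difference BIC_reference - BIC_model.

    Positive values favor the model over the reference; the reference column
    is identically zero.
    """
    wide = _pivot_bic(fit_table)
    if reference_model not in wide.columns:
        raise KeyError(f"reference model {reference_model!r} not in table")
    if wide.isna().any().any():
        raise ValueError("missing subject x model rows in fit table")
    return wide.sub(wide[reference_model], axis=0).mul(-1).add(0.0)


def count_favoring(fit_table: pd.DataFrame) -> pd.Series:
    """Number of subjects whose minimal BIC selects each model.

    Ties are broken in favor of the model earliest in canonical order, so
    counts always sum to the number of subjects.
    """
    wide = _pivot_bic(fit_table)
    if wide.isna().any().any():
        raise ValueError("missing subject x model rows in fit table")
    winners = wide.idxmin(axis=1)  # idxmin takes the first column on ties
    return winners.value_counts().reindex(wide.columns, fill_value=0)


def log_evidence_from_bic(fit_table: pd.DataFrame) -> pd.DataFrame:
    """Subject x model log-evidence surrogate -BIC/2."""
    return _pivot_bic(fit_table) * -0.5


@dataclass(frozen=True)
class BMSResult:
    """Random-effects model-selection estimates."""

    model_names: tuple[str, ...]
    dirichlet_alpha: np.ndarray
    expected_frequency: np.ndarray
    exceedance_prob: np.ndarray
    n_samples: int
    seed: int

    def summary(self) -> str:
        lines = ["Random-effects Bayesian model selection",
                 f"{'model':>8s} {'alpha':>8s} {'freq':>8s} {'xp':>8s}"]
        for m, a, f, x in zip(self.model_names, self.dirichlet_alpha,
                              self.expected_frequency, self.exceedance_prob):
            lines.append(f"{m:>8s} {a:8.3f} {f:8.3f} {x:8.3f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": self.model_names,
            "dirichlet_alpha": self.dirichlet_alpha,
            "expected_frequency": self.expected_frequency,
            "exceedance_prob": self.exceedance_prob,
        })


def bms(log_evidence, prior_alpha: float = 1.0, n_samples: int = 1_000_000,
        seed: int = 0, tol: float = 1e-6, max_iter: int = 10_000) -> BMSResult:
    """Variational random-effects Bayesian model selection.

    Iterates between subject-wise model responsibilities (softmax of log
    evidence plus the Dirichlet digamma terms) and Dirichlet counts until the
    parameters change by less than ``tol``. Exceedance probabilities are the
    Monte-Carlo frequencies with which each model has the largest sampled
    Dirichlet frequency.

    ``log_evidence`` is a subject x model array or DataFrame; see
    :func:`log_evidence_from_bic`.
    """
    if isinstance(log_evidence, pd.DataFrame):
        model_names = tuple(str(c) for c in log_evidence.columns)
        lme = log_evidence.to_numpy(dtype=float)
    else:
        lme = np.asarray(log_evidence, dtype=float)
        model_names = tuple(f"m{i + 1}" for i in range(lme.shape[1]))
    if lme.ndim != 2:
        raise ValueError("log_evidence must be 2-D (subjects x models)")
    if not np.all(np.isfinite(lme)):
        raise ValueError("log evidences must be finite")

    n_subj, n_models = lme.shape
    alpha = np.full(n_models, float(prior_alpha))
    for _ in range(max_iter):
        # responsibilities: r_nk ∝ exp(lme_nk + ψ(α_k) − ψ(Σα))
        log_u = lme + digamma(alpha) - digamma(alpha.sum())
        r = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        new_alpha = prior_alpha + r.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha

    expected_frequency = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    wins = np.bincount(np.argmax(draws, axis=1), minlength=n_models)
    exceedance = wins / n_samples
    return BMSResult(model_names=model_names, dirichlet_alpha=alpha,
                     expected_frequency=expected_frequency,
                     exceedance_prob=exceedance, n_samples=n_samples, seed=seed)
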