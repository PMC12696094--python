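"""Trial-wise model regressors for fMRI parametric-modulation designs.

From a session and Rescorla-Wagner parameters, produce the forward-pass
latents (chosen-person value Q, prediction error delta, choice probability)
and export a BIDS-events-style table: the 8 s imagination period modulated by
the trial's prediction error, the choice onset (stick function) modulated by
the chosen person's value, rating onsets, and missed-trial onsets. Modulators
are mean-centered within event type. Group analyses use the population median
of the fitted alpha and beta, which is less noisy than per-subject estimates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import LatentTrajectory, RescorlaWagner
from .task import Session

__all__ = ["latent_trajectories", "population_median_params", "export_events"]

SIM_DURATION = 8.0


def latent_trajectories(session: Session, alpha: float, beta: float) -> pd.DataFrame:
    """Forward pass of the Rescorla-Wagner model over a session.

    One row per valid trial: t, Q_chosen (pre-update value of the chosen
    person), delta (prediction error), p_choice (probability the model gave
    the made choice). Missed trials yield no rows and no updates.
    """
    traj: LatentTrajectory = RescorlaWagner(session).forward(
        {"alpha": alpha, "beta": beta})
    return pd.DataFrame({
        "t": traj.t,
        "Q_chosen": traj.Q_chosen,
        "delta": traj.delta,
        "p_choice": traj.p_choice,
    })


def population_median_params(fit_table: pd.DataFrame, model_name: str = "RW"
                             ) -> dict[str, float]:
    """Per-parameter median across subjects for one model.

    Even subject counts take the midpoint of the central pair (the ordinary
    median convention).
    """
    sub = fit_table[fit_table["model"] == model_name]
    if sub.empty:
        raise ValueError(f"no fitted subjects for model {model_name!r}")
    from .models import MODEL_CLASSES
    names = MODEL_CLASSES[model_name].param_names
    return {name: float(sub[name].median()) for name in names}


def export_events(session: Session, trajectories: pd.DataFrame) -> pd.DataFrame:
    """BIDS-style events table with mean-centered modulators.

    Rows per valid trial: ``simulation`` (onset, duration 8 s, modulator =
    prediction error), ``choice`` (stick, modulator = Q of the chosen
    person), ``rating`` (stick). Missed trials appear only as ``missed``
    stick events. Onsets are seconds from run start.
    """
    by_t = trajectories.set_index("t")
    valid_t = {tr.t for tr in session.valid_trials}
    if not valid_t <= set(by_t.index):
        raise ValueError("trajectories missing rows for some valid trials")
    delta_c = by_t["delta"] - by_t["delta"].mean()
    q_c = by_t["Q_chosen"] - by_t["Q_chosen"].mean()
    rows = []
    for tr in session.trials:
        if tr.missed:
            rows.append({"onset": tr.choice_onset, "duration": 0.0,
                         "trial_type": "missed", "modulator": np.nan})
            continue
        rows.append({"onset": tr.sim_onset, "duration": SIM_DURATION,
                     "trial_type": "simulation",
                     "modulator": float(delta_c.loc[tr.t])})
        rows.append({"onset": tr.choice_onset, "duration": 0.0,
                     "trial_type": "choice", "modulator": float(q_c.loc[tr.t])})
        rows.append({"onset": tr.rating_onset, "duration": 0.0,
                     "trial_type": "rating", "modulator": np.nan})
    events = pd.DataFrame(rows, columns=["onset", "duration", "trial_type",
                                         "modulator"])
    return events.sort_values(["onset", "trial_type"]).reset_index(drop=True)
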