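"""Candidate choice models for the imagined-reward bandit task.

Five models compete to explain trial-wise choices between a high-reward (HR)
and a low-reward (LR) person:

``RW``
    Rescorla-Wagner value learning. The value Q of the chosen person is
    updated by the prediction error delta = r - Q scaled by the learning rate
    alpha; values map to choice probabilities through a softmax with inverse
    temperature beta. Free parameters: alpha, beta.
``CK``
    A choice kernel capturing perseveration: a running average of past
    choices, updated like a value but toward "was chosen" rather than reward,
    entering its own softmax. Free parameters: alpha_c, beta_c.
``RWCK``
    Value learning plus choice kernel; a single softmax over the combined
    logit beta*Q + beta_c*CK. Free parameters: alpha, beta, alpha_c, beta_c.
``WSLS``
    Noisy win-stay-lose-shift: repeat a rewarded choice, leave an unrewarded
    one, each applied with probability 1 - epsilon/2. Free parameter: epsilon.
``NULL``
    No learning; a constant bias b toward the HR option. Free parameter: b.

Each model class follows the Model/Results convention: build from a
:class:`~simbandit.task.Session`, call ``loglike``/``negloglik`` at a
parameter vector, or ``fit()`` for maximum-likelihood estimates.

Parameter counts (degrees of freedom in the BIC) are RW=2, CK=2, RWCK=4,
WSLS=1, NULL=1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task import MODEL_ORDER, Session, TrialRecord

#: probabilities are floored here before taking logs
P_FLOOR = 1e-12

_WIN, _LOSE, _NONE = "win", "lose", "none"


class InvalidParameterError(ValueError):
    """A model parameter is outside its admissible range."""


# ---------------------------------------------------------------------------
# Elementary update and choice rules


def rw_update(q_chosen: float, reward: float, alpha: float) -> tuple[float, float]:
    """Rescorla-Wagner update of the chosen option's value.

    Returns ``(q_new, delta)`` where ``delta = reward - q_chosen`` is the
    prediction error and ``q_new = q_chosen + alpha * delta``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise InvalidParameterError(f"alpha={alpha} outside [0, 1]")
    delta = reward - q_chosen
    return q_chosen + alpha * delta, delta


def softmax_pair(q_pair: tuple[float, float], beta: float) -> tuple[float, float]:
    """Two-option softmax, computed with max subtraction for stability."""
    if not np.isfinite(beta) or beta < 0:
        raise InvalidParameterError(f"beta={beta} must be finite and >= 0")
    logits = beta * np.asarray(q_pair, dtype=float)
    logits -= logits.max()
    e = np.exp(logits)
    p = e / e.sum()
    return float(p[0]), float(p[1])


def ck_update(ck_all: dict[str, float], chosen: str, alpha_c: float) -> dict[str, float]:
    """Update the choice kernel: chosen decays toward 1, all others toward 0."""
    if not 0.0 <= alpha_c <= 1.0:
        raise InvalidParameterError(f"alpha_c={alpha_c} outside [0, 1]")
    if chosen not in ck_all:
        raise KeyError(f"unknown person {chosen!r}")
    return {
        pid: ck + alpha_c * ((1.0 if pid == chosen else 0.0) - ck)
        for pid, ck in ck_all.items()
    }


def wsls_prob(prev_outcome: str, candidate_is_prev_choice: bool, epsilon: float) -> float:
    """Noisy win-stay-lose-shift probability for one candidate.

    Stay after a win and shift after a loss, each with probability
    ``1 - epsilon/2``. With no usable previous outcome both candidates get 0.5.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise InvalidParameterError(f"epsilon={epsilon} outside [0, 1]")
    if prev_outcome == _NONE:
        return 0.5
    if prev_outcome == _WIN:
        p_prev = 1.0 - epsilon / 2.0
    elif prev_outcome == _LOSE:
        p_prev = epsilon / 2.0
    else:
        raise ValueError(f"prev_outcome must be win/lose/none, got {prev_outcome!r}")
    return p_prev if candidate_is_prev_choice else 1.0 - p_prev


def null_prob(candidate_is_hr: bool, b: float) -> float:
    """History-independent bias: b for the HR option, 1 - b for the LR option."""
    if not 0.0 <= b <= 1.0:
        raise InvalidParameterError(f"b={b} outside [0, 1]")
    return b if candidate_is_hr else 1.0 - b


# ---------------------------------------------------------------------------
# Forward pass machinery


@dataclass
class AgentState:
    """Evolving latent state of an agent over a session.

    Q values start at 0.5 (persons are approximately neutral before the
    task); choice kernels start at 0. WSLS memory is reset after a missed
    trial.
    """

    Q: dict[str, float]
    CK: dict[str, float]
    prev_chosen: str | None = None
    prev_outcome: str = _NONE

    @classmethod
    def initial(cls, person_ids: list[str]) -> "AgentState":
        return cls(Q={p: 0.5 for p in person_ids}, CK={p: 0.0 for p in person_ids})


@dataclass
class LatentTrajectory:
    """Per-valid-trial latents from a forward pass: value of the chosen
    person before the update, the prediction error, and the probability the
    model assigned to the made choice."""

    t: list[int] = field(default_factory=list)
    Q_chosen: list[float] = field(default_factory=list)
    delta: list[float] = field(default_factory=list)
    p_choice: list[float] = field(default_factory=list)
    p_hr: list[float] = field(default_factory=list)


class ChoiceModel:
    """Base class: likelihood of a session under one candidate model.

    Subclasses define ``name``, ``param_names``, ``bounds`` and the pair
    choice rule / state update. ``loglike`` runs a single forward pass over
    the session; missed trials contribute no likelihood term and trigger no
    update.
    """

    name: str = ""
    param_names: tuple[str, ...] = ()
    bounds: tuple[tuple[float, float], ...] = ()

    def __init__(self, session: Session):
        if not session.trials:
            raise ValueError("empty session")
        self.session = session
        self.person_ids = session.task_person_ids
        if not self.person_ids:
            raise ValueError("session has no task (HR/LR) persons")

    # -- interface for subclasses -------------------------------------------
    def pair_probs(self, state: AgentState, trial: TrialRecord,
                   params: dict[str, float]) -> tuple[float, float]:
        """(p_hr, p_lr) for the offered pair given the current state."""
        raise NotImplementedError

    def update_state(self, state: AgentState, chosen: str, reward: int,
                     params: dict[str, float]) -> float:
        """Advance the state after a completed trial; returns the prediction
        error (0.0 for models without one)."""
        raise NotImplementedError

    # -- shared machinery ---------------------------------------------------
    @property
    def df(self) -> int:
        return len(self.param_names)

    def params_to_dict(self, params) -> dict[str, float]:
        if isinstance(params, dict):
            missing = set(self.param_names) - set(params)
            if missing:
                raise InvalidParameterError(f"missing parameters: {sorted(missing)}")
            return {k: float(params[k]) for k in self.param_names}
        vec = np.asarray(params, dtype=float).ravel()
        if vec.size != len(self.param_names):
            raise InvalidParameterError(
                f"{self.name} expects {len(self.param_names)} parameters, got {vec.size}")
        return dict(zip(self.param_names, vec))

    def _validate(self, params: dict[str, float]) -> None:
        for name, (lo, hi) in zip(self.param_names, self.bounds):
            v = params[name]
            if not np.isfinite(v) or v < lo or v > hi:
                raise InvalidParameterError(f"{self.name}: {name}={v} outside [{lo}, {hi}]")

    def forward(self, params) -> LatentTrajectory:
        """Forward pass collecting per-trial latents for all valid trials."""
        p = self.params_to_dict(params)
        self._validate(p)
        state = AgentState.initial(self.person_ids)
        traj = LatentTrajectory()
        for trial in self.session.trials:
            if trial.missed:
                state.prev_chosen = None
                state.prev_outcome = _NONE
                continue
            p_hr, p_lr = self.pair_probs(state, trial, p)
            p_made = p_hr if trial.chose_hr else p_lr
            traj.t.append(trial.t)
            traj.Q_chosen.append(state.Q[trial.chosen])
            traj.p_choice.append(p_made)
            traj.p_hr.append(p_hr)
            delta = self.update_state(state, trial.chosen, trial.reward, p)
            traj.delta.append(delta)
        return traj

    def loglike(self, params) -> float:
        traj = self.forward(params)
        p = np.maximum(np.asarray(traj.p_choice), P_FLOOR)
        return float(np.log(p).sum())

    def negloglik(self, params) -> float:
        return -self.loglike(params)

    def fit(self, n_starts: int = 10, seed: int = 0):
        """Maximum-likelihood fit; see :func:`simbandit.fitting.fit_subject`."""
        from .fitting import fit_subject
        return fit_subject(self.name, self.session, n_starts=n_starts, seed=seed)

    @property
    def n_valid(self) -> int:
        return len(self.session.valid_trials)


class RescorlaWagner(ChoiceModel):
    """Error-driven value learning with a softmax choice rule."""

    name = "RW"
    param_names = ("alpha", "beta")
    bounds = ((0.0, 1.0), (0.0, 20.0))

    def pair_probs(self, state, trial, params):
        return softmax_pair(
            (state.Q[trial.hr_person], state.Q[trial.lr_person]), params["beta"])

    def update_state(self, state, chosen, reward, params):
        state.Q[chosen], delta = rw_update(state.Q[chosen], reward, params["alpha"])
        return delta


class ChoiceKernelModel(ChoiceModel):
    """Perseveration only: softmax over the choice kernel."""

    name = "CK"
    param_names = ("alpha_c", "beta_c")
    bounds = ((0.0, 1.0), (0.0, 20.0))

    def pair_probs(self, state, trial, params):
        return softmax_pair(
            (state.CK[trial.hr_person], state.CK[trial.lr_person]), params["beta_c"])

    def update_state(self, state, chosen, reward, params):
        state.CK = ck_update(state.CK, chosen, params["alpha_c"])
        return 0.0


class RWChoiceKernel(ChoiceModel):
    """Value learning plus choice kernel in one softmax over
    beta*Q + beta_c*CK."""

    name = "RWCK"
    param_names = ("alpha", "beta", "alpha_c", "beta_c")
    bounds = ((0.0, 1.0), (0.0, 20.0), (0.0, 1.0), (0.0, 20.0))

    def pair_probs(self, state, trial, params):
        logit = lambda pid: (params["beta"] * state.Q[pid]
                             + params["beta_c"] * state.CK[pid])
        return softmax_pair((logit(trial.hr_person), logit(trial.lr_person)), 1.0)

    def update_state(self, state, chosen, reward, params):
        state.Q[chosen], delta = rw_update(state.Q[chosen], reward, params["alpha"])
        state.CK = ck_update(state.CK, chosen, params["alpha_c"])
        return delta


class WinStayLoseShift(ChoiceModel):
    """Noisy win-stay-lose-shift on person identity.

    If the previously chosen person is not offered again (pairings vary
    trial to trial), no stay/shift information applies and both candidates
    get 0.5.
    """

    name = "WSLS"
    param_names = ("epsilon",)
    bounds = ((0.0, 1.0),)

    def pair_probs(self, state, trial, params):
        eps = params["epsilon"]
        offered = (trial.hr_person, trial.lr_person)
        if state.prev_outcome == _NONE or state.prev_chosen not in offered:
            return 0.5, 0.5
        p_hr = wsls_prob(state.prev_outcome, trial.hr_person == state.prev_chosen, eps)
        return p_hr, 1.0 - p_hr

    def update_state(self, state, chosen, reward, params):
        state.prev_chosen = chosen
        state.prev_outcome = _WIN if reward == 1 else _LOSE
        return 0.0


class NullBias(ChoiceModel):
    """No learning: constant bias toward the HR option."""

    name = "NULL"
    param_names = ("b",)
    bounds = ((0.0, 1.0),)

    def pair_probs(self, state, trial, params):
        p_hr = null_prob(True, params["b"])
        return p_hr, 1.0 - p_hr

    def update_state(self, state, chosen, reward, params):
        return 0.0


MODEL_CLASSES: dict[str, type[ChoiceModel]] = {
    cls.name: cls
    for cls in (RescorlaWagner, ChoiceKernelModel, RWChoiceKernel,
                WinStayLoseShift, NullBias)
}
assert tuple(MODEL_CLASSES) == MODEL_ORDER


def get_model(name: str, session: Session) -> ChoiceModel:
    try:
        return MODEL_CLASSES[name](session)
    except KeyError:
        raise KeyError(f"unknown model {name!r}; choose from {MODEL_ORDER}") from None


def session_negloglik(model_name: str, params, session: Session
                      ) -> tuple[float, LatentTrajectory]:
    """Negative log-likelihood of a session under one model.

    Convenience wrapper returning ``(negll, latents)`` in one forward pass.
    """
    model = get_model(model_name, session)
    traj = model.forward(params)
    p = np.maximum(np.asarray(traj.p_choice), P_FLOOR)
    return float(-np.log(p).sum()), traj
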