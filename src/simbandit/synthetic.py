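"""Synthetic cohorts for the imagined-reward bandit task.

Generates (i) sessions in which a simulated agent — any of the five candidate
models — performs the two-armed choice task, (ii) pre/post liking ratings with
a planted across-subject correlation between acquired preference and the
liking update of the high-reward persons, and (iii) person x run activity
patterns with person-consistent structure for the representational similarity
analysis. All output is fully determined by the spec and its seed.

Scenario valences follow the task design: when an HR person is chosen the
imagined scenario is pleasant with probability 0.8, for LR persons with
probability 0.3. Continuous pleasantness ratings are drawn from
valence-conditional truncated normals on [-1, 1] (pleasant: mean +0.5, sd
0.25; neutral-to-unpleasant: mean -0.25, sd 0.25), so that binarizing at the
neutral midpoint recovers the drawn valence for virtually every trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .models import MODEL_CLASSES, AgentState
from .task import (MISSED, Condition, DesignSpec, Person, Session,
                   TrialRecord, Valence)

__all__ = [
    "CohortSpec", "PatternSpec", "PleasantnessSpec",
    "generate_session", "generate_cohort", "generate_patterns",
    "default_param_dists",
]

#: default per-person ids in the 2 HR + 2 LR + 2 baseline design
HR_IDS = ("hr1", "hr2")
LR_IDS = ("lr1", "lr2")
BASELINE_IDS = ("base1", "base2")

# trial timing (seconds): choice window, chosen-name display, fixation,
# simulation (imagination) period, rating window, ITI jitter range
CHOICE_MAX = 3.0
NAME_DUR = 2.5
FIX_DUR = 2.5
SIM_DUR = 8.0
RATING_MAX = 5.0
ITI_RANGE = (2.0, 5.0)


@dataclass(frozen=True)
class PleasantnessSpec:
    """Valence-conditional rating distributions (truncated normal on [-1, 1])."""

    pleasant_mean: float = 0.5
    pleasant_sd: float = 0.25
    unpleasant_mean: float = -0.25
    unpleasant_sd: float = 0.25

    def draw_batch(self, rng: np.random.Generator, pleasant: bool,
                   size: int) -> np.ndarray:
        mu = self.pleasant_mean if pleasant else self.unpleasant_mean
        sd = self.pleasant_sd if pleasant else self.unpleasant_sd
        a, b = (-1.0 - mu) / sd, (1.0 - mu) / sd
        return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size,
                                   random_state=rng)

    def draw(self, rng: np.random.Generator, pleasant: bool) -> float:
        return float(self.draw_batch(rng, pleasant, 1)[0])


def default_param_dists(model_name: str) -> dict[str, tuple[float, float]]:
    """Uniform sampling ranges for agent parameters, kept 10% inside the
    fitting bounds so simulated cohorts stay away from the boundary."""
    ranges = {
        "RW": {"alpha": (0.1, 0.9), "beta": (1.0, 10.0)},
        "CK": {"alpha_c": (0.1, 0.9), "beta_c": (1.0, 10.0)},
        "RWCK": {"alpha": (0.1, 0.9), "beta": (1.0, 10.0),
                 "alpha_c": (0.1, 0.9), "beta_c": (1.0, 10.0)},
        "WSLS": {"epsilon": (0.1, 0.9)},
        "NULL": {"b": (0.2, 0.8)},
    }
    return ranges[model_name]


@dataclass(frozen=True)
class CohortSpec:
    """A cohort of simulated subjects sharing one generating model.

    ``liking_effect`` plants the across-subject association between acquired
    preference and liking: the post-task liking of each HR person increases by
    ``liking_effect * (p(HR) - 0.5)`` plus noise, while LR and baseline
    persons change by noise only.
    """

    n_subjects: int = 49
    design: DesignSpec = field(default_factory=DesignSpec)
    agent_model: str = "RW"
    agent_params: dict | None = None  # fixed params; None -> draw per subject
    param_dists: dict | None = None   # uniform (lo, hi) per parameter
    liking_effect: float = 0.6
    liking_noise_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.agent_model not in MODEL_CLASSES:
            raise ValueError(f"unknown agent model {self.agent_model!r}")


@dataclass(frozen=True)
class PatternSpec:
    """Person x run activity patterns: a person-specific component shared
    across runs plus independent voxel noise."""

    n_voxels: int = 100
    n_persons: int = 4
    n_runs: int = 4
    signal_sd: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_voxels < 2:
            raise ValueError("n_voxels must be >= 2")


def _default_persons(rng: np.random.Generator) -> list[Person]:
    persons = []
    for ids, cond in ((HR_IDS, Condition.HR), (LR_IDS, Condition.LR),
                      (BASELINE_IDS, Condition.BASELINE)):
        for pid in ids:
            liking = float(np.clip(rng.normal(0.5, 0.05), 0.0, 1.0))
            fam = float(np.clip(rng.normal(0.6, 0.1), 0.0, 1.0))
            persons.append(Person(pid, cond, liking_pre=liking, liking_post=liking,
                                  familiarity_pre=fam, familiarity_post=fam))
    return persons


def _pairing_schedule(design: DesignSpec, rng: np.random.Generator) -> list[tuple[str, str]]:
    """Balanced HR x LR pairings: each of the 4 pairs equally often per block."""
    per_block = design.n_trials // design.n_blocks
    pairs = [(h, l) for h in HR_IDS for l in LR_IDS]
    if per_block % len(pairs):
        # fall back to uniform random pairing when balance is impossible
        idx = rng.integers(0, len(pairs), size=design.n_trials)
        return [pairs[i] for i in idx]
    schedule = []
    for _ in range(design.n_blocks):
        block = pairs * (per_block // len(pairs))
        rng.shuffle(block)
        schedule.extend(block)
    return schedule


def generate_session(design: DesignSpec, agent_model: str, agent_params: dict,
                     seed: int, subject_id: str = "sim",
                     persons: list[Person] | None = None,
                     pleasantness: PleasantnessSpec | None = None) -> Session:
    """Simulate one session: the agent chooses by its own choice rule and the
    environment supplies valences, ratings, and timing."""
    rng = np.random.default_rng(seed)
    if persons is None:
        persons = _default_persons(rng)
    if pleasantness is None:
        pleasantness = PleasantnessSpec()
    # build on a 0-trial shell to reuse the model's pair_probs/update machinery
    model_cls = MODEL_CLASSES[agent_model]
    shell = Session.__new__(Session)  # bypass validation for the agent shell
    shell.subject_id = subject_id
    shell.persons = persons
    shell.trials = []
    shell.design = design
    agent = model_cls.__new__(model_cls)
    agent.session = shell
    agent.person_ids = [p.person_id for p in persons
                        if p.condition is not Condition.BASELINE]
    params = agent.params_to_dict(agent_params)
    agent._validate(params)

    state = AgentState.initial(agent.person_ids)
    schedule = _pairing_schedule(design, rng)
    # ratings pre-drawn in two batches (one per valence) and consumed in order
    pleasant_pool = iter(pleasantness.draw_batch(rng, True, design.n_trials))
    unpleasant_pool = iter(pleasantness.draw_batch(rng, False, design.n_trials))
    per_block = design.n_trials // design.n_blocks
    trials: list[TrialRecord] = []
    t_clock = 0.0
    for t in range(1, design.n_trials + 1):
        hr_id, lr_id = schedule[t - 1]
        block = (t - 1) // per_block + 1
        side = "left" if rng.random() < 0.5 else "right"
        choice_onset = t_clock
        rt = float(rng.uniform(0.3, CHOICE_MAX))
        sim_onset = choice_onset + CHOICE_MAX + NAME_DUR + FIX_DUR
        rating_onset = sim_onset + SIM_DUR
        iti = float(rng.uniform(*ITI_RANGE))
        t_clock = rating_onset + RATING_MAX + iti

        missed = rng.random() < design.miss_rate
        if missed:
            trials.append(TrialRecord(
                t=t, block=block, hr_person=hr_id, lr_person=lr_id,
                chosen=MISSED, side_of_hr=side, choice_onset=choice_onset,
                sim_onset=sim_onset, rating_onset=rating_onset))
            state.prev_chosen = None
            state.prev_outcome = "none"
            continue

        probe = TrialRecord(t=t, block=block, hr_person=hr_id, lr_person=lr_id,
                            chosen=hr_id)  # pair container for the choice rule
        p_hr, _ = agent.pair_probs(state, probe, params)
        chose_hr = rng.random() < p_hr
        chosen = hr_id if chose_hr else lr_id
        p_pleasant = design.p_pleasant_hr if chose_hr else design.p_pleasant_lr
        pleasant = rng.random() < p_pleasant
        rating = float(next(pleasant_pool) if pleasant else next(unpleasant_pool))
        trial = TrialRecord(
            t=t, block=block, hr_person=hr_id, lr_person=lr_id, chosen=chosen,
            valence=Valence.PLEASANT if pleasant else Valence.NEUTRAL_UNPLEASANT,
            pleasantness=rating, side_of_hr=side, choice_onset=choice_onset,
            sim_onset=sim_onset, rating_onset=rating_onset)
        agent.update_state(state, chosen, trial.reward, params)
        trials.append(trial)

    return Session(subject_id=subject_id, persons=persons, trials=trials,
                   design=design)


def _draw_params(model_name: str, dists: dict, rng: np.random.Generator) -> dict:
    return {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in dists.items()}


def generate_cohort(spec: CohortSpec) -> tuple[list[Session], pd.DataFrame]:
    """Simulate a cohort and plant the liking structure.

    Returns the sessions (post-task liking filled in) and a long persons
    table with one row per subject x person.
    """
    rng = np.random.default_rng(spec.seed)
    dists = spec.param_dists or default_param_dists(spec.agent_model)
    sessions: list[Session] = []
    person_rows = []
    for i in range(spec.n_subjects):
        sid = f"sub{i + 1:03d}"
        params = spec.agent_params or _draw_params(spec.agent_model, dists, rng)
        sess = generate_session(spec.design, spec.agent_model, params,
                                seed=int(rng.integers(0, 2**31 - 1)),
                                subject_id=sid)
        valid = sess.valid_trials
        p_hr = (np.mean([tr.chose_hr for tr in valid]) if valid else 0.5)
        persons = []
        for p in sess.persons:
            noise = float(rng.normal(0.0, spec.liking_noise_sd))
            bump = (spec.liking_effect * (p_hr - 0.5)
                    if p.condition is Condition.HR else 0.0)
            post = float(np.clip(p.liking_pre + bump + noise, 0.0, 1.0))
            persons.append(replace(p, liking_post=post))
        sess.persons = persons
        sessions.append(sess)
        for p in persons:
            person_rows.append({
                "subject_id": sid, "person_id": p.person_id,
                "condition": p.condition.value,
                "liking_pre": p.liking_pre, "liking_post": p.liking_post,
                "familiarity_pre": p.familiarity_pre,
                "familiarity_post": p.familiarity_post,
            })
    return sessions, pd.DataFrame(person_rows)


def generate_patterns(spec: PatternSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Person x run voxel patterns with a person-consistent component.

    Returns ``(patterns, labels)`` where ``patterns`` has shape
    ``(n_persons * n_runs, n_voxels)`` and ``labels`` carries
    (person_id, run, condition) per row. The first half of the persons are HR,
    the second half LR.
    """
    rng = np.random.default_rng(spec.seed)
    person_comp = rng.standard_normal((spec.n_persons, spec.n_voxels))
    rows, labels = [], []
    half = spec.n_persons // 2
    for p in range(spec.n_persons):
        cond = "HR" if p < half else "LR"
        for r in range(spec.n_runs):
            noise = rng.standard_normal(spec.n_voxels)
            rows.append(spec.signal_sd * person_comp[p] + spec.noise_sd * noise)
            labels.append({"person_id": f"p{p + 1}", "run": r + 1,
                           "condition": cond})
    return np.vstack(rows), pd.DataFrame(labels)


def write_patterns(patterns: np.ndarray, labels: pd.DataFrame,
                   matrix_path, labels_path) -> None:
    np.savetxt(matrix_path, patterns, delimiter="\t")
    labels.to_csv(labels_path, sep="\t", index=False)


def read_patterns(matrix_path, labels_path) -> tuple[np.ndarray, pd.DataFrame]:
    return (np.loadtxt(matrix_path, delimiter="\t"),
            pd.read_csv(labels_path, sep="\t"))
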