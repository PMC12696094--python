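import numpy as np
import pytest

from simbandit.task import (Condition, DesignSpec, MISSED, Person, Session,
                            TrialRecord, Valence)

TASK_PERSONS = [
    Person("hr1", Condition.HR), Person("hr2", Condition.HR),
    Person("lr1", Condition.LR), Person("lr2", Condition.LR),
    Person("base1", Condition.BASELINE), Person("base2", Condition.BASELINE),
]


def build_session(chosen, rewards, pairs=None, missed=None,
                  subject_id="s1") -> Session:
    """Hand-build a session: per-trial chosen person and binary reward.

    ``chosen`` entries are person ids (or MISSED); ``rewards`` are 0/1 and
    are encoded as pleasantness +/-0.5. Default pairing is (hr1, lr1) on
    every trial.
    """
    n = len(chosen)
    pairs = pairs or [("hr1", "lr1")] * n
    missed = missed or [c == MISSED for c in chosen]
    trials = []
    t_clock = 0.0
    for i in range(n):
        hr, lr = pairs[i]
        if missed[i]:
            trials.append(TrialRecord(
                t=i + 1, block=1 + i * 1 // max(1, n), hr_person=hr,
                lr_person=lr, chosen=MISSED, choice_onset=t_clock,
                sim_onset=t_clock + 8, rating_onset=t_clock + 16))
        else:
            r = rewards[i]
            trials.append(TrialRecord(
                t=i + 1, block=1, hr_person=hr, lr_person=lr,
                chosen=chosen[i],
                valence=Valence.PLEASANT if r else Valence.NEUTRAL_UNPLEASANT,
                pleasantness=0.5 if r else -0.5,
                choice_onset=t_clock, sim_onset=t_clock + 8,
                rating_onset=t_clock + 16))
        t_clock += 25.0
    design = DesignSpec(n_trials=n, n_blocks=1)
    return Session(subject_id=subject_id, persons=TASK_PERSONS, trials=trials,
                   design=design)


@pytest.fixture(scope="session")
def rw_session():
    """A 96-trial session simulated from an RW agent (alpha=.4, beta=5)."""
    from simbandit.synthetic import generate_session
    return generate_session(DesignSpec(), "RW", {"alpha": 0.4, "beta": 5.0},
                            seed=7)


@pytest.fixture(scope="session")
def full_hr_session():
    """96 complete trials, always choosing HR, alternating reward."""
    chosen = ["hr1"] * 96
    rewards = [i % 2 for i in range(96)]
    return build_session(chosen, rewards)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
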