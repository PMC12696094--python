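"""Domain types for the imagined-reward bandit task.

A session is a sequence of trials in which the subject chooses between one
high-reward (HR) and one low-reward (LR) person, imagines an interaction with
the chosen person in a pleasant or neutral-to-unpleasant scenario, and rates
the pleasantness of the imagined episode. The binarized pleasantness rating is
the reward signal used by the learning models. Two further baseline persons
are rated before and after the task but never appear in trials.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

MISSED = "MISSED"

#: Canonical model order used everywhere (tables, tie-breaks, confusion rows).
MODEL_ORDER = ("RW", "CK", "RWCK", "WSLS", "NULL")


class Condition(str, enum.Enum):
    """Reward condition of a person."""

    HR = "HR"
    LR = "LR"
    BASELINE = "BASELINE"


class Valence(str, enum.Enum):
    PLEASANT = "pleasant"
    NEUTRAL_UNPLEASANT = "neutral_unpleasant"


@dataclass(frozen=True)
class Person:
    """A familiar person with pre/post liking and familiarity ratings in [0, 1]."""

    person_id: str
    condition: Condition
    liking_pre: float = 0.5
    liking_post: float = 0.5
    familiarity_pre: float = 0.5
    familiarity_post: float = 0.5

    def __post_init__(self) -> None:
        for name in ("liking_pre", "liking_post", "familiarity_pre", "familiarity_post"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class TrialRecord:
    """One trial: an HR/LR pairing, the choice made, and the imagined outcome.

    ``pleasantness`` lives on [-1, 1] with 0 the neutral midpoint; the binary
    reward is ``pleasantness > 0``. Missed trials carry no outcome. The
    simulation (imagination) period has a fixed 8 s duration.
    """

    t: int
    block: int
    hr_person: str
    lr_person: str
    chosen: str  # person_id or MISSED
    valence: Valence | None = None
    pleasantness: float | None = None
    side_of_hr: str = "left"
    choice_onset: float = 0.0
    sim_onset: float = 0.0
    rating_onset: float = 0.0

    SIM_DURATION: float = field(default=8.0, init=False, repr=False)

    @property
    def missed(self) -> bool:
        return self.chosen == MISSED

    @property
    def reward(self) -> int | None:
        """Binarized reward: 1 if pleasantness strictly above neutral, else 0."""
        if self.missed or self.pleasantness is None:
            return None
        return int(self.pleasantness > 0.0)

    @property
    def chose_hr(self) -> bool | None:
        if self.missed:
            return None
        return self.chosen == self.hr_person

    def __post_init__(self) -> None:
        if not self.missed and self.chosen not in (self.hr_person, self.lr_person):
            raise ValueError(
                f"trial {self.t}: chosen {self.chosen!r} not in offered pair "
                f"({self.hr_person!r}, {self.lr_person!r})"
            )
        if self.pleasantness is not None and not -1.0 <= self.pleasantness <= 1.0:
            raise ValueError(f"pleasantness {self.pleasantness} outside [-1, 1]")


@dataclass(frozen=True)
class DesignSpec:
    """Task design: trial counts and scenario-valence probabilities.

    Defaults follow the standard design: 96 trials in 4 blocks, pleasant
    scenarios with probability 0.8 for HR and 0.3 for LR persons.
    """

    n_trials: int = 96
    n_blocks: int = 4
    p_pleasant_hr: float = 0.8
    p_pleasant_lr: float = 0.3
    miss_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_pleasant_hr", "p_pleasant_lr", "miss_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_trials % self.n_blocks:
            raise ValueError("n_trials must be divisible by n_blocks")


@dataclass
class Session:
    """One subject's ordered trials plus the persons of the design."""

    subject_id: str
    persons: Sequence[Person]
    trials: Sequence[TrialRecord]
    design: DesignSpec = field(default_factory=DesignSpec)

    def __post_init__(self) -> None:
        if len(self.trials) != self.design.n_trials:
            raise ValueError(
                f"{len(self.trials)} trials but design.n_trials={self.design.n_trials}"
            )
        ts = [tr.t for tr in self.trials]
        if ts != sorted(ts):
            raise ValueError("trials must be sorted by t")

    @property
    def valid_trials(self) -> list[TrialRecord]:
        return [tr for tr in self.trials if not tr.missed]

    @property
    def task_person_ids(self) -> list[str]:
        """Person ids that can appear in trials (HR and LR, not baseline)."""
        return [p.person_id for p in self.persons if p.condition is not Condition.BASELINE]

    def persons_by_condition(self, condition: Condition) -> list[Person]:
        return [p for p in self.persons if p.condition is condition]


# ---------------------------------------------------------------------------
# TSV round-trip

_TRIAL_COLUMNS = [
    "subject_id", "t", "block", "hr_person", "lr_person", "chosen", "missed",
    "valence", "pleasantness", "reward", "side_of_hr",
    "choice_onset", "sim_onset", "rating_onset",
]

_PERSON_COLUMNS = [
    "person_id", "condition", "liking_pre", "liking_post",
    "familiarity_pre", "familiarity_post",
]


def session_to_frame(session: Session) -> pd.DataFrame:
    rows = []
    for tr in session.trials:
        rows.append({
            "subject_id": session.subject_id,
            "t": tr.t,
            "block": tr.block,
            "hr_person": tr.hr_person,
            "lr_person": tr.lr_person,
            "chosen": tr.chosen,
            "missed": int(tr.missed),
            "valence": tr.valence.value if tr.valence is not None else "",
            "pleasantness": tr.pleasantness if tr.pleasantness is not None else "",
            "reward": tr.reward if tr.reward is not None else "",
            "side_of_hr": tr.side_of_hr,
            "choice_onset": tr.choice_onset,
            "sim_onset": tr.sim_onset,
            "rating_onset": tr.rating_onset,
        })
    return pd.DataFrame(rows, columns=_TRIAL_COLUMNS)


def persons_to_frame(persons: Sequence[Person], subject_id: str | None = None) -> pd.DataFrame:
    rows = [{
        "person_id": p.person_id,
        "condition": p.condition.value,
        "liking_pre": p.liking_pre,
        "liking_post": p.liking_post,
        "familiarity_pre": p.familiarity_pre,
        "familiarity_post": p.familiarity_post,
    } for p in persons]
    df = pd.DataFrame(rows, columns=_PERSON_COLUMNS)
    if subject_id is not None:
        df.insert(0, "subject_id", subject_id)
    return df


def write_session(session: Session, trials_path: str | Path,
                  persons_path: str | Path | None = None) -> None:
    session_to_frame(session).to_csv(trials_path, sep="\t", index=False)
    if persons_path is not None:
        persons_to_frame(session.persons).to_csv(persons_path, sep="\t", index=False)


def _frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    trials = []
    for row in df.itertuples(index=False):
        missed = bool(int(row.missed))
        pleas = getattr(row, "pleasantness", "")
        pleas = None if (missed or pd.isna(pleas) or pleas == "") else float(pleas)
        val = getattr(row, "valence", "")
        valence = None if (pd.isna(val) or val == "") else Valence(val)
        trials.append(TrialRecord(
            t=int(row.t), block=int(row.block),
            hr_person=str(row.hr_person), lr_person=str(row.lr_person),
            chosen=MISSED if missed else str(row.chosen),
            valence=valence, pleasantness=pleas,
            side_of_hr=str(row.side_of_hr),
            choice_onset=float(row.choice_onset),
            sim_onset=float(row.sim_onset),
            rating_onset=float(row.rating_onset),
        ))
    return trials


def read_session(trials_path: str | Path, persons_path: str | Path,
                 design: DesignSpec | None = None) -> Session:
    """Read a session from trial and persons TSVs written by :func:`write_session`."""
    tdf = pd.read_csv(trials_path, sep="\t", keep_default_na=False, na_values=[])
    pdf = pd.read_csv(persons_path, sep="\t")
    persons = [Person(
        person_id=str(r.person_id), condition=Condition(r.condition),
        liking_pre=float(r.liking_pre), liking_post=float(r.liking_post),
        familiarity_pre=float(r.familiarity_pre),
        familiarity_post=float(r.familiarity_post),
    ) for r in pdf.itertuples(index=False)]
    trials = _frame_to_trials(tdf)
    if design is None:
        blocks = {tr.block for tr in trials}
        design = DesignSpec(n_trials=len(trials), n_blocks=len(blocks))
    subject_id = str(tdf["subject_id"].iloc[0]) if len(tdf) else "unknown"
    return Session(subject_id=subject_id, persons=persons, trials=trials, design=design)
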