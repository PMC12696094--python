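"""The synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest

from simbandit.behavior import prob_hr
from simbandit.synthetic import (CohortSpec, PatternSpec, generate_cohort,
                                 generate_patterns, generate_session,
                                 read_patterns, write_patterns)
from simbandit.task import DesignSpec, session_to_frame


def test_same_seed_identical_sessions():
    d = DesignSpec()
    a = generate_session(d, "RW", {"alpha": 0.4, "beta": 5.0}, seed=42)
    b = generate_session(d, "RW", {"alpha": 0.4, "beta": 5.0}, seed=42)
    assert session_to_frame(a).equals(session_to_frame(b))


def test_always_hr_agent():
    # NULL agent with b=1 chooses HR deterministically
    s = generate_session(DesignSpec(), "NULL", {"b": 1.0}, seed=0)
    assert prob_hr(s) == 1.0


def _pleasant_fraction(b, n_sessions=110):
    from simbandit.task import Valence
    pleasant = total = 0
    for seed in range(n_sessions):
        s = generate_session(DesignSpec(), "NULL", {"b": b}, seed=seed)
        for tr in s.valid_trials:
            total += 1
            pleasant += tr.valence is Valence.PLEASANT
    return pleasant, total


def test_valence_frequencies_match_design():
    # pool HR-chosen trials across always-HR sessions: pleasant fraction 0.8
    pleasant, total = _pleasant_fraction(b=1.0)
    assert total >= 10_000
    assert pleasant / total == pytest.approx(0.8, abs=0.01)


def test_lr_valence_probability():
    pleasant, total = _pleasant_fraction(b=0.0)
    assert pleasant / total == pytest.approx(0.3, abs=0.01)


def test_miss_rate_marks_missed_trials():
    d = DesignSpec(miss_rate=0.2)
    s = generate_session(d, "RW", {"alpha": 0.4, "beta": 5.0}, seed=5)
    n_missed = sum(tr.missed for tr in s.trials)
    assert 0 < n_missed < 96
    for tr in s.trials:
        if tr.missed:
            assert tr.pleasantness is None and tr.reward is None


def test_balanced_pairing_per_block():
    s = generate_session(DesignSpec(), "RW", {"alpha": 0.4, "beta": 5.0},
                         seed=9)
    for block in (1, 2, 3, 4):
        pairs = [(tr.hr_person, tr.lr_person) for tr in s.trials
                 if tr.block == block]
        counts = pd.Series(pairs).value_counts()
        assert len(counts) == 4 and (counts == 6).all()


def test_rw_agents_learn_preference():
    # learning is possible in this design: mean p(HR) > 0.5 across agents
    spec = CohortSpec(n_subjects=40, seed=3)
    sessions, _ = generate_cohort(spec)
    p = [prob_hr(s) for s in sessions]
    assert np.mean(p) > 0.5


def test_cohort_liking_planting():
    spec = CohortSpec(n_subjects=10, liking_effect=0.0, liking_noise_sd=0.0,
                      seed=0)
    _, persons = generate_cohort(spec)
    assert (persons["liking_post"] == persons["liking_pre"]).all()


def test_cohort_planted_correlation_is_monotone():
    from scipy.stats import spearmanr
    spec = CohortSpec(n_subjects=30, liking_effect=0.8, liking_noise_sd=0.005,
                      seed=1)
    sessions, persons = generate_cohort(spec)
    p_hr = np.array([prob_hr(s) for s in sessions])
    hr_change = (persons[persons["condition"] == "HR"]
                 .groupby("subject_id", sort=True)
                 .apply(lambda g: (g["liking_post"] - g["liking_pre"]).mean(),
                        include_groups=False))
    order = [s.subject_id for s in sessions]
    r = spearmanr(p_hr, hr_change.reindex(order)).statistic
    assert r > 0.9


def test_cohort_size_and_determinism():
    spec = CohortSpec(n_subjects=5, seed=7)
    a_sessions, a_persons = generate_cohort(spec)
    b_sessions, b_persons = generate_cohort(spec)
    assert len(a_sessions) == 5
    assert a_persons.equals(b_persons)
    assert session_to_frame(a_sessions[3]).equals(session_to_frame(b_sessions[3]))


def test_patterns_noise_free_are_person_consistent():
    patterns, labels = generate_patterns(PatternSpec(noise_sd=0.0, seed=0))
    same = labels[labels["person_id"] == "p1"].index
    c = np.corrcoef(patterns[same])
    assert c == pytest.approx(np.ones((4, 4)))


def test_patterns_round_trip(tmp_path):
    patterns, labels = generate_patterns(PatternSpec(n_voxels=20, seed=2))
    write_patterns(patterns, labels, tmp_path / "m.tsv", tmp_path / "l.tsv")
    p2, l2 = read_patterns(tmp_path / "m.tsv", tmp_path / "l.tsv")
    assert np.allclose(p2, patterns)
    assert l2.equals(labels)


def test_pattern_condition_labels():
    _, labels = generate_patterns(PatternSpec(seed=0))
    counts = labels.groupby("condition")["person_id"].nunique()
    assert counts["HR"] == 2 and counts["LR"] == 2
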