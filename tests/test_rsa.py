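"""Hypothesis and data RSMs and their agreement."""

import numpy as np
import pytest

from simbandit.rsa import (build_model_rsm, kendall_tau_a, neural_rsm,
                           rsm_agreement)
from simbandit.synthetic import PatternSpec, generate_patterns


@pytest.fixture(scope="module")
def labels():
    return generate_patterns(PatternSpec(seed=0))[1]


def test_model_rsm_cell_counts(labels):
    rsm = build_model_rsm(labels)
    vals = rsm.included_lower_triangle()
    assert len(vals) == 48
    assert (vals == 1).sum() == 24   # same person, different run
    assert (vals == -1).sum() == 24  # different person, same condition
    # excluded: same-run pairs and cross-condition pairs
    n = 16
    assert rsm.include_mask.sum() // 2 == 48
    assert not np.any(np.diag(rsm.include_mask))


def test_model_rsm_excludes_same_run_and_cross_condition(labels):
    rsm = build_model_rsm(labels)
    rows = list(rsm.labels.itertuples())
    for i in range(16):
        for j in range(16):
            if rsm.include_mask[i, j]:
                assert rows[i].run != rows[j].run
                assert rows[i].condition == rows[j].condition


def test_model_rsm_person_swap_symmetry(labels):
    rsm = build_model_rsm(labels)
    swapped = labels.copy()
    swapped["person_id"] = swapped["person_id"].map(
        {"p1": "p2", "p2": "p1", "p3": "p3", "p4": "p4"})
    rsm2 = build_model_rsm(swapped)
    # swapping the two HR persons' labels permutes rows identically: here the
    # matrix itself is unchanged because both persons share the condition
    assert np.array_equal(rsm.values, rsm2.values)
    assert np.array_equal(rsm.include_mask, rsm2.include_mask)


def test_model_rsm_rejects_bad_design(labels):
    bad = labels.copy()
    bad.loc[0, "condition"] = "LR"  # 1 HR person, 3 LR persons
    with pytest.raises(ValueError):
        build_model_rsm(bad)


def test_neural_rsm_self_and_negation(labels):
    rng = np.random.default_rng(0)
    patterns = rng.standard_normal((16, 50))
    rsm = neural_rsm(patterns, labels)
    assert np.allclose(np.diag(rsm.values), 1.0)
    from scipy.stats import kendalltau
    assert kendalltau(patterns[0], -patterns[0]).statistic == pytest.approx(-1)


def test_neural_rsm_rejects_constant_pattern(labels):
    patterns = np.ones((16, 10))
    with pytest.raises(ValueError):
        neural_rsm(patterns, labels)


def test_independent_patterns_near_zero_tau():
    rng = np.random.default_rng(1)
    from scipy.stats import kendalltau
    tau = kendalltau(rng.standard_normal(1000),
                     rng.standard_normal(1000)).statistic
    assert abs(tau) < 0.1


def test_kendall_tau_a_values():
    assert kendall_tau_a([1, 2, 3], [1, 2, 3]) == 1.0
    assert kendall_tau_a([1, 2, 3], [3, 2, 1]) == -1.0
    # the tied pair counts zero in the numerator but stays in the
    # denominator: 2 concordant of 3 pairs
    assert kendall_tau_a([1, 1, 2], [1, 2, 3]) == pytest.approx(2 / 3)


def test_agreement_maximal_when_data_equals_model(labels):
    # tau-a keeps tied pairs in the denominator, so a matrix of +/-1 codes
    # agrees with itself at the tie-limited ceiling 24*24 / C(48,2), and any
    # data RSM can only score lower
    model = build_model_rsm(labels)
    ceiling = 24 * 24 / (48 * 47 / 2)
    assert rsm_agreement(model, model) == pytest.approx(ceiling)
    patterns, lab = generate_patterns(PatternSpec(signal_sd=5.0, noise_sd=0.1,
                                                  seed=0))
    assert rsm_agreement(model, neural_rsm(patterns, lab)) <= ceiling + 1e-12


def test_agreement_mask_mismatch_raises(labels):
    model = build_model_rsm(labels)
    other = build_model_rsm(labels)
    other.include_mask = other.include_mask.copy()
    # include a same-run pair (patterns 0 and 4 share run 1) in one mask only
    assert other.labels.loc[0, "run"] == other.labels.loc[4, "run"]
    other.include_mask[0, 4] = other.include_mask[4, 0] = True
    with pytest.raises(ValueError):
        rsm_agreement(model, other)


def test_agreement_monotone_transform_invariance(labels):
    patterns, _ = generate_patterns(PatternSpec(signal_sd=2.0, noise_sd=1.0,
                                                seed=3))
    model = build_model_rsm(labels)
    data = neural_rsm(patterns, labels)
    tau1 = rsm_agreement(model, data)
    import copy
    data2 = copy.deepcopy(data)
    data2.values = np.tanh(3 * data2.values)  # strictly monotone transform
    assert rsm_agreement(model, data2) == pytest.approx(tau1)


def test_planted_signal_yields_positive_agreement(labels):
    model = build_model_rsm(labels)
    taus = []
    for seed in range(10):
        patterns, lab = generate_patterns(
            PatternSpec(signal_sd=2.0, noise_sd=1.0, seed=seed))
        taus.append(rsm_agreement(model, neural_rsm(patterns, lab)))
    assert np.mean(taus) > 0.2
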