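"""Elementary rules, session likelihoods, and their invariants."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from simbandit.models import (InvalidParameterError, ck_update, get_model,
                              null_prob, rw_update, session_negloglik,
                              softmax_pair, wsls_prob)
from simbandit.task import MODEL_ORDER

from conftest import build_session


@pytest.mark.parametrize("q, r, alpha, q_exp, d_exp", [
    (0.5, 1, 0.5, 0.75, 0.5),
    (0.7, 0, 0.0, 0.7, -0.7),
    (0.5, 0, 1.0, 0.0, -0.5),
])
def test_rw_update_arithmetic(q, r, alpha, q_exp, d_exp):
    q_new, delta = rw_update(q, r, alpha)
    assert q_new == pytest.approx(q_exp)
    assert delta == pytest.approx(d_exp)


def test_rw_update_rejects_bad_alpha():
    with pytest.raises(InvalidParameterError):
        rw_update(0.5, 1, 1.5)


@pytest.mark.parametrize("q_pair, beta, expected", [
    ((0.5, 0.5), 5.0, (0.5, 0.5)),
    ((1.0, 0.0), 0.0, (0.5, 0.5)),
    ((1.0, 0.0), math.log(3), (0.75, 0.25)),
])
def test_softmax_pair_values(q_pair, beta, expected):
    p = softmax_pair(q_pair, beta)
    assert p == pytest.approx(expected)
    assert sum(p) == pytest.approx(1.0)


def test_softmax_rejects_negative_beta():
    with pytest.raises(InvalidParameterError):
        softmax_pair((0.1, 0.2), -1.0)


def test_softmax_stable_at_huge_logits():
    p = softmax_pair((1.0, 0.0), 20.0)
    assert 0 < p[1] < p[0] < 1


@pytest.mark.parametrize("ck, chosen, ac, expected", [
    ({"A": 0.0, "B": 0.0}, "A", 1.0, {"A": 1.0, "B": 0.0}),
    ({"A": 0.5, "B": 0.5}, "A", 0.0, {"A": 0.5, "B": 0.5}),
    ({"A": 0.2, "B": 0.8}, "B", 0.5, {"A": 0.1, "B": 0.9}),
])
def test_ck_update_values(ck, chosen, ac, expected):
    assert ck_update(ck, chosen, ac) == pytest.approx(expected)


def test_ck_update_unknown_person():
    with pytest.raises(KeyError):
        ck_update({"A": 0.0}, "Z", 0.5)


@pytest.mark.parametrize("outcome, is_prev, eps, expected", [
    ("win", True, 0.0, 1.0),
    ("lose", True, 1.0, 0.5),
    ("win", True, 0.2, 0.9),
    ("lose", True, 0.2, 0.1),
    ("none", True, 0.2, 0.5),
])
def test_wsls_prob_values(outcome, is_prev, eps, expected):
    assert wsls_prob(outcome, is_prev, eps) == pytest.approx(expected)


def test_null_prob_is_history_free():
    assert null_prob(True, 0.5) == 0.5
    assert null_prob(False, 0.8) == pytest.approx(0.2)


# ---------------------------------------------------------------------------
# session likelihoods


def test_null_negloglik_closed_form(full_hr_session):
    negll, _ = session_negloglik("NULL", {"b": 0.5}, full_hr_session)
    assert negll == pytest.approx(96 * math.log(2), abs=1e-10)


def test_rw_beta_zero_is_random_choice(full_hr_session):
    for alpha in (0.0, 0.3, 1.0):
        negll, _ = session_negloglik(
            "RW", {"alpha": alpha, "beta": 0.0}, full_hr_session)
        assert negll == pytest.approx(96 * math.log(2), abs=1e-10)


def test_missed_trials_skip_likelihood_and_updates():
    # identical reward history around a missed trial: latents must match a
    # session with the missed trial simply absent
    chosen = ["hr1", "MISSED", "hr1", "lr1"]
    rewards = [1, 0, 1, 0]
    s_miss = build_session(chosen, rewards)
    s_compact = build_session(["hr1", "hr1", "lr1"], [1, 1, 0])
    params = {"alpha": 0.5, "beta": 3.0}
    nll_m, traj_m = session_negloglik("RW", params, s_miss)
    nll_c, traj_c = session_negloglik("RW", params, s_compact)
    assert nll_m == pytest.approx(nll_c)
    assert traj_m.Q_chosen == pytest.approx(traj_c.Q_chosen)


def _enumerate_total_probability(model_name, params, T=4):
    """Brute-force oracle: total probability of all 2^T choice sequences.

    Rewards for either candidate are predetermined per trial, so the product
    of per-trial choice probabilities must sum to 1 over all sequences.
    """
    pairs = [("hr1", "lr1"), ("hr1", "lr2"), ("hr2", "lr1"), ("hr1", "lr1")][:T]
    r_hr = [1, 0, 1, 1][:T]
    r_lr = [0, 1, 0, 0][:T]
    total = 0.0
    for picks in itertools.product([0, 1], repeat=T):
        chosen = [pairs[i][picks[i]] for i in range(T)]
        rewards = [(r_hr[i] if picks[i] == 0 else r_lr[i]) for i in range(T)]
        negll, _ = session_negloglik(
            model_name, params, build_session(chosen, rewards, pairs=pairs))
        total += math.exp(-negll)
    return total


@pytest.mark.parametrize("model_name, params", [
    ("RW", {"alpha": 0.37, "beta": 4.2}),
    ("CK", {"alpha_c": 0.6, "beta_c": 2.5}),
    ("RWCK", {"alpha": 0.3, "beta": 3.0, "alpha_c": 0.5, "beta_c": 1.5}),
    ("WSLS", {"epsilon": 0.3}),
    ("NULL", {"b": 0.71}),
])
def test_likelihood_normalization_oracle(model_name, params):
    assert _enumerate_total_probability(model_name, params) == pytest.approx(
        1.0, abs=1e-10)


@settings(max_examples=30, deadline=None)
@given(st.lists(st.integers(0, 1), min_size=1, max_size=60),
       st.floats(0.0, 1.0))
def test_value_boundedness(rewards, alpha):
    """Q stays in [0,1] for any 0/1 reward sequence and alpha in [0,1]."""
    q = 0.5
    for r in rewards:
        q, _ = rw_update(q, r, alpha)
        assert 0.0 <= q <= 1.0


def test_choice_probability_monotone_in_beta():
    probs = [softmax_pair((0.8, 0.3), b)[0] for b in (0.5, 1, 2, 5, 10, 20)]
    assert all(b > a for a, b in zip(probs, probs[1:]))
    assert probs[-1] > 0.99


def test_rwck_nests_rw_and_ck(rw_session):
    from simbandit.fitting import fit_subject
    nested = fit_subject("RWCK", rw_session, n_starts=10, seed=0).negll
    for parent in ("RW", "CK"):
        assert nested <= fit_subject(parent, rw_session, n_starts=10,
                                     seed=0).negll + 1e-6


def test_unknown_model_name(full_hr_session):
    with pytest.raises(KeyError):
        get_model("Q-LEARN", full_hr_session)


def test_first_trial_value_is_neutral(rw_session):
    _, traj = session_negloglik("RW", {"alpha": 0.4, "beta": 5.0}, rw_session)
    assert traj.Q_chosen[0] == 0.5


@pytest.mark.parametrize("model_name", MODEL_ORDER)
def test_p_choice_is_probability(model_name, rw_session):
    params = {
        "RW": {"alpha": 0.4, "beta": 5.0},
        "CK": {"alpha_c": 0.4, "beta_c": 5.0},
        "RWCK": {"alpha": 0.4, "beta": 5.0, "alpha_c": 0.4, "beta_c": 1.0},
        "WSLS": {"epsilon": 0.3}, "NULL": {"b": 0.6},
    }[model_name]
    _, traj = session_negloglik(model_name, params, rw_session)
    p = np.asarray(traj.p_choice)
    assert np.all((p > 0) & (p < 1))
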