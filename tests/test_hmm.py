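"""HMM segmentation and scoring against brute-force path enumeration."""

import numpy as np
import pytest

from exodel.calls import DEL
from exodel.hmm import (
    STATE_DEL,
    HmmParams,
    _adjacent_distances,
    forward_backward,
    posteriors,
    score_call,
    viterbi_paths,
    viterbi_segment,
)

from ._oracles import (
    brute_posteriors,
    brute_some_probability,
    brute_viterbi_logprob,
    enumerate_path_logprobs,
)
from .conftest import make_targets

PARAMS = HmmParams()


def _viterbi_logprob(z, targets, params):
    """Log-probability of the Viterbi path (recomputed from the path)."""
    from scipy.stats import norm

    states = viterbi_paths(np.asarray(z)[None, :], targets, params)[0]
    means = np.array([0.0, params.del_mean, params.dup_mean])
    dists = _adjacent_distances(targets)
    lp = float(
        np.log(params.initial[states[0]])
        + norm.logpdf(z[0], means[states[0]], params.emission_sd)
    )
    for t in range(1, len(z)):
        lp += float(np.log(params.transition(dists[t - 1])[states[t - 1], states[t]]))
        lp += float(norm.logpdf(z[t], means[states[t]], params.emission_sd))
    return lp


def test_flat_diploid_row_yields_no_calls(targets8):
    assert viterbi_segment(np.zeros(8), targets8, PARAMS) == []


def test_embedded_run_of_low_z_yields_single_del_call():
    targets = make_targets(20)
    z = np.zeros(20)
    z[5:15] = -4.0  # targets 6..15, 1-based
    calls = viterbi_segment(z, targets, PARAMS, sample="S1")
    assert len(calls) == 1
    call = calls[0]
    assert call.type == DEL
    assert call.n_targets == 10
    assert call.start == int(targets["start"].iloc[5])
    assert call.end == int(targets["end"].iloc[14])
    assert call.z_mean == pytest.approx(-4.0)


def test_length_mismatch_raises(targets8):
    with pytest.raises(ValueError, match="targets"):
        viterbi_segment(np.zeros(5), targets8, PARAMS)


@pytest.mark.parametrize("seed", range(30))
def test_viterbi_matches_exhaustive_enumeration(seed):
    """Viterbi log-probability equals the max over all 3^n paths."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 9))
    targets = make_targets(n, spacing=int(rng.integers(300, 50_000)))
    z = rng.normal(rng.choice([-3, 0, 3]), 1.5, size=n)
    dists = _adjacent_distances(targets)
    expected = brute_viterbi_logprob(z, dists, PARAMS)
    assert _viterbi_logprob(z, targets, PARAMS) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("seed", range(20))
def test_posteriors_match_enumeration_and_sum_to_one(seed):
    rng = np.random.default_rng(1000 + seed)
    n = int(rng.integers(2, 8))
    targets = make_targets(n, spacing=int(rng.integers(300, 50_000)))
    z = rng.normal(0, 2.0, size=n)
    post = posteriors(z[None, :], targets, PARAMS)[0]
    np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)
    expected = brute_posteriors(z, _adjacent_distances(targets), PARAMS)
    np.testing.assert_allclose(post, expected, atol=1e-9)


@pytest.mark.parametrize("seed", range(20))
def test_q_some_probability_matches_enumeration(seed):
    """P(>=1 DEL target in a segment) equals summed enumerated path mass."""
    rng = np.random.default_rng(2000 + seed)
    n = int(rng.integers(2, 7))
    targets = make_targets(n, spacing=int(rng.integers(300, 50_000)))
    z = rng.normal(-1.0, 2.0, size=n)
    t0 = int(rng.integers(0, n))
    t1 = int(rng.integers(t0, n))
    expected = brute_some_probability(z, _adjacent_distances(targets), PARAMS, t0, t1, STATE_DEL)
    alpha, beta, log_c = forward_backward(z[None, :], targets, PARAMS)
    from exodel.hmm import _log_emissions, _segment_some_probability, _transition_stack

    log_e = _log_emissions(z[None, :], PARAMS)
    emis = np.exp(log_e - log_e.max(axis=2, keepdims=True))
    got = _segment_some_probability(
        alpha, beta, emis, _transition_stack(targets, PARAMS), log_c, t0, t1, STATE_DEL
    )[0]
    assert got == pytest.approx(expected, abs=1e-9)


def test_extreme_segment_scores_at_cap():
    targets = make_targets(5)
    z = np.full(5, -10.0)
    calls = viterbi_segment(z, targets, PARAMS, sample="S")
    assert len(calls) == 1
    scored = score_call(z, targets, PARAMS, calls[0])
    assert scored.q_some == 99


def test_z_mean_is_arithmetic_mean():
    targets = make_targets(3)
    z = np.array([-3.5, -4.0, -4.5])
    calls = viterbi_segment(z, targets, PARAMS, sample="S")
    scored = score_call(z, targets, PARAMS, calls[0])
    assert scored.z_mean == pytest.approx(-4.0)


def test_q_some_monotone_in_segment_depth_drop():
    """Making z in a called segment more negative never lowers q_some."""
    targets = make_targets(12)
    q_prev = -1
    for depth in (-2.5, -3.0, -3.5, -4.0, -5.0):
        z = np.zeros(12)
        z[3:9] = depth
        calls = viterbi_segment(z, targets, PARAMS, sample="S")
        if not calls:
            continue
        scored = score_call(z, targets, PARAMS, calls[0])
        assert scored.q_some >= q_prev
        q_prev = scored.q_some


def test_scores_remain_finite_on_long_extreme_rows():
    targets = make_targets(400)
    z = np.full(400, -8.0)
    alpha, beta, log_c = forward_backward(z[None, :], targets, PARAMS)
    assert np.isfinite(alpha).all() and np.isfinite(beta).all() and np.isfinite(log_c).all()
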