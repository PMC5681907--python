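"""Event-based model core: likelihood recursion, greedy fit, MCMC, staging."""
import itertools

import numpy as np
import pytest
from scipy import stats

from connebm.ebm import (
    EBMData,
    EventSequence,
    bootstrap_sequences,
    greedy_ascent,
    mcmc_sample,
    positional_variance,
    sequence_loglik,
    stage_subjects,
)
from connebm.errors import NumericalError
from connebm.kde import fit_kde_mixture
from connebm.synthetic import default_truth, generate_ebm_cohort
import oracles


def _random_data(rng, n_subjects=15, n_events=4):
    pe = rng.uniform(0.01, 1.0, (n_subjects, n_events))
    pn = rng.uniform(0.01, 1.0, (n_subjects, n_events))
    return EBMData.from_densities(pe, pn)


def _flat_data(n_subjects=10, n_events=4):
    """Identical columns: every permutation has the same likelihood."""
    pe = np.full((n_subjects, n_events), 0.3)
    pn = np.full((n_subjects, n_events), 0.6)
    return EBMData.from_densities(pe, pn)


def _separated_cohort_data(seed, n_events=10, n_controls=50, n_patients=100,
                           delta=3.0):
    """Planted cohort -> per-event KDE mixtures -> EBM data + truth."""
    truth = default_truth(n_events, post=(delta, 1.0))
    df = generate_ebm_cohort(n_controls, n_patients, truth, seed=seed,
                             include_covariates=False)
    labs = (df["diagnosis"] == "AD").to_numpy()
    pe = np.empty((len(df), n_events))
    pn = np.empty((len(df), n_events))
    for j, e in enumerate(truth.planted_sequence):
        fit = fit_kde_mixture(df[e].to_numpy(float), labs)
        pe[:, j], pn[:, j] = fit.event_component.pdf(df[e]), fit.normal_component.pdf(df[e])
    return EBMData.from_densities(pe, pn, truth.planted_sequence), df


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_events", [2, 3, 4, 5, 6])
def test_loglik_matches_stage_sum_enumeration(n_events, rng):
    for _ in range(20):
        data = _random_data(rng, n_subjects=8, n_events=n_events)
        order = rng.permutation(n_events)
        ref = oracles.ebm_loglik_stage_sum(data.log_p_event, data.log_p_noevent, order)
        assert sequence_loglik(data, order) == pytest.approx(ref, abs=1e-10)


def test_loglik_symmetric_under_identical_columns(rng):
    data = _flat_data()
    lls = {sequence_loglik(data, np.array(p)) for p in itertools.permutations(range(4))}
    assert max(lls) - min(lls) < 1e-12


def test_loglik_pure_noevent_subject_closed_form():
    pe = np.zeros((1, 3))
    pn = np.ones((1, 3))
    data = EBMData.from_densities(pe, pn)
    assert sequence_loglik(data, np.array([0, 1, 2])) == pytest.approx(np.log(1 / 4))


def test_loglik_all_zero_subject_raises():
    data = EBMData.from_densities(np.zeros((1, 3)), np.zeros((1, 3)))
    with pytest.raises(NumericalError):
        sequence_loglik(data, np.array([0, 1, 2]))


# ---------------------------------------------------------------------------
# greedy ascent
# ---------------------------------------------------------------------------

def test_greedy_reaches_exhaustive_optimum(rng):
    for _ in range(5):
        data = _random_data(rng, n_subjects=25, n_events=4)
        ml = greedy_ascent(data, seed=0, n_restarts=10)
        best = max(
            (oracles.ebm_loglik_stage_sum(data.log_p_event, data.log_p_noevent, p)
             for p in itertools.permutations(range(4))),
        )
        assert ml.loglik == pytest.approx(best, abs=1e-9)


def test_greedy_restarts_agree_on_easy_data():
    data, _ = _separated_cohort_data(seed=0, n_events=5, delta=5.0)
    one = greedy_ascent(data, seed=1, n_restarts=1)
    ten = greedy_ascent(data, seed=2, n_restarts=10)
    assert one.loglik == pytest.approx(ten.loglik, abs=1e-8)


def test_greedy_deterministic_under_seed(rng):
    data = _random_data(rng, n_subjects=30, n_events=6)
    a = greedy_ascent(data, seed=5)
    b = greedy_ascent(data, seed=5)
    np.testing.assert_array_equal(a.order, b.order)


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

def test_mcmc_flat_likelihood_is_uniform_over_permutations():
    """With identical columns the stationary law is uniform on S_N."""
    data = _flat_data(n_subjects=5, n_events=4)
    init = EventSequence(order=np.arange(4))
    chain = mcmc_sample(data, init, n_samples=50_000, seed=3)
    pv = positional_variance(chain, EventSequence(order=np.arange(4)))
    assert np.max(np.abs(pv - 0.25)) < 0.05
    # chi-square on thinned draws against uniform over all 24 permutations;
    # the stride is odd because a flat-target transposition chain accepts
    # every proposal and so alternates permutation parity deterministically
    perm_index = {p: i for i, p in enumerate(itertools.permutations(range(4)))}
    thin = chain.sequences[::21]
    counts = np.zeros(24)
    for row in thin:
        counts[perm_index[tuple(row)]] += 1
    assert stats.chisquare(counts).pvalue > 0.01


def test_mcmc_peaked_likelihood_concentrates():
    data, _ = _separated_cohort_data(seed=1, n_events=5, delta=5.0)
    ml = greedy_ascent(data, seed=0)
    chain = mcmc_sample(data, ml, n_samples=20_000, seed=0)
    pv = positional_variance(chain, ml)
    assert np.diag(pv).min() > 0.9


def test_mcmc_deterministic_under_seed(rng):
    data = _random_data(rng)
    init = EventSequence(order=np.arange(4))
    a = mcmc_sample(data, init, n_samples=500, seed=7)
    b = mcmc_sample(data, init, n_samples=500, seed=7)
    np.testing.assert_array_equal(a.sequences, b.sequences)
    np.testing.assert_allclose(a.logliks, b.logliks, atol=1e-9)


def test_mcmc_logliks_consistent_with_direct_evaluation(rng):
    """Incrementally updated chain log-likelihoods match from-scratch evaluation."""
    data = _random_data(rng, n_subjects=12, n_events=5)
    init = greedy_ascent(data, seed=0)
    chain = mcmc_sample(data, init, n_samples=200, seed=2)
    for row, ll in zip(chain.sequences[::37], chain.logliks[::37]):
        assert sequence_loglik(data, np.asarray(row, int)) == pytest.approx(ll, abs=1e-8)


# ---------------------------------------------------------------------------
# positional variance
# ---------------------------------------------------------------------------

def test_positional_variance_identity_and_swap():
    ml = EventSequence(order=np.array([2, 0, 1]))
    pv = positional_variance(np.array([[2, 0, 1], [2, 0, 1]]), ml)
    np.testing.assert_allclose(pv, np.eye(3))
    pv2 = positional_variance(np.array([[2, 0, 1], [0, 2, 1]]), ml)
    np.testing.assert_allclose(pv2[:2, :2], 0.5)
    np.testing.assert_allclose(pv2[2], [0, 0, 1])


def test_positional_variance_doubly_stochastic(rng):
    seqs = np.stack([rng.permutation(6) for _ in range(40)])
    pv = positional_variance(seqs, EventSequence(order=np.arange(6)))
    np.testing.assert_allclose(pv.sum(axis=0), 1.0, atol=1e-12)
    np.testing.assert_allclose(pv.sum(axis=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_dominant_ordering_is_stable():
    data, _ = _separated_cohort_data(seed=2, n_events=4, delta=5.0)
    ml = greedy_ascent(data, seed=0)
    seqs, pv = bootstrap_sequences(data, B=10, seed=0, ml=ml)
    assert len(seqs) == 10
    orders = {tuple(s.order) for s in seqs}
    assert orders == {tuple(ml.order)}
    np.testing.assert_allclose(pv, np.eye(4))


def test_bootstrap_empty_is_allowed(rng):
    data = _random_data(rng)
    seqs, pv = bootstrap_sequences(data, B=0, seed=0)
    assert seqs == [] and pv is None


# ---------------------------------------------------------------------------
# staging
# ---------------------------------------------------------------------------

def test_stage_posterior_hand_computation():
    # N=2 with densities (p_e, p_n) = (0.9, 0.1) and (0.1, 0.9) in order
    pe = np.array([[0.9, 0.1]])
    pn = np.array([[0.1, 0.9]])
    data = EBMData.from_densities(pe, pn)
    post = stage_subjects(data, EventSequence(order=np.array([0, 1])))
    np.testing.assert_allclose(
        post[0], np.array([0.09, 0.81, 0.09]) / 0.99, atol=1e-12
    )


def test_stage_extremes():
    pe = np.array([[0.001] * 4, [0.999] * 4])
    pn = np.array([[0.999] * 4, [0.001] * 4])
    data = EBMData.from_densities(pe, pn)
    post = stage_subjects(data, EventSequence(order=np.arange(4)))
    assert post[0].argmax() == 0 and post[1].argmax() == 4
    np.testing.assert_allclose(post.sum(axis=1), 1.0)


# ---------------------------------------------------------------------------
# recovery of a planted cascade
# ---------------------------------------------------------------------------

def test_planted_sequence_and_stage_recovery():
    """ML ordering and staging recover the planted cascade on a mid-size cohort."""
    data, df = _separated_cohort_data(seed=4, n_events=10, delta=3.0)
    ml = greedy_ascent(data, seed=0)
    positions = np.empty(10)
    positions[ml.order] = np.arange(10)
    tau = stats.kendalltau(positions, np.arange(10)).statistic
    assert tau >= 0.8
    post = stage_subjects(data, ml)
    mean_stage = post @ np.arange(11)
    rho = stats.spearmanr(mean_stage, df["stage"]).statistic
    assert rho >= 0.9
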