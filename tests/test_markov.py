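import numpy as np
import pytest

import sexflux as sf
from tests._oracles import power_iteration_stationary


def test_stationary_uniform_chain():
    P = np.full((3, 3), 1.0 / 3.0)
    assert np.allclose(sf.stationary(P), 1.0 / 3.0, atol=1e-12)


def test_stationary_two_state_closed_form():
    # pi = (b, a) / (a + b) for off-diagonal rates a=0.1, b=0.3
    P = np.array([[0.9, 0.1], [0.3, 0.7]])
    assert np.allclose(sf.stationary(P), [0.75, 0.25], atol=1e-12)


def test_stationary_matches_power_iteration_on_random_chains():
    rng = np.random.default_rng(42)
    for k in (3, 6):
        for _ in range(500):
            P = rng.dirichlet(np.full(k, 0.5), size=k)
            P = 0.99 * P + 0.01 / k  # strictly positive -> irreducible
            pi = sf.stationary(P)
            assert np.abs(pi - power_iteration_stationary(P)).max() < 1e-8
            assert np.abs(pi @ P - pi).max() < 1e-10


def test_stationary_of_field_matrix(pooled_counts):
    P = sf.to_probabilities(pooled_counts)
    pi = sf.stationary(P)
    assert np.abs(pi - [0.5008, 0.2101, 0.2891]).max() < 5e-4
    assert np.abs(pi - power_iteration_stationary(P.probs)).max() < 1e-8


def test_reducible_chain_raises_naming_states():
    P = np.array([[1.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.0, 0.5, 0.5]])
    with pytest.raises(sf.ReducibleChainError, match="M"):
        sf.stationary(sf.TransitionMatrix(("F", "M", "HALL"), P, np.array([1, 1, 1])))


def test_undefined_row_raises():
    P = np.array([[0.5, 0.5], [np.nan, np.nan]])
    with pytest.raises(sf.ReducibleChainError, match="undefined"):
        sf.stationary(sf.TransitionMatrix(("F", "M"), P, np.array([5, 0])))


def test_bootstrap_same_seed_bit_identical(pooled_counts):
    a = sf.bootstrap_matrices(pooled_counts, n_boot=50, seed=9)
    b = sf.bootstrap_matrices(pooled_counts, n_boot=50, seed=9)
    assert np.array_equal(a.matrices, b.matrices)
    c = sf.bootstrap_matrices(pooled_counts, n_boot=50, seed=10)
    assert not np.array_equal(a.matrices, c.matrices)


def test_bootstrap_degenerate_counts_error():
    counts = sf.TransitionCounts(("F", "M"), np.array([[7, 0], [0, 0]]))
    with pytest.raises(ValueError, match="consecutive"):
        sf.bootstrap_matrices(counts, n_boot=1, seed=0)


def test_bootstrap_all_zero_counts_error():
    counts = sf.TransitionCounts(("F", "M"), np.zeros((2, 2), dtype=int))
    with pytest.raises(ValueError, match="zero"):
        sf.bootstrap_matrices(counts, n_boot=1, seed=0)


@pytest.mark.parametrize("scheme", ["pooled", "row-stratified"])
def test_bootstrap_replicates_unbiased(pooled_counts, scheme):
    """Multinomial resampling is unbiased for every transition probability."""
    P0 = sf.to_probabilities(pooled_counts).probs
    reps = sf.bootstrap_matrices(pooled_counts, n_boot=2000, seed=3, scheme=scheme)
    mean = reps.matrices.mean(axis=0)
    mc_se = reps.matrices.std(axis=0) / np.sqrt(len(reps.matrices))
    assert (np.abs(mean - P0) <= 3.0 * mc_se + 1e-12).all()


def test_steady_state_no_calls_under_uniform_null():
    counts = sf.TransitionCounts(
        ("F", "M", "HALL"), np.full((3, 3), 500, dtype=int)
    )
    res = sf.steady_state_test(counts, n_boot=800, seed=4)
    assert not res.exceeds_null.any()
    assert not res.below_null.any()
    assert np.allclose(res.boot_mean.sum(), 1.0, atol=1e-9)
    assert (res.ci_low <= res.boot_mean + 1e-12).all()
    assert (res.boot_mean <= res.ci_high + 1e-12).all()


def test_transition_prob_cis_degenerate_cell():
    counts = sf.TransitionCounts(
        ("F", "M"), np.array([[0, 10], [5, 5]])
    )
    table = sf.transition_prob_cis(counts, n_boot=200, seed=1)
    cell = table[(table["from"] == "F") & (table["to"] == "M")].iloc[0]
    assert cell.ci_low == cell.ci_high == 1.0


def test_transition_prob_cis_field_matrix(pooled_counts):
    table = sf.transition_prob_cis(pooled_counts, n_boot=2000, seed=2)
    ff = table[(table["from"] == "F") & (table["to"] == "F")].iloc[0]
    assert abs(ff.boot_mean - 0.9524) < 0.01
    again = sf.transition_prob_cis(pooled_counts, n_boot=2000, seed=2)
    assert table.equals(again)


def test_percentile_ci_coverage_near_nominal(pooled_counts):
    """95% percentile CIs cover the true stationary vector >= 90% of the time
    at the field-census sample size."""
    P0 = sf.to_probabilities(pooled_counts).probs
    pi0 = sf.stationary(P0)
    n = pooled_counts.n_pairs
    p_flat = (pooled_counts.counts / n).ravel()
    rng = np.random.default_rng(17)
    covered = np.zeros(3)
    n_data = 200
    for _ in range(n_data):
        sample = rng.multinomial(n, p_flat).reshape(3, 3)
        counts = sf.TransitionCounts(sf.POOLED_STATES, sample)
        res = sf.steady_state_test(
            counts, n_boot=400, seed=int(rng.integers(2**31))
        )
        covered += (res.ci_low <= pi0) & (pi0 <= res.ci_high)
    assert (covered / n_data >= 0.90).all()


def test_estimation_recovers_generating_matrix_at_large_n(pooled_counts):
    """Simulation from a known chain followed by estimation recovers the
    matrix and its stationary vector (parameter-recovery round trip).

    The stationary vector is checked at ~100k pairs: its sampling SD at 20k
    pairs (~0.018 for the female state, because the chain is near-diagonal
    and the stationary point amplifies cell noise) is of the same order as
    the 0.02 bound, so the bound only has headroom at larger samples.
    """
    P0 = sf.to_probabilities(pooled_counts).probs
    config = sf.SimConfig(
        n_individuals=(170, 170, 170, 170),
        years=tuple(range(1920, 2071)),
        seed=12,
        p_nonflower=0.0,
        initial_dist=sf.stationary(P0),
    )
    records = sf.simulate_census(config)
    counts = sf.count_transitions(
        sf.build_trajectories(records), sf.POOLED_STATES
    )
    assert counts.n_pairs >= 100_000
    P_hat = sf.to_probabilities(counts).probs
    assert np.abs(P_hat - P0).max() < 0.02
    assert np.abs(sf.stationary(P_hat) - sf.stationary(P0)).max() < 0.02
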