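"""Mixture MCMC: proposal mechanics, conditional updates, full chain,
relabeling, diagnostics."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from mallowsmix import (MallowsParams, PartitionTable, PriorSpec, diagnostics,
                        footrule_distance, leap_and_shift_propose, relabel,
                        run_mcmc, sample_mallows)
from mallowsmix.mixture import (MixtureState, _log_lik, update_alpha,
                                update_assignments, update_rho, update_weights)


def enumerate_leap_shift(rho: np.ndarray, L: int) -> dict[tuple, float]:
    """Brute-force oracle: exact proposal distribution of the leap-and-shift
    mechanism, by enumerating every (item, new rank) choice."""
    n = len(rho)
    out: dict[tuple, float] = {}
    for u in range(n):
        cur = rho[u]
        lo, hi = max(1, cur - L), min(n, cur + L)
        for new in range(lo, hi + 1):
            if new == cur:
                continue
            prop = rho.copy()
            if new > cur:
                prop[(rho > cur) & (rho <= new)] -= 1
            else:
                prop[(rho >= new) & (rho < cur)] += 1
            prop[u] = new
            key = tuple(prop)
            out[key] = out.get(key, 0.0) + 1.0 / (n * (hi - lo))
    return out


class TestLeapAndShift:
    def test_proposal_is_valid_permutation_at_distance_two_or_more(self):
        rng = np.random.default_rng(0)
        rho = rng.permutation(10) + 1
        for _ in range(200):
            prop, _ = leap_and_shift_propose(rho, 3, rng)
            assert sorted(prop) == list(range(1, 11))
            assert footrule_distance(prop, rho) >= 2

    def test_support_for_unit_leap_is_adjacent_transpositions(self):
        support = set(enumerate_leap_shift(np.array([1, 2, 3]), 1))
        assert support == {(2, 1, 3), (1, 3, 2)}

    def test_empirical_frequencies_match_enumeration_oracle(self):
        rho = np.array([2, 4, 1, 3])
        oracle = enumerate_leap_shift(rho, 2)
        rng = np.random.default_rng(1)
        m = 40_000
        counts: dict[tuple, int] = {}
        for _ in range(m):
            prop, _ = leap_and_shift_propose(rho, 2, rng)
            counts[tuple(prop)] = counts.get(tuple(prop), 0) + 1
        assert set(counts) == set(oracle)
        for key, p in oracle.items():
            assert counts[key] / m == pytest.approx(p, abs=4 * np.sqrt(p / m))

    def test_log_ratio_matches_enumerated_forward_backward(self):
        rng = np.random.default_rng(2)
        rho = rng.permutation(6) + 1
        fwd = enumerate_leap_shift(rho, 2)
        for _ in range(100):
            prop, log_ratio = leap_and_shift_propose(rho, 2, rng)
            bwd = enumerate_leap_shift(prop, 2)
            expected = np.log(bwd[tuple(rho)]) - np.log(fwd[tuple(prop)])
            assert log_ratio == pytest.approx(expected, abs=1e-12)

    def test_invalid_leap_size(self):
        with pytest.raises(ValueError):
            leap_and_shift_propose(np.array([1, 2, 3]), 3, 0)


def make_state(rho, alpha, z, weights=None):
    rho = np.atleast_2d(np.asarray(rho, dtype=np.int64))
    C = rho.shape[0]
    weights = np.full(C, 1.0 / C) if weights is None else np.asarray(weights)
    return MixtureState(rho=rho, alpha=np.asarray(alpha, float),
                        z=np.asarray(z), weights=weights)


class TestConditionalUpdates:
    def test_assignments_reduce_to_weights_at_alpha_zero(self, exact_tables):
        rng = np.random.default_rng(0)
        ranks = np.stack([rng.permutation(5) + 1 for _ in range(40)])
        w = np.array([0.7, 0.3])
        state = make_state([rng.permutation(5) + 1, rng.permutation(5) + 1],
                           [0.0, 0.0], np.zeros(40, int), w)
        _, probs = update_assignments(ranks, state, exact_tables[5], rng)
        assert np.allclose(probs, w)

    def test_single_cluster_assigns_everything(self, exact_tables):
        rng = np.random.default_rng(1)
        ranks = np.stack([rng.permutation(4) + 1 for _ in range(10)])
        state = make_state([np.arange(1, 5)], [2.0], np.zeros(10, int))
        z, probs = update_assignments(ranks, state, exact_tables[4], rng)
        assert np.all(z == 0) and np.allclose(probs, 1.0)

    def test_equidistant_symmetric_clusters_split_half_half(self, exact_tables):
        # two components mirror-images of each other; observation symmetric
        state = make_state([[1, 2, 3, 4], [4, 3, 2, 1]], [1.5, 1.5],
                           np.zeros(1, int))
        r = np.array([[3, 1, 4, 2]])  # footrule distance 6 from both rho's
        _, probs = update_assignments(r, state, exact_tables[4],
                                      np.random.default_rng(0))
        assert np.allclose(probs, 0.5)

    def test_weights_posterior_moments_and_simplex(self):
        rng = np.random.default_rng(3)
        z = np.array([0] * 30 + [1] * 10)
        psi = 5.0
        draws = np.stack([update_weights(z, 3, psi, rng) for _ in range(4000)])
        assert np.allclose(draws.sum(axis=1), 1.0)
        expected = (psi + np.array([30, 10, 0])) / (3 * psi + 40)
        assert np.allclose(draws.mean(axis=0), expected, atol=0.01)

    def test_weights_concentrate_when_one_cluster_dominates(self):
        z = np.zeros(5000, int)
        w = update_weights(z, 2, 1.0, np.random.default_rng(0))
        assert w[0] > 0.99

    def test_alpha_recovery_within_quarter(self, exact_tables):
        n, alpha_true = 6, 3.0
        rho = np.arange(1, n + 1)
        ranks = sample_mallows(MallowsParams(rho, alpha_true), 500, seed=5,
                               method="exact-enum")
        state = make_state([rho], [1.0], np.zeros(500, int))
        rng = np.random.default_rng(6)
        prior = PriorSpec(alpha_proposal_sd=0.15)
        trace = []
        for _ in range(3000):
            a, _ = update_alpha(0, ranks, state, prior, exact_tables[n], rng)
            state.alpha[0] = a
            trace.append(a)
        post_mean = np.mean(trace[500:])
        assert abs(post_mean - alpha_true) / alpha_true < 0.25

    def test_alpha_acceptance_rate_interior(self, exact_tables):
        rng = np.random.default_rng(7)
        ranks = sample_mallows(MallowsParams(np.arange(1, 7), 2.0), 100,
                               seed=8, method="exact-enum")
        state = make_state([np.arange(1, 7)], [2.0], np.zeros(100, int))
        acc = 0
        for _ in range(1000):
            a, ok = update_alpha(0, ranks, state, PriorSpec(), exact_tables[6], rng)
            state.alpha[0] = a
            acc += ok
        assert 0 < acc < 1000

    def test_rho_recovery_modal_consensus(self):
        n, alpha = 7, 4.0
        rng = np.random.default_rng(9)
        rho_true = rng.permutation(n) + 1
        ranks = sample_mallows(MallowsParams(rho_true, alpha), 200, seed=10,
                               method="exact-enum")
        state = make_state([ranks[0]], [alpha], np.zeros(200, int))
        prior = PriorSpec(leap_size=1)
        visited: dict[tuple, int] = {}
        for _ in range(3000):
            r, _ = update_rho(0, ranks, state, prior, rng)
            state.rho[0] = r
            key = tuple(r)
            visited[key] = visited.get(key, 0) + 1
            assert sorted(key) == list(range(1, n + 1))
        modal = max(visited, key=visited.get)
        assert np.array_equal(modal, rho_true)

    def test_rho_rejects_uphill_moves_at_optimum(self):
        # every member identical to rho: any proposal strictly increases the
        # total distance, so acceptance comes from the proposal ratio alone
        ranks = np.tile(np.arange(1, 9), (50, 1))
        state = make_state([np.arange(1, 9)], [20.0], np.zeros(50, int))
        rng = np.random.default_rng(11)
        moved = 0
        for _ in range(300):
            r, ok = update_rho(0, ranks, state, PriorSpec(leap_size=1), rng)
            moved += ok
        assert moved == 0  # alpha=20, 50 members: uphill prob e^-250


class TestRunMcmc:
    def test_identical_rankings_pin_the_consensus(self, exact_tables):
        ranks = np.tile(np.array([3, 1, 4, 2, 5]), (20, 1))
        s = run_mcmc(ranks, C=1, n_iter=400, table=exact_tables[5], seed=0)
        assert np.all(s.within_distance == 0)
        assert np.all(s.rho[:, 0, :] == ranks[0])

    def test_same_seed_gives_identical_chains(self, exact_tables):
        rng = np.random.default_rng(1)
        ranks = np.stack([rng.permutation(6) + 1 for _ in range(30)])
        a = run_mcmc(ranks, C=2, n_iter=300, table=exact_tables[6], seed=42)
        b = run_mcmc(ranks, C=2, n_iter=300, table=exact_tables[6], seed=42)
        for name in ("rho", "alpha", "z", "weights", "log_lik"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_rejects_more_clusters_than_samples(self, exact_tables):
        ranks = np.array([[1, 2, 3, 4]])
        with pytest.raises(ValueError):
            run_mcmc(ranks, C=2, n_iter=10, table=exact_tables[4], seed=0)

    def test_empty_cluster_safety(self, exact_tables):
        rng = np.random.default_rng(2)
        rho_a, rho_b = np.arange(1, 9), np.arange(8, 0, -1)
        ranks = np.vstack([
            sample_mallows(MallowsParams(rho_a, 8.0), 30, seed=3),
            sample_mallows(MallowsParams(rho_b, 8.0), 30, seed=4)])
        s = run_mcmc(ranks, C=5, n_iter=600, table=exact_tables[8]
                     if 8 in exact_tables else PartitionTable.exact(8), seed=5)
        votes = np.bincount(np.apply_along_axis(
            lambda col: np.bincount(col, minlength=5).argmax(), 0, s.z),
            minlength=5)
        assert (votes >= 6).sum() >= 2  # at least 2 clusters hold >=10% each

    def test_posterior_rho_frequencies_match_exact_enumeration(self, exact_tables):
        """Detailed-balance smoke test: for n=4, C=1, the chain's visited
        consensus frequencies correlate with the exact posterior computed by
        enumerating all 24 permutations and integrating out alpha."""
        from itertools import permutations as iperms
        n, N = 4, 30
        table = exact_tables[4]
        rho_true = np.array([2, 1, 4, 3])
        # a modest generative alpha keeps the posterior spread over many
        # permutations, so the visited-frequency comparison has power in
        # the tail as well as the mode
        ranks = sample_mallows(MallowsParams(rho_true, 0.5), N, seed=6,
                               method="exact-enum")
        lam = 0.1
        alphas = np.linspace(1e-6, 50, 2001)
        log_z = np.array([table(a) for a in alphas])
        log_post = []
        perms = list(iperms(range(1, n + 1)))
        for p in perms:
            D = np.abs(ranks - np.array(p)).sum()
            integrand = -alphas * D / n - N * log_z - lam * alphas
            m = integrand.max()
            log_post.append(m + np.log(np.trapezoid(np.exp(integrand - m),
                                                    alphas)))
        exact = np.exp(log_post - np.logaddexp.reduce(log_post))
        s = run_mcmc(ranks, C=1, n_iter=30_000, burn_in=2000, table=table,
                     seed=7, prior=PriorSpec(leap_size=3, alpha_proposal_sd=0.3,
                                             rho_proposals_per_sweep=2))
        codes = {p: i for i, p in enumerate(perms)}
        freq = np.zeros(len(perms))
        for r in s.rho[:, 0, :]:
            freq[codes[tuple(r)]] += 1
        freq /= freq.sum()
        assert spearmanr(freq, exact).statistic >= 0.95


class TestRelabel:
    def _tiny_chain(self, seed=0):
        rng = np.random.default_rng(seed)
        ranks = np.vstack([
            sample_mallows(MallowsParams(np.arange(1, 7), 6.0), 15, seed=1),
            sample_mallows(MallowsParams(np.arange(6, 0, -1), 6.0), 15, seed=2)])
        from mallowsmix import PartitionTable
        table = PartitionTable.exact(6)
        return ranks, run_mcmc(ranks, C=2, n_iter=400, table=table, seed=seed), table

    def test_no_switching_is_identity(self):
        _, s, _ = self._tiny_chain()
        r = relabel(s)
        # the chain never switches here, so relabeling must not reorder
        assert np.array_equal(r.z, s.z) and np.array_equal(r.rho, s.rho)

    def test_manual_swap_is_undone(self):
        ranks, s, table = self._tiny_chain()
        swapped = relabel(s)
        half = swapped.n_stored // 2
        swapped.rho[:half] = swapped.rho[:half, ::-1]
        swapped.alpha[:half] = swapped.alpha[:half, ::-1]
        swapped.weights[:half] = swapped.weights[:half, ::-1]
        swapped.z[:half] = 1 - swapped.z[:half]
        fixed = relabel(swapped)
        modal = np.round(fixed.z.mean(axis=0))
        agree = (fixed.z == modal[None, :]).mean()
        assert agree > 0.95

    def test_relabeling_preserves_likelihood(self):
        ranks, s, table = self._tiny_chain(seed=3)
        r = relabel(s)
        for t in range(s.n_stored):
            before = _log_lik(ranks, MixtureState(
                rho=s.rho[t], alpha=s.alpha[t], z=s.z[t],
                weights=s.weights[t]), table)
            after = _log_lik(ranks, MixtureState(
                rho=r.rho[t], alpha=r.alpha[t], z=r.z[t],
                weights=r.weights[t]), table)
            assert after == pytest.approx(before, abs=1e-9)


class TestDiagnostics:
    def test_report_contents(self, exact_tables):
        rng = np.random.default_rng(4)
        ranks = np.stack([rng.permutation(5) + 1 for _ in range(20)])
        s = run_mcmc(ranks, C=2, n_iter=200, table=exact_tables[5], seed=1)
        rep = diagnostics(s)
        rates = rep["acceptance_rates"]
        assert set(rates) == {("alpha", 0), ("alpha", 1), ("rho", 0), ("rho", 1)}
        assert all(0 <= v <= 1 for v in rates.values())
        assert all(len(rep["alpha_traces"][c]) == s.n_stored for c in range(2))
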