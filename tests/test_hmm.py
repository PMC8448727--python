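import itertools

import numpy as np
import pytest
from scipy import stats as sps

from cfcna.genome import BinTrack, make_genome_grid
from cfcna import hmm as H
from cfcna import normalize as norm
from cfcna import simulate as sim


# ---------------------------------------------------------------------------
# independent exhaustive-enumeration oracle


def brute_force_ll_and_path(x, means, var, df, txn_e, n_states):
    """Sum/argmax over all n_states**len(x) paths with uniform initial dist."""
    A = H.transition_matrix(n_states, txn_e)
    scale = np.sqrt(var)
    best_path, best_logp = None, -np.inf
    total = -np.inf
    for path in itertools.product(range(n_states), repeat=len(x)):
        logp = -np.log(n_states)
        for t, state in enumerate(path):
            if t > 0:
                logp += np.log(A[path[t - 1], state])
            logp += sps.t.logpdf(x[t], df, loc=means[state], scale=scale)
        total = np.logaddexp(total, logp)
        if logp > best_logp:  # strict: first (lowest-index) max wins
            best_logp, best_path = logp, path
    return total, np.array(best_path)


def _small_instance(rng, n_bins, n_states):
    grid = make_genome_grid({"A": n_bins * 1_000_000}, 1_000_000)
    x = rng.normal(0.0, 0.3, n_bins)
    track = BinTrack(grid=grid, values=x)
    config = H.HMMConfig(max_cn=n_states - 1, subclonal_cn=())
    states = H.build_state_space(config)
    alpha = rng.uniform(0.1, 0.8)
    phi = rng.uniform(1.8, 3.0)
    var = rng.uniform(0.02, 0.2)
    return track, config, states, alpha, phi, var


class TestStateSpace:
    def test_default_eight_states(self):
        states = H.build_state_space(H.HMMConfig())
        assert len(states) == 8
        assert [s.copy_number for s in states] == [0, 1, 2, 3, 4, 5, 1, 3]
        assert [s.subclonal for s in states] == [False] * 6 + [True, True]

    def test_no_subclonal_small_cn(self):
        states = H.build_state_space(H.HMMConfig(max_cn=2, subclonal_cn=()))
        assert len(states) == 3

    def test_ordering_stable(self):
        a = H.build_state_space(H.HMMConfig())
        b = H.build_state_space(H.HMMConfig())
        assert [s.label for s in a] == [s.label for s in b]


class TestExpectedLogRatio:
    def test_alpha_zero_always_zero(self):
        for cn in range(6):
            st = H.HMMState(f"CN{cn}", cn)
            assert H.expected_log_ratio(st, 0.0, 1.0, 2.0) == pytest.approx(0.0)

    def test_pure_tumor_cn4(self):
        st = H.HMMState("CN4", 4)
        assert H.expected_log_ratio(st, 1.0, 1.0, 2.0) == pytest.approx(1.0)

    def test_half_mix_cn3(self):
        st = H.HMMState("CN3", 3)
        assert H.expected_log_ratio(st, 0.5, 1.0, 2.0) == pytest.approx(0.32193, abs=1e-5)

    def test_subclonal_value(self):
        st = H.HMMState("CN3s", 3, subclonal=True)
        assert H.expected_log_ratio(st, 0.4, 0.5, 2.0) == pytest.approx(0.13750, abs=1e-5)

    def test_subclonal_continuity_at_s1(self):
        clonal = H.HMMState("CN3", 3)
        sub = H.HMMState("CN3s", 3, subclonal=True)
        for alpha in (0.1, 0.4, 0.9):
            assert H.expected_log_ratio(sub, alpha, 1.0, 2.2) == pytest.approx(
                H.expected_log_ratio(clonal, alpha, 1.0, 2.2), abs=1e-12
            )

    def test_zero_ratio_clamped(self):
        st = H.HMMState("CN0", 0)
        out = H.expected_log_ratio(st, 1.0, 1.0, 2.0)
        assert out == pytest.approx(np.log2(H.LOG_RATIO_FLOOR))


class TestTransitionMatrix:
    def test_default_off_diagonal(self):
        A = H.transition_matrix(8, 0.99)
        assert A[0, 1] == pytest.approx(0.01 / 7, abs=1e-12)
        assert np.allclose(np.diag(A), 0.99)

    def test_two_state_half_uniform(self):
        A = H.transition_matrix(2, 0.5)
        assert np.allclose(A, 0.5)

    def test_rows_sum_to_one_exactly(self):
        for n in (2, 3, 5, 8, 11):
            A = H.transition_matrix(n, 0.99)
            assert np.allclose(A.sum(axis=1), 1.0, atol=1e-12)


class TestForwardBackwardOracle:
    def test_matches_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n_bins = int(rng.integers(2, 8))
            n_states = int(rng.integers(2, 4))
            track, config, states, alpha, phi, var = _small_instance(rng, n_bins, n_states)
            means = H.state_means(states, alpha, 1.0, phi)
            _, ll = H.forward_backward(track, states, alpha, phi, var, config)
            oracle_ll, _ = brute_force_ll_and_path(
                track.values, means, var, config.t_df, config.txn_e, n_states
            )
            assert ll == pytest.approx(oracle_ll, abs=1e-10)

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        track, config, states, alpha, phi, var = _small_instance(rng, 50, 3)
        gamma, _ = H.forward_backward(track, states, alpha, phi, var, config)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-10)

    def test_single_state_posterior_one_and_ll_is_emission_sum(self):
        grid = make_genome_grid({"A": 5_000_000}, 1_000_000)
        track = BinTrack(grid=grid, values=np.array([0.1, -0.2, 0.0, 0.3, 0.05]))
        config = H.HMMConfig(max_cn=5, subclonal_cn=())
        states = [H.HMMState("CN2", 2)]
        gamma, ll = H.forward_backward(track, states, 0.3, 2.0, 0.04, config)
        assert np.allclose(gamma, 1.0)
        mean = H.expected_log_ratio(states[0], 0.3, 1.0, 2.0)
        expected = sps.t.logpdf(track.values, config.t_df, loc=mean, scale=0.2).sum()
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_masked_bins_skipped(self):
        grid = make_genome_grid({"A": 6_000_000}, 1_000_000)
        mask = np.array([False, True, False, False, True, False])
        track = BinTrack(grid=grid, values=np.zeros(6), mask=mask)
        config = H.HMMConfig(max_cn=2, subclonal_cn=())
        states = H.build_state_space(config)
        gamma, _ = H.forward_backward(track, states, 0.2, 2.0, 0.05, config)
        assert np.isnan(gamma[mask]).all()
        assert np.isfinite(gamma[~mask]).all()

    def test_nonfinite_track_raises(self):
        grid = make_genome_grid({"A": 4_000_000}, 1_000_000)
        track = BinTrack(grid=grid, values=np.array([0.0, np.inf, 0.0, 0.0]))
        config = H.HMMConfig(max_cn=2, subclonal_cn=())
        with pytest.raises(ValueError, match="not sanitized"):
            H.forward_backward(track, H.build_state_space(config), 0.2, 2.0, 0.05, config)


class TestViterbiOracle:
    def test_matches_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n_bins = int(rng.integers(2, 8))
            n_states = int(rng.integers(2, 4))
            track, config, states, alpha, phi, var = _small_instance(rng, n_bins, n_states)
            means = H.state_means(states, alpha, 1.0, phi)
            path = H.viterbi(track, states, alpha, phi, var, config)
            _, oracle_path = brute_force_ll_and_path(
                track.values, means, var, config.t_df, config.txn_e, n_states
            )
            assert (path == oracle_path).all()

    def test_recovers_generating_states_at_tiny_noise(self):
        grid = make_genome_grid({"A": 40_000_000}, 1_000_000)
        config = H.HMMConfig(max_cn=3, subclonal_cn=())
        states = H.build_state_space(config)
        alpha, phi = 0.5, 2.0
        means = H.state_means(states, alpha, 1.0, phi)
        true_path = np.array([2] * 10 + [3] * 15 + [2] * 10 + [1] * 5)
        rng = np.random.default_rng(3)
        x = means[true_path] + rng.normal(0, 1e-4, len(true_path))
        track = BinTrack(grid=grid, values=x)
        path = H.viterbi(track, states, alpha, phi, 1e-6, config)
        assert (path == true_path).all()

    def test_all_equal_emissions_constant_lowest_state(self):
        grid = make_genome_grid({"A": 6_000_000}, 1_000_000)
        track = BinTrack(grid=grid, values=np.zeros(6))
        config = H.HMMConfig(max_cn=2, subclonal_cn=())
        states = H.build_state_space(config)
        # alpha=0 collapses all means to 0 -> identical emissions everywhere
        path = H.viterbi(track, states, 0.0, 2.0, 0.05, config)
        assert (path == 0).all()


class TestEMFit:
    def test_loglik_monotone(self, toy_grid, toy_gc, deep_config, toy_panel_log2):
        t = sim.simulate_truth_profile(toy_grid, 6, (10, 30), alpha=0.3, seed=17)
        counts = sim.simulate_bin_counts(t, toy_grid, deep_config, gc=toy_gc, seed=17, stream=(0, 1))
        track = norm.normalize_sample(counts, toy_panel_log2)
        sol = H.em_fit(track, H.HMMConfig.deep_profile(), alpha_init=0.3, ploidy_init=2.0)
        ll = np.array(sol.ll_history)
        assert (np.diff(ll) >= -1e-6 * np.abs(ll[:-1])).all()

    def test_alpha_recovery_single_case(self, mid_grid, deep_config):
        gc = sim.simulate_gc_track(mid_grid, 41)
        panel = norm.build_panel_log2(
            sim.simulate_panel_of_normals(mid_grid, 27, deep_config, gc=gc, seed=41)
        )
        t = sim.simulate_truth_profile(mid_grid, 15, (15, 40), alpha=0.30, seed=41)
        counts = sim.simulate_bin_counts(t, mid_grid, deep_config, gc=gc, seed=41, stream=(0, 1))
        track = norm.normalize_sample(counts, panel)
        best, _ = H.fit_tumor_fraction(track, H.HMMConfig.deep_profile())
        assert best.tumor_fraction == pytest.approx(0.30, abs=0.05)

    def test_nonconvergence_flag_not_exception(self, toy_grid, toy_gc, deep_config, toy_panel_log2):
        t = sim.simulate_truth_profile(toy_grid, 6, (10, 30), alpha=0.2, seed=19)
        counts = sim.simulate_bin_counts(t, toy_grid, deep_config, gc=toy_gc, seed=19, stream=(0, 1))
        track = norm.normalize_sample(counts, toy_panel_log2)
        sol = H.em_fit(
            track, H.HMMConfig.deep_profile(max_iter=2), alpha_init=0.5, ploidy_init=3.0
        )
        assert sol.converged is False

    def test_segments_partition_unmasked_bins(self, toy_grid, toy_gc, deep_config, toy_panel_log2):
        t = sim.simulate_truth_profile(toy_grid, 5, (10, 30), alpha=0.3, seed=23)
        counts = sim.simulate_bin_counts(t, toy_grid, deep_config, gc=toy_gc, seed=23, stream=(0, 1))
        track = norm.normalize_sample(counts, toy_panel_log2)
        sol = H.em_fit(track, H.HMMConfig.deep_profile(), alpha_init=0.2, ploidy_init=2.0)
        assert sol.segments["n_bins"].sum() == track.n_unmasked


class TestSelectSolution:
    def _sol(self, ll, frac_sub=0.0, sub_fracs=None, frac_alt=0.2, ploidy=2.0, mean_cn=2.0):
        import pandas as pd

        return H.TumorFractionSolution(
            tumor_fraction=0.2, tumor_ploidy=ploidy, subclonal_prevalence=0.5,
            variance=0.01, log_likelihood=ll, state_path=np.array([2, 2]),
            segments=pd.DataFrame(
                {"chrom": ["A"], "start": [0], "end": [2_000_000], "n_bins": [2],
                 "mean_log2": [0.0], "copy_number": [2], "state_label": ["CN2"],
                 "subclonal": [False]}
            ),
            frac_genome_altered=frac_alt, frac_genome_subclonal=frac_sub,
            subclone_fractions=sub_fracs or {}, mean_tumor_cn=mean_cn,
            converged=True, n_iter=5, alpha_init=0.2, ploidy_init=2.0,
        )

    def test_highest_ll_among_admissible(self):
        a, b = self._sol(-1000.0), self._sol(-990.0)
        assert H.select_solution([a, b]) is b

    def test_subclonal_fraction_rule_excludes(self):
        good = self._sol(-1000.0)
        bad = self._sol(-900.0, frac_sub=0.6)
        assert H.select_solution([good, bad]) is good

    def test_per_subclone_rule_excludes(self):
        good = self._sol(-1000.0)
        bad = self._sol(-900.0, sub_fracs={"CN3s": 0.75})
        assert H.select_solution([good, bad]) is good

    def test_single_inadmissible_returned_with_flag(self):
        bad = self._sol(-900.0, frac_sub=0.9)
        out = H.select_solution([bad])
        assert "no admissible solution" in out.flags

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            H.select_solution([])

    def test_parsimony_within_tie_window(self):
        clean = self._sol(-1002.0, frac_alt=0.0)
        noisy = self._sol(-1000.0, frac_alt=0.5)
        assert H.select_solution([clean, noisy]) is clean

    def test_ploidy_discordant_excluded(self):
        good = self._sol(-1000.0)
        bad = self._sol(-900.0, ploidy=2.9, mean_cn=2.4)
        assert H.select_solution([good, bad]) is good


class TestDetectionGate:
    def _with_segments(self, frac_alt, seg_bins):
        import pandas as pd

        segs = pd.DataFrame(
            {
                "chrom": ["A", "A"],
                "start": [0, seg_bins * 1_000_000],
                "end": [seg_bins * 1_000_000, (seg_bins + 100) * 1_000_000],
                "n_bins": [seg_bins, 100],
                "mean_log2": [0.3, 0.0],
                "copy_number": [3, 2],
                "state_label": ["CN3", "CN2"],
                "subclonal": [False, False],
            }
        )
        return H.TumorFractionSolution(
            tumor_fraction=0.1, tumor_ploidy=2.0, subclonal_prevalence=0.5,
            variance=0.01, log_likelihood=0.0, state_path=np.array([3, 2]),
            segments=segs, frac_genome_altered=frac_alt, frac_genome_subclonal=0.0,
            subclone_fractions={}, mean_tumor_cn=2.0, converged=True, n_iter=3,
            alpha_init=0.1, ploidy_init=2.0,
        )

    def test_low_altered_fraction_not_detected(self):
        config = H.HMMConfig.deep_profile()  # threshold 0.01
        out = H.detection_gate(self._with_segments(0.005, seg_bins=30), config)
        assert out.tumor_fraction == 0.0
        assert out.detected is False

    def test_segment_of_25_bins_passes_min_20(self):
        config = H.HMMConfig.deep_profile()
        out = H.detection_gate(self._with_segments(0.05, seg_bins=25), config)
        assert out.detected is True
        assert out.tumor_fraction == 0.1

    def test_short_segments_not_detected(self):
        config = H.HMMConfig.deep_profile()
        out = H.detection_gate(self._with_segments(0.02, seg_bins=10), config)
        assert out.detected is False

    def test_profiles_differ(self):
        ulp, deep = H.HMMConfig.ulp_profile(), H.HMMConfig.deep_profile()
        assert (ulp.min_segment_bins, ulp.alt_frac_threshold) == (50, 0.05)
        assert (deep.min_segment_bins, deep.alt_frac_threshold) == (20, 0.01)


class TestConfigValidation:
    def test_bad_txn_e(self):
        with pytest.raises(ValueError):
            H.HMMConfig(txn_e=1.0)

    def test_bad_restarts(self):
        with pytest.raises(ValueError):
            H.HMMConfig(normal_restarts=(0.5, 1.2))
        with pytest.raises(ValueError):
            H.HMMConfig(ploidy_restarts=())
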