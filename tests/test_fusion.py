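"""Neighborhoods, matching weights, bias-corrected means and mean-shift fusion."""

import numpy as np
import pytest

import dwifuse as dw
from dwifuse.fusion import (
    _feature_operator,
    build_neighborhood,
    direction_neighborhoods,
    matching_bandwidth,
    patch_feature_magnitudes,
)
from dwifuse.patches import aep_project
from dwifuse.pcet import pcet_moments, pcet_order_pairs


def small_population(scheme, name="single", theta=15.0, noise=5.0, D=6, grid=(2, 2, 1), seed=5):
    sim = dw.SimulationConfig(
        theta_T=theta, noise_percent=noise, population_size=D, grid_shape=grid, seed=seed
    )
    return dw.make_population(sim, dw.named_fiber_config(name), scheme)


class TestBuildNeighborhood:
    def test_degenerate_is_self_only(self, scheme81):
        nb = build_neighborhood(3, 7, scheme81, (3, 3, 3), r_s=0.0, alpha_s=5.0)
        assert nb == [(3, 7)]

    def test_counts_match_brute_force(self, scheme81):
        grid = (5, 5, 5)
        coords = np.stack(np.unravel_index(np.arange(125), grid), axis=1).astype(float)
        for i, k in [(62, 0), (0, 40), (124, 80)]:
            nb = set(build_neighborhood(i, k, scheme81, grid, 2.0, 30.0))
            brute = set()
            for j in range(125):
                if np.linalg.norm(coords[j] - coords[i]) > 2.0:
                    continue
                for l in range(81):
                    ang = np.degrees(
                        np.arccos(
                            min(abs(scheme81.directions[k] @ scheme81.directions[l]), 1.0)
                        )
                    )
                    if ang <= 30.0 + 1e-9:
                        brute.add((j, l))
            assert nb == brute
            assert (i, k) in nb

    def test_symmetry(self, scheme81):
        grid = (3, 3, 3)
        nb = build_neighborhood(13, 10, scheme81, grid, 1.5, 25.0)
        for j, l in nb:
            assert (13, 10) in build_neighborhood(j, l, scheme81, grid, 1.5, 25.0)


class TestMatchingBandwidth:
    def test_values(self):
        assert matching_bandwidth(0.5, 1.0, 1) == pytest.approx(1.0)
        assert matching_bandwidth(0.1, 7.5, 81) == pytest.approx(np.sqrt(911.25), rel=1e-12)
        assert matching_bandwidth(0.1, 0.0, 81) == 0.0

    def test_monotone(self):
        base = matching_bandwidth(0.1, 7.5, 81)
        assert matching_bandwidth(0.2, 7.5, 81) > base
        assert matching_bandwidth(0.1, 9.0, 81) > base
        assert matching_bandwidth(0.1, 7.5, 100) > base


class TestComputeWeights:
    def test_single_candidate(self):
        cfg = dw.FusionConfig(sigma=7.5)
        w, _ = dw.compute_weights(
            np.ones(81), np.ones((1, 81)) * 3.0, np.zeros(3), np.zeros((1, 3)), cfg
        )
        np.testing.assert_allclose(w, [1.0])

    def test_symmetric_candidates_split_evenly(self):
        cfg = dw.FusionConfig(sigma=7.5)
        ref = np.zeros(81)
        cands = np.stack([np.full(81, 1.0), np.full(81, -1.0)])
        w, _ = dw.compute_weights(ref, cands, np.zeros(3), np.zeros((2, 3)), cfg)
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-12)

    def test_hand_computed_normalization(self):
        cfg = dw.FusionConfig(sigma=7.5, sigma_x=1.0)
        h2 = matching_bandwidth(0.1, 7.5, 3) ** 2
        ref = np.zeros(3)
        cands = np.array([[1.0, 0, 0], [2.0, 0, 0], [0, 3.0, 0]])
        pos = np.array([[0, 0, 0], [1.0, 0, 0], [0, 2.0, 0]], dtype=float)
        w, Z = dw.compute_weights(ref[:3], cands, np.zeros(3), pos, cfg)
        raw = np.array(
            [
                np.exp(-1.0 / h2),
                np.exp(-4.0 / h2) * np.exp(-1.0 / 2.0),
                np.exp(-9.0 / h2) * np.exp(-4.0 / 2.0),
            ]
        )
        np.testing.assert_allclose(w, raw / raw.sum(), rtol=1e-12)
        assert Z == pytest.approx(raw.sum())

    def test_underflow_falls_back_to_uniform(self):
        cfg = dw.FusionConfig(sigma=1e-4)
        ref = np.zeros(81)
        cands = np.full((3, 81), 1e6)
        with pytest.warns(UserWarning, match="underflow"):
            w, Z = dw.compute_weights(ref, cands, np.zeros(3), np.zeros((3, 3)), cfg)
        np.testing.assert_allclose(w, 1.0 / 3.0)
        assert Z == 0.0


class TestWeightedMeanSignal:
    def test_no_noise_constant(self):
        assert dw.weighted_mean_signal([0.5, 0.5], [4.0, 4.0], 0.0) == pytest.approx(4.0)

    def test_hand_computed(self):
        got = dw.weighted_mean_signal([0.25, 0.75], [10.0, 20.0], 1.0)
        assert got == pytest.approx(np.sqrt(323.0), rel=1e-12)

    def test_clamped_at_zero(self):
        assert dw.weighted_mean_signal([1.0], [1.0], 10.0) == 0.0

    def test_weights_must_normalize(self):
        with pytest.raises(ValueError):
            dw.weighted_mean_signal([0.5, 0.2], [1.0, 2.0], 0.0)


class TestSimpleAverage:
    def test_identity_cases(self, scheme81):
        pop = small_population(scheme81, D=1, noise=0.0)
        np.testing.assert_allclose(dw.simple_average(pop).signals, pop.signals[0])
        pop5 = small_population(scheme81, D=5, noise=0.0, theta=1e-9)
        np.testing.assert_allclose(dw.simple_average(pop5).signals, pop5.ground_truth, atol=1e-9)

    def test_equals_uniform_weighted_mean(self, scheme81):
        """Simple averaging is the uniform-weight special case of the weighted mean."""
        pop = small_population(scheme81, D=4, noise=5.0)
        avg = dw.simple_average(pop)
        i, k = 1, 40
        manual = dw.weighted_mean_signal(
            np.full(4, 0.25), pop.signals[:, i, k], pop.sigma
        )
        assert avg.signals[i, k] == pytest.approx(manual, rel=1e-12)

    def test_bias_correction_recovery(self, scheme81):
        """Averaging many Rician-noisy copies recovers the clean profile.

        The Monte-Carlo precision at D = 1000 is direction dependent
        (Var(S_noisy^2) = 4 sigma^2 S^2 + 4 sigma^4), so the check is a z-test
        per direction plus a profile-level relative error bound.
        """
        sim = dw.SimulationConfig(
            theta_T=1e-9, noise_percent=5.0, population_size=1000,
            grid_shape=(1, 1, 1), seed=7,
        )
        pop = dw.make_population(sim, dw.named_fiber_config("single"), scheme81)
        gt = pop.ground_truth[0]
        est = dw.simple_average(pop).signals[0]
        sd_mean = np.sqrt(4 * pop.sigma**2 * gt**2 + 4 * pop.sigma**4) / np.sqrt(1000)
        z = np.abs(est**2 - gt**2) / sd_mean
        assert z.max() < 5.0
        assert np.linalg.norm(est - gt) / np.linalg.norm(gt) < 0.03
        # high-signal directions do reach percent-level per-direction accuracy
        strong = gt >= 4 * pop.sigma
        assert np.max(np.abs(est[strong] - gt[strong]) / gt[strong]) < 0.03


class TestFeaturePipeline:
    def test_member_operator_matches_explicit_loop(self, scheme81, rng):
        """The fused operator equals the per-patch PCET sum over member samples."""
        cfg = dw.FusionConfig()
        signal = rng.uniform(0, 150, 81)
        feats = patch_feature_magnitudes(signal, scheme81, cfg)
        k = 13
        patch = dw.extract_patch(scheme81, k, cfg.alpha_p)
        rho, theta = aep_project(patch.center, patch.member_axes)
        rho_n = rho / np.radians(cfg.alpha_p)
        vals = signal[patch.member_indices]
        expected = []
        for n, l in pcet_order_pairs(cfg.m):
            basis = np.exp(1j * (2 * np.pi * n * rho_n**2 + l * theta))
            expected.append(abs(np.mean(np.conj(basis) * vals)))
        np.testing.assert_allclose(feats[k], expected, atol=1e-10)

    def test_sh_grid_operator_matches_module_chain(self, scheme81, rng):
        cfg = dw.FusionConfig(feature_pipeline="sh_grid")
        signal = rng.uniform(0, 150, 81)
        feats = patch_feature_magnitudes(signal, scheme81, cfg)
        k = 27
        proj = dw.resample_to_polar_grid(
            dw.extract_patch(scheme81, k, cfg.alpha_p), signal,
            sh_order=cfg.sh_order, sh_lambda=cfg.sh_lambda,
        )
        expected = pcet_moments(proj, cfg.m).magnitudes
        np.testing.assert_allclose(feats[k], expected, atol=1e-9)


class TestMeanShiftFuse:
    def test_identical_noise_free_subjects_fixed_point(self, scheme81):
        pop = small_population(scheme81, D=5, noise=0.0, theta=1e-9)
        tpl = dw.mean_shift_fuse(pop, config=dw.FusionConfig(r_s=1.0))
        assert tpl.iterations_used == 1
        assert len(tpl.trace) == 1 and tpl.trace[0] < 1e-9
        np.testing.assert_allclose(tpl.signals, pop.ground_truth, atol=1e-9)

    def test_uniform_self_weights_equal_simple_average(self, scheme81):
        pop = small_population(scheme81, D=6, noise=5.0)
        cfg = dw.FusionConfig(r_s=0.0, alpha_s=5.0, uniform_weights=True, T_max=1)
        tpl = dw.mean_shift_fuse(pop, config=cfg)
        np.testing.assert_allclose(tpl.signals, dw.simple_average(pop).signals, atol=1e-10)

    def test_one_iteration_matches_manual_weights(self, scheme81):
        """The vectorized update equals the per-target compute_weights path."""
        pop = small_population(scheme81, D=4, grid=(2, 2, 1), noise=5.0)
        cfg = dw.FusionConfig(r_s=1.0, T_max=1, bias_correction="per_iteration")
        tpl = dw.mean_shift_fuse(pop, config=cfg)

        init = dw.simple_average(pop)
        ref_feats = patch_feature_magnitudes(init.signals, scheme81, cfg)
        subj_feats = patch_feature_magnitudes(pop.signals, scheme81, cfg)
        coords = np.stack(np.unravel_index(np.arange(4), (2, 2, 1)), axis=1).astype(float)
        for i, k in [(0, 0), (3, 57)]:
            nbrs = build_neighborhood(i, k, scheme81, (2, 2, 1), cfg.r_s, cfg.alpha_s)
            cand_feats, cand_pos, cand_sig = [], [], []
            for d in range(4):
                for j, l in nbrs:
                    cand_feats.append(subj_feats[d, j, l])
                    cand_pos.append(coords[j])
                    cand_sig.append(pop.signals[d, j, l])
            w, _ = dw.compute_weights(
                ref_feats[i, k], np.array(cand_feats), coords[i],
                np.array(cand_pos), cfg, sigma=pop.sigma,
            )
            manual = dw.weighted_mean_signal(w, np.array(cand_sig), pop.sigma)
            assert tpl.signals[i, k] == pytest.approx(manual, rel=1e-9, abs=1e-9)

    def test_fused_values_bounded_by_candidates(self, scheme81):
        pop = small_population(scheme81, D=6, noise=3.0, grid=(2, 2, 1))
        tpl = dw.mean_shift_fuse(pop, config=dw.FusionConfig(r_s=2.0))
        dn = direction_neighborhoods(scheme81, 30.0)
        for i in range(4):
            for k in (0, 33, 80):
                cand_max = pop.signals[:, :, dn[k]].max()
                bound = np.sqrt(max(cand_max**2 - 2 * pop.sigma**2, 0.0))
                assert tpl.signals[i, k] <= bound + 1e-9

    def test_mode_beats_mean_on_contaminated_population(self, scheme81):
        """80/20 two-population mixture: the template tracks the majority mode."""
        closer = 0
        for seed in range(10):
            pop = contaminated_population(scheme81, seed)
            majority = pop.meta["majority_profile"]
            tpl = dw.mean_shift_fuse(pop, config=dw.FusionConfig(r_s=0.0))
            avg = dw.simple_average(pop)
            if np.linalg.norm(tpl.signals[0] - majority) < np.linalg.norm(
                avg.signals[0] - majority
            ):
                closer += 1
        assert closer >= 9

    def test_zero_sigma_stops_on_absolute_tolerance(self, scheme81):
        pop = small_population(scheme81, D=3, noise=0.0, theta=1e-9)
        tpl = dw.mean_shift_fuse(pop, config=dw.FusionConfig(r_s=0.0, T_max=3))
        assert tpl.iterations_used <= 3
        assert tpl.trace[-1] < 1e-12


def contaminated_population(scheme, seed, D=20, theta=15.0, noise=3.0):
    """16 subjects near axis A, 4 near an orthogonal axis B (single voxel)."""
    simA = dw.SimulationConfig(
        theta_T=theta, noise_percent=noise, population_size=16,
        grid_shape=(1, 1, 1), seed=seed,
    )
    simB = dw.SimulationConfig(
        theta_T=theta, noise_percent=noise, population_size=4,
        grid_shape=(1, 1, 1), seed=seed + 10_000,
    )
    popA = dw.make_population(simA, dw.named_fiber_config("single"), scheme)
    cfgB = dw.FiberConfig(((np.array([1.0, 0.0, 0.0]), 1.0),))
    popB = dw.make_population(simB, cfgB, scheme)
    merged = dw.PopulationDataset(
        signals=np.concatenate([popA.signals, popB.signals]),
        scheme=scheme,
        grid_shape=(1, 1, 1),
        ground_truth=popA.ground_truth,
        true_axes=popA.true_axes,
        sigma=popA.sigma,
        meta={"majority_profile": popA.ground_truth[0]},
    )
    return merged
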