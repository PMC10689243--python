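"""Tests for profile peaks, multiplicative scaling, E:I and c-Fos measures."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from homeoplast.structure import (IntensityProfile, PeakSet, cfos_bootstrap,
                                  cfos_quantify, colocalized_ratio,
                                  fit_scaling_factor, profile_peaks,
                                  structural_ei)
from homeoplast.synth import (GeneratorSpec, gen_ei_profile_pair, gen_profiles,
                              gen_scaled_pair)

BG = 100.0


def profile(intensity, dx=0.01, bg=BG, channel="eGFP"):
    intensity = np.asarray(intensity, dtype=float)
    return IntensityProfile(positions=np.arange(intensity.size) * dx,
                            intensity=intensity, background_level=bg,
                            channel=channel)


class TestProfilePeaks:
    def test_flat_profile_no_peaks(self):
        out = profile_peaks(profile(np.full(1000, BG)))
        assert out.centers.size == 0
        assert out.density == 0.0

    def test_rectangular_bump_width_and_density(self):
        y = np.full(1001, BG)          # 10 um at 0.01 um spacing
        y[450:550] = 2 * BG            # 1.0 um wide bump
        out = profile_peaks(profile(y))
        assert out.centers.size == 1
        assert out.widths[0] == pytest.approx(1.0, abs=0.02)
        assert out.density == pytest.approx(0.1, rel=0.01)

    def test_gaussian_bump_analytic_crossing_width(self):
        """Gaussian sigma=0.3, height 1.5x background: width equals the
        analytic 1.15-level crossing within one sample spacing."""
        dx, sigma, h = 0.01, 0.3, 0.5
        x = np.arange(0, 10 + dx / 2, dx)
        y = BG * (1 + h * np.exp(-0.5 * ((x - 5) / sigma) ** 2))
        out = profile_peaks(profile(y, dx=dx))
        expected = 2 * sigma * np.sqrt(2 * np.log(h / 0.15))
        assert out.widths[0] == pytest.approx(expected, abs=dx)

    def test_scale_invariance(self):
        """Multiplying profile and background by a constant leaves the
        peak set unchanged."""
        rng = np.random.default_rng(3)
        y = BG * (1 + np.abs(rng.normal(0, 0.3, 500)))
        a = profile_peaks(profile(y))
        b = profile_peaks(IntensityProfile(
            positions=np.arange(500) * 0.01, intensity=7.0 * y,
            background_level=7.0 * BG))
        np.testing.assert_allclose(b.centers, a.centers)
        np.testing.assert_allclose(b.widths, a.widths)

    def test_degenerate_profile_rejected(self):
        with pytest.raises(ValueError):
            profile_peaks(profile(np.array([BG, BG])))

    def test_generator_density_recovered(self):
        spec = GeneratorSpec(seed=31)
        dendrites, truth = gen_profiles(spec, n_dendrites=20)
        counts = [profile_peaks(d["spine"]).centers.size for d in dendrites]
        assert np.mean(counts) == pytest.approx(truth["n_spines"], abs=0.5)


class TestColocalizedRatio:
    def test_matched_peak_ratio(self):
        spines = PeakSet(centers=np.array([5.0]), widths=np.array([1.5]),
                         heights=np.array([2.0]), density=0.1)
        protein = PeakSet(centers=np.array([5.1]), widths=np.array([0.3]),
                          heights=np.array([3.0]), density=0.1)
        out = colocalized_ratio(protein, spines)
        assert out[0] == pytest.approx(2.0)

    def test_no_overlap_all_undefined(self):
        spines = PeakSet(centers=np.array([1.0, 2.0]), widths=np.ones(2),
                         heights=np.ones(2), density=0.2)
        protein = PeakSet(centers=np.array([8.0]), widths=np.array([0.3]),
                          heights=np.array([3.0]), density=0.1)
        assert np.all(np.isnan(colocalized_ratio(protein, spines)))

    def test_planted_levels_rank_recovered(self):
        """Planted per-spine protein levels vs recovered ratios: rank
        correlation > 0.8 despite measurement noise."""
        spec = GeneratorSpec(seed=32, measurement_cv=0.2)
        dendrites, truth = gen_profiles(spec, n_dendrites=10)
        planted, recovered = [], []
        for dend, tr in zip(dendrites, truth["dendrites"]):
            sp = profile_peaks(dend["spine"])
            pr = profile_peaks(dend["protein"])
            ratios = colocalized_ratio(pr, sp, tolerance_um=0.4)
            # planted ratio = planted level / analytic spine crossing width
            w_true = 2 * tr["spine_sigmas"] * np.sqrt(
                2 * np.log(tr["spine_heights"] / 0.15))
            for c, lvl, w in zip(tr["spine_centers"], tr["protein_levels"],
                                 w_true):
                k = np.argmin(np.abs(sp.centers - c))
                if abs(sp.centers[k] - c) < 0.3 and np.isfinite(ratios[k]):
                    planted.append(lvl / w)
                    recovered.append(ratios[k])
        assert len(planted) > 20
        assert spearmanr(planted, recovered).statistic > 0.8


class TestFitScalingFactor:
    def test_exact_pair_recovers_factor_with_zero_ks(self):
        rng = np.random.default_rng(4)
        control = rng.lognormal(0, 0.4, 300)
        fit = fit_scaling_factor(control, 0.8 * control)
        assert fit.factor == pytest.approx(0.8, abs=1e-9)
        assert fit.ks_distance < 1e-12

    def test_identical_distributions_factor_one(self):
        rng = np.random.default_rng(5)
        control = rng.lognormal(0, 0.4, 300)
        fit = fit_scaling_factor(control, control.copy())
        assert fit.factor == pytest.approx(1.0, abs=1e-9)

    def test_noisy_resampled_factor_recovered(self):
        spec = GeneratorSpec(seed=33)
        control, stim = gen_scaled_pair(spec, n=500, factor=0.75,
                                        noise_cv=0.05)
        fit = fit_scaling_factor(control, stim)
        assert 0.72 <= fit.factor <= 0.78

    def test_objective_no_worse_than_seed(self):
        """KS at the returned factor <= KS at the median-ratio seed."""
        from scipy.stats import ks_2samp
        spec = GeneratorSpec(seed=34)
        control, stim = gen_scaled_pair(spec, n=200, factor=0.9, noise_cv=0.1)
        fit = fit_scaling_factor(control, stim)
        ks_seed = ks_2samp(fit.seed_factor * control, stim).statistic
        assert fit.ks_distance <= ks_seed + 1e-12

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            fit_scaling_factor(np.array([1.0, -1.0]), np.array([1.0]))


class TestStructuralEI:
    def test_equal_integrals_ratio_one(self):
        y = np.full(500, 2 * BG)
        assert structural_ei(profile(y), profile(y, channel="VGAT")
                             ).ratio == pytest.approx(1.0)

    def test_two_to_one_ratio(self):
        spine = profile(np.full(501, 3 * BG))   # normalized integral 3*L
        vgat = profile(np.full(501, 1.5 * BG), channel="VGAT")
        assert structural_ei(spine, vgat).ratio == pytest.approx(2.0)

    def test_planted_ratio_recovered(self):
        spec = GeneratorSpec(seed=35)
        pairs, truth = gen_ei_profile_pair(spec, target_ratio=0.6,
                                           n_dendrites=30)
        ratios = [structural_ei(s, v).ratio for s, v in pairs]
        assert np.mean(ratios) == pytest.approx(0.6, rel=0.10)


class TestCfos:
    def test_fraction_above_background_margin(self):
        vals = np.array([1.0, 1.1, 1.3]) * BG
        _, frac = cfos_quantify(vals, BG)
        assert frac == pytest.approx(1 / 3)

    def test_all_below_margin(self):
        _, frac = cfos_quantify(np.array([0.9, 1.0, 1.19]) * BG, BG)
        assert frac == 0.0

    def test_planted_positive_fraction_recovered(self, rng):
        n = 300
        pos = rng.uniform(size=n) < 0.4
        vals = np.where(pos, 1.5 * BG, 1.05 * BG)
        _, frac = cfos_quantify(vals, BG)
        se = np.sqrt(0.4 * 0.6 / n)
        assert frac == pytest.approx(0.4, abs=3 * se)

    def test_weak_strong_split_against_control_pool(self, rng):
        vals = rng.lognormal(0, 0.3, 200) * BG
        pool = rng.lognormal(0, 0.3, 500)
        pool = pool / pool.mean()
        measures, _ = cfos_quantify(vals, BG, control_pool=pool)
        labels = np.array([m.expression for m in measures])
        assert set(labels) <= {"weak", "strong"}
        assert 0.1 < np.mean(labels == "weak") < 0.5

    def test_bootstrap_all_positive_degenerate(self):
        out = cfos_bootstrap(np.ones(50, dtype=bool), rng=0)
        assert np.all(out["replicates"] == 100.0)
        out1 = cfos_bootstrap(np.array([True]), rng=0)
        assert np.all(out1["replicates"] == 100.0)

    def test_bootstrap_binomial_sd(self):
        """Replicate s.d. approximates sqrt(p(1-p)/batch)*100 at p=0.5."""
        flags = np.array([True] * 100 + [False] * 100)
        out = cfos_bootstrap(flags, n_boot=500, batch=10, rng=1)
        expected_sd = np.sqrt(0.25 / 10) * 100
        assert out["sd"] == pytest.approx(expected_sd, rel=0.10)
        assert out["mean"] == pytest.approx(50.0, abs=3 * expected_sd / np.sqrt(500) * 10)

    def test_bootstrap_mean_converges(self):
        rng = np.random.default_rng(2)
        flags = rng.uniform(size=173) < 0.37
        p_emp = flags.mean() * 100
        out = cfos_bootstrap(flags, n_boot=10_000, batch=10, rng=3)
        assert abs(out["mean"] - p_emp) < 1.0

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            cfos_quantify(np.array([]), BG)
        with pytest.raises(ValueError):
            cfos_bootstrap(np.array([], dtype=bool))
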