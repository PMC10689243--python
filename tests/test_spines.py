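"""Tests for dendrite subtraction, visual responsivity and spatial clustering."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from homeoplast.spines import (SpineRecord, clustering_probability,
                               classify_responsivity, fit_dendrite_scaling,
                               subtract_dendrite, timelocked_fraction)
from homeoplast.synth import GeneratorSpec, gen_spine_dendrite
from homeoplast.traces import (ActivitySummary, DffTrace, StimulusSchedule,
                               detect_events)


def dff(values, rate=30.0):
    return DffTrace(values=np.asarray(values, dtype=float), rate_hz=rate)


def events_trace(onsets_s, rate=30.0, duration_s=100.0, amp=60.0, tau=1.5):
    v = np.zeros(int(duration_s * rate))
    kern = amp * np.exp(-np.arange(int(3 * tau * rate)) / (tau * rate))
    for t in onsets_s:
        k = int(t * rate)
        v[k:k + kern.size] += kern[:max(v.size - k, 0)][:v.size - k]
    v[v < 15.0] = 0.0
    return dff(v, rate)


class TestFitDendriteScaling:
    def test_exact_mixture_recovered(self):
        d = events_trace([5, 20, 40, 60, 80])
        s = dff(0.5 * d.values)
        assert fit_dendrite_scaling(s, d) == pytest.approx(0.5, abs=1e-9)

    def test_silent_dendrite_gives_zero(self):
        d = dff(np.zeros(300))
        s = events_trace([2.0], duration_s=10.0)
        assert fit_dendrite_scaling(s, d) == 0.0

    def test_kappa_clipped_at_zero(self):
        d = events_trace([5, 20, 40])
        s = dff(np.maximum(30.0 - 0.3 * d.values, 0.0))
        assert fit_dendrite_scaling(s, d) == 0.0

    def test_generator_mixture_recovered(self):
        spec = GeneratorSpec(seed=21)
        records, truth = gen_spine_dendrite(spec, n_spines=12, kappa=0.7,
                                            duration_s=200.0)
        kappas = [fit_dendrite_scaling(r.spine_trace, r.dendrite_trace)
                  for r in records]
        assert 0.6 <= np.median(kappas) <= 0.8


class TestSubtractDendrite:
    def test_pure_backpropagation_removed(self):
        d = events_trace([5, 20, 40, 60, 80])
        rec = SpineRecord(spine_trace=dff(0.7 * d.values), dendrite_trace=d,
                          kappa=0.7)
        corrected = subtract_dendrite(rec)
        assert np.all(corrected.values == 0.0)

    def test_spine_only_events_preserved(self):
        s = events_trace([10, 30, 50])
        rec = SpineRecord(spine_trace=s, dendrite_trace=dff(np.zeros_like(s.values)))
        corrected = subtract_dendrite(rec)
        np.testing.assert_allclose(corrected.values, s.values)
        assert rec.kappa == 0.0  # fitted on the fly

    def test_subtraction_bounds(self):
        """Corrected trace is pointwise <= spine and >= 0."""
        spec = GeneratorSpec(seed=3)
        records, _ = gen_spine_dendrite(spec, n_spines=5, kappa=0.6,
                                        duration_s=100.0)
        for rec in records:
            corrected = subtract_dendrite(rec)
            assert np.all(corrected.values <= rec.spine_trace.values + 1e-12)
            assert np.all(corrected.values >= 0.0)

    def test_mixed_events_separated(self):
        """10 spine-only + 10 coincident events: the spine-only ones
        survive, the dendrite-coincident ones are removed."""
        spine_onsets = np.arange(5, 100, 10.0)          # 10 spine-only
        dend_onsets = np.arange(110, 205, 10.0)         # 10 dendrite events
        d = events_trace(dend_onsets, duration_s=210.0)
        s_only = events_trace(spine_onsets, duration_s=210.0)
        rng = np.random.default_rng(0)
        mix = np.maximum(
            s_only.values + 0.7 * d.values + rng.normal(0, 4.0, d.values.size),
            0.0)
        mix[mix < 15.0] = 0.0
        rec = SpineRecord(spine_trace=dff(mix), dendrite_trace=d)
        det = detect_events(subtract_dendrite(rec))
        n_true = sum(np.any(np.abs(det.event_times - t) < 1.0)
                     for t in spine_onsets)
        n_spurious = sum(np.any(np.abs(det.event_times - t) < 1.0)
                         for t in dend_onsets)
        assert n_true >= 9
        assert n_spurious <= 1


class TestTimelockedFraction:
    def test_partial_response_fraction(self):
        """48 stimulus events with responses on 20 of them."""
        sched = StimulusSchedule.flicker_trial(n_events=48)
        onsets = [s + 0.5 for s, _ in sched.on_epochs()[:20]]
        summary = ActivitySummary(auc_per_s=0.0,
                                  event_amplitudes=np.ones(20),
                                  event_times=np.asarray(onsets),
                                  frequency_hz=0.0)
        frac = timelocked_fraction(summary, sched)
        assert frac == pytest.approx(20 / 48, abs=1e-12)
        assert frac == pytest.approx(0.4167, abs=5e-5)

    def test_full_response_is_visual_at_any_threshold(self):
        sched = StimulusSchedule.flicker_trial(n_events=10)
        tr = events_trace([s + 0.2 for s, _ in sched.on_epochs()],
                          duration_s=50.0)
        assert timelocked_fraction(tr, sched) == 1.0

    def test_no_stimulus_epochs_rejected(self):
        sched = StimulusSchedule(epochs=[(0, 10, "dark")])
        with pytest.raises(ValueError):
            timelocked_fraction(events_trace([1.0], duration_s=10), sched)


class TestClassifyResponsivity:
    def test_null_population_calibration(self):
        """Spines with no stimulus coupling: visual-label rate stays at or
        below the 80th-percentile construction (~20%)."""
        spec = GeneratorSpec(seed=5)
        sched = StimulusSchedule.flicker_trial(n_events=48)
        stim_recs, _ = gen_spine_dendrite(spec, 200, kappa=0.0, coupling=0.0,
                                          schedule=sched)
        dark_spec = GeneratorSpec(seed=6)
        dark_recs, _ = gen_spine_dendrite(dark_spec, 200, kappa=0.0,
                                          duration_s=240.0)
        results = classify_responsivity(
            [r.spine_trace for r in stim_recs], sched,
            [r.spine_trace for r in dark_recs])
        rate = np.mean([r.label == "visual" for r in results])
        se = np.sqrt(0.2 * 0.8 / 200)
        assert rate <= 0.20 + 2 * se

    def test_coupling_monotonicity(self):
        """Time-locked fraction rises with planted coupling strength."""
        spec = GeneratorSpec(seed=7)
        sched = StimulusSchedule.flicker_trial(n_events=20)
        levels = [0.0, 0.25, 0.5, 0.75, 1.0]
        coup = np.repeat(levels, 20)
        recs, _ = gen_spine_dendrite(spec, coup.size, kappa=0.0,
                                     coupling=coup, schedule=sched)
        fracs = [timelocked_fraction(r.spine_trace, sched) for r in recs]
        rho = spearmanr(coup, fracs).statistic
        assert rho > 0
        means = [np.mean([f for f, c in zip(fracs, coup) if c == l])
                 for l in levels]
        assert means[-1] > means[0]

    def test_label_follows_conjunctive_threshold(self):
        sched = StimulusSchedule.flicker_trial(n_events=10)
        responder = events_trace([s + 0.2 for s, _ in sched.on_epochs()],
                                 duration_s=50.0)
        silent = dff(np.zeros_like(responder.values))
        results = classify_responsivity([responder, silent], sched,
                                        [silent, silent])
        assert results[0].label == "visual"
        assert results[1].label == "nonvisual"
        assert results[0].min_fraction == 0.20


class TestClusteringProbability:
    def test_uniform_labels_probability_one(self):
        out = clustering_probability(["v"] * 6, n_shuffles=10, rng=0)
        np.testing.assert_allclose(out.match_probability, 1.0)

    def test_alternating_labels(self):
        out = clustering_probability(list("vnvnvnvn"), n_shuffles=10, rng=0)
        assert out.match_probability[0] == 0.0   # offset 1
        assert out.match_probability[1] == 1.0   # offset 2

    def test_single_spine_rejected(self):
        with pytest.raises(ValueError):
            clustering_probability(["v"])

    def test_random_labels_closed_form(self):
        """p(match at offset 1) = p^2 + (1-p)^2 for iid labels (p = 0.3)."""
        rng = np.random.default_rng(8)
        probs = []
        for _ in range(1000):
            labels = np.where(rng.uniform(size=8) < 0.3, "v", "n")
            out = clustering_probability(labels, max_offset=1, n_shuffles=1,
                                         rng=rng)
            probs.append(out.match_probability[0])
        expected = 0.3 ** 2 + 0.7 ** 2
        assert np.mean(probs) == pytest.approx(expected, abs=0.02)

    def test_shuffle_null_covers_exchangeable_labels(self):
        """For exchangeable labels the observed offset-1 match rate falls in
        the central 95% of its shuffle distribution >= 90% of branches."""
        rng = np.random.default_rng(9)
        covered = 0
        n_branches = 100
        for _ in range(n_branches):
            labels = np.where(rng.uniform(size=10) < 0.4, "v", "n")
            out = clustering_probability(labels, max_offset=1, n_shuffles=200,
                                         rng=rng)
            lo, hi = np.percentile(out.shuffled[:, 0], [2.5, 97.5])
            covered += lo <= out.match_probability[0] <= hi
        assert covered / n_branches >= 0.90
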