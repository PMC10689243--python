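"""Synthetic data with known ground truth for every pipeline input.

The generators emulate the statistical structure the analyses assume:
GCaMP6s-like slow calcium transients (single-exponential decay, 1.5 s)
on noisy drifting baselines; paired spine/dendrite traces mixed with a
known dendritic coefficient and known visual coupling; miniature-event
trains with exponential inter-event intervals and lognormal
amplitudes; 1-D dendritic intensity profiles with Gaussian spine/
puncta bumps of known width and density; and session-wise Bernoulli
touchscreen outcomes with a known learning slope.

Scenario presets plant effect directions matching the overstimulation
biology: in young adults overstimulation suppresses activity, shrinks
spines/mEPSPs, raises inhibitory event frequency and VGAT density and
strengthens excitatory-inhibitory coupling; in late adults the same
stimulus elevates activity, enlarges spines/mEPSPs, weakens the
inhibitory response and strengthens excitatory-excitatory coupling.
Effect sizes are round numbers serving as recovery-test ground truth,
not claims about real data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .behavior import RcptSession
from .ephys import MiniTrain, VoltageTrace
from .spines import SpineRecord
from .structure import IntensityProfile
from .traces import DffTrace, RawTrace, StimulusSchedule

__all__ = [
    "GeneratorSpec",
    "SCENARIOS",
    "gen_cell_traces",
    "gen_spine_dendrite",
    "gen_minis",
    "gen_voltage",
    "gen_profiles",
    "gen_ei_profile_pair",
    "gen_scaled_pair",
    "gen_population",
    "gen_rcpt",
]

# Per-scenario planted effects (multiplicative factors / additive shifts
# relative to control). Directions follow the overstimulation biology
# summarized in the module docstring.
SCENARIOS: dict[str, dict[str, float]] = {
    "young_control": {},
    "young_stim": dict(activity_factor=0.7, spine_scaling_factor=0.8,
                       mepsp_amp_factor=0.8, mipsp_freq_factor=1.5,
                       vgat_density_factor=1.3, ei_corr_shift=0.15,
                       ee_corr_shift=0.0, rcpt_slope=0.05),
    "old_control": {},
    "old_stim": dict(activity_factor=1.3, spine_scaling_factor=1.2,
                     mepsp_amp_factor=1.2, mipsp_freq_factor=0.8,
                     vgat_density_factor=0.85, ee_corr_shift=0.15,
                     ei_corr_shift=0.0, rcpt_slope=0.02),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Master configuration of the synthetic cohort.

    Factors are multiplicative against the control condition;
    correlation shifts are additive on the planted channel correlation.
    """

    seed: int = 0
    scenario: str = "young_control"
    # planted effects
    activity_factor: float = 1.0       # post-stim calcium event-rate multiplier
    spine_scaling_factor: float = 1.0  # multiplicative spine-size factor
    mepsp_amp_factor: float = 1.0
    mipsp_freq_factor: float = 1.0
    vgat_density_factor: float = 1.0
    ee_corr_shift: float = 0.0
    ei_corr_shift: float = 0.0
    rcpt_slope: float = 0.05           # performance units per session
    # noise / kinetics
    calcium_tau_s: float = 1.5         # GCaMP6s-like decay time constant
    trace_noise_sd: float = 2.0        # a.u. on raw fluorescence
    drift_amplitude: float = 10.0      # a.u., slow baseline drift
    dff_noise_pct: float = 4.0         # %dF/F0 noise on synthetic spine traces
    measurement_cv: float = 0.05

    @classmethod
    def for_scenario(cls, scenario: str, seed: int = 0, **overrides
                     ) -> "GeneratorSpec":
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}")
        kw = dict(SCENARIOS[scenario])
        kw.update(overrides)
        return cls(seed=seed, scenario=scenario, **kw)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent reproducible substream per generator."""
        return np.random.default_rng([self.seed, stream])


def _exp_kernel(tau_s: float, rate_hz: float) -> np.ndarray:
    n = max(int(round(5 * tau_s * rate_hz)), 2)
    return np.exp(-np.arange(n) / (tau_s * rate_hz))


def _event_signal(event_times: np.ndarray, amplitudes: np.ndarray,
                  n_frames: int, rate_hz: float, tau_s: float) -> np.ndarray:
    """Sum of exponential-decay transients on a frame grid."""
    impulses = np.zeros(n_frames)
    idx = np.floor(event_times * rate_hz).astype(int)
    ok = (idx >= 0) & (idx < n_frames)
    np.add.at(impulses, idx[ok], amplitudes[ok])
    return np.convolve(impulses, _exp_kernel(tau_s, rate_hz))[:n_frames]


def _poisson_times(rng: np.random.Generator, rate_hz: float,
                   duration_s: float) -> np.ndarray:
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def gen_cell_traces(spec: GeneratorSpec, n_cells: int,
                    schedule: StimulusSchedule,
                    rate_hz: float = 7.0,
                    base_rate_hz: float = 0.1,
                    visual_rate_gain: float = 2.0,
                    tuning_range: tuple[float, float] = (0.0, 1.0),
                    baseline_f: float = 100.0,
                    background_f: float = 20.0,
                    event_amp: float = 60.0,
                    ) -> tuple[list[RawTrace], RawTrace, dict]:
    """Raw ROI fluorescence for a cell population plus a background ROI.

    Each cell fires calcium events as an inhomogeneous Poisson process:
    rate ``base_rate_hz * activity_factor`` in the dark, multiplied by
    ``1 + visual_rate_gain * tuning`` during flicker-on epochs (tuning
    ~ U(*tuning_range*) per cell).  Events convolve with the exponential calcium
    kernel; the trace adds baseline, sinusoidal drift and Gaussian
    noise.  Returns the traces, the background ROI trace and a truth
    dict (event times, tuning, rates).
    """
    rng = spec.rng(1)
    duration_s = max(e for _, e, _ in schedule.epochs)
    n_frames = int(round(duration_s * rate_hz))
    t = np.arange(n_frames) / rate_hz
    on = np.zeros(n_frames, dtype=bool)
    for s, e in schedule.on_epochs():
        on |= (t >= s) & (t < e)

    traces, truth_cells = [], []
    for c in range(n_cells):
        tuning = rng.uniform(*tuning_range)
        r_dark = base_rate_hz * spec.activity_factor
        r_on = r_dark * (1.0 + visual_rate_gain * tuning)
        # thin a homogeneous train at the max rate by the epoch-wise rate
        cand = _poisson_times(rng, r_on, duration_s)
        if cand.size:
            idx = np.minimum((cand * rate_hz).astype(int), n_frames - 1)
            keep = np.where(on[idx], True, rng.uniform(size=cand.size) < r_dark / r_on)
            events = cand[keep]
        else:
            events = cand
        amps = event_amp * rng.lognormal(0.0, 0.3, size=events.size)
        signal = _event_signal(events, amps, n_frames, rate_hz,
                               spec.calcium_tau_s)
        drift = spec.drift_amplitude * np.sin(2 * np.pi * t / (duration_s * 2.0)
                                              + rng.uniform(0, 2 * np.pi))
        values = (baseline_f + background_f + drift + signal
                  + rng.normal(0.0, spec.trace_noise_sd, size=n_frames))
        traces.append(RawTrace(values=values, rate_hz=rate_hz,
                               roi_id=f"cell{c:03d}", roi_kind="cell"))
        truth_cells.append({"tuning": tuning, "event_times": events,
                            "rate_dark_hz": r_dark, "rate_on_hz": r_on})
    background = RawTrace(
        values=background_f + rng.normal(0.0, spec.trace_noise_sd / 2,
                                         size=n_frames),
        rate_hz=rate_hz, roi_id="background", roi_kind="background")
    return traces, background, {"cells": truth_cells,
                                "activity_factor": spec.activity_factor}


def gen_spine_dendrite(spec: GeneratorSpec, n_spines: int,
                       kappa: float = 0.7,
                       coupling: float | Sequence[float] = 0.0,
                       schedule: StimulusSchedule | None = None,
                       duration_s: float | None = None,
                       rate_hz: float = 30.0,
                       spont_rate_hz: float = 0.08,
                       dendrite_rate_hz: float = 0.15,
                       spine_amp: float = 60.0,
                       dendrite_amp: float = 80.0,
                       threshold_pct: float = 15.0,
                       branch_id: str = "branch0",
                       ) -> tuple[list[SpineRecord], dict]:
    """Paired spine/dendrite ΔF/F0 traces with a known mixing coefficient.

    The spine trace is spine-only events plus ``kappa`` times the
    dendrite trace plus Gaussian noise, floored at 0 and thresholded.
    With a ``schedule``, each spine additionally responds to each
    flicker-on epoch with probability equal to its coupling (uniformly
    jittered onset within the epoch); ``coupling`` may be a scalar or
    one value per spine.  Without a schedule the period is dark
    (spontaneous only) of length ``duration_s``.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = spec.rng(2)
    if schedule is not None:
        duration_s = max(e for _, e, _ in schedule.epochs)
    if duration_s is None:
        raise ValueError("need schedule or duration_s")
    n_frames = int(round(duration_s * rate_hz))
    coup = np.broadcast_to(np.asarray(coupling, dtype=float), (n_spines,))

    records, truth_spines = [], []
    for k in range(n_spines):
        dend_events = _poisson_times(rng, dendrite_rate_hz, duration_s)
        dend_amps = dendrite_amp * rng.lognormal(0.0, 0.25, size=dend_events.size)
        dend = _event_signal(dend_events, dend_amps, n_frames, rate_hz,
                             spec.calcium_tau_s)
        dend_vals = dend.copy()
        dend_vals[dend_vals < threshold_pct] = 0.0

        spine_events = list(_poisson_times(rng, spont_rate_hz, duration_s))
        if schedule is not None and coup[k] > 0:
            for s, e in schedule.on_epochs():
                if rng.uniform() < coup[k]:
                    spine_events.append(rng.uniform(s, min(e, s + 1.0)))
        spine_events = np.sort(np.asarray(spine_events))
        spine_amps = spine_amp * rng.lognormal(0.0, 0.25,
                                               size=spine_events.size)
        spine_only = _event_signal(spine_events, spine_amps, n_frames,
                                   rate_hz, spec.calcium_tau_s)
        mix = (spine_only + kappa * dend
               + rng.normal(0.0, spec.dff_noise_pct, size=n_frames))
        mix = np.maximum(mix, 0.0)
        mix[mix < threshold_pct] = 0.0

        records.append(SpineRecord(
            spine_trace=DffTrace(values=mix, rate_hz=rate_hz,
                                 threshold_pct=threshold_pct,
                                 roi_id=f"spine{k:03d}"),
            dendrite_trace=DffTrace(values=dend_vals, rate_hz=rate_hz,
                                    threshold_pct=threshold_pct,
                                    roi_id=f"dend{k:03d}"),
            branch_id=branch_id, position_index=k))
        truth_spines.append({"coupling": float(coup[k]),
                             "spine_event_times": spine_events,
                             "dendrite_event_times": dend_events})
    return records, {"kappa": kappa, "spines": truth_spines}


def gen_minis(spec: GeneratorSpec, n_cells: int, duration_s: float = 60.0,
              epsp_rate_hz: float = 2.0, epsp_amp_mv: float = 0.5,
              ipsp_rate_hz: float = 3.0, ipsp_amp_mv: float = 0.6,
              amp_sigma: float = 0.3,
              ) -> tuple[list[dict[str, MiniTrain]], dict]:
    """Miniature-event trains per cell: exponential IEIs, lognormal amplitudes.

    The scenario scales mEPSP amplitude by ``mepsp_amp_factor`` and
    mIPSP frequency by ``mipsp_freq_factor``; mEPSP frequency and mIPSP
    amplitude are left at control values (the channels the biology
    leaves untouched).
    """
    rng = spec.rng(3)
    e_amp = epsp_amp_mv * spec.mepsp_amp_factor
    i_rate = ipsp_rate_hz * spec.mipsp_freq_factor
    cells = []
    for _ in range(n_cells):
        et = _poisson_times(rng, epsp_rate_hz, duration_s)
        it = _poisson_times(rng, i_rate, duration_s)
        cells.append({
            "epsp": MiniTrain(
                event_times=et,
                amplitudes=e_amp * rng.lognormal(0.0, amp_sigma, size=et.size)
                / np.exp(amp_sigma ** 2 / 2),
                polarity="excitatory", duration_s=duration_s),
            "ipsp": MiniTrain(
                event_times=it,
                amplitudes=ipsp_amp_mv * rng.lognormal(0.0, amp_sigma, size=it.size)
                / np.exp(amp_sigma ** 2 / 2),
                polarity="inhibitory", duration_s=duration_s),
        })
    truth = {"epsp_rate_hz": epsp_rate_hz, "epsp_amp_mv": e_amp,
             "ipsp_rate_hz": i_rate, "ipsp_amp_mv": ipsp_amp_mv}
    return cells, truth


def gen_voltage(rng: np.random.Generator | int, duration_s: float,
                event_times: np.ndarray, amplitudes_mv: np.ndarray | float,
                noise_rms_mv: float = 0.05, rate_hz: float = 20_000.0,
                tau_rise_s: float = 1e-3, tau_decay_s: float = 8e-3,
                baseline_mv: float = -70.0) -> VoltageTrace:
    """Voltage trace with planted synaptic events in Gaussian noise.

    Events have a difference-of-exponentials shape normalized to unit
    peak, so ``amplitudes_mv`` is the true peak deflection.
    """
    rng = np.random.default_rng(rng)
    n = int(round(duration_s * rate_hz))
    t = np.arange(int(round(6 * tau_decay_s * rate_hz))) / rate_hz
    kern = np.exp(-t / tau_decay_s) - np.exp(-t / tau_rise_s)
    kern /= kern.max()
    amps = np.broadcast_to(np.asarray(amplitudes_mv, dtype=float),
                           np.asarray(event_times).shape)
    impulses = np.zeros(n)
    idx = np.floor(np.asarray(event_times) * rate_hz).astype(int)
    ok = (idx >= 0) & (idx < n)
    np.add.at(impulses, idx[ok], amps[ok])
    signal = np.convolve(impulses, kern)[:n]
    values = baseline_mv + signal + rng.normal(0.0, noise_rms_mv, size=n)
    return VoltageTrace(values=values, rate_hz=rate_hz, condition="mEPSP")


def _gaussian_bumps(x: np.ndarray, centers: np.ndarray, sigmas: np.ndarray,
                    heights: np.ndarray) -> np.ndarray:
    y = np.zeros_like(x)
    for c, s, h in zip(centers, sigmas, heights):
        y += h * np.exp(-0.5 * ((x - c) / s) ** 2)
    return y


def _placed_centers(rng: np.random.Generator, n: int, length: float,
                    min_sep: float) -> np.ndarray:
    """n centers on (margin, length - margin) at least min_sep apart."""
    slots = np.linspace(min_sep, length - min_sep, n)
    jitter = rng.uniform(-0.3, 0.3, size=n) * min_sep
    return np.sort(slots + jitter)


def gen_profiles(spec: GeneratorSpec, n_dendrites: int,
                 length_um: float = 20.0, dx_um: float = 0.05,
                 spine_density_per_um: float = 0.4,
                 vgat_density_per_um: float = 0.6,
                 background: float = 100.0,
                 spine_sigma_um: float = 0.3,
                 protein_level: float = 2.0,
                 ) -> tuple[list[dict[str, IntensityProfile]], dict]:
    """1-D intensity profiles per dendrite: spine, VGAT and protein channels.

    Spine bumps are Gaussians whose widths scale with the scenario's
    ``spine_scaling_factor`` (the spine-size proxy); VGAT puncta count
    scales with ``vgat_density_factor``.  The protein channel places a
    bump at every spine center with a planted per-spine level
    (lognormal, measurement noise ``measurement_cv``).
    """
    rng = spec.rng(4)
    x = np.arange(0.0, length_um + dx_um / 2, dx_um)
    dendrites, truth = [], []
    n_spines = int(round(spine_density_per_um * length_um))
    n_vgat = int(round(vgat_density_per_um * spec.vgat_density_factor
                       * length_um))
    for _ in range(n_dendrites):
        centers = _placed_centers(rng, n_spines, length_um, min_sep=1.0)
        sigmas = (spine_sigma_um * spec.spine_scaling_factor
                  * rng.uniform(0.8, 1.2, size=n_spines))
        heights = background * rng.uniform(0.5, 2.0, size=n_spines)
        spine = IntensityProfile(
            positions=x,
            intensity=background + _gaussian_bumps(x, centers, sigmas, heights)
            + rng.normal(0, background * 0.02, size=x.size),
            background_level=background, channel="eGFP")

        v_centers = np.sort(rng.uniform(0.3, length_um - 0.3, size=n_vgat))
        vgat = IntensityProfile(
            positions=x,
            intensity=background + _gaussian_bumps(
                x, v_centers, np.full(n_vgat, 0.15),
                background * rng.uniform(0.6, 1.5, size=n_vgat))
            + rng.normal(0, background * 0.02, size=x.size),
            background_level=background, channel="VGAT")

        levels = protein_level * rng.lognormal(0.0, 0.4, size=n_spines)
        measured = levels * (1 + rng.normal(0, spec.measurement_cv,
                                            size=n_spines))
        protein = IntensityProfile(
            positions=x,
            intensity=background * (1 + _gaussian_bumps(
                x, centers, np.full(n_spines, 0.2), measured)) / 1.0,
            background_level=background, channel="GluA2")

        dendrites.append({"spine": spine, "vgat": vgat, "protein": protein})
        truth.append({"spine_centers": centers, "spine_sigmas": sigmas,
                      "spine_heights": heights / background,
                      "vgat_centers": v_centers,
                      "protein_levels": levels})
    return dendrites, {"dendrites": truth, "n_spines": n_spines,
                       "n_vgat": n_vgat,
                       "scaling_factor": spec.spine_scaling_factor}


def gen_ei_profile_pair(spec: GeneratorSpec, target_ratio: float,
                        n_dendrites: int = 1, length_um: float = 20.0,
                        dx_um: float = 0.05, background: float = 100.0,
                        ) -> tuple[list[tuple[IntensityProfile, IntensityProfile]], dict]:
    """Spine/VGAT profile pairs with a planted structural E:I ratio.

    The VGAT channel carries bump area equal to the profile length (in
    background-normalized units); the spine channel's bump area is set
    so that (length + spine area) / (length + VGAT area) equals
    ``target_ratio`` in expectation, with ``measurement_cv`` noise on
    each dendrite's bump heights.
    """
    if target_ratio <= 0:
        raise ValueError("target_ratio must be positive")
    rng = spec.rng(5)
    x = np.arange(0.0, length_um + dx_um / 2, dx_um)
    vgat_area = length_um                       # normalized units * um
    spine_area = target_ratio * (length_um + vgat_area) - length_um
    if spine_area <= 0:
        raise ValueError("target_ratio too small for this profile length")
    pairs = []
    for _ in range(n_dendrites):
        out = []
        for channel, total_area, n_bumps, sig in (
                ("eGFP", spine_area, 8, 0.3), ("VGAT", vgat_area, 12, 0.15)):
            centers = _placed_centers(rng, n_bumps, length_um, min_sep=0.8)
            h = total_area / (n_bumps * sig * np.sqrt(2 * np.pi))
            heights = h * (1 + rng.normal(0, spec.measurement_cv, size=n_bumps))
            out.append(IntensityProfile(
                positions=x,
                intensity=background * (1 + _gaussian_bumps(
                    x, centers, np.full(n_bumps, sig), heights)),
                background_level=background, channel=channel))
        pairs.append(tuple(out))
    return pairs, {"target_ratio": target_ratio}


def gen_scaled_pair(spec: GeneratorSpec, n: int, factor: float,
                    noise_cv: float = 0.0, mu: float = 0.0,
                    sigma: float = 0.4) -> tuple[np.ndarray, np.ndarray]:
    """Control values ~ lognormal(mu, sigma) and a multiplicatively
    scaled stim population.

    With ``noise_cv == 0`` the stim sample is exactly
    ``factor * control`` (an exact multiplicative pair); otherwise it
    is resampled with replacement and perturbed by lognormal-preserving
    multiplicative noise.
    """
    rng = spec.rng(6)
    control = rng.lognormal(mu, sigma, size=n)
    if noise_cv > 0:
        stim = factor * rng.choice(control, size=n, replace=True)
        stim = np.abs(stim * (1 + rng.normal(0, noise_cv, size=n)))
    else:
        stim = factor * control
    return control, stim


def gen_population(spec: GeneratorSpec, n_exc: int = 12, n_inh: int = 6,
                   n_frames: int = 1000, rate_hz: float = 30.0,
                   rho_ee: float = 0.50, rho_ei: float = 0.30,
                   rho_ii: float = 0.50, session: str = "baseline",
                   ) -> tuple[dict[str, DffTrace], dict[str, str], dict]:
    """Population traces with planted block correlation structure.

    Excitatory traces load on a shared excitatory factor and a global
    factor; inhibitory traces on an inhibitory and the global factor.
    Loadings are chosen so the expected pairwise Pearson correlations
    are ``rho_ee`` within excitatory cells, ``rho_ii`` within
    inhibitory cells and ``rho_ei`` across classes; in the post-stim
    session the scenario's ``ee_corr_shift``/``ei_corr_shift`` are
    added to the planted channel values.  Traces are shifted to be
    positive (thresholded signals), which leaves correlations intact.
    """
    if session == "poststim":
        rho_ee = rho_ee + spec.ee_corr_shift
        rho_ei = rho_ei + spec.ei_corr_shift
    rng = spec.rng(7 if session == "baseline" else 8)
    b = np.sqrt(rho_ei)          # loading on the global factor, both classes
    a = np.sqrt(rho_ee - b ** 2) if rho_ee > b ** 2 else 0.0
    c = np.sqrt(rho_ii - b ** 2) if rho_ii > b ** 2 else 0.0
    if rho_ee < b ** 2 - 1e-12 or rho_ii < b ** 2 - 1e-12:
        raise ValueError("rho_ee and rho_ii must be >= rho_ei")
    f_e = rng.normal(size=n_frames)
    f_i = rng.normal(size=n_frames)
    g = rng.normal(size=n_frames)
    traces: dict[str, DffTrace] = {}
    classes: dict[str, str] = {}
    for k in range(n_exc):
        resid = np.sqrt(max(1 - a ** 2 - b ** 2, 0.0))
        z = a * f_e + b * g + resid * rng.normal(size=n_frames)
        traces[f"e{k:02d}"] = DffTrace(values=20 * (z + 5), rate_hz=rate_hz)
        classes[f"e{k:02d}"] = "excitatory"
    for k in range(n_inh):
        resid = np.sqrt(max(1 - c ** 2 - b ** 2, 0.0))
        z = c * f_i + b * g + resid * rng.normal(size=n_frames)
        traces[f"i{k:02d}"] = DffTrace(values=20 * (z + 5), rate_hz=rate_hz)
        classes[f"i{k:02d}"] = "inhibitory"
    return traces, classes, {"rho_ee": rho_ee, "rho_ei": rho_ei,
                             "rho_ii": rho_ii, "session": session}


def gen_rcpt(spec: GeneratorSpec, n_animals: int, n_sessions: int = 7,
             trials_per_session: int = 100, hr0: float = 0.35,
             far0: float = 0.25) -> tuple[list[list[RcptSession]], dict]:
    """Session-wise Bernoulli rCPT outcomes with a planted learning slope.

    Half the trials present the rewarded stimulus.  The hit rate climbs
    linearly by ``rcpt_slope`` per session from ``hr0`` while the false
    alarm rate stays at ``far0``, so the planted performance slope is
    ``rcpt_slope``; counts are binomial draws.
    """
    rng = spec.rng(9)
    n_go = trials_per_session // 2
    n_nogo = trials_per_session - n_go
    animals = []
    for _ in range(n_animals):
        sessions = []
        for s in range(1, n_sessions + 1):
            hr = float(np.clip(hr0 + spec.rcpt_slope * (s - 1), 0.0, 1.0))
            hits = int(rng.binomial(n_go, hr))
            mistakes = int(rng.binomial(n_nogo, far0))
            sessions.append(RcptSession(
                hits=hits, misses=n_go - hits, mistakes=mistakes,
                correct_rejections=n_nogo - mistakes, session_index=s))
        animals.append(sessions)
    return animals, {"slope": spec.rcpt_slope, "hr0": hr0, "far0": far0}
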