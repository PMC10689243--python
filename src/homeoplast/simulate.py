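"""Two-compartment rate-neuron model of cortical overstimulation.

A single postsynaptic neuron receives feedforward somatic drive and N
plastic excitatory dendritic inputs whose visual responsiveness v_i is
drawn uniformly on [0, 1].  The postsynaptic rate r follows

    tau * dr/dt = -r + [I_soma + [I_dend]+]+

with I_soma = I_ffw + r_exc - r_inh and
I_dend = (1/N) sum_i w_i r_i - I_inh.  Weights evolve under a Hebbian
term gated by dendritic inhibition and an activity-proportional
homeostatic downscaling term:

    dw_i/dt = A1 * r_i * (r_i - r0) * r * (1 - I_inh) - A2 * r

Presynaptic rates are visually modulated during stimulus-on epochs and
recurrently coupled to the postsynaptic rate:

    r_i(t) = r0 + v_i * on(t) + alpha * r(t) + zeta_i(t)

The "young adult" regime upregulates inhibition during overstimulation
(I_inh = 0.4) and uses strong downscaling (A2 = 0.56e-4); the "late
adult" (old) regime keeps inhibition at its baseline value (0.2) and
weakens downscaling (A2 = 0.48e-4).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SimConfig",
    "SimNoise",
    "SimResult",
    "SweepResult",
    "young_config",
    "old_config",
    "draw_noise",
    "simulate",
    "weight_change_by_responsivity",
    "sweep_inhibition",
    "sweep_downscaling",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the two-compartment plasticity model.

    Rates, time constants and step counts are in the model's arbitrary
    units (explicit Euler, ``dt`` per step, network time constant
    ``tau``); stimulus on/off epochs last ``t_on``/``t_off`` steps.
    """

    tau: float = 10.0          # network integration time constant
    i_ffw: float = 0.5         # feedforward somatic input
    r0: float = 1.0            # baseline presynaptic/postsynaptic rate
    n_inputs: int = 200        # number of presynaptic excitatory inputs
    t_total: int = 10_000      # total number of Euler steps
    dt: float = 1.0            # step size
    t_on: int = 100            # stimulus-on epoch length (steps)
    t_off: int = 100           # stimulus-off epoch length (steps)
    a1: float = 1e-4           # Hebbian learning rate
    a2: float = 0.56e-4        # homeostatic downscaling rate
    i_inh_baseline: float = 0.2  # dendritic inhibition before overstimulation
    i_inh_stim: float = 0.4    # dendritic inhibition during overstimulation
    alpha: float = 0.1         # recurrent feedback of r onto presynaptic rates
    w_init_sd: float = 0.1     # s.d. of initial weight noise xi
    presyn_noise_sd: float = 0.1   # s.d. of per-step presynaptic noise zeta
    soma_noise_range: float = 0.1  # somatic aggregate noise ~ U(0, range)
    seed: int = 0
    gated_stimulus: bool = True    # v_i contributes only during t_on epochs
    rectify_presyn: bool = True    # clip presynaptic rates at 0

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        if self.t_total < 1:
            raise ValueError("t_total must be >= 1")
        if self.t_on < 1 or self.t_off < 1:
            raise ValueError("t_on and t_off must be >= 1")
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("plasticity rates must be nonnegative")
        for name in ("i_inh_baseline", "i_inh_stim"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.tau <= 0 or self.dt <= 0:
            raise ValueError("tau and dt must be positive")
        if min(self.w_init_sd, self.presyn_noise_sd, self.soma_noise_range) < 0:
            raise ValueError("noise scales must be nonnegative")


def young_config(**overrides) -> SimConfig:
    """Young-adult overstimulation regime: strong downscaling, upregulated inhibition."""
    return SimConfig(a2=0.56e-4, i_inh_stim=0.4, **overrides)


def old_config(**overrides) -> SimConfig:
    """Late-adult overstimulation regime: weak downscaling, inhibition stays at baseline."""
    return SimConfig(a2=0.48e-4, i_inh_stim=0.2, **overrides)


@dataclass
class SimNoise:
    """All random draws of one simulation, pre-generated from the config seed.

    Exposing the stream lets an independent re-implementation integrate
    the identical realization.
    """

    v: np.ndarray        # (N,) visual responsiveness ~ U(0, 1)
    xi: np.ndarray       # (N,) initial weight noise ~ N(0, w_init_sd)
    zeta: np.ndarray     # (T, N) presynaptic rate noise ~ N(0, presyn_noise_sd)
    u_exc: np.ndarray    # (T,) somatic excitatory noise ~ U(0, soma_noise_range)
    u_inh: np.ndarray    # (T,) somatic inhibitory noise ~ U(0, soma_noise_range)


def draw_noise(config: SimConfig, rng: np.random.Generator | None = None) -> SimNoise:
    """Draw every random variable of a run in a fixed, documented order."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, t = config.n_inputs, config.t_total
    return SimNoise(
        v=rng.uniform(0.0, 1.0, size=n),
        xi=rng.normal(0.0, config.w_init_sd, size=n),
        zeta=rng.normal(0.0, config.presyn_noise_sd, size=(t, n)),
        u_exc=rng.uniform(0.0, config.soma_noise_range, size=t),
        u_inh=rng.uniform(0.0, config.soma_noise_range, size=t),
    )


@dataclass
class SimResult:
    config: SimConfig
    v: np.ndarray          # (N,) per-input visual responsiveness
    w0: np.ndarray         # (N,) initial weights
    w_final: np.ndarray    # (N,) final weights
    r: np.ndarray          # (T,) postsynaptic rate trajectory
    w: np.ndarray          # (T//record_every, N) thinned weight trajectory
    r_pre: np.ndarray      # (T//record_every, N) thinned presynaptic rates
    record_every: int

    @property
    def dw(self) -> np.ndarray:
        """Per-input weight change w_i(T) - w_i(0)."""
        return self.w_final - self.w0


def _stimulus_on(t: np.ndarray | int, t_on: int, t_off: int) -> np.ndarray:
    """Boolean stimulus gate: cycles of t_on on followed by t_off off."""
    return (np.asarray(t) % (t_on + t_off)) < t_on


def simulate(config: SimConfig, noise: SimNoise | None = None,
             record_every: int = 1) -> SimResult:
    """Euler-integrate the model and return full trajectories.

    Parameters
    ----------
    config : SimConfig
    noise : SimNoise, optional
        Pre-drawn noise stream; drawn from ``config.seed`` if omitted.
    record_every : int
        Thinning for the weight / presynaptic-rate trajectories (the
        postsynaptic rate is always recorded at every step).
    """
    if noise is None:
        noise = draw_noise(config)
    n, t_total, dt = config.n_inputs, config.t_total, config.dt
    v = noise.v
    w = 1.0 + noise.xi
    w0 = w.copy()
    r = config.r0
    i_inh = config.i_inh_stim  # the run models the overstimulation phase

    n_rec = (t_total + record_every - 1) // record_every
    r_traj = np.empty(t_total)
    w_traj = np.empty((n_rec, n))
    rpre_traj = np.empty((n_rec, n))

    hebb_gain = config.a1 * (1.0 - i_inh)
    on = _stimulus_on(np.arange(t_total), config.t_on, config.t_off)

    for t in range(t_total):
        r_m = v if (on[t] or not config.gated_stimulus) else 0.0
        r_i = config.r0 + r_m + config.alpha * r + noise.zeta[t]
        if config.rectify_presyn:
            r_i = np.maximum(r_i, 0.0)

        r_exc = config.r0 + noise.u_exc[t]
        r_inh = config.r0 + noise.u_inh[t]
        i_soma = config.i_ffw + r_exc - r_inh
        i_dend = w @ r_i / n - i_inh
        drive = max(i_soma + max(i_dend, 0.0), 0.0)

        r_new = r + dt / config.tau * (-r + drive)
        dw = dt * (hebb_gain * r_i * (r_i - config.r0) * r - config.a2 * r)
        if not np.isfinite(r_new) or not np.all(np.isfinite(dw)):
            raise FloatingPointError(
                f"non-finite state at step {t}: r={r_new!r}")

        if t % record_every == 0:
            k = t // record_every
            w_traj[k] = w
            rpre_traj[k] = r_i
        w = w + dw
        r = r_new
        r_traj[t] = r

    return SimResult(config=config, v=v, w0=w0, w_final=w, r=r_traj,
                     w=w_traj, r_pre=rpre_traj, record_every=record_every)


@dataclass
class BinnedWeightChange:
    """Mean weight change per equal-width visual-responsiveness bin on [0, 1]."""

    bin_edges: np.ndarray    # (n_bins + 1,)
    bin_centers: np.ndarray  # (n_bins,)
    mean_dw: np.ndarray      # (n_bins,) NaN where empty
    counts: np.ndarray       # (n_bins,)

    @property
    def empty_bins(self) -> np.ndarray:
        return self.counts == 0


def weight_change_by_responsivity(result: SimResult, n_bins: int = 10
                                  ) -> BinnedWeightChange:
    """Bin inputs by visual responsiveness and average the weight change.

    Empty bins are reported as NaN with a zero count, never dropped.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(result.v, edges) - 1, 0, n_bins - 1)
    dw = result.dw
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=dw, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_dw = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return BinnedWeightChange(bin_edges=edges,
                              bin_centers=0.5 * (edges[:-1] + edges[1:]),
                              mean_dw=mean_dw, counts=counts)


@dataclass
class SweepResult:
    """Reinstatement sweep: binned weight change per parameter level,
    normalized bin-wise to the late-adult reference level.

    ``normalized[k, b] = mean_dw[k, b] / mean_dw[ref, b]``; bins whose
    reference change is ~0 are NaN (undefined), never infinite.
    """

    parameter: str
    levels: np.ndarray               # strictly increasing
    reference_level: float
    bin_centers: np.ndarray
    mean_dw: np.ndarray              # (n_levels, n_bins)
    normalized: np.ndarray           # (n_levels, n_bins)
    mean_final_weight: np.ndarray    # (n_levels,) across seeds and inputs
    n_seeds: int


def _run_sweep(base: SimConfig, parameter: str, levels: Sequence[float],
               reference_level: float, n_seeds: int, n_bins: int,
               record_every: int) -> SweepResult:
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("levels must be nonempty")
    if not np.all(np.diff(levels) > 0):
        raise ValueError("levels must be strictly increasing")

    seeds = np.random.SeedSequence(base.seed).spawn(n_seeds)
    n_bins_eff = n_bins
    sum_dw = np.zeros((levels.size, n_bins_eff))
    cnt_dw = np.zeros((levels.size, n_bins_eff))
    wfin = np.zeros(levels.size)
    centers = None
    for s, seed_seq in enumerate(seeds):
        for k, level in enumerate(levels):
            cfg = replace(base, **{parameter: float(level)})
            noise = draw_noise(cfg, np.random.default_rng(seed_seq))
            res = simulate(cfg, noise=noise, record_every=record_every)
            binned = weight_change_by_responsivity(res, n_bins=n_bins_eff)
            centers = binned.bin_centers
            ok = binned.counts > 0
            sum_dw[k, ok] += binned.mean_dw[ok]
            cnt_dw[k, ok] += 1
            wfin[k] += res.w_final.mean() / n_seeds

    with np.errstate(invalid="ignore"):
        mean_dw = np.where(cnt_dw > 0, sum_dw / np.maximum(cnt_dw, 1), np.nan)
    ref_idx = int(np.argmin(np.abs(levels - reference_level)))
    ref = mean_dw[ref_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(np.abs(ref) > 1e-12, mean_dw / ref, np.nan)
    return SweepResult(parameter=parameter, levels=levels,
                       reference_level=float(levels[ref_idx]),
                       bin_centers=centers, mean_dw=mean_dw,
                       normalized=normalized, mean_final_weight=wfin,
                       n_seeds=n_seeds)


def sweep_inhibition(base: SimConfig | None = None,
                     levels: Sequence[float] = (0.2, 0.3, 0.4, 0.5),
                     n_seeds: int = 20, n_bins: int = 10,
                     record_every: int = 1000) -> SweepResult:
    """Reinstate inhibitory plasticity from the late-adult value upward.

    All other parameters stay at late-adult values; runs share matched
    seed substreams across levels.
    """
    if base is None:
        base = old_config()
    if len(levels) == 0:
        raise ValueError("levels must be nonempty")
    return _run_sweep(base, "i_inh_stim", levels, reference_level=levels[0],
                      n_seeds=n_seeds, n_bins=n_bins, record_every=record_every)


def sweep_downscaling(base: SimConfig | None = None,
                      levels: Sequence[float] = (0.6e-4, 0.7e-4, 0.8e-4, 0.9e-4),
                      n_seeds: int = 20, n_bins: int = 10,
                      record_every: int = 1000) -> SweepResult:
    """Reinstate homeostatic downscaling with inhibition fixed at late-adult 0.2.

    The reference is the late-adult configuration itself (A2 = 0.48e-4),
    prepended if absent from ``levels``.
    """
    if base is None:
        base = old_config()
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("levels must be nonempty")
    if base.a2 not in levels:
        levels = np.concatenate([[base.a2], levels])
        levels.sort()
    return _run_sweep(base, "a2", levels, reference_level=base.a2,
                      n_seeds=n_seeds, n_bins=n_bins, record_every=record_every)
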