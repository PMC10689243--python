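"""Miniature synaptic event detection and the functional synaptic E:I ratio.

Miniature EPSPs/IPSPs are detected on current-clamp voltage traces
(20 kHz) as deflections of the holding-condition-appropriate sign
exceeding 2.5x the noise RMS.  Noise RMS is estimated robustly (MAD of
the high-pass residual), the trace is lightly smoothed before
thresholding, events narrower than 1 ms are rejected and events closer
than a 2 ms refractory gap are merged.  The synaptic E:I ratio is
(mEPSP_amp x mEPSP_freq) / (mIPSP_amp x mIPSP_freq); an AUC-based
variant (summed event area per second) is provided as an alternative
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "VoltageTrace",
    "MiniTrain",
    "EIRatio",
    "detect_minis",
    "ei_ratio",
    "ei_ratio_auc",
    "iei_distribution",
]

Polarity = Literal["excitatory", "inhibitory"]


@dataclass
class VoltageTrace:
    """Membrane voltage in mV sampled at ``rate_hz`` (typically 20 kHz)."""

    values: np.ndarray
    rate_hz: float = 20_000.0
    condition: str = "mEPSP"   # mEPSP | mIPSP | sEPSP | sIPSP

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate_hz

    @property
    def polarity(self) -> Polarity:
        # mEPSPs at -70 mV and mIPSPs at +10 mV are both recorded as
        # depolarizing/hyperpolarizing deflections per holding condition
        return "inhibitory" if "IPSP" in self.condition else "excitatory"


@dataclass
class MiniTrain:
    event_times: np.ndarray   # s, strictly increasing
    amplitudes: np.ndarray    # mV, > 0 (peak deflection from local baseline)
    polarity: Polarity
    duration_s: float
    areas: np.ndarray | None = None  # mV*s per event, for the AUC estimator

    @property
    def frequency_hz(self) -> float:
        return self.event_times.size / self.duration_s

    @property
    def iei(self) -> np.ndarray:
        return np.diff(self.event_times)


@dataclass
class EIRatio:
    value: float
    mepsp_amp: float
    mepsp_freq: float
    mipsp_amp: float
    mipsp_freq: float


def _noise_rms(x: np.ndarray) -> float:
    """Robust noise RMS: scaled MAD of the first difference.

    Differencing suppresses the slow synaptic events so the estimate
    reflects the sample-to-sample noise even on event-rich traces.
    """
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad * 1.4826 / np.sqrt(2.0))


def detect_minis(trace: VoltageTrace, threshold_sigma: float = 2.5,
                 noise_rms: float | None = None,
                 min_width_s: float = 1e-3,
                 refractory_s: float = 2e-3,
                 smooth_s: float = 0.5e-3) -> MiniTrain:
    """Detect miniature synaptic events by threshold crossing.

    The trace (sign-flipped for inhibitory conditions so events are
    positive) is baseline-subtracted (median), boxcar-smoothed over
    ``smooth_s``, and thresholded strictly above
    ``threshold_sigma * noise_rms``; suprathreshold runs shorter than
    ``min_width_s`` are dropped and runs separated by less than
    ``refractory_s`` are merged.  Amplitude is the unsmoothed peak
    deflection within the run.
    """
    if trace.duration_s < 1.0:
        raise ValueError("trace must be at least 1 s long")
    # Holding potentials are chosen so both event types deflect upward
    # (mEPSP at -70 mV, mIPSP at +10 mV); polarity metadata labels the train.
    x = trace.values - np.median(trace.values)
    if noise_rms is None:
        noise_rms = _noise_rms(x)
    if noise_rms <= 0:
        raise ValueError("noise RMS is zero")
    fs = trace.rate_hz
    m = max(int(round(smooth_s * fs)), 1)
    xs = ndimage.uniform_filter1d(x, size=m, mode="nearest")
    thr = threshold_sigma * noise_rms
    above = xs > thr
    edges = np.diff(above.astype(int), prepend=0, append=0)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)

    min_w = int(round(min_width_s * fs))
    keep = (ends - starts) >= min_w
    starts, ends = starts[keep], ends[keep]

    # merge runs separated by less than the refractory gap
    gap = int(round(refractory_s * fs))
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    times, amps, areas = [], [], []
    for s, e in merged:
        # peak on the smoothed trace: the raw-sample maximum carries an
        # extreme-value noise bias of ~2 sigma
        k = s + int(np.argmax(xs[s:e]))
        times.append(k / fs)
        amps.append(xs[k])
        areas.append(np.trapezoid(np.maximum(x[s:e], 0.0), dx=1.0 / fs))
    return MiniTrain(event_times=np.asarray(times), amplitudes=np.asarray(amps),
                     polarity=trace.polarity, duration_s=trace.duration_s,
                     areas=np.asarray(areas))


def ei_ratio(mepsp_amp: float, mepsp_freq: float,
             mipsp_amp: float, mipsp_freq: float) -> EIRatio:
    """Synaptic E:I ratio = (mEPSP_amp x mEPSP_freq) / (mIPSP_amp x mIPSP_freq)."""
    for name, v in (("mepsp_amp", mepsp_amp), ("mepsp_freq", mepsp_freq),
                    ("mipsp_amp", mipsp_amp), ("mipsp_freq", mipsp_freq)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    return EIRatio(value=(mepsp_amp * mepsp_freq) / (mipsp_amp * mipsp_freq),
                   mepsp_amp=mepsp_amp, mepsp_freq=mepsp_freq,
                   mipsp_amp=mipsp_amp, mipsp_freq=mipsp_freq)


def ei_ratio_from_trains(epsp: MiniTrain, ipsp: MiniTrain) -> EIRatio:
    return ei_ratio(float(epsp.amplitudes.mean()), epsp.frequency_hz,
                    float(ipsp.amplitudes.mean()), ipsp.frequency_hz)


def ei_ratio_auc(epsp: MiniTrain, ipsp: MiniTrain) -> float:
    """Alternative estimator: summed mEPSP area per second over summed
    mIPSP area per second."""
    if epsp.areas is None or ipsp.areas is None:
        raise ValueError("trains lack event areas")
    e = epsp.areas.sum() / epsp.duration_s
    i = ipsp.areas.sum() / ipsp.duration_s
    if i <= 0:
        raise ValueError("inhibitory area must be positive")
    return float(e / i)


def iei_distribution(train: MiniTrain) -> dict:
    """Inter-event intervals with summary and cumulative distribution."""
    if train.event_times.size < 2:
        raise ValueError("need at least 2 events")
    iei = train.iei
    order = np.sort(iei)
    return {"iei_s": iei, "mean_s": float(iei.mean()),
            "median_s": float(np.median(iei)),
            "cdf_x": order,
            "cdf_y": np.arange(1, order.size + 1) / order.size}
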