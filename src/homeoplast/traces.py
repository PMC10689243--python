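"""ΔF/F0 processing and cellular activity metrics for calcium imaging ROIs.

Raw ROI fluorescence is background-subtracted, detrended against a
running low-percentile baseline F0, expressed as percent ΔF/F0 and
floored at a threshold (15 %ΔF/F0 by default).  Activity is summarized
as the trapezoidal area under the thresholded trace per second, by
event (peak) detection, and by quartile-based activity classes computed
on a reference (young-adult control) distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "RawTrace",
    "DffTrace",
    "ActivitySummary",
    "StimulusSchedule",
    "compute_dff",
    "activity_auc",
    "detect_events",
    "normalize_to_baseline",
    "classify_activity_levels",
]


@dataclass
class RawTrace:
    """Raw fluorescence of one ROI, arbitrary units per frame."""

    values: np.ndarray
    rate_hz: float
    roi_id: str = ""
    roi_kind: Literal["cell", "spine", "dendrite", "background"] = "cell"
    session: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.values.size < 2:
            raise ValueError("trace must have at least 2 frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate_hz


@dataclass
class DffTrace:
    """Thresholded ΔF/F0 trace in percent per frame."""

    values: np.ndarray
    rate_hz: float
    threshold_pct: float = 15.0
    f0_definition: dict = field(default_factory=dict)
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.values.size) / self.rate_hz


@dataclass
class ActivitySummary:
    """Event-level summary of a thresholded ΔF/F0 trace."""

    auc_per_s: float
    event_amplitudes: np.ndarray  # percent ΔF/F0 at each event peak
    event_times: np.ndarray       # event onset times, s, strictly increasing
    frequency_hz: float


@dataclass
class StimulusSchedule:
    """Epoch table of a visual stimulation protocol.

    Epochs are half-open ``[start_s, end_s)`` with labels ``flicker_on``
    or ``dark``; the flicker itself is 40 Hz (not resolved per frame).
    """

    epochs: list[tuple[float, float, str]]
    flicker_hz: float = 40.0
    is_dummy: bool = False

    def __post_init__(self) -> None:
        eps = sorted(self.epochs, key=lambda e: e[0])
        for (s0, e0, _), (s1, _, _) in zip(eps, eps[1:]):
            if s1 < e0:
                raise ValueError("epochs overlap")
        for s0, e0, _ in eps:
            if e0 <= s0:
                raise ValueError("epoch end must exceed start")

    def on_epochs(self) -> list[tuple[float, float]]:
        return [(s, e) for s, e, lab in self.epochs if lab == "flicker_on"]

    def dark_epochs(self) -> list[tuple[float, float]]:
        return [(s, e) for s, e, lab in self.epochs if lab == "dark"]

    @classmethod
    def flicker_trial(cls, start_s: float = 0.0, n_events: int = 17,
                      on_s: float = 3.0, off_s: float = 2.0,
                      is_dummy: bool = False) -> "StimulusSchedule":
        """Build the standard trial: repeated 3 s flicker-on / 2 s off epochs."""
        epochs = []
        t = start_s
        for _ in range(n_events):
            epochs.append((t, t + on_s, "flicker_on"))
            epochs.append((t + on_s, t + on_s + off_s, "dark"))
            t += on_s + off_s
        return cls(epochs=epochs, is_dummy=is_dummy)

    def shifted(self, offset_s: float, is_dummy: bool = True
                ) -> "StimulusSchedule":
        """Time-shifted copy (used to build dummy schedules on dark data)."""
        return StimulusSchedule(
            epochs=[(s + offset_s, e + offset_s, lab) for s, e, lab in self.epochs],
            flicker_hz=self.flicker_hz, is_dummy=is_dummy)


def _running_percentile(x: np.ndarray, window: int, q: float) -> np.ndarray:
    """Centered running percentile; edges use the truncated window."""
    half = max(window // 2, 1)
    n = x.size
    out = np.empty(n)
    # windows are evaluated on a stride grid then interpolated: exact at
    # the grid points, linear between, which is ample for a slow baseline
    step = max(half // 4, 1)
    grid = np.arange(0, n, step)
    vals = np.array([np.percentile(x[max(i - half, 0):min(i + half + 1, n)], q)
                     for i in grid])
    return np.interp(np.arange(n), grid, vals)


def compute_dff(raw: RawTrace, background: RawTrace | None = None,
                drift_window_s: float = 30.0, threshold_pct: float = 15.0,
                f0_percentile: float = 10.0,
                threshold_mode: Literal["absolute", "fraction_of_max"] = "absolute",
                ) -> DffTrace:
    """Convert raw fluorescence to thresholded percent ΔF/F0.

    The background ROI trace is subtracted, slow drift is removed by a
    running ``f0_percentile`` baseline F0 over ``drift_window_s``, and
    ΔF/F0 = 100·(F − F0)/F0 is floored: values below ``threshold_pct``
    (absolute %ΔF/F0 by default, or that fraction of the trace maximum
    with ``threshold_mode="fraction_of_max"``) are set to 0.
    """
    f = raw.values.copy()
    if background is not None:
        if background.values.size != f.size or background.rate_hz != raw.rate_hz:
            raise ValueError("background must match trace length and rate")
        f = f - background.values
    window = int(round(drift_window_s * raw.rate_hz))
    f0 = _running_percentile(f, window, f0_percentile)
    if np.any(f0 <= 0):
        raise ValueError("baseline F0 <= 0; trace rejected")
    dff = 100.0 * (f - f0) / f0
    if threshold_mode == "absolute":
        floor = threshold_pct
    elif threshold_mode == "fraction_of_max":
        floor = threshold_pct / 100.0 * dff.max()
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    dff[dff < floor] = 0.0
    return DffTrace(values=dff, rate_hz=raw.rate_hz, threshold_pct=threshold_pct,
                    f0_definition={"drift_window_s": drift_window_s,
                                   "f0_percentile": f0_percentile,
                                   "threshold_mode": threshold_mode},
                    roi_id=raw.roi_id)


def _window_mask(dff: DffTrace, epochs: Sequence[tuple[float, float]]
                 ) -> np.ndarray:
    t = dff.times_s
    mask = np.zeros(t.size, dtype=bool)
    for s, e in epochs:
        mask |= (t >= s) & (t < e)
    return mask


def activity_auc(dff: DffTrace,
                 window: StimulusSchedule | Sequence[tuple[float, float]] | None = None,
                 which: Literal["all", "flicker_on", "dark"] = "all") -> float:
    """Trapezoidal AUC of ΔF/F0 over a window, per second (%·s/s).

    ``window=None`` integrates the full trace.  With a schedule, pass
    ``which`` to select the stimulated or dark epochs (``"all"`` uses
    every epoch).  Disjoint epochs are integrated separately and the
    total area is divided by the total epoch duration.
    """
    if window is None:
        dur = (dff.values.size - 1) / dff.rate_hz
        if dur <= 0:
            raise ValueError("empty window")
        return float(np.trapezoid(dff.values, dx=1.0 / dff.rate_hz) / dur)
    if isinstance(window, StimulusSchedule):
        if which == "flicker_on":
            epochs = window.on_epochs()
        elif which == "dark":
            epochs = window.dark_epochs()
        else:
            epochs = [(s, e) for s, e, _ in window.epochs]
    else:
        epochs = list(window)
    if not epochs:
        raise ValueError("empty window")
    t = dff.times_s
    total_area = 0.0
    total_dur = 0.0
    for s, e in epochs:
        s_c, e_c = max(s, t[0]), min(e, t[-1])
        if e_c <= s_c:
            continue
        # integrate the piecewise-linear trace over exactly [s_c, e_c]
        inner = t[(t > s_c) & (t < e_c)]
        grid = np.concatenate([[s_c], inner, [e_c]])
        total_area += np.trapezoid(np.interp(grid, t, dff.values), grid)
        total_dur += e_c - s_c
    if total_dur <= 0:
        raise ValueError("window contains no samples")
    return float(total_area / total_dur)


def detect_events(dff: DffTrace, min_width_frames: int = 2) -> ActivitySummary:
    """Detect calcium events as maximal suprathreshold runs.

    One contiguous run of nonzero (post-threshold) samples is one event;
    runs shorter than ``min_width_frames`` are discarded as single-frame
    noise.  Amplitude is the run maximum, onset time the first frame.
    """
    above = dff.values > 0
    edges = np.diff(above.astype(int), prepend=0, append=0)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    amps, times = [], []
    for s, e in zip(starts, ends):
        if e - s < min_width_frames:
            continue
        amps.append(dff.values[s:e].max())
        times.append(s / dff.rate_hz)
    duration = dff.duration_s
    return ActivitySummary(
        auc_per_s=activity_auc(dff),
        event_amplitudes=np.asarray(amps),
        event_times=np.asarray(times),
        frequency_hz=len(times) / duration,
    )


def normalize_to_baseline(values: np.ndarray, baseline_values: np.ndarray,
                          mode: Literal["subtract", "divide"] = "divide"
                          ) -> np.ndarray:
    """Normalize per-cell activity values to their baseline session.

    ``subtract`` returns ``values - baseline_values`` element-wise (one
    baseline per cell); ``divide`` returns ``values / mean(baseline)``.
    """
    values = np.asarray(values, dtype=float)
    baseline = np.asarray(baseline_values, dtype=float)
    if baseline.size == 0:
        raise ValueError("baseline is empty")
    if mode == "subtract":
        return values - baseline
    if mode == "divide":
        m = baseline.mean()
        if m <= 0:
            raise ValueError("divide mode requires baseline mean > 0")
        return values / m
    raise ValueError(f"unknown mode {mode!r}")


def classify_activity_levels(frequencies: np.ndarray,
                             reference_frequencies: np.ndarray) -> np.ndarray:
    """Label activity as low / middle / high by reference quartiles.

    Quartiles are computed on the reference (young-adult control)
    distribution; boundaries are closed on the left: f <= Q1 is low,
    Q1 < f <= Q3 is middle, f > Q3 is high.
    """
    freqs = np.asarray(frequencies, dtype=float)
    ref = np.asarray(reference_frequencies, dtype=float)
    if freqs.size == 0 or ref.size == 0:
        raise ValueError("empty inputs")
    q1, q3 = np.percentile(ref, [25, 75])
    labels = np.where(freqs <= q1, "low",
                      np.where(freqs <= q3, "middle", "high"))
    return labels
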