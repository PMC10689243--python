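"""Spine-specific calcium signals: dendrite subtraction, visual
responsivity against a dummy-stimulus null, and spatial clustering.

Spine ROIs pick up back-propagating global dendritic signal; the
spine-specific component is isolated by subtracting a scaled copy of
the adjacent parent-dendrite trace, with the scale kappa fitted
robustly on dendrite-active frames.  A spine is "visual" when its
fraction of stimulus events with a time-locked response exceeds both a
population null threshold (80th percentile of false-positive fractions
computed on dark-period activity against a time-matched dummy
schedule) and a fixed 20%-of-trials floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .traces import ActivitySummary, DffTrace, StimulusSchedule, detect_events

__all__ = [
    "SpineRecord",
    "ResponsivityResult",
    "ClusteringCurve",
    "fit_dendrite_scaling",
    "subtract_dendrite",
    "timelocked_fraction",
    "classify_responsivity",
    "clustering_probability",
]


@dataclass
class SpineRecord:
    """Paired spine / parent-dendrite ΔF/F0 traces on one branch."""

    spine_trace: DffTrace
    dendrite_trace: DffTrace
    branch_id: str = ""
    position_index: int = 0
    kappa: float | None = None  # fitted dendrite scaling coefficient

    def __post_init__(self) -> None:
        if self.spine_trace.values.size != self.dendrite_trace.values.size:
            raise ValueError("spine and dendrite traces must match in length")
        if self.spine_trace.rate_hz != self.dendrite_trace.rate_hz:
            raise ValueError("spine and dendrite traces must match in rate")
        if self.position_index < 0:
            raise ValueError("position_index must be >= 0")


@dataclass
class ResponsivityResult:
    timelocked_fraction: float
    null_threshold: float      # 80th percentile of the null fractions
    min_fraction: float        # fixed floor, default 0.20
    label: str                 # "visual" | "nonvisual"

    def __post_init__(self) -> None:
        for v in (self.timelocked_fraction, self.null_threshold, self.min_fraction):
            if not 0.0 <= v <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class ClusteringCurve:
    """Probability of matching functional label at each positional offset."""

    offsets: np.ndarray          # 1..max_offset
    match_probability: np.ndarray
    shuffled: np.ndarray         # (n_shuffles, n_offsets) null distribution

    def shuffle_pvalue(self) -> float:
        """Rank-sum comparison of observed vs shuffled offset-1 matches."""
        return float(stats.mannwhitneyu(
            self.match_probability, self.shuffled.mean(axis=1),
            alternative="two-sided").pvalue)


def fit_dendrite_scaling(spine: DffTrace, dendrite: DffTrace) -> float:
    """Fit the dendrite scaling coefficient kappa.

    Theil–Sen slope of spine on dendrite, restricted to frames where
    the dendrite is active (nonzero after thresholding); the median
    pairwise slope resists spine-only transients that would bias an
    ordinary least-squares fit upward.  Clipped at 0.
    """
    if spine.values.size != dendrite.values.size:
        raise ValueError("traces must have equal length")
    active = dendrite.values > 0
    d = dendrite.values[active]
    s = spine.values[active]
    if d.size < 2 or np.ptp(d) == 0:
        return 0.0
    slope = stats.theilslopes(s, d).slope
    return float(max(slope, 0.0))


def subtract_dendrite(record: SpineRecord) -> DffTrace:
    """Remove the scaled global dendritic component from the spine trace.

    corrected = max(spine − kappa·dendrite, 0), re-floored at the spine
    trace threshold so residual crumbs below threshold do not count as
    events.
    """
    kappa = record.kappa
    if kappa is None:
        kappa = fit_dendrite_scaling(record.spine_trace, record.dendrite_trace)
        record.kappa = kappa
    corrected = np.maximum(
        record.spine_trace.values - kappa * record.dendrite_trace.values, 0.0)
    thr = record.spine_trace.threshold_pct
    corrected[corrected < thr] = 0.0
    return DffTrace(values=corrected, rate_hz=record.spine_trace.rate_hz,
                    threshold_pct=thr, roi_id=record.spine_trace.roi_id,
                    f0_definition={"dendrite_kappa": kappa})


def timelocked_fraction(events: ActivitySummary | DffTrace,
                        schedule: StimulusSchedule,
                        response_window_s: float = 0.5) -> float:
    """Fraction of stimulus events with an event onset inside the
    response window [epoch start, epoch end + response_window_s)."""
    if isinstance(events, DffTrace):
        events = detect_events(events)
    on = schedule.on_epochs()
    if not on:
        raise ValueError("schedule has no flicker_on epochs")
    t = events.event_times
    hits = sum(bool(np.any((t >= s) & (t < e + response_window_s)))
               for s, e in on)
    return hits / len(on)


def classify_responsivity(corrected: Sequence[DffTrace],
                          schedule: StimulusSchedule,
                          dark: Sequence[DffTrace],
                          dummy: StimulusSchedule | None = None,
                          response_window_s: float = 0.5,
                          null_percentile: float = 80.0,
                          min_fraction: float = 0.20,
                          ) -> list[ResponsivityResult]:
    """Classify each spine as visual or nonvisual.

    ``corrected`` are the dendrite-subtracted stimulated-period traces;
    ``dark`` the same spines' dark-period traces, scored against the
    ``dummy`` schedule (a time-matched copy of ``schedule`` by default)
    to form per-spine false-positive fractions.  The null threshold is
    the ``null_percentile`` of those fractions across the population; a
    spine is visual iff its fraction strictly exceeds
    ``max(null_threshold, min_fraction)``.
    """
    if len(corrected) != len(dark):
        raise ValueError("corrected and dark trace lists must align")
    if dummy is None:
        dummy = StimulusSchedule(epochs=schedule.epochs,
                                 flicker_hz=schedule.flicker_hz, is_dummy=True)
    fractions = np.array([timelocked_fraction(tr, schedule, response_window_s)
                          for tr in corrected])
    null_fracs = np.array([timelocked_fraction(tr, dummy, response_window_s)
                           for tr in dark])
    null_thr = float(np.percentile(null_fracs, null_percentile))
    cut = max(null_thr, min_fraction)
    return [ResponsivityResult(timelocked_fraction=float(f),
                               null_threshold=null_thr,
                               min_fraction=min_fraction,
                               label="visual" if f > cut else "nonvisual")
            for f in fractions]


def clustering_probability(branch_labels: Sequence[str],
                           max_offset: int | None = None,
                           n_shuffles: int = 1000,
                           rng: np.random.Generator | int | None = None
                           ) -> ClusteringCurve:
    """Probability that spines n positions apart share the functional label.

    Every spine serves as the anchor; matches (1) and non-matches (0)
    with the spines n positions away in both directions are averaged
    per offset (branch ends contribute only defined offsets).  The null
    is built by shuffling labels within the branch.
    """
    labels = np.asarray(branch_labels)
    n = labels.size
    if n < 2:
        raise ValueError("branch must have at least 2 spines")
    if max_offset is None:
        max_offset = n - 1
    rng = np.random.default_rng(rng)

    def curve(lab: np.ndarray) -> np.ndarray:
        out = np.full(max_offset, np.nan)
        for k in range(1, max_offset + 1):
            if k < lab.size:
                out[k - 1] = np.mean(lab[:-k] == lab[k:])
        return out

    observed = curve(labels)
    shuffled = np.empty((n_shuffles, max_offset))
    for i in range(n_shuffles):
        shuffled[i] = curve(rng.permutation(labels))
    return ClusteringCurve(offsets=np.arange(1, max_offset + 1),
                           match_probability=observed, shuffled=shuffled)
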