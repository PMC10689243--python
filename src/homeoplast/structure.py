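"""Structural synaptic quantification from 1-D dendritic intensity profiles.

Spines and inhibitory (VGAT) puncta appear as peaks in fluorescence
intensity profiles drawn along dendrites.  Peak width at the
1.15x-background crossing is the spine-size proxy; peak count per
micron is the density.  Population-wide multiplicative synaptic
scaling is tested by the factor that minimizes the Kolmogorov–Smirnov
distance between the scaled control distribution and the
post-overstimulation distribution.  The structural E:I ratio is the
ratio of background-normalized spine-channel to VGAT-channel profile
integrals; c-Fos activity tagging is quantified by the fraction of
neurons more than 20% above background, with a batched bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "IntensityProfile",
    "PeakSet",
    "ScalingFit",
    "StructuralEI",
    "CfosMeasure",
    "profile_peaks",
    "colocalized_ratio",
    "fit_scaling_factor",
    "structural_ei",
    "cfos_quantify",
    "cfos_bootstrap",
]


@dataclass
class IntensityProfile:
    """Fluorescence intensity along a dendrite (positions in µm, a.u.)."""

    positions: np.ndarray
    intensity: np.ndarray
    background_level: float
    channel: str = "eGFP"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.positions.size != self.intensity.size:
            raise ValueError("positions and intensity must align")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.background_level <= 0:
            raise ValueError("background_level must be positive")

    @property
    def length_um(self) -> float:
        return float(self.positions[-1] - self.positions[0])

    def normalized(self) -> np.ndarray:
        """Intensity in units of background."""
        return self.intensity / self.background_level


@dataclass
class PeakSet:
    centers: np.ndarray   # µm
    widths: np.ndarray    # µm at the threshold crossing (spine-size proxy)
    heights: np.ndarray   # a.u., in units of background
    density: float        # peaks per µm of profile length


@dataclass
class ScalingFit:
    factor: float
    ks_distance: float
    seed_factor: float        # median(stim) / median(control)
    grid: dict = field(default_factory=dict)


@dataclass
class StructuralEI:
    spine_integral: float
    vgat_integral: float

    @property
    def ratio(self) -> float:
        if self.vgat_integral <= 0:
            raise ValueError("E:I ratio undefined for VGAT integral <= 0")
        return self.spine_integral / self.vgat_integral


@dataclass
class CfosMeasure:
    intensity: float
    background: float
    positive: bool            # intensity > 1.2 * background
    normalized: float         # per-group mean-normalized intensity
    expression: str = ""      # "weak" | "strong" vs pooled control 30th pctile


def profile_peaks(profile: IntensityProfile,
                  rel_threshold: float = 0.15) -> PeakSet:
    """Detect peaks as maximal runs above background*(1 + rel_threshold).

    Width is the run extent at the threshold crossing, linearly
    interpolated between samples; height is the run maximum of the
    background-normalized profile; density is run count divided by
    profile length.
    """
    if rel_threshold <= 0:
        raise ValueError("rel_threshold must be positive")
    if profile.positions.size < 3:
        raise ValueError("degenerate profile (< 3 samples)")
    y = profile.normalized()
    x = profile.positions
    level = 1.0 + rel_threshold
    above = y > level
    edges = np.diff(above.astype(int), prepend=0, append=0)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1  # inclusive index of last sample above

    centers, widths, heights = [], [], []
    for s, e in zip(starts, ends):
        # interpolate the crossing on each flank; profile ends clamp
        if s > 0 and y[s] > y[s - 1]:
            left = np.interp(level, [y[s - 1], y[s]], [x[s - 1], x[s]])
        else:
            left = x[s]
        if e < y.size - 1 and y[e] > y[e + 1]:
            right = np.interp(level, [y[e + 1], y[e]], [x[e + 1], x[e]])
        else:
            right = x[e]
        k = s + int(np.argmax(y[s:e + 1]))
        centers.append(x[k])
        heights.append(y[k])
        widths.append(right - left)
    length = profile.length_um
    return PeakSet(centers=np.asarray(centers), widths=np.asarray(widths),
                   heights=np.asarray(heights),
                   density=len(centers) / length if length > 0 else 0.0)


def colocalized_ratio(protein: PeakSet, spines: PeakSet,
                      tolerance_um: float = 0.25) -> np.ndarray:
    """Per-spine ratio of colocalized protein peak height to spine width.

    A protein peak matches a spine when their centers are within
    ``tolerance_um``; the nearest match wins.  Unmatched spines are NaN
    (undefined).
    """
    out = np.full(spines.centers.size, np.nan)
    if protein.centers.size == 0:
        return out
    for i, (c, w) in enumerate(zip(spines.centers, spines.widths)):
        d = np.abs(protein.centers - c)
        j = int(np.argmin(d))
        if d[j] <= tolerance_um:
            out[i] = protein.heights[j] / w
    return out


def fit_scaling_factor(control_values: np.ndarray, stim_values: np.ndarray,
                       span: tuple[float, float] = (0.5, 1.5),
                       step: float = 0.001) -> ScalingFit:
    """Multiplicative scaling factor between control and overstimulated
    synaptic-measure distributions.

    Seeded at median(stim)/median(control), factors on the grid
    seed*[span[0], span[1]] (step ``step``) are scored by the two-sample
    Kolmogorov–Smirnov distance between factor*control and stim; the
    minimizing factor is returned (ties: smallest factor).
    """
    control = np.asarray(control_values, dtype=float)
    stim = np.asarray(stim_values, dtype=float)
    if control.size == 0 or stim.size == 0:
        raise ValueError("both samples must be nonempty")
    if np.any(control <= 0) or np.any(stim <= 0):
        raise ValueError("values must be positive")
    seed = float(np.median(stim) / np.median(control))
    n_steps = int(round((span[1] - span[0]) / step))
    factors = seed * (span[0] + step * np.arange(n_steps + 1))
    # the seed point itself is always tested, and factors are snapped to
    # 12 decimals so an exact short-decimal factor is hit without a
    # one-ulp mismatch that would inflate the KS distance
    factors = np.unique(np.round(np.concatenate([factors, [seed]]), 12))
    best_factor, best_ks = None, np.inf
    for f in factors:
        ks = stats.ks_2samp(f * control, stim).statistic
        if ks < best_ks - 1e-15:
            best_factor, best_ks = float(f), float(ks)
    return ScalingFit(factor=best_factor, ks_distance=best_ks,
                      seed_factor=seed,
                      grid={"span": list(span), "step": step,
                            "n_factors": int(factors.size)})


def structural_ei(spine_profile: IntensityProfile,
                  vgat_profile: IntensityProfile) -> StructuralEI:
    """Structural synaptic E:I ratio: spine-channel profile integral over
    VGAT-channel profile integral, both background-normalized
    (trapezoidal AUC over position)."""
    spine = float(np.trapezoid(spine_profile.normalized(),
                               spine_profile.positions))
    vgat = float(np.trapezoid(vgat_profile.normalized(),
                              vgat_profile.positions))
    if vgat <= 0:
        raise ValueError("VGAT integral must be positive")
    return StructuralEI(spine_integral=spine, vgat_integral=vgat)


def cfos_quantify(intensities: np.ndarray, background: float,
                  control_pool: np.ndarray | None = None,
                  positive_margin: float = 0.2,
                  weak_percentile: float = 30.0,
                  ) -> tuple[list[CfosMeasure], float]:
    """Quantify c-Fos expression: positive flags and positive fraction.

    A neuron is c-Fos positive when its intensity exceeds background by
    more than ``positive_margin`` (20%).  Normalized values (to the
    group mean) are classed weak when <= the ``weak_percentile`` of the
    pooled, mean-normalized control distribution (if given).
    """
    vals = np.asarray(intensities, dtype=float)
    if vals.size == 0:
        raise ValueError("empty intensities")
    if background <= 0:
        raise ValueError("background must be positive")
    norm = vals / vals.mean()
    cut = None
    if control_pool is not None and len(control_pool):
        cut = float(np.percentile(np.asarray(control_pool, dtype=float),
                                  weak_percentile))
    measures = []
    for v, nv in zip(vals, norm):
        positive = v > (1.0 + positive_margin) * background
        expr = "" if cut is None else ("weak" if nv <= cut else "strong")
        measures.append(CfosMeasure(intensity=float(v), background=background,
                                    positive=bool(positive),
                                    normalized=float(nv), expression=expr))
    fraction = sum(m.positive for m in measures) / len(measures)
    return measures, float(fraction)


def cfos_bootstrap(positive_flags: np.ndarray, n_boot: int = 500,
                   batch: int = 10,
                   rng: np.random.Generator | int | None = None
                   ) -> dict:
    """Bootstrap the percent of c-Fos-positive neurons.

    Each replicate draws ``batch`` neurons with replacement and records
    the percent positive; returns the replicate distribution with its
    mean and central 95% interval.
    """
    flags = np.asarray(positive_flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("empty flags")
    if n_boot < 1 or batch < 1:
        raise ValueError("n_boot and batch must be >= 1")
    rng = np.random.default_rng(rng)
    draws = rng.integers(0, flags.size, size=(n_boot, batch))
    pct = flags[draws].mean(axis=1) * 100.0
    lo, hi = np.percentile(pct, [2.5, 97.5])
    return {"replicates": pct, "mean": float(pct.mean()),
            "sd": float(pct.std(ddof=1)) if n_boot > 1 else 0.0,
            "ci95": (float(lo), float(hi))}
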