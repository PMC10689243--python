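"""Functional-assembly association strength from population calcium imaging.

Excitatory and inhibitory neurons imaged simultaneously are associated
through pairwise Pearson correlations of their thresholded ΔF/F0
signals during visual stimulation.  A pair qualifies when its
correlation is positive and significant; each neuron's association
strength with a partner class (E–E, E–I, I–I) is the mean correlation
over its qualifying partners of that class.  Session-wise change is
the post-stimulation / baseline ratio per neuron and channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .traces import DffTrace, StimulusSchedule, _window_mask

__all__ = [
    "PopulationRecording",
    "CorrelationMatrix",
    "AssemblyStrengths",
    "pairwise_correlations",
    "assembly_strength",
    "normalize_session_change",
]

CellClass = Literal["excitatory", "inhibitory"]


@dataclass
class PopulationRecording:
    """Simultaneously recorded neuron traces with cell-class labels."""

    traces: dict[str, DffTrace]
    cell_class: dict[str, CellClass]
    session: str = "baseline"

    def __post_init__(self) -> None:
        if len(self.traces) < 2:
            raise ValueError("need at least 2 neurons")
        lengths = {t.values.size for t in self.traces.values()}
        rates = {t.rate_hz for t in self.traces.values()}
        if len(lengths) != 1 or len(rates) != 1:
            raise ValueError("all traces must share length and rate")
        missing = set(self.traces) - set(self.cell_class)
        if missing:
            raise ValueError(f"cell_class missing for {sorted(missing)}")


@dataclass
class CorrelationMatrix:
    neuron_ids: list[str]
    r: np.ndarray        # (n, n) symmetric, NaN diagonal / undefined pairs
    p: np.ndarray        # (n, n) two-sided p-values


def pairwise_correlations(rec: PopulationRecording,
                          window: StimulusSchedule | None = None,
                          which: Literal["all", "flicker_on", "dark"] = "flicker_on",
                          ) -> CorrelationMatrix:
    """Pearson correlation (r, p) for every neuron pair over the window.

    Zero-variance traces yield NaN entries (flagged undefined) and are
    excluded downstream.  ``window=None`` uses the whole trace.
    """
    ids = sorted(rec.traces)
    sample = rec.traces[ids[0]]
    if window is None:
        mask = np.ones(sample.values.size, dtype=bool)
    else:
        if which == "flicker_on":
            epochs = window.on_epochs()
        elif which == "dark":
            epochs = window.dark_epochs()
        else:
            epochs = [(s, e) for s, e, _ in window.epochs]
        mask = _window_mask(sample, epochs)
    if mask.sum() < 3:
        raise ValueError("window too short for correlation")

    data = np.vstack([rec.traces[i].values[mask] for i in ids])
    n = len(ids)
    r = np.full((n, n), np.nan)
    p = np.full((n, n), np.nan)
    sd = data.std(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            if sd[i] == 0 or sd[j] == 0:
                continue
            res = stats.pearsonr(data[i], data[j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return CorrelationMatrix(neuron_ids=ids, r=r, p=p)


@dataclass
class AssemblyStrengths:
    """Per-neuron mean correlation with qualifying partners, by channel.

    Neurons with zero qualifying partners in a channel are NaN
    (undefined), never zero.  ``n_pairs`` counts qualifying partners.
    """

    ee: dict[str, float] = field(default_factory=dict)   # excitatory neurons
    ei: dict[str, float] = field(default_factory=dict)   # excitatory neurons
    ii: dict[str, float] = field(default_factory=dict)   # inhibitory neurons
    n_pairs: dict[tuple[str, str], int] = field(default_factory=dict)


def assembly_strength(matrix: CorrelationMatrix,
                      classes: dict[str, CellClass],
                      alpha: float = 0.05,
                      fdr: bool = False) -> AssemblyStrengths:
    """Average qualifying (r > 0, p < alpha) correlations per neuron/channel.

    Significance is per-pair and uncorrected by default; ``fdr=True``
    applies Benjamini–Hochberg across the upper triangle instead.
    """
    ids = matrix.neuron_ids
    missing = set(ids) - set(classes)
    if missing:
        raise ValueError(f"classes missing for {sorted(missing)}")
    if not any(classes[i] == "excitatory" for i in ids):
        raise ValueError("no excitatory neurons")
    n = len(ids)
    p = matrix.p.copy()
    if fdr:
        iu = np.triu_indices(n, k=1)
        pv = p[iu]
        ok = np.isfinite(pv)
        adj = np.full(pv.size, np.nan)
        if ok.any():
            adj[ok] = stats.false_discovery_control(pv[ok])
        p[iu] = adj
        p.T[iu] = adj
    qualifies = (matrix.r > 0) & (p < alpha)

    out = AssemblyStrengths()
    for i, nid in enumerate(ids):
        for channel, partner_class in (("ee", "excitatory"), ("ei", "inhibitory"),
                                       ("ii", "inhibitory")):
            own = "excitatory" if channel in ("ee", "ei") else "inhibitory"
            if classes[nid] != own:
                continue
            sel = [j for j in range(n) if j != i
                   and classes[ids[j]] == partner_class and qualifies[i, j]]
            value = float(np.mean(matrix.r[i, sel])) if sel else float("nan")
            getattr(out, channel)[nid] = value
            out.n_pairs[(nid, channel)] = len(sel)
    return out


def normalize_session_change(baseline: AssemblyStrengths,
                             poststim: AssemblyStrengths
                             ) -> dict[str, dict[str, float]]:
    """Post-stimulation / baseline ratio per neuron and channel.

    Undefined (NaN) values propagate; a zero baseline raises.  Returns
    ``{channel: {neuron_id: ratio}}`` over neuron ids present in both
    sessions.
    """
    out: dict[str, dict[str, float]] = {}
    for channel in ("ee", "ei", "ii"):
        base = getattr(baseline, channel)
        post = getattr(poststim, channel)
        ratios = {}
        for nid in base.keys() & post.keys():
            b, q = base[nid], post[nid]
            if np.isnan(b) or np.isnan(q):
                ratios[nid] = float("nan")
            elif b == 0:
                raise ZeroDivisionError(f"baseline value 0 for {nid} ({channel})")
            else:
                ratios[nid] = q / b
        out[channel] = ratios
    return out
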