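"""Rodent continuous-performance-task (rCPT) metrics and learning rates.

Each touchscreen session yields hits, misses, mistakes and correct
rejections (correction trials already excluded upstream).  These give
HR = hits/(hits + misses), FAR = mistakes/(mistakes + correct
rejections) and performance = HR - FAR; the learning rate is the
ordinary-least-squares slope of performance over session index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RcptSession",
    "SessionMetrics",
    "LearningRate",
    "session_metrics",
    "learning_rate",
    "fraction_pct",
]


@dataclass
class RcptSession:
    hits: int
    misses: int
    mistakes: int
    correct_rejections: int
    session_index: int = 1
    reward_latency_s: float | None = None
    correct_choice_latency_s: float | None = None

    def __post_init__(self) -> None:
        for name in ("hits", "misses", "mistakes", "correct_rejections"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class SessionMetrics:
    hr: float | None           # None when hits + misses == 0
    far: float | None          # None when mistakes + CRs == 0
    session_index: int = 1

    @property
    def performance(self) -> float | None:
        if self.hr is None or self.far is None:
            return None
        return self.hr - self.far


@dataclass
class LearningRate:
    slope: float               # performance units per session
    intercept: float
    r_value: float
    n_sessions_used: int
    n_sessions_dropped: int


def session_metrics(session: RcptSession) -> SessionMetrics:
    """HR, FAR and performance for one session; undefined metrics are None."""
    go = session.hits + session.misses
    nogo = session.mistakes + session.correct_rejections
    hr = session.hits / go if go > 0 else None
    far = session.mistakes / nogo if nogo > 0 else None
    return SessionMetrics(hr=hr, far=far, session_index=session.session_index)


def learning_rate(metrics: Sequence[SessionMetrics]) -> LearningRate:
    """OLS slope of performance on 1-based session index.

    Sessions with undefined performance are dropped (and counted), not
    imputed.
    """
    pairs = [(m.session_index, m.performance) for m in metrics]
    used = [(x, y) for x, y in pairs if y is not None]
    dropped = len(pairs) - len(used)
    if len(used) < 2:
        raise ValueError("need at least 2 sessions with defined performance")
    x = np.array([p[0] for p in used], dtype=float)
    y = np.array([p[1] for p in used], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct session indices")
    fit = stats.linregress(x, y)
    return LearningRate(slope=float(fit.slope), intercept=float(fit.intercept),
                        r_value=float(fit.rvalue), n_sessions_used=len(used),
                        n_sessions_dropped=dropped)


def fraction_pct(numerator: int, denominator: int) -> float:
    """Population-summary percentage (e.g. weakened spines / all spines)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    return 100.0 * numerator / denominator
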