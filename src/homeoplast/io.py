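"""Delimited-table readers/writers for traces, schedules and session counts."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .behavior import RcptSession
from .traces import RawTrace, StimulusSchedule

__all__ = [
    "read_trace_table", "write_trace_table",
    "read_schedule", "write_schedule",
    "read_sessions", "write_sessions",
]


def write_trace_table(path: str | Path, traces: list[RawTrace]) -> None:
    """Long-format table (frame, roi_id, value) + JSON metadata sidecar."""
    rows = []
    meta = {}
    for tr in traces:
        rows.append(pd.DataFrame({"frame": range(tr.values.size),
                                  "roi_id": tr.roi_id, "value": tr.values}))
        meta[tr.roi_id] = {"rate_hz": tr.rate_hz, "roi_kind": tr.roi_kind,
                           "session": tr.session}
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_trace_table(path: str | Path) -> list[RawTrace]:
    df = pd.read_csv(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    out = []
    for roi_id, grp in df.groupby("roi_id", sort=True):
        m = meta[str(roi_id)]
        out.append(RawTrace(values=grp.sort_values("frame")["value"].to_numpy(),
                            rate_hz=m["rate_hz"], roi_id=str(roi_id),
                            roi_kind=m.get("roi_kind", "cell"),
                            session=m.get("session", "")))
    return out


def write_schedule(path: str | Path, schedule: StimulusSchedule) -> None:
    pd.DataFrame(schedule.epochs,
                 columns=["start_s", "end_s", "label"]).to_csv(path, index=False)


def read_schedule(path: str | Path, is_dummy: bool = False) -> StimulusSchedule:
    df = pd.read_csv(path)
    epochs = [(float(r.start_s), float(r.end_s), str(r.label))
              for r in df.itertuples()]
    return StimulusSchedule(epochs=epochs, is_dummy=is_dummy)


def write_sessions(path: str | Path,
                   animals: dict[str, list[RcptSession]]) -> None:
    rows = [{"animal": a, "session": s.session_index, "hits": s.hits,
             "misses": s.misses, "mistakes": s.mistakes,
             "correct_rejections": s.correct_rejections}
            for a, sessions in animals.items() for s in sessions]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sessions(path: str | Path) -> dict[str, list[RcptSession]]:
    df = pd.read_csv(path)
    out: dict[str, list[RcptSession]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.animal), []).append(RcptSession(
            hits=int(r.hits), misses=int(r.misses), mistakes=int(r.mistakes),
            correct_rejections=int(r.correct_rejections),
            session_index=int(r.session)))
    for sessions in out.values():
        sessions.sort(key=lambda s: s.session_index)
    return out
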