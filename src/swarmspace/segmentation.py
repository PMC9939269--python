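"""Segmentation of kinematic series into events of polarized collective motion.

An *event* is a maximal uninterrupted run of frames on which the group moves
fast (group speed above a threshold) and in an aligned fashion (polarization
above a threshold). Thresholds are set per dataset as a common quantile of
each variable's distribution — the studied systems used quantiles from 0.05
(pigeon flocks, almost always coordinated) to 0.9 (baboon troops, rarely so).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import KinematicSeries

logger = logging.getLogger(__name__)

#: default minimum representative event duration, seconds
MIN_WINDOW_S = 15.0


@dataclass(frozen=True)
class Thresholds:
    """Joint speed / polarization detection thresholds."""

    speed_thr: float
    pol_thr: float
    quantile: float | None = None


@dataclass
class Event:
    """One uninterrupted period of polarized collective motion."""

    group_id: str
    event_id: str
    start_idx: int          # first frame index (inclusive)
    stop_idx: int           # last frame index (inclusive)
    start_t: float
    end_t: float            # start_t + n_frames * dt (window semantics)
    series: KinematicSeries

    @property
    def n_frames(self) -> int:
        return self.stop_idx - self.start_idx + 1

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t

    @property
    def frame_slice(self) -> slice:
        return slice(self.start_idx, self.stop_idx + 1)

    @property
    def n_members(self) -> int:
        sl = self.frame_slice
        return int(self.series.valid[sl].any(axis=0).sum())


def quantile_thresholds(ks: KinematicSeries, q: float) -> Thresholds:
    """Per-variable q-quantile thresholds over all defined frames."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("quantile must be in [0, 1]")
    ok = np.isfinite(ks.polarization) & np.isfinite(ks.group_speed)
    if ok.sum() < 10:
        raise ValueError("need at least 10 frames with defined speed and "
                         "polarization to set thresholds")
    return Thresholds(speed_thr=float(np.quantile(ks.group_speed[ok], q)),
                      pol_thr=float(np.quantile(ks.polarization[ok], q)),
                      quantile=q)


def _passing_mask(ks: KinematicSeries, thr: Thresholds) -> np.ndarray:
    # frames with undefined polarization fail detection (conservative)
    defined = np.isfinite(ks.polarization) & np.isfinite(ks.group_speed)
    mask = np.zeros(ks.n_frames, dtype=bool)
    mask[defined] = ((ks.group_speed[defined] >= thr.speed_thr)
                     & (ks.polarization[defined] >= thr.pol_thr))
    return mask


def _runs(mask: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Maximal [start, stop] index runs of True, bridging gaps <= max_gap."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > max_gap + 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, stops)]


def detect_events(ks: KinematicSeries, thr: Thresholds,
                  min_duration: float = 0.0, max_gap: int = 0) -> list[Event]:
    """Extract maximal runs of frames passing both detection criteria.

    Runs separated by at most ``max_gap`` failing frames are merged
    (``max_gap=0`` demands strict contiguity; nonzero values tolerate brief
    sensor dropouts). Runs shorter than ``min_duration`` seconds are
    discarded. An event's duration counts ``n_frames * dt`` — each frame
    represents one sampling interval of motion.
    """
    mask = _passing_mask(ks, thr)
    events = []
    for k, (a, b) in enumerate(_runs(mask, max_gap)):
        n = b - a + 1
        if n * ks.dt < min_duration:
            continue
        events.append(Event(ks.group_id, f"{ks.group_id}-e{k:04d}", a, b,
                            start_t=float(ks.t[a]),
                            end_t=float(ks.t[a]) + n * ks.dt, series=ks))
    return events


def filter_min_window(events: list[Event],
                      min_window: float = MIN_WINDOW_S) -> tuple[list[Event], int]:
    """Drop events shorter than the minimum representative window (inclusive).

    Returns (kept events, number removed).
    """
    kept = [ev for ev in events if ev.duration >= min_window]
    removed = len(events) - len(kept)
    if removed:
        logger.info("filter_min_window: removed %d events shorter than %.3g s",
                    removed, min_window)
    return kept, removed


def events_table(events: list[Event]) -> pd.DataFrame:
    """Summary table of detected events."""
    rows = []
    for ev in events:
        sl = ev.frame_slice
        pol = ev.series.polarization[sl]
        spd = ev.series.group_speed[sl]
        rows.append({"group_id": ev.group_id, "event_id": ev.event_id,
                     "start_t": ev.start_t, "end_t": ev.end_t,
                     "duration_s": ev.duration, "n_members": ev.n_members,
                     "mean_speed": float(np.nanmean(spd)),
                     "mean_polarization": float(np.nanmean(pol))})
    cols = ["group_id", "event_id", "start_t", "end_t", "duration_s",
            "n_members", "mean_speed", "mean_polarization"]
    return pd.DataFrame(rows, columns=cols)
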