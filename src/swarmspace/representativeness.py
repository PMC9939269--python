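"""Minimum representative snapshot duration via intraclass correlation.

Events of collective motion vary widely in length, so short "snapshots" are
sampled from within events and their means compared with the full-event
means. Agreement is quantified with a two-way random-effects, absolute-
agreement, single-measure intraclass correlation coefficient (ICC(A,1) in
McGraw & Wong's nomenclature), treating events as subjects and the pair
(full mean, snapshot mean) as two raters. The shortest duration whose ICC
clears a threshold for every dataset is the minimum representative window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg

from .metrics import frame_metrics_table
from .segmentation import Event

logger = logging.getLogger(__name__)

#: metrics compared between snapshot and full event
SNAPSHOT_METRICS = ("polarization", "shape")


@dataclass
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    model: str
    n_subjects: int
    p_value: float = np.nan


def snapshot_frame_tables(events: list[Event]) -> dict:
    """Pre-computed per-frame polarization/shape tables keyed by event id."""
    return {ev.event_id: (frame_metrics_table(ev), ev.series.dt)
            for ev in events}


def sample_snapshot_means(frame_tables: dict, duration: float,
                          rng) -> pd.DataFrame:
    """One uniformly placed snapshot per eligible event.

    ``frame_tables`` maps event_id -> (per-frame metric table, dt), as built
    by :func:`snapshot_frame_tables`. Events shorter than ``duration`` are
    ineligible. Returns long-format rows (event_id, duration, metric,
    true_mean, snapshot_mean).
    """
    rng = np.random.default_rng(rng)
    w_rows = []
    for event_id, (tab, dt) in frame_tables.items():
        n = len(tab)
        w = int(round(duration / dt))
        if w < 1 or w > n:
            continue
        start = int(rng.integers(0, n - w + 1))
        window = tab.iloc[start:start + w]
        for metric in SNAPSHOT_METRICS:
            w_rows.append({"event_id": event_id, "duration": duration,
                           "metric": metric,
                           "true_mean": float(tab[metric].mean()),
                           "snapshot_mean": float(window[metric].mean())})
    return pd.DataFrame(w_rows)


def icc_agreement(true_vals, snapshot_vals) -> ICCResult:
    """ICC(A,1): two-way random effects, absolute agreement, single measure.

    Raises ``ValueError`` when there is no between-subject variance (the ICC
    is undefined there: any rating pattern is pure noise around a constant).
    """
    true_vals = np.asarray(true_vals, dtype=float)
    snapshot_vals = np.asarray(snapshot_vals, dtype=float)
    n = len(true_vals)
    if n < 5:
        raise ValueError("need at least 5 subjects (events) for a stable ICC")
    subject_means = (true_vals + snapshot_vals) / 2.0
    if np.var(subject_means) == 0 and np.var(true_vals) == 0:
        raise ValueError("zero between-subject variance; ICC undefined")
    long = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "rater": np.repeat(["true", "snapshot"], n),
        "score": np.concatenate([true_vals, snapshot_vals]),
    })
    with warnings.catch_warnings():
        # degenerate mean squares (e.g. perfect agreement) are handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        icc = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score")
    icc["Type"] = icc["Type"].astype(str)
    key = "ICC(A,1)" if "ICC(A,1)" in set(icc["Type"]) else "ICC2"
    row = icc.set_index("Type").loc[key]
    ci_col = "CI95" if "CI95" in row.index else "CI95%"
    lo, hi = row[ci_col]
    return ICCResult(icc=float(row["ICC"]), ci95=(float(lo), float(hi)),
                     model="two-way random, absolute agreement, single measure",
                     n_subjects=n, p_value=float(row["pval"]))


def icc_curve(frame_tables: dict, durations, seed=0,
              metric: str = "polarization") -> pd.DataFrame:
    """ICC versus snapshot duration for one dataset."""
    rng = np.random.default_rng(seed)
    rows = []
    for dur in durations:
        pairs = sample_snapshot_means(frame_tables, dur, rng)
        pairs = pairs[pairs["metric"] == metric]
        if len(pairs) < 5:
            logger.info("duration %.3g s: only %d eligible events; skipped",
                        dur, len(pairs))
            continue
        res = icc_agreement(pairs["true_mean"], pairs["snapshot_mean"])
        rows.append({"duration_s": dur, "icc": res.icc,
                     "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                     "n_events": res.n_subjects})
    return pd.DataFrame(rows)


def select_min_window(icc_by_duration: dict, icc_min: float = 0.9) -> float:
    """Smallest duration whose ICC >= icc_min for every dataset.

    ``icc_by_duration`` maps dataset -> {duration: icc}. When no tested
    duration qualifies for all datasets, the largest tested duration is
    returned with a warning — more data would be needed to certify it.
    """
    if not icc_by_duration:
        raise ValueError("no ICC curves supplied")
    durations = sorted({d for curve in icc_by_duration.values() for d in curve})
    if not durations:
        raise ValueError("ICC curves are empty")
    for dur in durations:
        if all(curve.get(dur, -np.inf) >= icc_min
               for curve in icc_by_duration.values()):
            return dur
    logger.warning("no tested duration reaches ICC >= %.2f in all datasets; "
                   "returning the largest tested duration", icc_min)
    return durations[-1]
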