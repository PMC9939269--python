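"""Local and group-level metrics of collective motion.

Per frame the module computes:

* pairwise Euclidean distances and topological neighbour ranks;
* the **bearing angle** beta of every neighbour relative to a focal
  individual's heading — 0 deg means the neighbour is directly ahead,
  +/-180 deg directly behind (sign positive to the focal's right);
* **frontness** f = |beta| / 180 in [0, 1] — 1 when the focal is directly in
  front of its neighbour, 0 when directly behind;
* nearest-neighbour distance (NND) statistics;
* the **group shape angle** theta in [0, 90] deg between the group's heading
  and the short-side direction of the minimum-area rotated bounding box of
  member positions (90 deg = group elongated along its direction of motion,
  0 deg = perfectly wide), normalized to s = theta / 90.

Per event these are aggregated into a 10-component vector: four means (NND,
|bearing|, polarization, shape), four temporal standard deviations (NND,
polarization, shape, group speed) and two mean within-group SDs (NND,
frontness).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import LineString, MultiPoint, Point, Polygon

from .segmentation import Event

logger = logging.getLogger(__name__)

#: full event-level metric vector, in canonical order
METRIC_NAMES = [
    "mean_nnd", "mean_abs_bearing", "mean_polarization", "mean_shape",
    "sd_t_nnd", "sd_t_polarization", "sd_t_shape", "sd_t_speed",
    "mean_sd_within_nnd", "mean_sd_within_frontness",
]

#: metrics entering the swarm space by default; the mean absolute bearing is
#: redundant with frontness (|beta| = 180 f over the same relations) and is
#: excluded from embeddings
DEFAULT_SWARM_METRICS = [m for m in METRIC_NAMES if m != "mean_abs_bearing"]

_SQUARE_TIE_RTOL = 1e-9


def pairwise_distances(positions: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix of an (n, 2) position array."""
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] < 2:
        raise ValueError("need at least 2 positions")
    return squareform(pdist(positions))


def _wrap_deg(angle: np.ndarray) -> np.ndarray:
    """Wrap degrees into (-180, 180]."""
    a = np.asarray(angle, dtype=float) % 360.0
    return np.where(a > 180.0, a - 360.0, a)


def neighbour_relations(positions: np.ndarray, heading: np.ndarray,
                        labels=None) -> pd.DataFrame:
    """Ordered focal->neighbour relations for one frame.

    Parameters
    ----------
    positions : (n, 2) metres.
    heading : (n,) heading angles in radians (CCW from +x); NaN marks an
        undefined heading, whose focal relations are omitted.
    labels : member labels (default 0..n-1); also the tie-break order for
        equal-distance ranks.

    Returns a DataFrame with columns focal, neighbour, rank, distance,
    bearing_deg and frontness. ``rank`` 1 is the nearest neighbour. Bearings
    are signed degrees in (-180, 180], positive to the focal's right.
    """
    positions = np.asarray(positions, dtype=float)
    heading = np.asarray(heading, dtype=float)
    n = positions.shape[0]
    if labels is None:
        labels = list(range(n))
    dmat = pairwise_distances(positions)
    rows = []
    for i in range(n):
        if not np.isfinite(heading[i]):
            continue
        others = [j for j in range(n) if j != i]
        order = sorted(others, key=lambda j: (dmat[i, j], j))
        rel = positions[order] - positions[i]
        phi = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))
        beta = _wrap_deg(np.degrees(heading[i]) - phi)
        for rank, (j, b) in enumerate(zip(order, beta), start=1):
            rows.append((labels[i], labels[j], rank, dmat[i, j], b,
                         abs(b) / 180.0))
    return pd.DataFrame(rows, columns=["focal", "neighbour", "rank",
                                       "distance", "bearing_deg", "frontness"])


def _axial_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Acute angle in [0, 90] deg between two directions (axial, mod 180)."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    c = abs(float(np.dot(u, v))) / (nu * nv)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def min_bounding_box(positions: np.ndarray):
    """Minimum-area rotated bounding rectangle of a point set.

    Returns (short_dir, long_dir, short_len, long_len) with unit direction
    vectors; uses the convex hull (rotating-calipers result via shapely).
    Collinear inputs yield a zero-width box whose short side is perpendicular
    to the line; fully coincident inputs raise ``ValueError``.
    """
    positions = np.asarray(positions, dtype=float)
    geom = MultiPoint(positions).minimum_rotated_rectangle
    if isinstance(geom, Point):
        raise ValueError("all points coincide; bounding box undefined")
    if isinstance(geom, LineString):
        (x0, y0), (x1, y1) = geom.coords[0], geom.coords[-1]
        long_dir = np.array([x1 - x0, y1 - y0])
        long_len = float(np.linalg.norm(long_dir))
        long_dir /= long_len
        short_dir = np.array([-long_dir[1], long_dir[0]])
        return short_dir, long_dir, 0.0, long_len
    assert isinstance(geom, Polygon)
    corners = np.asarray(geom.exterior.coords)[:4]
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    l1, l2 = np.linalg.norm(e1), np.linalg.norm(e2)
    if l1 <= l2:
        short, long_, sl, ll = e1, e2, l1, l2
    else:
        short, long_, sl, ll = e2, e1, l2, l1
    return short / sl, long_ / ll, float(sl), float(ll)


def shape_angle(positions: np.ndarray, group_heading: np.ndarray) -> float:
    """Angle (degrees, [0, 90]) between group heading and the box short side.

    90 deg: group perfectly oblong, elongated along its direction of motion;
    0 deg: group perfectly wider than long. For an exactly square box (side
    lengths equal to relative tolerance 1e-9) the side making the smaller
    angle with the heading is taken as the short side, a deterministic
    tie-break.
    """
    group_heading = np.asarray(group_heading, dtype=float)
    if not np.all(np.isfinite(group_heading)) or np.allclose(group_heading, 0):
        raise ValueError("group heading undefined")
    short_dir, long_dir, sl, ll = min_bounding_box(positions)
    if ll > 0 and abs(sl - ll) <= _SQUARE_TIE_RTOL * ll:
        return min(_axial_angle_deg(group_heading, short_dir),
                   _axial_angle_deg(group_heading, long_dir))
    return _axial_angle_deg(group_heading, short_dir)


def frame_metrics(positions: np.ndarray, heading: np.ndarray,
                  polarization: float = np.nan,
                  group_speed: float = np.nan) -> dict:
    """All per-frame metrics for one frame.

    NND statistics use every member present in ``positions``; bearing and
    frontness statistics use the focals whose heading is defined. Per-focal
    frontness (and |bearing|) is first averaged over all of that focal's
    neighbours, then the group mean and sample SD are taken across focals,
    weighting individuals equally. Returns NaN entries where a quantity is
    undefined (e.g. shape for a coincident group).
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n < 2:
        raise ValueError("need at least 2 members in a frame")
    dmat = pairwise_distances(positions)
    np.fill_diagonal(dmat, np.inf)
    nnd = dmat.min(axis=1)

    rel = neighbour_relations(positions, heading)
    if len(rel):
        per_focal = rel.groupby("focal", sort=True).agg(
            frontness=("frontness", "mean"),
            abs_bearing=("bearing_deg", lambda b: b.abs().mean()))
        mean_frontness = float(per_focal["frontness"].mean())
        sd_within_frontness = float(per_focal["frontness"].std(ddof=1)) \
            if len(per_focal) > 1 else np.nan
        mean_abs_bearing = float(per_focal["abs_bearing"].mean())
    else:
        mean_frontness = sd_within_frontness = mean_abs_bearing = np.nan

    ux = np.nanmean(np.where(np.isfinite(heading), np.cos(heading), np.nan))
    uy = np.nanmean(np.where(np.isfinite(heading), np.sin(heading), np.nan))
    theta = np.nan
    if np.isfinite(ux) and np.isfinite(uy) and not np.allclose([ux, uy], 0):
        try:
            theta = shape_angle(positions, np.array([ux, uy]))
        except ValueError:
            pass
    return {"mean_nnd": float(nnd.mean()),
            "sd_within_nnd": float(np.std(nnd, ddof=1)) if n > 1 else np.nan,
            "mean_frontness": mean_frontness,
            "sd_within_frontness": sd_within_frontness,
            "mean_abs_bearing": mean_abs_bearing,
            "polarization": polarization,
            "group_speed": group_speed,
            "shape_angle": theta,
            "shape": theta / 90.0 if np.isfinite(theta) else np.nan}


def frame_metrics_table(event: Event) -> pd.DataFrame:
    """Per-frame metric table over an event's frames.

    Frames with fewer than two valid members are skipped with a log entry.
    """
    ks = event.series
    rows, times = [], []
    for k in range(event.start_idx, event.stop_idx + 1):
        sel = ks.valid[k]
        if sel.sum() < 2:
            logger.info("event %s: frame t=%.3f has <2 valid members; skipped",
                        event.event_id, ks.t[k])
            continue
        pos = np.column_stack([ks.x[k, sel], ks.y[k, sel]])
        head = np.where(ks.heading_valid[k, sel], ks.heading[k, sel], np.nan)
        rows.append(frame_metrics(pos, head,
                                  polarization=float(ks.polarization[k]),
                                  group_speed=float(ks.group_speed[k])))
        times.append(ks.t[k])
    out = pd.DataFrame(rows)
    out.insert(0, "t", times)
    return out


def event_metric_vector(frames: pd.DataFrame) -> pd.Series | None:
    """Aggregate a per-frame metric table into the 10-component event vector.

    Means over frames of {NND, |bearing|, polarization, shape}; sample SDs
    over frames of {NND, polarization, shape, group speed}; means over frames
    of the within-group SDs of {NND, frontness}. Returns None (with a log
    entry) when fewer than two frames have defined metrics.
    """
    if len(frames.dropna(subset=["mean_nnd", "polarization"])) < 2:
        logger.info("event dropped: fewer than 2 frames with defined metrics")
        return None
    agg = {
        "mean_nnd": frames["mean_nnd"].mean(),
        "mean_abs_bearing": frames["mean_abs_bearing"].mean(),
        "mean_polarization": frames["polarization"].mean(),
        "mean_shape": frames["shape"].mean(),
        "sd_t_nnd": frames["mean_nnd"].std(ddof=1),
        "sd_t_polarization": frames["polarization"].std(ddof=1),
        "sd_t_shape": frames["shape"].std(ddof=1),
        "sd_t_speed": frames["group_speed"].std(ddof=1),
        "mean_sd_within_nnd": frames["sd_within_nnd"].mean(),
        "mean_sd_within_frontness": frames["sd_within_frontness"].mean(),
    }
    return pd.Series(agg, index=METRIC_NAMES)


def compute_event_metrics(events: list[Event],
                          dataset: str | None = None) -> pd.DataFrame:
    """Event-level metric table (one row per event, columns = 10 metrics).

    Events with fewer than two metric-defined frames are dropped.
    """
    rows = []
    for ev in events:
        vec = event_metric_vector(frame_metrics_table(ev))
        if vec is None:
            continue
        meta = {"event_id": ev.event_id, "group_id": ev.group_id,
                "start_t": ev.start_t, "duration_s": ev.duration,
                "n_members": ev.n_members}
        if dataset is not None:
            meta["dataset"] = dataset
        rows.append({**meta, **vec.to_dict()})
    return pd.DataFrame(rows)


def neighbour_density_map(events: list[Event], max_rank: int = 4,
                          n_bins: int = 36) -> pd.DataFrame:
    """Bearing-angle density by neighbour rank, pooled over events.

    For each topological rank 1..max_rank, histogram of the signed bearing
    angle over all frames and focals, normalized to sum to 1 within the rank.
    Long-format output: rank, bin_left, bin_right, density.
    """
    if not events:
        raise ValueError("need at least one event")
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    counts = np.zeros((max_rank, n_bins))
    for ev in events:
        ks = ev.series
        for k in range(ev.start_idx, ev.stop_idx + 1):
            sel = ks.valid[k]
            if sel.sum() < 2:
                continue
            pos = np.column_stack([ks.x[k, sel], ks.y[k, sel]])
            head = np.where(ks.heading_valid[k, sel], ks.heading[k, sel], np.nan)
            rel = neighbour_relations(pos, head)
            rel = rel[rel["rank"] <= max_rank]
            for r, sub in rel.groupby("rank"):
                h, _ = np.histogram(sub["bearing_deg"], bins=edges)
                counts[r - 1] += h
    rows = []
    for r in range(max_rank):
        total = counts[r].sum()
        dens = counts[r] / total if total > 0 else counts[r]
        for b in range(n_bins):
            rows.append((r + 1, edges[b], edges[b + 1], dens[b]))
    return pd.DataFrame(rows, columns=["rank", "bin_left", "bin_right",
                                       "density"])
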