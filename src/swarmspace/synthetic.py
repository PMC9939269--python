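"""Synthetic trajectory and metric-series generators with known ground truth.

Real datasets of collective motion (schools filmed at 50 fps, flocks and
herds tracked by GPS at 0.2–1 s) cannot be bundled, so every downstream
stage is exercised on generated groups whose formation, coordination regime
and change-point structure are known by construction:

* ``generate_formation_group`` — a group travelling in a chosen formation
  (single-file column, line abreast, diagonal echelon, or isotropic blob)
  with von-Mises heading noise and Gaussian speed noise;
* ``generate_regime_sequence`` — alternating coordinated / uncoordinated
  phases, the ground truth for event detection;
* ``generate_metric_sequence`` — a per-event metric series whose cumulative
  mean trends and then plateaus at a known event index.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import RawTrack

FORMATIONS = ("column", "line_abreast", "diagonal", "blob")

#: static per-member lattice jitter, as a fraction of the target NND, so
#: nearest-neighbour statistics are nondegenerate even in noiseless groups
LATTICE_JITTER_FRAC = 0.10


@dataclass
class FormationConfig:
    """Configuration of one travelling group.

    Parameters
    ----------
    n_members : group size (studied species ranged from 5 to 34 members).
    formation : lattice arrangement relative to the travel direction.
    nnd_target : target nearest-neighbour spacing, metres.
    heading_noise_kappa : von-Mises concentration of per-member, per-step
        heading noise about the travel direction; ``inf`` means noiseless,
        0 means uniformly random headings.
    speed_mean, speed_sd : per-member per-step speed draw, m/s.
    dt : sampling interval, seconds (0.02–1 s covers the studied systems).
    duration : seconds.
    heading_deg : travel direction, degrees CCW from +x.
    """

    n_members: int = 10
    formation: str = "column"
    nnd_target: float = 2.0
    heading_noise_kappa: float = 20.0
    speed_mean: float = 1.0
    speed_sd: float = 0.1
    dt: float = 0.5
    duration: float = 60.0
    heading_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError("n_members must be >= 2")
        if self.formation not in FORMATIONS:
            raise ValueError(f"formation must be one of {FORMATIONS}")
        if self.nnd_target <= 0:
            raise ValueError("nnd_target must be positive")
        if self.heading_noise_kappa < 0:
            raise ValueError("heading_noise_kappa must be >= 0")
        if self.dt <= 0 or self.duration / self.dt < 2:
            raise ValueError("need duration/dt >= 2 frames")


@dataclass
class RegimeConfig:
    """Alternating coordinated / uncoordinated phases over a base group."""

    phases: Sequence[tuple[str, float]] = field(
        default_factory=lambda: [("uncoordinated", 30.0), ("collective", 60.0),
                                 ("uncoordinated", 30.0)])
    base: FormationConfig = field(default_factory=FormationConfig)

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("need at least one phase")
        for phase in self.phases:
            regime, dur = phase[0], phase[1]
            if regime not in ("collective", "uncoordinated"):
                raise ValueError(f"unknown regime {regime!r}")
            if dur <= 0:
                raise ValueError("phase durations must be positive")
            if len(phase) > 2 and not isinstance(phase[2], dict):
                raise ValueError("phase overrides must be a dict of "
                                 "FormationConfig fields")


def _lattice(cfg: FormationConfig, rng: np.random.Generator) -> np.ndarray:
    """Member slots (metres) in group coordinates; +x is the travel direction."""
    n, a = cfg.n_members, cfg.nnd_target
    idx = np.arange(n) - (n - 1) / 2.0
    if cfg.formation == "column":
        slots = np.column_stack([a * idx, np.zeros(n)])
    elif cfg.formation == "line_abreast":
        slots = np.column_stack([np.zeros(n), a * idx])
    elif cfg.formation == "diagonal":
        s = a / np.sqrt(2.0)
        slots = np.column_stack([s * idx, s * idx])
    else:  # blob: isotropic Gaussian scaled so the mean NND is close to target
        sigma = a * np.sqrt(n) / 2.0
        slots = rng.normal(0.0, sigma, size=(n, 2))
    slots += rng.normal(0.0, LATTICE_JITTER_FRAC * a, size=(n, 2))
    return slots


def _heading_noise(rng: np.random.Generator, kappa: float, size) -> np.ndarray:
    if np.isinf(kappa):
        return np.zeros(size)
    return rng.vonmises(0.0, kappa, size=size)


def _simulate(cfg: FormationConfig, rng: np.random.Generator,
              start: np.ndarray, n_steps: int) -> np.ndarray:
    """Integrate member positions over n_steps; returns (n_steps+1, n, 2)."""
    theta0 = np.radians(cfg.heading_deg)
    angles = theta0 + _heading_noise(rng, cfg.heading_noise_kappa,
                                     (n_steps, cfg.n_members))
    speeds = cfg.speed_mean + (rng.normal(0.0, cfg.speed_sd,
                                          (n_steps, cfg.n_members))
                               if cfg.speed_sd > 0 else 0.0)
    speeds = np.maximum(speeds, 0.0)
    steps = (speeds * cfg.dt)[..., None] * np.stack(
        [np.cos(angles), np.sin(angles)], axis=-1)
    pos = np.empty((n_steps + 1, cfg.n_members, 2))
    pos[0] = start
    np.cumsum(steps, axis=0, out=pos[1:])
    pos[1:] += start
    return pos


def _to_tracks(pos: np.ndarray, t: np.ndarray, group_id: str) -> list[RawTrack]:
    n = pos.shape[1]
    width = len(str(n - 1))
    return [RawTrack(group_id, f"m{j:0{width}d}", t, pos[:, j, 0], pos[:, j, 1])
            for j in range(n)]


def generate_formation_group(cfg: FormationConfig,
                             group_id: str = "sim") -> tuple[list[RawTrack], dict]:
    """Generate one group travelling in formation.

    Members start on a (jittered) rigid lattice oriented to the travel
    direction and each takes independent noisy steps; with ``kappa=inf`` and
    ``speed_sd=0`` the group translates rigidly (polarization exactly 1
    downstream), while ``kappa=0`` yields uncoordinated wandering.

    Returns the tracks plus a ground-truth record (formation label, slots,
    travel heading, config).
    """
    rng = np.random.default_rng(cfg.seed)
    n_steps = int(round(cfg.duration / cfg.dt))
    theta0 = np.radians(cfg.heading_deg)
    rot = np.array([[np.cos(theta0), -np.sin(theta0)],
                    [np.sin(theta0), np.cos(theta0)]])
    slots = _lattice(cfg, rng) @ rot.T
    pos = _simulate(cfg, rng, slots, n_steps)
    t = cfg.dt * np.arange(n_steps + 1)
    truth = {"formation": cfg.formation, "slots": slots,
             "heading_deg": cfg.heading_deg, "config": cfg}
    return _to_tracks(pos, t, group_id), truth


#: uncoordinated phases move at this fraction of the coordinated speed
UNCOORDINATED_SPEED_FRAC = 0.1


def generate_regime_sequence(cfg: RegimeConfig,
                             group_id: str = "sim") -> tuple[list[RawTrack], pd.DataFrame]:
    """Concatenate coordinated and uncoordinated phases into one recording.

    Collective phases use the base formation parameters; uncoordinated phases
    draw uniformly random headings (kappa=0) at a tenth of the base speed, so
    both detection criteria (speed and polarization) fail there. A phase may
    carry a third element, a dict of FormationConfig overrides, to make
    phases heterogeneous (real events differ in coordination strength).
    Positions are continuous across phase boundaries. Returns tracks plus the
    true phase table (regime, t_start, t_end) — the collective rows are the
    ground-truth events.
    """
    base = cfg.base
    rng = np.random.default_rng(base.seed)
    theta0 = np.radians(base.heading_deg)
    rot = np.array([[np.cos(theta0), -np.sin(theta0)],
                    [np.sin(theta0), np.cos(theta0)]])
    start = _lattice(base, rng) @ rot.T

    chunks, rows = [], []
    t_cursor = 0.0
    for phase in cfg.phases:
        regime, dur = phase[0], phase[1]
        overrides = phase[2] if len(phase) > 2 else {}
        n_steps = int(round(dur / base.dt))
        if regime == "collective":
            phase_cfg = replace(base, **overrides) if overrides else base
        else:
            phase_cfg = replace(
                base, heading_noise_kappa=0.0,
                speed_mean=base.speed_mean * UNCOORDINATED_SPEED_FRAC,
                speed_sd=base.speed_sd * UNCOORDINATED_SPEED_FRAC, **overrides)
        pos = _simulate(phase_cfg, rng, start, n_steps)
        rows.append({"regime": regime, "t_start": t_cursor,
                     "t_end": t_cursor + n_steps * base.dt})
        # drop the first frame of every chunk after the first (shared boundary)
        chunks.append(pos if not chunks else pos[1:])
        start = pos[-1]
        t_cursor += n_steps * base.dt
    pos = np.concatenate(chunks, axis=0)
    t = base.dt * np.arange(pos.shape[0])
    truth = pd.DataFrame(rows)
    return _to_tracks(pos, t, group_id), truth


def true_events(truth: pd.DataFrame) -> pd.DataFrame:
    """Collective-phase rows of a regime truth table."""
    return truth[truth["regime"] == "collective"].reset_index(drop=True)


def generate_metric_sequence(n_events: int, tau: int, pre_slope: float = 0.05,
                             sd: float = 0.1, seed: int = 0,
                             level: float = 1.0) -> tuple[np.ndarray, int]:
    """Per-event metric values whose cumulative mean ramps then plateaus.

    The noiseless cumulative mean follows the broken line
    ``c_k = level + pre_slope * (min(k, tau) - tau)``: rising (or falling)
    until event ``tau``, flat afterwards. Per-event values are recovered as
    the telescoping differences ``x_k = k*c_k - (k-1)*c_{k-1}`` and i.i.d.
    Gaussian noise of scale ``sd`` is added to each event value.

    Returns (values, tau).
    """
    if not 1 <= tau <= n_events:
        raise ValueError("need 1 <= tau <= n_events")
    k = np.arange(1, n_events + 1, dtype=float)
    c = level + pre_slope * (np.minimum(k, tau) - tau)
    x = k * c - np.concatenate([[0.0], (k[:-1]) * c[:-1]])
    if sd > 0:
        x = x + np.random.default_rng(seed).normal(0.0, sd, n_events)
    return x, tau


def tracks_to_csv(tracks: Sequence[RawTrack], path) -> None:
    """Write tracks in the CSV dialect :func:`swarmspace.io.read_trajectories` reads."""
    frames = [pd.DataFrame({"group_id": tr.group_id,
                            "individual_id": tr.individual_id,
                            "t": tr.t, "x": tr.x, "y": tr.y})
              for tr in tracks]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
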