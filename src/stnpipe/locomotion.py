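"""Open-field locomotion analysis.

Position tracks sampled at a nominal 12.8 Hz are turned into a smoothed
speed series (moving-window net displacement), segmented into rest and
motion episodes against a 4 cm/s noise level, and reduced to per-episode
maximal-speed statistics ("max-SD", reported in cm/s).  The natural-log
max-SD values of motion episodes form a bimodal distribution whose
antimode separates weak movements from episodes of full motion; summary
statistics (spatial spread, average max-SD) are computed on full-motion
episodes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LocomotionTrack",
    "Episode",
    "EpisodeSet",
    "ModeSplit",
    "compute_speed",
    "segment_episodes",
    "episode_max_sd",
    "identify_motion_modes",
    "motion_summary",
    "relative_change",
]

NOMINAL_RATE_HZ = 12.8
DEFAULT_NOISE_LEVEL = 4.0  # cm/s
DEFAULT_SPEED_WINDOW_S = 0.3
DEFAULT_MIN_DURATION_S = 0.5


@dataclass
class LocomotionTrack:
    """Uniformly sampled x-y positions (cm) with timestamps (s)."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.time.shape == self.x.shape == self.y.shape):
            raise ValueError("time, x, y must have equal length")
        if self.time.size < 2 or np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing with >= 2 samples")
        if np.any(~np.isfinite(self.x)) or np.any(~np.isfinite(self.y)):
            raise ValueError("positions must be finite")

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.time, "x_cm": self.x, "y_cm": self.y}).to_csv(
            path, index=False
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "LocomotionTrack":
        tab = pd.read_csv(path)
        return cls(tab["time_s"].to_numpy(), tab["x_cm"].to_numpy(), tab["y_cm"].to_numpy())


@dataclass
class Episode:
    start: int  # inclusive sample index
    end: int    # exclusive sample index
    label: str  # "rest" | "motion"


@dataclass
class EpisodeSet:
    episodes: list[Episode]
    max_sd: dict[int, float] = field(default_factory=dict)       # episode idx -> cm/s
    log_max_sd: dict[int, float] = field(default_factory=dict)   # natural log
    full_motion: dict[int, bool] = field(default_factory=dict)

    def motion_indices(self) -> list[int]:
        return [i for i, ep in enumerate(self.episodes) if ep.label == "motion"]


@dataclass
class ModeSplit:
    """Two-mode split of log max-SD values at the density antimode."""

    threshold: float | None
    labels: np.ndarray  # True = full motion (above threshold)
    bimodal: bool
    bandwidth: float


def compute_speed(track: LocomotionTrack, window_s: float = DEFAULT_SPEED_WINDOW_S) -> np.ndarray:
    """Smoothed speed (cm/s): net displacement across a centered window.

    The window shrinks symmetrically at the track edges; the first and last
    samples use a one-sided single-step difference.
    """
    n = track.time.size
    dt = float(np.median(np.diff(track.time)))
    half = int(round(window_s / dt / 2.0))
    if half < 1:
        raise ValueError("window must span at least 2 samples")
    if 2 * half + 1 > n:
        raise ValueError("window longer than track")
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    h = np.maximum(h, 1)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, n - 1)
    disp = np.hypot(track.x[hi] - track.x[lo], track.y[hi] - track.y[lo])
    span = track.time[hi] - track.time[lo]
    return disp / span


def segment_episodes(
    speed: np.ndarray,
    noise_level: float = DEFAULT_NOISE_LEVEL,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
    rate_hz: float = NOMINAL_RATE_HZ,
) -> EpisodeSet:
    """Partition the recording into alternating rest/motion episodes.

    Samples are motion where speed exceeds ``noise_level``; runs shorter
    than ``min_duration_s`` are merged into their longer neighbour until
    none remain, keeping a strict rest/motion alternation.
    """
    speed = np.asarray(speed, dtype=float)
    if np.any(~np.isfinite(speed)):
        raise ValueError("speed series must be finite")
    moving = speed > noise_level
    # run-length encode
    bounds = [0] + list(np.nonzero(np.diff(moving))[0] + 1) + [speed.size]
    runs = [
        Episode(bounds[i], bounds[i + 1], "motion" if moving[bounds[i]] else "rest")
        for i in range(len(bounds) - 1)
    ]
    min_len = max(1, int(round(min_duration_s * rate_hz)))

    def merge_pass(runs: list[Episode]) -> list[Episode] | None:
        if len(runs) < 2:
            return None
        lengths = [ep.end - ep.start for ep in runs]
        order = np.argsort(lengths, kind="stable")
        for i in order:
            if lengths[i] >= min_len:
                return None  # shortest remaining run is long enough
            ep = runs[i]
            left = runs[i - 1] if i > 0 else None
            right = runs[i + 1] if i < len(runs) - 1 else None
            # absorb into the longer neighbour (ties -> left)
            if left is not None and (
                right is None or (left.end - left.start) >= (right.end - right.start)
            ):
                merged = Episode(left.start, ep.end, left.label)
                new = runs[: i - 1] + [merged] + runs[i + 1 :]
            else:
                merged = Episode(ep.start, right.end, right.label)
                new = runs[:i] + [merged] + runs[i + 2 :]
            # collapse any adjacent same-label runs introduced by the merge
            collapsed: list[Episode] = []
            for r in new:
                if collapsed and collapsed[-1].label == r.label:
                    collapsed[-1] = Episode(collapsed[-1].start, r.end, r.label)
                else:
                    collapsed.append(r)
            return collapsed
        return None

    while True:
        nxt = merge_pass(runs)
        if nxt is None:
            break
        runs = nxt
    return EpisodeSet(episodes=runs)


def episode_max_sd(
    speed: np.ndarray,
    episodes: EpisodeSet,
    variant: str = "max-speed",
    rate_hz: float = NOMINAL_RATE_HZ,
) -> EpisodeSet:
    """Per-motion-episode maximal speed statistic (max-SD, cm/s).

    The default "max-speed" variant takes the maximum of the smoothed
    speed within the episode; "max-derivative" takes the maximum absolute
    central-difference speed derivative.  Natural-log values are stored
    alongside for the mode analysis.
    """
    speed = np.asarray(speed, dtype=float)
    for i in episodes.motion_indices():
        ep = episodes.episodes[i]
        seg = speed[ep.start : ep.end]
        if seg.size == 0:
            raise ValueError("empty episode")
        if variant == "max-speed":
            val = float(seg.max())
        elif variant == "max-derivative":
            if seg.size < 3:
                val = 0.0
            else:
                deriv = (seg[2:] - seg[:-2]) * rate_hz / 2.0
                val = float(np.abs(deriv).max())
        else:
            raise ValueError(f"unknown max-SD variant {variant!r}")
        episodes.max_sd[i] = val
        episodes.log_max_sd[i] = float(np.log(val)) if val > 0 else float("-inf")
    return episodes


def _silverman_bandwidth(values: np.ndarray) -> float:
    sd = values.std(ddof=1)
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * values.size ** (-0.2)


def identify_motion_modes(log_max_sd: np.ndarray, bandwidth: float | None = None) -> ModeSplit:
    """Split log max-SD values at the antimode of their smoothed density.

    A Gaussian KDE (Silverman's rule unless a bandwidth is given) is
    evaluated on a fine grid; the two highest local maxima define the
    modes and the deepest local minimum between them is the threshold.
    Values above the threshold are flagged as full motion.  If the density
    is unimodal, no threshold is returned and ``bimodal`` is False — all
    episodes are then treated as full motion rather than silently split.
    """
    values = np.asarray(log_max_sd, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 10:
        raise ValueError("need at least 10 motion episodes for the mode analysis")
    h = bandwidth if bandwidth is not None else _silverman_bandwidth(values)
    if h <= 0:
        return ModeSplit(None, np.ones_like(values, dtype=bool), False, h)
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, 1024)
    dens = np.exp(-0.5 * ((grid[:, None] - values[None, :]) / h) ** 2).sum(axis=1)
    dens /= values.size * h * np.sqrt(2 * np.pi)

    interior = np.arange(1, grid.size - 1)
    maxima = interior[(dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])]
    if maxima.size < 2:
        return ModeSplit(None, np.ones(values.size, dtype=bool), False, h)
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo_m, hi_m = int(top2.min()), int(top2.max())
    between = np.arange(lo_m + 1, hi_m)
    if between.size == 0:
        return ModeSplit(None, np.ones(values.size, dtype=bool), False, h)
    threshold = float(grid[between[np.argmin(dens[between])]])
    labels = np.asarray(log_max_sd, dtype=float) > threshold
    return ModeSplit(threshold, labels, True, h)


def motion_summary(track: LocomotionTrack, episodes: EpisodeSet) -> dict:
    """Spatial spread (cm) and average max-SD (cm/s) over full-motion
    episodes.

    Spatial spread is the cumulative path length accrued during
    full-motion episodes.  Returns zeros (with a flag) when no episode is
    flagged as full motion.
    """
    step = np.hypot(np.diff(track.x), np.diff(track.y))
    spread = 0.0
    max_sds = []
    any_full = False
    for i in episodes.motion_indices():
        if not episodes.full_motion.get(i, False):
            continue
        any_full = True
        ep = episodes.episodes[i]
        spread += float(step[ep.start : max(ep.end - 1, ep.start)].sum())
        max_sds.append(episodes.max_sd[i])
    return {
        "spatial_spread_cm": spread,
        "avg_max_sd_cm_s": float(np.mean(max_sds)) if max_sds else 0.0,
        "n_full_motion": len(max_sds),
        "no_full_motion": not any_full,
    }


def relative_change(before: float, after: float) -> float:
    """Percent change 100 * (after - before) / before."""
    if before == 0:
        raise ValueError("baseline value must be nonzero")
    return 100.0 * (after - before) / before


def analyze_track(
    track: LocomotionTrack,
    noise_level: float = DEFAULT_NOISE_LEVEL,
    window_s: float = DEFAULT_SPEED_WINDOW_S,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
    variant: str = "max-speed",
) -> tuple[EpisodeSet, dict]:
    """Full per-track analysis: speed, episodes, modes, summary."""
    speed = compute_speed(track, window_s)
    episodes = segment_episodes(speed, noise_level, min_duration_s, rate_hz=track.rate_hz)
    episode_max_sd(speed, episodes, variant=variant, rate_hz=track.rate_hz)
    motion = episodes.motion_indices()
    if len(motion) >= 10:
        logs = np.array([episodes.log_max_sd[i] for i in motion])
        split = identify_motion_modes(logs)
        for j, i in enumerate(motion):
            episodes.full_motion[i] = bool(split.labels[j])
    else:
        for i in motion:
            episodes.full_motion[i] = True
    summary = motion_summary(track, episodes)
    return episodes, summary
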