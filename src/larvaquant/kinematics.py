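"""Peristalsis-cycle crawling kinematics from spine-tracking tables.

The measurement chain mirrors the classic FIM-based analysis of larval
crawling: the spine length (sum of the distances between the five tracked
spine points) oscillates once per peristaltic contraction; its smoothed
time derivative oscillates around zero, and successive positive-going zero
crossings delimit the cycles.  Per cycle we measure the stride length (net
centroid displacement) and stride duration; the walking rate is the mean
per-frame centroid displacement rate over the whole record.

Cycle-boundary convention: a boundary sits at each positive-going zero
crossing of dL/dt, i.e. the onset of elongation.  Any consistent crossing
phase yields the same durations and net displacements over full cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .io import SpineTrack

#: default smoothing window in frames (0.6 s at 5 fps; wider windows start
#: to erase the ~5.5-frame cycles of real recordings)
DEFAULT_WINDOW = 3

#: cycles shorter than this are treated as jitter and merged forward (s)
DEFAULT_MIN_CYCLE_DURATION = 0.4


@dataclass
class SpineLengthSeries:
    """Spine length L(t) and, once computed, its smoothed derivative."""

    time: np.ndarray
    L: np.ndarray
    fps: float
    dLdt: Optional[np.ndarray] = None


@dataclass
class PeristalsisCycle:
    """One contraction cycle between interpolated crossing times."""

    t_start: float
    t_end: float
    stride_length: Optional[float] = None

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class LarvaKinematics:
    """Per-larva summary over the recording."""

    larva_id: str
    walking_rate: float
    n_cycles: int
    stride_length_mean: Optional[float] = None
    stride_duration_mean: Optional[float] = None
    genotype: str = ""

    @property
    def has_cycles(self) -> bool:
        return self.n_cycles > 0


def spine_length(track: SpineTrack) -> SpineLengthSeries:
    """L(t) = sum of the 4 distances between successive spine points.

    Gap frames propagate as NaN.
    """
    seg = np.diff(track.points, axis=1)          # (n, 4, 2)
    L = np.linalg.norm(seg, axis=2).sum(axis=1)  # (n,)
    return SpineLengthSeries(time=track.time, L=L, fps=track.fps)


def smooth_derivative(series: SpineLengthSeries,
                      window: int = DEFAULT_WINDOW) -> SpineLengthSeries:
    """Moving-average smoothing of L then central-difference derivative.

    ``window`` must be odd; a window of 1 means no smoothing.  Endpoints
    use one-sided differences.  NaN gaps propagate (and widen by half a
    window), so cycles near gaps are later discarded rather than distorted.
    """
    n = len(series.L)
    if n < 3:
        raise ValueError("need at least 3 frames to differentiate")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd number of frames")
    if window > n:
        raise ValueError(f"window ({window}) larger than series ({n})")
    if window == 1:
        Ls = series.L.astype(float)
    else:
        Ls = uniform_filter1d(series.L.astype(float), size=window,
                              mode="nearest")
    dLdt = np.gradient(Ls, series.time)
    return SpineLengthSeries(time=series.time, L=series.L, fps=series.fps,
                             dLdt=dLdt)


#: derivative magnitudes below this are numerical zero (mm/s); guards
#: against float noise on perfectly constant spine lengths
ZERO_TOL = 1e-9


def _positive_crossings(time: np.ndarray, d: np.ndarray,
                        tol: float = ZERO_TOL) -> np.ndarray:
    """Interpolated times of positive-going zero crossings of d(t)."""
    with np.errstate(invalid="ignore"):
        neg = d[:-1] < -tol
        nonneg = d[1:] >= -tol
    ok = neg & nonneg & np.isfinite(d[:-1]) & np.isfinite(d[1:])
    idx = np.nonzero(ok)[0]
    # linear interpolation of the crossing time inside each bracket
    t0, t1 = time[idx], time[idx + 1]
    d0, d1 = d[idx], d[idx + 1]
    frac = np.where(d1 > d0, -d0 / (d1 - d0), 0.0)
    crossings = t0 + frac * (t1 - t0)
    # a record that opens exactly at a crossing (d=0 then rising) starts
    # a complete cycle at its first frame
    if len(d) > 1 and abs(d[0]) <= tol and d[1] > tol:
        crossings = np.concatenate([[time[0]], crossings])
    return crossings


def segment_cycles(series: SpineLengthSeries,
                   min_cycle_duration: float = DEFAULT_MIN_CYCLE_DURATION
                   ) -> List[PeristalsisCycle]:
    """Cycle boundaries at successive positive-going zero crossings of dL/dt.

    Crossing times are linearly interpolated between frames.  Cycles
    shorter than ``min_cycle_duration`` are merged into the following
    cycle (the short cycle's start boundary survives, its end boundary is
    dropped).  Partial cycles before the first and after the last crossing
    are discarded; cycles containing a gap frame are discarded.
    """
    if series.dLdt is None:
        raise ValueError("series has no derivative; call smooth_derivative first")
    crossings = _positive_crossings(series.time, series.dLdt)
    if len(crossings) < 2:
        return []
    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] >= min_cycle_duration:
            kept.append(c)
    gaps = series.time[~np.isfinite(series.L)]
    cycles = []
    for a, b in zip(kept[:-1], kept[1:]):
        if gaps.size and np.any((gaps > a) & (gaps < b)):
            continue
        cycles.append(PeristalsisCycle(t_start=float(a), t_end=float(b)))
    return cycles


def _interp_centroid(track: SpineTrack, t: float) -> np.ndarray:
    """Centroid position linearly interpolated at time t (gap-aware)."""
    good = ~track.gap_mask
    tt = track.time[good]
    c = track.centroid[good]
    x = np.interp(t, tt, c[:, 0])
    y = np.interp(t, tt, c[:, 1])
    return np.array([x, y])


def stride_metrics(track: SpineTrack,
                   cycles: List[PeristalsisCycle]) -> List[PeristalsisCycle]:
    """Fill stride length S = |centroid(t_end) - centroid(t_start)| per cycle."""
    for cyc in cycles:
        p0 = _interp_centroid(track, cyc.t_start)
        p1 = _interp_centroid(track, cyc.t_end)
        cyc.stride_length = float(np.linalg.norm(p1 - p0))
    return cycles


def walking_rate(track: SpineTrack) -> float:
    """Mean per-frame centroid displacement rate, in mm/s.

    Steps adjacent to a gap frame are skipped.  Raises if no valid step
    remains.
    """
    c = track.centroid
    good = ~track.gap_mask
    valid = good[:-1] & good[1:]
    if not valid.any():
        raise ValueError(f"track {track.larva_id}: no valid centroid steps")
    steps = np.linalg.norm(np.diff(c, axis=0), axis=1)[valid]
    return float(steps.mean() * track.fps)


def summarize_larva(track: SpineTrack, window: int = DEFAULT_WINDOW,
                    min_cycle_duration: float = DEFAULT_MIN_CYCLE_DURATION
                    ) -> LarvaKinematics:
    """Full per-larva measurement: walking rate plus per-cycle averages.

    Larvae with zero detected cycles carry the walking rate only; their
    stride fields stay None (``has_cycles`` is False).
    """
    series = smooth_derivative(spine_length(track), window=window)
    cycles = stride_metrics(track, segment_cycles(series, min_cycle_duration))
    v = walking_rate(track)
    if not cycles:
        return LarvaKinematics(larva_id=track.larva_id, walking_rate=v,
                               n_cycles=0, genotype=track.genotype)
    S = [c.stride_length for c in cycles]
    T = [c.duration for c in cycles]
    return LarvaKinematics(
        larva_id=track.larva_id,
        walking_rate=v,
        n_cycles=len(cycles),
        stride_length_mean=float(np.mean(S)),
        stride_duration_mean=float(np.mean(T)),
        genotype=track.genotype,
    )


def analyze_cohort(tracks, window: int = DEFAULT_WINDOW,
                   min_cycle_duration: float = DEFAULT_MIN_CYCLE_DURATION):
    """Summaries for a collection of tracks.

    Returns (per_larva, per_cycle) DataFrames.  per_larva has one row per
    larva (walking_rate, stride_length_mean, stride_duration_mean,
    n_cycles); per_cycle one row per detected cycle.
    """
    larva_rows, cycle_rows = [], []
    for tr in tracks:
        series = smooth_derivative(spine_length(tr), window=window)
        cycles = stride_metrics(tr, segment_cycles(series, min_cycle_duration))
        v = walking_rate(tr)
        S = [c.stride_length for c in cycles]
        T = [c.duration for c in cycles]
        larva_rows.append({
            "larva_id": tr.larva_id, "genotype": tr.genotype,
            "walking_rate": v,
            "stride_length_mean": float(np.mean(S)) if cycles else None,
            "stride_duration_mean": float(np.mean(T)) if cycles else None,
            "n_cycles": len(cycles),
        })
        for cyc in cycles:
            cycle_rows.append({
                "larva_id": tr.larva_id, "genotype": tr.genotype,
                "t_start": cyc.t_start, "t_end": cyc.t_end,
                "stride_duration": cyc.duration,
                "stride_length": cyc.stride_length,
            })
    per_larva = pd.DataFrame(larva_rows)
    per_cycle = pd.DataFrame(cycle_rows, columns=[
        "larva_id", "genotype", "t_start", "t_end",
        "stride_duration", "stride_length"])
    return per_larva, per_cycle
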