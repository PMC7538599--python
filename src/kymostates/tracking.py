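"""Protomer localisation and tracking in line-scan kymographs.

The tracking chain is: low-pass filter the time axis, detect lateral
peaks per scan line, link candidates into tracks (looking forward in
time across disappearances, e.g. inward-facing excursions), then read
the height/time trace of each track from the *unfiltered* kymograph so
state amplitudes are not smoothed away.  The module also provides the
height-histogram membrane packing analysis used on topography images.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .containers import HeightTrace, Kymograph, TopographyImage
from .errors import ConfigurationError

__all__ = [
    "ProtomerTrack",
    "lowpass_time",
    "membrane_columns",
    "line_baseline",
    "detect_peaks",
    "link_tracks",
    "extract_trace",
    "membrane_packing_analysis",
]


def lowpass_time(kymo: Kymograph, cutoff_window: float) -> Kymograph:
    """Zero-phase moving average along the time axis of each column.

    ``cutoff_window`` is the averaging window in seconds; it is rounded
    to an odd number of scan lines (odd so the filter stays zero-phase).
    A one-line window is the identity.  The lateral axis is untouched.
    """
    if cutoff_window < kymo.line_period:
        raise ConfigurationError("cutoff_window must be at least one line period")
    w = int(round(cutoff_window / kymo.line_period))
    if w % 2 == 0:
        w += 1
    if w > kymo.n_lines:
        raise ConfigurationError("cutoff_window longer than the recording")
    if w == 1:
        filtered = kymo.heights.copy()
    else:
        filtered = uniform_filter1d(kymo.heights, size=w, axis=0, mode="nearest")
    return Kymograph(
        heights=filtered,
        line_period=kymo.line_period,
        pixel_size=kymo.pixel_size,
        meta=dict(kymo.meta, lowpass_window_lines=w),
        truths=kymo.truths,
    )


def membrane_columns(kymo: Kymograph, rel_threshold: float = 0.5) -> np.ndarray:
    """Boolean mask of protomer-free columns.

    A column is considered bare membrane when its temporal median height
    lies within ``rel_threshold`` nm of the lowest column median; columns
    under protomer ridges have systematically higher medians.
    """
    col_median = np.median(kymo.heights, axis=0)
    return col_median < col_median.min() + rel_threshold


def line_baseline(
    kymo: Kymograph,
    smooth_window: float = 0.33,
    rel_threshold: float = 0.5,
    min_free_columns: int = 3,
) -> np.ndarray:
    """Per-line membrane baseline (nm), one value per scan line.

    The baseline is the median over protomer-free columns, smoothed with
    a moving average (baseline drift is slow compared to state dynamics).
    When fewer than ``min_free_columns`` bare columns exist, a global
    scalar baseline is used with a warning.
    """
    free = membrane_columns(kymo, rel_threshold)
    if free.sum() < min_free_columns:
        warnings.warn(
            "no protomer-free columns found; falling back to a global baseline",
            stacklevel=2,
        )
        return np.full(kymo.n_lines, float(np.median(kymo.heights)))
    base = np.median(kymo.heights[:, free], axis=1)
    w = int(round(smooth_window / kymo.line_period))
    if w % 2 == 0:
        w += 1
    if w > 1:
        base = uniform_filter1d(base, size=min(w, kymo.n_lines), mode="nearest")
    return base


def _subpixel(h: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """3-point parabolic refinement of integer peak columns."""
    y0 = h[idx - 1]
    y1 = h[idx]
    y2 = h[idx + 1]
    denom = y0 - 2 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 0.5 * (y0 - y2) / denom
    delta = np.where(np.abs(denom) < 1e-12, 0.0, delta)
    return idx + np.clip(delta, -0.5, 0.5)


def detect_peaks(
    kymo: Kymograph,
    min_height: float = 0.5,
    min_separation: float = 3.0,
    lateral_smooth: int = 2,
) -> list:
    """Per-line lateral peak candidates above the membrane baseline.

    Local maxima at least ``min_height`` nm above the per-line baseline
    and ``min_separation`` nm apart (taller peaks win) are refined to
    sub-pixel positions by 3-point parabolic interpolation.  Each line
    is first smoothed laterally with a small binomial kernel
    (``lateral_smooth`` passes of [1,2,1]/4; 0 disables) — tip-broadened
    ridges have nearly flat apices on which a raw 3-point parabola is
    degenerate and the located maximum rattles across the plateau.
    Returns a list with one float array of pixel positions per scan
    line; lines without candidates yield empty arrays.
    """
    if min_height <= 0 or min_separation <= 0:
        raise ConfigurationError("thresholds must be positive")
    base = line_baseline(kymo)
    h = kymo.heights - base[:, None]
    for _ in range(lateral_smooth):
        padded = np.pad(h, ((0, 0), (1, 1)), mode="edge")
        h = 0.25 * padded[:, :-2] + 0.5 * padded[:, 1:-1] + 0.25 * padded[:, 2:]
    sep_px = max(int(round(min_separation / kymo.pixel_size)), 1)

    interior = h[:, 1:-1]
    is_peak = (interior > h[:, :-2]) & (interior >= h[:, 2:]) & (interior > min_height)
    lines, cols = np.nonzero(is_peak)
    cols = cols + 1
    out = [np.empty(0) for _ in range(kymo.n_lines)]
    if lines.size == 0:
        return out
    boundaries = np.searchsorted(lines, np.arange(kymo.n_lines + 1))
    for ln in np.unique(lines):
        cand = cols[boundaries[ln] : boundaries[ln + 1]]
        if cand.size > 1:
            order = np.argsort(h[ln, cand])[::-1]
            kept: list = []
            for c in cand[order]:
                if all(abs(int(c) - int(k)) >= sep_px for k in kept):
                    kept.append(c)
            cand = np.sort(np.array(kept))
        out[ln] = _subpixel(h[ln], cand.astype(np.intp))
    return out


class _RunningFit:
    """Incremental least-squares line fit over a sliding window of
    (line, position) observations; used for per-track drift estimates."""

    def __init__(self, window: int):
        self.buf: deque = deque()
        self.window = max(window, 2)
        self.sx = self.sy = self.sxx = self.sxy = 0.0

    def add(self, x: float, y: float) -> None:
        self.buf.append((x, y))
        self.sx += x
        self.sy += y
        self.sxx += x * x
        self.sxy += x * y
        while len(self.buf) > self.window:
            ox, oy = self.buf.popleft()
            self.sx -= ox
            self.sy -= oy
            self.sxx -= ox * ox
            self.sxy -= ox * oy

    def slope(self) -> float:
        n = len(self.buf)
        if n < 2:
            return 0.0
        denom = n * self.sxx - self.sx * self.sx
        if abs(denom) < 1e-12:
            return 0.0
        return (n * self.sxy - self.sx * self.sy) / denom


@dataclass
class ProtomerTrack:
    """One protomer ridge followed through the kymograph.

    ``positions`` holds a sub-pixel lateral position (pixels) for every
    line in ``[first_line, last_line]``; inside recorded gaps the
    position is the drift-extrapolated estimate and ``gap_mask`` is
    True.  ``ambiguous_lines`` lists lines where competing candidates
    fell within the search radius.
    """

    track_id: int
    first_line: int
    last_line: int
    positions: np.ndarray
    gap_mask: np.ndarray
    gaps: list = field(default_factory=list)
    ambiguous_lines: list = field(default_factory=list)

    @property
    def n_lines(self) -> int:
        return self.last_line - self.first_line + 1

    def duration(self, line_period: float) -> float:
        return self.n_lines * line_period


class _TrackBuilder:
    def __init__(self, track_id: int, line: int, pos: float, drift_window: int):
        self.track_id = track_id
        self.first_line = line
        self.positions = [pos]
        self.gap_mask = [False]
        self.gaps: list = []
        self.ambiguous: list = []
        self.gap_run = 0
        self.last_obs_line = line
        self.last_obs_pos = pos
        self.fit = _RunningFit(drift_window)
        self.fit.add(line, pos)

    def predict(self, line: int) -> float:
        return self.last_obs_pos + self.fit.slope() * (line - self.last_obs_line)

    def observe(self, line: int, pos: float) -> None:
        if self.gap_run:
            self.gaps.append((line - self.gap_run, line - 1))
            self.gap_run = 0
        self.positions.append(pos)
        self.gap_mask.append(False)
        self.last_obs_line = line
        self.last_obs_pos = pos
        self.fit.add(line, pos)

    def miss(self, line: int) -> None:
        self.positions.append(self.predict(line))
        self.gap_mask.append(True)
        self.gap_run += 1

    def close(self) -> ProtomerTrack:
        # trim an unresolved trailing gap
        n = len(self.positions) - self.gap_run
        last = self.first_line + n - 1
        return ProtomerTrack(
            track_id=self.track_id,
            first_line=self.first_line,
            last_line=last,
            positions=np.array(self.positions[:n]),
            gap_mask=np.array(self.gap_mask[:n], dtype=bool),
            gaps=self.gaps,
            ambiguous_lines=self.ambiguous,
        )


def link_tracks(
    candidates: Sequence[np.ndarray],
    *,
    line_period: float,
    pixel_size: float,
    search_radius: float = 2.0,
    max_gap: float = 1.0,
    drift_window: float = 1.0,
    min_duration: float = 0.0,
) -> list:
    """Link per-line peak candidates into protomer tracks.

    Line-to-line association is greedy nearest neighbour within
    ``search_radius`` (nm) of each track's drift-extrapolated position;
    a track that loses its candidate (for instance during an
    inward-facing excursion below the detection threshold) keeps looking
    forward in time for up to ``max_gap`` seconds before it is closed.
    Unclaimed candidates start new tracks; a protomer lost beyond
    ``max_gap`` and refound is deliberately counted as a new track.
    """
    radius_px = search_radius / pixel_size
    max_gap_lines = int(round(max_gap / line_period))
    drift_lines = max(int(round(drift_window / line_period)), 2)
    min_lines = int(round(min_duration / line_period))

    active: list = []
    done: list = []
    next_id = 0
    for line, cand in enumerate(candidates):
        cand = np.asarray(cand, dtype=float)
        assigned_tracks = set()
        assigned_cands: set = set()
        if active and cand.size:
            preds = np.array([b.predict(line) for b in active])
            d = np.abs(preds[:, None] - cand[None, :])
            within = d <= radius_px
            order = np.argsort(d, axis=None, kind="stable")
            for flat in order:
                ti, ci = divmod(int(flat), cand.size)
                if d[ti, ci] > radius_px:
                    break
                if ti in assigned_tracks or ci in assigned_cands:
                    continue
                b = active[ti]
                # ambiguity: another candidate in reach of this track, or
                # another track in reach of this candidate
                if within[ti].sum() > 1 or within[:, ci].sum() > 1:
                    b.ambiguous.append(line)
                b.observe(line, float(cand[ci]))
                assigned_tracks.add(ti)
                assigned_cands.add(ci)
        still_active = []
        for ti, b in enumerate(active):
            if ti in assigned_tracks:
                still_active.append(b)
                continue
            b.miss(line)
            if b.gap_run > max_gap_lines:
                done.append(b.close())
            else:
                still_active.append(b)
        active = still_active
        # unclaimed candidates seed new tracks, but not on top of an
        # existing track (an unclaimed candidate within reach of a track
        # is a shoulder or localisation outlier, not a new protomer)
        preds = np.array([b.predict(line) for b in active])
        for ci in range(cand.size):
            if ci in assigned_cands:
                continue
            if preds.size and np.min(np.abs(preds - cand[ci])) <= radius_px:
                continue
            active.append(_TrackBuilder(next_id, line, float(cand[ci]), drift_lines))
            next_id += 1
    done.extend(b.close() for b in active)
    tracks = [t for t in done if t.n_lines >= max(min_lines, 1)]
    tracks.sort(key=lambda t: (t.first_line, t.positions[0]))
    for i, t in enumerate(tracks):
        t.track_id = i
    return tracks


def extract_trace(
    kymo_raw: Kymograph,
    track: ProtomerTrack,
    read_halfwidth: float = 1.5,
    baseline: Optional[np.ndarray] = None,
) -> HeightTrace:
    """Read a protomer's height/time trace from the unfiltered kymograph.

    Per line the height is the maximum of the raw line within
    ``read_halfwidth`` nm of the tracked (or, in gaps, extrapolated)
    position, minus the per-line membrane baseline.  Using the raw
    maximum keeps state amplitudes unbiased by the tracking filter and
    robust to sub-pixel tracking error.
    """
    if track.first_line < 0 or track.last_line >= kymo_raw.n_lines:
        raise ConfigurationError("track extends outside the kymograph")
    if baseline is None:
        baseline = line_baseline(kymo_raw)
    k = max(int(np.ceil(read_halfwidth / kymo_raw.pixel_size)), 0)
    lines = np.arange(track.first_line, track.last_line + 1)
    centers = np.clip(np.round(track.positions).astype(np.intp), 0, kymo_raw.n_pixels - 1)
    offsets = np.arange(-k, k + 1)
    cols = np.clip(centers[:, None] + offsets[None, :], 0, kymo_raw.n_pixels - 1)
    vals = kymo_raw.heights[lines[:, None], cols]
    heights = vals.max(axis=1) - baseline[lines]
    return HeightTrace(
        times=lines * kymo_raw.line_period,
        heights=heights,
        track_id=track.track_id,
    )


def membrane_packing_analysis(
    img: TopographyImage,
    t_lo: float = 3.5,
    t_mid: float = 6.1,
    t_hi: float = 10.0,
    bins: int = 120,
) -> dict:
    """Height-histogram packing analysis of a topography image.

    Pixels in ``(t_lo, t_mid]`` count as bare membrane and pixels in
    ``(t_mid, t_hi]`` as protein-packed domain; both area fractions are
    normalised by the combined membrane + domain area.
    """
    if not t_lo < t_mid < t_hi:
        raise ConfigurationError("thresholds must satisfy t_lo < t_mid < t_hi")
    h = img.heights.ravel()
    counts, edges = np.histogram(h, bins=bins)
    n_mem = int(np.count_nonzero((h > t_lo) & (h <= t_mid)))
    n_dom = int(np.count_nonzero((h > t_mid) & (h <= t_hi)))
    total = n_mem + n_dom
    return {
        "histogram": {"counts": counts, "bin_edges": edges},
        "membrane_area_fraction": n_mem / total if total else float("nan"),
        "domain_area_fraction": n_dom / total if total else float("nan"),
        "n_pixels": h.size,
    }
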