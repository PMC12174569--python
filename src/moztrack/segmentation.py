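"""Track interpolation, sliding-window segmentation and quality filtering.

Raw tracks have missing frames (occlusion, detection failure).  Missing
interior frames are filled by linear interpolation against frame index and
flagged as interpolated; tracks are then split into fixed-duration
overlapping windows (default 7.5 s windows with 7 s overlap at 50 fps) so
all modelling units have equal duration.  Each segment carries a quality
score that grows superlinearly with consecutive interpolated runs; the
removal threshold is chosen by maximising the mutual information between
features and the class label across candidate quality levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from .synthio import Track

__all__ = [
    "Segment",
    "filter_min_duration",
    "interpolate_gaps",
    "window_track",
    "n_windows",
    "segment_quality",
    "select_quality_threshold",
    "apply_quality_filter",
    "segment_study",
    "segments_table",
]

log = logging.getLogger(__name__)


@dataclass
class Segment:
    """A fixed-length window of one track, the unit of classification."""

    trial_id: str
    track_id: str
    segment_index: int
    start_s: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    real: np.ndarray
    quality: float
    label: str | None = None
    resistance: str | None = None
    strain: str | None = None

    @property
    def n_samples(self) -> int:
        return len(self.t)


def filter_min_duration(tracks: list[Track], min_s: float = 1.0) -> list[Track]:
    """Keep tracks whose observed duration is at least ``min_s`` (inclusive)."""
    kept = [t for t in tracks if t.duration_s >= min_s]
    if len(kept) < len(tracks):
        log.info("min-duration filter: %d/%d tracks kept", len(kept), len(tracks))
    return kept


def interpolate_gaps(track: Track) -> Track:
    """Fill every missing interior frame by linear interpolation.

    Interpolation is against frame index (the uniform camera clock), not
    wall time.  Inserted samples are flagged interpolated; endpoints and
    observed samples are untouched.  The result has frame step 1.
    """
    if track.n_samples < 2:
        raise ValueError("cannot interpolate a track with < 2 samples")
    f0, f1 = int(track.frames[0]), int(track.frames[-1])
    full = np.arange(f0, f1 + 1, dtype=np.int64)
    if len(full) == track.n_samples:
        return track
    x = np.interp(full, track.frames, track.x)
    y = np.interp(full, track.frames, track.y)
    real = np.zeros(len(full), dtype=bool)
    real[np.searchsorted(full, track.frames)] = track.real
    from dataclasses import replace

    return replace(track, frames=full, x=x, y=y, real=real)


def n_windows(n: int, n_w: int, stride: int) -> int:
    """Number of full windows of length ``n_w`` at the given stride."""
    if n < n_w:
        return 0
    return (n - n_w) // stride + 1


def _window_geometry(window_s: float, overlap_s: float, fps: float) -> tuple[int, int]:
    if not (0 <= overlap_s < window_s):
        raise ValueError("require 0 <= overlap_s < window_s")
    n_w = int(round(window_s * fps))
    stride = int(round((window_s - overlap_s) * fps))
    if stride <= 0:
        raise ValueError("window/overlap give a non-positive stride")
    if n_w < 2:
        raise ValueError("window too short for the frame rate")
    return n_w, stride


def window_track(
    track: Track, window_s: float, overlap_s: float, fps: float
) -> list[Segment]:
    """Split an interpolated (step-1) track into full overlapping windows.

    Only complete windows are emitted; a track shorter than the window
    yields no segments.
    """
    n_w, stride = _window_geometry(window_s, overlap_s, fps)
    if np.any(np.diff(track.frames) != 1):
        raise ValueError("window_track requires an interpolated (step-1) track")
    n = track.n_samples
    t = track.t
    segments = []
    for k in range(n_windows(n, n_w, stride)):
        lo = k * stride
        sl = slice(lo, lo + n_w)
        real = track.real[sl]
        segments.append(
            Segment(
                trial_id=track.trial_id,
                track_id=track.track_id,
                segment_index=k,
                start_s=float(t[lo]),
                t=t[sl].copy(),
                x=track.x[sl].copy(),
                y=track.y[sl].copy(),
                real=real.copy(),
                quality=_quality_from_flags(real),
            )
        )
    return segments


def _quality_from_flags(real: np.ndarray) -> float:
    """Sum of squared interpolated-run lengths over segment length.

    Zero iff gap-free; one run of length r costs r^2/L, so consecutive
    interpolation is penalised more than the same amount scattered.
    """
    gaps = ~np.asarray(real, dtype=bool)
    if not gaps.any():
        return 0.0
    # run-length encode the gap mask
    edges = np.diff(gaps.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if gaps[0]:
        starts = np.concatenate([[0], starts])
    if gaps[-1]:
        ends = np.concatenate([ends, [len(gaps)]])
    runs = ends - starts
    return float(np.sum(runs.astype(np.float64) ** 2) / len(gaps))


def segment_quality(segment: Segment) -> float:
    """Information-quality score of a segment (larger = worse)."""
    return _quality_from_flags(segment.real)


def _equal_frequency_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretise into (up to) ``n_bins`` equal-frequency bins."""
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), values, side="right")


def select_quality_threshold(
    qualities: np.ndarray,
    labels: np.ndarray,
    feature_table: pd.DataFrame,
    grid: np.ndarray | None = None,
    n_bins: int = 10,
) -> float:
    """Choose the quality-removal threshold by mutual information.

    For each feature and each candidate threshold q, the mutual
    information MI(feature; label) is computed among segments with quality
    <= q (feature discretised into equal-frequency bins).  Each feature
    votes for the q maximising its MI (ties resolved toward the largest q,
    keeping more data); the final threshold is the MI-weighted average of
    the per-feature winners.
    """
    qualities = np.asarray(qualities, dtype=float)
    labels = np.asarray(labels)
    if grid is None:
        nz = qualities[qualities > 0]
        if nz.size == 0:
            return 0.0
        grid = np.unique(np.concatenate([[0.0], np.quantile(nz, np.linspace(0.1, 1.0, 10))]))
    grid = np.unique(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty threshold grid")

    best_q = []
    weights = []
    usable_any = False
    for col in feature_table.columns:
        vals = feature_table[col].to_numpy(dtype=float)
        mis = np.full(grid.size, np.nan)
        for i, q in enumerate(grid):
            keep = (qualities <= q) & np.isfinite(vals)
            if keep.sum() < max(n_bins, 4) or len(np.unique(labels[keep])) < 2:
                continue
            binned = _equal_frequency_bins(vals[keep], n_bins)
            mis[i] = mutual_info_score(labels[keep], binned)
        if np.all(np.isnan(mis)):
            continue
        usable_any = True
        best = np.nanmax(mis)
        # ties toward the largest q: take the last argmax
        idx = np.nonzero(mis == best)[0][-1]
        best_q.append(grid[idx])
        weights.append(best)
    if not usable_any:
        raise ValueError("no usable grid point for any feature (need >= 2 classes)")
    w = np.asarray(weights)
    if w.sum() == 0:
        log.warning("all features carry zero MI; keeping all segments")
        return float(grid.max())
    return float(np.sum(np.asarray(best_q) * w) / w.sum())


def apply_quality_filter(segments: list[Segment], threshold: float) -> list[Segment]:
    """Keep segments with quality <= threshold (inclusive)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    kept = [s for s in segments if s.quality <= threshold]
    log.info(
        "quality filter at %.4g: kept %d/%d segments", threshold, len(kept), len(segments)
    )
    return kept


def segment_study(
    tracks: list[Track],
    metadata: pd.DataFrame,
    window_s: float = 7.5,
    overlap_s: float = 7.0,
    fps: float = 50.0,
    min_track_duration_s: float = 1.0,
) -> list[Segment]:
    """Full segmentation stage: duration filter, interpolation, windowing.

    Trial metadata (net type, strain, resistance) is attached to every
    segment as its inherited class label.
    """
    meta = metadata.set_index("trial_id")
    tracks = filter_min_duration(tracks, min_track_duration_s)
    segments: list[Segment] = []
    for track in tracks:
        try:
            row = meta.loc[track.trial_id]
        except KeyError:
            raise KeyError(f"no metadata for trial {track.trial_id!r}") from None
        for seg in window_track(interpolate_gaps(track), window_s, overlap_s, fps):
            seg.label = str(row["net_type"])
            seg.resistance = str(row["resistance"])
            seg.strain = str(row["strain"])
            segments.append(seg)
    log.info("segmentation: %d tracks -> %d segments", len(tracks), len(segments))
    return segments


def segments_table(segments: list[Segment]) -> pd.DataFrame:
    """Summary table (one row per segment) for export."""
    return pd.DataFrame(
        {
            "trial_id": [s.trial_id for s in segments],
            "track_id": [s.track_id for s in segments],
            "segment_index": [s.segment_index for s in segments],
            "start_s": [s.start_s for s in segments],
            "quality": [s.quality for s in segments],
            "label": [s.label for s in segments],
            "resistance": [s.resistance for s in segments],
        }
    )
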