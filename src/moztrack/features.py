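"""Kinematic and geometric flight features per segment.

Velocity, speed, acceleration, heading change and curvature series are
derived from first differences of the 2D positions; each series carries a
validity mask so that statistical summaries only ever use observed (not
interpolated) positions.  The summary set per series is
{mean, sd, min, max, Q1, median, Q3} plus zero-crossing counts; geometric
scalars (path length, net displacement, straightness) describe track
shape.  The headline discriminators between treated- and untreated-net
flight are the zero-crossing count and first quartile of the flight-angle
change and the zero-crossing count of the horizontal velocity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import Segment

__all__ = [
    "KinematicSeries",
    "kinematic_series",
    "zero_crossings",
    "summarize_series",
    "extract_segment_features",
    "build_feature_table",
    "PROVENANCE_COLS",
    "feature_columns",
]

log = logging.getLogger(__name__)

#: columns of the feature table that are provenance, not model input
PROVENANCE_COLS = [
    "trial_id",
    "track_id",
    "segment_index",
    "start_s",
    "strain",
    "resistance",
    "net_type",
    "quality",
]

SUMMARY_STATS = ["mean", "sd", "min", "max", "q1", "median", "q3"]


@dataclass
class KinematicSeries:
    """Per-segment kinematic series with per-sample validity masks.

    Velocity samples are valid iff both endpoint positions are observed;
    angle-change, acceleration and curvature samples iff all three
    contributing positions are observed (curvature additionally requires a
    non-zero step).
    """

    vx: np.ndarray
    vy: np.ndarray
    speed: np.ndarray
    accel: np.ndarray
    angle_change: np.ndarray
    curvature: np.ndarray
    valid_v: np.ndarray
    valid_a: np.ndarray
    valid_curv: np.ndarray


def kinematic_series(x: np.ndarray, y: np.ndarray, real: np.ndarray, fps: float) -> KinematicSeries:
    """First-difference kinematics of a position series.

    vx_t = (x_{t+1} - x_t) * fps (likewise vy); speed = |v|; heading =
    atan2(vy, vx); angle change = |wrap(heading diff)| in [0, pi]; accel =
    |v_{t+1} - v_t| * fps; curvature = angle change / step length.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    real = np.asarray(real, dtype=bool)
    if len(x) < 3:
        raise ValueError("need >= 3 positions for kinematic series")
    vx = np.diff(x) * fps
    vy = np.diff(y) * fps
    speed = np.hypot(vx, vy)
    heading = np.arctan2(vy, vx)
    dtheta = np.diff(heading)
    angle_change = np.abs((dtheta + np.pi) % (2.0 * np.pi) - np.pi)
    accel = np.hypot(np.diff(vx), np.diff(vy)) * fps
    step_len = speed[:-1] / fps
    with np.errstate(divide="ignore", invalid="ignore"):
        curvature = np.where(step_len > 0, angle_change / np.where(step_len > 0, step_len, 1.0), np.nan)
    valid_v = real[:-1] & real[1:]
    valid_a = real[:-2] & real[1:-1] & real[2:]
    valid_curv = valid_a & (step_len > 0)
    return KinematicSeries(
        vx=vx,
        vy=vy,
        speed=speed,
        accel=accel,
        angle_change=angle_change,
        curvature=curvature,
        valid_v=valid_v,
        valid_a=valid_a,
        valid_curv=valid_curv,
    )


def zero_crossings(series: np.ndarray, signed: bool, mask: np.ndarray | None = None) -> int:
    """Zero-crossing count over valid samples.

    For a signed series: exact-zero samples plus adjacent valid pairs with
    strictly opposite signs (adjacency broken across masked samples).  For
    a non-negative series: exact-zero samples only, since such a series
    touches zero without crossing it.
    """
    series = np.asarray(series, dtype=float)
    if mask is None:
        mask = np.ones(len(series), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    vals = series[mask]
    zeros = int(np.count_nonzero(vals == 0.0))
    if not signed:
        return zeros
    adjacent = mask[:-1] & mask[1:]
    flips = int(np.count_nonzero((series[:-1] * series[1:] < 0.0) & adjacent))
    return zeros + flips


def summarize_series(series: np.ndarray, mask: np.ndarray | None = None) -> dict[str, float]:
    """mean/sd/min/max and quartiles over valid samples only.

    Quartiles use linear interpolation of order statistics; sd uses the
    n-1 denominator and is missing (NaN) with fewer than two valid
    samples.  With no valid samples every statistic is NaN.
    """
    series = np.asarray(series, dtype=float)
    if mask is not None:
        series = series[np.asarray(mask, dtype=bool)]
    series = series[np.isfinite(series)]
    if series.size == 0:
        return {k: np.nan for k in SUMMARY_STATS}
    q1, med, q3 = np.quantile(series, [0.25, 0.5, 0.75])
    return {
        "mean": float(np.mean(series)),
        "sd": float(np.std(series, ddof=1)) if series.size >= 2 else np.nan,
        "min": float(np.min(series)),
        "max": float(np.max(series)),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
    }


def _geometric_scalars(x: np.ndarray, y: np.ndarray, real: np.ndarray) -> dict[str, float]:
    """Path length, net displacement and straightness over real positions.

    The path is the polyline through consecutive observed positions
    (interpolated vertices skipped), so straightness = net/path is always
    in [0, 1] by the triangle inequality.
    """
    xr = x[real]
    yr = y[real]
    if xr.size < 2:
        return {"path_length": np.nan, "net_displacement": np.nan, "straightness": np.nan}
    path = float(np.sum(np.hypot(np.diff(xr), np.diff(yr))))
    net = float(np.hypot(xr[-1] - xr[0], yr[-1] - yr[0]))
    return {
        "path_length": path,
        "net_displacement": net,
        "straightness": net / path if path > 0 else 0.0,
    }


def extract_segment_features(
    segment: Segment, fps: float, toggles: dict[str, bool] | None = None
) -> dict[str, float]:
    """The full feature vector of one segment.

    Summaries of each kinematic series over observed positions, signed
    zero-crossings of vx and vy, the zero-value count of the (non-negative)
    angle change, and the geometric scalars.  ``toggles`` can switch off
    feature families by series name.
    """
    ks = kinematic_series(segment.x, segment.y, segment.real, fps)
    series = {
        "vx": (ks.vx, ks.valid_v),
        "vy": (ks.vy, ks.valid_v),
        "speed": (ks.speed, ks.valid_v),
        "accel": (ks.accel, ks.valid_a),
        "angle_change": (ks.angle_change, ks.valid_a),
        "curvature": (ks.curvature, ks.valid_curv),
    }
    out: dict[str, float] = {}
    for name, (values, mask) in series.items():
        if toggles is not None and not toggles.get(name, True):
            continue
        for stat, val in summarize_series(values, mask).items():
            out[f"{name}_{stat}"] = val
    out["vx_zero_crossings"] = float(zero_crossings(ks.vx, signed=True, mask=ks.valid_v))
    out["vy_zero_crossings"] = float(zero_crossings(ks.vy, signed=True, mask=ks.valid_v))
    out["angle_change_zero_crossings"] = float(
        zero_crossings(ks.angle_change, signed=False, mask=ks.valid_a)
    )
    out.update(_geometric_scalars(segment.x, segment.y, segment.real))
    return out


def build_feature_table(
    segments: list[Segment],
    fps: float,
    toggles: dict[str, bool] | None = None,
    drop_incomplete: bool = True,
) -> pd.DataFrame:
    """One row per segment: provenance columns plus named features.

    Rows with missing modelling features (e.g. segments whose observed
    samples are too few for a summary) are dropped and logged.
    """
    if not segments:
        raise ValueError("no segments to featurise")
    rows = []
    for s in segments:
        row = {
            "trial_id": s.trial_id,
            "track_id": s.track_id,
            "segment_index": s.segment_index,
            "start_s": s.start_s,
            "strain": s.strain,
            "resistance": s.resistance,
            "net_type": s.label,
            "quality": s.quality,
        }
        row.update(extract_segment_features(s, fps, toggles))
        rows.append(row)
    table = pd.DataFrame(rows)
    if drop_incomplete:
        feats = feature_columns(table)
        ok = table[feats].notna().all(axis=1)
        if (~ok).any():
            log.warning("dropping %d/%d segments with missing features", int((~ok).sum()), len(table))
        table = table.loc[ok].reset_index(drop=True)
    if table.empty:
        raise ValueError("no usable feature rows")
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the modelling feature columns of a feature table."""
    return [c for c in table.columns if c not in PROVENANCE_COLS]
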