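import numpy as np
import pandas as pd
import pytest

from moztrack.segmentation import Segment
from moztrack.synthio import Track


def make_track(x, y, frames=None, real=None, trial="T1", track="a", fps=50.0):
    x = np.asarray(x, dtype=float)
    if frames is None:
        frames = np.arange(len(x))
    if real is None:
        real = np.ones(len(x), dtype=bool)
    return Track(
        trial_id=trial,
        track_id=track,
        frames=np.asarray(frames),
        x=x,
        y=np.asarray(y, dtype=float),
        real=np.asarray(real, dtype=bool),
        fps=fps,
    )


def make_segment(x, y, real=None, start_s=0.0, label="UT", fps=50.0):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if real is None:
        real = np.ones(len(x), dtype=bool)
    real = np.asarray(real, dtype=bool)
    t = start_s + np.arange(len(x)) / fps
    return Segment(
        trial_id="T1",
        track_id="a",
        segment_index=0,
        start_s=start_s,
        t=t,
        x=x,
        y=y,
        real=real,
        quality=0.0,
        label=label,
        resistance="IS",
        strain="Kisumu",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_segment(rng, n=40, gap_frac=0.0):
    x = np.cumsum(rng.normal(0, 5, n))
    y = np.cumsum(rng.normal(0, 5, n))
    real = np.ones(n, dtype=bool)
    if gap_frac > 0:
        k = int(gap_frac * (n - 2))
        if k:
            real[rng.choice(np.arange(1, n - 1), size=k, replace=False)] = False
    return make_segment(x, y, real=real)


def toy_feature_table(rng, n_trials=6, tracks_per_trial=8, segs_per_track=4,
                      informative=True):
    """Small synthetic feature table with provenance columns, for model tests."""
    rows = []
    for ti in range(n_trials):
        net = "OL" if ti % 2 else "UT"
        res = "IS" if (ti // 2) % 2 == 0 else "IR"
        for tr in range(tracks_per_trial):
            start = float(rng.uniform(0, 3600))
            shift = (1.5 if net == "OL" else 0.0) if informative else 0.0
            for si in range(segs_per_track):
                rows.append(
                    {
                        "trial_id": f"tr{ti}",
                        "track_id": f"t{tr}",
                        "segment_index": si,
                        "start_s": start + 0.5 * si,
                        "strain": "Kisumu" if ti % 2 == 0 else "VK7",
                        "resistance": res,
                        "net_type": net,
                        "quality": 0.0,
                        "f_a": float(rng.normal(shift, 1)),
                        "f_b": float(rng.normal(-shift, 1)),
                        "f_c": float(rng.normal(0, 1)),
                    }
                )
    return pd.DataFrame(rows)
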