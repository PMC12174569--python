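"""Imbalance-aware gradient-boosted classification of track segments.

The classifier distinguishes Olyset (OL, positive class) from untreated
(UT) net exposure.  Training sets follow one of three strategies: the
balanced strategy anchors on the OL/IS tracks observed before mosquitoes
are killed (within 30 min) and subsamples each other condition cell to
that track count; the early strategy keeps all tracks starting within
30 min; the comprehensive strategy keeps everything.  Features are
Z-score normalised with training statistics, the minority class is
up-weighted by the UT/OL segment ratio, the decision boundary is swept
over {0.01..0.99} to maximise training MCC, and track-level calls are the
mode of their segment calls.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb

from .features import feature_columns

__all__ = [
    "DEFAULT_HYPERPARAMS",
    "ModelBundle",
    "build_training_set",
    "zscore_fit",
    "zscore_apply",
    "train_classifier",
    "mcc_curve",
    "tune_decision_boundary",
    "fit_bundle",
    "predict_segments",
    "predict_tracks",
]

log = logging.getLogger(__name__)

EARLY_CUTOFF_S = 1800.0  # "within 30 min" boundary, inclusive

DEFAULT_HYPERPARAMS: dict = {
    "max_depth": 4,
    "n_estimators": 200,
    "learning_rate": 0.1,
    "subsample": 0.8,
}

BOUNDARY_GRID = np.round(np.arange(0.01, 1.0, 0.01), 2)


def _track_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Track-level view: one row per (trial, track) with start time and labels."""
    return (
        table.groupby(["trial_id", "track_id"], sort=True)
        .agg(
            start_s=("start_s", "min"),
            net_type=("net_type", "first"),
            resistance=("resistance", "first"),
        )
        .reset_index()
    )


def build_training_set(table: pd.DataFrame, strategy: str, seed: int) -> pd.DataFrame:
    """Assemble training rows under one of the three strategies.

    Sampling is at track level (a track's segments travel together),
    without replacement, seeded.  The 30-min boundary is inclusive.
    """
    tracks = _track_groups(table)
    if strategy == "comprehensive":
        return table.copy()
    if strategy == "early":
        keep = tracks[tracks["start_s"] <= EARLY_CUTOFF_S]
    elif strategy == "balanced":
        rng = np.random.default_rng(seed)
        cells = {
            (net, res): tracks[(tracks["net_type"] == net) & (tracks["resistance"] == res)]
            for net in ("UT", "OL")
            for res in ("IS", "IR")
        }
        anchor = cells[("OL", "IS")]
        anchor = anchor[anchor["start_s"] <= EARLY_CUTOFF_S]
        if anchor.empty:
            raise ValueError("balanced strategy: no OL/IS tracks within 30 min")
        n_anchor = len(anchor)
        parts = [anchor]
        for key, cell in cells.items():
            if key == ("OL", "IS"):
                continue
            if len(cell) > n_anchor:
                idx = rng.choice(len(cell), size=n_anchor, replace=False)
                cell = cell.iloc[np.sort(idx)]
            parts.append(cell)
        keep = pd.concat(parts, ignore_index=True)
    else:
        raise ValueError(f"unknown training strategy {strategy!r}")
    key_cols = ["trial_id", "track_id"]
    merged = table.merge(keep[key_cols], on=key_cols, how="inner")
    log.info(
        "training set (%s): %d tracks, %d segments", strategy, len(keep), len(merged)
    )
    return merged


def zscore_fit(train: pd.DataFrame, features: list[str]) -> tuple[pd.Series, pd.Series]:
    """Training-set mean and sd per feature (sd 0 flagged and mapped to 1)."""
    if len(train) < 2:
        raise ValueError("need >= 2 training rows for normalisation")
    mean = train[features].mean()
    sd = train[features].std(ddof=1)
    if (sd == 0).any():
        log.warning(
            "constant training feature(s) %s emitted as all-zero",
            list(sd.index[sd == 0]),
        )
    return mean, sd


def zscore_apply(
    table: pd.DataFrame, features: list[str], mean: pd.Series, sd: pd.Series
) -> np.ndarray:
    """(x - mean_train) / sd_train; constant features become all-zero."""
    safe_sd = sd.replace(0.0, 1.0)
    z = (table[features] - mean) / safe_sd
    z.loc[:, sd == 0.0] = 0.0
    return z.to_numpy(dtype=float)


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    hyperparams: dict | None = None,
    class_weight: float | None = None,
    seed: int = 0,
) -> xgb.XGBClassifier:
    """Fit the boosted-tree ensemble (positive class OL encoded as 1)."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contain a single class")
    params = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        params.update(hyperparams)
    if class_weight is None:
        class_weight = float(np.sum(y == 0)) / float(np.sum(y == 1))
    clf = xgb.XGBClassifier(
        **params,
        scale_pos_weight=class_weight,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )
    clf.fit(X, y)
    return clf


def mcc_curve(probs: np.ndarray, y: np.ndarray, grid: np.ndarray = BOUNDARY_GRID) -> np.ndarray:
    """MCC of (prob >= tau) against y for every grid boundary.

    Any zero denominator defines MCC as 0.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=bool)
    calls = probs[None, :] >= grid[:, None]
    tp = np.sum(calls & y[None, :], axis=1, dtype=float)
    fp = np.sum(calls & ~y[None, :], axis=1, dtype=float)
    fn = np.sum(~calls & y[None, :], axis=1, dtype=float)
    tn = np.sum(~calls & ~y[None, :], axis=1, dtype=float)
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    num = tp * tn - fp * fn
    with np.errstate(divide="ignore", invalid="ignore"):
        mcc = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return mcc


def tune_decision_boundary(probs: np.ndarray, y: np.ndarray) -> float:
    """Grid argmax of training MCC over {0.01..0.99}; ties take the smallest."""
    mcc = mcc_curve(probs, y)
    return float(BOUNDARY_GRID[int(np.argmax(mcc))])


@dataclass
class ModelBundle:
    """Everything needed to score new segments: normaliser, ensemble, boundary."""

    feature_names: list[str]
    mean: pd.Series
    sd: pd.Series
    booster: xgb.Booster
    tau: float
    class_weight: float
    strategy: str
    hyperparams: dict = field(default_factory=dict)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(directory / "ensemble.json")
        meta = {
            "feature_names": self.feature_names,
            "mean": self.mean.to_dict(),
            "sd": self.sd.to_dict(),
            "tau": self.tau,
            "class_weight": self.class_weight,
            "strategy": self.strategy,
            "hyperparams": self.hyperparams,
            "format_version": 1,
        }
        (directory / "bundle.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        directory = Path(directory)
        meta = json.loads((directory / "bundle.json").read_text())
        booster = xgb.Booster()
        booster.load_model(str(directory / "ensemble.json"))
        return cls(
            feature_names=meta["feature_names"],
            mean=pd.Series(meta["mean"]),
            sd=pd.Series(meta["sd"]),
            booster=booster,
            tau=meta["tau"],
            class_weight=meta["class_weight"],
            strategy=meta["strategy"],
            hyperparams=meta.get("hyperparams", {}),
        )


def fit_bundle(
    table: pd.DataFrame,
    features: list[str] | None = None,
    strategy: str = "balanced",
    hyperparams: dict | None = None,
    seed: int = 0,
) -> ModelBundle:
    """End-to-end model fit on a feature table of training trials."""
    if features is None:
        features = feature_columns(table)
    train = build_training_set(table, strategy, seed)
    y = (train["net_type"] == "OL").to_numpy()
    n_ol = int(y.sum())
    n_ut = int((~y).sum())
    if n_ol == 0 or n_ut == 0:
        raise ValueError("training set must contain both classes")
    weight = n_ut / n_ol
    mean, sd = zscore_fit(train, features)
    X = zscore_apply(train, features, mean, sd)
    clf = train_classifier(X, y.astype(int), hyperparams, weight, seed)
    probs = clf.predict_proba(X)[:, 1]
    tau = tune_decision_boundary(probs, y)
    booster = clf.get_booster()
    booster.feature_names = list(features)
    return ModelBundle(
        feature_names=list(features),
        mean=mean,
        sd=sd,
        booster=booster,
        tau=tau,
        class_weight=weight,
        strategy=strategy,
        hyperparams=dict(hyperparams or DEFAULT_HYPERPARAMS),
    )


def predict_segments(bundle: ModelBundle, table: pd.DataFrame) -> np.ndarray:
    """P(OL) per segment row."""
    missing = [f for f in bundle.feature_names if f not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks model features: {missing}")
    X = zscore_apply(table, bundle.feature_names, bundle.mean, bundle.sd)
    return np.asarray(
        bundle.booster.predict(xgb.DMatrix(X, feature_names=bundle.feature_names))
    )


def predict_tracks(bundle: ModelBundle, table: pd.DataFrame) -> pd.DataFrame:
    """Track-level predictions: mode of segment calls at the tuned boundary.

    An exact tie between segment calls goes to OL iff the mean segment
    probability reaches the boundary.  The track score is the mean segment
    probability; start_s is the track's first segment start.
    """
    table = table.reset_index(drop=True)
    probs = predict_segments(bundle, table)
    out = table[["trial_id", "track_id", "start_s"]].copy()
    out["prob"] = probs
    out["call"] = probs >= bundle.tau
    truth_cols = [c for c in ("net_type", "strain", "resistance") if c in table.columns]
    for c in truth_cols:
        out[c] = table[c]
    rows = []
    for (trial, track), grp in out.groupby(["trial_id", "track_id"], sort=True):
        n_ol = int(grp["call"].sum())
        n_ut = len(grp) - n_ol
        score = float(grp["prob"].mean())
        if n_ol > n_ut:
            call = "OL"
        elif n_ol < n_ut:
            call = "UT"
        else:
            call = "OL" if score >= bundle.tau else "UT"
        row = {
            "trial_id": trial,
            "track_id": track,
            "n_segments": len(grp),
            "start_s": float(grp["start_s"].min()),
            "track_call": call,
            "track_score": score,
        }
        for c in truth_cols:
            row[c] = grp[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)
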