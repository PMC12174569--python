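"""Trial-level cross-validation, metric panel and time-resolved accuracy.

Evaluation splits at the trial level so the model is always scored on
experiments it has never seen, preventing leakage of trial-specific
conditions (volunteer, day, colony batch) into the test set.  Each fold
draws a test set honouring a per-strain (or class-level) composition of
UT and OL trials; the metric panel mirrors standard imbalance-aware
reporting, with precision/recall/F1/PR-AUC computed for both choices of
positive class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
from sklearn import metrics as skm

__all__ = [
    "LeakageError",
    "FoldSpec",
    "assert_trial_disjoint",
    "generate_folds",
    "compute_metrics",
    "confusion_normalized",
    "time_resolved_accuracy",
    "summarize_metric_panels",
    "grid_search",
]

log = logging.getLogger(__name__)


class LeakageError(RuntimeError):
    """Raised when a trial appears on both sides of a split."""


def assert_trial_disjoint(a, b, context: str) -> None:
    overlap = set(a) & set(b)
    if overlap:
        raise LeakageError(f"{context}: trials on both sides of the split: {sorted(overlap)}")


@dataclass(frozen=True)
class FoldSpec:
    fold_id: int
    train_trials: tuple[str, ...]
    test_trials: tuple[str, ...]
    composition: dict = field(default_factory=dict, hash=False, compare=False)


def _composition_cells(
    meta: pd.DataFrame,
    per_strain: bool,
    stratify_resistance: bool,
    ut_k: int,
    ol_k: int,
    n_ut: int,
    n_ol: int,
) -> list[tuple[list[str], int]]:
    """Test-set composition as (trial pool, how many to draw) cells."""
    cells: list[tuple[list[str], int]] = []
    if per_strain:
        for strain, grp in meta.groupby("strain", sort=True):
            for net, k in (("UT", ut_k), ("OL", ol_k)):
                pool = sorted(grp.loc[grp["net_type"] == net, "trial_id"])
                if len(pool) < k:
                    raise ValueError(
                        f"strain {strain}: only {len(pool)} {net} trials, need {k}"
                    )
                cells.append((pool, k))
        return cells
    for net, k in (("UT", n_ut), ("OL", n_ol)):
        grp = meta[meta["net_type"] == net]
        statuses = sorted(grp["resistance"].unique())
        if stratify_resistance and len(statuses) == 2 and k >= 2:
            k_is = k - k // 2
            k_ir = k // 2
            for res, kk in (("IS", k_is), ("IR", k_ir)):
                pool = sorted(grp.loc[grp["resistance"] == res, "trial_id"])
                if len(pool) < kk:
                    raise ValueError(
                        f"net {net}: only {len(pool)} {res} trials, need {kk}"
                    )
                cells.append((pool, kk))
        else:
            pool = sorted(grp["trial_id"])
            if len(pool) < k:
                raise ValueError(f"net {net}: only {len(pool)} trials, need {k}")
            cells.append((pool, k))
    return cells


def generate_folds(
    metadata: pd.DataFrame,
    n_folds: int = 30,
    n_train: int = 12,
    n_test: int = 9,
    seed: int = 0,
    *,
    per_strain: bool = True,
    test_ut_per_strain: int = 1,
    test_ol_per_strain: int = 2,
    test_n_ut: int = 2,
    test_n_ol: int = 2,
    stratify_resistance: bool = True,
    enumeration_cap: int = 200_000,
) -> list[FoldSpec]:
    """Sample trial-level train/test folds without replacement.

    With ``per_strain=True`` every test set contains ``test_ut_per_strain``
    UT and ``test_ol_per_strain`` OL trials per strain; surplus slots over
    ``n_test`` are shed by dropping UT trials at random (seeded).  With
    ``per_strain=False`` the composition is class-level
    (``test_n_ut``/``test_n_ol``, split as evenly as possible between
    resistance statuses when ``stratify_resistance``), for small studies
    whose per-strain cells are too thin.  Remaining trials form the
    training set, sampled round-robin over strains up to ``n_train``.
    """
    rng = np.random.default_rng(seed)
    all_trials = list(metadata["trial_id"])
    if len(set(all_trials)) != len(all_trials):
        raise ValueError("duplicate trial ids in metadata")
    by_trial = metadata.set_index("trial_id")

    cells = _composition_cells(
        metadata, per_strain, stratify_resistance,
        test_ut_per_strain, test_ol_per_strain, test_n_ut, test_n_ol,
    )
    cell_combos = [list(combinations(pool, k)) for pool, k in cells]
    total = math.prod(len(c) for c in cell_combos)
    if total <= enumeration_cap:
        pool = list(product(*cell_combos))
        picks = rng.choice(len(pool), size=min(n_folds, len(pool)), replace=False)
        raw_tests = [tuple(t for part in pool[i] for t in part) for i in picks]
    else:
        seen: set = set()
        raw_tests = []
        attempts = 0
        while len(raw_tests) < n_folds and attempts < 100 * n_folds:
            attempts += 1
            combo = tuple(c[rng.integers(len(c))] for c in cell_combos)
            flat = tuple(t for part in combo for t in part)
            if flat not in seen:
                seen.add(flat)
                raw_tests.append(flat)
    if len(raw_tests) < n_folds:
        log.warning("only %d distinct balanced test sets available", len(raw_tests))

    folds = []
    for fid, test in enumerate(raw_tests):
        test = list(test)
        if len(test) > n_test:
            # shed surplus UT slots at random, keeping all OL trials
            ut_in_test = [t for t in test if by_trial.loc[t, "net_type"] == "UT"]
            n_drop = len(test) - n_test
            if n_drop > len(ut_in_test):
                raise ValueError("cannot reach n_test by dropping UT trials only")
            drop = set(rng.choice(ut_in_test, size=n_drop, replace=False))
            test = [t for t in test if t not in drop]
        remaining = [t for t in all_trials if t not in set(test)]
        train = _balanced_train(remaining, by_trial, n_train, rng)
        assert_trial_disjoint(train, test, f"fold {fid}")
        for side, name in ((train, "train"), (test, "test")):
            nets = {by_trial.loc[t, "net_type"] for t in side}
            if side and len(nets) < 2:
                raise ValueError(f"fold {fid}: {name} set lacks a class")
        folds.append(
            FoldSpec(
                fold_id=fid,
                train_trials=tuple(sorted(train)),
                test_trials=tuple(sorted(test)),
                composition={
                    "per_strain": per_strain,
                    "n_train": len(train),
                    "n_test": len(test),
                },
            )
        )
    return folds


def _balanced_train(remaining, by_trial, n_train, rng) -> list[str]:
    """Round-robin over strains from the remaining trials, up to n_train."""
    if len(remaining) <= n_train:
        return list(remaining)
    by_strain: dict[str, list[str]] = {}
    for t in remaining:
        by_strain.setdefault(str(by_trial.loc[t, "strain"]), []).append(t)
    queues = []
    for strain in sorted(by_strain):
        lst = by_strain[strain]
        order = rng.permutation(len(lst))
        queues.append([lst[i] for i in order])
    train: list[str] = []
    qi = 0
    while len(train) < n_train and any(queues):
        q = queues[qi % len(queues)]
        if q:
            train.append(q.pop(0))
        qi += 1
    return train


# ---------------------------------------------------------------------------
# metric panel


def compute_metrics(
    y_true: np.ndarray, y_call: np.ndarray, scores: np.ndarray
) -> dict[str, float]:
    """The evaluation panel on whole-track predictions.

    ``y_true``/``y_call`` are 'UT'/'OL' labels; ``scores`` are P(OL) track
    scores.  AUCs are undefined (NaN) when the truth is single-class.
    """
    y_true = np.asarray(y_true)
    y_call = np.asarray(y_call)
    scores = np.asarray(scores, dtype=float)
    t = y_true == "OL"
    c = y_call == "OL"
    panel: dict[str, float] = {}
    two_class = 0 < t.sum() < len(t)
    panel["balanced_accuracy"] = float(skm.balanced_accuracy_score(t, c)) if two_class else np.nan
    panel["mcc"] = float(skm.matthews_corrcoef(t, c))
    panel["cohen_kappa"] = float(skm.cohen_kappa_score(t, c))
    panel["log_loss"] = float(skm.log_loss(t, scores, labels=[False, True]))
    panel["roc_auc"] = float(skm.roc_auc_score(t, scores)) if two_class else np.nan
    for pos, mask_t, mask_c, s in (
        ("OL", t, c, scores),
        ("UT", ~t, ~c, 1.0 - scores),
    ):
        panel[f"f1_{pos}"] = float(skm.f1_score(mask_t, mask_c, zero_division=0))
        panel[f"precision_{pos}"] = float(skm.precision_score(mask_t, mask_c, zero_division=0))
        panel[f"recall_{pos}"] = float(skm.recall_score(mask_t, mask_c, zero_division=0))
        panel[f"pr_auc_{pos}"] = (
            float(skm.average_precision_score(mask_t, s)) if two_class else np.nan
        )
    return panel


def confusion_normalized(
    y_true: np.ndarray | list, y_call: np.ndarray | list
) -> pd.DataFrame:
    """2x2 confusion matrix normalised by the true class (rows sum to 1)."""
    y_true = np.asarray(y_true)
    y_call = np.asarray(y_call)
    classes = ["UT", "OL"]
    mat = np.zeros((2, 2))
    for i, tc in enumerate(classes):
        row_mask = y_true == tc
        denom = row_mask.sum()
        if denom == 0:
            raise ValueError(f"true class {tc} absent; cannot row-normalise")
        for j, pc in enumerate(classes):
            mat[i, j] = np.sum(row_mask & (y_call == pc)) / denom
    return pd.DataFrame(mat, index=classes, columns=classes)


def mean_confusion(matrices: list[pd.DataFrame]) -> pd.DataFrame:
    """Unweighted mean of per-fold normalised confusion matrices."""
    return sum(matrices) / len(matrices)


def summarize_metric_panels(panels: list[dict[str, float]]) -> pd.DataFrame:
    """Arithmetic mean, minimum and maximum of each metric across folds."""
    df = pd.DataFrame(panels)
    return pd.DataFrame(
        {"mean": df.mean(), "min": df.min(), "max": df.max()}
    )


def time_resolved_accuracy(
    fold_predictions: list[pd.DataFrame],
    bin_s: float = 300.0,
    duration_s: float = 7200.0,
) -> dict[str, pd.DataFrame]:
    """Accuracy by experiment time and condition panels.

    Tracks are binned by start time into half-open [k*bin_s, (k+1)*bin_s)
    bins.  Per bin the accuracy is computed within each fold over the
    tracks starting there, then averaged (unweighted) across folds that
    have tracks in the bin; bins empty in every fold are reported missing
    (NaN), never zero.  Also returns per-strain, per-class and
    before/after-30-min accuracy panels.
    """
    edges = np.arange(0.0, duration_s + bin_s, bin_s)
    n_bins = len(edges) - 1
    per_fold = np.full((len(fold_predictions), n_bins), np.nan)
    counts = np.zeros(n_bins, dtype=int)
    strain_rows, class_rows, halves_rows = [], [], []
    for fi, preds in enumerate(fold_predictions):
        start = preds["start_s"].to_numpy(dtype=float)
        correct = (preds["track_call"] == preds["net_type"]).to_numpy()
        which = np.floor(start / bin_s).astype(int)
        which = np.clip(which, 0, n_bins - 1)
        for b in range(n_bins):
            m = which == b
            if m.any():
                per_fold[fi, b] = correct[m].mean()
                counts[b] += int(m.sum())
        if "strain" in preds.columns:
            for strain, grp in preds.groupby("strain"):
                strain_rows.append(
                    {
                        "fold": fi,
                        "strain": strain,
                        "accuracy": (grp["track_call"] == grp["net_type"]).mean(),
                        "n": len(grp),
                    }
                )
        for cls, grp in preds.groupby("net_type"):
            class_rows.append(
                {
                    "fold": fi,
                    "net_type": cls,
                    "accuracy": (grp["track_call"] == grp["net_type"]).mean(),
                    "n": len(grp),
                }
            )
        for name, m in (("before_30min", start <= 1800.0), ("after_30min", start > 1800.0)):
            if m.any():
                halves_rows.append(
                    {
                        "fold": fi,
                        "period": name,
                        "accuracy": float(correct[m].mean()),
                        "n": int(m.sum()),
                    }
                )
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        bins = pd.DataFrame(
            {
                "bin_start_s": edges[:-1],
                "n_tracks": counts,
                "mean_accuracy": np.nanmean(per_fold, axis=0)
                if len(fold_predictions)
                else np.nan,
                "sd_accuracy": np.nanstd(per_fold, axis=0, ddof=0),
            }
        )
    bins.loc[bins["n_tracks"] == 0, ["mean_accuracy", "sd_accuracy"]] = np.nan

    def _agg(rows, key):
        if not rows:
            return pd.DataFrame(columns=[key, "mean_accuracy", "sd_accuracy", "n_tracks"])
        df = pd.DataFrame(rows)
        return (
            df.groupby(key)
            .agg(
                mean_accuracy=("accuracy", "mean"),
                sd_accuracy=("accuracy", "std"),
                n_tracks=("n", "sum"),
            )
            .reset_index()
        )

    return {
        "bins": bins,
        "per_strain": _agg(strain_rows, "strain"),
        "per_class": _agg(class_rows, "net_type"),
        "before_after": _agg(halves_rows, "period"),
    }


def grid_search(
    tuning_tracks,
    tuning_metadata: pd.DataFrame,
    window_grid: list[float],
    overlap_grid: list[float],
    model_grid: list[dict] | None = None,
    seed: int = 0,
    *,
    fps: float = 50.0,
    n_folds: int = 5,
    strategy: str = "balanced",
    fold_kwargs: dict | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Windowing/model grid search on the tuning trials only.

    Every (window, overlap, hyperparameter) point reruns segmentation,
    feature extraction, selection and a small trial-level cross-validation
    within the tuning set; the point with the highest mean track-level
    balanced accuracy wins, ties resolved toward the smaller window, then
    the larger overlap (more data).
    """
    if model_grid is None:
        model_grid = [dict()]
    fold_kwargs = dict(fold_kwargs or {})
    rows = []
    best = None
    for window_s in window_grid:
        for overlap_s in overlap_grid:
            if not (0 <= overlap_s < window_s):
                continue
            for hp in model_grid:
                try:
                    acc = _evaluate_grid_point(
                        tuning_tracks, tuning_metadata, window_s, overlap_s, hp,
                        fps, n_folds, strategy, seed, fold_kwargs,
                    )
                except ValueError as exc:
                    log.warning(
                        "grid point (w=%.3g, o=%.3g, %s) skipped: %s",
                        window_s, overlap_s, hp, exc,
                    )
                    continue
                rows.append(
                    {"window_s": window_s, "overlap_s": overlap_s,
                     "hyperparams": dict(hp), "balanced_accuracy": acc}
                )
                key = (acc, -window_s, overlap_s)
                if best is None or key > best[0]:
                    best = (key, rows[-1])
    if best is None:
        raise ValueError("every grid point was skipped")
    return best[1], pd.DataFrame(rows)


def _evaluate_grid_point(
    tracks, metadata, window_s, overlap_s, hyperparams,
    fps, n_folds, strategy, seed, fold_kwargs,
):
    from .features import build_feature_table, feature_columns
    from .model import fit_bundle, predict_tracks
    from .segmentation import segment_study
    from .selection import select_features

    segs = segment_study(tracks, metadata, window_s, overlap_s, fps)
    if not segs:
        raise ValueError("zero segments")
    table = build_feature_table(segs, fps)
    report = select_features(table, feature_columns(table))
    feats = report.final or feature_columns(table)
    kwargs = {"per_strain": False, "n_folds": n_folds, "n_train": len(metadata) - 2,
              "n_test": 2, "test_n_ut": 1, "test_n_ol": 1}
    kwargs.update(fold_kwargs)
    folds = generate_folds(metadata, seed=seed, **kwargs)
    accs = []
    for fold in folds:
        train_tab = table[table["trial_id"].isin(fold.train_trials)]
        test_tab = table[table["trial_id"].isin(fold.test_trials)]
        if train_tab.empty or test_tab.empty:
            continue
        bundle = fit_bundle(train_tab, feats, strategy=strategy,
                            hyperparams=hyperparams, seed=seed + fold.fold_id)
        preds = predict_tracks(bundle, test_tab)
        t = preds["net_type"] == "OL"
        c = preds["track_call"] == "OL"
        if 0 < t.sum() < len(t):
            accs.append(float(skm.balanced_accuracy_score(t, c)))
    if not accs:
        raise ValueError("no scorable folds")
    return float(np.mean(accs))
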