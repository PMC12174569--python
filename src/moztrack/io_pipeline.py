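"""File formats, configuration and the end-to-end pipeline.

The track table is delimited text with columns trial_id, track_id, frame,
t_s, x_mm, y_mm, real_flag; trial metadata is a second CSV keyed by
trial_id.  ``run_pipeline`` drives the whole analysis: simulate or load
tracks, split trials into tuning and modelling sets, segment and
quality-filter, extract features, screen features on the tuning set,
cross-validate the classifier over trial-level folds on the modelling
set, and attribute the best fold's predictions to features.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthio
from .evaluation import (
    FoldSpec,
    assert_trial_disjoint,
    compute_metrics,
    confusion_normalized,
    generate_folds,
    mean_confusion,
    summarize_metric_panels,
    time_resolved_accuracy,
)
from .explain import (
    AttributionTable,
    attribute_segments,
    concat_attributions,
    rank_features,
)
from .features import build_feature_table, feature_columns
from .model import DEFAULT_HYPERPARAMS, ModelBundle, fit_bundle, predict_tracks
from .segmentation import apply_quality_filter, segment_study, select_quality_threshold
from .selection import SelectionReport, select_features
from .synthio import Track

__all__ = [
    "TRACK_COLUMNS",
    "ParseError",
    "StudyConfig",
    "read_tracks",
    "write_tracks",
    "read_metadata",
    "write_metadata",
    "run_pipeline",
    "StudyReport",
    "FoldReport",
]

log = logging.getLogger(__name__)

TRACK_COLUMNS = ["trial_id", "track_id", "frame", "t_s", "x_mm", "y_mm", "real_flag"]
META_COLUMNS = ["trial_id", "net_type", "strain", "resistance"]


class ParseError(ValueError):
    """A track or metadata file violated the format contract."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ScenarioConfig:
    """Synthetic study to simulate when no track file is given.

    The modelling arm has ``n_ut_trials``/``n_ol_trials``; a further
    ``n_tuning_ut``/``n_tuning_ol`` trials are simulated as a disjoint
    tuning set for the quality threshold and feature screening.
    """

    n_ut_trials: int = 8
    n_ol_trials: int = 8
    n_tuning_ut: int = 4
    n_tuning_ol: int = 4
    n_mosquitoes: int = 25
    tracks_per_mosquito: float = 1.0
    duration_s: float = 7200.0
    gap_dropout: float = 0.03
    gap_max_run: int = 12
    identical_regimes: bool = False
    is_ol_mortality_cutoff_s: float | None = 1800.0


@dataclass
class FoldConfig:
    """Trial-level cross-validation layout.

    The default class-level composition (2 UT + 2 OL test trials, split
    between resistance statuses) suits the bundled synthetic scenario;
    ``per_strain=True`` with 1 UT / 2 OL per strain reproduces the full
    40-trial study design.
    """

    n_folds: int = 30
    n_train: int = 12
    n_test: int = 4
    per_strain: bool = False
    test_ut_per_strain: int = 1
    test_ol_per_strain: int = 2
    test_n_ut: int = 2
    test_n_ol: int = 2
    stratify_resistance: bool = True


@dataclass
class StudyConfig:
    """All pipeline parameters, loadable from YAML."""

    window_s: float = 7.5
    overlap_s: float = 7.0
    fps: float = 50.0
    min_track_duration_s: float = 1.0
    quality_bins: int = 10
    alpha: float = 0.05
    rho_threshold: float = 0.85
    strategy: str = "balanced"
    hyperparams: dict = field(default_factory=lambda: dict(DEFAULT_HYPERPARAMS))
    tuning_fraction: float = 0.25
    folds: FoldConfig = field(default_factory=FoldConfig)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_s < self.window_s):
            raise ValueError("require 0 <= overlap_s < window_s")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.rho_threshold <= 1):
            raise ValueError("rho_threshold must be in (0, 1]")
        if self.strategy not in ("balanced", "early", "comprehensive"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not (0 <= self.tuning_fraction < 1):
            raise ValueError("tuning_fraction must be in [0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "folds" in d and isinstance(d["folds"], dict):
            d["folds"] = FoldConfig(**d["folds"])
        if "scenario" in d and isinstance(d["scenario"], dict):
            d["scenario"] = ScenarioConfig(**d["scenario"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# track table I/O


def write_tracks(tracks: list[Track], path: str | Path) -> None:
    """Write the track table CSV in deterministic (trial, track, frame) order."""
    frames = []
    for tr in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": tr.trial_id,
                    "track_id": tr.track_id,
                    "frame": tr.frames,
                    "t_s": tr.t,
                    "x_mm": tr.x,
                    "y_mm": tr.y,
                    "real_flag": tr.real.astype(int),
                }
            )
        )
    if frames:
        table = pd.concat(frames, ignore_index=True)
        table = table.sort_values(["trial_id", "track_id", "frame"], kind="mergesort")
    else:
        table = pd.DataFrame(columns=TRACK_COLUMNS)
    table.to_csv(path, index=False)


def read_tracks(path: str | Path, fps: float = 50.0) -> list[Track]:
    """Read a track table CSV into Track objects.

    One Track per (trial_id, track_id), rows sorted by frame; duplicate
    frames, non-monotone input or non-numeric coordinates raise
    :class:`ParseError` naming the offending rows.
    """
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ParseError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in TRACK_COLUMNS if c not in table.columns and c != "real_flag"]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if "real_flag" not in table.columns:
        table["real_flag"] = 1
    for col in ("frame", "x_mm", "y_mm"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = vals.isna() & table[col].notna()
        if bad.any() or vals.isna().any():
            rows = list(table.index[vals.isna()][:5])
            raise ParseError(f"{path}: non-numeric {col} at rows {rows}")
        table[col] = vals
    tracks = []
    for (trial, track), grp in table.groupby(["trial_id", "track_id"], sort=True):
        grp = grp.sort_values("frame", kind="mergesort")
        dup = grp["frame"].duplicated()
        if dup.any():
            raise ParseError(
                f"{path}: duplicate frame(s) {sorted(grp.loc[dup, 'frame'].head())} "
                f"in trial {trial!r} track {track!r}"
            )
        tracks.append(
            Track(
                trial_id=str(trial),
                track_id=str(track),
                frames=grp["frame"].to_numpy(dtype=np.int64),
                x=grp["x_mm"].to_numpy(dtype=float),
                y=grp["y_mm"].to_numpy(dtype=float),
                real=grp["real_flag"].to_numpy(dtype=bool),
                fps=fps,
            )
        )
    return tracks


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.sort_values("trial_id", kind="mergesort").to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"{path}: missing metadata columns {missing}")
    return meta


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class FoldReport:
    spec: FoldSpec
    metrics: dict[str, float]
    confusion: pd.DataFrame
    predictions: pd.DataFrame


@dataclass
class StudyReport:
    config: StudyConfig
    tuning_trials: list[str]
    modelling_trials: list[str]
    n_tracks: int
    n_segments: int
    n_segments_kept: int
    quality_threshold: float
    selection: SelectionReport
    folds: list[FoldReport]
    metrics_summary: pd.DataFrame
    confusion_mean: pd.DataFrame
    time_resolved: dict[str, pd.DataFrame]
    importance: pd.DataFrame | None
    importance_best_fold: pd.DataFrame | None
    best_fold_id: int | None

    def to_dir(self, out: str | Path) -> None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics_summary.to_csv(out / "metrics_summary.csv")
        self.confusion_mean.to_csv(out / "confusion_mean.csv")
        for name, df in self.time_resolved.items():
            df.to_csv(out / f"time_resolved_{name}.csv", index=False)
        if self.importance is not None:
            self.importance.to_csv(out / "importance.csv", index=False)
        summary = {
            "tuning_trials": self.tuning_trials,
            "modelling_trials": self.modelling_trials,
            "n_tracks": self.n_tracks,
            "n_segments": self.n_segments,
            "n_segments_kept": self.n_segments_kept,
            "quality_threshold": self.quality_threshold,
            "selected_features": self.selection.final,
            "best_fold_id": self.best_fold_id,
            "folds": [
                {
                    "fold_id": f.spec.fold_id,
                    "train_trials": list(f.spec.train_trials),
                    "test_trials": list(f.spec.test_trials),
                    "metrics": {k: _jsonable(v) for k, v in f.metrics.items()},
                }
                for f in self.folds
            ],
        }
        (out / "report.json").write_text(json.dumps(summary, indent=2))
        (out / "selection.json").write_text(json.dumps(self.selection.to_dict(), indent=2))


def _jsonable(v):
    if isinstance(v, float) and np.isnan(v):
        return None
    return v


def _split_tuning(metadata: pd.DataFrame, fraction: float, seed: int):
    """Stratified tuning/modelling trial split by (net_type, strain)."""
    if fraction == 0:
        return [], list(metadata["trial_id"])
    rng = np.random.default_rng(seed)
    tuning: list[str] = []
    for _, grp in metadata.groupby(["net_type", "strain"], sort=True):
        ids = sorted(grp["trial_id"])
        k = int(round(fraction * len(ids)))
        if k >= len(ids):
            k = len(ids) - 1
        if k > 0:
            pick = rng.choice(len(ids), size=k, replace=False)
            tuning.extend(ids[i] for i in sorted(pick))
    modelling = [t for t in metadata["trial_id"] if t not in set(tuning)]
    return tuning, modelling


def _simulate_source(cfg: StudyConfig):
    """Simulate the modelling study plus a disjoint tuning study.

    Returns (tracks, metadata, tuning_trial_ids); tuning trials carry a
    ``TUN_`` id prefix and a seed derived from the master seed.
    """
    sc = cfg.scenario
    params = {
        "UT": synthio.UT_PARAMS,
        "OL": synthio.UT_PARAMS if sc.identical_regimes else synthio.OL_PARAMS,
    }
    common = dict(
        params_by_condition=params,
        n_mosquitoes=sc.n_mosquitoes,
        tracks_per_mosquito=sc.tracks_per_mosquito,
        duration_s=sc.duration_s,
        gap_law=synthio.GapLaw(sc.gap_dropout, sc.gap_max_run),
        is_ol_mortality_cutoff_s=sc.is_ol_mortality_cutoff_s,
    )
    study = synthio.simulate_study(
        sc.n_ut_trials, sc.n_ol_trials, seed=cfg.seed, **common
    )
    tracks = synthio.study_tracks(study)
    metadata = synthio.study_metadata(study)
    tuning_ids: list[str] = []
    if sc.n_tuning_ut > 0 or sc.n_tuning_ol > 0:
        tuning = synthio.simulate_study(
            sc.n_tuning_ut, sc.n_tuning_ol, seed=cfg.seed + 10_007,
            trial_prefix="TUN_", **common,
        )
        tracks = tracks + synthio.study_tracks(tuning)
        tmeta = synthio.study_metadata(tuning)
        tuning_ids = list(tmeta["trial_id"])
        metadata = pd.concat([metadata, tmeta], ignore_index=True)
    return tracks, metadata, tuning_ids


def run_pipeline(
    config: StudyConfig,
    data_source: tuple[list[Track], pd.DataFrame] | dict | None = None,
    *,
    permute_labels: bool = False,
) -> StudyReport:
    """Execute the full analysis and return a :class:`StudyReport`.

    ``data_source`` is None (simulate the configured scenario), a dict
    with ``tracks``/``metadata`` file paths, or an in-memory
    ``(tracks, metadata)`` pair.  ``permute_labels`` shuffles the
    trial-to-net assignment (seeded) for null calibration.
    """
    explicit_tuning: list[str] | None = None
    if data_source is None:
        tracks, metadata, explicit_tuning = _simulate_source(config)
    elif isinstance(data_source, dict):
        tracks = read_tracks(data_source["tracks"], fps=config.fps)
        metadata = read_metadata(data_source["metadata"])
    else:
        tracks, metadata = data_source
    metadata = metadata.copy()
    if metadata["net_type"].nunique() < 2:
        raise ValueError("fewer than 2 classes present at fold construction")
    if permute_labels:
        rng = np.random.default_rng(config.seed + 7)
        perm = rng.permutation(len(metadata))
        for col in ("net_type",):
            metadata[col] = metadata[col].to_numpy()[perm]
    log.info("pipeline: %d tracks in, %d trials", len(tracks), len(metadata))

    # --- segment + features on everything
    segments = segment_study(
        tracks, metadata, config.window_s, config.overlap_s, config.fps,
        config.min_track_duration_s,
    )
    if not segments:
        raise ValueError("segmentation produced no segments")
    table = build_feature_table(segments, config.fps)
    feats = feature_columns(table)
    log.info("features: %d segments x %d features", len(table), len(feats))

    # --- tuning / modelling split (leakage guard)
    if explicit_tuning is not None and explicit_tuning:
        tuning = explicit_tuning
        modelling = [t for t in metadata["trial_id"] if t not in set(tuning)]
    else:
        tuning, modelling = _split_tuning(metadata, config.tuning_fraction, config.seed)
    assert_trial_disjoint(tuning, modelling, "tuning/modelling split")
    tuning_tab = table[table["trial_id"].isin(tuning)] if tuning else table
    if tuning_tab["net_type"].nunique() < 2:
        tuning_tab = table  # degenerate tiny studies: fall back, logged
        log.warning("tuning split single-class; thresholding on full table")

    # --- quality threshold (MI-based) and filter
    threshold = select_quality_threshold(
        tuning_tab["quality"].to_numpy(),
        tuning_tab["net_type"].to_numpy(),
        tuning_tab[feats],
        n_bins=config.quality_bins,
    )
    kept = table[table["quality"] <= threshold].reset_index(drop=True)
    log.info("quality filter at %.4g: kept %d/%d segments", threshold, len(kept), len(table))

    # --- feature screening on the tuning split, frozen before modelling
    screen_tab = kept[kept["trial_id"].isin(tuning)] if tuning else kept
    if screen_tab["net_type"].nunique() < 2:
        screen_tab = kept
    selection = select_features(
        screen_tab, feats, alpha=config.alpha, rho_threshold=config.rho_threshold
    )
    selected = selection.final or feats
    if not selection.final:
        log.warning("screening kept nothing; falling back to all features")

    # --- folds on the modelling trials
    model_meta = metadata[metadata["trial_id"].isin(modelling)]
    fc = config.folds
    folds = generate_folds(
        model_meta,
        n_folds=fc.n_folds,
        n_train=fc.n_train,
        n_test=fc.n_test,
        seed=config.seed + 1,
        per_strain=fc.per_strain,
        test_ut_per_strain=fc.test_ut_per_strain,
        test_ol_per_strain=fc.test_ol_per_strain,
        test_n_ut=fc.test_n_ut,
        test_n_ol=fc.test_n_ol,
        stratify_resistance=fc.stratify_resistance,
    )

    model_tab = kept[kept["trial_id"].isin(modelling)]
    fold_reports: list[FoldReport] = []
    bundles: dict[int, ModelBundle] = {}
    for fold in folds:
        assert_trial_disjoint(fold.train_trials, fold.test_trials, f"fold {fold.fold_id}")
        assert_trial_disjoint(tuning, fold.test_trials, "tuning vs fold test")
        train_tab = model_tab[model_tab["trial_id"].isin(fold.train_trials)]
        test_tab = model_tab[model_tab["trial_id"].isin(fold.test_trials)]
        if train_tab.empty or test_tab.empty:
            log.warning("fold %d has an empty side; skipped", fold.fold_id)
            continue
        bundle = fit_bundle(
            train_tab, selected, strategy=config.strategy,
            hyperparams=config.hyperparams, seed=config.seed + 100 + fold.fold_id,
        )
        preds = predict_tracks(bundle, test_tab)
        panel = compute_metrics(
            preds["net_type"].to_numpy(),
            preds["track_call"].to_numpy(),
            preds["track_score"].to_numpy(),
        )
        conf = confusion_normalized(preds["net_type"], preds["track_call"])
        fold_reports.append(FoldReport(fold, panel, conf, preds))
        bundles[fold.fold_id] = bundle
        log.info(
            "fold %d: balanced accuracy %.3f over %d tracks",
            fold.fold_id, panel["balanced_accuracy"], len(preds),
        )
    if not fold_reports:
        raise ValueError("no fold produced predictions")

    summary = summarize_metric_panels([f.metrics for f in fold_reports])
    conf_mean = mean_confusion([f.confusion for f in fold_reports])
    tra = time_resolved_accuracy(
        [f.predictions for f in fold_reports], duration_s=config.scenario.duration_s
    )

    # --- attributions: every fold's test segments, aggregated, plus the
    # best-performing fold on its own (the headline explanation)
    all_atts: list[AttributionTable] = []
    for rep in fold_reports:
        t = model_tab[model_tab["trial_id"].isin(rep.spec.test_trials)]
        if not t.empty:
            all_atts.append(attribute_segments(bundles[rep.spec.fold_id], t))
    importance = rank_features(concat_attributions(all_atts)) if all_atts else None
    best = max(fold_reports, key=lambda f: f.metrics["balanced_accuracy"])
    best_bundle = bundles[best.spec.fold_id]
    test_tab = model_tab[model_tab["trial_id"].isin(best.spec.test_trials)]
    importance_best = None
    if not test_tab.empty:
        att: AttributionTable = attribute_segments(best_bundle, test_tab)
        importance_best = rank_features(att)

    return StudyReport(
        config=config,
        tuning_trials=list(tuning),
        modelling_trials=list(modelling),
        n_tracks=len(tracks),
        n_segments=len(table),
        n_segments_kept=len(kept),
        quality_threshold=float(threshold),
        selection=selection,
        folds=fold_reports,
        metrics_summary=summary,
        confusion_mean=conf_mean,
        time_resolved=tra,
        importance=importance,
        importance_best_fold=importance_best,
        best_fold_id=best.spec.fold_id,
    )
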