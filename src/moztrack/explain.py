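"""Shapley-value attribution of segment predictions to flight features.

Attributions are exact path-dependent TreeSHAP values computed by the
boosted-tree library itself, in the model's margin (log-odds) space where
additivity is exact: per segment, the base value plus the per-feature
attributions reconstructs the raw margin output.  Positive attributions
push the prediction toward the Olyset class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb

from .model import ModelBundle, zscore_apply

__all__ = [
    "AttributionTable",
    "attribute_segments",
    "concat_attributions",
    "rank_features",
]

log = logging.getLogger(__name__)


@dataclass
class AttributionTable:
    """Per-segment Shapley attributions in margin space.

    ``values`` is segments x features; ``base`` the per-row expected
    margin; ``margin`` the model's raw output; ``feature_values`` the raw
    (un-normalised) feature values of the scored rows.
    """

    values: pd.DataFrame
    base: np.ndarray
    margin: np.ndarray
    feature_values: pd.DataFrame

    def check_additivity(self, atol: float = 1e-5) -> None:
        recon = self.base + self.values.to_numpy().sum(axis=1)
        if not np.allclose(recon, self.margin, rtol=1e-5, atol=atol):
            worst = float(np.abs(recon - self.margin).max())
            raise AssertionError(f"Shapley additivity violated (max error {worst:.3g})")


def attribute_segments(bundle: ModelBundle, table: pd.DataFrame) -> AttributionTable:
    """Exact tree-path Shapley attribution for every segment row."""
    missing = [f for f in bundle.feature_names if f not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks model features: {missing}")
    X = zscore_apply(table, bundle.feature_names, bundle.mean, bundle.sd)
    booster = bundle.booster
    dmat = xgb.DMatrix(X, feature_names=bundle.feature_names)
    contribs = booster.predict(dmat, pred_contribs=True).astype(np.float64)
    margin = booster.predict(dmat, output_margin=True).astype(np.float64)
    att = AttributionTable(
        values=pd.DataFrame(contribs[:, :-1], columns=bundle.feature_names),
        base=contribs[:, -1],
        margin=margin,
        feature_values=table[bundle.feature_names].reset_index(drop=True),
    )
    att.check_additivity()
    return att


def concat_attributions(tables: list[AttributionTable]) -> AttributionTable:
    """Stack attribution tables (e.g. all folds' test segments) row-wise."""
    if not tables:
        raise ValueError("nothing to concatenate")
    return AttributionTable(
        values=pd.concat([t.values for t in tables], ignore_index=True),
        base=np.concatenate([t.base for t in tables]),
        margin=np.concatenate([t.margin for t in tables]),
        feature_values=pd.concat(
            [t.feature_values for t in tables], ignore_index=True
        ),
    )


def rank_features(attribution: AttributionTable) -> pd.DataFrame:
    """Importance ranking by mean |attribution|, with direction summaries.

    ``direction`` is the sign of the correlation between feature value and
    attribution: +1 means high feature values push toward the Olyset
    class.  Ties in importance are broken lexicographically, and the
    ranking is invariant to row order.
    """
    vals = attribution.values
    if vals.empty:
        raise ValueError("empty attribution table")
    rows = []
    for feat in vals.columns:
        a = vals[feat].to_numpy()
        x = attribution.feature_values[feat].to_numpy(dtype=float)
        if np.ptp(a) == 0 or np.ptp(x) == 0:
            direction = 0.0
        else:
            direction = float(np.sign(np.corrcoef(x, a)[0, 1]))
        rows.append(
            {
                "feature": feat,
                "mean_abs_shap": float(np.mean(np.abs(a))),
                "mean_shap": float(np.mean(a)),
                "direction": direction,
            }
        )
    ranked = pd.DataFrame(rows).sort_values(
        ["mean_abs_shap", "feature"], ascending=[False, True], kind="mergesort"
    )
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked.reset_index(drop=True)
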