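"""Feature screening on the tuning split.

Each candidate feature is tested for a distributional difference between
the two net-type classes with the Mann-Whitney U test; the family-wise
error rate is controlled at 0.05 by Bonferroni correction.  Surviving
features are then de-duplicated: of every pair with Spearman |rho| above
0.85, the member with the weaker marginal signal (larger U-test p) is
dropped.  Selection runs on the tuning trials only and is frozen before
any modelling.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MWUResult",
    "SelectionReport",
    "mann_whitney_u",
    "fwer_select",
    "correlation_dedup",
    "select_features",
]

log = logging.getLogger(__name__)

# exact enumeration is used for small samples only; beyond this many
# rank splits the tie-corrected normal approximation is used instead
_EXACT_MAX_GROUP = 8
_EXACT_MAX_SPLITS = 2_000_000


@dataclass(frozen=True)
class MWUResult:
    """U statistic and two-sided p; ``log_p`` (natural log) stays finite
    where ``p`` underflows, for comparing extremely small p-values."""

    U: float
    p: float
    log_p: float = 0.0
    degenerate: bool = False


def _u_from_ranks(rank_sum_a: float, n_a: int) -> float:
    return rank_sum_a - n_a * (n_a + 1) / 2.0


def mann_whitney_u(a, b) -> MWUResult:
    """Two-sided Mann-Whitney U test with midranks for ties.

    Small samples (both groups <= 8) get an exact tie-aware permutation
    p-value by enumerating all rank splits; larger samples use the normal
    approximation with tie-corrected variance and continuity correction.
    Identical pooled values return p = 1 with a degeneracy flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    if n < 1 or m < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = _u_from_ranks(float(ranks[:n].sum()), n)
    if np.all(pooled == pooled[0]):
        return MWUResult(U=u_a, p=1.0, log_p=0.0, degenerate=True)

    if min(n, m) <= _EXACT_MAX_GROUP and math.comb(n + m, min(n, m)) <= _EXACT_MAX_SPLITS:
        p = _exact_two_sided_p(ranks, n, u_a)
        return MWUResult(U=u_a, p=p, log_p=math.log(p))

    N = n + m
    mu = n * m / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (N * (N - 1))
    sigma2 = n * m / 12.0 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        return MWUResult(U=u_a, p=1.0, log_p=0.0, degenerate=True)
    diff = u_a - mu
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(sigma2)
    log_p = min(0.0, math.log(2.0) + float(stats.norm.logsf(abs(z))))
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return MWUResult(U=u_a, p=p, log_p=log_p)


def _exact_two_sided_p(ranks: np.ndarray, n: int, u_obs: float) -> float:
    """Exact permutation distribution of U over all rank splits.

    Enumerates which pooled positions belong to the smaller group and
    counts splits at least as extreme as the observed U in either tail.
    Works with midranks, so ties are handled exactly.
    """
    N = len(ranks)
    k = min(n, N - n)
    offset = k * (k + 1) / 2.0
    total = math.comb(N, k)
    lo = hi = 0
    # U of group a and of its complement sum to n*m, so tails of the
    # smaller group's distribution give both tail probabilities.
    if k == n:
        u_small = u_obs
    else:
        u_small = n * (N - n) - u_obs
    eps = 1e-9
    for idx in combinations(range(N), k):
        u = ranks[list(idx)].sum() - offset
        if u <= u_small + eps:
            lo += 1
        if u >= u_small - eps:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def fwer_select(p_values: dict[str, float], alpha: float = 0.05) -> list[str]:
    """Bonferroni selection: keep features with p <= alpha / m."""
    m = len(p_values)
    if m < 1:
        raise ValueError("no p-values to select from")
    cut = alpha / m
    return [f for f, p in p_values.items() if p <= cut]


def correlation_dedup(
    feature_table: pd.DataFrame,
    selected: list[str],
    rho_threshold: float = 0.85,
    p_values: dict[str, float] | None = None,
) -> tuple[list[str], list[tuple[str, str, float, str]]]:
    """Drop one member of every highly rank-correlated pair.

    Pairs with Spearman |rho| > threshold are visited in decreasing |rho|
    order; from each still-intact pair the member with the larger U-test p
    is dropped (ties: the lexicographically later name).  Returns the
    surviving features and a record of (kept, dropped, rho, reason).
    """
    if not selected:
        raise ValueError("selected feature list is empty")
    if len(selected) == 1:
        return list(selected), []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = feature_table[selected].corr(method="spearman").to_numpy()
    if np.isnan(rho).any():
        log.warning("constant feature(s) give undefined correlations; treated as 0")
        rho = np.nan_to_num(rho, nan=0.0)
    p_values = p_values or {}
    pairs = []
    for i, j in combinations(range(len(selected)), 2):
        r = abs(float(rho[i, j]))
        if r > rho_threshold:
            pairs.append((r, selected[i], selected[j]))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    alive = set(selected)
    dropped_log = []
    for r, fi, fj in pairs:
        if fi not in alive or fj not in alive:
            continue
        pi = p_values.get(fi, np.inf)
        pj = p_values.get(fj, np.inf)
        if pi < pj or (pi == pj and fi < fj):
            keep, drop = fi, fj
        else:
            keep, drop = fj, fi
        alive.discard(drop)
        dropped_log.append((keep, drop, r, "rho"))
    final = [f for f in selected if f in alive]
    return final, dropped_log


@dataclass
class SelectionReport:
    """Outcome of the screening stage."""

    u_stats: dict[str, float]
    p_values: dict[str, float]
    alpha: float
    passed_fwer: list[str]
    dropped_pairs: list[tuple[str, str, float, str]] = field(default_factory=list)
    final: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "u_stats": self.u_stats,
            "p_values": self.p_values,
            "passed_fwer": self.passed_fwer,
            "dropped_pairs": [list(t) for t in self.dropped_pairs],
            "final": self.final,
        }


def select_features(
    table: pd.DataFrame,
    feature_names: list[str],
    label_col: str = "net_type",
    positive: str = "OL",
    alpha: float = 0.05,
    rho_threshold: float = 0.85,
) -> SelectionReport:
    """Run the full screening stage on a (tuning) feature table."""
    labels = table[label_col].to_numpy()
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    pos_mask = labels == positive
    u_stats: dict[str, float] = {}
    p_values: dict[str, float] = {}
    log_p: dict[str, float] = {}
    for f in feature_names:
        vals = table[f].to_numpy(dtype=float)
        res = mann_whitney_u(vals[pos_mask], vals[~pos_mask])
        u_stats[f] = res.U
        p_values[f] = res.p
        log_p[f] = res.log_p
    passed = fwer_select(p_values, alpha)
    if not passed:
        log.warning("no feature passed the FWER screen at alpha=%.3g", alpha)
        return SelectionReport(u_stats, p_values, alpha, [], [], [])
    # compare strengths on the log scale so that extremely small p-values
    # (which underflow to 0.0) still order features correctly
    final, dropped = correlation_dedup(table, passed, rho_threshold, log_p)
    log.info(
        "selection: %d tested, %d passed FWER, %d after dedup",
        len(feature_names), len(passed), len(final),
    )
    return SelectionReport(u_stats, p_values, alpha, passed, dropped, final)
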