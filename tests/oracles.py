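"""Independent brute-force implementations used as test oracles.

Everything here is written with naive loops and first-principles formulas,
deliberately sharing no code with the package, so that agreement between
the two routes is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import json
import math
from itertools import combinations

import numpy as np


# ---------------------------------------------------------------------------
# feature oracles


def naive_quantile(values, q):
    """Linear interpolation of order statistics."""
    xs = sorted(values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = (n - 1) * q
    lo = int(math.floor(h))
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def naive_summary(values):
    vals = [v for v in values]
    n = len(vals)
    mean = sum(vals) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1)) if n >= 2 else float("nan")
    return {
        "mean": mean,
        "sd": sd,
        "min": min(vals),
        "max": max(vals),
        "q1": naive_quantile(vals, 0.25),
        "median": naive_quantile(vals, 0.5),
        "q3": naive_quantile(vals, 0.75),
    }


def naive_segment_features(x, y, real, fps):
    """Loop-based re-derivation of the full per-segment feature vector."""
    n = len(x)
    vx = [(x[i + 1] - x[i]) * fps for i in range(n - 1)]
    vy = [(y[i + 1] - y[i]) * fps for i in range(n - 1)]
    speed = [math.hypot(vx[i], vy[i]) for i in range(n - 1)]
    heading = [math.atan2(vy[i], vx[i]) for i in range(n - 1)]
    angle = []
    for i in range(n - 2):
        d = heading[i + 1] - heading[i]
        while d <= -math.pi:
            d += 2 * math.pi
        while d > math.pi:
            d -= 2 * math.pi
        angle.append(abs(d))
    accel = [
        math.hypot(vx[i + 1] - vx[i], vy[i + 1] - vy[i]) * fps for i in range(n - 2)
    ]
    valid_v = [real[i] and real[i + 1] for i in range(n - 1)]
    valid_a = [real[i] and real[i + 1] and real[i + 2] for i in range(n - 2)]
    step = [speed[i] / fps for i in range(n - 1)]
    curv, valid_c = [], []
    for i in range(n - 2):
        if step[i] > 0:
            curv.append(angle[i] / step[i])
            valid_c.append(valid_a[i])
        else:
            curv.append(float("nan"))
            valid_c.append(False)

    out = {}
    for name, series, mask in (
        ("vx", vx, valid_v),
        ("vy", vy, valid_v),
        ("speed", speed, valid_v),
        ("accel", accel, valid_a),
        ("angle_change", angle, valid_a),
        ("curvature", curv, valid_c),
    ):
        kept = [s for s, m in zip(series, mask) if m]
        if kept:
            for stat, val in naive_summary(kept).items():
                out[f"{name}_{stat}"] = val
        else:
            for stat in ("mean", "sd", "min", "max", "q1", "median", "q3"):
                out[f"{name}_{stat}"] = float("nan")

    out["vx_zero_crossings"] = naive_zero_crossings(vx, True, valid_v)
    out["vy_zero_crossings"] = naive_zero_crossings(vy, True, valid_v)
    out["angle_change_zero_crossings"] = naive_zero_crossings(angle, False, valid_a)

    pts = [(x[i], y[i]) for i in range(n) if real[i]]
    if len(pts) >= 2:
        path = sum(
            math.hypot(pts[i + 1][0] - pts[i][0], pts[i + 1][1] - pts[i][1])
            for i in range(len(pts) - 1)
        )
        net = math.hypot(pts[-1][0] - pts[0][0], pts[-1][1] - pts[0][1])
        out["path_length"] = path
        out["net_displacement"] = net
        out["straightness"] = net / path if path > 0 else 0.0
    else:
        out["path_length"] = out["net_displacement"] = out["straightness"] = float("nan")
    return out


def naive_zero_crossings(series, signed, mask):
    count = 0
    for s, m in zip(series, mask):
        if m and s == 0:
            count += 1
    if signed:
        for i in range(len(series) - 1):
            if mask[i] and mask[i + 1] and series[i] * series[i + 1] < 0:
                count += 1
    return count


# ---------------------------------------------------------------------------
# statistics oracles


def naive_mwu(a, b):
    """Exact Mann-Whitney U and two-sided permutation p (midranks, ties)."""
    pooled = list(a) + list(b)
    n, m = len(a), len(b)
    ranks = _midranks(pooled)
    u_a = sum(ranks[:n]) - n * (n + 1) / 2.0
    k = min(n, m)
    u_small = u_a if k == n else n * m - u_a
    total = lo = hi = 0
    offset = k * (k + 1) / 2.0
    for idx in combinations(range(n + m), k):
        u = sum(ranks[i] for i in idx) - offset
        total += 1
        if u <= u_small + 1e-9:
            lo += 1
        if u >= u_small - 1e-9:
            hi += 1
    return u_a, min(1.0, 2.0 * min(lo, hi) / total)


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k2 in range(i, j + 1):
            ranks[order[k2]] = avg
        i = j + 1
    return ranks


def naive_mcc(tp, fp, tn, fn):
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return ((tp * tn) - (fp * fn)) / denom if denom > 0 else 0.0


def naive_mcc_sweep(probs, y, grid):
    """Exhaustive boundary sweep; ties -> smallest boundary."""
    best_tau, best = None, -2.0
    for tau in grid:
        tp = sum(1 for p, t in zip(probs, y) if p >= tau and t)
        fp = sum(1 for p, t in zip(probs, y) if p >= tau and not t)
        fn = sum(1 for p, t in zip(probs, y) if p < tau and t)
        tn = sum(1 for p, t in zip(probs, y) if p < tau and not t)
        mcc = naive_mcc(tp, fp, tn, fn)
        if mcc > best + 1e-12:
            best, best_tau = mcc, tau
    return best_tau


def naive_metric_panel(y_true, y_call, scores):
    """First-principles metric panel ('OL' positive plus dual versions)."""
    t = [yy == "OL" for yy in y_true]
    c = [yy == "OL" for yy in y_call]
    n = len(t)
    tp = sum(1 for a, b in zip(t, c) if a and b)
    fp = sum(1 for a, b in zip(t, c) if not a and b)
    fn = sum(1 for a, b in zip(t, c) if a and not b)
    tn = n - tp - fp - fn
    panel = {}
    panel["balanced_accuracy"] = 0.5 * (tp / (tp + fn) + tn / (tn + fp))
    panel["mcc"] = naive_mcc(tp, fp, tn, fn)
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n**2
    panel["cohen_kappa"] = (po - pe) / (1 - pe) if pe != 1 else 0.0
    panel["log_loss"] = -sum(
        math.log(s) if a else math.log(1 - s) for a, s in zip(t, scores)
    ) / n
    panel["roc_auc"] = naive_roc_auc(t, scores)
    for pos in ("OL", "UT"):
        tt = t if pos == "OL" else [not a for a in t]
        cc = c if pos == "OL" else [not a for a in c]
        ss = scores if pos == "OL" else [1 - s for s in scores]
        tp2 = sum(1 for a, b in zip(tt, cc) if a and b)
        fp2 = sum(1 for a, b in zip(tt, cc) if not a and b)
        fn2 = sum(1 for a, b in zip(tt, cc) if a and not b)
        prec = tp2 / (tp2 + fp2) if tp2 + fp2 else 0.0
        rec = tp2 / (tp2 + fn2) if tp2 + fn2 else 0.0
        panel[f"precision_{pos}"] = prec
        panel[f"recall_{pos}"] = rec
        panel[f"f1_{pos}"] = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        panel[f"pr_auc_{pos}"] = naive_average_precision(tt, ss)
    return panel


def naive_roc_auc(t, scores):
    """Pair-counting AUC with half credit for score ties."""
    pos = [s for s, a in zip(scores, t) if a]
    neg = [s for s, a in zip(scores, t) if not a]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def naive_average_precision(t, scores):
    """AP = sum over ranked positives of precision * recall increment."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    n_pos = sum(t)
    tp = 0
    ap = 0.0
    for k, i in enumerate(order, start=1):
        if t[i]:
            tp += 1
            ap += (tp / k) * (1.0 / n_pos)
    return ap


# ---------------------------------------------------------------------------
# brute-force Shapley values for an xgboost ensemble


def _parse_tree(node):
    if "leaf" in node:
        return {"leaf": node["leaf"], "cover": node["cover"]}
    children = {c["nodeid"]: c for c in node["children"]}
    return {
        "split": int(node["split"].lstrip("f")),
        "threshold": node["split_condition"],
        "yes": _parse_tree(children[node["yes"]]),
        "no": _parse_tree(children[node["no"]]),
        "cover": node["cover"],
    }


def load_trees(booster):
    dumps = booster.get_dump(dump_format="json", with_stats=True)
    return [_parse_tree(json.loads(d)) for d in dumps]


def tree_expectation(tree, x, subset):
    """Cover-weighted conditional expectation: features outside ``subset``
    are marginalised along the tree's own training distribution."""
    if "leaf" in tree:
        return tree["leaf"]
    if tree["split"] in subset:
        # the library evaluates splits in single precision
        go_left = np.float32(x[tree["split"]]) < np.float32(tree["threshold"])
        return tree_expectation(tree["yes"] if go_left else tree["no"], x, subset)
    wy = tree["yes"]["cover"]
    wn = tree["no"]["cover"]
    return (
        wy * tree_expectation(tree["yes"], x, subset)
        + wn * tree_expectation(tree["no"], x, subset)
    ) / (wy + wn)


def margin_intercept(booster):
    """The constant margin offset of a booster (logit of base_score for a
    logistic objective)."""
    cfg = json.loads(booster.save_config())["learner"]
    base = float(cfg["learner_model_param"]["base_score"])
    objective = cfg["learner_train_param"]["objective"]
    if objective.startswith(("binary:logistic", "binary:logitraw")):
        return math.log(base / (1.0 - base))
    return base


def brute_force_shap(booster, x, n_features):
    """Exact Shapley values over all feature coalitions (exponential time).

    Returns (phi, base) with phi of length n_features; base is the
    expected margin (empty-coalition value).
    """
    trees = load_trees(booster)
    intercept = margin_intercept(booster)

    def value(subset):
        return intercept + sum(tree_expectation(t, x, subset) for t in trees)

    feats = list(range(n_features))
    phi = np.zeros(n_features)
    for i in feats:
        others = [f for f in feats if f != i]
        for r in range(len(others) + 1):
            for sub in combinations(others, r):
                s = set(sub)
                w = (
                    math.factorial(len(s))
                    * math.factorial(n_features - len(s) - 1)
                    / math.factorial(n_features)
                )
                phi[i] += w * (value(s | {i}) - value(s))
    return phi, value(set())
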