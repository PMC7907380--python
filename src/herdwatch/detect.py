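"""System-level intrusion detection from 15-min summary features.

Per 15-min block of a segment, features describe the SVM response
probabilities over the sentinel network and their spatial structure: level
statistics, local spatial autocorrelation over animal positions, the
nearest-neighbor clustering of predicted-undisturbed animals, and the
intrusion-association log-odds of the animals' unsupervised behavior
clusters. Blocks are aggregated per segment by eight statistics (mean, sd,
min, max and the same four over lagged first differences). Features are
then ordered by an iterative residualized two-sample t-test — the winning
feature is added, its correlation regressed out of the rest, residuals
standardized, and the t-tests repeated — and a logistic model on the top-n
ordered features separates intrusions from controls, validated by 25x
stratified twofold cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import MultiPoint
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import PolynomialFeatures

logger = logging.getLogger(__name__)

BLOCK_S = 15 * 60.0
SUMMARY_STATS = ("mean", "sd", "min", "max",
                 "dmean", "dsd", "dmin", "dmax")


# ---------------------------------------------------------------------------
# Segment pairing
# ---------------------------------------------------------------------------


def make_segments(intrusions: list, seed: int = 0,
                  offsets_s=(-2 * 86400.0, -86400.0, 86400.0, 2 * 86400.0),
                  blocked: list | None = None) -> list[dict]:
    """Pair every intrusion with a same-clock-time control window.

    The control is the same period one or two days earlier or later,
    drawn seeded-random among offsets whose window overlaps no intrusion
    or blocked interval. Intrusions without a valid control are dropped
    (logged). ``intrusions`` may be IntrusionEvent objects or (id, t0, t1)
    tuples; returns dicts with intrusion and control windows.
    """
    rng = np.random.default_rng(seed)

    def _tup(iv):
        if hasattr(iv, "t_start"):
            return iv.intrusion_id, float(iv.t_start), float(iv.t_end)
        return str(iv[0]), float(iv[1]), float(iv[2])

    windows = [_tup(iv) for iv in intrusions]
    occupied = [(t0, t1) for _, t0, t1 in windows]
    occupied += [(float(b[0]), float(b[1])) for b in (blocked or [])]

    out = []
    for iv, (iid, t0, t1) in zip(intrusions, windows):
        valid = []
        for off in offsets_s:
            c0, c1 = t0 + off, t1 + off
            if all(c1 <= o0 or c0 >= o1 for o0, o1 in occupied):
                valid.append(off)
        if not valid:
            logger.info("make_segments: no valid control window for %s", iid)
            continue
        off = valid[int(rng.integers(len(valid)))]
        out.append({"intrusion_id": iid, "intrusion": iv,
                    "t_start": t0, "t_end": t1,
                    "control_t_start": t0 + off, "control_t_end": t1 + off,
                    "offset_s": off})
    return out


# ---------------------------------------------------------------------------
# Block and segment summaries
# ---------------------------------------------------------------------------


def morans_i(values: np.ndarray, positions: np.ndarray) -> float:
    """Moran's I with inverse-distance weights over animal positions.

    Positive values mean similar response probabilities cluster in space.
    Returns 0.0 by convention when the values have no variance.
    """
    v = np.asarray(values, dtype=float)
    p = np.asarray(positions, dtype=float)
    n = len(v)
    if n < 2:
        return np.nan
    z = v - v.mean()
    denom = np.sum(z ** 2)
    if denom <= 1e-15:
        return 0.0
    d = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=2)
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    w[~np.isfinite(w)] = 0.0
    sw = w.sum()
    if sw <= 0:
        return np.nan
    return float((n / sw) * np.sum(w * np.outer(z, z)) / denom)


def nearest_neighbor_index(positions: np.ndarray) -> float:
    """Clark-Evans nearest-neighbor index within the point set's hull.

    Observed mean NN distance over the expectation 0.5 * sqrt(A / n)
    under complete spatial randomness in the convex-hull area A. Values
    < 1 indicate clustering. Needs >= 3 non-collinear points.
    """
    p = np.asarray(positions, dtype=float)
    n = len(p)
    if n < 3:
        return np.nan
    d = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    observed = d.min(axis=1).mean()
    area = MultiPoint([tuple(q) for q in p]).convex_hull.area
    if area <= 0:
        return np.nan
    expected = 0.5 * np.sqrt(area / n)
    return float(observed / expected)


def summarize_block(probs: np.ndarray, positions: np.ndarray,
                    cluster_logodds: np.ndarray | None = None,
                    undisturbed_boundary: float = 0.5) -> pd.Series:
    """Feature vector for one 15-min block of one segment.

    ``probs``: per-animal smoothed response probability (block mean);
    ``positions``: per-animal representative position; optional
    ``cluster_logodds``: per-animal log-odds of its behavior cluster's
    association with intrusions (from training segments).
    """
    probs = np.asarray(probs, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if len(probs) < 2:
        feats = {k: np.nan for k in
                 ("prob_mean", "prob_max", "prob_sd", "prob_q90",
                  "prob_moran", "undist_nni", "cluster_logodds_mean")}
        if len(probs) == 1:
            feats["prob_mean"] = float(probs[0])
            feats["prob_max"] = float(probs[0])
        return pd.Series(feats)
    feats = {
        "prob_mean": float(np.mean(probs)),
        "prob_max": float(np.max(probs)),
        "prob_sd": float(np.std(probs, ddof=1)),
        "prob_q90": float(np.quantile(probs, 0.9)),
        "prob_moran": morans_i(probs, positions),
    }
    undist = probs < undisturbed_boundary
    feats["undist_nni"] = (nearest_neighbor_index(positions[undist])
                           if undist.sum() >= 3 else np.nan)
    feats["cluster_logodds_mean"] = (float(np.nanmean(cluster_logodds))
                                     if cluster_logodds is not None
                                     and len(cluster_logodds) else np.nan)
    return pd.Series(feats)


def summarize_segment(block_features: pd.DataFrame) -> pd.Series:
    """Aggregate block features with the eight summary statistics.

    mean / sd / min / max of the block series, and the same four of its
    lagged (first) differences across consecutive blocks.
    """
    out = {}
    for col in block_features.columns:
        v = block_features[col].to_numpy(float)
        v = v[np.isfinite(v)]
        d = np.diff(v)
        out[f"{col}__mean"] = v.mean() if len(v) else np.nan
        out[f"{col}__sd"] = v.std(ddof=1) if len(v) > 1 else np.nan
        out[f"{col}__min"] = v.min() if len(v) else np.nan
        out[f"{col}__max"] = v.max() if len(v) else np.nan
        out[f"{col}__dmean"] = d.mean() if len(d) else np.nan
        out[f"{col}__dsd"] = d.std(ddof=1) if len(d) > 1 else np.nan
        out[f"{col}__dmin"] = d.min() if len(d) else np.nan
        out[f"{col}__dmax"] = d.max() if len(d) else np.nan
    return pd.Series(out)


def cluster_odds_table(cluster_ids: pd.Series, is_intrusion: pd.Series,
                       pseudo: float = 0.5) -> pd.Series:
    """Log odds-ratio of each behavior cluster's association with intrusions.

    Haldane-corrected 2x2 odds ratio per cluster (cluster membership vs
    rest, intrusion vs control rows), on training segments only.
    """
    ci = pd.crosstab(cluster_ids, is_intrusion.astype(bool))
    for col in (False, True):
        if col not in ci:
            ci[col] = 0
    a = ci[True] + pseudo
    b = ci[False] + pseudo
    tot_t = float(ci[True].sum()) + pseudo
    tot_f = float(ci[False].sum()) + pseudo
    return np.log((a / (tot_t - a)) / (b / (tot_f - b)))


# ---------------------------------------------------------------------------
# Residualized t-test feature ordering
# ---------------------------------------------------------------------------


def order_features(summaries: pd.DataFrame, y: np.ndarray) -> pd.DataFrame:
    """Importance ordering by iterative residualized two-sample t-tests.

    Each round: two-sample t-test per remaining (working) feature between
    intrusion and control segments; the feature with the largest |t| is
    appended to the order; the *original* values of that feature are then
    regressed out of every remaining working feature, residuals are
    standardized, and the t-tests repeat. Zero-variance features are
    skipped with a warning; ties break on feature name.
    """
    y = np.asarray(y).astype(bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need >= 2 segments per class")
    X = summaries.astype(float)
    X = X.fillna(X.mean())
    drop = [c for c in X.columns if X[c].std(ddof=0) <= 1e-12
            or not np.isfinite(X[c]).all()]
    if drop:
        warnings.warn(f"order_features: skipping {len(drop)} degenerate features")
        X = X.drop(columns=drop)

    work = (X - X.mean()) / X.std(ddof=1)
    remaining = list(X.columns)
    order = []
    while remaining:
        tvals = {}
        for c in remaining:
            v = work[c].to_numpy()
            t, _ = stats.ttest_ind(v[y], v[~y], equal_var=True)
            tvals[c] = 0.0 if not np.isfinite(t) else float(t)
        best = max(remaining, key=lambda c: (abs(tvals[c]), c))
        order.append({"feature": best, "t_value": tvals[best],
                      "abs_t": abs(tvals[best])})
        remaining.remove(best)
        if remaining:
            xb = X[best].to_numpy()
            xb = np.column_stack([np.ones(len(xb)), xb])
            for c in remaining:
                beta, *_ = np.linalg.lstsq(xb, work[c].to_numpy(), rcond=None)
                resid = work[c].to_numpy() - xb @ beta
                sd = resid.std(ddof=1)
                work[c] = resid / sd if sd > 1e-12 else 0.0
    return pd.DataFrame(order)


# ---------------------------------------------------------------------------
# Logistic detector
# ---------------------------------------------------------------------------


@dataclass
class DetectorModel:
    ordered_features: pd.DataFrame
    n_features: int
    interactions: bool
    model: LogisticRegression
    feature_means: pd.Series
    regularized_fallback: bool = False
    poly: PolynomialFeatures | None = None

    @property
    def features(self) -> list[str]:
        return self.ordered_features["feature"].head(self.n_features).tolist()

    def _design(self, summaries: pd.DataFrame) -> np.ndarray:
        X = (summaries[self.features].astype(float)
             .fillna(self.feature_means[self.features]).to_numpy())
        if self.poly is not None:
            X = self.poly.transform(X)
        return X

    def predict_proba(self, summaries: pd.DataFrame) -> np.ndarray:
        return self.model.predict_proba(self._design(summaries))[:, 1]

    def predict(self, summaries: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(summaries) >= 0.5).astype(int)


def fit_detector(summaries: pd.DataFrame, y: np.ndarray,
                 n_features: int = 7, interactions: bool = False,
                 ordered: pd.DataFrame | None = None) -> DetectorModel:
    """Logistic regression on the top-n ordered summary features.

    ``n_features=7`` is the parsimonious default; ``interactions=True``
    adds all 2-way interaction terms. Perfect separation triggers a
    ridge-regularized fallback (flagged on the model).
    """
    y = np.asarray(y).astype(int)
    if ordered is None:
        ordered = order_features(summaries, y)
    if n_features > len(ordered):
        raise ValueError("n_features exceeds available features")
    feats = ordered["feature"].head(n_features).tolist()
    means = summaries.astype(float).mean()
    X = summaries[feats].astype(float).fillna(means[feats]).to_numpy()
    poly = None
    if interactions:
        poly = PolynomialFeatures(degree=2, interaction_only=True,
                                  include_bias=False).fit(X)
        X = poly.transform(X)
    fallback = False
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("error", category=ConvergenceWarning)
        try:
            # unpenalized maximum-likelihood logistic regression
            model = LogisticRegression(C=np.inf, max_iter=2000)
            model.fit(X, y)
        except ConvergenceWarning:
            fallback = True
    if fallback:
        logger.info("fit_detector: separation/convergence issue; "
                    "ridge-regularized fallback")
        model = LogisticRegression(C=1.0, max_iter=2000)
        model.fit(X, y)
    return DetectorModel(ordered_features=ordered, n_features=n_features,
                         interactions=interactions, model=model,
                         feature_means=means, regularized_fallback=fallback,
                         poly=poly)


@dataclass
class DetectorCV:
    accuracy: np.ndarray           # per repeat
    precision: np.ndarray
    recall: np.ndarray
    confusion: pd.DataFrame        # pooled, truth rows x prediction columns

    @property
    def summary(self) -> dict:
        return {
            "accuracy_mean": float(self.accuracy.mean()),
            "accuracy_sd": float(self.accuracy.std(ddof=1)),
            "precision_mean": float(np.nanmean(self.precision)),
            "precision_sd": float(np.nanstd(self.precision, ddof=1)),
            "recall_mean": float(np.nanmean(self.recall)),
            "recall_sd": float(np.nanstd(self.recall, ddof=1)),
        }


def cross_validate_detector(summaries: pd.DataFrame, y: np.ndarray,
                            n_features: int = 7, interactions: bool = False,
                            n_repeats: int = 25, seed: int = 0) -> DetectorCV:
    """Stratified repeated twofold cross-validation of the detector.

    Feature ordering is re-fit inside every training fold (no leakage).
    Returns per-repeat accuracy/precision/recall and the pooled confusion
    matrix (truth in rows, prediction in columns).
    """
    y = np.asarray(y).astype(int)
    if (y == 1).sum() < 4 or (y == 0).sum() < 4:
        raise ValueError("need >= 4 segments per class for stratified "
                         "twofold CV with per-fold t-test ordering")
    rng = np.random.default_rng(seed)
    acc, prec, rec = [], [], []
    cm = np.zeros((2, 2), dtype=int)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    for rep in range(n_repeats):
        for _attempt in range(20):
            pos = rng.permutation(idx_pos)
            neg = rng.permutation(idx_neg)
            fold_of = np.zeros(len(y), dtype=int)
            fold_of[pos[len(pos) // 2:]] = 1
            fold_of[neg[len(neg) // 2:]] = 1
            ok = all(len(np.unique(y[fold_of == f])) == 2 for f in (0, 1))
            if ok:
                break
        tp = fp = tn = fn = 0
        for f in (0, 1):
            tr = fold_of != f
            te = ~tr
            model = fit_detector(summaries[tr], y[tr], n_features, interactions)
            pred = model.predict(summaries[te])
            yt = y[te]
            tp += int(np.sum((pred == 1) & (yt == 1)))
            fp += int(np.sum((pred == 1) & (yt == 0)))
            tn += int(np.sum((pred == 0) & (yt == 0)))
            fn += int(np.sum((pred == 0) & (yt == 1)))
        acc.append((tp + tn) / (tp + tn + fp + fn))
        prec.append(tp / (tp + fp) if tp + fp else np.nan)
        rec.append(tp / (tp + fn) if tp + fn else np.nan)
        cm += np.array([[tn, fp], [fn, tp]])
    confusion = pd.DataFrame(cm, index=pd.Index(["control", "intrusion"],
                                                name="truth"),
                             columns=pd.Index(["control", "intrusion"],
                                              name="prediction"))
    return DetectorCV(accuracy=np.asarray(acc), precision=np.asarray(prec),
                      recall=np.asarray(rec), confusion=confusion)
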