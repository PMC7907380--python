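"""Per-animal behavior classification: undisturbed vs response (and
flight vs regroup).

An RBF-kernel C-SVM consumes the leading principal components of the
selected feature space and emits per-minute response probabilities; a
centered moving-window quantile (default: the maximum over +/-15 min)
smooths the probability series. Training sets mirror the field protocol:
undisturbed rows are restricted to > 1 km from the intruder and thinned to
10% for balance, response rows to medium/high intensity, and everything to
intrusion-present periods. Model selection and evaluation use
leave-one-intrusion-out cross-validation scored by the average precision
of the rarer class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score
from sklearn.metrics import precision_recall_curve as _sk_pr_curve
from sklearn.svm import SVC

# selected hyperparameters of the two classifiers
UNDISTURBED_RESPONSE = dict(gamma=10 ** -3.2, C=10 ** -2.2, n_components=8)
FLIGHT_REGROUP = dict(gamma=10 ** -2.0, C=10 ** -1.5, n_components=12)


@dataclass
class BehaviorModelSpec:
    gamma: float = UNDISTURBED_RESPONSE["gamma"]
    C: float = UNDISTURBED_RESPONSE["C"]
    n_components: int = UNDISTURBED_RESPONSE["n_components"]
    class_weight: dict | None = None      # None = equal weights
    window_min: int = 15                  # smoothing half-window (minutes)
    window_quantile: float = 1.0          # 1.0 = running maximum
    window_align: str = "center"
    per_species: bool = True


@dataclass
class BehaviorModel:
    spec: BehaviorModelSpec
    svm: SVC
    classes_: np.ndarray

    def predict_proba(self, components: pd.DataFrame) -> np.ndarray:
        """Probability of the positive (response / regroup) class."""
        X = components.to_numpy(float)[:, :self.spec.n_components]
        proba = self.svm.predict_proba(X)
        pos = int(np.argmax(self.svm.classes_))
        return proba[:, pos]


def build_training_set(rows: pd.DataFrame, seed: int = 0,
                       exclusion_radius_m: float = 1000.0,
                       undisturbed_keep_fraction: float = 0.10,
                       min_intensity: int = 2) -> pd.DataFrame:
    """Select training rows per the field protocol.

    ``rows`` must carry ``label`` (0 undisturbed / 1 flight / 2 regroup),
    ``intensity`` (0..3), ``dist_to_intruder`` (m; inf when no intruder)
    and ``intrusion_present`` (bool). Undisturbed rows farther than
    ``exclusion_radius_m`` from the intruder are thinned to
    ``undisturbed_keep_fraction`` (seeded, exact count); response rows
    require intensity >= ``min_intensity`` (medium). Only rows from
    intrusion-present periods qualify.
    """
    rng = np.random.default_rng(seed)
    live = rows[rows["intrusion_present"].astype(bool)]
    undisturbed = live[(live["label"] == 0)
                       & (live["dist_to_intruder"] > exclusion_radius_m)]
    response = live[(live["label"] > 0) & (live["intensity"] >= min_intensity)]
    if len(response) == 0:
        raise ValueError("no qualifying response rows; training aborted")
    n_keep = int(round(len(undisturbed) * undisturbed_keep_fraction))
    take = rng.choice(len(undisturbed), size=n_keep, replace=False)
    return pd.concat([undisturbed.iloc[np.sort(take)], response]).sort_index()


def fit_behavior_model(components: pd.DataFrame, y: np.ndarray,
                       spec: BehaviorModelSpec | None = None,
                       seed: int = 0) -> BehaviorModel:
    """Train the probability-emitting SVM on the leading components."""
    spec = spec or BehaviorModelSpec()
    X = components.to_numpy(float)[:, :spec.n_components]
    y = np.asarray(y).astype(int)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in classifier inputs")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for training")
    svm = SVC(kernel="rbf", gamma=spec.gamma, C=spec.C, probability=True,
              class_weight=spec.class_weight, random_state=seed)
    svm.fit(X, y)
    return BehaviorModel(spec=spec, svm=svm, classes_=svm.classes_)


def smooth_probabilities(series: pd.Series, window_min: int = 15,
                         quantile: float = 1.0,
                         align: str = "center") -> pd.Series:
    """Moving-window quantile of a per-minute probability series.

    Default: centered running maximum over +/-``window_min`` minutes —
    a brief response spike therefore flags the whole surrounding window.
    Edges use whatever support is available. Grouped by animal when the
    series carries a MultiIndex with an ``animal_id`` level.
    """
    if align not in ("center", "right"):
        raise ValueError("align must be 'center' or 'right'")
    w = 2 * window_min + 1 if align == "center" else window_min + 1

    def _one(v: pd.Series) -> pd.Series:
        r = v.rolling(w, center=(align == "center"), min_periods=1)
        return r.max() if quantile >= 1.0 else r.quantile(quantile)

    if isinstance(series.index, pd.MultiIndex) and "animal_id" in series.index.names:
        return series.groupby(level="animal_id", group_keys=False).apply(_one)
    return _one(series)


@dataclass
class CVResult:
    probabilities: pd.Series       # pooled out-of-fold positive-class probs
    y: pd.Series
    folds: pd.Series               # fold (intrusion) id per row
    ap_pooled: float
    ap_per_fold: dict
    ap_mean_folds: float
    subgroup_ap: dict = field(default_factory=dict)
    fold_audit: list = field(default_factory=list)


def loio_cross_validate(components: pd.DataFrame, y: pd.Series,
                        groups: pd.Series,
                        spec: BehaviorModelSpec | None = None,
                        subgroups: pd.DataFrame | None = None,
                        seed: int = 0,
                        fold_fitter=None) -> CVResult:
    """Leave-one-intrusion-out cross-validation.

    Every intrusion's rows are predicted by a model that never saw that
    intrusion. ``fold_fitter(train_idx)`` may supply a per-fold fitted
    ``(transform, model)`` pair so that upstream steps (standardization
    references, PC stack) are re-fit per fold; by default the provided
    components are used as-is and only the SVM is re-fit. Average
    precision is reported pooled over all out-of-fold predictions and as
    the mean of per-fold APs; optional ``subgroups`` columns (species,
    mode, time of day) yield subset APs.
    """
    spec = spec or BehaviorModelSpec()
    y = pd.Series(np.asarray(y).astype(int), index=components.index)
    groups = pd.Series(np.asarray(groups), index=components.index)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need >= 2 intrusion groups for LOIO CV")

    probs = pd.Series(np.nan, index=components.index)
    fold_ids = pd.Series("", index=components.index, dtype=object)
    ap_per_fold = {}
    audit = []
    for g in uniq:
        test = groups == g
        train = ~test
        audit.append({"fold": g,
                      "train_groups": sorted(set(groups[train])),
                      "test_groups": sorted(set(groups[test]))})
        if y[train].nunique() < 2:
            continue
        if fold_fitter is not None:
            transform, model = fold_fitter(components.index[train])
            p = model.predict_proba(transform(components.index[test]))
        else:
            model = fit_behavior_model(components[train], y[train], spec, seed)
            p = model.predict_proba(components[test])
        probs[test] = p
        fold_ids[test] = str(g)
        if y[test].nunique() == 2:
            ap_per_fold[str(g)] = float(average_precision_score(y[test], p))

    valid = probs.notna()
    ap_pooled = float(average_precision_score(y[valid], probs[valid]))
    result = CVResult(
        probabilities=probs, y=y, folds=fold_ids,
        ap_pooled=ap_pooled, ap_per_fold=ap_per_fold,
        ap_mean_folds=(float(np.mean(list(ap_per_fold.values())))
                       if ap_per_fold else np.nan),
        fold_audit=audit)
    if subgroups is not None:
        for col in subgroups.columns:
            for val in subgroups[col].dropna().unique():
                sub = valid & (subgroups[col] == val)
                if sub.any() and y[sub].nunique() == 2:
                    result.subgroup_ap[f"{col}={val}"] = float(
                        average_precision_score(y[sub], probs[sub]))
    return result


def precision_recall_summary(probs: np.ndarray, labels: np.ndarray) -> dict:
    """Full PR curve, average precision, and the max-F1 operating point.

    The F1-maximizing probability boundary is what downstream localization
    uses as the response-onset clock trigger.
    """
    labels = np.asarray(labels).astype(int)
    probs = np.asarray(probs, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("PR curve needs both classes")
    precision, recall, thresholds = _sk_pr_curve(labels, probs)
    ap = float(average_precision_score(labels, probs))
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = 2 * precision * recall / (precision + recall)
    f1 = np.nan_to_num(f1)
    best = int(np.argmax(f1[:-1])) if len(f1) > 1 else 0
    return {
        "curve": pd.DataFrame({"precision": precision[:-1],
                               "recall": recall[:-1],
                               "threshold": thresholds}),
        "average_precision": ap,
        "max_f1": float(f1[best]),
        "max_f1_threshold": float(thresholds[best]),
    }
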