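"""Segment filtering, feature-importance scoring and dimensionality reduction.

The analysis dataset is segmented into intrusion and control periods.
Before modelling: segments with too few active sensors are dropped, as are
animal-minutes near unrelated vehicles. Features are then scored with four
importance metrics on proximity-labelled data (within 1 km of a concurrent
intrusion vs an equal-sized random control draw), the union of the top-k
features per metric is retained, and a two-stage PCA (within feature class,
then across pooled class scores) collapses them into a compact orthogonal
basis. A per-species k-means clustering of the reduced space provides the
unsupervised behavioral vocabulary used by the system-level detector.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from herdwatch.features import feature_class, feature_columns
from herdwatch.synthetic import IntrusionEvent

logger = logging.getLogger(__name__)


@dataclass
class SegmentData:
    """One intrusion or control period with its animal-minute rows."""

    segment_id: str
    kind: str                      # "intrusion" | "control"
    t_start: float
    t_end: float
    matrix: pd.DataFrame           # feature matrix rows for this period
    intrusion: IntrusionEvent | None = None
    n_active_sensors: int | None = None
    pair_id: str | None = None     # links an intrusion to its control

    @property
    def active_sensors(self) -> int:
        if self.n_active_sensors is not None:
            return self.n_active_sensors
        return self.matrix.index.get_level_values("animal_id").nunique()


def filter_segments(segments: list[SegmentData],
                    min_active_sensors: int = 30,
                    vehicles: list[IntrusionEvent] | None = None,
                    vehicle_dist_m: float = 250.0,
                    vehicle_window_s: float = 20 * 60.0) -> list[SegmentData]:
    """Apply the dataset filters.

    Intrusion periods with fewer than ``min_active_sensors`` active animal
    sensors are dropped (with their paired controls). Animal-minutes
    recorded within ``vehicle_dist_m`` and ``vehicle_window_s`` of an
    unrelated vehicle track are removed row-wise.
    """
    dropped_pairs = set()
    for seg in segments:
        if seg.kind == "intrusion" and seg.active_sensors < min_active_sensors:
            dropped_pairs.add(seg.pair_id or seg.segment_id)
    kept = []
    n_rows_removed = 0
    for seg in segments:
        if (seg.pair_id or seg.segment_id) in dropped_pairs:
            continue
        if vehicles:
            mask = np.zeros(len(seg.matrix), dtype=bool)
            times = seg.matrix.index.get_level_values("time").to_numpy(float)
            xy = seg.matrix[["x", "y"]].to_numpy(float)
            for veh in vehicles:
                t_lo = veh.t_start - vehicle_window_s
                t_hi = veh.t_end + vehicle_window_s
                in_t = (times >= t_lo) & (times <= t_hi)
                if not in_t.any():
                    continue
                t_clamped = np.clip(times[in_t], veh.t_start, veh.t_end)
                vp = veh.position_at(t_clamped)
                d = np.linalg.norm(xy[in_t] - vp, axis=1)
                sub = np.flatnonzero(in_t)
                mask[sub[d < vehicle_dist_m]] = True
            if mask.any():
                n_rows_removed += int(mask.sum())
                seg = SegmentData(seg.segment_id, seg.kind, seg.t_start,
                                  seg.t_end, seg.matrix.loc[~mask],
                                  seg.intrusion, seg.n_active_sensors,
                                  seg.pair_id)
        kept.append(seg)
    if dropped_pairs or n_rows_removed:
        logger.info("filter_segments: dropped %d segment pairs, removed %d "
                    "vehicle-proximal rows", len(dropped_pairs), n_rows_removed)
    if not kept:
        raise ValueError("all segments filtered out")
    return kept


def proximity_labels(segments: list[SegmentData], seed: int = 0,
                     radius_m: float = 1000.0) -> pd.Series:
    """Binary labels for importance scoring.

    Label 1: animal-minutes within ``radius_m`` of the concurrent intruder
    position during intrusion segments. Label 0: an equal-sized seeded
    random draw from control-segment rows. Everything else is NaN
    (unused). Raises if no row falls inside the radius.
    """
    rng = np.random.default_rng(seed)
    ones, ctrl_pool = [], []
    for seg in segments:
        if seg.kind == "intrusion" and seg.intrusion is not None:
            times = seg.matrix.index.get_level_values("time").to_numpy(float)
            live = (times >= seg.intrusion.t_start) & (times <= seg.intrusion.t_end)
            xy = seg.matrix[["x", "y"]].to_numpy(float)
            d = np.full(len(times), np.inf)
            d[live] = np.linalg.norm(
                xy[live] - seg.intrusion.position_at(times[live]), axis=1)
            idx = seg.matrix.index[d < radius_m]
            ones.append(pd.Series(1.0, index=idx))
        elif seg.kind == "control":
            ctrl_pool.append(seg.matrix.index.to_frame(index=False)
                             .assign(_seg=seg.segment_id))
    if not ones or sum(len(s) for s in ones) == 0:
        raise ValueError("no rows within the proximity radius; aborting "
                         "importance labelling")
    pos = pd.concat(ones)
    pool = pd.concat(ctrl_pool, ignore_index=True) if ctrl_pool else None
    if pool is None or len(pool) < len(pos):
        raise ValueError("not enough control rows to match the label-1 set")
    take = rng.choice(len(pool), size=len(pos), replace=False)
    neg_idx = pd.MultiIndex.from_frame(pool.iloc[take][["animal_id", "time"]])
    out = pd.concat([pos, pd.Series(0.0, index=neg_idx)])
    return out


@dataclass
class ImportanceScores:
    """Four importance metrics and their rankings per feature."""

    table: pd.DataFrame            # index feature; mahalanobis, marginality,
                                   # specialization, rf_mda + *_rank columns
    excluded: list = field(default_factory=list)

    METRICS = ("mahalanobis", "marginality", "specialization", "rf_mda")


def importance(X: pd.DataFrame, y: np.ndarray, seed: int = 0,
               n_estimators: int = 100, mda_repeats: int = 3,
               mda_max_rows: int = 2000) -> ImportanceScores:
    """Score every feature column on binary proximity labels.

    * Mahalanobis (univariate): |mu1 - mu0| / pooled sd.
    * Marginality: (mu1 - mu0) / sd0 — standardized mean shift.
    * Specialization: sd1 / sd0 — variance inflation near intrusions.
    * rf_mda: Mean Decrease Accuracy of a random forest — permutation
      importance evaluated on rows held out from the forest fit (the
      analog of out-of-bag permutation importance; in-sample permutation
      scores would reward overfitting).

    Features with sd0 == 0 are excluded with a warning. Rankings: higher
    mahalanobis, |marginality|, |log specialization| and rf_mda rank first;
    ties break on feature name.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("importance needs both label groups")
    X1 = X[y == 1]
    X0 = X[y == 0]
    n1, n0 = len(X1), len(X0)
    mu1, mu0 = X1.mean(), X0.mean()
    sd1 = X1.std(ddof=1)
    sd0 = X0.std(ddof=1)
    pooled = np.sqrt(((n1 - 1) * sd1 ** 2 + (n0 - 1) * sd0 ** 2)
                     / max(n1 + n0 - 2, 1))

    excluded = sd0.index[(sd0 <= 0) | ~np.isfinite(sd0)].tolist()
    if excluded:
        warnings.warn(f"{len(excluded)} features excluded (sd0 == 0)")
    with np.errstate(divide="ignore", invalid="ignore"):
        tab = pd.DataFrame({
            "mahalanobis": (mu1 - mu0).abs() / pooled,
            "marginality": (mu1 - mu0) / sd0,
            "specialization": sd1 / sd0,
        })
    tab.loc[excluded, ["marginality", "specialization"]] = np.nan

    rng = np.random.default_rng(seed)
    Xf = X.fillna(X.mean()).to_numpy(float)
    rows = np.arange(len(X))
    if len(rows) > mda_max_rows:
        rows = rng.choice(rows, mda_max_rows, replace=False)
    rows = rng.permutation(rows)
    half = len(rows) // 2
    fit_rows, eval_rows = rows[:half], rows[half:]
    if len(np.unique(y[fit_rows])) < 2 or len(np.unique(y[eval_rows])) < 2:
        fit_rows = eval_rows = rows
    rf = RandomForestClassifier(n_estimators=n_estimators,
                                random_state=int(rng.integers(2 ** 31)),
                                n_jobs=1)
    rf.fit(Xf[fit_rows], y[fit_rows])
    pi = permutation_importance(rf, Xf[eval_rows], y[eval_rows],
                                n_repeats=mda_repeats,
                                random_state=int(rng.integers(2 ** 31)),
                                n_jobs=1)
    tab["rf_mda"] = pi.importances_mean

    order_keys = {
        "mahalanobis": tab["mahalanobis"],
        "marginality": tab["marginality"].abs(),
        "specialization": np.abs(np.log(tab["specialization"].where(
            tab["specialization"] > 0))),
        "rf_mda": tab["rf_mda"],
    }
    for m, key in order_keys.items():
        df = pd.DataFrame({"key": -key.fillna(-np.inf), "name": key.index})
        tab[f"{m}_rank"] = (df.sort_values(["key", "name"])
                            .assign(r=np.arange(1, len(df) + 1))
                            .loc[tab.index, "r"])
    return ImportanceScores(table=tab, excluded=excluded)


def select_top_union(scores: ImportanceScores, k: int = 125) -> list[str]:
    """Union of the top-k features across all four importance rankings."""
    if k > len(scores.table):
        raise ValueError("k exceeds the number of scored features")
    chosen: set[str] = set()
    for m in ImportanceScores.METRICS:
        top = scores.table.index[scores.table[f"{m}_rank"] <= k]
        chosen.update(top)
    return sorted(chosen)


# ---------------------------------------------------------------------------
# Two-stage PCA
# ---------------------------------------------------------------------------


@dataclass
class PCStack:
    """Per-class PCA followed by a pooled second-stage PCA.

    Stage 1 retains, within every main feature class, the smallest number
    of components reaching ``var_target`` of that class's variance (so the
    pooled retained variance also reaches the target); single-feature
    classes pass through standardized. Stage 2 re-orthogonalizes the
    pooled stage-1 scores; downstream models consume the first
    ``n_components`` stage-2 scores.
    """

    var_target: float
    class_models: dict             # class -> (features, mean, scale, components)
    stage2_mean: np.ndarray
    stage2_components: np.ndarray
    stage2_explained: np.ndarray
    n_stage1: int

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        parts = []
        for cls in sorted(self.class_models):
            feats, mean, scale, comps = self.class_models[cls]
            Z = (matrix[feats].fillna(pd.Series(mean, index=feats))
                 .to_numpy(float) - mean) / scale
            parts.append(Z @ comps.T if comps is not None else Z)
        S = np.hstack(parts)
        S2 = (S - self.stage2_mean) @ self.stage2_components.T
        cols = [f"PC{i + 1}" for i in range(S2.shape[1])]
        return pd.DataFrame(S2, index=matrix.index, columns=cols)


def fit_pc_stack(matrix: pd.DataFrame, selected: list[str],
                 var_target: float = 0.95) -> PCStack:
    """Fit the two-stage PCA on training rows only."""
    classes: dict[str, list[str]] = {}
    for f in selected:
        classes.setdefault(feature_class(f), []).append(f)
    if len(classes) < 2:
        raise ValueError("selected features must span at least two classes")
    class_models = {}
    n_stage1 = 0
    parts = []
    for cls in sorted(classes):
        feats = sorted(classes[cls])
        Xc = matrix[feats].astype(float)
        mean = Xc.mean().to_numpy()
        Xc = Xc.fillna(pd.Series(mean, index=feats))
        scale = Xc.std(ddof=0).replace(0.0, 1.0).to_numpy()
        Z = (Xc.to_numpy() - mean) / scale
        if len(feats) == 1:
            class_models[cls] = (feats, mean, scale, None)
            parts.append(Z)
            n_stage1 += 1
            continue
        pca = PCA()
        scores = pca.fit_transform(Z)
        cum = np.cumsum(pca.explained_variance_ratio_)
        keep = int(np.searchsorted(cum, var_target)) + 1
        keep = min(keep, scores.shape[1])
        comps = pca.components_[:keep]
        class_models[cls] = (feats, mean, scale, comps)
        parts.append(scores[:, :keep])
        n_stage1 += keep
    S = np.hstack(parts)
    stage2 = PCA()
    stage2.fit(S)
    return PCStack(var_target=var_target, class_models=class_models,
                   stage2_mean=S.mean(axis=0),
                   stage2_components=stage2.components_,
                   stage2_explained=stage2.explained_variance_ratio_,
                   n_stage1=n_stage1)


# ---------------------------------------------------------------------------
# Unsupervised clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    models: dict                   # species -> fitted KMeans
    n_clusters: int

    def assign(self, scores: pd.DataFrame, species: pd.Series) -> pd.Series:
        out = pd.Series(-1, index=scores.index, dtype=int)
        offset = 0
        for sp in sorted(self.models):
            km = self.models[sp]
            mask = (species == sp).to_numpy()
            if mask.any():
                out.iloc[mask] = km.predict(scores.to_numpy(float)[mask]) + offset
            offset += km.n_clusters
        return out


def unsupervised_clusters(scores: pd.DataFrame, species: pd.Series,
                          n_clusters: int = 25, seed: int = 0) -> ClusterModel:
    """Per-species k-means over the reduced feature space.

    Cluster labels are offset per species so they are globally unique.
    ``n_clusters`` is capped at the species' row count.
    """
    models = {}
    for sp in sorted(species.unique()):
        X = scores.to_numpy(float)[(species == sp).to_numpy()]
        k = min(n_clusters, len(X))
        km = KMeans(n_clusters=k, n_init=5, random_state=seed)
        km.fit(X)
        models[sp] = km
    return ClusterModel(models=models, n_clusters=n_clusters)
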