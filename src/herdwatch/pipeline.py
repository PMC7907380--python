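"""End-to-end orchestration: simulate -> preprocess -> features -> classify
-> detect -> localize -> evaluate.

Every run is driven by one :class:`PipelineConfig` and one seed; the seed
fans out deterministically to per-stage generators so stages are
independently reproducible. Each staged intrusion is paired with a control
period of the same clock window on a nearby day without intrusion (here:
an independently simulated world, the synthetic analog of "the same herd a
day or two earlier"). Cross-validation leaves one intrusion (with its
paired control) out at a time, and all data-dependent fitting —
standardization references, discretization, importance selection, the PC
stack and the SVM — happens inside the training fold.

When the response model is disabled (null calibration) there are no true
response labels; the behavior classifier then trains against proximity
pseudo-labels (within 1 km of the concurrent intruder), which carry no
behavioral signal, so its average precision collapses to prevalence and
detection accuracy to chance — the property the calibration tests assert.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from herdwatch import localize as loc
from herdwatch.classify import (BehaviorModel, BehaviorModelSpec,
                                build_training_set, fit_behavior_model,
                                precision_recall_summary, smooth_probabilities)
from herdwatch.detect import (BLOCK_S, cluster_odds_table,
                              cross_validate_detector, fit_detector,
                              make_segments, order_features, summarize_block,
                              summarize_segment)
from herdwatch.features import (FeatureConfig, build_feature_matrix,
                                build_reference, feature_columns,
                                fit_discretizer, standardize_columns,
                                window_features)
from herdwatch.preprocess import (EmptyTrackError, PreprocessConfig,
                                  preprocess_track)
from herdwatch.selection import (fit_pc_stack, importance, select_top_union,
                                 unsupervised_clusters)
from herdwatch.synthetic import (SimulationConfig, apply_response_model,
                                 degrade_to_sensor, generate_landscape,
                                 make_intrusion, simulate_herds)

logger = logging.getLogger(__name__)

META_ROW_COLS = ("label", "intensity", "dist_to_intruder", "intrusion_present",
                 "segment_id", "pair_id", "kind", "mode")


def stage_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage child seed below 2**31."""
    h = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    seed: int = 0
    # world
    landscape_extent_m: float = 3000.0
    landscape_cell_m: float = 10.0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    pre: PreprocessConfig = field(default_factory=PreprocessConfig)
    feat: FeatureConfig = field(default_factory=FeatureConfig)
    n_intrusions: int = 10
    segment_duration_s: float = 2 * 3600.0
    warmup_s: float = 1800.0
    response_enabled: bool = True
    route_through_herd: bool = True
    fast_settings: tuple = (120.0, 600.0)   # alternated over animals
    # selection
    reference_kinds: tuple = ("area", "timeofday_5wk", "area_timeofday_5wk",
                              "individual_timeofday_5wk")
    top_k: int = 25
    var_target: float = 0.95
    n_clusters: int = 25
    importance_kwargs: dict = field(default_factory=lambda: dict(
        n_estimators=50, mda_repeats=1, mda_max_rows=800))
    # behavior classifier
    behavior: BehaviorModelSpec = field(default_factory=BehaviorModelSpec)
    min_training_rows: int = 20
    max_training_rows_per_model: int = 1500   # seeded stratified cap (SVM cost)
    # detection
    detector_features: int = 7
    detector_interactions: bool = False
    detector_repeats: int = 25
    min_active_sensors: int = 0             # field default is 30; demo worlds
                                            # are smaller, so off by default
    # localization
    surface_cell_m: float = 50.0
    surface_cadence_s: float = 300.0
    n_select_surfaces: int = 10
    min_heading_step_m: float = 2.0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        for key, sub in (("sim", SimulationConfig), ("pre", PreprocessConfig),
                         ("feat", FeatureConfig), ("behavior", BehaviorModelSpec)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class SimulatedSegment:
    segment_id: str
    pair_id: str
    kind: str                      # "intrusion" | "control"
    t_start: float
    t_end: float
    true_tracks: list
    regular_tracks: list
    intrusion: object | None = None


@dataclass
class PipelineResult:
    config: PipelineConfig
    landscape: object = None
    segments: list = None
    matrix: pd.DataFrame = None
    behavior_cv: dict = None
    detection: dict = None
    localization: dict = None
    manifest: dict = None


# ---------------------------------------------------------------------------
# Stage 1: simulate the paired dataset
# ---------------------------------------------------------------------------


def simulate_dataset(cfg: PipelineConfig):
    """Landscape plus paired intrusion/control segments with sensor tracks."""
    t0 = _time.time()
    landscape = generate_landscape(stage_seed(cfg.seed, "landscape"),
                                   cfg.landscape_extent_m, cfg.landscape_cell_m)
    # staged-intrusion calendar: one intrusion every other day, alternating
    # morning/afternoon starts and foot/vehicle modes
    windows = []
    for i in range(cfg.n_intrusions):
        day = 2 * i
        hour = 8.0 if i % 2 == 0 else 15.0
        t_start = day * 86400.0 + hour * 3600.0
        windows.append((f"intr_{i:02d}", t_start,
                        t_start + cfg.segment_duration_s))
    pairs = make_segments(windows, seed=stage_seed(cfg.seed, "pairing"))

    segments: list[SimulatedSegment] = []
    for i, pair in enumerate(pairs):
        iid = pair["intrusion_id"]
        for kind in ("intrusion", "control"):
            t_start = pair["t_start"] if kind == "intrusion" else pair["control_t_start"]
            seed_k = stage_seed(cfg.seed, f"world:{iid}:{kind}")
            sim_t0 = t_start - cfg.warmup_s
            duration = cfg.warmup_s + cfg.segment_duration_s
            tracks = simulate_herds(landscape, cfg.sim, duration,
                                    seed=seed_k, t_start=sim_t0)
            intrusion = None
            if kind == "intrusion":
                rng = np.random.default_rng(stage_seed(cfg.seed, f"route:{iid}"))
                waypoint = None
                if cfg.route_through_herd and tracks:
                    a = int(rng.integers(len(tracks)))
                    waypoint = tracks[a].positions[int(cfg.warmup_s)]
                intrusion = make_intrusion(
                    landscape, stage_seed(cfg.seed, f"intruder:{iid}"),
                    mode=("foot" if i % 2 == 0 else "vehicle"),
                    t_start=t_start, duration_s=cfg.segment_duration_s,
                    intrusion_id=iid, waypoint=waypoint)
                if cfg.response_enabled:
                    tracks = apply_response_model(
                        tracks, intrusion, cfg.sim, landscape,
                        seed=stage_seed(cfg.seed, f"response:{iid}"))
            regular = []
            for a, tr in enumerate(tracks):
                fast = cfg.fast_settings[a % len(cfg.fast_settings)]
                raw = degrade_to_sensor(
                    tr, cfg.sim, seed=stage_seed(cfg.seed, f"sensor:{iid}:{kind}:{a}"),
                    fast_interval_s=fast)
                try:
                    regular.append(preprocess_track(raw, landscape.bbox, cfg.pre))
                except (EmptyTrackError, ValueError) as exc:
                    logger.info("dropping %s in %s/%s: %s", tr.animal_id,
                                iid, kind, exc)
            segments.append(SimulatedSegment(
                segment_id=f"{iid}_{kind}", pair_id=iid, kind=kind,
                t_start=t_start, t_end=t_start + cfg.segment_duration_s,
                true_tracks=tracks, regular_tracks=regular,
                intrusion=intrusion))
    logger.info("simulate_dataset: %d segments in %.1f s",
                len(segments), _time.time() - t0)
    return landscape, segments


# ---------------------------------------------------------------------------
# Stage 2: base features + truth metadata per row
# ---------------------------------------------------------------------------


def build_segment_matrix(seg: SimulatedSegment, landscape,
                         feat_cfg: FeatureConfig) -> pd.DataFrame:
    m = build_feature_matrix(seg.regular_tracks, landscape, feat_cfg)
    times = m.index.get_level_values("time").to_numpy(float)
    animals = m.index.get_level_values("animal_id")
    truth = {tr.animal_id: tr for tr in seg.true_tracks}
    label = np.zeros(len(m), dtype=int)
    intensity = np.zeros(len(m), dtype=int)
    for a, tr in truth.items():
        sel = (animals == a).to_numpy() if hasattr(animals == a, "to_numpy") \
            else np.asarray(animals == a)
        idx = np.clip((times[sel] - tr.t0).astype(int), 0, tr.n - 1)
        label[sel] = tr.labels[idx]
        intensity[sel] = tr.intensity[idx]
    dist = np.full(len(m), np.inf)
    if seg.intrusion is not None:
        live = (times >= seg.intrusion.t_start) & (times <= seg.intrusion.t_end)
        xy = m[["x", "y"]].to_numpy(float)
        dist[live] = np.linalg.norm(
            xy[live] - seg.intrusion.position_at(times[live]), axis=1)
    m["label"] = label
    m["intensity"] = intensity
    m["dist_to_intruder"] = dist
    m["intrusion_present"] = seg.intrusion is not None
    m["segment_id"] = seg.segment_id
    m["pair_id"] = seg.pair_id
    m["kind"] = seg.kind
    m["mode"] = seg.intrusion.mode if seg.intrusion is not None else ""
    # analysis rows: within the segment window (warmup rows only feed windows)
    m["analysis"] = (times >= seg.t_start) & (times < seg.t_end)
    return m


def build_dataset_matrix(segments, landscape, feat_cfg) -> pd.DataFrame:
    parts = [build_segment_matrix(s, landscape, feat_cfg) for s in segments]
    out = pd.concat(parts)
    out.index = pd.MultiIndex.from_arrays(
        [out["segment_id"].to_numpy() + "|" + out.index.get_level_values("animal_id").astype(str),
         out.index.get_level_values("time")],
        names=["animal_id", "time"])
    return out


# ---------------------------------------------------------------------------
# Stage 3: behavior classification (leakage-safe fold fitting)
# ---------------------------------------------------------------------------


class BehaviorStage:
    """Everything between base features and response probabilities.

    ``fit`` consumes training rows only: reference sets are built on
    undisturbed training rows, the discretizer on all training rows,
    proximity-labelled importance selects the top-k union, the two-stage
    PCA compresses it, and per-species SVMs are trained on the
    protocol-constructed training set. ``predict`` maps any rows through
    the stored transforms to smoothed response probabilities.
    """

    def __init__(self, cfg: PipelineConfig, landscape):
        self.cfg = cfg
        self.landscape = landscape
        self.refs = []
        self.discretizer = None
        self.selected = None
        self.pcstack = None
        self.models: dict[str, BehaviorModel] = {}
        self.pooled_model: BehaviorModel | None = None
        self.pseudo_labels = False

    # ---- transform chain -------------------------------------------------
    def _pre_transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        cfg = self.cfg
        z_parts = [standardize_columns(matrix, ref,
                                       divide_by=cfg.feat.divide_by,
                                       landscape=self.landscape)
                   for ref in self.refs]
        m = pd.concat([matrix] + z_parts, axis=1)
        win_cols = [f"{f}__z_species" for f in cfg.feat.window_subset
                    if f"{f}__z_species" in m.columns]
        return window_features(m, win_cols)

    def _transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return self.discretizer.transform(self._pre_transform(matrix))

    @staticmethod
    def _feature_cols(matrix: pd.DataFrame) -> list[str]:
        skip = set(META_ROW_COLS) | {"analysis"}
        return [c for c in feature_columns(matrix) if c not in skip]

    def _proximity_y(self, rows: pd.DataFrame, seed: int) -> pd.Series:
        dist = rows["dist_to_intruder"]
        pos = (rows["kind"] == "intrusion") & (dist < 1000.0)
        ctrl = rows.index[rows["kind"] == "control"]
        n_pos = int(pos.sum())
        if n_pos == 0 or len(ctrl) < n_pos:
            raise ValueError("cannot build proximity labels")
        rng = np.random.default_rng(seed)
        neg = ctrl[rng.choice(len(ctrl), n_pos, replace=False)]
        y = pd.Series(np.nan, index=rows.index)
        y[pos] = 1.0
        y[neg] = 0.0
        return y

    # ---- fitting ---------------------------------------------------------
    def fit(self, train: pd.DataFrame, seed: int) -> "BehaviorStage":
        cfg = self.cfg
        undisturbed = train[(train["label"] == 0)
                            & (train["dist_to_intruder"] > 1000.0)]
        base_feats = list(cfg.feat.standardized_subset)
        self.refs = [build_reference(undisturbed, "species",
                                     features=self._base_present(train))]
        for kind in cfg.reference_kinds:
            self.refs.append(build_reference(
                undisturbed, kind, features=base_feats,
                landscape=self.landscape,
                area_cell_m=cfg.feat.area_cell_m))
        t_pre = self._pre_transform(train)
        self.discretizer = fit_discretizer(
            t_pre, n_bins=cfg.feat.n_bins, log_features=cfg.feat.log_features,
            truncate_q=cfg.feat.truncate_q,
            features=self._feature_cols(t_pre))
        t_train = self.discretizer.transform(t_pre)

        ord_cols = [c for c in t_train.columns if c.endswith("__ord")]
        y_prox = self._proximity_y(t_train, stage_seed(seed, "prox"))
        lab = y_prox.dropna()
        scores = importance(t_train.loc[lab.index, ord_cols],
                            lab.to_numpy(), seed=stage_seed(seed, "imp"),
                            **cfg.importance_kwargs)
        k = min(cfg.top_k, len(ord_cols))
        self.selected = select_top_union(scores, k=k)
        self.importance_scores = scores
        self.pcstack = fit_pc_stack(t_train, self.selected, cfg.var_target)

        # SVM training rows: intrusion-present periods only
        live = t_train[t_train["intrusion_present"].astype(bool)
                       & t_train["analysis"].astype(bool)]
        self.pseudo_labels = int((live["label"] > 0).sum()) < cfg.min_training_rows
        if self.pseudo_labels:
            yp = self._proximity_y(t_train, stage_seed(seed, "pseudo"))
            pseudo = t_train.loc[yp.dropna().index].copy()
            pseudo["label"] = yp.dropna().astype(int)
            pseudo["intensity"] = np.where(pseudo["label"] > 0, 3, 0)
            pseudo["intrusion_present"] = True
            rows = build_training_set(pseudo, seed=stage_seed(seed, "train"))
        else:
            rows = build_training_set(live, seed=stage_seed(seed, "train"))
        rows = self._cap_rows(rows, stage_seed(seed, "cap"))
        comp = self.pcstack.transform(rows)
        y = (rows["label"] > 0).astype(int).to_numpy()
        if cfg.behavior.per_species:
            for sp in sorted(rows["species"].unique()):
                mask = (rows["species"] == sp).to_numpy()
                if len(np.unique(y[mask])) == 2:
                    self.models[sp] = fit_behavior_model(
                        comp[mask], y[mask], cfg.behavior,
                        seed=stage_seed(seed, f"svm:{sp}"))
        if len(np.unique(y)) == 2:
            self.pooled_model = fit_behavior_model(
                comp, y, cfg.behavior, seed=stage_seed(seed, "svm"))
        if not self.models and self.pooled_model is None:
            raise ValueError("behavior stage: no trainable model")
        return self

    def _cap_rows(self, rows: pd.DataFrame, seed: int) -> pd.DataFrame:
        """Stratified per-species cap on SVM training rows (kernel cost)."""
        cap = self.cfg.max_training_rows_per_model
        rng = np.random.default_rng(seed)
        keep = []
        for sp in rows["species"].unique():
            sub = rows[rows["species"] == sp]
            if len(sub) <= cap:
                keep.append(sub)
                continue
            pos = sub[sub["label"] > 0]
            neg = sub[sub["label"] == 0]
            n_pos = min(len(pos), cap // 2)
            n_neg = cap - n_pos
            if len(pos):
                keep.append(pos.iloc[np.sort(rng.choice(
                    len(pos), min(n_pos, len(pos)), replace=False))])
            keep.append(neg.iloc[np.sort(rng.choice(
                len(neg), min(n_neg, len(neg)), replace=False))])
        return pd.concat(keep)

    def _base_present(self, matrix) -> list[str]:
        skip = set(META_ROW_COLS) | {"analysis"}
        return [c for c in feature_columns(matrix)
                if c not in skip and "__" not in c]

    # ---- prediction ------------------------------------------------------
    def predict(self, rows: pd.DataFrame) -> pd.DataFrame:
        """Raw and window-smoothed response probabilities per animal-minute."""
        t_rows = self._transform(rows)
        comp = self.pcstack.transform(t_rows)
        p = pd.Series(np.nan, index=rows.index)
        sp_col = rows["species"]
        for sp, model in self.models.items():
            mask = (sp_col == sp).to_numpy()
            if mask.any():
                p[mask] = model.predict_proba(comp[mask])
        missing = p.isna()
        if missing.any() and self.pooled_model is not None:
            p[missing.to_numpy()] = self.pooled_model.predict_proba(
                comp[missing.to_numpy()])
        smoothed = smooth_probabilities(
            p, window_min=self.cfg.behavior.window_min,
            quantile=self.cfg.behavior.window_quantile,
            align=self.cfg.behavior.window_align)
        return pd.DataFrame({"raw": p, "smoothed": smoothed})


def behavior_loio(matrix: pd.DataFrame, cfg: PipelineConfig, landscape,
                  seed: int) -> dict:
    """Leave-one-intrusion-out run of the behavior stage.

    Returns pooled out-of-fold smoothed probabilities, average precision
    (pooled and per fold), the fold audit and the label source used.
    """
    pairs = sorted(matrix["pair_id"].unique())
    if len(pairs) < 2:
        raise ValueError("need >= 2 intrusion pairs")
    probs = pd.Series(np.nan, index=matrix.index)
    probs_raw = pd.Series(np.nan, index=matrix.index)
    audit = []
    pseudo_any = False
    for pid in pairs:
        test = (matrix["pair_id"] == pid).to_numpy()
        train = matrix[~test]
        stage = BehaviorStage(cfg, landscape)
        stage.fit(train, seed=stage_seed(seed, f"fold:{pid}"))
        pseudo_any |= stage.pseudo_labels
        pred = stage.predict(matrix[test])
        probs[test] = pred["smoothed"].to_numpy()
        probs_raw[test] = pred["raw"].to_numpy()
        ref_checksum = hashlib.sha256(
            stage.refs[0].stats.to_csv().encode()).hexdigest()[:12]
        audit.append({"fold": pid,
                      "train_pairs": sorted(set(train["pair_id"])),
                      "n_train": int((~test).sum()),
                      "n_test": int(test.sum()),
                      "ref_checksum": ref_checksum,
                      "pseudo_labels": stage.pseudo_labels})
        logger.info("behavior_loio: fold %s done", pid)

    from sklearn.metrics import average_precision_score
    eval_rows = matrix["analysis"].astype(bool) & (matrix["kind"] == "intrusion")
    if pseudo_any:
        y_eval = ((matrix["dist_to_intruder"] < 1000.0) & eval_rows).astype(int)
    else:
        y_eval = (matrix["label"] > 0).astype(int)
    valid = eval_rows & probs.notna()
    ap_pooled = float(average_precision_score(y_eval[valid], probs[valid])) \
        if y_eval[valid].nunique() == 2 else np.nan
    per_fold = {}
    for pid in pairs:
        sel = valid & (matrix["pair_id"] == pid)
        if sel.any() and y_eval[sel].nunique() == 2:
            per_fold[pid] = float(average_precision_score(y_eval[sel], probs[sel]))
    prevalence = float(y_eval[valid].mean()) if valid.any() else np.nan
    subgroup_ap = {}
    tods = pd.Series([("morning" if (t / 3600.0) % 24 < 11 else
                       "midday" if (t / 3600.0) % 24 < 15 else "afternoon")
                      for t in matrix.index.get_level_values("time")],
                     index=matrix.index)
    for col, values in (("species", matrix["species"]),
                        ("mode", matrix["mode"]), ("tod", tods)):
        for val in values[valid].unique():
            sel = valid & (values == val) & (val != "")
            if sel.any() and y_eval[sel].nunique() == 2:
                subgroup_ap[f"{col}={val}"] = float(
                    average_precision_score(y_eval[sel], probs[sel]))
    return {"probs": probs, "probs_raw": probs_raw, "y": y_eval, "valid": valid,
            "subgroup_ap": subgroup_ap,
            "ap_pooled": ap_pooled, "ap_per_fold": per_fold,
            "ap_mean_folds": (float(np.mean(list(per_fold.values())))
                              if per_fold else np.nan),
            "prevalence": prevalence, "audit": audit,
            "pseudo_labels": pseudo_any}


# ---------------------------------------------------------------------------
# Stage 4: detection
# ---------------------------------------------------------------------------


def detection_stage(matrix: pd.DataFrame, probs: pd.Series,
                    cfg: PipelineConfig, landscape, seed: int) -> dict:
    """15-min summary features per segment, ordering, logistic CV.

    The unsupervised cluster vocabulary is fit once on all rows (k-means
    sees no labels), but each segment's cluster-association log-odds are
    computed leaving that segment's pair out — otherwise a segment's own
    rows would vote for their clusters' intrusion association and inflate
    the feature under the null.
    """
    stage = BehaviorStage(cfg, landscape)
    stage.fit(matrix, seed=stage_seed(seed, "clusters"))
    comp = stage.pcstack.transform(stage._transform(matrix))
    cmodel = unsupervised_clusters(comp, matrix["species"],
                                   n_clusters=cfg.n_clusters,
                                   seed=stage_seed(seed, "kmeans"))
    clusters = cmodel.assign(comp, matrix["species"])
    ana = matrix["analysis"].astype(bool)
    odds_by_pair = {}
    for pid in matrix["pair_id"].unique():
        keep = ana & (matrix["pair_id"] != pid)
        odds_by_pair[pid] = cluster_odds_table(
            clusters[keep], (matrix["kind"] == "intrusion")[keep])

    rows_sum = []
    seg_ids, y = [], []
    times_all = matrix.index.get_level_values("time").to_numpy(float)
    for sid in sorted(matrix["segment_id"].unique()):
        sel = (matrix["segment_id"] == sid).to_numpy()
        sub = matrix[sel]
        sub_probs = probs[sel]
        sub_clusters = clusters[sel]
        odds = odds_by_pair[sub["pair_id"].iloc[0]]
        t = times_all[sel]
        ana = sub["analysis"].to_numpy(bool)
        t0 = float(t[ana].min())
        t1 = float(t[ana].max()) + 60.0
        blocks = []
        b0 = t0
        while b0 < t1:
            in_b = (t >= b0) & (t < b0 + BLOCK_S)
            if in_b.sum() >= 2:
                bsub = sub[in_b]
                g = bsub.groupby(level="animal_id", sort=True)
                pa = sub_probs[in_b].groupby(level="animal_id").mean()
                pos = g[["x", "y"]].mean()
                lo = sub_clusters[in_b].groupby(level="animal_id") \
                    .agg(lambda v: odds.reindex(v).mean())
                blocks.append(summarize_block(pa.to_numpy(),
                                              pos.to_numpy(),
                                              lo.to_numpy()))
            b0 += BLOCK_S
        if not blocks:
            continue
        rows_sum.append(summarize_segment(pd.DataFrame(blocks)))
        seg_ids.append(sid)
        y.append(1 if sub["kind"].iloc[0] == "intrusion" else 0)

    summaries = pd.DataFrame(rows_sum, index=seg_ids)
    y = np.asarray(y)
    ordered = order_features(summaries, y)
    n_feat = min(cfg.detector_features, len(ordered))
    model = fit_detector(summaries, y, n_features=n_feat,
                         interactions=cfg.detector_interactions,
                         ordered=ordered)
    cv = cross_validate_detector(summaries, y, n_features=n_feat,
                                 interactions=cfg.detector_interactions,
                                 n_repeats=cfg.detector_repeats,
                                 seed=stage_seed(seed, "cv"))
    detected = model.predict(summaries)
    return {"summaries": summaries, "y": y, "segment_ids": seg_ids,
            "ordered": ordered, "model": model, "cv": cv,
            "detected_segments": [sid for sid, d, yy in
                                  zip(seg_ids, detected, y) if d and yy],
            "cluster_odds_by_pair": odds_by_pair}


# ---------------------------------------------------------------------------
# Stage 5: localization
# ---------------------------------------------------------------------------


def _headings(matrix: pd.DataFrame, min_step_m: float) -> pd.Series:
    """Per-row movement direction from consecutive positions (NaN if still)."""
    out = pd.Series(np.nan, index=matrix.index)
    for _, g in matrix.groupby(level="animal_id", sort=False):
        xy = g[["x", "y"]].to_numpy(float)
        d = np.diff(xy, axis=0)
        ln = np.linalg.norm(d, axis=1)
        h = np.full(len(g), np.nan)
        ok = ln > min_step_m
        h[1:][ok] = np.arctan2(d[ok, 1], d[ok, 0])
        out[g.index] = h
    return out


def localization_stage(matrix: pd.DataFrame, probs: pd.Series,
                       probs_raw: pd.Series, segments,
                       cfg: PipelineConfig, landscape, boundary: float,
                       seed: int) -> dict:
    """Fit geometry from detected intrusions, emit and score surfaces.

    The t_s clock starts where the *raw* probability series first crosses
    the max-F1 boundary (the smoothed running-max series would lead the
    true onset by up to the smoothing half-window); the smoothed series
    supplies p_j for the odds surfaces.
    """
    rng = np.random.default_rng(stage_seed(seed, "null"))
    headings = _headings(matrix, cfg.min_heading_step_m)
    times = matrix.index.get_level_values("time").to_numpy(float)

    # response onsets per animal-segment: first minute above the boundary
    onset = pd.Series(np.nan, index=matrix.index)
    for _, g in matrix.groupby(level="animal_id", sort=False):
        p = probs_raw[g.index].to_numpy(float)
        above = np.flatnonzero(p >= boundary)
        if len(above):
            t_on = g.index.get_level_values("time")[above[0]]
            onset[g.index] = t_on
    ts_min = (times - onset.to_numpy(float)) / 60.0
    responding = np.isfinite(ts_min) & (ts_min >= 0)

    seg_by_id = {s.segment_id: s for s in segments}
    obs_rows = []
    for sid, s in seg_by_id.items():
        if s.intrusion is None:
            continue
        sel = ((matrix["segment_id"] == sid).to_numpy() & responding
               & matrix["analysis"].to_numpy(bool)
               & np.isfinite(headings.to_numpy(float)))
        if not sel.any():
            continue
        xy = matrix.loc[sel, ["x", "y"]].to_numpy(float)
        ip = s.intrusion.position_at(times[sel])
        d = xy - ip
        dist = np.linalg.norm(d, axis=1)
        theta = np.arctan2(d[:, 1], d[:, 0])
        rel = np.angle(np.exp(1j * (theta - headings.to_numpy(float)[sel])))
        for dd, rr, tt in zip(dist, rel, ts_min[sel]):
            if dd > 0:
                obs_rows.append({"distance_m": dd, "rel_angle": rr,
                                 "ts_min": tt, "response": True})
    # null observations from control segments against random intruder spots
    ctrl = (matrix["kind"] == "control").to_numpy() \
        & matrix["analysis"].to_numpy(bool) \
        & np.isfinite(headings.to_numpy(float))
    ctrl_idx = np.flatnonzero(ctrl)
    if len(ctrl_idx) > 2000:
        ctrl_idx = rng.choice(ctrl_idx, 2000, replace=False)
    null_obs = loc.make_null_observations(
        matrix.iloc[ctrl_idx][["x", "y"]].to_numpy(float),
        headings.to_numpy(float)[ctrl_idx], landscape.bbox, rng,
        n_random_intruders=10)
    observations = pd.concat([pd.DataFrame(obs_rows), null_obs],
                             ignore_index=True)
    params = loc.fit_geometry(observations)

    surfaces_by_intrusion: dict[str, list] = {}
    truths: dict[str, object] = {}
    for sid, s in seg_by_id.items():
        if s.intrusion is None:
            continue
        sel_seg = (matrix["segment_id"] == sid).to_numpy()
        surfaces = []
        t_cursor = s.t_start + cfg.surface_cadence_s
        while t_cursor < s.t_end:
            at = sel_seg & (np.abs(times - (np.round(t_cursor / 60) * 60)) < 1)
            h = headings.to_numpy(float)[at]
            ok = np.isfinite(h)
            if ok.sum() >= 1:
                snap = loc.SentinelSnapshot(
                    positions=matrix.loc[at, ["x", "y"]].to_numpy(float)[ok],
                    headings=h[ok],
                    probs=np.clip(probs[at].to_numpy(float)[ok], 0, 1),
                    ts_min=np.nan_to_num(np.clip(ts_min[at][ok], 0,
                                                 params.ts_max_min)),
                    time=t_cursor)
                surfaces.append(loc.probability_surface(
                    snap, params, landscape.bbox, cfg.surface_cell_m))
            t_cursor += cfg.surface_cadence_s
        if surfaces:
            surfaces_by_intrusion[sid] = surfaces
            truths[sid] = s.intrusion.position_at
    evaluation = loc.evaluate_localization(surfaces_by_intrusion, truths,
                                           n_select=cfg.n_select_surfaces)
    return {"params": params, "surfaces": surfaces_by_intrusion,
            "evaluation": evaluation, "n_observations": len(observations)}


# ---------------------------------------------------------------------------
# run_pipeline
# ---------------------------------------------------------------------------

STAGES = ("simulate", "features", "classify", "detect", "localize")


def run_pipeline(cfg: PipelineConfig, out_dir=None,
                 until: str = "localize") -> PipelineResult:
    """Execute the pipeline up to (and including) ``until``.

    Writes stage artifacts and a run manifest under ``out_dir`` when
    given; returns everything in memory either way.
    """
    if until not in STAGES:
        raise ValueError(f"until must be one of {STAGES}")
    horizon = STAGES.index(until)
    result = PipelineResult(config=cfg)
    manifest = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                "stages": {}, "artifacts": {}, "metrics": {}}
    t_all = _time.time()

    landscape, segments = simulate_dataset(cfg)
    result.landscape = landscape
    result.segments = segments
    manifest["stages"]["simulate"] = {
        "n_segments": len(segments),
        "n_tracks": int(sum(len(s.regular_tracks) for s in segments))}

    if horizon >= 1:
        matrix = build_dataset_matrix(segments, landscape, cfg.feat)
        result.matrix = matrix
        manifest["stages"]["features"] = {
            "n_rows": int(len(matrix)),
            "n_feature_columns": len(feature_columns(matrix)) - len(META_ROW_COLS) - 1}

    if horizon >= 2:
        bcv = behavior_loio(matrix, cfg, landscape,
                            seed=stage_seed(cfg.seed, "behavior"))
        result.behavior_cv = bcv
        manifest["metrics"]["behavior_ap_pooled"] = bcv["ap_pooled"]
        manifest["metrics"]["behavior_prevalence"] = bcv["prevalence"]
        manifest["stages"]["classify"] = {"pseudo_labels": bcv["pseudo_labels"]}

    if horizon >= 3:
        det = detection_stage(matrix, result.behavior_cv["probs"], cfg,
                              landscape, seed=stage_seed(cfg.seed, "detect"))
        result.detection = det
        manifest["metrics"].update(det["cv"].summary)

    if horizon >= 4:
        valid = result.behavior_cv["valid"]
        pr = precision_recall_summary(
            result.behavior_cv["probs_raw"][valid].to_numpy(),
            result.behavior_cv["y"][valid].to_numpy()) \
            if result.behavior_cv["y"][valid].nunique() == 2 else None
        boundary = pr["max_f1_threshold"] if pr else 0.5
        try:
            locr = localization_stage(matrix, result.behavior_cv["probs"],
                                      result.behavior_cv["probs_raw"],
                                      segments, cfg, landscape, boundary,
                                      seed=stage_seed(cfg.seed, "localize"))
            result.localization = locr
            ev = locr["evaluation"]
            for k, v in ev.items():
                if isinstance(v, float):
                    manifest["metrics"][f"localization_{k}"] = v
        except ValueError as exc:
            logger.warning("localization skipped: %s", exc)
            manifest["stages"]["localize"] = {"skipped": str(exc)}

    manifest["runtime_s"] = round(_time.time() - t_all, 1)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_artifacts(result, manifest, out)
    result.manifest = manifest
    return result


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_artifacts(result: PipelineResult, manifest: dict, out: Path) -> None:
    from herdwatch.io import landscape_to_tiff, tracks_to_csv
    cfgp = out / "config.yaml"
    result.config.to_yaml(cfgp)
    landscape_to_tiff(result.landscape, out / "landscape.tiff")
    if result.matrix is not None:
        # analysis rows only; full matrices are bulky scratch data
        result.matrix[result.matrix["analysis"]].head(50000).to_csv(
            out / "feature_matrix_sample.csv")
    if result.detection is not None:
        result.detection["summaries"].to_csv(out / "segment_summaries.csv")
        result.detection["ordered"].to_csv(out / "feature_order.csv",
                                           index=False)
        result.detection["cv"].confusion.to_csv(out / "confusion.csv")
    if result.localization is not None:
        tab = result.localization["evaluation"].get("per_intrusion")
        if tab is not None and len(tab):
            tab.to_csv(out / "localization_errors.csv", index=False)
    for p in out.iterdir():
        if p.is_file():
            manifest["artifacts"][p.name] = _digest(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))


# ---------------------------------------------------------------------------
# Optional field-data adapter
# ---------------------------------------------------------------------------

FIELD_SCHEMA = {
    "animals.csv": ["animal_id", "species", "time", "x", "y"],
    "odba.csv": ["animal_id", "window_start", "mean", "max", "variance"],
    "intrusions.csv": ["intrusion_id", "mode", "group_size", "time", "x", "y"],
}


def load_field_data(path):
    """Adapter for a user-supplied download of the deposited field data.

    Maps the external CSV schema onto internal types and reports unmapped
    columns; never touched by the synthetic pipeline or the tests.
    """
    from herdwatch.synthetic import IntrusionEvent, RawSensorTrack
    root = Path(path)
    if not root.exists():
        raise FileNotFoundError(f"field data directory not found: {root}")
    report = {}
    out = {"tracks": [], "intrusions": []}
    for fname, cols in FIELD_SCHEMA.items():
        fp = root / fname
        if not fp.exists():
            report[fname] = "missing"
            continue
        df = pd.read_csv(fp)
        missing = [c for c in cols if c not in df.columns]
        extra = [c for c in df.columns if c not in cols]
        report[fname] = {"missing_columns": missing, "unmapped_columns": extra}
        if missing:
            raise ValueError(f"{fname}: missing columns {missing}")
    animals = pd.read_csv(root / "animals.csv", parse_dates=["time"])
    odba = (pd.read_csv(root / "odba.csv")
            if (root / "odba.csv").exists() else None)
    for aid, g in animals.groupby("animal_id"):
        w = (odba[odba["animal_id"] == aid][["window_start", "mean", "max",
                                             "variance"]]
             if odba is not None else
             pd.DataFrame(columns=["window_start", "mean", "max", "variance"]))
        out["tracks"].append(RawSensorTrack(
            animal_id=str(aid), species=str(g["species"].iloc[0]),
            fix_times=g["time"].astype("int64").to_numpy() / 1e9,
            fixes=g[["x", "y"]].to_numpy(float), odba_windows=w))
    if (root / "intrusions.csv").exists():
        intr = pd.read_csv(root / "intrusions.csv", parse_dates=["time"])
        for iid, g in intr.groupby("intrusion_id"):
            t = g["time"].astype("int64").to_numpy() / 1e9
            out["intrusions"].append(IntrusionEvent(
                intrusion_id=str(iid), mode=str(g["mode"].iloc[0]),
                group_size=int(g["group_size"].iloc[0]),
                t_start=float(t.min()), t_end=float(t.max()),
                route=g[["x", "y"]].to_numpy(float)))
    out["column_report"] = report
    return out
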