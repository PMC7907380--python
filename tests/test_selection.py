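"""Filtering, importance metrics, top-k union, two-stage PCA, clustering."""

import numpy as np
import pandas as pd
import pytest

from herdwatch.selection import (ImportanceScores, SegmentData,
                                 filter_segments, fit_pc_stack, importance,
                                 proximity_labels, select_top_union,
                                 unsupervised_clusters)
from herdwatch.synthetic import IntrusionEvent


def _segment(seg_id, kind, n_animals=35, n_min=30, intrusion=None,
             rng=None, t0=0.0):
    rng = rng or np.random.default_rng(0)
    rows = []
    for a in range(n_animals):
        for m in range(n_min):
            rows.append((f"{seg_id}|a{a}", t0 + 60.0 * m,
                         rng.uniform(0, 3000), rng.uniform(0, 3000)))
    df = pd.DataFrame(rows, columns=["animal_id", "time", "x", "y"])
    df = df.set_index(["animal_id", "time"])
    df["species"] = "zebra"
    return SegmentData(segment_id=seg_id, kind=kind, t_start=t0,
                       t_end=t0 + 60.0 * n_min, matrix=df,
                       intrusion=intrusion, pair_id=seg_id.split("_")[0])


def _intrusion(t0=0.0, duration=1800.0, xy=(1500.0, 1500.0)):
    route = np.tile(xy, (int(duration / 5) + 1, 1))
    return IntrusionEvent("i0", "foot", 2, t0, t0 + duration, route)


class TestFilterSegments:
    def test_low_sensor_segment_dropped_with_pair(self):
        segs = [_segment("p0_intr", "intrusion", n_animals=29,
                         intrusion=_intrusion()),
                _segment("p0_ctrl", "control", n_animals=29),
                _segment("p1_intr", "intrusion", n_animals=35,
                         intrusion=_intrusion()),
                _segment("p1_ctrl", "control", n_animals=35)]
        kept = filter_segments(segs, min_active_sensors=30)
        assert {s.segment_id for s in kept} == {"p1_intr", "p1_ctrl"}

    def test_vehicle_proximal_rows_removed(self):
        seg = _segment("p0_intr", "intrusion", n_animals=5, n_min=40,
                       intrusion=_intrusion())
        # vehicle parked at a spot some rows are near
        target = seg.matrix.iloc[0][["x", "y"]].to_numpy(float)
        veh = IntrusionEvent("veh", "vehicle", 1, 0.0, 2400.0,
                             np.tile(target, (481, 1)))
        kept = filter_segments([seg], min_active_sensors=0, vehicles=[veh])
        xy = kept[0].matrix[["x", "y"]].to_numpy()
        d = np.linalg.norm(xy - target, axis=1)
        assert (d >= 250.0).all()
        assert len(kept[0].matrix) < len(seg.matrix)

    def test_clean_dataset_unchanged(self):
        segs = [_segment("p0_intr", "intrusion", intrusion=_intrusion()),
                _segment("p0_ctrl", "control")]
        kept = filter_segments(segs, min_active_sensors=30)
        assert len(kept) == 2
        assert len(kept[0].matrix) == len(segs[0].matrix)


class TestProximityLabels:
    def _pair(self, rng):
        intr = _intrusion()
        return [_segment("p0_intr", "intrusion", intrusion=intr, rng=rng),
                _segment("p0_ctrl", "control", rng=rng)]

    def test_threshold_and_balance(self):
        rng = np.random.default_rng(1)
        segs = self._pair(rng)
        y = proximity_labels(segs, seed=0)
        ones = y[y == 1.0]
        zeros = y[y == 0.0]
        assert len(ones) == len(zeros) > 0
        intr_m = segs[0].matrix
        d = np.linalg.norm(intr_m[["x", "y"]].to_numpy()
                           - [1500.0, 1500.0], axis=1)
        within = set(intr_m.index[d < 1000.0])
        assert set(ones.index) == within

    def test_reseeding_changes_controls_not_size(self):
        rng = np.random.default_rng(2)
        segs = self._pair(rng)
        y1 = proximity_labels(segs, seed=1)
        y2 = proximity_labels(segs, seed=2)
        z1 = set(y1[y1 == 0.0].index)
        z2 = set(y2[y2 == 0.0].index)
        assert len(z1) == len(z2)
        assert z1 != z2
        assert set(y1[y1 == 1.0].index) == set(y2[y2 == 1.0].index)


class TestImportance:
    def test_plugin_formulas(self):
        rng = np.random.default_rng(3)
        n = 4000
        y = np.concatenate([np.ones(n), np.zeros(n)])
        x = np.concatenate([rng.normal(2, 1, n), rng.normal(0, 1, n)])
        X = pd.DataFrame({"f": x})
        sc = importance(X, y, seed=0, n_estimators=20).table
        mu1, mu0 = x[:n].mean(), x[n:].mean()
        s1 = x[:n].std(ddof=1)
        s0 = x[n:].std(ddof=1)
        assert sc.loc["f", "marginality"] == pytest.approx((mu1 - mu0) / s0)
        assert sc.loc["f", "specialization"] == pytest.approx(s1 / s0)
        pooled = np.sqrt(((n - 1) * s1 ** 2 + (n - 1) * s0 ** 2) / (2 * n - 2))
        assert sc.loc["f", "mahalanobis"] == pytest.approx(
            abs(mu1 - mu0) / pooled)

    def test_null_feature_scores(self):
        rng = np.random.default_rng(4)
        y = np.concatenate([np.ones(2000), np.zeros(2000)])
        X = pd.DataFrame({"f": rng.normal(0, 1, 4000)})
        sc = importance(X, y, seed=0, n_estimators=20).table
        assert abs(sc.loc["f", "marginality"]) < 0.1
        assert sc.loc["f", "specialization"] == pytest.approx(1.0, abs=0.1)
        assert abs(sc.loc["f", "rf_mda"]) < 0.05

    def test_zero_variance_reference_excluded(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 5.0, 5.0, 5.0],
                          "g": [1, 2, 3, 4, 5, 6.0]})
        with pytest.warns(UserWarning):
            sc = importance(X, y, seed=0, n_estimators=5)
        assert "f" in sc.excluded
        assert np.isnan(sc.table.loc["f", "marginality"])


class TestTopUnion:
    def _scores(self, tab):
        t = tab.copy()
        for m in ImportanceScores.METRICS:
            key = {"mahalanobis": t["mahalanobis"],
                   "marginality": t["marginality"].abs(),
                   "specialization": np.abs(np.log(t["specialization"])),
                   "rf_mda": t["rf_mda"]}[m]
            df = pd.DataFrame({"k": -key, "n": key.index})
            t[f"{m}_rank"] = (df.sort_values(["k", "n"])
                              .assign(r=np.arange(1, len(df) + 1))
                              .loc[t.index, "r"])
        return ImportanceScores(table=t)

    def test_identical_rankings_union_is_k(self):
        n = 50
        v = np.linspace(2, 1, n)
        tab = pd.DataFrame({"mahalanobis": v, "marginality": v,
                            "specialization": np.exp(v), "rf_mda": v},
                           index=[f"f{i:02d}" for i in range(n)])
        assert len(select_top_union(self._scores(tab), k=10)) == 10

    def test_disjoint_rankings_union_is_4k(self):
        n = 40
        idx = [f"f{i:02d}" for i in range(n)]
        base = np.zeros(n)
        tab = pd.DataFrame({"mahalanobis": base.copy(),
                            "marginality": base.copy(),
                            "specialization": np.ones(n),
                            "rf_mda": base.copy()}, index=idx)
        tab.iloc[0:5, 0] = np.arange(5, 0, -1)
        tab.iloc[5:10, 1] = np.arange(5, 0, -1)
        tab.iloc[10:15, 2] = np.exp(np.arange(5, 0, -1))
        tab.iloc[15:20, 3] = np.arange(5, 0, -1)
        assert len(select_top_union(self._scores(tab), k=5)) == 20

    def test_random_scores_match_bruteforce_union(self):
        rng = np.random.default_rng(5)
        n, k = 2000, 125
        idx = [f"f{i:04d}" for i in range(n)]
        tab = pd.DataFrame({
            "mahalanobis": rng.random(n), "marginality": rng.normal(size=n),
            "specialization": rng.lognormal(size=n), "rf_mda": rng.random(n),
        }, index=idx)
        scores = self._scores(tab)
        got = set(select_top_union(scores, k=k))
        expected = set()
        keys = {"mahalanobis": tab["mahalanobis"],
                "marginality": tab["marginality"].abs(),
                "specialization": np.abs(np.log(tab["specialization"])),
                "rf_mda": tab["rf_mda"]}
        for key in keys.values():
            expected |= set(key.sort_values(ascending=False).index[:k])
        assert got == expected


class TestPCStack:
    def _matrix(self, X, classes):
        cols = []
        for i, cls in enumerate(classes):
            base = {"individual_geometry": "speed", "accelerometer": "odba_mean",
                    "collective": "alignment", "space_use": "suitability"}[cls]
            cols.append(f"{base}__v{i}")
        return pd.DataFrame(X, columns=cols), cols

    def test_white_noise_retention_scales_with_target(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(2000, 40))
        m, cols = self._matrix(X, ["individual_geometry"] * 20
                               + ["accelerometer"] * 20)
        st = fit_pc_stack(m, cols, var_target=0.9)
        # identity covariance: need ~target fraction of dimensions per class
        assert 30 <= st.n_stage1 <= 40

    def test_rank_one_class_single_component(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=2000)
        X = np.column_stack([z, 2 * z, -z, rng.normal(size=2000)])
        m, cols = self._matrix(X, ["individual_geometry"] * 3
                               + ["accelerometer"])
        st = fit_pc_stack(m, cols, var_target=0.95)
        feats, mean, scale, comps = st.class_models["individual_geometry"]
        assert comps.shape[0] == 1

    def test_training_mean_row_maps_to_zero(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(500, 6))
        m, cols = self._matrix(X, ["individual_geometry"] * 3
                               + ["accelerometer"] * 3)
        st = fit_pc_stack(m, cols, var_target=0.95)
        mean_row = pd.DataFrame([m.mean()], columns=m.columns)
        scores = st.transform(mean_row)
        assert np.abs(scores.to_numpy()).max() < 1e-9

    def test_roundtrip_variance_retained(self):
        rng = np.random.default_rng(9)
        latent = rng.normal(size=(1000, 3))
        X = latent @ rng.normal(size=(3, 8)) + 0.05 * rng.normal(size=(1000, 8))
        m, cols = self._matrix(X, ["individual_geometry"] * 4
                               + ["accelerometer"] * 4)
        st = fit_pc_stack(m, cols, var_target=0.95)
        scores = st.transform(m)
        # stage-2 scores carry >= 95% of the standardized variance
        total = 0.0
        for cls, (feats, mean, scale, comps) in st.class_models.items():
            Z = (m[feats].to_numpy() - mean) / scale
            total += Z.var(axis=0).sum()
        assert scores.to_numpy().var(axis=0).sum() >= 0.95 * total * 0.95

    def test_single_class_rejected(self):
        m, cols = self._matrix(np.random.default_rng(0).normal(size=(50, 3)),
                               ["individual_geometry"] * 3)
        with pytest.raises(ValueError):
            fit_pc_stack(m, cols)


class TestClustering:
    def test_blob_recovery(self):
        rng = np.random.default_rng(10)
        centers = rng.uniform(-50, 50, size=(25, 4))
        X, truth = [], []
        for i, c in enumerate(centers):
            X.append(c + rng.normal(0, 0.3, size=(40, 4)))
            truth += [i] * 40
        X = np.vstack(X)
        scores = pd.DataFrame(X, columns=[f"PC{i+1}" for i in range(4)])
        species = pd.Series(["zebra"] * len(X))
        cm = unsupervised_clusters(scores, species, n_clusters=25, seed=0)
        got = cm.assign(scores, species)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, got) > 0.95

    def test_single_cluster_and_determinism(self):
        rng = np.random.default_rng(11)
        scores = pd.DataFrame(rng.normal(size=(100, 3)),
                              columns=["PC1", "PC2", "PC3"])
        species = pd.Series(["zebra"] * 100)
        one = unsupervised_clusters(scores, species, n_clusters=1, seed=0)
        assert one.assign(scores, species).nunique() == 1
        a = unsupervised_clusters(scores, species, n_clusters=5, seed=3)
        b = unsupervised_clusters(scores, species, n_clusters=5, seed=3)
        pd.testing.assert_series_equal(a.assign(scores, species),
                                       b.assign(scores, species))
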