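"""Engineered movement features with contextual standardization.

Features come in four classes — individual geometry, accelerometer,
collective movement, and space use — and are computed per animal-minute
from regular 1-min tracks. On top of the base features the module provides:

* z-standardization against *reference sets*: per species (global), per
  area (30 x 30 m neighborhoods), per time of day within a 5-week period,
  per area x time-of-day, and per individual x time-of-day — each capturing
  "deviation from normal behavior under comparable conditions";
* moving-window derivatives (5-min centered, 10- and 20-min lagging means
  and SDs, and centered-minus-lagging differences);
* log transforms, 0.001/0.999 winsorization and ordinal (quantile-bin)
  discretization.

No feature depends on absolute coordinates or absolute timestamps: spatial
context enters only through landscape rasters and origin-relative area
bins, temporal context only through time-of-day and period bins.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from herdwatch.preprocess import RegularTrack
from herdwatch.synthetic import Landscape, time_of_day_bin

META_COLS = ("species", "x", "y", "tod", "period")

FEATURE_CLASSES = {
    "speed": "individual_geometry",
    "turn_angle": "individual_geometry",
    "persistence": "individual_geometry",
    "net_gross": "individual_geometry",
    "msd_alpha": "individual_geometry",
    "msd_logc": "individual_geometry",
    "fpt_logvar_50": "individual_geometry",
    "fpt_logvar_100": "individual_geometry",
    "fpt_logvar_250": "individual_geometry",
    "odba_mean": "accelerometer",
    "odba_max": "accelerometer",
    "odba_var": "accelerometer",
    "nn_dist": "collective",
    "density": "collective",
    "alignment": "collective",
    "synchrony": "collective",
    "centroid_dist": "collective",
    "suitability": "space_use",
    "tree_cover": "space_use",
    "elev_change": "space_use",
    "tobler_speed": "space_use",
    "cost_proxy": "space_use",
    "suit_gradient": "space_use",
}


def feature_class(column: str) -> str:
    """Main feature class of a (possibly derived) column."""
    base = column
    for sep in ("__", ":"):
        if sep in base:
            base = base.split(sep)[0]
    return FEATURE_CLASSES.get(base, "other")


@dataclass
class FeatureConfig:
    window_min: int = 10                 # trailing window for windowed geometry
    msd_lags_min: tuple = (1, 2, 3, 4, 5)
    fpt_radii_m: tuple = (50.0, 100.0, 250.0)
    neighbor_radius_m: float = 200.0
    area_cell_m: float = 30.0
    period_weeks: float = 5.0
    n_bins: int = 10
    truncate_q: float = 0.001
    log_features: tuple = ("speed", "odba_mean", "odba_max", "odba_var",
                           "nn_dist", "centroid_dist", "cost_proxy")
    divide_by: str = "sd"                # "sd" | "variance" (literal reading)
    standardized_subset: tuple = ("speed", "persistence", "net_gross",
                                  "odba_mean", "odba_var", "alignment",
                                  "nn_dist", "suitability", "cost_proxy")
    window_subset: tuple = ("speed", "persistence", "odba_mean", "alignment",
                            "suitability")


def tobler_speed_ms(slope: np.ndarray) -> np.ndarray:
    """Tobler's hiking function: 6 * exp(-3.5 * |slope + 0.05|) km/h, in m/s.

    Maximum walking speed (6 km/h) occurs on a gentle -5% downhill.
    """
    return 6.0 * np.exp(-3.5 * np.abs(np.asarray(slope, float) + 0.05)) / 3.6


# ---------------------------------------------------------------------------
# Base feature classes
# ---------------------------------------------------------------------------


def individual_geometry(track: RegularTrack,
                        config: FeatureConfig | None = None) -> pd.DataFrame:
    """Per-minute geometry of one trajectory.

    Step speed and turning angle are instantaneous; directional
    persistence (mean cosine of turning angles), net-gross distance ratio,
    mean-squared-displacement power-law fit parameters (slope and
    intercept of log MSD vs log lag — the diffusive/ballistic signature)
    and the variance of log first-passage times through configured radii
    are computed over a trailing window. Zero-length steps leave the
    turning angle undefined (NaN, imputed at standardization).
    """
    config = config or FeatureConfig()
    p = track.positions
    n = track.n
    step_s = float(track.times[1] - track.times[0]) if n > 1 else 60.0
    d = np.diff(p, axis=0)
    step_len = np.linalg.norm(d, axis=1)
    speed = np.concatenate([[np.nan], step_len]) / step_s

    heading = np.arctan2(d[:, 1], d[:, 0])
    turn = np.full(n, np.nan)
    moving = step_len > 1e-9
    for i in range(1, len(d)):
        if moving[i] and moving[i - 1]:
            turn[i + 1] = np.angle(np.exp(1j * (heading[i] - heading[i - 1])))
    turn = np.abs(turn)

    w = config.window_min
    cos_turn = pd.Series(np.cos(turn))
    persistence = cos_turn.rolling(w, min_periods=2).mean().to_numpy()

    gross = pd.Series(np.concatenate([[0.0], step_len])).rolling(w, min_periods=w).sum()
    net = np.full(n, np.nan)
    net[w:] = np.linalg.norm(p[w:] - p[:-w], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        net_gross = np.where(gross.to_numpy() > 0, net / gross.to_numpy(), np.nan)

    msd_alpha, msd_logc = _msd_fit(p, config.msd_lags_min, w)

    feats = {
        "speed": speed,
        "turn_angle": turn,
        "persistence": persistence,
        "net_gross": net_gross,
        "msd_alpha": msd_alpha,
        "msd_logc": msd_logc,
    }
    pairwise = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=2)
    for r in config.fpt_radii_m:
        feats[f"fpt_logvar_{int(r)}"] = _fpt_logvar(track.times, p, r, w,
                                                    pairwise=pairwise)

    df = pd.DataFrame(feats, index=_row_index(track))
    return df


def _msd_fit(p: np.ndarray, lags, w: int):
    """Rolling log-log MSD regression: slope (alpha) and intercept (logc)."""
    n = len(p)
    lags = [lag for lag in lags if lag < n]
    if len(lags) < 2:
        return np.full(n, np.nan), np.full(n, np.nan)
    msd_rows = []
    for lag in lags:
        sq = np.full(n, np.nan)
        sq[lag:] = np.sum((p[lag:] - p[:-lag]) ** 2, axis=1)
        msd_rows.append(pd.Series(sq).rolling(w, min_periods=max(2, w // 2))
                        .mean().to_numpy())
    msd = np.stack(msd_rows)                       # (n_lags, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.log(msd)
    x = np.log(np.asarray(lags, float))[:, None]
    valid = np.isfinite(y)
    cnt = valid.sum(axis=0)
    xm = np.where(valid, x, 0.0).sum(axis=0) / np.maximum(cnt, 1)
    ym = np.nansum(np.where(valid, y, 0.0), axis=0) / np.maximum(cnt, 1)
    sxx = np.where(valid, (x - xm) ** 2, 0.0).sum(axis=0)
    sxy = np.nansum(np.where(valid, (x - xm) * (y - ym), 0.0), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where((cnt >= 2) & (sxx > 0), sxy / sxx, np.nan)
    logc = np.where(cnt >= 2, ym - alpha * xm, np.nan)
    return alpha, logc


def _fpt_logvar(times, p, radius, w, pairwise=None):
    """Rolling variance of log forward first-passage time through radius."""
    n = len(p)
    if pairwise is None:
        pairwise = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=2)
    beyond = pairwise > radius
    beyond[np.tril_indices(n)] = False          # forward passages only
    hit_any = beyond.any(axis=1)
    first = np.argmax(beyond, axis=1)
    fpt = np.where(hit_any, times[np.minimum(first, n - 1)] - times, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        logfpt = np.log(fpt)
    return pd.Series(logfpt).rolling(w, min_periods=3).var().to_numpy()


def accelerometer_features(track: RegularTrack,
                           config: FeatureConfig | None = None) -> pd.DataFrame:
    """Per-step ODBA summaries (windowed aggregates come from window_features)."""
    return pd.DataFrame({
        "odba_mean": track.odba_mean,
        "odba_max": track.odba_max,
        "odba_var": track.odba_var,
    }, index=_row_index(track))


def collective_features(tracks: list[RegularTrack],
                        config: FeatureConfig | None = None) -> pd.DataFrame:
    """Herd-topology features per animal-minute across a set of tracks.

    Neighbors are conspecifics within ``neighbor_radius_m``. With no
    neighbor, density is 0 and alignment/synchrony are missing; nearest
    neighbor and centroid distances are computed over the species.
    """
    config = config or FeatureConfig()
    frames = []
    by_species: dict[str, list[RegularTrack]] = {}
    for tr in tracks:
        by_species.setdefault(tr.species, []).append(tr)

    for sp, group in by_species.items():
        all_times = sorted(set(np.concatenate([tr.times for tr in group])))
        pos_at = {}
        head_at = {}
        speed_at = {}
        for tr in group:
            tmap = {t: i for i, t in enumerate(tr.times)}
            pos_at[tr.animal_id] = (tmap, tr.positions)
            d = np.diff(tr.positions, axis=0)
            h = np.arctan2(d[:, 1], d[:, 0])
            sp_len = np.linalg.norm(d, axis=1)
            head_at[tr.animal_id] = (tmap, np.concatenate([[np.nan], h]),
                                     np.concatenate([[0.0], sp_len]))
        rows = {tr.animal_id: {k: np.full(tr.n, np.nan)
                               for k in ("nn_dist", "density", "alignment",
                                         "synchrony", "centroid_dist")}
                for tr in group}
        for t in all_times:
            present = [tr.animal_id for tr in group if t in pos_at[tr.animal_id][0]]
            if not present:
                continue
            P = np.array([pos_at[a][1][pos_at[a][0][t]] for a in present])
            H = np.array([head_at[a][1][head_at[a][0][t]] for a in present])
            V = np.array([head_at[a][2][head_at[a][0][t]] for a in present])
            centroid = P.mean(axis=0)
            if len(present) > 1:
                D = np.linalg.norm(P[:, None, :] - P[None, :, :], axis=2)
                np.fill_diagonal(D, np.inf)
            for k, a in enumerate(present):
                tmap, _ = pos_at[a]
                i = tmap[t]
                store = rows[a]
                store["centroid_dist"][i] = np.linalg.norm(P[k] - centroid)
                if len(present) == 1:
                    store["density"][i] = 0.0
                    continue
                store["nn_dist"][i] = D[k].min()
                nb = np.flatnonzero(D[k] < config.neighbor_radius_m)
                area = np.pi * config.neighbor_radius_m ** 2
                store["density"][i] = len(nb) / area
                if len(nb):
                    nh = H[nb]
                    nh = nh[np.isfinite(nh)]
                    if len(nh):
                        store["alignment"][i] = float(np.abs(np.mean(np.exp(1j * nh))))
                    vn = V[nb].mean()
                    store["synchrony"][i] = 1.0 - abs(V[k] - vn) / (V[k] + vn + 1e-9)
        for tr in group:
            frames.append(pd.DataFrame(rows[tr.animal_id], index=_row_index(tr)))
    return pd.concat(frames).sort_index()


def space_use_features(track: RegularTrack, landscape: Landscape,
                       config: FeatureConfig | None = None) -> pd.DataFrame:
    """Animal-environment interplay per minute.

    Suitability/tree cover at position, elevation change per step, the
    Tobler walking speed implied by the step's slope, an energetic cost
    proxy (realized speed over Tobler speed: moving fast uphill is
    expensive), and the suitability gradient along the current heading
    (negative = moving toward worse habitat).
    """
    config = config or FeatureConfig()
    p = track.positions
    n = track.n
    step_s = float(track.times[1] - track.times[0]) if n > 1 else 60.0
    tods = [time_of_day_bin(t) for t in track.times]
    suit = np.array([landscape.suitability_at(track.species, tod, x, y)
                     for tod, (x, y) in zip(tods, p)])
    tree = landscape.value_at(landscape.tree_cover, p[:, 0], p[:, 1])
    elev = landscape.value_at(landscape.elevation, p[:, 0], p[:, 1])
    d = np.diff(p, axis=0)
    step_len = np.linalg.norm(d, axis=1)
    dz = np.diff(elev)
    elev_change = np.concatenate([[np.nan], dz])
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(step_len > 1e-9, dz / step_len, 0.0)
    tob = tobler_speed_ms(np.concatenate([[0.0], slope]))
    speed = np.concatenate([[np.nan], step_len]) / step_s
    cost = speed / tob

    heading = np.arctan2(d[:, 1], d[:, 0])
    grad = np.full(n, np.nan)
    eps = 15.0
    for i, h in enumerate(heading):
        if step_len[i] <= 1e-9:
            continue
        u = np.array([np.cos(h), np.sin(h)])
        ahead = p[i + 1] + eps * u
        behind = p[i + 1] - eps * u
        tod = tods[i + 1]
        grad[i + 1] = (landscape.suitability_at(track.species, tod, *ahead)
                       - landscape.suitability_at(track.species, tod, *behind)) / (2 * eps)
    return pd.DataFrame({
        "suitability": suit,
        "tree_cover": tree,
        "elev_change": elev_change,
        "tobler_speed": tob,
        "cost_proxy": cost,
        "suit_gradient": grad,
    }, index=_row_index(track))


def _row_index(track: RegularTrack) -> pd.MultiIndex:
    return pd.MultiIndex.from_arrays(
        [np.repeat(track.animal_id, track.n), track.times],
        names=["animal_id", "time"])


def build_feature_matrix(tracks: list[RegularTrack], landscape: Landscape,
                         config: FeatureConfig | None = None) -> pd.DataFrame:
    """All base features plus meta columns for every track."""
    config = config or FeatureConfig()
    per_track = []
    for tr in tracks:
        parts = [individual_geometry(tr, config),
                 accelerometer_features(tr, config),
                 space_use_features(tr, landscape, config)]
        df = pd.concat(parts, axis=1)
        df.insert(0, "species", tr.species)
        df.insert(1, "x", tr.positions[:, 0])
        df.insert(2, "y", tr.positions[:, 1])
        df.insert(3, "tod", [time_of_day_bin(t) for t in tr.times])
        period = (np.asarray(tr.times) // (config.period_weeks * 7 * 86400.0)).astype(int)
        df.insert(4, "period", period)
        per_track.append(df)
    out = pd.concat(per_track)
    coll = collective_features(tracks, config)
    out = out.join(coll)
    return out.sort_index()


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c not in META_COLS]


def feature_report(matrix: pd.DataFrame) -> pd.Series:
    """Engineered-column count per main feature class (bookkeeping)."""
    cols = feature_columns(matrix)
    return pd.Series([feature_class(c) for c in cols]).value_counts()


# ---------------------------------------------------------------------------
# Reference-set standardization
# ---------------------------------------------------------------------------

REFERENCE_KINDS = ("species", "area", "timeofday_5wk", "area_timeofday_5wk",
                   "individual_timeofday_5wk")


def _group_keys(matrix: pd.DataFrame, kind: str, landscape: Landscape | None,
                area_cell_m: float) -> pd.Series:
    sp = matrix["species"].astype(str)
    if kind == "species":
        return sp
    ox, oy = (landscape.origin if landscape is not None else (0.0, 0.0))
    ax = ((matrix["x"] - ox) // area_cell_m).astype(int).astype(str)
    ay = ((matrix["y"] - oy) // area_cell_m).astype(int).astype(str)
    tod = matrix["tod"].astype(str)
    per = matrix["period"].astype(str)
    animal = matrix.index.get_level_values("animal_id").astype(str)
    if kind == "area":
        return sp + "|" + ax + "," + ay
    if kind == "timeofday_5wk":
        return sp + "|" + tod + "|" + per
    if kind == "area_timeofday_5wk":
        return sp + "|" + ax + "," + ay + "|" + tod + "|" + per
    if kind == "individual_timeofday_5wk":
        return pd.Series(animal, index=matrix.index) + "|" + tod + "|" + per
    raise ValueError(f"unknown reference kind: {kind}")


@dataclass
class ReferenceSet:
    """Per-group mean/sd of features over an undisturbed reference pool."""

    kind: str
    features: list
    stats: pd.DataFrame             # index: group key; columns (feat, mean|sd)
    species_stats: pd.DataFrame     # fallback: index species
    area_cell_m: float = 30.0
    min_group_n: int = 5
    degenerate_groups: list = field(default_factory=list)


def build_reference(matrix: pd.DataFrame, kind: str,
                    features: list | None = None,
                    landscape: Landscape | None = None,
                    area_cell_m: float = 30.0,
                    min_group_n: int = 5) -> ReferenceSet:
    """Fit reference statistics from (undisturbed) rows.

    The caller is responsible for passing only undisturbed data; groups
    with fewer than ``min_group_n`` rows or ~zero variance are flagged
    degenerate and fall back to species-level statistics at transform.
    """
    features = list(features or feature_columns(matrix))
    keys = _group_keys(matrix, kind, landscape, area_cell_m)
    g = matrix[features].groupby(keys)
    mean = g.mean()
    sd = g.std(ddof=1)
    cnt = g.size()
    sp_g = matrix[features].groupby(matrix["species"].astype(str))
    sp_stats = pd.concat({"mean": sp_g.mean(), "sd": sp_g.std(ddof=1)}, axis=1)
    degenerate = cnt.index[cnt < min_group_n].tolist()
    stats = pd.concat({"mean": mean, "sd": sd}, axis=1)
    return ReferenceSet(kind=kind, features=features, stats=stats,
                        species_stats=sp_stats, area_cell_m=area_cell_m,
                        min_group_n=min_group_n, degenerate_groups=degenerate)


def standardize_columns(matrix: pd.DataFrame, reference: ReferenceSet,
                        divide_by: str = "sd",
                        landscape: Landscape | None = None,
                        suffix: str | None = None) -> pd.DataFrame:
    """z-variant columns only (callers concat; see :func:`standardize`)."""
    if divide_by not in ("sd", "variance"):
        raise ValueError("divide_by must be 'sd' or 'variance'")
    keys = _group_keys(matrix, reference.kind, landscape, reference.area_cell_m)
    suffix = suffix or f"__z_{reference.kind}"
    mean_tab = reference.stats["mean"]
    sd_tab = reference.stats["sd"]
    bad_groups = set(reference.degenerate_groups)
    known = mean_tab.index
    usable = keys.isin(known) & ~keys.isin(bad_groups)
    sp_keys = matrix["species"].astype(str)
    new_cols = {}
    for f in reference.features:
        mu = pd.Series(np.nan, index=matrix.index)
        sd = pd.Series(np.nan, index=matrix.index)
        mu[usable.values] = mean_tab[f].reindex(keys[usable.values]).to_numpy()
        sd[usable.values] = sd_tab[f].reindex(keys[usable.values]).to_numpy()
        fb = ~usable.values | ~np.isfinite(sd.to_numpy()) | (sd.to_numpy() <= 1e-12)
        if fb.any():
            mu[fb] = reference.species_stats[("mean", f)].reindex(
                sp_keys[fb]).to_numpy()
            sd[fb] = reference.species_stats[("sd", f)].reindex(
                sp_keys[fb]).to_numpy()
        denom = sd if divide_by == "sd" else sd ** 2
        z = (matrix[f] - mu) / denom.replace(0.0, np.nan)
        new_cols[f"{f}{suffix}"] = z.fillna(0.0)
    return pd.DataFrame(new_cols, index=matrix.index)


def standardize(matrix: pd.DataFrame, reference: ReferenceSet,
                divide_by: str = "sd",
                landscape: Landscape | None = None,
                suffix: str | None = None) -> pd.DataFrame:
    """Add z-variant columns ``<feature>__z_<kind>``.

    z = (v - group mean) / group sd (or / group variance with
    ``divide_by='variance'``, the literal reading). Rows in degenerate or
    unseen groups use species-level statistics; missing values standardize
    to 0 (group-mean imputation).
    """
    z = standardize_columns(matrix, reference, divide_by, landscape, suffix)
    return pd.concat([matrix, z], axis=1)


def inverse_standardize(z: pd.Series, reference: ReferenceSet, feature: str,
                        group_key: str, divide_by: str = "sd") -> pd.Series:
    mu = reference.stats["mean"].loc[group_key, feature]
    sd = reference.stats["sd"].loc[group_key, feature]
    denom = sd if divide_by == "sd" else sd ** 2
    return z * denom + mu


# ---------------------------------------------------------------------------
# Moving windows and discretization
# ---------------------------------------------------------------------------

WINDOW_VARIANTS = ("win_5c", "win_10l", "win_20l", "win_diff_5c_10l",
                   "win_diff_5c_20l")


def _group_bounds(matrix: pd.DataFrame) -> np.ndarray:
    """Start indices of contiguous animal blocks (matrix sorted by animal)."""
    ids = matrix.index.get_level_values("animal_id").to_numpy()
    starts = np.flatnonzero(np.concatenate([[True], ids[1:] != ids[:-1]]))
    return np.concatenate([starts, [len(ids)]])


def window_features(matrix: pd.DataFrame,
                    features: list | None = None) -> pd.DataFrame:
    """Moving-window mean/sd variants per animal.

    5-min centered, 10- and 20-min lagging windows, plus the difference
    between centered and lagging means (recent behavior minus its own
    recent history). Rows without sufficient history stay missing.

    Rollings run over the full (animal-sorted) column for speed; rows whose
    window would straddle an animal boundary are invalidated afterwards,
    which reproduces the per-animal min_periods semantics exactly.
    """
    features = list(features or feature_columns(matrix))
    bounds = _group_bounds(matrix)
    n = len(matrix)

    def _invalidate(arr, before, after):
        for s, e in zip(bounds[:-1], bounds[1:]):
            arr[s:min(s + before, e)] = np.nan
            if after:
                arr[max(e - after, s):e] = np.nan
        return arr

    out_parts = {}
    for f in features:
        s = pd.Series(matrix[f].to_numpy(float))
        r5 = s.rolling(5, center=True, min_periods=5)
        r10 = s.rolling(10, min_periods=10)
        r20 = s.rolling(20, min_periods=20)
        m5 = _invalidate(r5.mean().to_numpy(), 2, 2)
        s5 = _invalidate(r5.std().to_numpy(), 2, 2)
        m10 = _invalidate(r10.mean().to_numpy(), 9, 0)
        s10 = _invalidate(r10.std().to_numpy(), 9, 0)
        m20 = _invalidate(r20.mean().to_numpy(), 19, 0)
        s20 = _invalidate(r20.std().to_numpy(), 19, 0)
        out_parts[f"{f}__win_5c_mean"] = m5
        out_parts[f"{f}__win_5c_sd"] = s5
        out_parts[f"{f}__win_10l_mean"] = m10
        out_parts[f"{f}__win_10l_sd"] = s10
        out_parts[f"{f}__win_20l_mean"] = m20
        out_parts[f"{f}__win_20l_sd"] = s20
        out_parts[f"{f}__win_diff_5c_10l"] = m5 - m10
        out_parts[f"{f}__win_diff_5c_20l"] = m5 - m20
    return pd.concat([matrix, pd.DataFrame(out_parts, index=matrix.index)], axis=1)


@dataclass
class Discretizer:
    """Stored per-species transform: log flags, winsor bounds, bin edges.

    Fitting happens on training rows; transform maps any rows (including
    held-out folds) through the same monotone pipeline, so ordinal bins
    are comparable across folds without leakage.
    """

    n_bins: int
    log_features: tuple
    bounds: dict                   # (species, feature) -> (lo, hi)
    edges: dict                    # (species, feature) -> interior quantile edges
    features: list

    def _maybe_log(self, f: str, v: pd.Series) -> pd.Series:
        if any(f == lf or f.startswith(lf + "__") for lf in self.log_features):
            return np.log1p(v.clip(lower=0.0))
        return v

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        sp = matrix["species"].astype(str).to_numpy()
        masks = {s: sp == s for s in np.unique(sp)}
        cont_cols = {}
        ord_cols = {}
        for f in self.features:
            v = self._maybe_log(f, matrix[f].astype(float)).to_numpy(float)
            clipped = v.copy()
            ordv = np.full(len(v), np.nan)
            for s, mask in masks.items():
                key = (s, f)
                if key not in self.bounds:
                    continue
                lo, hi = self.bounds[key]
                vals = np.clip(v[mask], lo, hi)
                clipped[mask] = vals
                bins = np.searchsorted(self.edges[key], vals,
                                       side="right") + 1.0
                ordv[mask] = np.where(np.isfinite(vals),
                                      np.clip(bins, 1, self.n_bins), np.nan)
            cont_cols[f] = clipped
            ord_cols[f"{f}__ord"] = ordv
        others = matrix[[c for c in matrix.columns if c not in cont_cols]]
        return pd.concat([others,
                          pd.DataFrame(cont_cols, index=matrix.index),
                          pd.DataFrame(ord_cols, index=matrix.index)], axis=1)


def fit_discretizer(matrix: pd.DataFrame, n_bins: int = 10,
                    log_features: tuple = (), truncate_q: float = 0.001,
                    features: list | None = None) -> Discretizer:
    """Fit winsor bounds and quantile bin edges per species on training rows."""
    features = list(features or feature_columns(matrix))
    disc = Discretizer(n_bins=n_bins, log_features=tuple(log_features),
                       bounds={}, edges={}, features=features)
    sp = matrix["species"].astype(str).to_numpy()
    masks = {s: sp == s for s in np.unique(sp)}
    inner_q = np.linspace(0, 1, n_bins + 1)[1:-1]
    for f in features:
        v = disc._maybe_log(f, matrix[f].astype(float)).to_numpy(float)
        for s, mask in masks.items():
            vals = v[mask]
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                continue
            lo, hi = np.quantile(vals, [truncate_q, 1.0 - truncate_q])
            edges = np.quantile(np.clip(vals, lo, hi), inner_q)
            disc.bounds[(s, f)] = (float(lo), float(hi))
            disc.edges[(s, f)] = edges
    return disc


def transform_truncate_discretize(matrix: pd.DataFrame,
                                  n_bins: int = 10,
                                  log_features: tuple = (),
                                  truncate_q: float = 0.001,
                                  features: list | None = None) -> pd.DataFrame:
    """Log-transform configured columns, winsorize all, add ordinal bins.

    Distributions are pooled per species. Winsorization clips at the
    ``truncate_q`` and ``1 - truncate_q`` quantiles; ordinal columns
    ``<feature>__ord`` hold quantile-bin indices in [1, n_bins]
    (rank-invariant under monotone transforms). Constant columns collapse
    to a single bin with a warning-level note.
    """
    features = list(features or feature_columns(matrix))
    out = matrix.copy()
    sp = matrix["species"].astype(str)
    ord_cols = {}
    for f in features:
        v = out[f].astype(float)
        if any(f == lf or f.startswith(lf + "__") for lf in log_features):
            v = np.log1p(v.clip(lower=0.0))
        clipped = v.copy()
        ordv = pd.Series(np.nan, index=v.index)
        for s in sp.unique():
            mask = (sp == s).to_numpy()
            vals = v[mask]
            lo, hi = vals.quantile([truncate_q, 1.0 - truncate_q])
            clipped[mask] = vals.clip(lo, hi)
            ranked = vals.rank(pct=True, method="average")
            bins = np.ceil(ranked * n_bins).clip(1, n_bins)
            ordv[mask] = bins
        out[f] = clipped
        ord_cols[f"{f}__ord"] = ordv
    return pd.concat([out, pd.DataFrame(ord_cols, index=out.index)], axis=1)
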