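"""Trajectory reconstruction: raw collar fixes -> regular 1-min tracks.

Collar GPS data arrive irregularly (15/10/2-min adaptive schedule with
geofence suppressions) and carry substantial positional noise including
spike-shaped outliers. Reconstruction runs five steps:

1. gross-error filtering (out-of-area fixes, impossible speeds);
2. spike detection and correction (long in/out legs, small neighbor gap,
   near-180-degree turn; flagged points shifted toward the neighbor
   midpoint, the spikier the farther);
3. Kalman smoothing with a per-coordinate local-linear-trend dynamic
   linear model, variances estimated by maximum likelihood per track;
4. ODBA-informed densification to 10-s resolution, allocating displacement
   only to time slots in which the accelerometer says the animal moved;
5. weighted spline resampling onto a regular 60-s grid, observed fixes
   weighted higher than interpolated points.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import UnivariateSpline

from herdwatch.synthetic import RawSensorTrack

logger = logging.getLogger(__name__)


class EmptyTrackError(ValueError):
    """Raised when a processing stage is left with no usable fixes."""


@dataclass
class PreprocessConfig:
    bbox_inflation_m: float = 500.0
    speed_cap_ms: float = 30.0          # hard cap for the gross-error filter
    spike_leg_m: float = 500.0          # criterion (a): both legs longer
    spike_gap_m: float = 100.0          # criterion (b): neighbor gap smaller
    spike_turn_deg: float = 150.0       # criterion (c): turning angle larger
    spike_score_cap: float = 100.0
    kalman_var_floor: float = 1e-4
    kalman_mle_maxiter: int = 100
    odba_stationary_threshold: float = 0.17   # windowed mean ODBA below = at rest
    spline_weight_observed: float = 1.0
    spline_weight_interpolated: float = 0.3
    spline_residual_m: float = 2.0      # target RMS misfit at unit weight
    step_s: float = 60.0


@dataclass
class SpikeDiagnostic:
    index: int
    displacement_in_m: float
    displacement_out_m: float
    neighbor_gap_m: float
    turning_angle_rad: float
    spikiness: float
    shift_m: float


@dataclass
class RegularTrack:
    """Modelled trajectory on a strict 60-s grid with per-step ODBA stats."""

    animal_id: str
    species: str
    times: np.ndarray               # (n,) seconds, all == 0 mod step
    positions: np.ndarray           # (n, 2) m
    odba_mean: np.ndarray
    odba_max: np.ndarray
    odba_var: np.ndarray
    provenance: np.ndarray          # (n,) str: observed|corrected|interpolated

    @property
    def n(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "animal_id": self.animal_id,
            "species": self.species,
            "time": pd.to_datetime(self.times, unit="s", utc=True),
            "x": self.positions[:, 0],
            "y": self.positions[:, 1],
            "odba_mean": self.odba_mean,
            "odba_max": self.odba_max,
            "odba_var": self.odba_var,
            "provenance": self.provenance,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegularTrack":
        t = df["time"].astype("datetime64[ns, UTC]").astype("int64").to_numpy() / 1e9
        return cls(
            animal_id=str(df["animal_id"].iloc[0]),
            species=str(df["species"].iloc[0]),
            times=t,
            positions=df[["x", "y"]].to_numpy(float),
            odba_mean=df["odba_mean"].to_numpy(float),
            odba_max=df["odba_max"].to_numpy(float),
            odba_var=df["odba_var"].to_numpy(float),
            provenance=df["provenance"].to_numpy(str),
        )


# ---------------------------------------------------------------------------
# Step 1: gross errors
# ---------------------------------------------------------------------------


def filter_gross_errors(raw: RawSensorTrack, bbox,
                        config: PreprocessConfig | None = None) -> RawSensorTrack:
    """Drop fixes far outside the study area or implying impossible speeds."""
    config = config or PreprocessConfig()
    xmin, ymin, xmax, ymax = bbox
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("invalid bbox")
    m = config.bbox_inflation_m
    inside = ((raw.fixes[:, 0] >= xmin - m) & (raw.fixes[:, 0] <= xmax + m)
              & (raw.fixes[:, 1] >= ymin - m) & (raw.fixes[:, 1] <= ymax + m))
    t, p = raw.fix_times[inside], raw.fixes[inside]

    keep_idx = []
    for i in range(len(t)):
        if not keep_idx:
            keep_idx.append(i)
            continue
        j = keep_idx[-1]
        dt = t[i] - t[j]
        if dt <= 0:
            continue
        if np.linalg.norm(p[i] - p[j]) / dt <= config.speed_cap_ms:
            keep_idx.append(i)
    removed = raw.n_fixes - len(keep_idx)
    if removed:
        logger.info("filter_gross_errors: removed %d of %d fixes (%s)",
                    removed, raw.n_fixes, raw.animal_id)
    if not keep_idx:
        raise EmptyTrackError(f"all fixes removed for {raw.animal_id}")
    keep_idx = np.asarray(keep_idx)
    return dataclasses.replace(raw, fix_times=t[keep_idx], fixes=p[keep_idx])


# ---------------------------------------------------------------------------
# Step 2: spikes
# ---------------------------------------------------------------------------


def _turning_angle(p_prev, p, p_next) -> float:
    """Angle between incoming and outgoing directions (0 = straight on)."""
    v_in = p - p_prev
    v_out = p_next - p
    n1, n2 = np.linalg.norm(v_in), np.linalg.norm(v_out)
    if n1 == 0 or n2 == 0:
        return 0.0
    c = np.clip(np.dot(v_in, v_out) / (n1 * n2), -1.0, 1.0)
    return float(np.arccos(c))


def correct_spikes(raw: RawSensorTrack,
                   config: PreprocessConfig | None = None,
                   ) -> tuple[RawSensorTrack, list[SpikeDiagnostic]]:
    """Flag and correct spike outliers.

    A fix is a spike when (a) the displacements to and from it both exceed
    ``spike_leg_m``, (b) its neighbors are closer than ``spike_gap_m`` to
    each other, and (c) the turning angle at it exceeds ``spike_turn_deg``.
    Flagged fixes are shifted toward the midpoint of their neighbors; the
    shift fraction grows with a spikiness score (saturating in [0.5, 1)).
    The first and last fix have no two neighbors and are never flagged.
    Criteria are evaluated on the original coordinates.
    """
    config = config or PreprocessConfig()
    if raw.n_fixes < 3:
        return dataclasses.replace(raw), []
    p = raw.fixes
    out = p.copy()
    turn_thr = np.deg2rad(config.spike_turn_deg)
    diagnostics: list[SpikeDiagnostic] = []
    for i in range(1, raw.n_fixes - 1):
        leg_in = np.linalg.norm(p[i] - p[i - 1])
        leg_out = np.linalg.norm(p[i + 1] - p[i])
        gap = np.linalg.norm(p[i + 1] - p[i - 1])
        turn = _turning_angle(p[i - 1], p[i], p[i + 1])
        if (leg_in > config.spike_leg_m and leg_out > config.spike_leg_m
                and gap < config.spike_gap_m and turn > turn_thr):
            score = min((min(leg_in, leg_out) / max(gap, 1e-6))
                        / max(1.0 - turn / np.pi, 1e-6) / 100.0,
                        config.spike_score_cap)
            frac = 0.5 + 0.5 * (1.0 - np.exp(-score))
            mid = 0.5 * (p[i - 1] + p[i + 1])
            shifted = p[i] + frac * (mid - p[i])
            diagnostics.append(SpikeDiagnostic(
                index=i, displacement_in_m=float(leg_in),
                displacement_out_m=float(leg_out), neighbor_gap_m=float(gap),
                turning_angle_rad=turn, spikiness=float(score),
                shift_m=float(np.linalg.norm(shifted - p[i]))))
            out[i] = shifted
    return dataclasses.replace(raw, fixes=out), diagnostics


# ---------------------------------------------------------------------------
# Step 3: Kalman smoother
# ---------------------------------------------------------------------------


@numba.njit(cache=False, error_model="numpy")
def _kalman_core(t, z, q, r, smooth):
    """Local-linear-trend Kalman filter/smoother for one coordinate.

    State (position, velocity); exact irregular-interval transition
    F = [[1, dt], [0, 1]], process covariance q * [[dt^3/3, dt^2/2],
    [dt^2/2, dt]], observation variance r. Scalar-unrolled and jitted.
    Returns the log-likelihood and (if ``smooth``) RTS-smoothed positions.
    """
    n = len(z)
    # filter storages for smoothing pass
    xf1 = np.empty(n); xf2 = np.empty(n)
    Pf11 = np.empty(n); Pf12 = np.empty(n); Pf22 = np.empty(n)
    xp1 = np.empty(n); xp2 = np.empty(n)
    Pp11 = np.empty(n); Pp12 = np.empty(n); Pp22 = np.empty(n)

    x1, x2 = z[0], 0.0
    P11, P12, P22 = r + 1e4, 0.0, 10.0
    ll = 0.0
    for k in range(n):
        if k > 0:
            dt = t[k] - t[k - 1]
            x1 = x1 + dt * x2
            q11 = q * dt ** 3 / 3.0
            q12 = q * dt ** 2 / 2.0
            q22 = q * dt
            nP11 = P11 + dt * (P12 + P12) + dt * dt * P22 + q11
            nP12 = P12 + dt * P22 + q12
            nP22 = P22 + q22
            P11, P12, P22 = nP11, nP12, nP22
        xp1[k], xp2[k] = x1, x2
        Pp11[k], Pp12[k], Pp22[k] = P11, P12, P22
        # update with observation z[k] (H = [1, 0])
        S = P11 + r
        v = z[k] - x1
        ll += -0.5 * (np.log(2 * np.pi * S) + v * v / S)
        K1 = P11 / S
        K2 = P12 / S
        x1 = x1 + K1 * v
        x2 = x2 + K2 * v
        nP11 = (1 - K1) * P11
        nP12 = (1 - K1) * P12
        nP22 = P22 - K2 * P12
        P11, P12, P22 = nP11, nP12, nP22
        xf1[k], xf2[k] = x1, x2
        Pf11[k], Pf12[k], Pf22[k] = P11, P12, P22

    if not smooth:
        return ll, xf1

    xs1 = xf1.copy(); xs2 = xf2.copy()
    for k in range(n - 2, -1, -1):
        dt = t[k + 1] - t[k]
        # predicted covariance at k+1 and cross term C = Pf[k] @ F'
        C11 = Pf11[k] + dt * Pf12[k]
        C12 = Pf12[k]
        C21 = Pf12[k] + dt * Pf22[k]
        C22 = Pf22[k]
        det = Pp11[k + 1] * Pp22[k + 1] - Pp12[k + 1] ** 2
        if det <= 0:
            continue
        i11 = Pp22[k + 1] / det
        i12 = -Pp12[k + 1] / det
        i22 = Pp11[k + 1] / det
        G11 = C11 * i11 + C12 * i12
        G12 = C11 * i12 + C12 * i22
        G21 = C21 * i11 + C22 * i12
        G22 = C21 * i12 + C22 * i22
        d1 = xs1[k + 1] - xp1[k + 1]
        d2 = xs2[k + 1] - xp2[k + 1]
        xs1[k] = xf1[k] + G11 * d1 + G12 * d2
        xs2[k] = xf2[k] + G21 * d1 + G22 * d2
    return ll, xs1


def _kalman_loglik_and_smooth(t, z, q, r, smooth=False):
    ll, xs = _kalman_core(np.ascontiguousarray(t, dtype=np.float64),
                          np.ascontiguousarray(z, dtype=np.float64),
                          float(q), float(r), bool(smooth))
    return ll, (xs if smooth else None)


def kalman_smooth(raw: RawSensorTrack,
                  config: PreprocessConfig | None = None) -> RawSensorTrack:
    """Two-sided Kalman (RTS) smoothing of fix coordinates.

    Process and observation variances are shared between x and y and
    estimated per track by maximizing the joint Gaussian likelihood
    (Nelder-Mead on log variances). Degenerate estimates fall back to a
    configured floor with a warning.
    """
    config = config or PreprocessConfig()
    if raw.n_fixes < 4:
        raise ValueError("kalman_smooth needs >= 4 fixes")
    t = raw.fix_times
    zx, zy = raw.fixes[:, 0], raw.fixes[:, 1]

    def nll(params):
        q = np.exp(params[0])
        r = np.exp(params[1])
        llx, _ = _kalman_loglik_and_smooth(t, zx, q, r)
        lly, _ = _kalman_loglik_and_smooth(t, zy, q, r)
        return -(llx + lly)

    # moment-based starting point: observation var from fix scatter scale
    step_sd = np.std(np.diff(raw.fixes, axis=0)) + 1e-3
    x0 = np.array([np.log(1e-3), np.log(max(step_sd ** 2 / 2, 1.0))])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": config.kalman_mle_maxiter,
                                     "xatol": 0.02, "fatol": 0.05})
    q = float(np.exp(res.x[0]))
    r = float(np.exp(res.x[1]))
    if not np.isfinite(q) or q <= 0 or not np.isfinite(r) or r <= 0:
        logger.warning("kalman_smooth: degenerate variance estimate on %s; "
                       "using floor", raw.animal_id)
        q = max(q, config.kalman_var_floor)
        r = max(r, config.kalman_var_floor)
    q = max(q, config.kalman_var_floor * 1e-3)
    r = max(r, config.kalman_var_floor)
    _, sx = _kalman_loglik_and_smooth(t, zx, q, r, smooth=True)
    _, sy = _kalman_loglik_and_smooth(t, zy, q, r, smooth=True)
    return dataclasses.replace(raw, fixes=np.stack([sx, sy], axis=1))


# ---------------------------------------------------------------------------
# Step 4: ODBA-informed densification
# ---------------------------------------------------------------------------


@dataclass
class DensifiedTrack:
    """10-s resolution positions with per-point provenance (step-4 output)."""

    animal_id: str
    species: str
    times: np.ndarray
    positions: np.ndarray
    observed: np.ndarray            # bool: original fix vs interpolated
    odba_windows: pd.DataFrame


def _window_activity(odba_windows: pd.DataFrame, t0: float, t1: float,
                     threshold: float):
    """Mean ODBA per 15-s window overlapping [t0, t1); None if no coverage."""
    w = odba_windows
    if len(w) == 0:
        return None
    sel = w[(w["window_start"] < t1) & (w["window_start"] + 15.0 > t0)]
    if len(sel) == 0:
        return None
    return sel["mean"].to_numpy()


def odba_interpolate(raw: RawSensorTrack,
                     config: PreprocessConfig | None = None,
                     resolution_s: float = 10.0) -> DensifiedTrack:
    """Densify fixes to 10-s resolution guided by accelerometer activity.

    Within each inter-fix gap, the displacement is distributed uniformly
    over the 10-s slots whose windowed mean ODBA exceeds the stationarity
    threshold; slots below it repeat the previous position (the animal is
    taken to be standing still). Gaps without ODBA coverage fall back to
    plain linear interpolation and are flagged in the log.
    """
    config = config or PreprocessConfig()
    t, p = raw.fix_times, raw.fixes
    if len(t) == 0:
        return DensifiedTrack(raw.animal_id, raw.species, np.empty(0),
                              np.empty((0, 2)), np.empty(0, dtype=bool),
                              raw.odba_windows)
    times = [t[0]]
    positions = [p[0]]
    observed = [True]
    w = raw.odba_windows
    w_start = w["window_start"].to_numpy() if len(w) else np.empty(0)
    w_mean = w["mean"].to_numpy() if len(w) else np.empty(0)

    for i in range(1, len(t)):
        t0, t1 = t[i - 1], t[i]
        slot_starts = np.arange(t0, t1, resolution_s)[1:]  # interior slots
        if len(slot_starts):
            if len(w_start):
                wi = np.clip(np.searchsorted(w_start, slot_starts, side="right") - 1,
                             0, len(w_start) - 1)
                covered = (slot_starts >= w_start[wi]) & (slot_starts < w_start[wi] + 15.0)
            else:
                covered = np.zeros(len(slot_starts), dtype=bool)
            if covered.all():
                act = w_mean[wi] > config.odba_stationary_threshold
                # displacement also accrues on the final (slot -> fix) leg,
                # treated as an active slot terminating at the observed fix
                weights = np.concatenate([act.astype(float), [1.0]])
            else:
                logger.debug("odba_interpolate: missing ODBA in gap %.0f-%.0f (%s); "
                             "linear fallback", t0, t1, raw.animal_id)
                weights = np.ones(len(slot_starts) + 1)
            cum = np.cumsum(weights)
            frac = cum / cum[-1]
            delta = p[i] - p[i - 1]
            for k, ts in enumerate(slot_starts):
                times.append(ts)
                positions.append(p[i - 1] + frac[k] * delta)
                observed.append(False)
        times.append(t1)
        positions.append(p[i])
        observed.append(True)
    return DensifiedTrack(raw.animal_id, raw.species,
                          np.asarray(times, dtype=float),
                          np.asarray(positions, dtype=float),
                          np.asarray(observed, dtype=bool),
                          raw.odba_windows)


# ---------------------------------------------------------------------------
# Step 5: spline resampling to the regular grid
# ---------------------------------------------------------------------------


def xspline_resample(dense: DensifiedTrack,
                     config: PreprocessConfig | None = None) -> RegularTrack:
    """Fit a weighted smoothing spline and sample it on the 60-s grid.

    Observed fixes get weight 1.0 and ODBA-interpolated points 0.3, so the
    curve tracks the measurements and treats interpolated points as soft
    guidance. Per-step ODBA statistics are averaged from the 15-s windows
    falling inside each 60-s step.
    """
    config = config or PreprocessConfig()
    if len(dense.times) < 4:
        raise ValueError("xspline_resample needs >= 4 points")
    t = dense.times
    if t[-1] - t[0] < 2 * config.step_s:
        raise ValueError("coverage shorter than two steps")
    # strictly increasing guard
    keep = np.concatenate([[True], np.diff(t) > 0])
    t = t[keep]
    xy = dense.positions[keep]
    obs = dense.observed[keep]
    w = np.where(obs, config.spline_weight_observed,
                 config.spline_weight_interpolated)

    step = config.step_s
    g0 = np.ceil(t[0] / step) * step
    g1 = np.floor(t[-1] / step) * step
    grid = np.arange(g0, g1 + 0.5 * step, step)

    s = float(np.sum(w)) * config.spline_residual_m ** 2
    out = np.empty((len(grid), 2))
    for dim in range(2):
        k = min(3, len(t) - 1)
        spl = UnivariateSpline(t, xy[:, dim], w=w, k=k, s=s)
        out[:, dim] = spl(grid)

    # per-step ODBA stats from 15-s windows inside (grid_k - step, grid_k]
    n = len(grid)
    om = np.zeros(n); ox = np.zeros(n); ov = np.zeros(n)
    ww = dense.odba_windows
    if len(ww):
        ws = ww["window_start"].to_numpy()
        for k_i, gt in enumerate(grid):
            sel = (ws > gt - step - 7.5) & (ws <= gt)
            if sel.any():
                om[k_i] = ww["mean"].to_numpy()[sel].mean()
                ox[k_i] = ww["max"].to_numpy()[sel].max()
                ov[k_i] = ww["variance"].to_numpy()[sel].mean()
            elif k_i > 0:
                om[k_i], ox[k_i], ov[k_i] = om[k_i - 1], ox[k_i - 1], ov[k_i - 1]

    # provenance: nearest densified point
    idx = np.clip(np.searchsorted(t, grid), 0, len(t) - 1)
    near_obs = obs[idx]
    provenance = np.where(near_obs, "observed", "interpolated")
    return RegularTrack(dense.animal_id, dense.species, grid, out,
                        om, ox, ov, np.asarray(provenance, dtype=object))


def preprocess_track(raw: RawSensorTrack, bbox,
                     config: PreprocessConfig | None = None) -> RegularTrack:
    """Full five-step reconstruction of one sensor track."""
    config = config or PreprocessConfig()
    cleaned = filter_gross_errors(raw, bbox, config)
    corrected, diags = correct_spikes(cleaned, config)
    smoothed = kalman_smooth(corrected, config)
    dense = odba_interpolate(smoothed, config)
    track = xspline_resample(dense, config)
    if diags:
        corrected_idx = {d.index for d in diags}
        fix_t = corrected.fix_times[sorted(corrected_idx)]
        mark = np.isin(np.round(track.times / 60), np.round(fix_t / 60))
        track.provenance[mark & (track.provenance == "observed")] = "corrected"
    return track
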