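"""Intruder localization from sentinel positions, headings and response odds.

For every grid cell *i* of the study-area bounding box and every sentinel
*j*, an odds ratio O_ij compares the likelihood of the observed sentinel
geometry (direction from cell to animal, distance from cell to animal)
under "an intruder is at cell i" against the null geometry of undisturbed
periods. The directional component is a wrapped normal density around the
animal's movement direction; the radial component a lognormal density on
the cell-to-animal distance. The response-state geometry parameters evolve
with t_s — the minutes since the onset of the animal's predicted response,
truncated at 45 min — through 3rd-order polynomials; null parameters are
constants estimated from control periods against randomly placed
hypothetical intruders (correcting for study-area geometry).

The intrusion probability surface is the normalized cellwise sum
P_i = alpha * sum_j O_ij, integrating to 1 over the bounding box.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TS_MAX_MIN = 45.0


def wrapped_normal_pdf(angle, mean, sd_unwrapped, n_wraps: int = 10):
    """Wrapped normal density on the circle.

    ``sd_unwrapped`` is the standard deviation of the underlying (unwrapped)
    normal. The infinite wrap sum is truncated adaptively: at least
    ``n_wraps`` terms each side, more when the sd is large, keeping the
    truncation error far below 1e-9 for any sd.
    """
    if sd_unwrapped <= 0:
        raise ValueError("sd_unwrapped must be > 0")
    angle = np.asarray(angle, dtype=float)
    k_max = max(int(n_wraps), int(np.ceil(6.0 * sd_unwrapped / (2 * np.pi))) + 2)
    dev = angle - mean
    out = np.zeros_like(dev)
    norm = 1.0 / (sd_unwrapped * np.sqrt(2 * np.pi))
    for k in range(-k_max, k_max + 1):
        out += np.exp(-0.5 * ((dev + 2 * np.pi * k) / sd_unwrapped) ** 2)
    return norm * out


def lognormal_pdf(x, log_mean, log_sd):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = (np.exp(-0.5 * ((np.log(x[pos]) - log_mean) / log_sd) ** 2)
                / (x[pos] * log_sd * np.sqrt(2 * np.pi)))
    return out


@dataclass
class GeometryParams:
    """Intrusion-sentinel geometry: response polynomials + null constants.

    ``mu1_poly``, ``log_sigma1_poly`` and ``log_rho1_poly`` are polynomial
    coefficient arrays (highest order first, numpy convention, order 3 by
    default) in t_s minutes; ``mu0``/``sigma0``/``rho0`` are the null
    constants. sigma and rho are stored on log scale in the polynomials so
    the inverse transform keeps them positive.
    """

    mu1_poly: np.ndarray
    log_sigma1_poly: np.ndarray
    log_rho1_poly: np.ndarray
    mu0: float
    sigma0: float
    rho0: float
    ts_max_min: float = TS_MAX_MIN

    def clamp_ts(self, ts_min):
        return np.clip(ts_min, 0.0, self.ts_max_min)

    def mu1(self, ts_min):
        return np.polyval(self.mu1_poly, self.clamp_ts(ts_min))

    def sigma1(self, ts_min):
        return np.exp(np.polyval(self.log_sigma1_poly, self.clamp_ts(ts_min)))

    def rho1(self, ts_min):
        return np.exp(np.polyval(self.log_rho1_poly, self.clamp_ts(ts_min)))

    @classmethod
    def constant(cls, mu1, sigma1, rho1, mu0, sigma0, rho0) -> "GeometryParams":
        """Convenience: t_s-independent response geometry."""
        z = np.zeros(3)
        return cls(np.append(z, mu1), np.append(z, np.log(sigma1)),
                   np.append(z, np.log(rho1)), mu0, sigma0, rho0)


@dataclass
class SentinelSnapshot:
    """State of the sentinel network at one instant.

    Animals without a defined movement direction (not moving) are excluded
    before constructing the snapshot.
    """

    positions: np.ndarray       # (n, 2) m
    headings: np.ndarray        # (n,) rad, movement direction mu_j
    probs: np.ndarray           # (n,) response probability p_j in [0, 1]
    ts_min: np.ndarray          # (n,) minutes since predicted response onset
    time: float = 0.0
    animal_ids: list = field(default_factory=list)

    def __post_init__(self):
        n = len(self.positions)
        if not (len(self.headings) == len(self.probs) == len(self.ts_min) == n):
            raise ValueError("snapshot arrays must share length")
        if np.any((self.probs < 0) | (self.probs > 1)):
            raise ValueError("response probabilities must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.positions)


@dataclass
class ProbabilitySurface:
    """Normalized gridded intruder-location probability density."""

    origin: tuple[float, float]
    cell_size: float
    density: np.ndarray          # (ny, nx), row 0 at the south edge
    alpha: float
    time: float = 0.0

    def integral(self) -> float:
        return float(self.density.sum() * self.cell_size ** 2)

    @property
    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.density.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys

    def peak(self) -> np.ndarray:
        """Coordinates of the maximum-probability cell center."""
        if np.allclose(self.density, self.density.flat[0]):
            raise ValueError("flat surface: peak undefined")
        r, c = np.unravel_index(np.argmax(self.density), self.density.shape)
        xs, ys = self.cell_centers
        return np.array([xs[c], ys[r]])

    def condensation_area(self, top_fraction: float = 0.05) -> float:
        """Smallest area (m^2) containing ``top_fraction`` of the mass.

        Cells are accumulated in decreasing density order until the target
        mass is reached; smaller areas indicate more confident surfaces.
        """
        mass = np.sort(self.density.ravel())[::-1] * self.cell_size ** 2
        cum = np.cumsum(mass)
        k = int(np.searchsorted(cum, top_fraction)) + 1
        return k * self.cell_size ** 2


def odds_surface(cell_xy: np.ndarray, position_j, heading_j: float, p_j: float,
                 ts_j_min: float, params: GeometryParams,
                 numerator: str = "mixture",
                 odds_ceiling: float = 1e12) -> np.ndarray:
    """Odds ratio O_ij of intruder presence at each cell, for one sentinel.

    ``cell_xy`` is (..., 2) cell-center coordinates. The numerator is the
    response-probability mixture of the response-state joint density
    (wrapped normal around the animal heading with sd rho1(t_s); lognormal
    distance with mu1(t_s)/sigma1(t_s)) and the null joint density; the
    denominator is the null joint density. ``numerator="product"`` instead
    multiplies the two weighted terms (the printed-formula reading, kept
    for comparison). Cells where the null density underflows get a
    configured ceiling.
    """
    cell_xy = np.asarray(cell_xy, dtype=float)
    d = np.asarray(position_j, dtype=float) - cell_xy
    gamma = np.linalg.norm(d, axis=-1)
    theta = np.arctan2(d[..., 1], d[..., 0])

    ts = float(np.clip(ts_j_min, 0.0, params.ts_max_min))
    f_dir_1 = wrapped_normal_pdf(theta, heading_j, float(params.rho1(ts)))
    f_dist_1 = lognormal_pdf(gamma, float(params.mu1(ts)), float(params.sigma1(ts)))
    f_dir_0 = wrapped_normal_pdf(theta, heading_j, params.rho0)
    f_dist_0 = lognormal_pdf(gamma, params.mu0, params.sigma0)

    null = f_dir_0 * f_dist_0
    resp = f_dir_1 * f_dist_1
    if numerator == "mixture":
        num = p_j * resp + (1.0 - p_j) * null
    elif numerator == "product":
        num = (p_j * resp) * ((1.0 - p_j) * null)
    else:
        raise ValueError("numerator must be 'mixture' or 'product'")
    with np.errstate(divide="ignore", invalid="ignore"):
        o = num / null
    o = np.where(null > 0, o, odds_ceiling)
    return np.minimum(o, odds_ceiling)


def probability_surface(snapshot: SentinelSnapshot, params: GeometryParams,
                        bbox, cell_m: float = 50.0,
                        numerator: str = "mixture") -> ProbabilitySurface:
    """P_i = alpha * sum_j O_ij on a regular grid over the bounding box."""
    if snapshot.n < 1:
        raise ValueError("need at least one sentinel in the snapshot")
    xmin, ymin, xmax, ymax = bbox
    nx = max(int(np.ceil((xmax - xmin) / cell_m)), 1)
    ny = max(int(np.ceil((ymax - ymin) / cell_m)), 1)
    xs = xmin + (np.arange(nx) + 0.5) * cell_m
    ys = ymin + (np.arange(ny) + 0.5) * cell_m
    gx, gy = np.meshgrid(xs, ys)
    cells = np.stack([gx, gy], axis=-1)

    total = np.zeros((ny, nx))
    for j in range(snapshot.n):
        total += odds_surface(cells, snapshot.positions[j],
                              float(snapshot.headings[j]),
                              float(snapshot.probs[j]),
                              float(snapshot.ts_min[j]), params,
                              numerator=numerator)
    mass = total.sum() * cell_m ** 2
    alpha = 1.0 / mass if mass > 0 else 0.0
    return ProbabilitySurface(origin=(xmin, ymin), cell_size=cell_m,
                              density=total * alpha, alpha=alpha,
                              time=snapshot.time)


# ---------------------------------------------------------------------------
# Geometry fitting
# ---------------------------------------------------------------------------


def _circular_sd(rel_angles: np.ndarray) -> float:
    """Unwrapped-normal sd from the mean resultant length (wrapped-normal MLE)."""
    r = np.abs(np.mean(np.exp(1j * rel_angles)))
    r = min(max(r, 1e-12), 1.0 - 1e-12)
    return float(np.sqrt(-2.0 * np.log(r)))


def fit_geometry(observations: pd.DataFrame, poly_order: int = 3,
                 ts_bin_min: float = 5.0, min_per_bin: int = 8,
                 ts_max_min: float = TS_MAX_MIN) -> GeometryParams:
    """Fit GeometryParams from intruder-relative sentinel observations.

    ``observations`` needs columns ``distance_m`` (cell/intruder-to-animal
    distance), ``rel_angle`` (direction-to-animal minus animal heading,
    wrapped to (-pi, pi]), ``ts_min`` and boolean ``response``. Response
    rows are binned on t_s; each bin yields lognormal MLEs (mean/sd of log
    distance) and the wrapped-normal sd from the mean resultant length;
    polynomials of ``poly_order`` are then fitted through the per-bin
    estimates (bins with fewer than ``min_per_bin`` rows are pooled into
    their left neighbor). Null parameters are pooled constants over the
    non-response rows.
    """
    resp = observations[observations["response"]]
    ctrl = observations[~observations["response"]]
    if len(resp) < min_per_bin or len(ctrl) < min_per_bin:
        raise ValueError("not enough response/control observations")

    mu0 = float(np.mean(np.log(ctrl["distance_m"])))
    sigma0 = float(np.std(np.log(ctrl["distance_m"]), ddof=1))
    rho0 = _circular_sd(ctrl["rel_angle"].to_numpy())

    ts = np.clip(resp["ts_min"].to_numpy(float), 0.0, ts_max_min)
    edges = np.arange(0.0, ts_max_min + ts_bin_min, ts_bin_min)
    which = np.clip(np.digitize(ts, edges) - 1, 0, len(edges) - 2)

    centers, mu1s, lsig1s, lrho1s, weights = [], [], [], [], []
    pending_idx = np.empty(0, dtype=int)
    for b in range(len(edges) - 1):
        idx = np.flatnonzero(which == b)
        idx = np.concatenate([pending_idx, idx])
        if len(idx) < min_per_bin:
            pending_idx = idx  # pool into the next bin
            continue
        pending_idx = np.empty(0, dtype=int)
        d = resp["distance_m"].to_numpy()[idx]
        a = resp["rel_angle"].to_numpy()[idx]
        centers.append(float(np.mean(ts[idx])))
        mu1s.append(float(np.mean(np.log(d))))
        lsig1s.append(float(np.log(max(np.std(np.log(d), ddof=1), 1e-6))))
        lrho1s.append(float(np.log(max(_circular_sd(a), 1e-6))))
        weights.append(len(idx))
    if len(pending_idx) >= min_per_bin // 2 and centers:
        d = resp["distance_m"].to_numpy()[pending_idx]
        a = resp["rel_angle"].to_numpy()[pending_idx]
        centers.append(float(np.mean(ts[pending_idx])))
        mu1s.append(float(np.mean(np.log(d))))
        lsig1s.append(float(np.log(max(np.std(np.log(d), ddof=1), 1e-6))))
        lrho1s.append(float(np.log(max(_circular_sd(a), 1e-6))))
        weights.append(len(pending_idx))
    if not centers:
        raise ValueError("no t_s bin reached the minimum row count")

    order = min(poly_order, len(centers) - 1)
    c = np.asarray(centers)
    wts = np.sqrt(np.asarray(weights, dtype=float))
    mu1_poly = np.polyfit(c, mu1s, order, w=wts)
    lsig1_poly = np.polyfit(c, lsig1s, order, w=wts)
    lrho1_poly = np.polyfit(c, lrho1s, order, w=wts)

    def _pad(p):
        return np.concatenate([np.zeros(poly_order + 1 - len(p)), p])

    return GeometryParams(_pad(mu1_poly), _pad(lsig1_poly), _pad(lrho1_poly),
                          mu0=mu0, sigma0=sigma0, rho0=rho0,
                          ts_max_min=ts_max_min)


def make_null_observations(positions: np.ndarray, headings: np.ndarray,
                           bbox, rng: np.random.Generator,
                           n_random_intruders: int = 20) -> pd.DataFrame:
    """Control observations against randomly placed hypothetical intruders.

    Pairs every control sentinel state with uniformly drawn intruder
    locations inside the bounding box; this bakes the study-area geometry
    into the null distance/direction distributions.
    """
    xmin, ymin, xmax, ymax = bbox
    rows = []
    for _ in range(n_random_intruders):
        q = np.array([rng.uniform(xmin, xmax), rng.uniform(ymin, ymax)])
        d = positions - q
        dist = np.linalg.norm(d, axis=1)
        theta = np.arctan2(d[:, 1], d[:, 0])
        rel = np.angle(np.exp(1j * (theta - headings)))
        for k in range(len(positions)):
            rows.append({"distance_m": dist[k], "rel_angle": rel[k],
                         "ts_min": 0.0, "response": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def evaluate_localization(surfaces_by_intrusion: dict,
                          truths_by_intrusion: dict,
                          n_select: int = 10,
                          thresholds_m=(100.0, 300.0, 500.0)) -> dict:
    """Localization-error summary over intrusions.

    For each intrusion, the ``n_select`` surfaces with the smallest
    top-5%-mass area (most condensed) are kept; the spatial error is the
    mean Euclidean distance between each kept surface's peak and the true
    intruder position at that surface's time. If an intrusion has fewer
    surfaces than ``n_select``, all are used and the intrusion is flagged.
    Also reports, over intrusions, the fraction whose mean error falls
    within each threshold distance.
    """
    per_intrusion = []
    for iid, surfaces in surfaces_by_intrusion.items():
        truth = truths_by_intrusion[iid]
        flagged = len(surfaces) < n_select
        ranked = sorted(surfaces, key=lambda s: s.condensation_area())
        chosen = ranked[:n_select]
        errs = []
        for s in chosen:
            try:
                pk = s.peak()
            except ValueError:
                continue
            tp = truth(s.time) if callable(truth) else np.asarray(truth)
            errs.append(float(np.linalg.norm(pk - tp)))
        if not errs:
            continue
        per_intrusion.append({"intrusion_id": iid,
                              "mean_error_m": float(np.mean(errs)),
                              "n_surfaces": len(chosen),
                              "flagged_few_surfaces": flagged})
    table = pd.DataFrame(per_intrusion)
    out = {"per_intrusion": table}
    if len(table):
        for thr in thresholds_m:
            out[f"fraction_within_{int(thr)}m"] = float(
                (table["mean_error_m"] <= thr).mean())
        out["mean_error_m"] = float(table["mean_error_m"].mean())
    return out
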