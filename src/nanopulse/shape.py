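"""Ellipsoid electrical shape-factor model and per-event shape/volume fits.

A protein is modelled as an ellipsoid of revolution with semiaxes
``(a, a, b)`` and axis ratio ``m = b/a`` (``m < 1`` oblate, ``m > 1``
prolate). Inside the pore its excluded volume V perturbs the resistance by a
factor gamma that depends on the angle theta between the symmetry axis and
the pore axis:

    gamma(theta) = gamma_perp + (gamma_par - gamma_perp) cos^2(theta)

with ``gamma_par = 1/(1 - L_par)``, ``gamma_perp = 1/(1 - L_perp)`` and
``L_perp = (1 - L_par)/2``, where ``L_par`` is the depolarization factor
along the symmetry axis. The blockade follows the Maxwell relation

    dI = I0 * gamma * V / V_eff,   V_eff = (pi/4) d^2 (l + 0.8 d)

for a cylindrical pore of diameter d and length l (the 0.8 d term is the
access-resistance correction to the effective length). As the molecule
tumbles, gamma sweeps the interval between gamma_perp and gamma_par, so the
intraevent current histogram spans [dI_min, dI_max]; the ratio
|dI_max| / |dI_min| determines m and either extreme then yields V.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq, least_squares
from scipy.stats import norm

SPHERE_GAMMA = 1.5


def depolarization(m: float) -> float:
    """Depolarization factor along the symmetry axis of an ellipsoid of
    revolution with axis ratio ``m = b/a`` (continuous in m; 1/3 at m = 1)."""
    if m <= 0:
        raise ValueError("m must be positive")
    if abs(m - 1.0) < 1e-9:
        return 1.0 / 3.0
    if m > 1.0:  # prolate
        e = math.sqrt(1.0 - 1.0 / (m * m))
        return (1.0 - e * e) / e**3 * (math.atanh(e) - e)
    # oblate: polar (short) axis
    e = math.sqrt(1.0 - m * m)
    return (e - math.sqrt(1.0 - e * e) * math.asin(e)) / e**3


def shape_factor_extremes(m: float) -> tuple[float, float]:
    """(gamma_par, gamma_perp) for axis ratio m."""
    L_par = depolarization(m)
    L_perp = (1.0 - L_par) / 2.0
    return 1.0 / (1.0 - L_par), 1.0 / (1.0 - L_perp)


def shape_factor(m: float, theta: float) -> float:
    """Orientation-dependent electrical shape factor gamma(m, theta)."""
    if not 0.0 <= theta <= math.pi / 2.0 + 1e-12:
        raise ValueError("theta must lie in [0, pi/2]")
    g_par, g_perp = shape_factor_extremes(m)
    c = math.cos(theta)
    return g_perp + (g_par - g_perp) * c * c


def effective_pore_volume(diameter_nm: float, length_nm: float) -> float:
    """V_eff = (pi/4) d^2 (l + 0.8 d), nm^3."""
    return math.pi / 4.0 * diameter_nm**2 * (length_nm + 0.8 * diameter_nm)


def blockade(gamma: float, volume_nm3: float, pore, i0: float) -> float:
    """Current blockade dI = I0 * gamma * V / V_eff (pA, same sign as I0)."""
    v_eff = effective_pore_volume(pore.diameter, pore.length)
    d_i = i0 * gamma * volume_nm3 / v_eff
    if abs(d_i) >= abs(i0):
        raise ValueError("blockade exceeds the open-pore current")
    return d_i


# ---------------------------------------------------------------------------
# intraevent blockade distribution
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = leggauss(64)
_GL_C = 0.5 * (_GL_NODES + 1.0)  # cos(theta) ~ U(0, 1) on a sphere
_GL_W = 0.5 * _GL_WEIGHTS

# probability grid for stored quantiles of the band-limited orientation factor
_OQ_PROBS = (np.arange(2048) + 0.5) / 2048.0
# equal-weight mid-probabilities for noise convolution
_MIX_PROBS = (np.arange(64) + 0.5) / 64.0

_OQ_CACHE: dict = {}


def filtered_orientation_quantiles(
    rot_diffusion: float,
    fs: float,
    fc: float,
    n_samples: int = 1 << 19,
    seed: int = 1234,
) -> np.ndarray:
    """Quantiles of the band-limited orientation factor u = cos^2(theta).

    The recorded current is low-pass filtered, so the observable intraevent
    distribution is that of the *filtered* orientation process, not of the
    instantaneous one; ignoring this biases the fitted axis ratio toward the
    sphere. The filtered distribution has no closed form but depends only on
    the dimensionless pair (rot_diffusion/fs, fc/fs), so it is computed once
    per acquisition configuration by simulating a long rotational Brownian
    walk, filtering it with the same Gaussian kernel as the data path, and
    tabulating 2048 evenly spaced quantiles (cached).

    Returns the quantile array aligned with an implicit probability grid
    ``(i + 0.5)/2048``; pass it to :func:`fit_event` via
    ``orientation_quantiles``.
    """
    key = (round(float(rot_diffusion), 6), round(float(fs), 6), round(float(fc), 6),
           int(n_samples), int(seed))
    cached = _OQ_CACHE.get(key)
    if cached is not None:
        return cached
    from .simulate import orientation_walk
    from .streaming import gaussian_lowpass

    theta = orientation_walk(rot_diffusion, n_samples, 1.0 / fs, seed=seed)
    u = np.cos(theta) ** 2
    u_f = gaussian_lowpass(u, fc, fs)
    trim = 64  # discard edge-padded filter transients
    u_f = np.sort(u_f[trim:-trim])
    q = np.quantile(u_f, _OQ_PROBS)
    _OQ_CACHE[key] = q
    return q


def _orientation_cdf(
    y: np.ndarray,
    lo: float,
    hi: float,
    noise_sd: float,
    oblate: bool,
    quantiles: Optional[np.ndarray] = None,
) -> np.ndarray:
    """CDF of |dI| for a tumbling ellipsoid, blockade magnitudes spanning
    [lo, hi], Gaussian noise of sd ``noise_sd`` added per sample.

    With c = cos(theta) uniform on [0, 1], the noise-free magnitude is
    ``lo + (hi - lo) c^2`` on the oblate branch (common orientations at the
    small extreme) and ``hi - (hi - lo) c^2`` on the prolate branch. When
    ``quantiles`` (from :func:`filtered_orientation_quantiles`) is given, the
    band-limited orientation distribution replaces the instantaneous one.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    width = max(hi - lo, 1e-300)
    if quantiles is not None:
        u_q = quantiles if oblate else 1.0 - quantiles[::-1]
        if noise_sd <= 0:
            u = (y - lo) / width
            return np.interp(u, u_q, _OQ_PROBS, left=0.0, right=1.0)
        mix = np.interp(_MIX_PROBS, _OQ_PROBS, u_q)
        centers = lo + width * mix
        z = (y[:, None] - centers[None, :]) / noise_sd
        return norm.cdf(z).mean(axis=1)
    if noise_sd <= 0:
        # exact change-of-variables CDF, c = sqrt((y - lo)/(hi - lo))
        u = np.clip((y - lo) / width, 0.0, 1.0)
        return np.sqrt(u) if oblate else 1.0 - np.sqrt(1.0 - u)
    if oblate:
        centers = lo + (hi - lo) * _GL_C**2
    else:
        centers = hi - (hi - lo) * _GL_C**2
    z = (y[:, None] - centers[None, :]) / noise_sd
    return norm.cdf(z) @ _GL_W


def intraevent_pdf(
    m: float,
    volume_nm3: float,
    pore,
    i0: float,
    noise_sd: float,
    grid: Optional[np.ndarray] = None,
    orientation_quantiles: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Density of the intraevent blockade magnitude |dI| (pA).

    Pushforward of the uniform-orientation measure (sin(theta) on [0, pi/2])
    through gamma(theta) -> dI, convolved with the per-sample Gaussian noise;
    pass ``orientation_quantiles`` to use the band-limited orientation
    distribution instead of the instantaneous one.
    Returns ``(grid, density)`` with the density integrating to one.
    """
    g_par, g_perp = shape_factor_extremes(m)
    g_lo, g_hi = min(g_par, g_perp), max(g_par, g_perp)
    v_eff = effective_pore_volume(pore.diameter, pore.length)
    k = abs(i0) * volume_nm3 / v_eff
    lo, hi = k * g_lo, k * g_hi
    oblate = m < 1.0
    if grid is None:
        pad = max(5.0 * noise_sd, 0.05 * (hi - lo) + 1e-9)
        grid = np.linspace(lo - pad, hi + pad, 2001)
    cdf = _orientation_cdf(grid, lo, hi, noise_sd, oblate, orientation_quantiles)
    pdf = np.gradient(cdf, grid)
    return grid, pdf


# ---------------------------------------------------------------------------
# per-event fit
# ---------------------------------------------------------------------------


def _ratio_to_m(ratio: float, branch: str) -> float:
    """Invert gamma_max/gamma_min = ratio on the oblate or prolate branch."""
    if ratio < 1.0:
        raise ValueError("ratio must be >= 1")
    if ratio < 1.0 + 1e-9:
        return 1.0

    if branch == "oblate":
        def f(m: float) -> float:
            g_par, g_perp = shape_factor_extremes(m)
            return g_par / g_perp - ratio
        lo_m, hi_m = 1e-4, 1.0 - 1e-9
    elif branch == "prolate":
        def f(m: float) -> float:
            g_par, g_perp = shape_factor_extremes(m)
            return g_perp / g_par - ratio
        lo_m, hi_m = 1.0 + 1e-9, 1e4
    else:
        raise ValueError("branch must be 'oblate' or 'prolate'")
    f_lo, f_hi = f(lo_m), f(hi_m)
    if branch == "oblate" and f_lo < 0:
        return lo_m  # ratio beyond the representable range
    if branch == "prolate" and f_hi < 0:
        return hi_m
    return float(brentq(f, lo_m, hi_m, xtol=1e-12, rtol=1e-12))


@dataclass
class EventShapeEstimate:
    i_min_fit: float
    i_max_fit: float
    m_hat: float
    v_hat: float
    branch: str
    fit_residual: float
    converged: bool = True


def fit_event(
    samples: Sequence[float],
    noise_sd: float,
    pore,
    i0: float,
    min_samples: int = 10,
    orientation_quantiles: Optional[np.ndarray] = None,
) -> EventShapeEstimate:
    """Estimate (m, V) for one event from its intraevent blockade samples.

    ``samples`` are blockade magnitudes ``|I - I0|`` in pA. The empirical CDF
    is least-squares fitted to the tumbling-ellipsoid CDF (noise sd held
    fixed at the baseline value) over the two endpoints ``(|dI|min, |dI|max)``
    on both branches; the branch with the lower residual wins (the oblate
    density is singular at the small extreme, the prolate at the large one,
    so skew separates them). The endpoint ratio then gives m by a monotone
    1-D root find and the small extreme gives V.

    Pass ``orientation_quantiles`` (see
    :func:`filtered_orientation_quantiles`) when the recording bandwidth is
    known; it corrects the sphere-ward bias caused by low-pass filtering of
    the orientation fluctuations.
    """
    x = np.sort(np.abs(np.asarray(samples, dtype=float)))
    if x.size < min_samples:
        raise ValueError(f"need at least {min_samples} intraevent samples")
    ecdf = (np.arange(1, x.size + 1) - 0.5) / x.size
    q_lo = float(np.quantile(x, 0.08))
    q_hi = float(np.quantile(x, 0.92))
    if q_hi - q_lo < 1e-9:
        q_hi = q_lo + max(1e-9, 0.01 * abs(q_lo))
    span = q_hi - q_lo

    def residuals(params: np.ndarray, oblate: bool) -> np.ndarray:
        lo, width = params
        return (
            _orientation_cdf(x, lo, lo + width, noise_sd, oblate,
                             orientation_quantiles)
            - ecdf
        )

    best = None
    for branch, oblate in (("oblate", True), ("prolate", False)):
        p0 = np.asarray([q_lo, span])
        try:
            sol = least_squares(
                residuals,
                p0,
                args=(oblate,),
                bounds=([1e-9, 1e-9], [np.inf, np.inf]),
                xtol=1e-10,
                ftol=1e-10,
                max_nfev=200,
            )
        except Exception:
            continue
        cost = float(np.sqrt(np.mean(sol.fun**2)))
        if best is None or cost < best[0]:
            best = (cost, branch, sol)
    if best is None:
        raise RuntimeError("shape fit failed to converge")
    cost, branch, sol = best
    lo = float(sol.x[0])
    hi = float(sol.x[0] + sol.x[1])
    ratio = hi / lo
    # near-degenerate fit: treat as spherical
    if ratio < 1.0 + 1e-6:
        m_hat = 1.0
        branch = "sphere"
        g_min = SPHERE_GAMMA
    else:
        m_hat = _ratio_to_m(ratio, branch)
        g_par, g_perp = shape_factor_extremes(m_hat)
        g_min = min(g_par, g_perp)
    v_eff = effective_pore_volume(pore.diameter, pore.length)
    v_hat = lo * v_eff / (abs(i0) * g_min)
    return EventShapeEstimate(
        i_min_fit=lo,
        i_max_fit=hi,
        m_hat=m_hat,
        v_hat=v_hat,
        branch=branch,
        fit_residual=cost,
        converged=bool(sol.success),
    )


# ---------------------------------------------------------------------------
# cumulative (real-time) pooling
# ---------------------------------------------------------------------------


@dataclass
class CumulativeEstimate:
    """Residence-time-weighted pooled estimate over qualifying events.

    Only events with dwell above ``min_dwell_s`` (default 150 us, the
    shortest pulse that samples enough orientations at a 50 kHz bandwidth)
    contribute. The pooled statistic is the residence-time-weighted median of
    the per-event estimates, robust to occasional impurity events.
    """

    min_dwell_s: float = 150e-6
    cumulative_residence_s: float = 0.0
    n_events: int = 0
    m_values: List[float] = field(default_factory=list)
    v_values: List[float] = field(default_factory=list)
    weights: List[float] = field(default_factory=list)
    m_series: List[float] = field(default_factory=list)
    v_series: List[float] = field(default_factory=list)
    residence_series: List[float] = field(default_factory=list)

    @property
    def m_hat(self) -> float:
        if not self.m_series:
            raise ValueError("no qualifying events yet")
        return self.m_series[-1]

    @property
    def v_hat(self) -> float:
        if not self.v_series:
            raise ValueError("no qualifying events yet")
        return self.v_series[-1]


def _weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(v)
    v, w = v[order], w[order]
    cw = np.cumsum(w)
    cutoff = 0.5 * cw[-1]
    return float(v[np.searchsorted(cw, cutoff)])


def cumulative_update(
    acc: CumulativeEstimate, est: EventShapeEstimate, dwell_s: float
) -> CumulativeEstimate:
    """Fold one event's estimate into the running pooled estimate."""
    if dwell_s <= acc.min_dwell_s or not est.converged:
        return acc
    acc.n_events += 1
    acc.cumulative_residence_s += dwell_s
    acc.m_values.append(est.m_hat)
    acc.v_values.append(est.v_hat)
    acc.weights.append(dwell_s)
    acc.m_series.append(_weighted_median(acc.m_values, acc.weights))
    acc.v_series.append(_weighted_median(acc.v_values, acc.weights))
    acc.residence_series.append(acc.cumulative_residence_s)
    return acc
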