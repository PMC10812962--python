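"""Voxelwise mono-exponential relaxometry.

Quantitative T1rho and T2 maps are computed from a stack of
magnetization-prepared echo images by fitting, independently at every
voxel, the two-parameter decay model

    S(t) = S0 * exp(-t / T)

where ``t`` is the preparation time (spin-lock time TSL for T1rho,
T2-preparation time TE for T2), ``S0`` the unrelaxed signal and ``T``
the relaxation time in milliseconds.  Fitting is damped least squares
(Levenberg-Marquardt) with an analytic Jacobian, vectorized over all
voxels; initial values come from a log-linear regression of the echo
intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger("qmapsynth.relaxometry")

MapKind = Literal["T1rho", "T2"]

#: Display / evaluation clip window in ms.  Distinct from the fit bounds.
CLIP_RANGE_MS: Tuple[float, float] = (0.0, 150.0)

#: Default fit bounds in ms: wide enough for every physiological knee value,
#: tight enough to stabilize flat-decay (noise only) voxels.
FIT_BOUNDS_MS: Tuple[float, float] = (1.0, 300.0)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class EchoSeries:
    """A registered multi-echo image stack with its preparation-time axis.

    Attributes
    ----------
    data : ndarray, shape (n_echoes, slices, rows, cols)
        Echo intensities in arbitrary units.
    times_ms : ndarray, shape (n_echoes,)
        Strictly increasing preparation times (TSL or TE) in ms.
    kind : {"T1rho", "T2"}
        Which preparation the time axis refers to.
    spacing : (dz, dy, dx) voxel spacing in mm.
    noise_sigma_au : float
        Standard deviation (a.u.) of the additive noise the series carries,
        if known; used by domain-shift corruption to rescale SNR.
    """

    data: np.ndarray
    times_ms: np.ndarray
    kind: MapKind
    spacing: Tuple[float, float, float] = (4.0, 0.55, 0.55)
    noise_sigma_au: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("echo data must be 4D (echo, slice, row, col)")
        if self.times_ms.ndim != 1 or self.times_ms.size < 2:
            raise ValueError("need at least two preparation times")
        if self.times_ms.size != self.data.shape[0]:
            raise ValueError(
                f"{self.times_ms.size} times but {self.data.shape[0]} echoes"
            )
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("preparation times must be strictly increasing")
        if self.times_ms[0] < 0:
            raise ValueError("preparation times must be non-negative")
        if self.kind not in ("T1rho", "T2"):
            raise ValueError(f"unknown series kind {self.kind!r}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass
class QuantMap:
    """A single relaxation-time map in milliseconds."""

    values_ms: np.ndarray
    kind: MapKind
    spacing: Tuple[float, float, float] = (4.0, 0.55, 0.55)
    fit_quality: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values_ms = np.asarray(self.values_ms, dtype=float)
        if self.values_ms.ndim != 3:
            raise ValueError("a quantitative map must be a 3D volume")
        if self.kind not in ("T1rho", "T2"):
            raise ValueError(f"unknown map kind {self.kind!r}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values_ms.shape


@dataclass
class FitResult:
    """Output of :func:`fit_monoexponential`.

    Non-converged voxels (all-zero series, bound-clamped T, or iteration
    limit) are flagged in ``converged_mask`` rather than silently filled.
    """

    map: QuantMap
    s0_map: np.ndarray
    converged_mask: np.ndarray
    residual_map: np.ndarray


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _loglinear_init(
    y: np.ndarray, t: np.ndarray, t_lo: float, t_hi: float, eps: float = 1e-6
) -> Tuple[np.ndarray, np.ndarray]:
    """Log-linear least squares initial values.

    Fits log(max(y, eps)) = log(S0) - t/T by ordinary least squares.  The
    floor at ``eps`` affects only this initialization; the LM iterations
    see the raw intensities.
    """
    ly = np.log(np.maximum(y, eps))
    tm = t.mean()
    tc = t - tm
    denom = np.sum(tc * tc)
    slope = (ly @ tc) / denom
    intercept = ly.mean(axis=1) - slope * tm
    T0 = np.where(slope < 0, -1.0 / np.where(slope < 0, slope, -1.0), t_hi)
    T0 = np.clip(T0, t_lo, t_hi)
    S0 = np.exp(np.clip(intercept, -50.0, 50.0))
    return S0, T0


def _lm_monoexp(
    y: np.ndarray,
    t: np.ndarray,
    s0: np.ndarray,
    T: np.ndarray,
    rtol: float = 1e-8,
    max_iter: int = 200,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Damped Gauss-Newton (Levenberg-Marquardt) over a batch of voxels.

    Parameters evolve per voxel with an individual damping factor; steps
    that do not decrease the squared residual are rejected and re-damped.
    Returns (S0, T, converged) with T unclamped (bounds applied by caller).
    """
    V = y.shape[0]
    s0 = s0.astype(float).copy()
    T = T.astype(float).copy()
    lam = np.full(V, 1e-3)
    done = np.zeros(V, dtype=bool)

    scale = np.sum(y * y, axis=1)
    cost_floor = 1e-22 * np.maximum(scale, 1e-30)

    def model_cost(s0v, Tv):
        f = s0v[:, None] * np.exp(-t[None, :] / Tv[:, None])
        r = y - f
        return r, np.sum(r * r, axis=1)

    r, cost = model_cost(s0, T)
    for _ in range(max_iter):
        act = ~done
        if not act.any():
            break
        Ta, s0a, ya, ra = T[act], s0[act], y[act], r[act]
        E = np.exp(-t[None, :] / Ta[:, None])
        J1 = E
        J2 = s0a[:, None] * t[None, :] / (Ta[:, None] ** 2) * E
        a11 = np.sum(J1 * J1, axis=1)
        a12 = np.sum(J1 * J2, axis=1)
        a22 = np.sum(J2 * J2, axis=1)
        g1 = np.sum(J1 * ra, axis=1)
        g2 = np.sum(J2 * ra, axis=1)
        la = lam[act]
        A11 = a11 * (1.0 + la)
        A22 = a22 * (1.0 + la)
        det = A11 * A22 - a12 * a12
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        ds0 = (A22 * g1 - a12 * g2) / det
        dT = (A11 * g2 - a12 * g1) / det
        s0_new = s0a + ds0
        T_new = np.clip(Ta + dT, 1e-3, 1e6)
        f_new = s0_new[:, None] * np.exp(-t[None, :] / T_new[:, None])
        r_new = ya - f_new
        cost_new = np.sum(r_new * r_new, axis=1)
        improved = cost_new < cost[act]

        # accept improving steps, re-damp the rest
        idx = np.flatnonzero(act)
        good = idx[improved]
        bad = idx[~improved]
        s0[good] = s0_new[improved]
        T[good] = T_new[improved]
        rel_drop = (cost[good] - cost_new[improved]) / np.maximum(cost[good], 1e-30)
        r[good] = r_new[improved]
        cost[good] = cost_new[improved]
        lam[good] = np.maximum(lam[good] * 0.3, 1e-12)
        lam[bad] = np.minimum(lam[bad] * 4.0, 1e12)
        done[good] |= (rel_drop < rtol) | (cost[good] <= cost_floor[good])
        done[bad] |= lam[bad] >= 1e12
    return s0, T, done


def fit_monoexponential(
    series: EchoSeries,
    bounds: Tuple[float, float] = FIT_BOUNDS_MS,
    mask: Optional[np.ndarray] = None,
    rtol: float = 1e-8,
    max_iter: int = 200,
    s0_threshold_frac: float = 0.0,
) -> FitResult:
    """Fit S(t) = S0*exp(-t/T) at every voxel of an echo series.

    Parameters
    ----------
    series : EchoSeries
        Registered echoes with their preparation times.
    bounds : (t_lo, t_hi)
        Admissible relaxation-time window in ms, ``t_lo > 0``.  Voxels whose
        optimum falls outside are clamped to the nearer bound and flagged
        non-converged.
    mask : bool ndarray, optional
        Restrict the fit to these voxels (e.g. skip background for speed);
        outside, T = t_lo, S0 = 0, non-converged.  Default fits everything.
    s0_threshold_frac : float
        Background suppression: voxels whose fitted S0 falls below this
        fraction of the volume's 99th-percentile S0 carry no signal (air
        fitted to noise); their T is set to 0 and flagged non-converged.
        0 disables the threshold.

    Returns
    -------
    FitResult
        Map, S0 volume, convergence flags and per-voxel residual 2-norm.
    """
    t_lo, t_hi = bounds
    if not (0 < t_lo < t_hi):
        raise ValueError("bounds must satisfy 0 < t_lo < t_hi")
    vol_shape = series.shape
    y_all = series.data.reshape(series.data.shape[0], -1).T  # (V, E)
    t = series.times_ms

    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != vol_shape:
            raise ValueError("mask shape does not match series geometry")
        sel = mask.ravel()
    else:
        sel = np.ones(y_all.shape[0], dtype=bool)

    T_out = np.full(y_all.shape[0], t_lo)
    S0_out = np.zeros(y_all.shape[0])
    conv_out = np.zeros(y_all.shape[0], dtype=bool)
    res_out = np.zeros(y_all.shape[0])

    y = y_all[sel]
    nonzero = np.max(np.abs(y), axis=1) > 0
    if nonzero.any():
        yv = y[nonzero]
        s0_init, T_init = _loglinear_init(yv, t, t_lo, t_hi)
        s0_fit, T_fit, ok = _lm_monoexp(yv, t, s0_init, T_init, rtol, max_iter)
        clamped = (T_fit < t_lo) | (T_fit > t_hi)
        T_fit = np.clip(T_fit, t_lo, t_hi)
        resid = yv - s0_fit[:, None] * np.exp(-t[None, :] / T_fit[:, None])
        res_norm = np.sqrt(np.sum(resid * resid, axis=1))

        tmp_T = T_out[sel]
        tmp_S = S0_out[sel]
        tmp_c = conv_out[sel]
        tmp_r = res_out[sel]
        tmp_T[nonzero] = T_fit
        tmp_S[nonzero] = s0_fit
        tmp_c[nonzero] = ok & ~clamped
        tmp_r[nonzero] = res_norm
        T_out[sel] = tmp_T
        S0_out[sel] = tmp_S
        conv_out[sel] = tmp_c
        res_out[sel] = tmp_r

    if s0_threshold_frac > 0:
        thr = s0_threshold_frac * np.percentile(S0_out[sel], 99)
        background = sel & (S0_out < thr)
        T_out[background] = 0.0
        conv_out[background] = False
        logger.debug("fit_monoexponential: %d voxels below S0 threshold",
                     int(background.sum()))

    n_bad = int(np.count_nonzero(sel) - np.count_nonzero(conv_out))
    if n_bad:
        logger.debug("fit_monoexponential: %d voxels flagged non-converged", n_bad)

    qmap = QuantMap(
        values_ms=T_out.reshape(vol_shape),
        kind=series.kind,
        spacing=series.spacing,
        fit_quality=res_out.reshape(vol_shape),
    )
    return FitResult(
        map=qmap,
        s0_map=S0_out.reshape(vol_shape),
        converged_mask=conv_out.reshape(vol_shape),
        residual_map=res_out.reshape(vol_shape),
    )


def clip_map(qmap: QuantMap, lo: float = CLIP_RANGE_MS[0], hi: float = CLIP_RANGE_MS[1]) -> QuantMap:
    """Project map values onto [lo, hi] ms (background-noise suppression).

    The number of clipped voxels is logged; the input is left untouched.
    """
    if not lo < hi:
        raise ValueError("clip window requires lo < hi")
    v = qmap.values_ms
    n_clip = int(np.count_nonzero((v < lo) | (v > hi)))
    if n_clip:
        logger.debug("clip_map: %d voxels clipped to [%g, %g] ms", n_clip, lo, hi)
    return QuantMap(
        values_ms=np.clip(v, lo, hi),
        kind=qmap.kind,
        spacing=qmap.spacing,
        fit_quality=qmap.fit_quality,
    )
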