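"""Biolayer-interferometry preprocessing and 1:1 Langmuir binding analysis.

A 1:1 interaction A + L <-> AL observed on a sensor gives, at analyte
concentration C, an association phase

    R(t) = Req * (1 - exp(-kobs * t)),   kobs = kon*C + koff,
    Req  = Rmax * C / (KD + C),

and an exponential dissociation phase R(t) = R_end * exp(-koff * t).
KD = koff/kon kinetically, or the half-saturation point of the
steady-state hyperbola Response(C) = Rmax*C/(KD + C).

The module implements the standard processing chain: double reference
subtraction (instrument reference sensor and zero-analyte blank), baseline
alignment, inter-step alignment at the association/dissociation boundary,
Savitzky-Golay smoothing, per-curve rate fits over short early windows
(20 s by default), the kobs-versus-C line, a global 1:1 fit sharing
(kon, koff, Rmax) across all curves, and the steady-state hyperbola fit.

All concentrations are molar internally; rate units are 1/s and
1/(M*s); responses are in nm shift.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares
from scipy.signal import savgol_filter

from .errors import (AlignmentError, DegenerateFitError, FitError,
                     InsufficientDataError, ParameterError)
from .io_formats import Sensorgram, SensorgramSet

logger = logging.getLogger(__name__)

DEFAULT_FIT_WINDOW_S = 20.0
DEFAULT_SG_WINDOW = 11
DEFAULT_SG_ORDER = 3

_FIT_KW = dict(xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000)


# ---------------------------------------------------------------------------
# Model evaluators
# ---------------------------------------------------------------------------

def association_response(t, req, kobs):
    """R(t) = Req*(1 - exp(-kobs*t)) with t measured from association start."""
    return req * -np.expm1(-kobs * np.asarray(t, dtype=float))


def dissociation_response(t, r0, koff):
    """R(t) = R0*exp(-koff*t) with t measured from dissociation start."""
    return r0 * np.exp(-koff * np.asarray(t, dtype=float))


def steady_state_response(concentration, kd, rmax):
    """Equilibrium rectangular hyperbola Response = Rmax*C/(KD + C)."""
    c = np.asarray(concentration, dtype=float)
    # rmax*(c/(kd+c)) so that C = KD yields exactly Rmax/2 in floating point
    return rmax * (c / (kd + c))


def observed_rate(concentration, kon, koff):
    """kobs = kon*C + koff for the 1:1 model."""
    return kon * np.asarray(concentration, dtype=float) + koff


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _check_same_grid(curves: list[Sensorgram]) -> None:
    t0 = curves[0].time_s
    for c in curves[1:]:
        if t0.shape != c.time_s.shape or not np.array_equal(t0, c.time_s):
            raise AlignmentError(
                "sensorgram time grids differ; refusing to interpolate")


def baseline_align(curve: Sensorgram) -> Sensorgram:
    """Shift the response so the pre-association (baseline) mean is zero."""
    mask = curve.phase_mask("baseline")
    if mask.any():
        offset = float(curve.response[mask].mean())
    else:
        logger.warning("%s: no baseline points; aligning on first sample",
                       curve.label or "curve")
        offset = float(curve.response[0])
    return curve.with_response(curve.response - offset)


def double_reference_subtract(sample: Sensorgram, reference: Sensorgram,
                              zero_analyte_sample: Sensorgram,
                              zero_analyte_reference: Sensorgram) -> Sensorgram:
    """(sample - reference) - (zero-analyte sample - zero-analyte reference),
    then baseline-aligned.

    Removes both sensor-specific nonspecific signal and systematic drift
    common to the plate. All four curves must share the time grid exactly.
    """
    if sample.is_reference or sample.is_zero_analyte:
        raise ParameterError("the sample curve must be a loaded, analyte-bearing curve")
    _check_same_grid([sample, reference, zero_analyte_sample,
                      zero_analyte_reference])
    corrected = (sample.response - reference.response) - (
        zero_analyte_sample.response - zero_analyte_reference.response)
    return baseline_align(sample.with_response(corrected))


def align_interstep(curve: Sensorgram, edge_points: int = 51) -> Sensorgram:
    """Offset the dissociation segment so it continues the association end.

    Inter-step correction removes the vertical jump that appears when the
    sensor moves between wells. The boundary response is estimated from
    each side by a least-squares quadratic over the ``edge_points``
    samples nearest the boundary (quadratics track the local curvature of
    exponential phases, and the window averages down noise), and the
    dissociation segment is shifted by the difference. On a continuous
    noise-free trace the shift vanishes to third order in the sampling
    interval.
    """
    assoc = curve.phase_mask("association")
    diss = curve.phase_mask("dissociation")
    if not assoc.any() or not diss.any():
        return curve
    t_bound = curve.dissociation_start_s

    def boundary_value(t, y) -> float:
        n = min(edge_points, t.size)
        t, y = t[:n], y[:n]
        deg = 2 if n >= 6 else (1 if n >= 3 else 0)
        coef = np.polyfit(t - t_bound, y, deg)
        return float(coef[-1])

    ta, ya = curve.time_s[assoc], curve.response[assoc]
    from_assoc = boundary_value(ta[::-1], ya[::-1])
    from_diss = boundary_value(curve.time_s[diss], curve.response[diss])
    offset = from_assoc - from_diss
    resp = curve.response.copy()
    resp[diss] += offset
    return curve.with_response(resp)


def smooth_sensorgram(curve: Sensorgram, window_points: int = DEFAULT_SG_WINDOW,
                      poly_order: int = DEFAULT_SG_ORDER) -> Sensorgram:
    """Savitzky-Golay smoothing of the response, applied per phase.

    Smoothing each phase separately keeps the filter from blurring the
    kinks at phase boundaries into the fit windows. ``window_points`` must
    be odd, exceed ``poly_order``, and fit inside every phase segment.
    ``window_points=1`` is the identity.
    """
    if window_points % 2 == 0 or window_points < 1:
        raise ParameterError("window_points must be a positive odd integer")
    if window_points == 1:
        return curve
    if poly_order >= window_points:
        raise ParameterError("poly_order must be smaller than window_points")
    if window_points > curve.time_s.size:
        raise ParameterError("smoothing window exceeds series length")
    resp = curve.response.copy()
    for phase in ("baseline", "association", "dissociation"):
        mask = curve.phase_mask(phase)
        n = int(mask.sum())
        if n == 0:
            continue
        if n <= window_points:
            logger.warning("%s phase too short for window=%d; left unsmoothed",
                           phase, window_points)
            continue
        resp[mask] = savgol_filter(curve.response[mask], window_points,
                                   poly_order, mode="interp")
    return curve.with_response(resp)


def preprocess_set(sset: SensorgramSet,
                   window_points: int = DEFAULT_SG_WINDOW,
                   poly_order: int = DEFAULT_SG_ORDER,
                   interstep: bool = False) -> list[Sensorgram]:
    """Full correction chain for every sample curve of a set.

    Double reference subtraction is applied when the set carries matched
    reference and zero-analyte curves; otherwise the curve is only
    baseline-aligned (with a warning), then inter-step aligned and smoothed.
    """
    try:
        zero_s = sset.zero_analyte(reference=False)
        zero_r = sset.zero_analyte(reference=True)
    except Exception:
        zero_s = zero_r = None
    out = []
    for sample in sset.sample_curves():
        ref = None
        try:
            ref = sset.reference_for(sample)
        except Exception:
            pass
        if ref is not None and zero_s is not None and zero_r is not None:
            cur = double_reference_subtract(sample, ref, zero_s, zero_r)
        else:
            logger.warning("%s: missing reference/zero-analyte curves; "
                           "baseline alignment only", sample.label or "curve")
            cur = baseline_align(sample)
        cur = smooth_sensorgram(cur, window_points, poly_order)
        if interstep:  # after smoothing so the boundary estimate is stable
            cur = align_interstep(cur)
        out.append(cur)
    return out


# ---------------------------------------------------------------------------
# Per-curve fits
# ---------------------------------------------------------------------------

@dataclass
class ObservedRateFit:
    """Per-curve association/dissociation fit results."""

    concentration_M: float
    kobs: float
    kobs_se: float
    req_window: float            # Req extrapolated from the association window
    req_equilibrium: float       # Req from the full association phase
    req_equilibrium_se: float
    koff: float
    koff_se: float
    assoc_rmse: float
    dissoc_rmse: float
    flags: list[str] = field(default_factory=list)


def _multistart_curve_fit(model, jac, t, y, starts):
    best = None
    last_err: Exception | None = None
    for p0 in starts:
        try:
            popt, pcov = curve_fit(model, t, y, p0=p0, jac=jac, **_FIT_KW)
        except Exception as exc:  # pragma: no cover - solver failure path
            last_err = exc
            continue
        ssr = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or ssr < best[2]:
            best = (popt, pcov, ssr)
    if best is None:
        raise FitError(f"nonlinear fit failed for all starts: {last_err}")
    return best


def _assoc_jac(t, req, kobs):
    e = np.exp(-kobs * t)
    return np.column_stack([1.0 - e, req * t * e])


def _dissoc_jac(t, r0, koff):
    e = np.exp(-koff * t)
    return np.column_stack([e, -r0 * t * e])


def _assoc_starts(tau, y):
    """Initial (Req, kobs) guesses for an exponential-approach fit."""
    t_end = tau[-1] if tau[-1] > 0 else 1.0
    starts = []
    mid = np.searchsorted(tau, t_end / 2)
    if 0 < mid < tau.size and abs(y[mid]) > 0:
        a = y[-1] / y[mid] - 1.0
        if 0.0 < a < 1.0:
            k0 = -2.0 * math.log(a) / t_end
            req0 = y[mid] / (1.0 - a)
            starts.append((req0, k0))
    base_req = y[-1] if abs(y[-1]) > 0 else 1.0
    for fac in (1.0, 0.3, 3.0, 10.0):
        starts.append((base_req * 1.5, fac / t_end))
    return starts


def fit_association(curve: Sensorgram, window_s: float | None
                    ) -> tuple[float, float, float, float, float, float]:
    """Fit R = Req*(1-exp(-kobs*tau)) on the association phase.

    ``window_s`` limits the fit to the first seconds of association
    (None = whole phase). Returns (req, req_se, kobs, kobs_se, rmse, n).
    """
    mask = curve.phase_mask("association")
    tau = curve.time_s[mask] - curve.association_start_s
    y = curve.response[mask]
    if window_s is not None:
        sel = tau <= window_s
        tau, y = tau[sel], y[sel]
    if tau.size < 5:
        raise InsufficientDataError("fewer than 5 association points in window")
    if float(np.var(y)) <= 1e-18:
        raise DegenerateFitError("association signal is flat; nothing to fit")
    popt, pcov, ssr = _multistart_curve_fit(
        association_response, _assoc_jac, tau, y, _assoc_starts(tau, y))
    rmse = math.sqrt(ssr / tau.size)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return (float(popt[0]), float(se[0]), float(popt[1]), float(se[1]),
            rmse, tau.size)


def fit_dissociation(curve: Sensorgram, window_s: float | None
                     ) -> tuple[float, float, float, float, float]:
    """Fit R = R0*exp(-koff*tau) on the dissociation phase.

    Returns (r0, koff, koff_se, rmse, n). A fitted koff indistinguishable
    from zero is returned as-is; callers flag it as a lower bound.
    """
    mask = curve.phase_mask("dissociation")
    tau = curve.time_s[mask] - curve.dissociation_start_s
    y = curve.response[mask]
    if window_s is not None:
        sel = tau <= window_s
        tau, y = tau[sel], y[sel]
    if tau.size < 5:
        raise InsufficientDataError("fewer than 5 dissociation points in window")
    t_end = tau[-1] if tau[-1] > 0 else 1.0
    starts = [(y[0] if abs(y[0]) > 0 else 1.0, k0) for k0 in
              (0.5 / t_end, 1e-6, 2.0 / t_end)]
    if y[0] > 0 and y[-1] > 0 and y[0] > y[-1]:
        starts.insert(0, (y[0], math.log(y[0] / y[-1]) / t_end))
    popt, pcov, ssr = _multistart_curve_fit(
        dissociation_response, _dissoc_jac, tau, y, starts)
    rmse = math.sqrt(ssr / tau.size)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return float(popt[0]), float(popt[1]), float(se[1]), rmse, tau.size


def fit_observed_rates(curve: Sensorgram,
                       assoc_fit_window_s: float = DEFAULT_FIT_WINDOW_S,
                       dissoc_fit_window_s: float = DEFAULT_FIT_WINDOW_S
                       ) -> ObservedRateFit:
    """Observed association rate and off-rate for one corrected curve.

    kobs and the curve's koff come from the early fit windows (first 20 s
    of each phase by default, mirroring short-window kinetic analysis);
    the equilibrium response used for steady-state analysis is
    extrapolated from an exponential fit of the *entire* association
    phase, which constrains the plateau far better than the early window.
    Nonpositive rates are flagged, never clipped.
    """
    flags: list[str] = []
    req_w, _, kobs, kobs_se, assoc_rmse, _ = fit_association(
        curve, assoc_fit_window_s)
    req_eq, req_eq_se, _, _, _, _ = fit_association(curve, None)
    r0, koff, koff_se, dissoc_rmse, _ = fit_dissociation(
        curve, dissoc_fit_window_s)
    if kobs <= 0:
        flags.append("nonpositive_kobs")
    if koff < -1e-6:
        flags.append("negative_koff")
    elif koff < 1e-6:
        flags.append("koff_at_lower_bound")
    return ObservedRateFit(
        concentration_M=curve.analyte_concentration_M,
        kobs=kobs, kobs_se=kobs_se, req_window=req_w,
        req_equilibrium=req_eq, req_equilibrium_se=req_eq_se,
        koff=koff, koff_se=koff_se,
        assoc_rmse=assoc_rmse, dissoc_rmse=dissoc_rmse, flags=flags)


# ---------------------------------------------------------------------------
# Rate constants from per-curve observed rates
# ---------------------------------------------------------------------------

@dataclass
class KineticFit:
    """Rate constants for the 1:1 model with their standard errors."""

    kon: float                   # 1/(M*s)
    koff: float                  # 1/s
    kon_se: float
    koff_se: float
    kd_kinetic: float            # M, = koff/kon
    koff_intercept: float        # intercept of the kobs line (diagnostic)
    koff_intercept_se: float
    kobs_per_curve: list[tuple[float, float, float]]  # (C, kobs, rmse/se)
    koff_per_curve: list[tuple[float, float, float]]
    method: str = "per_curve"
    rmax: float | None = None    # populated by the global fit
    rmax_se: float | None = None

    def __post_init__(self) -> None:
        if self.kon <= 0:
            raise FitError("kon must be positive")
        if not math.isclose(self.kd_kinetic, self.koff / self.kon,
                            rel_tol=1e-12):
            raise FitError("KD_kinetic must equal koff/kon")


def derive_rate_constants(per_curve: list[tuple[float, float]],
                          per_curve_koff: list[float],
                          koff_se: list[float] | None = None,
                          koff_weighting: str = "inverse_variance"
                          ) -> KineticFit:
    """kon from the kobs-versus-concentration line; koff averaged across
    the dissociation fits.

    ``per_curve`` holds (C, kobs) pairs from >= 3 distinct concentrations.
    The kobs line's intercept is retained as a diagnostic cross-check of
    koff. With ``koff_weighting='inverse_variance'`` (default) the
    dissociation koff values are precision-weighted by their fit standard
    errors — low-concentration curves dissociate from a small amplitude
    and carry little information; ``'uniform'`` is the plain mean.
    """
    concs = np.array([c for c, _ in per_curve], dtype=float)
    kobs = np.array([k for _, k in per_curve], dtype=float)
    if np.unique(concs).size < 3:
        raise InsufficientDataError(
            "need >= 3 distinct concentrations with valid kobs")
    # OLS kobs = kon*C + b
    X = np.column_stack([concs, np.ones_like(concs)])
    coef, res, *_ = np.linalg.lstsq(X, kobs, rcond=None)
    kon, intercept = float(coef[0]), float(coef[1])
    dof = max(concs.size - 2, 1)
    ssr = float(np.sum((X @ coef - kobs) ** 2))
    cov = np.linalg.inv(X.T @ X) * ssr / dof
    kon_se, intercept_se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    if kon <= 0:
        raise FitError("fitted kon is nonpositive: data inconsistent with a "
                       "1:1 association model")
    koffs = np.array(per_curve_koff, dtype=float)
    if koff_weighting == "inverse_variance" and koff_se is not None \
            and np.all(np.asarray(koff_se) > 0):
        w = 1.0 / np.asarray(koff_se, dtype=float) ** 2
        koff = float(np.sum(w * koffs) / np.sum(w))
        koff_err = float(1.0 / math.sqrt(np.sum(w)))
        ses = list(koff_se)
    elif koff_weighting in ("inverse_variance", "uniform"):
        koff = float(koffs.mean())
        koff_err = float(koffs.std(ddof=1) / math.sqrt(koffs.size)
                         if koffs.size > 1 else 0.0)
        ses = list(koff_se) if koff_se is not None else [0.0] * koffs.size
    else:
        raise ParameterError(f"unknown koff_weighting: {koff_weighting}")
    return KineticFit(
        kon=kon, koff=koff, kon_se=kon_se, koff_se=koff_err,
        kd_kinetic=koff / kon,
        koff_intercept=intercept, koff_intercept_se=intercept_se,
        kobs_per_curve=[(float(c), float(k), 0.0) for c, k in per_curve],
        koff_per_curve=[(float(c), float(k), float(s))
                        for (c, _), k, s in zip(per_curve, koffs, ses)],
        method="per_curve")


# ---------------------------------------------------------------------------
# Global 1:1 fit
# ---------------------------------------------------------------------------

def global_kinetic_fit(curves: list[Sensorgram],
                       assoc_fit_window_s: float = DEFAULT_FIT_WINDOW_S,
                       dissoc_fit_window_s: float = DEFAULT_FIT_WINDOW_S,
                       p0: tuple[float, float, float] | None = None
                       ) -> KineticFit:
    """Fit (kon, koff, Rmax) shared across all curves of a titration.

    The model ties every curve together: Req = Rmax*C/(KD+C) and
    kobs = kon*C + koff during association, and dissociation decays with
    the shared koff from the response reached at the end of the *full*
    association phase. Residuals are taken over the same early fit windows
    as the per-curve analysis. Parameters are optimized in log space.
    """
    if len({c.analyte_concentration_M for c in curves}) < 3:
        raise InsufficientDataError("global fit needs >= 3 concentrations")
    segments = []
    for c in curves:
        am = c.phase_mask("association")
        dm = c.phase_mask("dissociation")
        ta = c.time_s[am] - c.association_start_s
        td = c.time_s[dm] - c.dissociation_start_s
        t_assoc_total = float(ta[-1]) if ta.size else 0.0
        sa = ta <= assoc_fit_window_s
        sd = td <= dissoc_fit_window_s
        segments.append((c.analyte_concentration_M, ta[sa], c.response[am][sa],
                         td[sd], c.response[dm][sd], t_assoc_total))

    def residuals(logp):
        kon, koff, rmax = np.exp(logp)
        kd = koff / kon
        out = []
        for conc, ta, ya, td, yd, t_tot in segments:
            req = rmax * conc / (kd + conc)
            kobs = kon * conc + koff
            out.append(req * -np.expm1(-kobs * ta) - ya)
            rend = req * -np.expm1(-kobs * t_tot)
            out.append(rend * np.exp(-koff * td) - yd)
        return np.concatenate(out)

    if p0 is None:
        cmax = max(c.analyte_concentration_M for c in curves)
        rtop = max(float(np.max(np.abs(c.response))) for c in curves)
        p0 = (1.0 / (cmax * 50.0), 1.0 / (2 * dissoc_fit_window_s),
              max(rtop, 1e-6) * 1.5)
    sol = least_squares(residuals, np.log(np.asarray(p0, dtype=float)),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000)
    if not sol.success:
        raise FitError(f"global 1:1 fit did not converge: {sol.message}")
    kon, koff, rmax = (float(v) for v in np.exp(sol.x))
    dof = max(sol.fun.size - 3, 1)
    sigma2 = float(np.sum(sol.fun ** 2)) / dof
    try:
        cov_log = np.linalg.inv(sol.jac.T @ sol.jac) * sigma2
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0, np.inf))
    except np.linalg.LinAlgError:  # pragma: no cover
        se_log = np.full(3, np.nan)
    return KineticFit(
        kon=kon, koff=koff,
        kon_se=kon * float(se_log[0]), koff_se=koff * float(se_log[1]),
        kd_kinetic=koff / kon,
        koff_intercept=koff, koff_intercept_se=koff * float(se_log[1]),
        kobs_per_curve=[(c.analyte_concentration_M,
                         kon * c.analyte_concentration_M + koff, 0.0)
                        for c in curves],
        koff_per_curve=[(c.analyte_concentration_M, koff, 0.0)
                        for c in curves],
        method="global", rmax=rmax, rmax_se=rmax * float(se_log[2]))


# ---------------------------------------------------------------------------
# Steady-state analysis
# ---------------------------------------------------------------------------

@dataclass
class SteadyStateFit:
    """Hyperbola fit Response = Rmax*C/(KD + C) over equilibrium responses."""

    kd: float                    # M
    rmax: float                  # response units
    kd_se: float
    rmax_se: float
    points: list[tuple[float, float]]   # (C, Req) used for the fit
    residual_norm: float

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.rmax <= 0:
            raise FitError("steady-state KD and Rmax must be positive")

    def response(self, concentration):
        return steady_state_response(concentration, self.kd, self.rmax)


def fit_steady_state(equilibrium_points: list[tuple[float, float]]
                     ) -> SteadyStateFit:
    """Nonlinear least squares for (KD, Rmax) of the binding hyperbola.

    Initialized at KD0 = median(C), Rmax0 = 1.1*max(Req), with a small
    ladder of perturbed restarts before declaring non-convergence.
    """
    pts = [(float(c), float(r)) for c, r in equilibrium_points]
    concs = np.array([c for c, _ in pts])
    reqs = np.array([r for _, r in pts])
    if np.unique(concs[concs > 0]).size < 3:
        raise InsufficientDataError(
            "need >= 3 distinct positive concentrations")
    if np.any(concs <= 0):
        raise ParameterError("concentrations must be positive")
    if not np.all(np.isfinite(reqs)):
        raise ParameterError("equilibrium responses must be finite")
    if np.all(reqs <= 0):
        raise DegenerateFitError("all equilibrium responses are nonpositive")
    kd0 = float(np.median(concs))
    rmax0 = 1.1 * float(np.max(reqs))

    def jac(c, kd, rmax):
        denom = (kd + c) ** 2
        return np.column_stack([-rmax * c / denom, c / (kd + c)])

    best = None
    last_err = None
    for fk in (1.0, 0.3, 3.0):
        for fr in (1.0, 2.0):
            try:
                popt, pcov = curve_fit(steady_state_response, concs, reqs,
                                       p0=(kd0 * fk, rmax0 * fr), jac=jac,
                                       **_FIT_KW)
            except Exception as exc:
                last_err = exc
                continue
            if popt[0] <= 0 or popt[1] <= 0:
                continue
            ssr = float(np.sum(
                (steady_state_response(concs, *popt) - reqs) ** 2))
            if best is None or ssr < best[2]:
                best = (popt, pcov, ssr)
    if best is None:
        raise FitError(
            f"steady-state fit failed after restart ladder "
            f"(KD0={kd0:g}, Rmax0={rmax0:g}): {last_err}")
    popt, pcov, ssr = best
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return SteadyStateFit(kd=float(popt[0]), rmax=float(popt[1]),
                          kd_se=float(se[0]), rmax_se=float(se[1]),
                          points=pts, residual_norm=math.sqrt(ssr))


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class BliAnalysis:
    """Complete analysis of one sensorgram titration.

    ``kinetic_global`` (shared-parameter 1:1 fit) supplies the headline
    kon/koff; ``kinetic_per_curve`` (kobs line + averaged dissociation
    fits) is retained as the classical cross-check, and ``steady_state``
    carries the equilibrium KD/Rmax from the hyperbola.
    """

    per_curve: list[ObservedRateFit]
    kinetic_per_curve: KineticFit | None
    kinetic_global: KineticFit | None
    steady_state: SteadyStateFit | None
    processed_curves: list[Sensorgram] = field(default_factory=list)

    @property
    def _primary(self) -> KineticFit:
        fit = self.kinetic_global or self.kinetic_per_curve
        if fit is None:
            raise FitError("no kinetic fit available")
        return fit

    @property
    def kon(self) -> float:
        return self._primary.kon

    @property
    def koff(self) -> float:
        return self._primary.koff

    @property
    def kd_kinetic(self) -> float:
        return self._primary.kd_kinetic


def analyze_sensorgram_set(sset: SensorgramSet,
                           assoc_fit_window_s: float = DEFAULT_FIT_WINDOW_S,
                           dissoc_fit_window_s: float = DEFAULT_FIT_WINDOW_S,
                           sg_window: int = DEFAULT_SG_WINDOW,
                           sg_order: int = DEFAULT_SG_ORDER,
                           interstep: bool = False) -> BliAnalysis:
    """Subtract, smooth and fit a full titration.

    Runs the per-curve path (observed rates -> kobs line, averaged koff),
    the global shared-parameter fit, and the steady-state hyperbola over
    equilibrium responses extrapolated from the full association phase.
    Fit failures on individual paths are logged and reported as None
    rather than aborting the whole analysis.

    ``interstep=True`` additionally applies inter-step alignment at the
    association/dissociation boundary. Enable it for instrument exports
    with visible well-change steps; on continuous traces the alignment
    only estimates (noisily) a step that is not there, degrading the
    dissociation fits, so it is off by default.
    """
    curves = preprocess_set(sset, window_points=sg_window,
                            poly_order=sg_order, interstep=interstep)
    per_curve = [fit_observed_rates(c, assoc_fit_window_s, dissoc_fit_window_s)
                 for c in curves]
    kinetic = None
    try:
        kinetic = derive_rate_constants(
            [(f.concentration_M, f.kobs) for f in per_curve],
            [f.koff for f in per_curve],
            koff_se=[f.koff_se for f in per_curve])
    except FitError as exc:
        logger.warning("per-curve kinetic path failed: %s", exc)
    g0 = None
    if kinetic is not None:
        rtop = max(f.req_equilibrium for f in per_curve)
        g0 = (kinetic.kon, max(kinetic.koff, 1e-8), max(rtop * 1.2, 1e-6))
    kin_global = None
    try:
        kin_global = global_kinetic_fit(curves, assoc_fit_window_s,
                                        dissoc_fit_window_s, p0=g0)
    except FitError as exc:
        logger.warning("global kinetic fit failed: %s", exc)
    steady = None
    try:
        steady = fit_steady_state(
            [(f.concentration_M, f.req_equilibrium) for f in per_curve])
    except FitError as exc:
        logger.warning("steady-state fit failed: %s", exc)
    return BliAnalysis(per_curve=per_curve, kinetic_per_curve=kinetic,
                       kinetic_global=kin_global, steady_state=steady,
                       processed_curves=curves)
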