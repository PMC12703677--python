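"""Quantitative-assay curve fitting.

Implements the analyses behind the wet-lab readouts:

* linear standard curves (BCS copper quantification, A255 ascorbate) and
  their inversion;
* copper-binding stoichiometry, (total − free)/[CBM];
* the one-site binding isotherm [P_bound] = B_max·[P_free]/(K_d + [P_free]);
* stopped-flow traces y(t) = a·t + b + c·e^(−k_obs·t) (rise for reduction,
  decay for oxidation, with optional linear instrument drift a·t);
* the apparent second-order rate constant, the OLS slope of k_obs against
  reagent concentration (M⁻¹ s⁻¹);
* linear-phase product-formation rates and ascorbate-depletion times.

Nonlinear fits use Levenberg–Marquardt least squares with positivity
enforced by fitting log-parameters (K_d, B_max, k_obs); standard errors
come from the Jacobian at the optimum (delta method back to natural scale).
Linear stages are ordinary least squares with closed-form standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import ConvergenceError, ValidationError

# Levenberg–Marquardt convergence contract: relative parameter change
# below XTOL or relative residual change below FTOL, bounded iterations.
XTOL = 1e-10
FTOL = 1e-12
MAX_NFEV = 2000  # ~500 LM iterations at 3-4 parameters


def _as_arrays(*seqs) -> tuple[np.ndarray, ...]:
    return tuple(np.asarray(s, dtype=float) for s in seqs)


def _param_se(jac: np.ndarray, rss: float, n: int, p: int) -> np.ndarray:
    """SEs of the fitted parameters from the Jacobian at the optimum."""
    if n <= p:
        return np.full(p, np.nan)
    s2 = rss / (n - p)
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


# ---------------------------------------------------------------------------
# Linear calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    concentrations: np.ndarray  # μM
    responses: np.ndarray
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float

    @property
    def response_range(self) -> tuple[float, float]:
        lo = self.intercept + self.slope * self.concentrations.min()
        hi = self.intercept + self.slope * self.concentrations.max()
        return (min(lo, hi), max(lo, hi))


def fit_linear_calibration(concentrations: Sequence[float],
                           responses: Sequence[float]) -> CalibrationCurve:
    """Ordinary least-squares standard curve, response = slope·conc + b.

    Needs >= 3 standards with non-identical, nonnegative concentrations.
    The slope sign is data-dependent (a quenching probe fits a negative
    slope); nothing is assumed about it.
    """
    conc, resp = _as_arrays(concentrations, responses)
    if conc.size != resp.size:
        raise ValidationError("concentrations and responses differ in length")
    if conc.size < 3:
        raise ValidationError("need >= 3 calibration standards")
    if np.any(conc < 0):
        raise ValidationError("negative standard concentration")
    if np.allclose(conc, conc[0]):
        raise ValidationError("singular design: all standard concentrations equal")
    res = stats.linregress(conc, resp)
    return CalibrationCurve(
        concentrations=conc, responses=resp, slope=float(res.slope),
        intercept=float(res.intercept), slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        r_squared=float(res.rvalue) ** 2)


def apply_calibration(curve: CalibrationCurve, response: float,
                      clip_negative: bool = True) -> float:
    """Invert the standard curve: concentration = (response − b)/slope.

    Responses outside the standard range raise an extrapolation warning;
    physically impossible negative concentrations are clipped to 0 (with a
    warning) unless ``clip_negative=False``.
    """
    if curve.slope == 0:
        raise ValidationError("calibration slope is zero; cannot invert")
    lo, hi = curve.response_range
    edge = 1e-9 * (hi - lo + 1.0)  # float round-off guard at the boundary
    if not lo - edge <= response <= hi + edge:
        warnings.warn(f"response {response:g} outside calibrated range "
                      f"[{lo:g}, {hi:g}]; extrapolating", stacklevel=2)
    conc = (response - curve.intercept) / curve.slope
    if conc < 0 and clip_negative:
        warnings.warn(f"calibrated concentration {conc:g} µM < 0; "
                      "clipped to 0", stacklevel=2)
        conc = 0.0
    return float(conc)


# ---------------------------------------------------------------------------
# Copper stoichiometry
# ---------------------------------------------------------------------------

@dataclass
class CopperBindingResult:
    total_cu: float        # μM added
    free_cu: float         # μM measured (possibly clipped into [0, total])
    cbm_concentration: float  # μM
    stoichiometry: float   # bound Cu per μM CBM

    @property
    def bound_cu(self) -> float:
        return self.total_cu - self.free_cu


def compute_bound_copper(total_cu: float, free_cu: float,
                         cbm_concentration: float,
                         tolerance: float = 0.5) -> CopperBindingResult:
    """Binding stoichiometry (total − free)/[CBM], e.g. 4 μM CBM + 8 μM Cu.

    ``free > total`` within ``tolerance`` μM is treated as calibration
    noise and clipped (with a warning); beyond it, the calibration is
    considered faulty and a :class:`ValidationError` is raised. Negative
    free concentrations are clipped to 0.
    """
    if cbm_concentration <= 0:
        raise ValidationError("CBM concentration must be positive")
    if free_cu > total_cu + tolerance:
        raise ValidationError(
            f"free Cu {free_cu:g} µM exceeds total {total_cu:g} µM beyond "
            f"tolerance {tolerance:g} µM: calibration fault")
    clipped = min(max(free_cu, 0.0), total_cu)
    if clipped != free_cu:
        warnings.warn(f"free Cu {free_cu:g} µM clipped to {clipped:g} µM",
                      stacklevel=2)
    return CopperBindingResult(
        total_cu=total_cu, free_cu=clipped,
        cbm_concentration=cbm_concentration,
        stoichiometry=(total_cu - clipped) / cbm_concentration)


# ---------------------------------------------------------------------------
# One-site binding
# ---------------------------------------------------------------------------

@dataclass
class BindingFit:
    kd: float              # μM
    bmax: float            # μmol/g
    kd_se: float
    bmax_se: float
    rss: float
    n: int
    saturation_warning: bool = False


def one_site(free: np.ndarray, kd: float, bmax: float) -> np.ndarray:
    return bmax * free / (kd + free)


def fit_one_site_binding(free: Sequence[float],
                         bound: Sequence[float]) -> BindingFit:
    """Nonlinear one-site fit returning K_d and B_max with SEs.

    Positivity is enforced by optimising (log K_d, log B_max) with
    Levenberg–Marquardt; SEs are mapped back with the delta method. When
    the data do not approach saturation (max free < fitted K_d) the fit is
    returned with ``saturation_warning`` set.
    """
    f, y = _as_arrays(free, bound)
    if f.size != y.size:
        raise ValidationError("free and bound differ in length")
    if np.unique(f).size < 4:
        raise ValidationError("need >= 4 distinct free concentrations")
    if np.any(f < 0) or np.any(np.isnan(y)):
        raise ValidationError("isotherm values must be nonnegative and finite")
    ymax = float(np.max(y))
    if ymax <= 0:
        raise ValidationError("all bound values <= 0: nothing to fit")

    # Deterministic start: B_max from the plateau, K_d from half-saturation.
    bmax0 = 1.05 * ymax
    half = bmax0 / 2.0
    above = f[y >= half]
    kd0 = float(above.min()) if above.size else float(np.median(f[f > 0]))
    kd0 = max(kd0, 1e-6)

    def resid(theta):
        kd, bmax = np.exp(theta)
        return one_site(f, kd, bmax) - y

    def jac(theta):
        kd, bmax = np.exp(theta)
        J = np.empty((f.size, 2))
        J[:, 0] = -bmax * f * kd / (kd + f) ** 2   # d r / d log kd
        J[:, 1] = bmax * f / (kd + f)              # d r / d log bmax
        return J

    sol = optimize.least_squares(resid, x0=np.log([kd0, bmax0]), jac=jac,
                                 method="lm", xtol=XTOL, ftol=FTOL,
                                 max_nfev=MAX_NFEV)
    if not sol.success:
        raise ConvergenceError(f"one-site fit did not converge: {sol.message}",
                               trace=[sol.message, f"nfev={sol.nfev}"])
    kd, bmax = np.exp(sol.x)
    rss = float(2 * sol.cost)
    se_log = _param_se(sol.jac, rss, f.size, 2)
    return BindingFit(kd=float(kd), bmax=float(bmax),
                      kd_se=float(kd * se_log[0]),
                      bmax_se=float(bmax * se_log[1]),
                      rss=rss, n=int(f.size),
                      saturation_warning=bool(np.max(f) < kd))


# ---------------------------------------------------------------------------
# Stopped-flow single-exponential
# ---------------------------------------------------------------------------

@dataclass
class ExponentialFit:
    a: float       # drift slope, signal units / s
    b: float       # offset
    c: float       # amplitude (negative for a rising trace)
    k_obs: float   # s⁻¹
    k_obs_se: float
    rss: float
    n: int
    concentration: Optional[float] = None  # μM, carried from the trace


def exponential_model(t: np.ndarray, a: float, b: float, c: float,
                      k: float) -> np.ndarray:
    return a * t + b + c * np.exp(-k * t)


def _exp_start(t: np.ndarray, y: np.ndarray, drift: bool
               ) -> tuple[float, float, float, float]:
    """Deterministic, derivative-free initialisation.

    Drift slope from OLS on the last quartile, offset from the drift-
    corrected last-quartile mean, amplitude from the first sample, rate
    from a log-linear regression of the residual magnitude over the first
    half of the trace.
    """
    n = t.size
    q = max(3, n // 4)
    tq, yq = t[-q:], y[-q:]
    a0 = float(stats.linregress(tq, yq).slope) if drift else 0.0
    b0 = float(np.mean(yq - a0 * tq))
    c0 = float(y[0] - a0 * t[0] - b0)
    half = max(3, n // 2)
    resid = np.abs(y[:half] - (a0 * t[:half] + b0))
    span = float(t[-1] - t[0])
    mask = resid > 1e-12 * max(np.ptp(y), 1.0)
    if mask.sum() >= 3:
        k0 = -float(stats.linregress(t[:half][mask],
                                     np.log(resid[mask])).slope)
    else:
        k0 = np.nan
    if not np.isfinite(k0) or k0 <= 0:
        k0 = 1.0 / (0.2 * span) if span > 0 else 1.0
    return a0, b0, c0, k0


def fit_single_exponential(time: Sequence[float], signal: Sequence[float],
                           drift: bool = True,
                           concentration: Optional[float] = None,
                           ) -> ExponentialFit:
    """Fit y(t) = a·t + b + c·e^(−k_obs·t) to a stopped-flow trace.

    The amplitude sign is free (rise for reduction, decay for oxidation);
    ``drift=False`` pins a = 0. k_obs is optimised in log space so it stays
    positive. A trace that is pure drift (vanishing fitted amplitude) is
    rejected as unidentifiable.
    """
    t, y = _as_arrays(time, signal)
    if t.size != y.size:
        raise ValidationError("time and signal differ in length")
    if t.size < 20:
        raise ValidationError("need >= 20 trace points")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("time points must be strictly increasing")

    a0, b0, c0, k0 = _exp_start(t, y, drift)
    scale = max(float(np.ptp(y)), 1e-12)
    if abs(c0) < 1e-9 * scale:
        c0 = np.sign(c0 or 1.0) * 1e-3 * scale

    if drift:
        def resid(theta):
            a, b, c, w = theta
            return exponential_model(t, a, b, c, np.exp(w)) - y

        def jac(theta):
            a, b, c, w = theta
            k = np.exp(w)
            e = np.exp(-k * t)
            return np.column_stack([t, np.ones_like(t), e, -c * k * t * e])

        x0 = np.array([a0, b0, c0, np.log(k0)])
    else:
        def resid(theta):
            b, c, w = theta
            return exponential_model(t, 0.0, b, c, np.exp(w)) - y

        def jac(theta):
            b, c, w = theta
            k = np.exp(w)
            e = np.exp(-k * t)
            return np.column_stack([np.ones_like(t), e, -c * k * t * e])

        x0 = np.array([b0, c0, np.log(k0)])

    sol = optimize.least_squares(resid, x0=x0, jac=jac, method="lm",
                                 xtol=XTOL, ftol=FTOL, max_nfev=MAX_NFEV)
    if not sol.success:
        raise ConvergenceError(
            f"exponential fit did not converge: {sol.message}",
            trace=[sol.message, f"nfev={sol.nfev}"])
    if drift:
        a, b, c, w = sol.x
    else:
        a = 0.0
        b, c, w = sol.x
    k = float(np.exp(w))
    if abs(c) < 1e-6 * scale:
        raise ConvergenceError(
            "degenerate amplitude: trace is indistinguishable from pure "
            f"drift (|c| = {abs(c):.3g})")
    rss = float(2 * sol.cost)
    se = _param_se(sol.jac, rss, t.size, sol.x.size)
    return ExponentialFit(a=float(a), b=float(b), c=float(c), k_obs=k,
                          k_obs_se=float(k * se[-1]), rss=rss,
                          n=int(t.size), concentration=concentration)


# ---------------------------------------------------------------------------
# Second-order regression
# ---------------------------------------------------------------------------

@dataclass
class SecondOrderFit:
    k_app: float           # M⁻¹ s⁻¹
    k_app_se: float
    intercept: float       # s⁻¹ (0 when forced through the origin)
    intercept_se: float
    concentrations: np.ndarray = field(repr=False)  # M
    k_obs: np.ndarray = field(repr=False)           # s⁻¹
    r_squared: float = float("nan")


def fit_second_order(concentrations_molar: Sequence[float],
                     k_obs: Sequence[float],
                     through_origin: bool = False) -> SecondOrderFit:
    """OLS of k_obs against reagent concentration (in M) → k_app, M⁻¹ s⁻¹.

    The intercept is free by default; ``through_origin=True`` forces the
    pseudo-first-order line through zero. Requires >= 4 distinct
    concentrations.
    """
    conc, kobs = _as_arrays(concentrations_molar, k_obs)
    if conc.size != kobs.size:
        raise ValidationError("concentrations and k_obs differ in length")
    if np.unique(conc).size < 4:
        raise ValidationError("need >= 4 distinct concentrations")
    if through_origin:
        sxx = float(np.sum(conc ** 2))
        slope = float(np.sum(conc * kobs)) / sxx
        resid = kobs - slope * conc
        dof = conc.size - 1
        se = float(np.sqrt(np.sum(resid ** 2) / dof / sxx)) if dof else np.nan
        sst = float(np.sum((kobs - kobs.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else 1.0
        return SecondOrderFit(k_app=slope, k_app_se=se, intercept=0.0,
                              intercept_se=0.0, concentrations=conc,
                              k_obs=kobs, r_squared=r2)
    res = stats.linregress(conc, kobs)
    return SecondOrderFit(k_app=float(res.slope), k_app_se=float(res.stderr),
                          intercept=float(res.intercept),
                          intercept_se=float(res.intercept_stderr),
                          concentrations=conc, k_obs=kobs,
                          r_squared=float(res.rvalue) ** 2)


# ---------------------------------------------------------------------------
# Linear-phase rate and depletion
# ---------------------------------------------------------------------------

@dataclass
class LinearPhaseRate:
    rate: float
    rate_se: float
    window: tuple[float, float]
    n_points: int
    r_squared: float


def _window_r2(t: np.ndarray, y: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return 1.0  # perfectly flat window: the line fits exactly
    res = stats.linregress(t, y)
    return float(res.rvalue) ** 2


def estimate_linear_phase_rate(time: Sequence[float], values: Sequence[float],
                               window: tuple[float, float] = (0.0, 120.0),
                               auto: bool = False,
                               r2_min: float = 0.98) -> LinearPhaseRate:
    """Initial-rate estimate: OLS slope over the linear phase.

    The default window is 0–120 min (the time axis carries whatever unit
    the series uses). In ``auto`` mode the window is the longest prefix of
    the series keeping R² >= ``r2_min`` (at least 3 points).
    """
    t, y = _as_arrays(time, values)
    if t.size != y.size:
        raise ValidationError("time and values differ in length")
    if auto:
        best = 3
        if t.size < 3:
            raise ValidationError("need >= 3 points for a rate")
        for m in range(3, t.size + 1):
            if _window_r2(t[:m], y[:m]) >= r2_min:
                best = m
            else:
                break
        sel = np.zeros(t.size, dtype=bool)
        sel[:best] = True
        window = (float(t[0]), float(t[best - 1]))
    else:
        sel = (t >= window[0]) & (t <= window[1])
        if sel.sum() < 3:
            raise ValidationError(
                f"fewer than 3 points in window {window}")
    res = stats.linregress(t[sel], y[sel])
    return LinearPhaseRate(rate=float(res.slope), rate_se=float(res.stderr),
                           window=(float(window[0]), float(window[1])),
                           n_points=int(sel.sum()),
                           r_squared=_window_r2(t[sel], y[sel]))


@dataclass
class DepletionSummary:
    status: str                 # "depleted" | "not_depleted"
    depletion_time: Optional[float]
    threshold_fraction: float
    initial_concentration: float


def summarize_depletion(time: Sequence[float],
                        concentration: Sequence[float],
                        threshold_fraction: float = 0.05) -> DepletionSummary:
    """Time at which a reductant trace falls below a fraction of its start.

    The crossing must be sustained — two consecutive samples at or below
    threshold·initial — to reject single-sample noise; the reported time is
    linearly interpolated between the last sample above threshold and the
    first of the sub-threshold pair. A trace that never crosses reports
    ``not_depleted``.
    """
    t, c = _as_arrays(time, concentration)
    if t.size != c.size or t.size < 2:
        raise ValidationError("need matching time/concentration series (n>=2)")
    if not 0 < threshold_fraction < 1:
        raise ValidationError("threshold fraction must be in (0, 1)")
    c0 = float(c[0])
    if c0 <= 0:
        raise ValidationError("initial concentration must be positive")
    thr = threshold_fraction * c0
    below = c <= thr
    for i in range(t.size):
        sustained = below[i] and (i + 1 < t.size and below[i + 1]
                                  or i + 1 == t.size)
        if not sustained:
            continue
        if i == 0:
            return DepletionSummary("depleted", float(t[0]),
                                    threshold_fraction, c0)
        # interpolate the crossing between samples i-1 (above) and i
        t_cross = t[i - 1] + (thr - c[i - 1]) / (c[i] - c[i - 1]) * (t[i] - t[i - 1])
        return DepletionSummary("depleted", float(t_cross),
                                threshold_fraction, c0)
    return DepletionSummary("not_depleted", None, threshold_fraction, c0)


# ---------------------------------------------------------------------------
# Replicate convention
# ---------------------------------------------------------------------------

def replicate_summary(values: Sequence[float]) -> tuple[float, float]:
    """Mean ± SD across replicate fits (ddof=1; SD 0 for a single value)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("no replicate values")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return float(np.mean(v)), sd
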