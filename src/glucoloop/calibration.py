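"""Sensor calibration: sigmoidal concentration-response fitting and inversion.

Blank-subtracted chronoamperometric responses fall sigmoidally with glucose
concentration on a log scale: a near-flat plateau at low concentration (the
enzyme-limited regime, within noise of the blank), a steep monotone decline
through the working range, and saturation toward the blank at high
concentration. The default model is the four-parameter logistic (4PL) on
x = log10(concentration):

    f(x) = lower + (upper - lower) / (1 + exp(slope * (x - xmid)))

with ``upper``/``lower`` the asymptotic responses (μA), ``xmid`` the
inflection log-concentration and ``slope`` > 0 for a response that
decreases with concentration. Unknown concentrations are estimated by
inverting the fitted curve on its usable monotone branch, with validity
flags instead of silent extrapolation, and approximate confidence
intervals from the fit covariance (first-order delta method).

A monotone piecewise interpolant (PCHIP) is available as a fallback for
sensors the 4PL fits poorly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, curve_fit

from .exceptions import DataError, FitError, InsufficientDataError, StateError
from .traces import CalibrationTable

#: Minimum |df/dx| (μA per log10 μM) for a region to count as usable slope.
DEFAULT_SLOPE_THRESHOLD: float = 1e-3

#: Inverse predictions are never extrapolated beyond fit_range scaled by these.
EXTRAPOLATION_GUARD: tuple[float, float] = (0.5, 2.0)


def four_param_logistic(x, lower, upper, xmid, slope):
    """4PL response at log10-concentration ``x`` (decreasing for slope > 0)."""
    return lower + (upper - lower) / (1.0 + np.exp(slope * (x - xmid)))


class EstimateStatus(str, Enum):
    OK = "ok"
    BELOW_RANGE = "below_range"
    ABOVE_RANGE = "above_range"
    AMBIGUOUS_NONMONOTONE = "ambiguous_nonmonotone"
    SATURATED = "saturated"


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Inverse-prediction result: value, interval and validity flag.

    ``value`` is in μM. When ``status`` is not OK the value is a boundary
    projection onto the curve's usable range and must not be read as a
    quantitative estimate.
    """

    value: float
    interval: tuple[float, float]
    status: EstimateStatus

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if self.status is EstimateStatus.OK and not (lo <= self.value <= hi):
            raise ValueError("interval must bracket the value when status is ok")


@dataclass
class CalibrationCurve:
    """Fitted concentration-response model for one sensor.

    ``params`` for the 4PL are (lower, upper, xmid, slope); ``fit_range``
    is the concentration span of the data; ``monotone_range`` the
    sub-range on which |df/dx| exceeds the slope threshold, i.e. where
    inversion is well conditioned.
    """

    sensor_id: int
    model_kind: str  # "four_param_logistic" | "monotone_interpolant"
    params: tuple[float, ...]
    fit_range: tuple[float, float]
    monotone_range: tuple[float, float]
    fit_rss: float
    covariance: np.ndarray | None = None
    residual_sd: float = 0.0
    excluded: list[tuple[float, float]] = field(default_factory=list)
    slope_threshold: float = DEFAULT_SLOPE_THRESHOLD
    _interpolant: PchipInterpolator | None = field(default=None, repr=False)

    # -- forward model ---------------------------------------------------
    def predict(self, concentration_um):
        """Fitted response (μA) at the given concentration(s) in μM."""
        c = np.asarray(concentration_um, dtype=float)
        if np.any(c <= 0):
            raise DataError("concentration must be > 0 μM")
        x = np.log10(c)
        if self.model_kind == "four_param_logistic":
            out = four_param_logistic(x, *self.params)
        else:
            out = self._interpolant(x)
        return float(out) if np.isscalar(concentration_um) else out

    def local_slope(self, concentration_um: float) -> float:
        """d(response)/d(log10 c), μA per decade, at a concentration."""
        x = math.log10(concentration_um)
        h = 1e-5
        if self.model_kind == "four_param_logistic":
            f = lambda z: four_param_logistic(z, *self.params)
        else:
            f = self._interpolant
        return float((f(x + h) - f(x - h)) / (2 * h))

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "sensor_id": self.sensor_id,
            "model_kind": self.model_kind,
            "params": list(self.params),
            "fit_range_uM": list(self.fit_range),
            "monotone_range_uM": list(self.monotone_range),
            "fit_rss": self.fit_rss,
            "residual_sd": self.residual_sd,
            "excluded_points": [list(p) for p in self.excluded],
            "slope_threshold": self.slope_threshold,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _initial_4pl_params(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    # deterministic initialization: asymptotes from observed extremes,
    # inflection at the median log-concentration, slope sign from the trend
    lower, upper = float(y.min()), float(y.max())
    xmid = float(np.median(x))
    trend = np.polyfit(x, y, 1)[0]
    slope = 2.0 if trend < 0 else -2.0  # slope>0 encodes a decreasing curve
    return lower, upper, xmid, slope


def _monotone_range_4pl(
    params: Sequence[float], fit_range: tuple[float, float], threshold: float
) -> tuple[float, float]:
    lower, upper, xmid, slope = params
    x_lo, x_hi = math.log10(fit_range[0]), math.log10(fit_range[1])
    grid = np.linspace(x_lo, x_hi, 512)
    s = np.exp(np.clip(slope * (grid - xmid), -500, 500))
    deriv = -(upper - lower) * slope * s / (1.0 + s) ** 2
    ok = np.abs(deriv) >= threshold
    if not ok.any():
        return (fit_range[0], fit_range[0])  # degenerate: no usable branch
    # |df/dx| of a 4PL is unimodal in x, so the usable region is contiguous
    idx = np.nonzero(ok)[0]
    return (float(10 ** grid[idx[0]]), float(10 ** grid[idx[-1]]))


def flag_nonmonotone_points(table: CalibrationTable) -> list[float]:
    """Concentrations whose delta breaks the overall decreasing trend.

    A point is flagged when its delta is larger than the delta at the
    previous (lower) concentration by more than 0.5 μA within the
    declining branch (past the response maximum). Flagged points are
    candidates for exclusion, never silently averaged in.
    """
    concs = table.concentrations
    deltas = table.delta_array
    peak = int(np.argmax(deltas))
    flagged = []
    for k in range(peak + 1, len(concs)):
        if deltas[k] > deltas[k - 1] + 0.5:
            flagged.append(float(concs[k]))
    return flagged


def fit_calibration_curve(
    table: CalibrationTable,
    model_kind: str = "four_param_logistic",
    slope_threshold: float = DEFAULT_SLOPE_THRESHOLD,
    exclude_outlier: bool = True,
) -> CalibrationCurve:
    """Least-squares fit of blank-subtracted response vs log10 concentration.

    Fitting is deterministic: initial values follow a fixed rule (observed
    extremes for the asymptotes, median log-concentration for the
    inflection, slope sign from the overall trend). Points that break the
    declining trend past the response peak (see
    :func:`flag_nonmonotone_points`) are excluded up front, and at most
    one further point may be excluded when its residual exceeds 3x the
    robust residual SD (1.4826*MAD); all exclusions are recorded on the
    returned curve — never silently averaged into a monotone fit.
    """
    excluded: list[tuple[float, float]] = []
    nonmono = set(flag_nonmonotone_points(table)) if exclude_outlier else set()
    concs = np.array([c for c in table.concentrations if c not in nonmono])
    deltas = np.array([table.deltas[c] for c in concs])
    excluded += [(float(c), float(table.deltas[c])) for c in sorted(nonmono)]
    if np.any(concs <= 0):
        raise DataError("calibration requires concentrations > 0")
    if np.allclose(deltas, deltas[0]):
        raise FitError("degenerate panel: all responses equal; nothing to fit")

    x = np.log10(concs)
    y = deltas.copy()
    fit_range = (float(concs.min()), float(concs.max()))

    if model_kind == "monotone_interpolant":
        order = np.argsort(x)
        interp = PchipInterpolator(x[order], y[order], extrapolate=False)
        rss = 0.0
        curve = CalibrationCurve(
            sensor_id=table.sensor_id,
            model_kind=model_kind,
            params=(),
            fit_range=fit_range,
            monotone_range=fit_range,
            fit_rss=rss,
            _interpolant=interp,
            excluded=excluded,
            slope_threshold=slope_threshold,
        )
        curve.monotone_range = _monotone_range_interp(curve, slope_threshold)
        return curve
    if model_kind != "four_param_logistic":
        raise FitError(f"unknown model_kind: {model_kind!r}")
    if len(concs) < 4:
        raise FitError("4PL needs at least 4 non-blank points")

    def do_fit(xv, yv):
        p0 = _initial_4pl_params(xv, yv)
        try:
            popt, pcov = curve_fit(
                four_param_logistic, xv, yv, p0=p0, maxfev=20000
            )
        except RuntimeError as exc:  # pragma: no cover - scipy convergence
            raise FitError(f"4PL fit failed to converge: {exc}") from exc
        resid = yv - four_param_logistic(xv, *popt)
        return popt, pcov, resid

    popt, pcov, resid = do_fit(x, y)
    if exclude_outlier and len(x) > 5:
        mad = np.median(np.abs(resid - np.median(resid)))
        robust_sd = 1.4826 * mad
        worst = int(np.argmax(np.abs(resid)))
        if robust_sd > 0 and abs(resid[worst]) > 3 * robust_sd:
            excluded.append((float(concs[worst]), float(y[worst])))
            keep = np.ones(len(x), bool)
            keep[worst] = False
            popt, pcov, resid = do_fit(x[keep], y[keep])

    rss = float(np.sum(resid**2))
    dof = max(len(resid) - 4, 1)
    return CalibrationCurve(
        sensor_id=table.sensor_id,
        model_kind="four_param_logistic",
        params=tuple(float(p) for p in popt),
        fit_range=fit_range,
        monotone_range=_monotone_range_4pl(popt, fit_range, slope_threshold),
        fit_rss=rss,
        covariance=pcov,
        residual_sd=float(math.sqrt(rss / dof)),
        excluded=excluded,
        slope_threshold=slope_threshold,
    )


def _monotone_range_interp(
    curve: CalibrationCurve, threshold: float
) -> tuple[float, float]:
    x_lo, x_hi = (math.log10(v) for v in curve.fit_range)
    grid = np.linspace(x_lo, x_hi, 512)
    deriv = curve._interpolant.derivative()(grid)
    sign = np.sign(np.median(deriv[np.abs(deriv) > 0])) if np.any(deriv) else 0
    ok = (np.abs(deriv) >= threshold) & (np.sign(deriv) == sign)
    if not ok.any():
        return (curve.fit_range[0], curve.fit_range[0])
    idx = np.nonzero(ok)[0]
    # take the longest contiguous run of usable, same-signed slope
    runs = np.split(idx, np.nonzero(np.diff(idx) > 1)[0] + 1)
    best = max(runs, key=len)
    return (float(10 ** grid[best[0]]), float(10 ** grid[best[-1]]))


def estimate_concentration(
    curve: CalibrationCurve, delta_ua: float, z: float = 1.96,
    min_slope: float | None = None,
) -> ConcentrationEstimate:
    """Invert the fitted curve to estimate concentration from a response.

    Inversion is restricted to the curve's monotone branch. Responses
    outside the branch's response span return boundary projections with
    ``below_range`` / ``above_range`` / ``saturated`` status; estimates
    are never extrapolated beyond the fitted concentration span scaled
    by the extrapolation guard. The interval is an approximate
    ``z``-score confidence interval from the fit covariance and residual
    scatter, propagated through the inverse (delta method).

    ``min_slope`` (μA per log10 μM) sets how much local sensitivity the
    curve must have at the inverted point for the estimate to be marked
    OK; below it the status is ``ambiguous_nonmonotone`` with a
    guard-wide interval. It defaults to the curve's own slope threshold;
    callers that act on estimates (e.g. the closed loop) may require a
    stricter gate.
    """
    if curve.params == () and curve._interpolant is None:
        raise StateError("curve is not fitted")
    if min_slope is None:
        min_slope = curve.slope_threshold
    if not math.isfinite(delta_ua):
        raise DataError("delta must be finite")
    c_lo, c_hi = curve.monotone_range
    if c_lo >= c_hi:
        return ConcentrationEstimate(
            value=c_lo, interval=(c_lo, c_hi), status=EstimateStatus.AMBIGUOUS_NONMONOTONE
        )
    f_lo = curve.predict(c_lo)   # response at low concentration (high for a decreasing curve)
    f_hi = curve.predict(c_hi)
    decreasing = f_lo > f_hi
    resp_hi, resp_lo = (f_lo, f_hi) if decreasing else (f_hi, f_lo)

    guard_lo = curve.fit_range[0] * EXTRAPOLATION_GUARD[0]
    guard_hi = curve.fit_range[1] * EXTRAPOLATION_GUARD[1]

    if delta_ua > resp_hi:
        # response larger than anything on the branch -> below the range
        value = c_lo if decreasing else c_hi
        status = EstimateStatus.BELOW_RANGE if decreasing else EstimateStatus.ABOVE_RANGE
        return ConcentrationEstimate(value=value, interval=(value, value), status=status)
    if delta_ua < resp_lo:
        value = c_hi if decreasing else c_lo
        # near/below the lower asymptote the sensor is saturated
        asymptote = min(f_lo, f_hi)
        status = (
            EstimateStatus.SATURATED
            if delta_ua <= asymptote + 0.05
            else (EstimateStatus.ABOVE_RANGE if decreasing else EstimateStatus.BELOW_RANGE)
        )
        return ConcentrationEstimate(value=value, interval=(value, value), status=status)

    x_lo, x_hi = math.log10(c_lo), math.log10(c_hi)
    if curve.model_kind == "four_param_logistic":
        g = lambda xv: four_param_logistic(xv, *curve.params) - delta_ua
    else:
        g = lambda xv: float(curve._interpolant(xv)) - delta_ua
    x_star = brentq(g, x_lo, x_hi, xtol=1e-12)
    value = float(10**x_star)
    value = min(max(value, guard_lo), guard_hi)

    # delta-method interval: response-space uncertainty divided by local slope
    sd_resp = curve.residual_sd
    if curve.covariance is not None and curve.model_kind == "four_param_logistic":
        grad = _4pl_param_gradient(x_star, curve.params)
        sd_resp = math.sqrt(
            max(float(grad @ curve.covariance @ grad), 0.0) + curve.residual_sd**2
        )
    slope = curve.local_slope(value)
    if abs(slope) < min_slope:
        return ConcentrationEstimate(
            value=value, interval=(guard_lo, guard_hi),
            status=EstimateStatus.AMBIGUOUS_NONMONOTONE,
        )
    half_x = z * sd_resp / abs(slope)
    lo = max(10.0 ** max(x_star - half_x, -300.0), guard_lo)
    hi = min(10.0 ** min(x_star + half_x, 300.0), guard_hi)
    return ConcentrationEstimate(
        value=value, interval=(min(lo, value), max(hi, value)), status=EstimateStatus.OK
    )


def _4pl_param_gradient(x: float, params: Sequence[float]) -> np.ndarray:
    lower, upper, xmid, slope = params
    e = math.exp(max(min(slope * (x - xmid), 500), -500))
    denom = 1.0 + e
    d_lower = 1.0 - 1.0 / denom
    d_upper = 1.0 / denom
    common = -(upper - lower) * e / denom**2
    d_xmid = common * (-slope)
    d_slope = common * (x - xmid)
    return np.array([d_lower, d_upper, d_xmid, d_slope])


def limit_of_blank(blank_deltas: Sequence[float]) -> float:
    """Limit of blank: mean + 3*SD of replicate blank-subtracted blanks.

    Responses whose |delta| falls below this threshold are statistically
    indistinguishable from the analyte-free matrix. Sample SD (n-1).
    """
    b = np.asarray(blank_deltas, dtype=float)
    if b.size < 3:
        raise InsufficientDataError("limit of blank needs >= 3 replicates")
    if not np.all(np.isfinite(b)):
        raise DataError("blank replicates must be finite")
    return float(b.mean() + 3.0 * b.std(ddof=1))
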