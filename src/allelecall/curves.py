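"""Amplification-curve processing: baseline, sigmoid fitting, Cq, detection.

A qPCR amplification trace is fluorescence (RFU) against cycle number. The
processing chain is:

1. background subtraction — an ordinary least-squares line fitted over the
   user's background range (the flat part before exponential growth) is
   subtracted from the whole trace;
2. sigmoid model fitting — nonlinear least squares of a 4- or 5-parameter
   logistic (``b4``/``b5``, linear in cycle) or log-logistic (``l4``/``l5``,
   logarithmic in cycle) model;
3. Cq computation — the quantification cycle extracted from the fitted
   curve by one of five methods (first/second-derivative maximum, maximum
   of the cycle-efficiency curve, start of the exponential region, or the
   20%-of-second-derivative-maximum fluorescence crossing);
4. amplification detection — a curve counts as amplified when a Cq exists,
   the fitted amplitude clears a noise floor, and the Cq lies inside the
   recorded cycle span.

Model parameterization (x = cycle):

    b5: F(x) = c + (d - c) / (1 + exp(b (x - e)))**f
    l5: F(x) = c + (d - c) / (1 + exp(b (ln x - ln e)))**f

with f fixed at 1 for the 4-parameter variants. A rising curve has b < 0,
lower asymptote c and plateau d; for ``b4``, e is exactly the inflection
point (the first-derivative maximum).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, stats

from .model import AnalysisSettings, CurveResult, Reaction, SettingsError, SigmoidFit

__all__ = [
    "subtract_background",
    "fit_sigmoid",
    "compute_cq",
    "detect_amplification",
    "endpoint_rfu",
    "analyze_reaction",
    "model_predict",
    "model_derivative",
    "CQ_METHODS",
    "MODELS",
]

MODELS = ("l4", "l5", "b4", "b5")
CQ_METHODS = ("cpD1", "cpD2", "maxE", "expR", "Cy20")

# fraction of the first-derivative maximum defining the start of the
# exponential region for the expR method
EXP_REGION_FRACTION = 0.05

_CLIP = 500.0  # exp argument clip avoiding overflow far from the transition


def _sig_b(x, b, c, d, e, f):
    z = np.clip(b * (x - e), -_CLIP, _CLIP)
    return c + (d - c) / (1.0 + np.exp(z)) ** f


def _sig_b_d1(x, b, c, d, e, f):
    z = np.clip(b * (x - e), -_CLIP, _CLIP)
    E = np.exp(z)
    return -(d - c) * f * b * E * (1.0 + E) ** (-f - 1.0)


def _sig_l(x, b, c, d, e, f):
    x = np.maximum(x, 1e-9)
    z = np.clip(b * (np.log(x) - np.log(e)), -_CLIP, _CLIP)
    return c + (d - c) / (1.0 + np.exp(z)) ** f


def _sig_l_d1(x, b, c, d, e, f):
    x = np.maximum(x, 1e-9)
    z = np.clip(b * (np.log(x) - np.log(e)), -_CLIP, _CLIP)
    E = np.exp(z)
    return -(d - c) * f * (b / x) * E * (1.0 + E) ** (-f - 1.0)


def model_predict(model_type: str, x, b, c, d, e, f=1.0):
    """Evaluate a sigmoid model at cycles ``x``."""
    if model_type in ("b4", "b5"):
        return _sig_b(x, b, c, d, e, f)
    if model_type in ("l4", "l5"):
        return _sig_l(x, b, c, d, e, f)
    raise SettingsError(f"unknown model_type {model_type!r}")


def model_derivative(model_type: str, x, b, c, d, e, f=1.0):
    """Analytic first derivative dF/dx of a sigmoid model."""
    if model_type in ("b4", "b5"):
        return _sig_b_d1(x, b, c, d, e, f)
    if model_type in ("l4", "l5"):
        return _sig_l_d1(x, b, c, d, e, f)
    raise SettingsError(f"unknown model_type {model_type!r}")


def _fit_predict(fit: SigmoidFit, x):
    return model_predict(fit.model_type, x, fit.b, fit.c, fit.d, fit.e, fit.f)


def _fit_d1(fit: SigmoidFit, x):
    return model_derivative(fit.model_type, x, fit.b, fit.c, fit.d, fit.e, fit.f)


def subtract_background(rfu, cycles, bg_range) -> np.ndarray:
    """Subtract a linear baseline fitted over the background cycle range.

    The background range must cover at least three cycles of the trace; the
    fitted line is extrapolated and subtracted across all cycles, so the
    corrected trace has mean ~0 over the background range.
    """
    cycles = np.asarray(cycles, dtype=float)
    rfu = np.asarray(rfu, dtype=float)
    lo, hi = bg_range
    mask = (cycles >= lo) & (cycles <= hi)
    if mask.sum() < 3:
        raise SettingsError(
            f"background range {bg_range} covers {int(mask.sum())} cycles; need >= 3"
        )
    slope, intercept = np.polyfit(cycles[mask], rfu[mask], 1)
    return rfu - (slope * cycles + intercept)


def _initial_params(corrected, cycles, model_type):
    c0 = float(np.min(corrected))
    d0 = float(np.max(corrected))
    amp = d0 - c0
    if amp <= 0:
        amp = 1.0
    half = c0 + amp / 2.0
    above = np.nonzero(corrected >= half)[0]
    if len(above) and above[0] > 0:
        i = above[0]
        x0, x1 = cycles[i - 1], cycles[i]
        y0, y1 = corrected[i - 1], corrected[i]
        e0 = float(x0 + (half - y0) / (y1 - y0) * (x1 - x0)) if y1 != y0 else float(x1)
    else:
        e0 = float(cycles[len(cycles) // 2])
    slopes = np.diff(corrected) / np.diff(cycles)
    m = float(np.max(slopes)) if len(slopes) else 1.0
    m = max(m, amp / (cycles[-1] - cycles[0] + 1.0))
    if model_type in ("b4", "b5"):
        b0 = -4.0 * m / amp
    else:
        e0 = max(e0, 1.0)
        b0 = -4.0 * m * e0 / amp
    return b0, c0, d0, e0


def fit_sigmoid(corrected_rfu, cycles, model_type: str = "b4",
                weights=None) -> SigmoidFit:
    """Fit a sigmoid model by (weighted) nonlinear least squares.

    Initial values come from the data: c from the minimum, d from the
    maximum, e from the half-rise crossing, b from the steepest observed
    rise. Optimizer failure is encoded as ``converged=False`` — never an
    exception — so a flat or garbage trace flows through the pipeline as a
    non-amplified reaction.
    """
    corrected = np.asarray(corrected_rfu, dtype=float)
    cycles = np.asarray(cycles, dtype=float)
    five = model_type in ("b5", "l5")
    n_params = 5 if five else 4
    fit = SigmoidFit(model_type=model_type)
    if len(cycles) < n_params + 3 or not np.all(np.isfinite(corrected)):
        return fit

    b0, c0, d0, e0 = _initial_params(corrected, cycles, model_type)
    p0 = [b0, c0, d0, e0] + ([1.0] if five else [])

    if five:
        def func(x, b, c, d, e, f):
            return model_predict(model_type, x, b, c, d, e, f)
        bounds = ([-np.inf, -np.inf, -np.inf, 1e-6, 1e-3],
                  [np.inf, np.inf, np.inf, 10.0 * cycles[-1], 50.0])
    else:
        def func(x, b, c, d, e):
            return model_predict(model_type, x, b, c, d, e, 1.0)
        bounds = ([-np.inf, -np.inf, -np.inf, 1e-6],
                  [np.inf, np.inf, np.inf, 10.0 * cycles[-1]])

    sigma = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        sigma = 1.0 / np.sqrt(np.maximum(w, 1e-12))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                func, cycles, corrected, p0=p0, sigma=sigma,
                bounds=bounds, maxfev=1500, method="trf",
            )
    except (RuntimeError, ValueError):
        return fit

    if not np.all(np.isfinite(popt)):
        return fit
    fit.b, fit.c, fit.d, fit.e = (float(v) for v in popt[:4])
    fit.f = float(popt[4]) if five else 1.0
    resid = corrected - _fit_predict(fit, cycles)
    fit.rss = float(np.sum(resid ** 2))
    fit.converged = True
    _normalize_orientation(fit)
    return fit


def _normalize_orientation(fit: SigmoidFit) -> None:
    """Normalize a converged fit so the curve rises (d >= c, b < 0).

    For f = 1 the logistic is symmetric and (b, c, d) -> (-b, d, c) is an
    exact reparameterization of the same function, so a mirrored optimizer
    solution is folded back without changing the fitted curve.
    """
    if fit.f == 1.0 and fit.d < fit.c:
        fit.b, fit.c, fit.d = -fit.b, fit.d, fit.c


def _is_rising(fit: SigmoidFit) -> bool:
    # the curve rises iff b and (d - c) have opposite signs; (b, c, d) and
    # (-b, d, c) describe the same symmetric curve, so d < c alone is not
    # an orientation indicator
    return fit.b * (fit.d - fit.c) <= 0


def _start_asymptote(fit: SigmoidFit) -> float:
    """The asymptote the transition departs from (x -> start of the run)."""
    return fit.c if fit.b < 0 else fit.d


def _refine_parabola(xs: np.ndarray, ys: np.ndarray, i: int) -> float:
    """Vertex of the parabola through three grid points around index i."""
    if i <= 0 or i >= len(xs) - 1:
        return float(xs[i])
    y0, y1, y2 = ys[i - 1], ys[i], ys[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0 or not np.isfinite(denom):
        return float(xs[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    return float(xs[i] + delta * (xs[i] - xs[i - 1]))


def _grid(fit: SigmoidFit, span: tuple[float, float], step: float = 0.01):
    lo, hi = span
    if fit.model_type in ("l4", "l5"):
        lo = max(lo, 0.05)
    return np.arange(lo, hi + step / 2.0, step)


def compute_cq(fit: SigmoidFit, cq_method: str,
               span: tuple[float, float] = (1.0, 40.0)) -> float | None:
    """Extract the quantification cycle from a converged fit.

    Methods: cpD1 — cycle of the first-derivative maximum; cpD2 — cycle of
    the second-derivative maximum; maxE — cycle of the maximum of the
    cycle-efficiency proxy E(x) = F(x)/F(x-1); expR — first cycle where the
    first derivative reaches 5% of its maximum (start of the exponential
    region); Cy20 — the cycle where the fitted fluorescence equals
    c + 0.20 (F(cpD2) - c).

    All maxima are located on a 0.01-cycle grid and refined by parabolic
    interpolation of the three bracketing points. Decreasing fits are
    handled by working with the derivative magnitude, so Cq is invariant to
    curve orientation. Returns None for a non-converged fit.
    """
    if fit is None or not fit.converged:
        return None
    sign = 1.0 if _is_rising(fit) else -1.0
    # search past the recorded span so a transition beyond the data is
    # reported where the fit puts it (and later rejected by the span check)
    # rather than clamped to the last cycle
    lo, hi = span
    xs = _grid(fit, (lo, hi + 0.5 * (hi - lo)))
    if len(xs) < 3:
        return None

    d1 = sign * _fit_d1(fit, xs)

    if cq_method == "cpD1":
        i = int(np.argmax(d1))
        return _refine_parabola(xs, d1, i)

    if cq_method in ("cpD2", "Cy20"):
        h = 1e-4
        d2 = sign * (_fit_d1(fit, xs + h) - _fit_d1(fit, xs - h)) / (2.0 * h)
        i = int(np.argmax(d2))
        cpd2 = _refine_parabola(xs, d2, i)
        if cq_method == "cpD2":
            return cpd2
        # Cy20: fluorescence crossing at 20% of the rise reached at cpD2
        base = _start_asymptote(fit)
        target = base + 0.20 * (float(_fit_predict(fit, np.array([cpd2]))[0]) - base)
        ys = sign * (_fit_predict(fit, xs) - target)
        crossing = np.nonzero(np.diff(np.signbit(ys)))[0]
        if len(crossing) == 0:
            return None
        j = int(crossing[0])
        y0, y1 = ys[j], ys[j + 1]
        if y1 == y0:
            return float(xs[j])
        return float(xs[j] - y0 * (xs[j + 1] - xs[j]) / (y1 - y0))

    if cq_method == "maxE":
        mask = xs >= xs[0] + 1.0
        xe = xs[mask]
        num = _fit_predict(fit, xe)
        den = _fit_predict(fit, xe - 1.0)
        floor = max(1e-9, 1e-6 * fit.amplitude)
        eff = sign * num / np.maximum(sign * den, floor)
        i = int(np.argmax(eff))
        return _refine_parabola(xe, eff, i)

    if cq_method == "expR":
        thr = EXP_REGION_FRACTION * float(np.max(d1))
        above = np.nonzero(d1 >= thr)[0]
        if len(above) == 0:
            return None
        j = int(above[0])
        if j == 0:
            return float(xs[0])
        y0, y1 = d1[j - 1], d1[j]
        if y1 == y0:
            return float(xs[j])
        return float(xs[j - 1] + (thr - y0) * (xs[j] - xs[j - 1]) / (y1 - y0))

    raise SettingsError(f"unknown cq_method {cq_method!r}")


def endpoint_rfu(corrected_rfu) -> float:
    """Endpoint fluorescence: mean of the last three corrected readings.

    Averaging damps final-cycle jitter without delaying the endpoint.
    """
    corrected = np.asarray(corrected_rfu, dtype=float)
    if corrected.size == 0:
        raise ValueError("empty trace")
    return float(np.mean(corrected[-3:]))


# amplitude noise floor: max(ABS_FLOOR, NOISE_MULT * baseline residual SD)
ABS_AMPLITUDE_FLOOR = 10.0
NOISE_FLOOR_MULT = 6.0

# significance level of the sigmoid-vs-line lack-of-fit F-test; a curve whose
# sigmoid fit does not beat a straight line at this level is residual baseline
# drift, not amplification
LOF_ALPHA = 1e-5


def _sigmoid_beats_line(fit: SigmoidFit, corrected, cycles) -> bool:
    """Nested-model F-test: does the sigmoid explain more than a line?

    Baseline subtraction extrapolates an 11-point line across the whole
    trace, so negative reactions keep a residual tilt that a sigmoid fit
    will happily absorb. A true amplification curve improves on the best
    straight line by orders of magnitude; residual drift does not.
    """
    n = len(cycles)
    k = 5 if fit.model_type in ("b5", "l5") else 4
    if n <= k:
        return False
    resid_line = corrected - np.polyval(np.polyfit(cycles, corrected, 1), cycles)
    rss_line = float(np.sum(resid_line**2))
    rss_sig = fit.rss
    if rss_sig <= 1e-12 * max(rss_line, 1.0):
        return True  # essentially perfect sigmoid fit
    f_stat = ((rss_line - rss_sig) / (k - 2)) / (rss_sig / (n - k))
    return f_stat > stats.f.isf(LOF_ALPHA, k - 2, n - k)


def _baseline_noise_sd(corrected, cycles, bg_range) -> float:
    lo, hi = bg_range
    mask = (cycles >= lo) & (cycles <= hi)
    if mask.sum() < 3:
        mask = np.zeros_like(cycles, dtype=bool)
        mask[: max(3, len(cycles) // 4)] = True
    seg = np.asarray(corrected, dtype=float)[mask]
    seg = seg - np.polyval(np.polyfit(cycles[mask], seg, 1), cycles[mask])
    return float(np.std(seg))


def detect_amplification(result: CurveResult, settings: AnalysisSettings) -> str:
    """Decide whether a curve shows genuine amplification.

    A reaction is amplified ("ok") when (a) a Cq exists (from the fit, or
    carried in the file when preprocessing is off), (b) the rise amplitude
    clears a noise floor of max(10 RFU, 6 x the baseline residual SD), and
    (c) the Cq lies within the recorded cycle span. Cq-range and RFU
    threshold checks are deliberately NOT part of detection: they are
    separate QC codes.
    """
    if result.cq is None or not np.isfinite(result.cq):
        return "no_amp"
    cycles = result.cycles
    if not (cycles[0] <= result.cq <= cycles[-1]):
        return "no_amp"
    noise_sd = _baseline_noise_sd(result.corrected_rfu, cycles, settings.bg_range)
    floor = max(ABS_AMPLITUDE_FLOOR, NOISE_FLOOR_MULT * noise_sd)
    # the rise must be sustained in the data itself: a fitted step that the
    # trace endpoint does not confirm is noise-chasing, not amplification
    data_rise = endpoint_rfu(result.corrected_rfu) - float(
        np.mean(np.asarray(result.corrected_rfu)[:3])
    )
    if result.fit is not None and result.fit.converged:
        amplitude = result.fit.amplitude
        # a fit whose plateau lies mostly beyond the recorded span
        # extrapolates amplitude it never observed; use the observed rise
        observed = float(_fit_predict(result.fit, np.array([cycles[-1]]))[0]
                         - _fit_predict(result.fit, np.array([cycles[0]]))[0])
        amplitude = min(amplitude, abs(observed), abs(data_rise))
        if amplitude >= floor and not _sigmoid_beats_line(
            result.fit, result.corrected_rfu, cycles
        ):
            return "no_amp"
    else:
        amplitude = data_rise
    if amplitude < floor:
        return "no_amp"
    return "ok"


def analyze_reaction(reaction: Reaction, settings: AnalysisSettings) -> CurveResult:
    """Run the full per-reaction chain and return a CurveResult.

    With ``preprocess`` on, the trace is baseline-corrected, fitted and the
    Cq recomputed with the configured method. With it off, the trace is
    taken as the instrument software produced it and the file's Cq is used;
    a missing file Cq then means the reaction cannot be scored as amplified.
    """
    cycles = reaction.cycles
    if settings.preprocess:
        corrected = subtract_background(reaction.rfu, cycles, settings.bg_range)
        if _worth_fitting(corrected, cycles, settings):
            fit = fit_sigmoid(corrected, cycles, settings.model_type,
                              weights=_weights(corrected, settings))
        else:
            # trace never rises above the noise floor: skip the (slow)
            # sigmoid fit of pure noise, the reaction cannot be amplified
            fit = SigmoidFit(model_type=settings.model_type)
        cq = compute_cq(fit, settings.cq_method, span=(cycles[0], cycles[-1]))
    else:
        corrected = np.asarray(reaction.rfu, dtype=float)
        fit = None
        cq = reaction.preprocessed_cq
    result = CurveResult(
        corrected_rfu=corrected,
        cycles=cycles,
        fit=fit,
        cq=cq,
        endpoint_rfu=endpoint_rfu(corrected),
        amp_status="no_amp",
    )
    result.amp_status = detect_amplification(result, settings)
    if result.amp_status != "ok":
        result.cq = None
    return result


def _worth_fitting(corrected, cycles, settings: AnalysisSettings) -> bool:
    """Cheap rise test deciding whether a sigmoid fit can possibly succeed.

    Uses the same noise floor as amplification detection, so the screen
    never changes a detection outcome — it only avoids fitting flat traces.
    """
    noise_sd = _baseline_noise_sd(corrected, cycles, settings.bg_range)
    floor = max(ABS_AMPLITUDE_FLOOR, NOISE_FLOOR_MULT * noise_sd)
    rise = endpoint_rfu(corrected) - float(np.mean(np.asarray(corrected)[:3]))
    return rise >= floor


def _weights(corrected, settings: AnalysisSettings):
    if not settings.weighted:
        return None
    # 1/F weighting, floored to keep baseline-level points finite
    f = np.maximum(np.abs(np.asarray(corrected, dtype=float)), 1.0)
    return 1.0 / f
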