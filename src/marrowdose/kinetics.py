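"""Time-activity curve fitting and analytic time-integrated activity.

Model selection follows the number of available points and the compartment:

* low compartment — bi-exponential ``A1*exp(-l1*t) + A2*exp(-l2*t)`` when
  four points are available, mono-exponential when three; extrapolated to
  t = 0 and integrated analytically to infinity.  Four points determine the
  four parameters exactly, so counting noise in the single early point can
  drive the fast phase to a non-physiological interpolation whose
  extrapolated area diverges; decay constants are therefore bounded to
  effective half-lives of at least a quarter of the earliest sample time
  (0.5 h for 2 h sampling) — faster phases are unresolvable from the data
  and well below any plasma clearance phase seen with peptide radioligands.
  The bound is expressed relative to the sampling times, so fits are
  invariant under a change of time units.
* high compartment — a two-point line through the ~2 h and ~24 h points
  (clipped at zero if the extrapolation to t = 0 goes negative), then a
  mono-exponential through the points from 24 h on; the time-integrated
  activity is the clipped-line integral over [0, 24 h] plus the analytic
  tail ``A(24)/lambda``.

Fits are bounded nonlinear least squares initialised from log-linear fits
of the tail and of the early residual; a failed or non-physical
bi-exponential falls back to the mono-exponential with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import KineticsError

LN2 = float(np.log(2.0))

#: fastest admissible clearance phase relative to the earliest sample:
#: half-life >= MIN_HALF_LIFE_FRACTION * t_first keeps the exactly-determined
#: 4-point fit away from noise-interpolating solutions
MIN_HALF_LIFE_FRACTION = 0.25


def _max_lambda(times) -> float:
    tpos = times[times > 0]
    if tpos.size == 0:
        return np.inf
    return LN2 / (MIN_HALF_LIFE_FRACTION * float(tpos.min()))


@dataclass
class KineticFit:
    """A fitted time-activity model with its analytic integral."""

    model: str                               # biexp | monoexp | linear_then_monoexp
    params: dict = field(default_factory=dict)
    tia: float = 0.0                         # MBq*h over [0, inf)
    residual_ss: float = 0.0
    uptake_phase: bool = False               # rising early phase flagged
    fallback: bool = False                   # biexp fell back to monoexp

    @property
    def half_lives_h(self) -> list[float]:
        """Effective half-lives ln2/lambda of the exponential phases."""
        if self.model == "monoexp":
            return [LN2 / self.params["lam"]]
        if self.model == "biexp":
            return [LN2 / self.params["lam1"], LN2 / self.params["lam2"]]
        return [LN2 / self.params["lam"]]    # tail of the hybrid model

    @property
    def terminal_half_life_h(self) -> float:
        return self.half_lives_h[-1]

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.model == "monoexp":
            return p["a0"] * np.exp(-p["lam"] * t)
        if self.model == "biexp":
            return (p["a1"] * np.exp(-p["lam1"] * t)
                    + p["a2"] * np.exp(-p["lam2"] * t))
        if self.model == "linear_then_monoexp":
            line = np.clip(p["intercept"] + p["slope"] * t, 0.0, None)
            tail = p["tail_a0"] * np.exp(-p["lam"] * t)
            return np.where(t < p["t_break"], line, tail)
        raise KineticsError(f"unknown model {self.model!r}")

    def auc(self) -> float:
        """Analytic area under the fitted curve over [0, inf), MBq*h."""
        p = self.params
        if self.model == "monoexp":
            return p["a0"] / p["lam"]
        if self.model == "biexp":
            return p["a1"] / p["lam1"] + p["a2"] / p["lam2"]
        if self.model == "linear_then_monoexp":
            early = _clipped_line_integral(p["intercept"], p["slope"],
                                           p["t_break"])
            tail = p["tail_a0"] * np.exp(-p["lam"] * p["t_break"]) / p["lam"]
            return early + tail
        raise KineticsError(f"unknown model {self.model!r}")


def _clipped_line_integral(b: float, m: float, t_end: float) -> float:
    """Integral of max(b + m*t, 0) over [0, t_end]."""
    y0, y1 = b, b + m * t_end
    if y0 >= 0 and y1 >= 0:
        return 0.5 * (y0 + y1) * t_end
    if y0 < 0 and y1 < 0:
        return 0.0
    t_zero = -b / m
    if y0 < 0:                               # rising through zero
        return 0.5 * (t_end - t_zero) * y1
    return 0.5 * t_zero * y0                 # falling through zero


def accumulated_activity(fit: KineticFit) -> float:
    """Time-integrated activity (area under the fitted curve), MBq*h."""
    tia = fit.auc()
    if not np.isfinite(tia) or tia < 0:
        raise KineticsError(f"non-physical time-integrated activity {tia}")
    return tia


# ---------------------------------------------------------------------------
# primitive fits
# ---------------------------------------------------------------------------

def _loglinear(times, acts):
    acts = np.clip(acts, np.max(acts) * 1e-12 + 1e-300, None)
    coef = np.polyfit(times, np.log(acts), 1)
    return float(np.exp(coef[1])), float(max(-coef[0], 1e-6))


def fit_monoexp(times, acts) -> KineticFit:
    times = np.asarray(times, dtype=float)
    acts = np.asarray(acts, dtype=float)
    if times.size < 2:
        raise KineticsError("mono-exponential fit needs >= 2 points")
    a0_0, lam_0 = _loglinear(times, acts)
    lam_max = _max_lambda(times)
    lam_0 = min(lam_0, 0.99 * lam_max)

    def model(t, a0, lam):
        return a0 * np.exp(-lam * t)

    def jac(t, a0, lam):
        e = np.exp(-lam * t)
        return np.stack([e, -a0 * t * e], axis=-1)

    try:
        with warnings.catch_warnings():
            # exactly-determined fits have a singular covariance; benign
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(model, times, acts, p0=(a0_0, lam_0), jac=jac,
                                bounds=([0.0, 1e-12], [np.inf, lam_max]),
                                maxfev=20000)
    except RuntimeError as exc:
        raise KineticsError(f"mono-exponential fit failed: {exc}") from exc
    a0, lam = map(float, popt)
    if lam <= 0:
        raise KineticsError("mono-exponential fit returned lambda <= 0")
    ss = float(np.sum((acts - model(times, *popt)) ** 2))
    return KineticFit(model="monoexp", params={"a0": a0, "lam": lam},
                      tia=a0 / lam, residual_ss=ss)


def _try_biexp(times, acts, p0):
    lam_max = _max_lambda(times)
    p0 = (p0[0], min(p0[1], 0.99 * lam_max), p0[2], min(p0[3], 0.99 * lam_max))

    def model(t, a1, lam1, a2, lam2):
        return a1 * np.exp(-lam1 * t) + a2 * np.exp(-lam2 * t)

    def jac(t, a1, lam1, a2, lam2):
        e1, e2 = np.exp(-lam1 * t), np.exp(-lam2 * t)
        return np.stack([e1, -a1 * t * e1, e2, -a2 * t * e2], axis=-1)

    with warnings.catch_warnings():
        # exactly-determined 4-point fits have a singular covariance; benign
        warnings.simplefilter("ignore", OptimizeWarning)
        popt, _ = curve_fit(model, times, acts, p0=p0, jac=jac,
                            bounds=([0.0, 1e-12, 0.0, 1e-12],
                                    [np.inf, lam_max, np.inf, lam_max]),
                            maxfev=5000)
    a1, lam1, a2, lam2 = map(float, popt)
    if lam1 < lam2:                           # order phases: lam1 > lam2
        a1, lam1, a2, lam2 = a2, lam2, a1, lam1
    ss = float(np.sum((acts - model(times, *popt)) ** 2))
    return KineticFit(model="biexp",
                      params={"a1": a1, "lam1": lam1, "a2": a2, "lam2": lam2},
                      tia=a1 / lam1 + a2 / lam2, residual_ss=ss)


def fit_biexp(times, acts) -> KineticFit:
    """Bounded bi-exponential fit with mono-exponential fallback.

    Initialised by curve peeling: the tail (last two points) seeds the slow
    phase, the early residual seeds the fast phase.  If the bi-exponential
    cannot do at least as well as the nested mono-exponential it is re-seeded
    from it; if it still fails the mono-exponential is returned (flagged).
    """
    times = np.asarray(times, dtype=float)
    acts = np.asarray(acts, dtype=float)
    if times.size < 4:
        raise KineticsError("bi-exponential fit needs >= 4 points")
    mono = fit_monoexp(times, acts)

    # curve peeling init
    a2_0, lam2_0 = _loglinear(times[-2:], acts[-2:])
    resid = acts - a2_0 * np.exp(-lam2_0 * times)
    # numerically-zero residuals would wreck the log-linear slope
    pos = resid > 0.01 * max(resid.max(), 0.0)
    if pos.sum() >= 2:
        a1_0, lam1_0 = _loglinear(times[pos], resid[pos])
    else:
        a1_0, lam1_0 = max(acts[0] - a2_0, acts[0] * 0.1), lam2_0 * 10
    lam1_0 = max(lam1_0, lam2_0 * 1.5)

    fits = []
    try:
        fits.append(_try_biexp(times, acts, (a1_0, lam1_0, a2_0, lam2_0)))
    except RuntimeError:
        pass
    # re-seed from the nested mono-exponential only when peeling failed or
    # did worse than it (rare; keeps the common path to one solver call)
    if not fits or fits[0].residual_ss > mono.residual_ss:
        try:
            fits.append(_try_biexp(times, acts,
                                   (mono.params["a0"] * 0.05,
                                    mono.params["lam"] * 10,
                                    mono.params["a0"], mono.params["lam"])))
        except RuntimeError:
            pass
    fits = [f for f in fits if np.isfinite(f.tia)]
    if fits:
        best = min(fits, key=lambda f: f.residual_ss)
        if best.residual_ss <= mono.residual_ss * (1.0 + 1e-9) + 1e-12:
            return best
    warnings.warn("bi-exponential fit failed or beaten by mono-exponential; "
                  "falling back")
    mono.fallback = True
    return mono


# ---------------------------------------------------------------------------
# compartment-level fitting rules
# ---------------------------------------------------------------------------

def _series_arrays(series):
    if hasattr(series, "times_h"):
        return np.asarray(series.times_h, float), np.asarray(series.activity_mbq, float)
    times, acts = series
    return np.asarray(times, float), np.asarray(acts, float)


def fit_low_tac(series) -> KineticFit:
    """Low compartment: bi-exponential at 4 points, mono-exponential at 3."""
    times, acts = _series_arrays(series)
    if times.size >= 4:
        return fit_biexp(times, acts)
    if times.size == 3:
        return fit_monoexp(times, acts)
    raise KineticsError(f"low-compartment fit needs 3 or 4 points, got {times.size}")


def fit_high_tac(series, t_break: float = 24.0,
                 early_max_h: float = 4.0) -> KineticFit:
    """High compartment: two-point line to 24 h, mono-exponential tail.

    The line runs through the earliest point (must be <= ``early_max_h``)
    and the point nearest ``t_break``; its extrapolation to t = 0 is clipped
    at zero.  Points from ``t_break`` on feed the tail fit.  A rising line
    flags an initial uptake phase.
    """
    times, acts = _series_arrays(series)
    if times.size < 3:
        raise KineticsError("high-compartment fit needs >= 3 points")
    if times[0] > early_max_h:
        raise KineticsError(f"no early (<= {early_max_h} h) point available")
    i_break = int(np.argmin(np.abs(times - t_break)))
    if not (0.5 * t_break <= times[i_break] <= 1.5 * t_break):
        raise KineticsError(f"no point near {t_break} h available")
    tb = float(times[i_break])
    slope = (acts[i_break] - acts[0]) / (tb - times[0])
    intercept = float(acts[0] - slope * times[0])

    tail_sel = times >= tb - 1e-9
    if tail_sel.sum() < 2:
        raise KineticsError("tail fit needs >= 2 points from 24 h on")
    tail = fit_monoexp(times[tail_sel], acts[tail_sel])
    params = {"intercept": intercept, "slope": float(slope), "t_break": tb,
              "tail_a0": tail.params["a0"], "lam": tail.params["lam"]}
    fit = KineticFit(model="linear_then_monoexp", params=params,
                     uptake_phase=slope > 0, residual_ss=tail.residual_ss)
    fit.tia = fit.auc()
    return fit
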