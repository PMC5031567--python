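"""Camera calibration and conjugate-view activity quantification.

The conjugate-view method estimates the activity of a source at arbitrary
depth from the geometric mean of opposed (anterior/posterior) count rates:

    A = sqrt(I_A * I_P) * exp(mu_eff * T / 2) / (C_sens * f(x)),

where ``T`` is the body thickness along the projection, ``x`` the source
slab thickness, and ``f(x) = sinh(mu_eff*x/2) / (mu_eff*x/2)`` the source
self-attenuation factor (f -> 1 for a thin source).  ``mu_eff`` and the
sensitivity ``C_sens`` come from a mono-exponential fit to a counts-versus-
depth calibration series.  No scatter correction is applied and counts
outside the body are ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import CalibrationError, GeometryError, PipelineError
from .imageio import GeometricMeanImage, PlanarImage, geometric_mean


def source_attenuation_factor(mu_eff: float, x_cm: float) -> float:
    """Self-attenuation factor f(x) = sinh(mu*x/2)/(mu*x/2); f(0) = 1.

    f >= 1 with equality only in the thin-source limit, so ignoring it
    (f=1) underestimates the activity of an extended source.
    """
    u = 0.5 * mu_eff * x_cm
    if abs(u) < 1e-8:
        return 1.0
    return float(np.sinh(u) / u)


@dataclass
class Calibration:
    """Fitted camera constants from the counts-vs-depth series."""

    mu_eff: float                        # cm^-1
    sensitivity: float                   # counts/s/MBq
    r_squared: float = 1.0
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if self.mu_eff <= 0 or self.sensitivity <= 0:
            raise CalibrationError(
                "calibration requires mu_eff > 0 and sensitivity > 0")


def fit_calibration(pairs, activity_mbq: float) -> Calibration:
    """Mono-exponential fit ``rate = C_sens * A * exp(-mu_eff * d)``.

    ``pairs`` are ``(depth_cm, count_rate)`` tuples from scintigraphy of a
    planar source of known activity at several depths.  Initialised from a
    log-linear regression and refined by nonlinear least squares.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 3:
        raise CalibrationError("calibration needs at least 3 (depth, rate) pairs")
    depths, rates = pairs[:, 0], pairs[:, 1]
    if np.unique(depths).size < 3:
        raise CalibrationError("calibration depths must be distinct")
    if activity_mbq <= 0:
        raise CalibrationError("source activity must be positive")
    if np.any(rates <= 0):
        raise CalibrationError("count rates must be positive for the fit")

    # log-linear start values
    coef = np.polyfit(depths, np.log(rates), 1)
    mu0, sens0 = max(-coef[0], 1e-6), np.exp(coef[1]) / activity_mbq

    def model(d, sens, mu):
        return sens * activity_mbq * np.exp(-mu * d)

    try:
        popt, _ = curve_fit(model, depths, rates, p0=(sens0, mu0),
                            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000)
    except RuntimeError as exc:
        raise CalibrationError(f"calibration fit did not converge: {exc}") from exc
    sens, mu = popt
    if mu <= 0 or sens <= 0:
        raise CalibrationError("calibration fit returned non-physical constants")
    fitted = model(depths, *popt)
    resid = rates - fitted
    ss_tot = float(np.sum((rates - rates.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return Calibration(mu_eff=float(mu), sensitivity=float(sens),
                       r_squared=r2, residuals=resid)


def conjugate_view_activity(ant_rate: float, post_rate: float, thickness_cm: float,
                            calib: Calibration, source_thickness_cm: float) -> float:
    """Activity (MBq) of a source slab from opposed count rates (counts/s)."""
    if thickness_cm <= 0:
        raise GeometryError("body thickness must be positive")
    if not (0 < source_thickness_cm <= thickness_cm):
        raise GeometryError("source thickness must be in (0, T]")
    if ant_rate < 0 or post_rate < 0:
        raise GeometryError("count rates must be non-negative")
    gm = np.sqrt(ant_rate * post_rate)
    f = source_attenuation_factor(calib.mu_eff, source_thickness_cm)
    return float(gm * np.exp(calib.mu_eff * thickness_cm / 2.0)
                 / (calib.sensitivity * f))


@dataclass
class PatientGeometry:
    """Compartment geometry derived from body weight and the masks.

    The high compartment is an ``x_high`` (default 8 cm) slab under the
    high-uptake area at the abdominal thickness; its mass assumes unit
    density.  The low compartment is the remaining body mass spread
    uniformly over the low-uptake area, giving its effective slab thickness.
    """

    weight_kg: float
    abdominal_thickness_cm: float        # T for the high compartment
    slab_thickness_cm: float             # x_high, general organ thickness
    area_high_cm2: float
    area_low_cm2: float
    m_high_kg: float
    m_low_kg: float
    low_thickness_cm: float              # T = x for the uniform low slab


def compartment_geometry(weight_kg: float, abdominal_thickness_cm: float,
                         masks, pixel_size_cm: float,
                         slab_thickness_cm: float = 8.0) -> PatientGeometry:
    """Derive compartment areas, masses and thicknesses.

    ``masks`` needs boolean ``high`` and ``low`` attributes on the image
    grid.  Unit density: mass (kg) = area (cm^2) x thickness (cm) / 1000.
    """
    if weight_kg <= 0:
        raise GeometryError("body weight must be positive")
    if abdominal_thickness_cm <= 0:
        raise GeometryError("abdominal thickness must be positive")
    pix_area = pixel_size_cm ** 2
    area_high = float(masks.high.sum()) * pix_area
    area_low = float(masks.low.sum()) * pix_area
    if area_low <= 0:
        raise GeometryError("low-uptake area is empty")
    m_high = area_high * slab_thickness_cm / 1000.0
    if m_high >= weight_kg:
        raise GeometryError(
            f"high-compartment mass {m_high:.1f} kg exceeds body weight")
    m_low = weight_kg - m_high
    low_thickness = m_low * 1000.0 / area_low
    return PatientGeometry(weight_kg=weight_kg,
                           abdominal_thickness_cm=abdominal_thickness_cm,
                           slab_thickness_cm=slab_thickness_cm,
                           area_high_cm2=area_high, area_low_cm2=area_low,
                           m_high_kg=m_high, m_low_kg=m_low,
                           low_thickness_cm=low_thickness)


@dataclass
class TimeActivitySeries:
    """Activity of one compartment over the acquisition times."""

    compartment: str                     # "high" | "low"
    times_h: np.ndarray
    activity_mbq: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.activity_mbq = np.asarray(self.activity_mbq, dtype=float)
        if np.any(np.diff(self.times_h) <= 0):
            raise PipelineError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times_h.size


def build_tac(image_pairs, masks_by_time, calib: Calibration,
              geometry: PatientGeometry):
    """Quantify both compartments at every time point.

    For each time point the geometric-mean count rates are summed within the
    high and low masks and converted to activity by the conjugate-view
    formula (high: T = abdominal thickness, x = organ slab; low: T = x =
    low-compartment thickness, uniform source).  The activity of the low-
    uptake tissue lying under and over the high-compartment slab — estimated
    as low concentration x (T_high - x_high) x high area — is then moved
    from the high to the low series; the transfer is zero-sum.

    Returns ``(high_series, low_series)``.
    """
    times, highs, lows = [], [], []
    for pair, masks in zip(image_pairs, masks_by_time):
        if pair is None or pair[0] is None or pair[1] is None:
            warnings.warn("missing view at a time point; dropping it")
            continue
        ant, post = pair
        gm = geometric_mean(ant, post)
        pix_area = gm.pixel_size ** 2
        r_high = float(gm.values[masks.high].sum())
        r_low = float(gm.values[masks.low].sum())
        a_high = conjugate_view_activity(
            r_high, r_high, geometry.abdominal_thickness_cm, calib,
            geometry.slab_thickness_cm) if r_high > 0 else 0.0
        a_low = conjugate_view_activity(
            r_low, r_low, geometry.low_thickness_cm, calib,
            geometry.low_thickness_cm) if r_low > 0 else 0.0

        # under/overlying tissue reassignment (per time point, zero-sum)
        area_high_t = float(masks.high.sum()) * pix_area
        area_low_t = float(masks.low.sum()) * pix_area
        conc_low = a_low / (area_low_t * geometry.low_thickness_cm) \
            if area_low_t > 0 else 0.0
        residual_thickness = max(
            geometry.abdominal_thickness_cm - geometry.slab_thickness_cm, 0.0)
        transfer = min(conc_low * residual_thickness * area_high_t, a_high)
        times.append(gm.time_pi)
        highs.append(a_high - transfer)
        lows.append(a_low + transfer)

    if len(times) < 3:
        raise PipelineError(
            f"only {len(times)} usable time points; need at least 3")
    order = np.argsort(times)
    t = np.asarray(times)[order]
    return (TimeActivitySeries("high", t, np.asarray(highs)[order]),
            TimeActivitySeries("low", t, np.asarray(lows)[order]))
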