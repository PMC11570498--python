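"""Quantitative curve analyses for candidate characterization.

Covers the four desk-side fits used around the screen: equilibrium
binding (Hill form with unit coefficient, ``y = Bmax*x/(K_D + x)``),
FRAP recovery (``y = A*(1 - exp(-k*t))`` on post-bleach data, with
background/photobleach/full-scale normalization of the raw traces),
droplet-sedimentation pellet fractions with a saturation-point estimator,
and absolute quantification from an external calibration line with
conversion to molar concentration in a compartment volume.

Uncertainties come from a seeded residual-resampling bootstrap
(percentile intervals), so confidence intervals are reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

AVOGADRO = 6.02214076e23

__all__ = [
    "TitrationCurve", "FrapTrace", "FitResult", "normalize_frap",
    "fit_frap", "fit_hill", "pellet_fraction", "titration_series",
    "calibration_quantify", "CalibrationResult",
]


@dataclass(frozen=True)
class TitrationCurve:
    """Analyte concentration (uM) versus response (arbitrary units)."""

    x: tuple[float, ...]
    y: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValueError("x and y differ in length")
        if len(self.x) < 3:
            raise ValueError("need at least 3 titration points")
        if any(v < 0 for v in self.x):
            raise ValueError("concentrations must be >= 0")


@dataclass(frozen=True)
class FrapTrace:
    """Raw FRAP intensity series; t is seconds relative to the bleach
    (negative = pre-bleach frames)."""

    t: tuple[float, ...]
    bleached: tuple[float, ...]
    unbleached: tuple[float, ...]
    background: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.bleached) == len(self.unbleached) == len(self.background) == n):
            raise ValueError("all FRAP series must share one length")
        if sum(1 for v in self.t if v < 0) < 5:
            warnings.warn("fewer than 5 pre-bleach points; full-scale "
                          "normalization will be noisy", stacklevel=2)


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters with derived quantities and bootstrap errors."""

    model: str
    params: dict[str, float]
    derived: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] | None = None
    ci95: dict[str, tuple[float, float]] | None = None
    rss: float = 0.0
    n_boot: int = 0
    seed: int | None = None


def _bootstrap(x: np.ndarray, y: np.ndarray, model, popt: np.ndarray,
               n_boot: int, seed: int | None, bounds) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    yhat = model(x, *popt)
    resid = y - yhat
    draws = []
    for _ in range(n_boot):
        yb = yhat + rng.choice(resid, size=resid.size, replace=True)
        try:
            pb, _ = curve_fit(model, x, yb, p0=popt, bounds=bounds, maxfev=2000)
            draws.append(pb)
        except RuntimeError:
            continue
    return {"draws": np.array(draws)}


def _boot_stats(draws: np.ndarray, names: list[str]) -> tuple[dict, dict]:
    se = {n: float(np.std(draws[:, i], ddof=1)) for i, n in enumerate(names)}
    ci = {n: (float(np.percentile(draws[:, i], 2.5)),
              float(np.percentile(draws[:, i], 97.5)))
          for i, n in enumerate(names)}
    return se, ci


def normalize_frap(trace: FrapTrace) -> np.ndarray:
    """Normalize a raw FRAP trace to the [0, 1] recovery scale.

    Order of operations: background subtraction from both signal series,
    photobleach correction (bleached divided by the unbleached reference),
    then full-scale normalization by the mean pre-bleach corrected value.
    The pre-bleach mean of the output is exactly 1.
    """
    t = np.asarray(trace.t, dtype=float)
    ble = np.asarray(trace.bleached, dtype=float) - np.asarray(trace.background, dtype=float)
    unb = np.asarray(trace.unbleached, dtype=float) - np.asarray(trace.background, dtype=float)
    if np.any(unb <= 0):
        raise ValueError("corrected unbleached reference is zero or negative")
    corrected = ble / unb
    pre = corrected[t < 0]
    if pre.size == 0:
        raise ValueError("no pre-bleach points (t < 0) for full-scale normalization")
    scale = pre.mean()
    if scale <= 0:
        raise ValueError("non-positive pre-bleach mean")
    return corrected / scale


def fit_frap(t_post: np.ndarray, y_post: np.ndarray,
             n_boot: int = 1000, seed: int = 0) -> FitResult:
    """Fit the single-exponential recovery ``y = A*(1 - exp(-k*t))`` to
    post-bleach data (t = 0 at the first post-bleach frame).

    Derived ``T_0.5 = ln(2)/k`` is the half-maximal recovery time.
    Degenerate flat data make k unidentifiable and raise.
    """
    t = np.asarray(t_post, dtype=float)
    y = np.asarray(y_post, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 post-bleach points")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("t_post must be nonnegative and strictly ascending")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in FRAP data")
    if np.ptp(y) < 1e-12 * max(1.0, abs(float(y.mean()))):
        raise ValueError("flat recovery data: k is unidentifiable")

    def model(tt, A, k):
        return A * (1.0 - np.exp(-k * tt))

    a0 = float(y[-1])
    if a0 <= 0:
        a0 = float(np.max(np.abs(y))) or 1.0
    half_idx = int(np.argmin(np.abs(y - a0 / 2.0)))
    t_half = t[half_idx] if t[half_idx] > 0 else (t[t > 0][0] if np.any(t > 0) else 1.0)
    k0 = 1.0 / t_half
    bounds = ([0.0, 1e-12], [np.inf, np.inf])
    popt, _ = curve_fit(model, t, y, p0=[a0, k0], bounds=bounds,
                        xtol=1e-10, ftol=1e-10, maxfev=5000)
    a, k = (float(v) for v in popt)
    rss = float(np.sum((y - model(t, *popt)) ** 2))
    se = ci = None
    if n_boot > 0:
        draws = _bootstrap(t, y, model, popt, n_boot, seed, bounds)["draws"]
        if draws.size:
            se, ci = _boot_stats(draws, ["A", "k"])
    return FitResult(model="frap_exponential", params={"A": a, "k": k},
                     derived={"T_0.5": math.log(2.0) / k},
                     se=se, ci95=ci, rss=rss, n_boot=n_boot, seed=seed)


def fit_hill(curve: TitrationCurve, n_boot: int = 1000, seed: int = 0,
             normalized_output: bool = False) -> FitResult:
    """Fit the unit-coefficient Hill binding curve ``y = Bmax*x/(K_D+x)``.

    ``K_0.5``, the half-occupancy concentration, equals K_D for this form
    and is reported alongside.  With ``normalized_output`` the fitted
    response normalized to Bmax is included in ``derived``-adjacent use
    via ``params``; the fit itself always uses the raw responses.
    """
    x = np.asarray(curve.x, dtype=float)
    y = np.asarray(curve.y, dtype=float)
    if np.any(x <= 0):
        raise ValueError("fit_hill requires strictly positive concentrations")
    if np.all(y == 0):
        raise ValueError("all-zero responses")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct concentrations")

    def model(xx, bmax, kd):
        return bmax * xx / (kd + xx)

    b0 = float(np.max(y))
    kd0 = float(x[np.argmin(np.abs(y - b0 / 2.0))])
    if not (x.min() < kd0 < x.max()):
        warnings.warn("apparent midpoint lies at the edge of the measured "
                      "range; K_D is poorly constrained", stacklevel=2)
    bounds = ([0.0, 1e-12], [np.inf, np.inf])
    popt, _ = curve_fit(model, x, y, p0=[b0, max(kd0, 1e-6)], bounds=bounds,
                        xtol=1e-12, ftol=1e-12, maxfev=5000)
    bmax, kd = (float(v) for v in popt)
    rss = float(np.sum((y - model(x, *popt)) ** 2))
    se = ci = None
    if n_boot > 0:
        draws = _bootstrap(x, y, model, popt, n_boot, seed, bounds)["draws"]
        if draws.size:
            se, ci = _boot_stats(draws, ["Bmax", "K_D"])
    res = FitResult(model="hill_n1", params={"Bmax": bmax, "K_D": kd},
                    derived={"K_0.5": kd}, se=se, ci95=ci, rss=rss,
                    n_boot=n_boot, seed=seed)
    if normalized_output:
        res.derived["y_normalized"] = tuple(float(v) for v in y / bmax)  # type: ignore[assignment]
    return res


def pellet_fraction(pellet_intensity: float, supernatant_intensity: float) -> float:
    """Fraction of material in the pellet, ``P / (P + S)``."""
    if pellet_intensity < 0 or supernatant_intensity < 0:
        raise ValueError("band intensities must be >= 0")
    total = pellet_intensity + supernatant_intensity
    if total == 0:
        raise ValueError("both band intensities are zero")
    return pellet_intensity / total


def titration_series(concentrations: np.ndarray, fractions: np.ndarray,
                     n_boot: int = 0, seed: int = 0,
                     noise_tolerance: float = 0.05) -> tuple[FitResult, float]:
    """Fit pellet fraction versus titrant concentration and estimate the
    saturation point.

    Uses the same hyperbolic binding form; the saturation concentration is
    where the fitted curve reaches 95% of its plateau (19 x K_D).  A
    non-monotone series (dips beyond ``noise_tolerance``) only warns.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 titration points")
    if np.ptp(y) < 1e-9:
        raise ValueError("flat titration series: no saturation point")
    order = np.argsort(x)
    if np.any(np.diff(y[order]) < -noise_tolerance):
        warnings.warn("titration series decreases beyond noise tolerance",
                      stacklevel=2)
    fit = fit_hill(TitrationCurve(tuple(x), tuple(y)), n_boot=n_boot, seed=seed)
    saturation = 19.0 * fit.params["K_D"]
    return fit, saturation


@dataclass(frozen=True)
class CalibrationResult:
    slope: float
    intercept: float
    amounts_ng: tuple[float, ...]
    copies_per_cell: tuple[float, ...]
    concentrations_uM: tuple[float, ...]
    extrapolated: tuple[bool, ...]


def calibration_quantify(standard_amounts_ng: np.ndarray,
                         standard_intensities: np.ndarray,
                         sample_intensities: np.ndarray,
                         cells_per_sample: float,
                         compartment_volume_fl: float,
                         molecular_weight_da: float,
                         allow_extrapolation: bool = False) -> CalibrationResult:
    """Absolute quantification from an external calibration line.

    An ordinary least-squares line through (amount, intensity) standards
    is inverted to convert sample intensities to amounts (ng), then to
    copies per cell via Avogadro's number and the molecular weight, and
    finally to molar concentration in the stated compartment volume
    (femtolitres), reported in uM.  Samples outside the standards'
    intensity range are flagged as extrapolated (an error unless
    explicitly allowed).
    """
    amt = np.asarray(standard_amounts_ng, dtype=float)
    inten = np.asarray(standard_intensities, dtype=float)
    samples = np.asarray(sample_intensities, dtype=float)
    if amt.size < 3:
        raise ValueError("need at least 3 calibration standards")
    if np.unique(amt).size < 2:
        raise ValueError("singular calibration: all standards share one amount")
    if compartment_volume_fl <= 0 or cells_per_sample <= 0 or molecular_weight_da <= 0:
        raise ValueError("volume, cell count and molecular weight must be positive")
    slope, intercept = np.polyfit(amt, inten, 1)
    if slope == 0:
        raise ValueError("flat calibration line")
    lo, hi = float(inten.min()), float(inten.max())
    extrapolated = tuple(bool(s < lo or s > hi) for s in samples)
    if any(extrapolated) and not allow_extrapolation:
        raise ValueError("sample intensity outside the calibration range "
                         "(pass allow_extrapolation=True to override)")
    amounts = (samples - intercept) / slope
    grams = amounts * 1e-9
    copies = grams * AVOGADRO / (molecular_weight_da * cells_per_sample)
    volume_l = compartment_volume_fl * 1e-15
    conc_um = copies / (AVOGADRO * volume_l) * 1e6
    return CalibrationResult(
        slope=float(slope), intercept=float(intercept),
        amounts_ng=tuple(float(a) for a in amounts),
        copies_per_cell=tuple(float(c) for c in copies),
        concentrations_uM=tuple(float(c) for c in conc_um),
        extrapolated=extrapolated,
    )
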