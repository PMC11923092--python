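"""Size-exclusion chromatography: fractions, Stokes radii, aggregation kinetics.

An aggregation-prone precursor elutes as two populations: a large soluble
aggregate at (or near) the void volume and a monomer further into the
column.  This module quantifies the aggregate/monomer split from integrated
peak areas, converts elution volumes to partition coefficients

    Kav = (Ve - V0) / (Vt - V0)

and estimates hydrodynamic size two ways: the Stokes radius from a linear
calibration of R_ST against sqrt(-log10 Kav) over globular standards, and an
apparent molecular weight from a separate log-linear (log10 MW vs Kav)
calibration.  Dis-/re-aggregation time courses of the monomer (or aggregate)
fraction are fitted with a one-phase exponential or, for nucleation-limited
re-aggregation with a lag phase, a logistic curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from ._fitting import ResultsBase
from .exceptions import ConfigurationError, DomainError, FitError

__all__ = [
    "Chromatogram", "SECCalibration", "FractionReport",
    "partition_coefficient", "calibrate_stokes", "integrate_fractions",
    "AggregationKinetics", "AggregationResults", "fit_aggregation_kinetics",
]


@dataclass(frozen=True)
class Chromatogram:
    """A280 absorbance trace over elution volume with column constants.

    ``v0`` is the void volume (blue-dextran marker) and ``vt`` the total bed
    volume (acetone marker), both in mL.
    """

    volumes: np.ndarray
    absorbance: np.ndarray
    v0: float = None
    vt: float = None

    def __post_init__(self):
        v = np.asarray(self.volumes, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "volumes", v)
        object.__setattr__(self, "absorbance", a)
        if v.shape != a.shape or v.ndim != 1 or len(v) < 5:
            raise ConfigurationError("need matching 1-D volume/absorbance "
                                     "arrays of >= 5 points")
        if np.any(np.diff(v) <= 0):
            raise ConfigurationError("elution volumes must be ascending")
        if self.v0 is not None and self.vt is not None and self.v0 >= self.vt:
            raise ConfigurationError("void volume must be below bed volume")


def partition_coefficient(ve: float, v0: float, vt: float) -> float:
    """Kav = (Ve - V0)/(Vt - V0).

    Values outside (0, 1] are returned as-is (void-volume elution gives
    Kav <= 0 and carries lower-bound size semantics downstream).
    """
    if v0 >= vt:
        raise DomainError("void volume must be below total bed volume")
    return (ve - v0) / (vt - v0)


@dataclass(frozen=True)
class SECCalibration:
    """Linear Stokes-radius calibration R_ST = slope*sqrt(-log10 Kav) + intercept.

    Optionally carries a molecular-weight calibration
    log10(MW) = mw_slope*Kav + mw_intercept.  The log base (10) and the MW
    functional form are conventions recorded in :attr:`metadata`.
    """

    slope: float
    intercept: float
    standards: tuple = ()
    mw_slope: float = None
    mw_intercept: float = None
    v0: float = None
    vt: float = None

    metadata = {"log_base": 10, "mw_form": "log10(MW) linear in Kav"}

    def stokes_radius(self, ve: float) -> float:
        """Stokes radius (A) for an elution volume on this column.

        Void-volume elution (Kav <= 0) is not interpolable; the calibration
        only bounds the radius from below, so a ``DomainError`` explains the
        "greater than the largest calibrated radius" semantics.
        """
        kav = partition_coefficient(ve, self.v0, self.vt)
        if kav <= 0:
            largest = max((s[1] for s in self.standards), default=None)
            bound = f" (> {largest:g} A, the largest calibrated radius)" \
                if largest else ""
            raise DomainError(
                f"elution at/before the void volume (Kav = {kav:.3g}): "
                f"Stokes radius is only bounded from below{bound}")
        if kav > 1:
            raise DomainError(f"Kav = {kav:.3g} > 1 is outside the column")
        return self.slope * math.sqrt(-math.log10(kav)) + self.intercept

    def apparent_mw(self, ve: float) -> float:
        """Apparent molecular weight (kDa) from the log-linear calibration."""
        if self.mw_slope is None:
            raise ConfigurationError("no molecular-weight calibration fitted")
        kav = partition_coefficient(ve, self.v0, self.vt)
        return 10.0 ** (self.mw_slope * kav + self.mw_intercept)


def calibrate_stokes(standards, v0: float, vt: float,
                     mw_standards=None) -> SECCalibration:
    """Fit the Stokes-radius calibration from (name, R_ST [A], Ve [mL]) tuples.

    Ordinary least squares of R_ST on sqrt(-log10 Kav); each standard must
    elute inside the column (0 < Kav < 1).  ``mw_standards`` are optional
    (name, MW [kDa], Ve [mL]) tuples for the apparent-MW calibration.
    """
    standards = list(standards)
    if len(standards) < 2:
        raise ConfigurationError("need >= 2 calibration standards")
    x, y = [], []
    for name, r_st, ve in standards:
        kav = partition_coefficient(ve, v0, vt)
        if not 0.0 < kav < 1.0:
            raise ConfigurationError(
                f"standard {name!r} has Kav = {kav:.3g} outside (0, 1)")
        x.append(math.sqrt(-math.log10(kav)))
        y.append(r_st)
    slope, intercept = np.polyfit(x, y, 1)
    mw_slope = mw_intercept = None
    if mw_standards:
        mx, my = [], []
        for name, mw, ve in mw_standards:
            kav = partition_coefficient(ve, v0, vt)
            if not 0.0 < kav <= 1.0:
                raise ConfigurationError(
                    f"MW standard {name!r} has Kav = {kav:.3g} outside (0, 1]")
            mx.append(kav)
            my.append(math.log10(mw))
        mw_slope, mw_intercept = (float(c) for c in np.polyfit(mx, my, 1))
    return SECCalibration(slope=float(slope), intercept=float(intercept),
                          standards=tuple((n, r, v) for n, r, v in standards),
                          mw_slope=mw_slope, mw_intercept=mw_intercept,
                          v0=v0, vt=vt)


@dataclass(frozen=True)
class FractionReport:
    """Aggregate/monomer split by integrated peak area."""

    aggregate_percent: float
    monomer_percent: float
    boundary_ml: float
    peak_areas: dict
    peak_volumes: dict


def _linear_baseline(v, a, flat_fraction=0.05):
    n = max(int(len(v) * flat_fraction), 1)
    x = np.concatenate([v[:n], v[-n:]])
    y = np.concatenate([a[:n], a[-n:]])
    coef = np.polyfit(x, y, 1)
    return np.polyval(coef, v)


def _smooth(a, window=5):
    if window <= 1:
        return a
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(a, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def integrate_fractions(chrom: Chromatogram, boundary_ml: float = None,
                        subtract_baseline: bool = True,
                        smooth_window: int = 5) -> FractionReport:
    """Split the trace into aggregate and monomer areas.

    The boundary defaults to the local minimum of a lightly smoothed trace
    between the two largest maxima.  The earlier (void-region) peak is the
    aggregate.  A single detected peak is assigned by its position: at/near
    the void volume it is all aggregate, otherwise all monomer.  Percentages
    are invariant under uniform rescaling of the trace.
    """
    v, a = chrom.volumes, chrom.absorbance.copy()
    if subtract_baseline:
        a = a - _linear_baseline(v, a)
    a = np.clip(a, 0.0, None)
    s = _smooth(a, smooth_window)
    prominence = 0.05 * s.max() if s.max() > 0 else None
    if prominence is None:
        raise FitError("no detectable peak in the chromatogram")
    peaks, props = signal.find_peaks(s, prominence=prominence)
    if len(peaks) == 0:
        raise FitError("no detectable peak in the chromatogram")
    order = np.argsort(props["prominences"])[::-1]
    main = np.sort(peaks[order[:2]])
    if boundary_ml is None and len(main) >= 2:
        i0, i1 = main[0], main[1]
        boundary_ml = float(v[i0 + int(np.argmin(s[i0:i1 + 1]))])
    total = np.trapezoid(a, v)
    if total <= 0:
        raise FitError("chromatogram has zero integrated area")
    if boundary_ml is None:
        # single peak: classify by proximity to the void volume
        apex = float(v[main[0]])
        near_void = (chrom.v0 is not None
                     and apex <= chrom.v0 + 0.05 * (chrom.vt - chrom.v0))
        agg = total if near_void else 0.0
        mono = 0.0 if near_void else total
        boundary = float(v[0]) if near_void else float(v[-1])
        return FractionReport(
            aggregate_percent=100.0 * agg / total,
            monomer_percent=100.0 * mono / total,
            boundary_ml=boundary,
            peak_areas={"aggregate": agg, "monomer": mono},
            peak_volumes={"apex": apex})
    mask = v <= boundary_ml
    agg = np.trapezoid(a[mask], v[mask])
    mono = total - agg
    return FractionReport(
        aggregate_percent=100.0 * agg / total,
        monomer_percent=100.0 * mono / total,
        boundary_ml=float(boundary_ml),
        peak_areas={"aggregate": float(agg), "monomer": float(mono)},
        peak_volumes={f"peak_{i}": float(v[p]) for i, p in enumerate(main)})


# ---------------------------------------------------------------------------
# dis-/re-aggregation kinetics

@dataclass
class AggregationResults(ResultsBase):
    """Fit of a monomer- or aggregate-fraction time course."""

    model_name: str
    k: float            # 1/time-unit of the input
    plateau: float      # M_inf
    initial: float      # M_0
    t_mid: float        # logistic midpoint; nan for one-phase
    resid_norm: float
    aic: float
    _bse: list = None

    param_names = ("k", "plateau", "initial", "t_mid")
    title = "Aggregation-kinetics fit"

    def predict(self, times):
        t = np.asarray(times, dtype=float)
        if self.model_name == "one_phase_exponential":
            return self.plateau + (self.initial - self.plateau) * np.exp(-self.k * t)
        return self.plateau + (self.initial - self.plateau) / (
            1.0 + np.exp(self.k * (t - self.t_mid)))


class AggregationKinetics:
    """Empirical fit of fraction-vs-time during dis- or re-aggregation.

    ``one_phase_exponential``: M(t) = M_inf + (M_0 - M_inf) exp(-k t) -
    appropriate for dilution-induced disaggregation and for the post-lag
    phase of re-aggregation.  ``logistic``: M(t) = M_inf +
    (M_0 - M_inf)/(1 + exp(k (t - t_mid))) - captures the nucleation lag of
    amyloid-like re-aggregation.  AIC is reported so the two can be
    compared on the same data.
    """

    MODELS = ("one_phase_exponential", "logistic")

    def __init__(self, times, fraction, model: str = "one_phase_exponential"):
        if model not in self.MODELS:
            raise ConfigurationError(f"unknown model {model!r}")
        self.model = model
        self.t = np.asarray(times, dtype=float)
        self.y = np.asarray(fraction, dtype=float)
        if len(self.t) < 5:
            raise ConfigurationError("need >= 5 time points")
        if np.ptp(self.y) == 0:
            raise FitError("fraction is constant; rate unidentifiable")

    def fit(self) -> AggregationResults:
        t, y = self.t, self.y
        span = t[-1] - t[0]
        if self.model == "one_phase_exponential":
            def f(t, k, plateau, m0):
                return plateau + (m0 - plateau) * np.exp(-k * t)
            p0 = [2.0 / span, y[-1], y[0]]
        else:
            def f(t, k, plateau, m0, t_mid):
                return plateau + (m0 - plateau) / (1.0 + np.exp(k * (t - t_mid)))
            p0 = [5.0 / span, y[-1], y[0], float(np.median(t))]
        try:
            popt, pcov = optimize.curve_fit(f, t, y, p0=p0, maxfev=40000)
        except RuntimeError as exc:
            raise FitError(f"aggregation fit did not converge: {exc}") from exc
        res = f(t, *popt) - y
        rss = float(res @ res)
        n, p = len(t), len(popt)
        aic = n * math.log(max(rss, 1e-300) / n) + 2 * p
        t_mid = float(popt[3]) if self.model == "logistic" else float("nan")
        se = list(np.sqrt(np.diag(pcov)))
        if self.model == "one_phase_exponential":
            se = se + [float("nan")]
        return AggregationResults(
            model_name=self.model, k=abs(float(popt[0])),
            plateau=float(popt[1]), initial=float(popt[2]), t_mid=t_mid,
            resid_norm=float(np.linalg.norm(res)), aic=float(aic), _bse=se)


def fit_aggregation_kinetics(times, fraction,
                             model: str = "one_phase_exponential") -> AggregationResults:
    """Convenience wrapper: build and fit :class:`AggregationKinetics`."""
    return AggregationKinetics(times, fraction, model=model).fit()
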