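"""Protein trans-splicing (PTS) kinetics from gel densitometry.

A split-intein splicing reaction followed on SDS-PAGE gives band intensities
for the limiting precursor (A), the branched intermediate (BI) and the splice
product (SP) over time.  Because Coomassie staining scales with protein mass,
intensities are divided by the molecular weight of each species to obtain
mole-proportional abundances before any kinetic analysis.

Two models are provided, statsmodels-style:

* :class:`SingleExponentialPTS` - pseudo-first-order product formation
  ``P(t) = P_max (1 - exp(-k_total t))`` where ``P_max`` is the fraction of
  precursor competent to splice (the "active fraction").
* :class:`ThreeStatePTS` - a global fit of the linear three-state scheme
  ``A <-> BI -> P`` with rates ``k1`` (association/branching), ``k2``
  (reversal) and ``k3`` (resolution to product), using the closed-form
  solution of the coupled first-order rate equations.

The closed form is an eigen-decomposition of the 2x2 rate matrix: with
``p = k1 + k2 + k3`` and ``q = sqrt(p^2 - 4 k1 k3)`` the decay constants are
``a = (p + q)/2`` and ``b = (p - q)/2``; ``q`` is always real because
``p^2 - 4 k1 k3 >= (k1 - k3)^2 + k2 (k2 + 2 k1 + 2 k3) >= 0`` for positive
rates, and ``a b = k1 k3``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._fitting import (ResultsBase, covariance_from_jacobian,
                       multistart_least_squares, standard_errors)
from .exceptions import ConfigurationError, DomainError, FitError

__all__ = [
    "TimeCourse", "YieldResult", "normalize_densitometry", "splice_yield",
    "half_life", "three_state_profiles", "SingleExponentialPTS",
    "SingleExponentialResults", "ThreeStatePTS", "ThreeStateResults",
    "fit_single_exponential", "fit_three_state",
]

# Degenerate-eigenvalue switchover: below this relative gap the a == b limit
# formula (with t*exp(-a t) secular terms) is used.
_EIGEN_DEGENERACY_RTOL = 1e-9


@dataclass(frozen=True)
class TimeCourse:
    """Abundance (or raw band intensity) of each species versus time.

    Parameters
    ----------
    times : array of float
        Sampling times in seconds, non-negative and strictly increasing.
    intensities : dict of str -> array
        One non-negative trace per species label, same length as ``times``.
    masses : dict of str -> float, optional
        Molecular mass of each species in kDa; required for normalisation.
    normalized : bool
        True once intensities are mole-proportional (mass-normalised).
    """

    times: np.ndarray
    intensities: dict
    masses: dict = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1 or len(times) == 0:
            raise ConfigurationError("times must be a non-empty 1-D array")
        if np.any(times < 0):
            raise ConfigurationError("times must be non-negative")
        if np.any(np.diff(times) <= 0):
            raise ConfigurationError("times must be strictly increasing")
        clean = {}
        for name, trace in self.intensities.items():
            trace = np.asarray(trace, dtype=float)
            if trace.shape != times.shape:
                raise ConfigurationError(
                    f"trace for {name!r} has length {len(trace)}, "
                    f"expected {len(times)}")
            if np.any(trace < 0):
                raise ConfigurationError(f"negative intensity for {name!r}")
            clean[name] = trace
        object.__setattr__(self, "intensities", clean)
        for name, mass in self.masses.items():
            if mass <= 0:
                raise ConfigurationError(f"mass for {name!r} must be > 0")

    @property
    def species(self):
        return tuple(self.intensities)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, masses=None,
                       time_col: str = "time_s") -> "TimeCourse":
        """Build from a long table (time_s, species, intensity) or a wide
        table with one column per species."""
        if {"species", "intensity"}.issubset(frame.columns):
            wide = frame.pivot_table(index=time_col, columns="species",
                                     values="intensity", aggfunc="mean")
        else:
            wide = frame.set_index(time_col)
        return cls(times=wide.index.to_numpy(dtype=float),
                   intensities={c: wide[c].to_numpy() for c in wide.columns},
                   masses=dict(masses or {}))

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame({"time_s": self.times})
        for name, trace in self.intensities.items():
            out[name] = trace
        return out


@dataclass(frozen=True)
class YieldResult:
    """Splice yield from the product/limiting-precursor ratio.

    ``x`` is the percent ratio 100*SP/A and ``P = 100*x/(100+x)``, which is
    algebraically the percentage 100*SP/(SP+A) of precursor converted.
    """

    x: float
    percent: float


def normalize_densitometry(timecourse: TimeCourse) -> TimeCourse:
    """Divide each band intensity by the species mass (kDa).

    Coomassie intensity is proportional to mass, so the quotient is
    proportional to moles; the relative scale within a lane is preserved.
    """
    missing = [s for s in timecourse.species if s not in timecourse.masses]
    if missing:
        raise ConfigurationError(
            f"no molecular mass configured for species: {', '.join(missing)}")
    scaled = {s: trace / timecourse.masses[s]
              for s, trace in timecourse.intensities.items()}
    return replace(timecourse, intensities=scaled, normalized=True)


def splice_yield(sp_abundance: float, limiting_precursor_abundance: float) -> YieldResult:
    """Percent splice yield from mole-proportional SP and A abundances."""
    sp = float(sp_abundance)
    a = float(limiting_precursor_abundance)
    if sp < 0 or a < 0:
        raise DomainError("abundances must be non-negative")
    if sp == 0 and a == 0:
        raise DomainError("yield undefined: both abundances are zero")
    if a == 0:
        return YieldResult(x=math.inf, percent=100.0)
    x = 100.0 * sp / a
    return YieldResult(x=x, percent=100.0 * x / (100.0 + x))


def half_life(k: float) -> float:
    """Half-life ln(2)/k in seconds of a first-order rate constant (1/s)."""
    if k <= 0:
        raise DomainError(f"rate constant must be positive, got {k}")
    return math.log(2.0) / k


def _eigenvalues(k1: float, k2: float, k3: float):
    p = k1 + k2 + k3
    q = math.sqrt(max(p * p - 4.0 * k1 * k3, 0.0))
    return 0.5 * (p + q), 0.5 * (p - q)


def three_state_profiles(k1, k2, k3, p_max, times):
    """Closed-form [A], [BI], [P] trajectories of the A <-> BI -> P scheme.

    Initial condition is intact active precursor: ([A], [BI], [P])(0) =
    (P_max, 0, 0).  Conservation [A]+[BI]+[P] = P_max holds identically.
    When the two decay constants coincide (p^2 = 4 k1 k3) the repeated-
    eigenvalue limit with secular ``t exp(-a t)`` terms is used.

    Returns
    -------
    dict with keys ``"A"``, ``"BI"``, ``"P"`` mapping to arrays.
    """
    if min(k1, k2, k3) < 0 or max(k1, k3) <= 0:
        raise DomainError("rates must be positive (k2 may be zero)")
    t = np.asarray(times, dtype=float)
    a, b = _eigenvalues(k1, k2, k3)
    if a - b < _EIGEN_DEGENERACY_RTOL * a:
        s = 0.5 * (a + b)
        decay = np.exp(-s * t)
        A = p_max * decay * (1.0 + (s - k1) * t)
        BI = p_max * k1 * t * decay
    else:
        ea, eb = np.exp(-a * t), np.exp(-b * t)
        # amplitudes in the printed form k1(a-k3)/(a(a-b)) etc. simplify via
        # a b = k1 k3 to (k1-b)/(a-b) and (a-k1)/(a-b)
        A = p_max * ((k1 - b) * ea + (a - k1) * eb) / (a - b)
        BI = p_max * k1 * (eb - ea) / (a - b)
    P = p_max - A - BI
    return {"A": A, "BI": BI, "P": P}


def _require_normalized(tc: TimeCourse):
    if not tc.normalized and tc.masses:
        tc = normalize_densitometry(tc)
    return tc


class SingleExponentialPTS:
    """Pseudo-first-order model of splice-product formation.

    Fits ``P(t) = P_max (1 - exp(-k_total t))`` to the product trace of a
    :class:`TimeCourse` whose abundances are normalised to the limiting
    precursor total (so ``P_max`` is the active fraction in (0, 1]).
    """

    def __init__(self, timecourse: TimeCourse, species: str = "P"):
        tc = _require_normalized(timecourse)
        if species not in tc.intensities:
            raise ConfigurationError(f"species {species!r} not in time course")
        self.times = tc.times
        self.y = tc.intensities[species]
        if len(self.times) < 4:
            raise ConfigurationError("need at least 4 time points")
        if np.all(self.y == 0):
            raise FitError("product trace is identically zero")

    def fit(self) -> "SingleExponentialResults":
        t, y = self.times, self.y
        ymax = y.max()
        if np.all(np.diff(y) <= 0):
            raise FitError("product trace is non-increasing; "
                           "single-exponential model inapplicable")

        def residual(theta):
            k, pmax = np.exp(theta)
            return pmax * (1.0 - np.exp(-k * t)) - y

        t_mid = t[int(np.argmax(y >= 0.5 * ymax))]
        k0 = math.log(2.0) / max(t_mid, t[1] if t[0] == 0 else t[0])
        starts = [np.log([k0 * f, max(ymax, 1e-6)]) for f in (0.1, 1.0, 10.0)]
        sol = multistart_least_squares(residual, starts)
        k_total, p_max = np.exp(sol.x)
        # delta-method covariance on the natural scale
        jac = sol.jac / np.exp(sol.x)[None, :]
        cov = covariance_from_jacobian(jac, sol.fun)
        return SingleExponentialResults(
            k_total=float(k_total), P_max=float(p_max),
            half_life=half_life(k_total),
            resid_norm=float(np.linalg.norm(sol.fun)),
            _bse=standard_errors(cov).tolist() + [float("nan")],
            model=self)


@dataclass
class SingleExponentialResults(ResultsBase):
    k_total: float
    P_max: float
    half_life: float
    resid_norm: float
    _bse: list = None
    model: SingleExponentialPTS = None

    param_names = ("k_total", "P_max", "half_life")
    title = "Single-exponential PTS fit"

    def predict(self, times):
        t = np.asarray(times, dtype=float)
        return self.P_max * (1.0 - np.exp(-self.k_total * t))

    @property
    def _summary_extra(self):
        return [f"residual norm  {self.resid_norm:.4g}",
                f"t_1/2 = ln2/k_total = {self.half_life:.3g} s"]


class ThreeStatePTS:
    """Global three-state fit over the [A], [BI], [P] traces.

    A single (k1, k2, k3, P_max) minimises the joint sum of squared
    residuals of all three closed-form trajectories against the data.
    """

    REQUIRED = ("A", "BI", "P")

    def __init__(self, timecourse: TimeCourse, species_map=None):
        tc = _require_normalized(timecourse)
        smap = dict(zip(self.REQUIRED, self.REQUIRED))
        if species_map:
            smap.update(species_map)
        missing = [smap[r] for r in self.REQUIRED
                   if smap[r] not in tc.intensities]
        if missing:
            raise ConfigurationError(
                f"three-state fit needs A, BI and P traces; missing: "
                f"{', '.join(missing)}")
        if len(tc.times) < 6:
            raise ConfigurationError("need at least 6 time points")
        self.times = tc.times
        self.data = {r: tc.intensities[smap[r]] for r in self.REQUIRED}

    def fit(self) -> "ThreeStateResults":
        t = self.times
        y = np.concatenate([self.data[r] for r in self.REQUIRED])

        def residual(theta):
            k1, k2, k3, pmax = np.exp(theta)
            prof = three_state_profiles(k1, k2, k3, pmax, t)
            return np.concatenate([prof[r] for r in self.REQUIRED]) - y

        total0 = self.data["A"][0] + self.data["BI"][0] + self.data["P"][0]
        pmax0 = max(total0, self.data["P"].max(), 1e-6)
        span = t[-1] - t[0] if t[-1] > t[0] else 1.0
        k_scales = np.array([0.2, 2.0, 20.0]) / span
        starts = [np.log([ks, ks, ks, pmax0]) for ks in k_scales]
        sol = multistart_least_squares(residual, starts)
        k1, k2, k3, p_max = np.exp(sol.x)
        # runaway-large rates signal an unconstrained fit; a tiny k2 merely
        # collapses to the irreversible nested model and is legitimate
        if np.any(sol.x > np.log(1e8)):
            raise FitError("a parameter ran away to its upper bound",
                           diagnostics=[s.tolist() for s in starts])
        p = k1 + k2 + k3
        q = math.sqrt(p * p - 4 * k1 * k3)
        jac = sol.jac / np.exp(sol.x)[None, :]
        cov = covariance_from_jacobian(jac, sol.fun)
        return ThreeStateResults(
            k1=float(k1), k2=float(k2), k3=float(k3), P_max=float(p_max),
            p=float(p), q=float(q), a=0.5 * (p + q), b=0.5 * (p - q),
            resid_norm=float(np.linalg.norm(sol.fun)),
            _bse=standard_errors(cov).tolist(), model=self)


@dataclass
class ThreeStateResults(ResultsBase):
    k1: float
    k2: float
    k3: float
    P_max: float
    p: float
    q: float
    a: float
    b: float
    resid_norm: float
    _bse: list = None
    model: ThreeStatePTS = None

    param_names = ("k1", "k2", "k3", "P_max")
    title = "Three-state PTS global fit"

    def predict(self, times):
        return three_state_profiles(self.k1, self.k2, self.k3, self.P_max,
                                    times)

    def plot(self, ax=None):
        """Data and fitted trajectories for all three species."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.times
        grid = np.linspace(t[0], t[-1], 200)
        fitted = self.predict(grid)
        for species, color in zip(("A", "BI", "P"), ("C0", "C1", "C2")):
            ax.plot(t, self.model.data[species], "o", color=color,
                    label=species)
            ax.plot(grid, fitted[species], "-", color=color)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("abundance (fraction of precursor)")
        ax.legend()
        return ax

    @property
    def _summary_extra(self):
        return [f"decay constants a = {self.a:.4g}/s, b = {self.b:.4g}/s",
                f"t_1/2(k3) = {half_life(self.k3):.3g} s",
                f"residual norm  {self.resid_norm:.4g}"]


def fit_single_exponential(timecourse: TimeCourse,
                           species: str = "P") -> SingleExponentialResults:
    """Convenience wrapper: build and fit :class:`SingleExponentialPTS`."""
    return SingleExponentialPTS(timecourse, species=species).fit()


def fit_three_state(timecourse: TimeCourse, species_map=None) -> ThreeStateResults:
    """Convenience wrapper: build and fit :class:`ThreeStatePTS`."""
    return ThreeStatePTS(timecourse, species_map=species_map).fit()
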