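"""Biphasic biolayer-interferometry (BLI) analysis.

The binding of a split-intein fragment (analyte N) to its sensor-immobilised
partner (ligand C) follows a two-step conformational-change mechanism:

    N + C  <=>(ka, kd)  N.C  <=>(kf, ku)  NC

a bimolecular encounter forming the loose complex [N.C], then a unimolecular
folding/locking step to the compact complex [NC].  Under pseudo-first-order
conditions (fixed analyte concentration C) the two complex species obey a
linear 2x2 system whose eigenvalue pair (sigma1, sigma2) depends linearly
on C:

    sigma1 + sigma2 = ka*C + kd + kf + ku
    sigma1 * sigma2 = ka*C*(kf + ku) + kd*ku

so the sensorgram is a double exponential in each phase.  Dissociation
(C = 0) has eigenvalues gamma1, gamma2 with gamma1 + gamma2 = kd + kf + ku
and gamma1*gamma2 = kd*ku.  Fitting both phases at several concentrations
and regressing the eigenvalue sums/products on C recovers all four
microscopic rates, from which equilibrium constants

    Ka1 = ka/kd,  Ka2 = kf/ku,  Ka = Ka1*(1 + Ka2),  Kd = 1/Ka

and the macroscopic (steady-state approximation) rates

    kon = ka*kf/(kd + kf),  koff = kd*ku/(kd + kf)

follow.  Note Kd and koff/kon = 1/(Ka1*Ka2) are distinct quantities for any
finite Ka2; Kd <= koff/kon always.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._fitting import (ResultsBase, covariance_from_jacobian,
                       multistart_least_squares, standard_errors)
from .exceptions import ConfigurationError, FitError, ModelInconsistencyError

__all__ = [
    "Sensorgram", "PhaseFitResults", "RateConstantSet", "BiphasicPhase",
    "RateExtraction", "RateConstantResults", "SteadyStateBinding",
    "SteadyStateResults", "two_step_matrix", "two_step_eigenvalues",
    "two_step_response", "fit_association", "fit_dissociation",
    "extract_rate_constants", "equilibrium_constants", "macroscopic_rates",
    "fit_steady_state", "validate_biphasic_model",
]

# sigma1/sigma2 below this ratio is treated as effectively mono-exponential
MONO_RATIO = 1.05


@dataclass(frozen=True)
class Sensorgram:
    """One BLI trace: response (nm) versus time at one analyte concentration.

    ``t_assoc_start`` and ``t_dissoc_start`` delimit the phases; times are in
    seconds and the analyte concentration ``conc`` in molar.
    """

    times: np.ndarray
    response: np.ndarray
    conc: float
    t_assoc_start: float = 0.0
    t_dissoc_start: float = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "response", y)
        if t.shape != y.shape or t.ndim != 1:
            raise ConfigurationError("times and response must match 1-D")
        if np.any(np.diff(t) <= 0):
            raise ConfigurationError("times must be strictly increasing")
        if self.conc <= 0:
            raise ConfigurationError("analyte concentration must be > 0")
        if self.t_dissoc_start is not None and not (
                t[0] <= self.t_dissoc_start <= t[-1]):
            raise ConfigurationError("t_dissoc_start outside the time range")

    def segment(self, phase: str):
        """Return (t_rel, y) for ``phase`` in {"association", "dissociation"},
        with time measured from the phase start."""
        t, y = self.times, self.response
        if phase == "association":
            stop = self.t_dissoc_start if self.t_dissoc_start is not None else t[-1]
            m = (t >= self.t_assoc_start) & (t <= stop)
            return t[m] - self.t_assoc_start, y[m]
        if phase == "dissociation":
            if self.t_dissoc_start is None:
                raise ConfigurationError("no dissociation start defined")
            m = t >= self.t_dissoc_start
            return t[m] - self.t_dissoc_start, y[m]
        raise ValueError(f"unknown phase {phase!r}")


# ---------------------------------------------------------------------------
# forward model (closed form of the linear two-step system)

def two_step_matrix(ka, kd, kf, ku, conc):
    """Rate matrix of ([N.C], [NC]) at fixed analyte concentration.

    Mass action with ligand conservation [C] = [C0] - [N.C] - [NC] gives
    d[N.C]/dt = ka*C*[C0] - (ka*C + kd + kf)[N.C] - (ka*C - ku)[NC]
    d[NC]/dt  = kf*[N.C] - ku*[NC]
    """
    return np.array([[-(ka * conc + kd + kf), -(ka * conc - ku)],
                     [kf, -ku]])


def two_step_eigenvalues(ka, kd, kf, ku, conc):
    """(sigma1, sigma2) decay constants, sigma1 >= sigma2, at analyte conc."""
    tr = ka * conc + kd + kf + ku
    det = ka * conc * (kf + ku) + kd * ku
    disc = math.sqrt(max(tr * tr - 4.0 * det, 0.0))
    return 0.5 * (tr + disc), 0.5 * (tr - disc)


def two_step_response(ka, kd, kf, ku, conc, t_assoc, t_dissoc=None,
                      c0=1.0, alpha=1.0, beta=1.0):
    """Closed-form sensorgram of the two-step model.

    Association starts from empty sensor ([N.C] = [NC] = 0); dissociation
    continues from the association end with C set to 0.  The response is
    Y = alpha*[N.C] + beta*[NC].  Returns the association response, and the
    dissociation response when ``t_dissoc`` (times from dissociation start)
    is given.
    """
    t_assoc = np.asarray(t_assoc, dtype=float)
    m = two_step_matrix(ka, kd, kf, ku, conc)
    g = np.array([ka * conc * c0, 0.0])
    # lstsq handles the singular kf = ku = 0 limit (zero eigenvalue mode)
    xeq, *_ = np.linalg.lstsq(-m, g, rcond=None)
    lam, vecs = np.linalg.eig(m)
    coeff = np.linalg.solve(vecs, -xeq)  # x(0) - xeq with x(0) = 0
    modes = vecs @ (coeff[:, None] * np.exp(np.outer(lam, t_assoc)))
    x_assoc = xeq[:, None] + modes
    w = np.array([alpha, beta])
    y_assoc = w @ x_assoc
    if t_dissoc is None:
        return np.real(y_assoc)
    x_end = x_assoc[:, -1]
    m0 = two_step_matrix(ka, kd, kf, ku, 0.0)
    lam0, vecs0 = np.linalg.eig(m0)
    coeff0 = np.linalg.solve(vecs0, x_end)
    t_dissoc = np.asarray(t_dissoc, dtype=float)
    x_dissoc = vecs0 @ (coeff0[:, None] * np.exp(np.outer(lam0, t_dissoc)))
    return np.real(y_assoc), np.real(w @ x_dissoc)


# ---------------------------------------------------------------------------
# phase fitting

@dataclass
class PhaseFitResults(ResultsBase):
    """Double-exponential fit of one sensorgram phase.

    Association: Y = D + E*exp(-sigma1*t) + F*exp(-sigma2*t), D = -(E+F)
    so Y(0) = 0.  Dissociation: Y = E*exp(-gamma1*(t-t0)) +
    F*exp(-gamma2*(t-t0)) with free E, F.  ``sigma1 >= sigma2`` by
    convention; for dissociation the exponents are the gammas.
    """

    phase: str
    sigma1: float
    sigma2: float
    E: float
    F: float
    conc: float
    resid_norm: float
    mono_exponential: bool = False
    _bse: list = None

    param_names = ("sigma1", "sigma2", "E", "F")

    @property
    def title(self):
        return f"Biphasic {self.phase} fit (C = {self.conc:.3g} M)"

    @property
    def D(self):
        return -(self.E + self.F) if self.phase == "association" else 0.0

    @property
    def eigen_sum(self):
        return self.sigma1 + self.sigma2 if not self.mono_exponential else self.sigma1

    @property
    def eigen_product(self):
        return self.sigma1 * self.sigma2

    def predict(self, t_rel):
        t = np.asarray(t_rel, dtype=float)
        e1 = np.exp(-self.sigma1 * t)
        e2 = np.exp(-self.sigma2 * t)
        if self.phase == "association":
            return self.E * (e1 - 1.0) + self.F * (e2 - 1.0)
        return self.E * e1 + self.F * e2


class BiphasicPhase:
    """Variable-projection fit of a double exponential to one phase.

    The amplitudes are linear given the exponents, so the nonlinear search
    runs over (log sigma1, log sigma2) only, seeded on a log-spaced grid;
    amplitudes come from a linear least-squares solve at each step.  Fits
    whose exponents are nearly degenerate (sigma1/sigma2 < 1.05) are re-run
    as a single exponential and flagged.
    """

    def __init__(self, trace: Sensorgram, phase: str):
        if phase not in ("association", "dissociation"):
            raise ValueError(f"unknown phase {phase!r}")
        self.phase = phase
        self.conc = trace.conc
        self.t, self.y = trace.segment(phase)
        if len(self.t) < 20:
            raise ConfigurationError(
                f"{phase} segment has {len(self.t)} points; need >= 20")
        if np.allclose(self.y, 0.0, atol=1e-12):
            raise FitError(f"{phase} trace is identically zero")

    def _design(self, sigmas):
        e = np.exp(-np.outer(self.t, sigmas))
        if self.phase == "association":
            e = e - 1.0
        return e

    def _amplitudes(self, sigmas):
        X = self._design(sigmas)
        amps, *_ = np.linalg.lstsq(X, self.y, rcond=None)
        return amps, X @ amps - self.y

    def fit(self) -> PhaseFitResults:
        span = self.t[-1] - self.t[0]
        rates = np.logspace(math.log10(0.2 / span), math.log10(200.0 / span), 6)
        starts = [np.log([r1, r2]) for i, r1 in enumerate(rates)
                  for r2 in rates[:i + 1] if r1 / r2 < 1e4]

        def residual(theta):
            return self._amplitudes(np.exp(theta))[1]

        sol = multistart_least_squares(residual, starts)
        s = np.sort(np.exp(sol.x))[::-1]
        amps, res = self._amplitudes(s)
        mono = s[0] / s[1] < MONO_RATIO or (
            abs(amps).min() < 1e-4 * abs(amps).max())
        if mono:
            return self._fit_single()
        jac = sol.jac / np.exp(sol.x)[None, :]
        cov = covariance_from_jacobian(jac, res)
        se = standard_errors(cov)
        if np.exp(sol.x)[0] < np.exp(sol.x)[1]:
            se = se[::-1]
        return PhaseFitResults(
            phase=self.phase, sigma1=float(s[0]), sigma2=float(s[1]),
            E=float(amps[0]), F=float(amps[1]), conc=self.conc,
            resid_norm=float(np.linalg.norm(res)),
            _bse=list(se) + [float("nan")] * 2)

    def _fit_single(self) -> PhaseFitResults:
        span = self.t[-1] - self.t[0]

        def residual(theta):
            return self._amplitudes(np.exp(theta))[1]

        starts = [[math.log(f / span)] for f in (0.5, 5.0, 50.0)]
        sol = multistart_least_squares(residual, starts)
        s = float(np.exp(sol.x[0]))
        amps, res = self._amplitudes(np.array([s]))
        return PhaseFitResults(
            phase=self.phase, sigma1=s, sigma2=float("nan"),
            E=float(amps[0]), F=0.0, conc=self.conc,
            resid_norm=float(np.linalg.norm(res)), mono_exponential=True)


def fit_association(trace: Sensorgram) -> PhaseFitResults:
    """Fit Y = D + E e^(-sigma1 t) + F e^(-sigma2 t), D = -(E+F)."""
    return BiphasicPhase(trace, "association").fit()


def fit_dissociation(trace: Sensorgram) -> PhaseFitResults:
    """Fit Y = E e^(-gamma1 (t-t0)) + F e^(-gamma2 (t-t0))."""
    return BiphasicPhase(trace, "dissociation").fit()


# ---------------------------------------------------------------------------
# rate-constant extraction

@dataclass(frozen=True)
class RateConstantSet:
    """Microscopic rates of the two-step model and derived constants."""

    ka: float   # 1/(M s)
    kd: float   # 1/s
    kf: float   # 1/s
    ku: float   # 1/s

    def __post_init__(self):
        for name in ("ka", "kd", "kf", "ku"):
            if getattr(self, name) <= 0:
                raise ModelInconsistencyError(
                    f"rate {name} must be positive, got {getattr(self, name)}")

    @property
    def Ka1(self):
        return self.ka / self.kd

    @property
    def Ka2(self):
        return self.kf / self.ku

    @property
    def Ka(self):
        return self.Ka1 * (1.0 + self.Ka2)

    @property
    def Kd(self):
        return 1.0 / self.Ka

    @property
    def kon(self):
        return self.ka * self.kf / (self.kd + self.kf)

    @property
    def koff(self):
        return self.kd * self.ku / (self.kd + self.kf)

    def as_dict(self):
        return {k: getattr(self, k) for k in
                ("ka", "kd", "kf", "ku", "Ka1", "Ka2", "Ka", "Kd",
                 "kon", "koff")}


def equilibrium_constants(rates: RateConstantSet) -> dict:
    """Ka1, Ka2, overall Ka = Ka1(1+Ka2) and Kd = 1/Ka."""
    return {"Ka1": rates.Ka1, "Ka2": rates.Ka2, "Ka": rates.Ka,
            "Kd": rates.Kd}


def macroscopic_rates(rates: RateConstantSet) -> dict:
    """Steady-state overall kon = ka kf/(kd+kf) and koff = kd ku/(kd+kf)."""
    return {"kon": rates.kon, "koff": rates.koff}


def _ols(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r_squared": float(res.rvalue ** 2),
            "slope_stderr": float(res.stderr)}


@dataclass
class RateConstantResults(ResultsBase):
    """Extraction result: the rate set plus the regression diagnostics."""

    rates: RateConstantSet
    sum_regression: dict
    product_regression: dict
    gamma_sum: float
    gamma_product: float
    _bse: list = None

    param_names = ("ka", "kd", "kf", "ku")
    title = "Two-step rate-constant extraction"

    def __getattr__(self, name):
        if name in ("ka", "kd", "kf", "ku", "Ka1", "Ka2", "Ka", "Kd",
                    "kon", "koff"):
            return getattr(self.rates, name)
        raise AttributeError(name)

    @property
    def _summary_extra(self):
        d = self.rates.as_dict()
        return [f"Ka1 = {d['Ka1']:.4g} /M   Ka2 = {d['Ka2']:.4g}",
                f"Ka  = {d['Ka']:.4g} /M   Kd  = {d['Kd']:.4g} M",
                f"kon = {d['kon']:.4g} /M/s  koff = {d['koff']:.4g} /s",
                f"R^2(sum vs C) = {self.sum_regression['r_squared']:.6f}",
                f"R^2(prod vs C) = {self.product_regression['r_squared']:.6f}"]


class RateExtraction:
    """Eigenvalue regressions recovering (ka, kd, kf, ku).

    From association fits at >= 3 concentrations: the slope of
    sigma1+sigma2 vs C gives ka and the slope of sigma1*sigma2/ka vs C gives
    kf+ku.  The concentration-independent dissociation eigenvalues then give
    kd = (gamma1+gamma2) - (kf+ku), ku = gamma1*gamma2/kd and
    kf = (gamma1+gamma2) - (kd+ku).  Regressions are ordinary least squares
    with a free intercept; gammas are averaged over replicates.
    """

    def __init__(self, assoc_fits, dissoc_fits):
        assoc = list(assoc_fits)
        if len({f.conc for f in assoc}) < 3:
            raise ConfigurationError(
                "need association fits at >= 3 distinct concentrations")
        self.assoc = assoc
        self.dissoc = list(dissoc_fits)
        if not self.dissoc:
            raise ConfigurationError("need at least one dissociation fit")

    def fit(self) -> RateConstantResults:
        conc = np.array([f.conc for f in self.assoc])
        sums = np.array([f.sigma1 + f.sigma2 for f in self.assoc])
        prods = np.array([f.sigma1 * f.sigma2 for f in self.assoc])
        reg_sum = _ols(conc, sums)
        ka = reg_sum["slope"]
        if not (ka > 0 and reg_sum["r_squared"] > 1e-6):
            raise ModelInconsistencyError(
                "sigma1+sigma2 does not increase with C; not a valid "
                "concentration series", diagnostics={"sum": reg_sum})
        reg_prod = _ols(conc, prods / ka)
        kf_plus_ku = reg_prod["slope"]
        g_sum = float(np.mean([f.sigma1 + f.sigma2 for f in self.dissoc]))
        g_prod = float(np.mean([f.sigma1 * f.sigma2 for f in self.dissoc]))
        kd = g_sum - kf_plus_ku
        diagnostics = {"sum_regression": reg_sum,
                       "product_regression": reg_prod,
                       "gamma_sum": g_sum, "gamma_product": g_prod,
                       "kf_plus_ku": kf_plus_ku}
        if kd <= 0:
            raise ModelInconsistencyError(
                f"derived kd = {kd:.3g} <= 0", diagnostics=diagnostics)
        ku = g_prod / kd
        kf = g_sum - kd - ku
        if min(ku, kf) <= 0:
            raise ModelInconsistencyError(
                f"derived kf = {kf:.3g}, ku = {ku:.3g}; model inconsistent",
                diagnostics=diagnostics)
        rates = RateConstantSet(ka=ka, kd=kd, kf=kf, ku=ku)
        return RateConstantResults(
            rates=rates, sum_regression=reg_sum, product_regression=reg_prod,
            gamma_sum=g_sum, gamma_product=g_prod,
            _bse=[reg_sum["slope_stderr"]] + [float("nan")] * 3)


def extract_rate_constants(assoc_fits, dissoc_fits) -> RateConstantResults:
    """Convenience wrapper: build and fit :class:`RateExtraction`."""
    return RateExtraction(assoc_fits, dissoc_fits).fit()


def validate_biphasic_model(assoc_fits, r2_threshold: float = 0.99) -> dict:
    """Model diagnostics: linearity in C of eigenvalue sum and product.

    Returns R^2 of the sigma1+sigma2 vs C and sigma1*sigma2 vs C
    regressions, whether any phase degraded to mono-exponential, and a
    pass/fail flag against ``r2_threshold``.
    """
    assoc = list(assoc_fits)
    if len({f.conc for f in assoc}) < 3:
        raise ConfigurationError("need >= 3 distinct concentrations")
    mono = any(f.mono_exponential for f in assoc)
    biphasic = [f for f in assoc if not f.mono_exponential]
    if len({f.conc for f in biphasic}) < 3:
        return {"r2_sum": float("nan"), "r2_product": float("nan"),
                "mono_exponential": True, "passes": False}
    conc = [f.conc for f in biphasic]
    reg_sum = _ols(conc, [f.sigma1 + f.sigma2 for f in biphasic])
    reg_prod = _ols(conc, [f.sigma1 * f.sigma2 for f in biphasic])
    passes = (not mono and reg_sum["r_squared"] >= r2_threshold
              and reg_prod["r_squared"] >= r2_threshold
              and reg_sum["slope"] > 0 and reg_prod["slope"] > 0)
    return {"r2_sum": reg_sum["r_squared"],
            "r2_product": reg_prod["r_squared"],
            "mono_exponential": mono, "passes": bool(passes)}


# ---------------------------------------------------------------------------
# steady state

@dataclass
class SteadyStateResults(ResultsBase):
    Kd: float
    Ymax: float
    resid_norm: float
    _bse: list = None

    param_names = ("Kd", "Ymax")
    title = "Steady-state binding fit"

    def predict(self, conc):
        x = np.asarray(conc, dtype=float)
        return self.Ymax * x / (self.Kd + x)


class SteadyStateBinding:
    """Langmuir fit Y = Ymax*X/(Kd + X) of plateau responses vs concentration.

    The plateau response is conventionally the average over the final
    seconds of the association phase.
    """

    def __init__(self, conc, response):
        self.conc = np.asarray(conc, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if len(np.unique(self.conc)) < 4:
            raise ConfigurationError("need >= 4 distinct concentrations")

    def fit(self) -> SteadyStateResults:
        x, y = self.conc, self.response
        # no curvature -> Kd unidentifiable; detect by linearity through 0
        reg = _ols(x, y)
        if reg["r_squared"] > 1.0 - 1e-9 and abs(reg["intercept"]) < 1e-12 * max(abs(y)):
            raise FitError("responses are proportional to C (no saturation); "
                           "Kd is unidentifiable")
        kd0 = float(np.median(x))
        ymax0 = float(y.max()) * 1.5

        def model(x, kd, ymax):
            return ymax * x / (kd + x)

        try:
            popt, pcov = optimize.curve_fit(
                model, x, y, p0=[kd0, ymax0],
                bounds=([1e-15, 1e-12], [np.inf, np.inf]), maxfev=20000)
        except RuntimeError as exc:
            raise FitError(f"steady-state fit failed: {exc}") from exc
        res = model(x, *popt) - y
        if popt[0] > 100 * x.max():
            raise FitError("no saturation curvature in the data; "
                           "Kd is unidentifiable")
        return SteadyStateResults(
            Kd=float(popt[0]), Ymax=float(popt[1]),
            resid_norm=float(np.linalg.norm(res)),
            _bse=list(np.sqrt(np.diag(pcov))))


def fit_steady_state(conc, response) -> SteadyStateResults:
    """Convenience wrapper: build and fit :class:`SteadyStateBinding`."""
    return SteadyStateBinding(conc, response).fit()
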