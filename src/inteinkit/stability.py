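"""Thermal-shift (dye-binding) melt-curve analysis.

A hydrophobic reporter dye gains fluorescence as a protein unfolds with
temperature; past the transition the signal decays again because
protein-dye complexes aggregate and quench.  The analysis therefore cuts
the profile at its global maximum, normalises to that maximum, and fits a
four-parameter logistic

    Y = Ymin + (Ymax - Ymin) / (1 + 10^((T_M - X) * b))

where ``T_M`` is the melting temperature (degC) and ``b`` the Hill
coefficient (1/degC, constrained positive so the sigmoid increases).  The
fitted curve passes through (Ymin+Ymax)/2 exactly at X = T_M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from ._fitting import ResultsBase
from .exceptions import ConfigurationError, FitError

__all__ = ["MeltCurve", "MeltResults", "MeltCurveModel", "fit_melt_curve"]


@dataclass(frozen=True)
class MeltCurve:
    """Fluorescence vs temperature, optionally with replicates.

    ``replicate`` labels rows of equal length; replicates are averaged on a
    common temperature grid before truncation.
    """

    temperature: np.ndarray
    fluorescence: np.ndarray
    replicate: np.ndarray = None

    def __post_init__(self):
        t = np.asarray(self.temperature, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "fluorescence", f)
        if t.shape != f.shape or t.ndim != 1:
            raise ConfigurationError("temperature/fluorescence must match 1-D")
        if self.replicate is not None:
            r = np.asarray(self.replicate)
            if r.shape != t.shape:
                raise ConfigurationError("replicate labels must match data")
            object.__setattr__(self, "replicate", r)

    def mean_curve(self):
        """(temperature, mean fluorescence) averaged over replicates."""
        if self.replicate is None:
            order = np.argsort(self.temperature)
            return self.temperature[order], self.fluorescence[order]
        frame = pd.DataFrame({"T": self.temperature, "F": self.fluorescence})
        g = frame.groupby("T", sort=True)["F"].mean()
        return g.index.to_numpy(), g.to_numpy()


@dataclass
class MeltResults(ResultsBase):
    T_M: float          # degC
    b: float            # Hill coefficient, 1/degC
    Ymin: float
    Ymax: float
    truncation_temperature: float
    resid_norm: float
    _bse: list = None

    param_names = ("T_M", "b", "Ymin", "Ymax")
    title = "Four-parameter logistic melt fit"

    def predict(self, temperature):
        x = np.asarray(temperature, dtype=float)
        return self.Ymin + (self.Ymax - self.Ymin) / (
            1.0 + 10.0 ** ((self.T_M - x) * self.b))

    def plot(self, model: "MeltCurveModel" = None, ax=None):
        """Fitted logistic with T_M marked; overlays data when given."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if model is not None:
            ax.plot(model.t, model.y, "o", ms=3, label="data (truncated)")
        lo = self.T_M - 4.0 / self.b
        hi = self.truncation_temperature
        grid = np.linspace(lo, hi, 200)
        ax.plot(grid, self.predict(grid), "-", label="logistic fit")
        ax.axvline(self.T_M, ls="--", color="gray",
                   label=f"T_M = {self.T_M:.1f} degC")
        ax.set_xlabel("temperature (degC)")
        ax.set_ylabel("normalised fluorescence")
        ax.legend()
        return ax


class MeltCurveModel:
    """Truncate-at-peak, normalise, and fit the four-parameter logistic."""

    def __init__(self, curve: MeltCurve):
        t, f = curve.mean_curve()
        if len(t) < 10:
            raise ConfigurationError("need >= 10 temperature points")
        peak = int(np.argmax(f))
        if peak < 4:
            raise FitError("no sigmoidal transition before the fluorescence "
                           "maximum; cannot fit")
        self.truncation_temperature = float(t[peak])
        t, f = t[:peak + 1], f[:peak + 1]
        fmax = f.max()
        if fmax <= 0 or np.ptp(f) < 1e-12 * max(fmax, 1.0):
            raise FitError("flat fluorescence profile; no transition")
        self.t = t
        self.y = f / fmax

    def fit(self) -> MeltResults:
        t, y = self.t, self.y
        half = 0.5 * (y.min() + y.max())
        tm0 = float(t[int(np.argmax(y >= half))])

        def f(x, tm, b, ymin, ymax):
            return ymin + (ymax - ymin) / (1.0 + 10.0 ** ((tm - x) * b))

        lo = [t.min() - 20.0, 1e-4, -np.inf, -np.inf]
        hi = [t.max() + 20.0, 10.0, np.inf, np.inf]
        errors = []
        for b0 in (0.1, 0.3, 1.0):
            try:
                popt, pcov = optimize.curve_fit(
                    f, t, y, p0=[tm0, b0, y.min(), y.max()],
                    bounds=(lo, hi), maxfev=40000)
                break
            except RuntimeError as exc:
                errors.append(str(exc))
        else:
            raise FitError("melt fit did not converge",
                           diagnostics=errors)
        res = f(t, *popt) - y
        if popt[3] - popt[2] < 1e-6:
            raise FitError("no sigmoidal transition detectable (Ymax == Ymin)")
        return MeltResults(
            T_M=float(popt[0]), b=float(popt[1]), Ymin=float(popt[2]),
            Ymax=float(popt[3]),
            truncation_temperature=self.truncation_temperature,
            resid_norm=float(np.linalg.norm(res)),
            _bse=list(np.sqrt(np.diag(pcov))))


def fit_melt_curve(curve: MeltCurve) -> MeltResults:
    """Convenience wrapper: build and fit :class:`MeltCurveModel`."""
    return MeltCurveModel(curve).fit()
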