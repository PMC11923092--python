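"""Shared nonlinear least-squares machinery.

All fitting models in the package share the same backbone: parameters that
must be positive are optimised on a log scale, starts are multi-seeded on a
log-spaced grid, and standard errors come from the Jacobian at the optimum
(Gauss-Newton covariance).  Results objects expose a statsmodels-flavoured
``summary()``.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .exceptions import FitError

__all__ = ["multistart_least_squares", "covariance_from_jacobian", "ResultsBase"]


def multistart_least_squares(residual, starts, bounds=None, xtol=1e-12,
                             ftol=1e-12, gtol=1e-12):
    """Run :func:`scipy.optimize.least_squares` from several starts.

    Parameters
    ----------
    residual : callable
        Vector residual function of the parameter array.
    starts : sequence of array-like
        Initial parameter vectors (already on the optimisation scale).
    bounds : tuple, optional
        ``(lower, upper)`` bounds passed through to ``least_squares``.

    Returns
    -------
    scipy.optimize.OptimizeResult
        The best converged solution (lowest cost).

    Raises
    ------
    FitError
        If no start converges; diagnostics carry every start tried.
    """
    best = None
    tried = []
    for x0 in starts:
        x0 = np.asarray(x0, dtype=float)
        try:
            kw = {} if bounds is None else {"bounds": bounds}
            sol = optimize.least_squares(residual, x0, xtol=xtol, ftol=ftol,
                                         gtol=gtol, **kw)
        except Exception as exc:  # noqa: BLE001 - recorded in diagnostics
            tried.append({"x0": x0.tolist(), "error": str(exc)})
            continue
        tried.append({"x0": x0.tolist(), "cost": float(sol.cost),
                      "success": bool(sol.success)})
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("least-squares fit failed from every start point",
                       diagnostics=tried)
    return best


def covariance_from_jacobian(jac, residuals, n_params=None):
    """Gauss-Newton parameter covariance s^2 (J^T J)^-1.

    Returns a matrix of ``nan`` when the problem is rank deficient or has no
    residual degrees of freedom.
    """
    n_params = jac.shape[1] if n_params is None else n_params
    dof = len(residuals) - n_params
    if dof <= 0:
        return np.full((n_params, n_params), np.nan)
    s2 = float(residuals @ residuals) / dof
    try:
        jtj_inv = np.linalg.pinv(jac.T @ jac)
    except np.linalg.LinAlgError:
        return np.full((n_params, n_params), np.nan)
    return s2 * jtj_inv


def standard_errors(cov):
    """sqrt of the covariance diagonal; non-positive entries become nan."""
    d = np.diag(cov).copy()
    d[~(d > 0)] = np.nan
    return np.sqrt(d)


class ResultsBase:
    """Base for fit results: parameter table and text summary."""

    #: ordered parameter names; subclasses set this
    param_names: tuple = ()

    @property
    def params(self) -> dict:
        return {name: getattr(self, name) for name in self.param_names}

    @property
    def bse(self) -> dict:
        """Standard errors, where available (nan otherwise)."""
        se = getattr(self, "_bse", None)
        if se is None:
            return {name: float("nan") for name in self.param_names}
        return dict(zip(self.param_names, se))

    def summary(self) -> str:
        title = getattr(self, "title", type(self).__name__)
        lines = [title, "=" * len(title),
                 f"{'parameter':<14}{'estimate':>14}{'std err':>14}"]
        bse = self.bse
        for name, value in self.params.items():
            lines.append(f"{name:<14}{value:>14.6g}{bse[name]:>14.3g}")
        extra = getattr(self, "_summary_extra", None)
        if extra:
            lines.append("-" * 42)
            lines.extend(extra)
        return "\n".join(lines)

    def __repr__(self):  # pragma: no cover - cosmetic
        pairs = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return f"<{type(self).__name__} {pairs}>"
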