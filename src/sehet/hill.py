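"""Hill dose-response fitting and switch-likeness categorization.

The dose-response model is

    f(d) = a + k * d^N / (Km^N + d^N)

with N the Hill coefficient (cooperativity), Km the half-maximal dose
(binding affinity), k the response amplitude, and a the basal term
(fixed to 0 for basal-free fits).  Parameters are estimated by
least squares with a multi-start strategy: an 8x8 log-spaced grid over
(N, Km) with the conditionally-linear (a, k) solved analytically at
each node, followed by Nelder-Mead and bounded quasi-Newton polishing
from the best grid nodes; the basket's best rss wins.  Among candidates
whose rss ties within a relative tolerance, the smallest N is preferred
(steepness is reported only when the data demand it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import minimize

__all__ = ["HillFit", "hill_curve", "fit_hill", "categorize_hill"]

N_BOUNDS = (0.05, 20.0)
GRID_SHAPE = (8, 8)
_TIE_RTOL = 1e-6


class FitError(ValueError):
    """Under-determined or degenerate dose-response fit."""


@dataclass
class HillFit:
    """Fitted Hill parameters plus fit diagnostics."""

    N: float
    Km: float
    k: float
    a: float
    rss: float
    n_points: int
    category: str = "none"
    with_basal: bool = True
    n_bounds: tuple = N_BOUNDS

    def predict(self, dose) -> np.ndarray:
        return hill_curve(dose, self.N, self.Km, self.k, self.a)

    def to_dict(self) -> dict:
        return {
            "N": self.N, "Km": self.Km, "k": self.k, "a": self.a,
            "rss": self.rss, "n_points": self.n_points,
            "category": self.category, "with_basal": self.with_basal,
        }


def hill_curve(dose, N: float, Km: float, k: float, a: float = 0.0) -> np.ndarray:
    """Evaluate a + k*d^N/(Km^N + d^N); value at d=0 is a (for N > 0)."""
    d = np.asarray(dose, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        ratio = np.where(d > 0, (d / Km) ** N, 0.0)
        frac = np.where(np.isinf(ratio), 1.0, ratio / (1.0 + ratio))
    return a + k * frac


def _linear_ak(theta: np.ndarray, y: np.ndarray, with_basal: bool):
    """Solve the conditionally-linear (a, k) given occupancy theta.

    Non-negativity of a and k is enforced by clipping and re-solving the
    remaining free parameter.
    """
    if with_basal:
        X = np.column_stack([np.ones_like(theta), theta])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        a, k = coef
        if a < 0:
            a = 0.0
            k = _nnls_scalar(theta, y)
        elif k < 0:
            k = 0.0
            a = max(float(np.mean(y)), 0.0)
    else:
        a = 0.0
        k = _nnls_scalar(theta, y)
    return float(a), float(k)


def _nnls_scalar(x: np.ndarray, y: np.ndarray) -> float:
    denom = float(x @ x)
    if denom == 0:
        return 0.0
    return max(float(x @ y) / denom, 0.0)


def _rss(dose, y, N, Km, k, a) -> float:
    r = y - hill_curve(dose, N, Km, k, a)
    return float(r @ r)


def fit_hill(
    response: Mapping[float, float] | tuple,
    with_basal: bool = True,
) -> HillFit:
    """Least-squares Hill fit of a dose -> response mapping.

    Parameters
    ----------
    response
        Mapping of dose to response value, or a (doses, values) pair.
    with_basal
        If False the basal term a is fixed to 0 (3 free parameters).

    Raises
    ------
    FitError
        If there are fewer points than free parameters, or the response
        is identically zero.
    """
    if isinstance(response, Mapping):
        doses = np.array(sorted(response), dtype=float)
        y = np.array([response[d] for d in doses], dtype=float)
    else:
        doses, y = (np.asarray(v, dtype=float) for v in response)
        order = np.argsort(doses)
        doses, y = doses[order], y[order]

    n_free = 4 if with_basal else 3
    if doses.size < n_free:
        raise FitError(
            f"{doses.size} points cannot determine {n_free} Hill parameters"
        )
    if np.all(y == 0):
        raise FitError("all-zero response: Hill fit is degenerate")

    pos = doses[doses > 0]
    km_lo, km_hi = pos.min() / 10.0, doses.max() * 10.0
    n_grid = np.geomspace(0.25, 16.0, GRID_SHAPE[0])
    km_grid = np.geomspace(km_lo, km_hi, GRID_SHAPE[1])

    candidates = []  # (rss, N, Km, k, a)
    for N0 in n_grid:
        for Km0 in km_grid:
            theta = hill_curve(doses, N0, Km0, 1.0, 0.0)
            a0, k0 = _linear_ak(theta, y, with_basal)
            candidates.append((_rss(doses, y, N0, Km0, k0, a0), N0, Km0, k0, a0))
    candidates.sort(key=lambda c: (c[0], c[1]))

    log_km_bounds = (np.log(km_lo / 10.0), np.log(km_hi * 10.0))
    log_n_bounds = tuple(np.log(N_BOUNDS))

    def objective(p):
        N = np.exp(np.clip(p[0], *log_n_bounds))
        Km = np.exp(np.clip(p[1], *log_km_bounds))
        theta = hill_curve(doses, N, Km, 1.0, 0.0)
        a, k = _linear_ak(theta, y, with_basal)
        return _rss(doses, y, N, Km, k, a)

    polished = list(candidates[:3])
    for _, N0, Km0, _, _ in candidates[:3]:
        x0 = np.array([np.log(N0), np.log(Km0)])
        for method in ("Nelder-Mead", "L-BFGS-B"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = minimize(objective, x0, method=method,
                               options={"xatol": 1e-10, "fatol": 1e-14}
                               if method == "Nelder-Mead" else None)
            N = float(np.exp(np.clip(res.x[0], *log_n_bounds)))
            Km = float(np.exp(np.clip(res.x[1], *log_km_bounds)))
            theta = hill_curve(doses, N, Km, 1.0, 0.0)
            a, k = _linear_ak(theta, y, with_basal)
            polished.append((_rss(doses, y, N, Km, k, a), N, Km, k, a))

    best_rss = min(c[0] for c in polished)
    # prefer the flattest curve among (near-)ties
    tol = best_rss * _TIE_RTOL + 1e-15
    rss, N, Km, k, a = min(
        (c for c in polished if c[0] <= best_rss + tol), key=lambda c: c[1]
    )
    return HillFit(N=N, Km=Km, k=k, a=a, rss=rss,
                   n_points=int(doses.size), with_basal=with_basal)


def categorize_hill(
    fit: HillFit | float,
    exclude_low: float = 0.3,
    exclude_high: float = 9.0,
    high: float = 5.0,
    low: float = 1.0,
) -> str:
    """Bin a Hill coefficient into switch-likeness categories.

    Coefficients outside (exclude_low, exclude_high] are 'excluded'
    (over-fitted or non-fitting); then high: high <= N, med:
    low < N < high, low: N <= low.
    """
    N = fit.N if isinstance(fit, HillFit) else float(fit)
    if N > exclude_high or N < exclude_low:
        return "excluded"
    if N >= high:
        return "high"
    if N > low:
        return "med"
    return "low"
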