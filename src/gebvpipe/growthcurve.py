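"""Individual growth-curve fitting and phenotype extrapolation.

Each animal's longitudinal yield measurements (five time points in the
default design) are fitted by nonlinear least squares to candidate growth
models — the three-parameter Gompertz curve ``A*exp(-b*exp(-k*t))`` and a
logistic comparator ``A/(1 + b*exp(-k*t))`` — and the winner by AIC is used
to extrapolate the phenotype to later ages (t600 in the default design).
Fits are per-individual, with a deterministic multi-start grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

MODELS = ("gompertz", "logistic")
N_PARAMS = 3          # A, b, k for both candidates
_K_GRID = (0.005, 0.01, 0.02)


@dataclass
class GrowthFit:
    model: str
    A: float
    b: float
    k: float
    rss: float
    n_points: int
    aic: float
    bic: float
    converged: bool
    message: str = ""

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.A, self.b, self.k)


def _curve(model: str, t: np.ndarray, A: float, b: float, k: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if model == "gompertz":
        return A * np.exp(-b * np.exp(-k * t))
    if model == "logistic":
        return A / (1.0 + b * np.exp(-k * t))
    raise ValueError(f"unknown growth model {model!r}")


def _jacobian(model: str, t: np.ndarray, A: float, b: float, k: float
              ) -> np.ndarray:
    """Analytic d(curve)/d(A, b, k), one row per time point."""
    t = np.asarray(t, dtype=float)
    ekt = np.exp(-k * t)
    if model == "gompertz":
        core = np.exp(-b * ekt)
        return np.column_stack([core, -A * core * ekt, A * core * b * t * ekt])
    denom = (1.0 + b * ekt) ** 2
    return np.column_stack([1.0 / (1.0 + b * ekt), -A * ekt / denom,
                            A * b * t * ekt / denom])


def information_criteria(rss: float, n: int, n_params: int = N_PARAMS
                         ) -> tuple[float, float]:
    """Gaussian-likelihood AIC/BIC from the residual sum of squares.

    k counts the curve parameters plus the residual variance.  RSS of
    exactly zero maps to -inf (a perfect fit dominates any competitor).
    """
    k = n_params + 1
    if rss <= 0.0:
        return (-np.inf, -np.inf)
    base = n * np.log(rss / n)
    return (base + 2 * k, base + k * np.log(n))


def _starts(model: str, t: np.ndarray, y: np.ndarray):
    """Deterministic start grid: A from the data maximum, k over a coarse
    growth-rate grid, b solved from the first observation."""
    ymax = float(np.max(y))
    if ymax <= 0:
        ymax = 1.0
    y0 = float(y[np.argmin(t)])
    out = []
    for A0 in (ymax, 1.5 * ymax):
        for k0 in _K_GRID:
            if model == "gompertz":
                b0 = -np.log(y0 / A0) if 0 < y0 < A0 else 3.0
            else:
                b0 = A0 / y0 - 1.0 if 0 < y0 < A0 else 3.0
            out.append((A0, max(b0, 1e-6), k0))
    return out


def fit_growth(times, values, model: str = "gompertz") -> GrowthFit:
    """Least-squares fit of one growth model to one individual's series.

    Runs every start on the deterministic grid and keeps the best solution;
    a fit that fails to improve on all starts is returned flagged
    (``converged=False``) rather than raising.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(np.unique(t)) < 4:
        raise ValueError("need at least 4 distinct time points")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("times and values must be finite")

    def resid(p):
        return _curve(model, t, *p) - y

    def jac(p):
        return _jacobian(model, t, *p)

    scale = max(float(np.sum(y**2)), 1.0)
    best = None
    ok = False
    for p0 in _starts(model, t, y):
        try:
            sol = least_squares(
                resid, p0, jac=jac, bounds=([1e-8, 0.0, 1e-8], [np.inf] * 3),
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=500,
            )
        except Exception:  # singular Jacobian etc.: try next start
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
            ok = ok or sol.success
        if rss < 1e-14 * scale:  # essentially perfect fit: stop searching
            break
    if best is None:
        aic, bic = np.inf, np.inf
        return GrowthFit(model, np.nan, np.nan, np.nan, np.inf, len(y),
                         aic, bic, False, "all starts failed")
    rss, (A, b, k) = best
    aic, bic = information_criteria(rss, len(y))
    return GrowthFit(model, float(A), float(b), float(k), rss, len(y),
                     aic, bic, ok, "" if ok else "no start converged")


def predict_timepoint(fit: GrowthFit, t) -> float | np.ndarray:
    """Evaluate the fitted curve at age ``t`` (extrapolation allowed)."""
    val = _curve(fit.model, np.asarray(t, dtype=float), fit.A, fit.b, fit.k)
    return float(val) if np.isscalar(t) else val


def select_model(fits: list[GrowthFit]) -> GrowthFit:
    """Minimum-AIC fit; ties broken by BIC, then parameter count, then the
    order the candidates were supplied in."""
    if not fits:
        raise ValueError("no candidate fits")
    best = fits[0]
    for f in fits[1:]:
        if (f.aic, f.bic, N_PARAMS) < (best.aic, best.bic, N_PARAMS):
            best = f
    return best


def fit_growth_table(pheno: pd.DataFrame, predict_at: float = 600.0,
                     models: tuple = MODELS) -> pd.DataFrame:
    """Fit every individual in a phenotype table and extrapolate.

    ``pheno`` has an ``id`` column and time-point columns named ``t<age>``.
    Returns one row per individual with the selected model's parameters,
    fit diagnostics and the extrapolated phenotype.
    """
    tcols = [c for c in pheno.columns if c.startswith("t") and c[1:].isdigit()]
    times = np.array([float(c[1:]) for c in tcols])
    rows = []
    for _, r in pheno.iterrows():
        y = r[tcols].to_numpy(dtype=float)
        fits = [fit_growth(times, y, model=mdl) for mdl in models]
        best = select_model(fits)
        rows.append({
            "id": int(r["id"]), "model": best.model, "A": best.A,
            "b": best.b, "k": best.k, "rss": best.rss, "aic": best.aic,
            "bic": best.bic, "converged": best.converged,
            f"t{int(predict_at)}": predict_timepoint(best, predict_at),
        })
    return pd.DataFrame(rows)


def write_fits(fits: pd.DataFrame, path) -> None:
    fits.to_csv(path, index=False)


def read_fits(path) -> pd.DataFrame:
    return pd.read_csv(path)
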