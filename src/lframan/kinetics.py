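"""Solid-state kinetic models and fitting for transformation curves.

The transformed fraction ρ(t) ∈ [0,1] of an isothermal solid-state
reaction is described by classical integral laws g(ρ) = k·t, where the
form of g encodes the rate-limiting mechanism:

======  ===========================================  ==========================
id      g(ρ)                                         mechanism
======  ===========================================  ==========================
avrami  −ln(1−ρ)  (= k·tⁿ)                           nucleation and growth,
                                                     ρ = 1 − exp(−k·tⁿ)
f1      −ln(1−ρ)                                     first-order (random nuclei)
r2      1 − (1−ρ)^(1/2)                              contracting area
r3      1 − (1−ρ)^(1/3)                              contracting volume
d1      ρ²                                           1-D diffusion
d2      (1−ρ)·ln(1−ρ) + ρ                            2-D diffusion (Valensi)
d3      [1 − (1−ρ)^(1/3)]²                           3-D diffusion (Jander)
d4      1 − 2ρ/3 − (1−ρ)^(2/3)                       3-D diffusion
                                                     (Ginstling–Brounshtein)
======  ===========================================  ==========================

The Avrami law is written f(t) = 1 − exp(−k·tⁿ) with k in min⁻ⁿ (not the
(k·t)ⁿ convention; see :func:`avrami_k_to_scaled`). Its exponent n
diagnoses the nucleation/growth dimensionality — n near 1 indicates
nucleation with little growth, n near 3 two-dimensional growth on
continuing nucleation.

Fitting is nonlinear least squares on ρ(t) directly, restricted by
default to ρ ∈ [0.05, 0.95] where the curve carries kinetic information.
The Avrami fit is initialized from the Sharp–Hancock linearization
(ln(−ln(1−ρ)) vs ln t); one-parameter models are initialized from the
observed half-transformation time. Model selection ranks fits by AICc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DegenerateDataError, DomainError, FitError
from .transform_rate import TransformationCurve

__all__ = [
    "KineticModel",
    "KineticFit",
    "MODELS",
    "get_model",
    "model_rho",
    "model_g",
    "fit_kinetics",
    "select_model",
    "avrami_k_to_scaled",
    "sharp_hancock",
]


def _check_rho(rho: np.ndarray) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    if np.any((rho < 0) | (rho > 1)):
        raise DomainError("rho must lie in [0, 1]")
    return rho


def _check_kt(t: np.ndarray, k: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("t must be >= 0")
    if k <= 0:
        raise DomainError(f"rate constant k must be > 0, got {k}")
    return t


# ---------------------------------------------------------------------------
# closed forms

def _g_avrami(rho):
    with np.errstate(divide="ignore"):  # g(1) = inf is the correct limit
        return -np.log1p(-_check_rho(rho))


def _rho_avrami(t, k, n):
    t = _check_kt(t, k)
    if n is None or n <= 0:
        raise DomainError(f"Avrami exponent n must be > 0, got {n}")
    return -np.expm1(-k * t ** n)


def _rho_f1(t, k, n=None):
    t = _check_kt(t, k)
    return -np.expm1(-k * t)


def _g_r2(rho):
    return 1.0 - np.sqrt(1.0 - _check_rho(rho))


def _rho_r2(t, k, n=None):
    kt = np.minimum(_check_kt(t, k) * k, 1.0)
    return 1.0 - (1.0 - kt) ** 2


def _g_r3(rho):
    return 1.0 - np.cbrt(1.0 - _check_rho(rho))


def _rho_r3(t, k, n=None):
    kt = np.minimum(_check_kt(t, k) * k, 1.0)
    return 1.0 - (1.0 - kt) ** 3


def _g_d1(rho):
    return _check_rho(rho) ** 2


def _rho_d1(t, k, n=None):
    kt = np.minimum(_check_kt(t, k) * k, 1.0)
    return np.sqrt(kt)


def _g_d2(rho):
    rho = _check_rho(rho)
    one_m = 1.0 - rho
    # (1-ρ)ln(1-ρ) → 0 as ρ → 1
    term = np.where(one_m > 0, one_m * np.log(np.where(one_m > 0, one_m, 1.0)), 0.0)
    return term + rho


def _g_d3(rho):
    return (1.0 - np.cbrt(1.0 - _check_rho(rho))) ** 2


def _rho_d3(t, k, n=None):
    kt = np.minimum(_check_kt(t, k) * k, 1.0)
    return 1.0 - (1.0 - np.sqrt(kt)) ** 3


def _g_d4(rho):
    rho = _check_rho(rho)
    return 1.0 - 2.0 * rho / 3.0 - (1.0 - rho) ** (2.0 / 3.0)


def _invert_g_newton(
    g: Callable, gprime: Callable, y: np.ndarray, g_max: float, table_rho: np.ndarray,
    table_g: np.ndarray,
) -> np.ndarray:
    """Invert a monotone g(ρ) = y: interpolation-table start + Newton polish."""
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    done = y >= g_max
    out[done] = 1.0
    active = ~done
    rho = np.interp(y[active], table_g, table_rho)
    for _ in range(60):
        gp = gprime(rho)
        resid = g(rho) - y[active]
        step = np.where(gp > 0, resid / np.where(gp > 0, gp, 1.0), 0.0)
        rho = np.clip(rho - step, 0.0, 1.0 - 1e-15)
        if np.all(np.abs(resid) < 1e-14):
            break
    out[active] = rho
    return out


_RHO_TABLE = 1.0 - np.logspace(0, -12, 4001)  # dense near both ends
_RHO_TABLE = np.union1d(_RHO_TABLE, np.linspace(0, 1 - 1e-12, 4001))

_D2_TABLE_G = _g_d2(_RHO_TABLE)
_D4_TABLE_G = _g_d4(_RHO_TABLE)


def _d2_gprime(rho):
    return -np.log(1.0 - rho)


def _d4_gprime(rho):
    return (2.0 / 3.0) * ((1.0 - rho) ** (-1.0 / 3.0) - 1.0)


def _rho_d2(t, k, n=None):
    kt = _check_kt(t, k) * k
    return _invert_g_newton(_g_d2, _d2_gprime, kt, 1.0, _RHO_TABLE, _D2_TABLE_G)


def _rho_d4(t, k, n=None):
    kt = _check_kt(t, k) * k
    return _invert_g_newton(_g_d4, _d4_gprime, kt, 1.0 / 3.0, _RHO_TABLE, _D4_TABLE_G)


@dataclass(frozen=True)
class KineticModel:
    """One solid-state kinetic law with closed ρ(t) and integral g(ρ) forms.

    ``rho_of_t(t, k, n)`` evaluates ρ; ``g_of_rho(rho)`` evaluates g, with
    g(ρ(t)) = k·tⁿ for the Avrami law and k·t for all others.
    """

    id: str
    name: str
    mechanism: str
    n_params: int
    rho_of_t: Callable = field(repr=False)
    g_of_rho: Callable = field(repr=False)

    def g_complete(self) -> float:
        """g at full conversion (time to completion is g_complete/k)."""
        return float(self.g_of_rho(1.0))


MODELS: dict[str, KineticModel] = {
    m.id: m
    for m in [
        KineticModel("avrami", "Avrami A(n)", "nucleation and growth", 2,
                     _rho_avrami, _g_avrami),
        KineticModel("f1", "F1 first-order", "random nucleation", 1,
                     _rho_f1, _g_avrami),
        KineticModel("r2", "R2 contracting area", "phase-boundary, 2-D", 1,
                     _rho_r2, _g_r2),
        KineticModel("r3", "R3 contracting volume", "phase-boundary, 3-D", 1,
                     _rho_r3, _g_r3),
        KineticModel("d1", "D1 one-dimensional diffusion", "diffusion, 1-D", 1,
                     _rho_d1, _g_d1),
        KineticModel("d2", "D2 Valensi", "diffusion, 2-D", 1,
                     _rho_d2, _g_d2),
        KineticModel("d3", "D3 Jander", "diffusion, 3-D", 1,
                     _rho_d3, _g_d3),
        KineticModel("d4", "D4 Ginstling-Brounshtein", "diffusion, 3-D", 1,
                     _rho_d4, _g_d4),
    ]
}


def get_model(model: str | KineticModel) -> KineticModel:
    if isinstance(model, KineticModel):
        return model
    try:
        return MODELS[model.lower()]
    except KeyError:
        raise DomainError(
            f"unknown kinetic model {model!r}; known: {sorted(MODELS)}"
        ) from None


def register_model(model: KineticModel) -> None:
    """Add a model to the catalog (extensibility hook)."""
    MODELS[model.id] = model


def model_rho(model: str | KineticModel, k: float, t, n: float | None = None):
    """Evaluate ρ(t; k[, n]) for a catalog model."""
    return get_model(model).rho_of_t(np.asarray(t, dtype=float), k, n)


def model_g(model: str | KineticModel, rho):
    """Evaluate the integral form g(ρ) for a catalog model."""
    return get_model(model).g_of_rho(np.asarray(rho, dtype=float))


def avrami_k_to_scaled(k: float, n: float) -> float:
    """Convert Avrami k (min⁻ⁿ, f = 1−exp(−k·tⁿ)) to the (k′·t)ⁿ convention."""
    return k ** (1.0 / n)


def sharp_hancock(times, rho) -> tuple[float, float]:
    """Sharp–Hancock linearization: slope n and intercept-derived k.

    Regresses ln(−ln(1−ρ)) on ln t over points with 0 < ρ < 1 and t > 0;
    returns (n, k) of the Avrami law.
    """
    times = np.asarray(times, dtype=float)
    rho = np.asarray(rho, dtype=float)
    mask = (rho > 0) & (rho < 1) & (times > 0)
    if mask.sum() < 2:
        raise FitError("Sharp-Hancock needs >= 2 points with 0 < rho < 1")
    x = np.log(times[mask])
    y = np.log(-np.log1p(-rho[mask]))
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(np.exp(intercept))


@dataclass
class KineticFit:
    """Result of fitting one kinetic model to a transformation curve."""

    model_id: str
    k: float
    k_stderr: float | None
    n: float | None
    n_stderr: float | None
    r_squared: float
    aicc: float
    residuals: np.ndarray = field(repr=False)
    converged: bool = True
    n_points: int = 0
    rho_window: tuple[float, float] = (0.05, 0.95)

    @property
    def half_time(self) -> float:
        """Model-implied time to half transformation."""
        g_half = model_g(self.model_id, 0.5)
        if self.model_id == "avrami":
            return float((g_half / self.k) ** (1.0 / self.n))
        return float(g_half / self.k)


def _aicc(rss: float, n_pts: int, n_params: int) -> float:
    # K counts the noise variance alongside the model parameters
    K = n_params + 1
    if n_pts < K + 2:
        return float("inf")
    rss = max(rss, 1e-300)
    aic = n_pts * np.log(rss / n_pts) + 2 * K
    return float(aic + 2 * K * (K + 1) / (n_pts - K - 1))


def fit_kinetics(
    curve: TransformationCurve,
    model: str | KineticModel = "avrami",
    rho_window: tuple[float, float] = (0.05, 0.95),
) -> KineticFit:
    """Fit one kinetic model to ρ(t) by nonlinear least squares.

    Points with ρ outside ``rho_window`` are excluded (baseline and
    saturation regions carry no mechanistic information); at least 6
    points must remain. Standard errors are asymptotic, from the local
    curvature of the least-squares objective. Non-convergence is flagged
    on the returned fit, not raised.
    """
    model = get_model(model)
    t = np.asarray(curve.times, dtype=float)
    rho = np.asarray(curve.rho, dtype=float)
    mask = (rho >= rho_window[0]) & (rho <= rho_window[1])
    if mask.sum() < 6:
        raise DegenerateDataError(
            f"only {int(mask.sum())} points with rho in {list(rho_window)}; need >= 6"
        )
    t_fit = t[mask]
    rho_fit = rho[mask]

    if model.id == "avrami":
        try:
            n0, k0 = sharp_hancock(t_fit, rho_fit)
            n0 = float(np.clip(n0, 0.2, 6.0))
            k0 = float(np.clip(k0, 1e-30, 1e30))
        except FitError:
            n0, k0 = 1.0, np.log(2.0) / np.median(t_fit)
        x0 = np.array([np.log(k0), np.log(n0)])

        def resid(x):
            return model.rho_of_t(t_fit, np.exp(x[0]), np.exp(x[1])) - rho_fit

    else:
        # anchor k to the observed half-transformation time
        g_half = float(model.g_of_rho(0.5))
        i_half = int(np.argmin(np.abs(rho_fit - 0.5)))
        k0 = g_half / max(t_fit[i_half], 1e-12)
        x0 = np.array([np.log(k0)])

        def resid(x):
            return model.rho_of_t(t_fit, np.exp(x[0]), None) - rho_fit

    sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                        max_nfev=2000)
    converged = bool(sol.success)
    params = np.exp(sol.x)
    residuals = sol.fun
    rss = float(residuals @ residuals)
    ss_tot = float(np.sum((rho_fit - rho_fit.mean()) ** 2))
    r_squared = 1.0 - rss / ss_tot if ss_tot > 0 else float("nan")

    # asymptotic covariance in log-parameter space, then delta method
    stderr = [None] * len(params)
    dof = t_fit.size - len(params)
    if dof > 0:
        try:
            JTJ = sol.jac.T @ sol.jac
            cov = np.linalg.inv(JTJ) * (rss / dof)
            log_err = np.sqrt(np.clip(np.diag(cov), 0, None))
            stderr = list(params * log_err)  # sigma_p = p * sigma_log(p)
        except np.linalg.LinAlgError:
            pass

    if model.id == "avrami":
        k, n = params
        k_err, n_err = stderr
    else:
        k, n = params[0], None
        k_err, n_err = stderr[0], None

    return KineticFit(
        model_id=model.id,
        k=float(k),
        k_stderr=k_err,
        n=float(n) if n is not None else None,
        n_stderr=n_err,
        r_squared=r_squared,
        aicc=_aicc(rss, t_fit.size, model.n_params),
        residuals=residuals,
        converged=converged,
        n_points=int(t_fit.size),
        rho_window=tuple(rho_window),
    )


def select_model(
    curve: TransformationCurve,
    catalog: Sequence[str | KineticModel] | None = None,
    rho_window: tuple[float, float] = (0.05, 0.95),
) -> list[KineticFit]:
    """Fit every catalog model and rank by AICc (ascending).

    Ties break deterministically: fewer parameters first, then model id.
    Per-model failures are skipped silently only if every other model fits;
    an empty result raises.
    """
    if catalog is None:
        catalog = list(MODELS)
    if not catalog:
        raise FitError("model catalog is empty")
    fits = []
    for m in catalog:
        model = get_model(m)
        try:
            fits.append(fit_kinetics(curve, model, rho_window=rho_window))
        except (DegenerateDataError, FitError):
            continue
    if not fits:
        raise FitError("no catalog model could be fitted to the curve")
    fits.sort(key=lambda f: (f.aicc, get_model(f.model_id).n_params, f.model_id))
    return fits
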