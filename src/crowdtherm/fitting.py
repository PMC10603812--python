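"""Fitting the crowding model to reduced folding data.

ε is the single free parameter of the ΔΔG⁰(c) fit — ν and χ are fixed by
binary-solution measurements. With ε in hand, ε_TS is the sole parameter
of the enthalpy–entropy fit: ε_s = −ε_TS and ε_h = ε − ε_s, so ε(T₀) is
preserved exactly. Uncertainties come from seeded residual-resampling
bootstrap (the percentile interval defaults to 68%, mirroring ±1σ bars).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import T_REF
from .crowding import delta_delta_g, model_enthalpy_entropy
from .params import CosoluteParams, ProteinCrowdingParams

__all__ = [
    "FitResult",
    "SoftInteractionRegression",
    "SoftEntropyRegression",
    "fit_epsilon",
    "fit_epsilon_ts",
    "bootstrap_ci",
]

EPS_BOUNDS = (-10.0, 10.0)


@dataclass
class FitResult:
    """Point estimate with a bootstrap percentile interval."""

    name: str
    estimate: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    ci_level: float = np.nan
    rss: float = np.nan
    n_points: int = 0
    bootstrap_b: int = 0
    bootstrap_seed: int | None = None
    converged: bool = True
    notes: dict = field(default_factory=dict)


def _minimize_eps(objective, bounds=EPS_BOUNDS, n_grid: int = 41) -> tuple[float, float, bool]:
    """Global-then-local scalar least squares over the bound interval.

    A coarse deterministic grid scan locates the basin (the objective need
    not be unimodal over the full interval for strongly attractive ε), then
    bounded minimization refines within the bracketing grid cell.
    """
    lo, hi = bounds
    for n in (n_grid, 21):  # two grid-refinement stages before Brent
        xs = np.linspace(lo, hi, n)
        vals = np.array([objective(x) for x in xs])
        i = int(np.argmin(vals))
        lo = xs[max(i - 1, 0)]
        hi = xs[min(i + 1, n - 1)]
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    est = float(res.x)
    at_bound = min(est - bounds[0], bounds[1] - est) < 1e-6
    if at_bound:
        warnings.warn("estimate at the bound of the search interval; not converged")
    return est, float(res.fun), not at_bound


def _check_unimodal(objective, bounds=EPS_BOUNDS, n: int = 41) -> bool:
    """Diagnostic: a single gradient sign change over the bound interval."""
    xs = np.linspace(bounds[0], bounds[1], n)
    vals = np.array([objective(x) for x in xs])
    grad_sign = np.sign(np.diff(vals))
    changes = np.count_nonzero(np.diff(grad_sign[grad_sign != 0]) != 0)
    return changes <= 1


class SoftInteractionRegression(RegressorMixin, BaseEstimator):
    """Fit the soft contact parameter ε from ΔΔG⁰ versus molality.

    One-dimensional bounded least squares: ν and χ enter through the fixed
    cosolute record; ε shifts the surface composition and the ε term.

    Attributes: ``epsilon_`` (estimate), ``rss_``, ``converged_``,
    ``result_`` (a :class:`FitResult` once ``bootstrap`` has run).
    """

    def __init__(self, cosolute: CosoluteParams = None,
                 protein: ProteinCrowdingParams = None,
                 temperature: float = T_REF, check_convexity: bool = True):
        self.cosolute = cosolute
        self.protein = protein
        self.temperature = temperature
        self.check_convexity = check_convexity

    def _model(self, c, eps: float) -> np.ndarray:
        prot = self.protein.model_copy(update={
            "epsilon": eps, "split_set": False, "eps_h": 0.0, "eps_s": 0.0,
        })
        return np.array([
            delta_delta_g(ci, self.temperature, self.cosolute, prot).total for ci in c
        ])

    def fit(self, c_molal, ddg0_kj):
        c = np.asarray(c_molal, dtype=float)
        y = np.asarray(ddg0_kj, dtype=float)
        if c.size < 3:
            raise ValueError("need ΔΔG⁰ at >= 3 concentrations")

        def objective(eps):
            r = y - self._model(c, eps)
            return float(r @ r)

        self.epsilon_, self.rss_, self.converged_ = _minimize_eps(objective)
        if self.check_convexity and not _check_unimodal(objective):
            warnings.warn("objective not unimodal in ε over the search interval")
        self._c, self._y = c, y
        self.residuals_ = y - self._model(c, self.epsilon_)
        return self

    def predict(self, c_molal):
        return self._model(np.asarray(c_molal, dtype=float), self.epsilon_)

    def bootstrap(self, b: int = 1000, seed: int = 0, level: float = 0.68) -> FitResult:
        yhat = self._model(self._c, self.epsilon_)

        def refit(y_star):
            def obj(eps):
                r = y_star - self._model(self._c, eps)
                return float(r @ r)
            return _minimize_eps(obj)[0]

        low, high = bootstrap_ci(refit, yhat, self.residuals_, b=b, seed=seed, level=level)
        self.result_ = FitResult(
            name="epsilon", estimate=self.epsilon_, ci_low=low, ci_high=high,
            ci_level=level, rss=self.rss_, n_points=self._c.size,
            bootstrap_b=b, bootstrap_seed=seed, converged=self.converged_,
            notes={"method": "residual-resampling bootstrap percentile"},
        )
        return self.result_


class SoftEntropyRegression(RegressorMixin, BaseEstimator):
    """Fit ε_TS from (ΔΔH⁰, TΔΔS⁰) points with ε fixed.

    The model side comes from the crowding model's Gibbs–Helmholtz route.
    ΔΔH⁰ and TΔΔS⁰ points are weighted equally; they are anticorrelated
    about the ΔΔG⁰ constraint, so any relative weighting only rescales the
    objective.
    """

    def __init__(self, cosolute: CosoluteParams = None,
                 protein: ProteinCrowdingParams = None,
                 epsilon: float = 0.0, t_ref: float = T_REF, dt: float = 0.5):
        self.cosolute = cosolute
        self.protein = protein
        self.epsilon = epsilon
        self.t_ref = t_ref
        self.dt = dt

    def _protein_with(self, eps_ts: float) -> ProteinCrowdingParams:
        eps_s = -eps_ts
        eps_h = self.epsilon - eps_s
        return self.protein.model_copy(update={
            "epsilon": self.epsilon, "eps_h": eps_h, "eps_s": eps_s,
            "split_set": True,
        })

    def _model(self, c, eps_ts: float) -> np.ndarray:
        prot = self._protein_with(eps_ts)
        out = np.empty((len(c), 2))
        for i, ci in enumerate(c):
            out[i] = model_enthalpy_entropy(ci, self.t_ref, self.cosolute, prot,
                                            dt=self.dt)
        return out

    def fit(self, c_molal, ddh0_kj, t_dds0_kj):
        c = np.asarray(c_molal, dtype=float)
        obs = np.column_stack([np.asarray(ddh0_kj, float), np.asarray(t_dds0_kj, float)])
        if c.size < 2:
            raise ValueError("need enthalpy/entropy points at >= 2 concentrations")

        def objective(eps_ts):
            r = (obs - self._model(c, eps_ts)).ravel()
            return float(r @ r)

        self.eps_ts_, self.rss_, self.converged_ = _minimize_eps(objective)
        prot = self._protein_with(self.eps_ts_)
        self.eps_h_, self.eps_s_ = prot.eps_h, prot.eps_s
        self._c, self._obs = c, obs
        self.residuals_ = (obs - self._model(c, self.eps_ts_)).ravel()
        return self

    def predict(self, c_molal):
        return self._model(np.asarray(c_molal, dtype=float), self.eps_ts_)

    def bootstrap(self, b: int = 1000, seed: int = 0, level: float = 0.68) -> FitResult:
        yhat = self._model(self._c, self.eps_ts_).ravel()

        def refit(y_star):
            obs = y_star.reshape(-1, 2)

            def obj(eps_ts):
                r = (obs - self._model(self._c, eps_ts)).ravel()
                return float(r @ r)
            return _minimize_eps(obj)[0]

        low, high = bootstrap_ci(refit, yhat, self.residuals_, b=b, seed=seed, level=level)
        self.result_ = FitResult(
            name="epsilon_ts", estimate=self.eps_ts_, ci_low=low, ci_high=high,
            ci_level=level, rss=self.rss_, n_points=self._c.size,
            bootstrap_b=b, bootstrap_seed=seed, converged=self.converged_,
            notes={"method": "residual-resampling bootstrap percentile",
                   "epsilon_fixed": self.epsilon},
        )
        return self.result_


def bootstrap_ci(refit, yhat, residuals, b: int = 1000, seed: int = 0,
                 level: float = 0.68) -> tuple[float, float]:
    """Residual-resampling bootstrap percentile interval.

    ``refit`` maps a resampled response vector to a scalar estimate; the
    interval is the central ``level`` percentile range over ``b`` resamples.
    Deterministic under a fixed seed.
    """
    if b < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    resid = np.asarray(residuals, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if np.allclose(resid, resid[0]):
        warnings.warn("degenerate residuals: zero-width bootstrap interval")
    rng = np.random.default_rng(seed)
    centered = resid - resid.mean()
    estimates = np.empty(b)
    for i in range(b):
        y_star = yhat + rng.choice(centered, size=resid.size, replace=True)
        estimates[i] = refit(y_star)
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(estimates, alpha)),
            float(np.quantile(estimates, 1.0 - alpha)))


def fit_epsilon(c_molal, ddg0_kj, cosolute: CosoluteParams, dsasa: float,
                temperature: float = T_REF, bootstrap_b: int = 0,
                seed: int = 0, level: float = 0.68) -> FitResult:
    """Fit ε from a ΔΔG⁰(c) table (thin wrapper over the estimator)."""
    protein = ProteinCrowdingParams(name="fit", dsasa=dsasa)
    est = SoftInteractionRegression(cosolute=cosolute, protein=protein,
                                    temperature=temperature)
    est.fit(c_molal, ddg0_kj)
    if bootstrap_b:
        return est.bootstrap(b=bootstrap_b, seed=seed, level=level)
    return FitResult(name="epsilon", estimate=est.epsilon_, rss=est.rss_,
                     n_points=len(np.atleast_1d(c_molal)), converged=est.converged_)


def fit_epsilon_ts(c_molal, ddh0_kj, t_dds0_kj, epsilon: float,
                   cosolute: CosoluteParams, dsasa: float,
                   t_ref: float = T_REF, dt: float = 0.5, bootstrap_b: int = 0,
                   seed: int = 0, level: float = 0.68) -> FitResult:
    """Fit ε_TS with ε fixed (thin wrapper over the estimator).

    ``dt`` is the Gibbs–Helmholtz finite-difference step of the model
    predictions; match it to the step used when deriving the observed
    ΔΔH⁰/TΔΔS⁰ from a surface.
    """
    protein = ProteinCrowdingParams(name="fit", dsasa=dsasa)
    est = SoftEntropyRegression(cosolute=cosolute, protein=protein,
                                epsilon=epsilon, t_ref=t_ref, dt=dt)
    est.fit(c_molal, ddh0_kj, t_dds0_kj)
    if bootstrap_b:
        return est.bootstrap(b=bootstrap_b, seed=seed, level=level)
    return FitResult(name="epsilon_ts", estimate=est.eps_ts_, rss=est.rss_,
                     n_points=len(np.atleast_1d(c_molal)), converged=est.converged_)
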