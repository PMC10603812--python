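"""Binary cosolute–water solutions: composition, activity, osmotic pressure.

The solution is described on a Flory–Huggins lattice in which one site holds
one water molecule and a cosolute occupies ν contiguous sites. The water
activity follows from the solvent chemical potential of the FH mixing free
energy:

    ln a_S = ln(1 − ϕ_C) + (1 − 1/ν)·ϕ_C + χ·ϕ_C²

and the osmotic pressure is Π = −(RT/V̄_S)·ln a_S.

Partial molar volumes are fitted from density series, χ from activity
series, and the van't Hoff split χ(T) = a + b/T from per-temperature χ
estimates. All three fits are sklearn-style estimators; `fit_*` module
functions are thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import CM3_PER_MOL_TO_M3, M_WATER, R, T_REF, VBAR_WATER
from .params import CosoluteParams

__all__ = [
    "DensitySeries",
    "ActivitySeries",
    "BulkComposition",
    "molality_to_composition",
    "water_activity_fh",
    "osmotic_pressure",
    "PartialMolarVolumeRegression",
    "ChiRegression",
    "ChiTemperatureRegression",
    "fit_partial_molar_volume",
    "fit_chi",
    "fit_chi_temperature",
]


@dataclass
class DensitySeries:
    """Densities of a binary cosolute–water mixture at one temperature."""

    cosolute: str
    temperature: float  # K
    molality: np.ndarray  # mol / kg water, strictly increasing, contains 0
    density: np.ndarray  # g / cm^3
    m_c: float = 0.0  # cosolute molar mass, g/mol
    m_s: float = M_WATER

    def __post_init__(self) -> None:
        self.molality = np.asarray(self.molality, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.molality.shape != self.density.shape:
            raise ValueError("molality and density must have equal length")
        if np.any(self.molality < 0):
            raise ValueError("negative molality")
        if np.any(np.diff(self.molality) <= 0):
            raise ValueError("molalities must be strictly increasing")
        if not np.isclose(self.molality[0], 0.0):
            raise ValueError("series must contain the m=0 (pure water) point")
        if np.any(self.density <= 0):
            raise ValueError("densities must be positive")


@dataclass
class ActivitySeries:
    """Water activities of a binary mixture at one temperature."""

    cosolute: str
    temperature: float  # K
    molality: np.ndarray
    activity: np.ndarray  # water activity a_S in (0, 1]
    sigma: np.ndarray | None = None  # optional per-point standard errors

    def __post_init__(self) -> None:
        self.molality = np.asarray(self.molality, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.molality.shape != self.activity.shape:
            raise ValueError("molality and activity must have equal length")
        if np.any((self.activity <= 0) | (self.activity > 1)):
            raise ValueError("water activity must lie in (0, 1]")


@dataclass
class BulkComposition:
    """Composition bookkeeping for one bulk state."""

    molality: float  # mol / kg water
    molarity: float  # mol / L solution
    phi_c: float  # cosolute volume fraction
    phi_s: float = field(init=False)

    def __post_init__(self) -> None:
        self.phi_s = 1.0 - self.phi_c


def molality_to_composition(molality: float, params: CosoluteParams) -> BulkComposition:
    """Convert molality to molarity and volume fractions via partial molar volumes."""
    if molality < 0:
        raise ValueError("molality must be >= 0")
    n_s = 1000.0 / params.m_s  # mol water per kg water
    volume_cm3 = n_s * params.vbar_s + molality * params.vbar_c  # per kg water
    phi_c = molality * params.vbar_c / volume_cm3
    molarity = molality / (volume_cm3 / 1000.0)  # mol / L
    return BulkComposition(molality=molality, molarity=molarity, phi_c=phi_c)


def molarity_to_molality(molarity: float, params: CosoluteParams) -> float:
    """Invert the molality→molarity map (constant partial molar volumes)."""
    if molarity < 0:
        raise ValueError("molarity must be >= 0")
    a = (1000.0 / params.m_s) * params.vbar_s  # cm^3 water per kg water
    denom = 1000.0 - molarity * params.vbar_c
    if denom <= 0:
        raise ValueError("molarity exceeds the close-packing limit")
    return molarity * a / denom


def water_activity_fh(phi_c, nu: float, chi: float):
    """FH water activity: ln a_S = ln(1−ϕ_C) + (1 − 1/ν)ϕ_C + χϕ_C²."""
    phi_c = np.asarray(phi_c, dtype=float)
    if np.any((phi_c < 0) | (phi_c >= 1)):
        raise ValueError("phi_c must lie in [0, 1)")
    ln_a = np.log1p(-phi_c) + (1.0 - 1.0 / nu) * phi_c + chi * phi_c**2
    out = np.exp(ln_a)
    return float(out) if out.ndim == 0 else out


def osmotic_pressure(
    phi_c,
    params: CosoluteParams,
    temperature: float = T_REF,
    chi: float | None = None,
) -> float | np.ndarray:
    """Osmotic pressure Π = −(RT/V̄_S)·ln a_S, in Pa.

    ``chi`` overrides the record's χ(T) when given (e.g. scanning χ).
    """
    if chi is None:
        chi = params.chi(temperature)
    a_s = water_activity_fh(phi_c, params.nu, chi)
    vbar_s_m3 = params.vbar_s * CM3_PER_MOL_TO_M3
    return -(R * temperature / vbar_s_m3) * np.log(a_s)


class PartialMolarVolumeRegression(RegressorMixin, BaseEstimator):
    """Fit V̄_C and V̄_S from a binary-solution density series.

    Per kg of water the solution volume is V(m) = (1000/M_S)·V̄_S + m·V̄_C
    with V(m) = (1000 + m·M_C)/ρ(m); an ordinary least-squares line in m
    yields intercept (1000/M_S)·V̄_S and slope V̄_C.

    Attributes
    ----------
    vbar_c_, vbar_s_ : fitted partial molar volumes, cm^3/mol
    vbar_c_se_, vbar_s_se_ : standard errors
    nu_ : fitted V̄_C / V̄_S
    """

    def __init__(self, m_c: float = 0.0, m_s: float = M_WATER):
        self.m_c = m_c
        self.m_s = m_s

    def fit(self, molality, density, m_c: float | None = None):
        m = np.asarray(molality, dtype=float)
        rho = np.asarray(density, dtype=float)
        if m.size < 3:
            raise ValueError("need at least 3 density points")
        mc = self.m_c if m_c is None else m_c
        volume = (1000.0 + m * mc) / rho  # cm^3 per kg water
        if np.any(np.diff(volume[np.argsort(m)]) < -1e-6 * volume.mean()):
            warnings.warn("solution volume decreases with molality beyond noise")
        design = np.column_stack([np.ones_like(m), m])
        coef, res, *_ = np.linalg.lstsq(design, volume, rcond=None)
        intercept, slope = coef
        n_s = 1000.0 / self.m_s
        dof = max(m.size - 2, 1)
        resid = volume - design @ coef
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(design.T @ design)
        self.vbar_s_ = intercept / n_s
        self.vbar_c_ = slope
        self.vbar_s_se_ = np.sqrt(cov[0, 0]) / n_s
        self.vbar_c_se_ = np.sqrt(cov[1, 1])
        self.nu_ = self.vbar_c_ / self.vbar_s_
        return self

    def predict(self, molality):
        """Predicted densities at the fitted volumes."""
        m = np.asarray(molality, dtype=float)
        volume = (1000.0 / self.m_s) * self.vbar_s_ + m * self.vbar_c_
        return (1000.0 + m * self.m_c) / volume


class ChiRegression(RegressorMixin, BaseEstimator):
    """Fit the FH χ at one temperature from a water-activity series.

    With ν fixed from densities, χ enters ln a_S linearly, so the estimate
    is the (optionally inverse-variance weighted) least-squares slope of
    the residual ln a_S − [ln(1−ϕ) + (1−1/ν)ϕ] against ϕ².
    """

    def __init__(self, nu: float = 1.0):
        self.nu = nu

    def fit(self, phi_c, activity, sigma=None):
        phi = np.asarray(phi_c, dtype=float)
        a_s = np.asarray(activity, dtype=float)
        if phi.size < 3:
            raise ValueError("need at least 3 activity points")
        resid = np.log(a_s) - (np.log1p(-phi) + (1.0 - 1.0 / self.nu) * phi)
        x = phi**2
        if sigma is not None:
            w = 1.0 / np.asarray(sigma, dtype=float) ** 2
        else:
            w = np.ones_like(x)
        sxx = float(np.sum(w * x * x))
        if sxx == 0:
            raise ValueError("all points at phi_c = 0; chi unidentifiable")
        self.chi_ = float(np.sum(w * x * resid)) / sxx
        dof = max(phi.size - 1, 1)
        s2 = float(np.sum(w * (resid - self.chi_ * x) ** 2)) / dof
        self.chi_se_ = np.sqrt(s2 / sxx)
        if abs(self.chi_) > 10:
            warnings.warn(f"fitted chi = {self.chi_:.3g} is suspiciously large")
        return self

    def predict(self, phi_c):
        return water_activity_fh(phi_c, self.nu, self.chi_)


class ChiTemperatureRegression(RegressorMixin, BaseEstimator):
    """van't Hoff split of χ(T) = a + b/T from per-temperature estimates.

    χ_H(T) = b/T is the enthalpic part, χ_TS(T) = −a the entropic part,
    so χ = χ_H − χ_TS identically.
    """

    def __init__(self, t_ref: float = T_REF):
        self.t_ref = t_ref

    def fit(self, temperature, chi, sigma=None):
        t = np.asarray(temperature, dtype=float)
        chi = np.asarray(chi, dtype=float)
        if np.unique(t).size < 3:
            raise ValueError("need chi estimates at >= 3 distinct temperatures")
        design = np.column_stack([np.ones_like(t), 1.0 / t])
        if sigma is not None:
            w = 1.0 / np.asarray(sigma, dtype=float)
            design_w = design * w[:, None]
            chi_w = chi * w
        else:
            design_w, chi_w = design, chi
        coef, *_ = np.linalg.lstsq(design_w, chi_w, rcond=None)
        resid = chi_w - design_w @ coef
        dof = max(t.size - 2, 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(design_w.T @ design_w)
        self.a_, self.b_ = float(coef[0]), float(coef[1])
        self.a_se_, self.b_se_ = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
        self.chi_h_ = self.b_ / self.t_ref
        self.chi_ts_ = -self.a_
        return self

    def predict(self, temperature):
        t = np.asarray(temperature, dtype=float)
        return self.a_ + self.b_ / t


def fit_partial_molar_volume(series: DensitySeries) -> PartialMolarVolumeRegression:
    """Fit (V̄_C, V̄_S) from a density series."""
    return PartialMolarVolumeRegression(m_c=series.m_c, m_s=series.m_s).fit(
        series.molality, series.density
    )


def fit_chi(series: ActivitySeries, nu: float, vbar_c: float, vbar_s: float = VBAR_WATER,
            m_s: float = M_WATER) -> ChiRegression:
    """Fit χ at the series temperature, converting molality to ϕ_C internally."""
    params = CosoluteParams(name=series.cosolute, m_c=1.0, vbar_c=vbar_c,
                            vbar_s=vbar_s, m_s=m_s)
    phi = np.array([molality_to_composition(m, params).phi_c for m in series.molality])
    return ChiRegression(nu=nu).fit(phi, series.activity, sigma=series.sigma)


def fit_chi_temperature(temperatures, chis, sigmas=None, t_ref: float = T_REF) -> ChiTemperatureRegression:
    return ChiTemperatureRegression(t_ref=t_ref).fit(temperatures, chis, sigma=sigmas)
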