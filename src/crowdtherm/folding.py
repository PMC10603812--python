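"""Two-state folding thermodynamics from CD-style measurements.

Fraction native from mean-residue-ellipticity baselines, folding free
energy from the two-state equilibrium, van't Hoff regression of ΔG⁰(T)
with an optional constant ΔC_P, and assembly of ΔΔ quantities relative to
the cosolute-free buffer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import R, T_REF

__all__ = [
    "SpectraSet",
    "fraction_native",
    "free_energy_from_fraction",
    "fraction_from_free_energy",
    "VantHoffRegression",
    "vant_hoff_fit",
    "assemble_deltas",
    "isodichroic_locate",
    "IsodichroicResult",
]


@dataclass
class SpectraSet:
    """MRE spectra on a common wavelength grid, one column per condition."""

    wavelength: np.ndarray  # nm
    mre: np.ndarray  # (n_wavelengths, n_conditions), deg cm^2 / dmol
    conditions: list | None = None  # e.g. list of (T, c) labels

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.mre = np.asarray(self.mre, dtype=float)
        if self.mre.shape[0] != self.wavelength.size:
            raise ValueError("mre rows must match wavelength grid")
        if not np.all(np.isfinite(self.mre)):
            raise ValueError("MRE values must be finite")


def fraction_native(mre, mre_n: float, mre_d: float, clip: float = 1e-6):
    """Two-state fraction native f_N = (MRE − MRE_D)/(MRE_N − MRE_D).

    Values outside [clip, 1−clip] are clipped with a warning; degenerate
    baselines are rejected.
    """
    if mre_n == mre_d:
        raise ValueError("degenerate baselines: MRE_N == MRE_D")
    f = (np.asarray(mre, dtype=float) - mre_d) / (mre_n - mre_d)
    if np.any((f < clip) | (f > 1 - clip)):
        warnings.warn("fraction native outside (0,1); clipping")
        f = np.clip(f, clip, 1 - clip)
    return float(f) if f.ndim == 0 else f


def free_energy_from_fraction(f_n, temperature: float):
    """ΔG⁰ = −RT·ln(f_N/(1−f_N)) in kJ/mol; f_N > 1/2 ⇒ ΔG⁰ < 0 (folding favored)."""
    f = np.asarray(f_n, dtype=float)
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("fraction native must lie strictly inside (0, 1)")
    out = -R * temperature * np.log(f / (1.0 - f)) / 1000.0
    return float(out) if out.ndim == 0 else out


def fraction_from_free_energy(dg0_kj, temperature: float):
    """Inverse of :func:`free_energy_from_fraction`."""
    k = np.exp(-np.asarray(dg0_kj, dtype=float) * 1000.0 / (R * temperature))
    out = k / (1.0 + k)
    return float(out) if out.ndim == 0 else out


class VantHoffRegression(RegressorMixin, BaseEstimator):
    """Integrated van't Hoff fit of ΔG⁰(T) with constant ΔC_P.

    ΔG⁰(T) = ΔH⁰ − T·ΔS⁰ + ΔC_P·[(T − T₀) − T·ln(T/T₀)], with ΔH⁰, ΔS⁰
    referenced to T₀. Linear least squares in (ΔH⁰, ΔS⁰[, ΔC_P]); the ΔC_P
    basis function and its first derivative vanish at T₀, so the fitted
    ΔH⁰ − T₀ΔS⁰ is the predicted ΔG⁰(T₀).

    Attributes (kJ/mol, J/(mol·K), J/(mol·K)): ``dh_``, ``ds_``, ``dcp_``,
    with covariance ``cov_`` in those units.
    """

    def __init__(self, t_ref: float = T_REF, fit_dcp: bool = False, dcp_fixed: float = 0.0):
        self.t_ref = t_ref
        self.fit_dcp = fit_dcp
        self.dcp_fixed = dcp_fixed

    @staticmethod
    def _dcp_basis(t: np.ndarray, t0: float) -> np.ndarray:
        return (t - t0) - t * np.log(t / t0)

    def fit(self, temperature, dg0_kj):
        t = np.asarray(temperature, dtype=float)
        g = np.asarray(dg0_kj, dtype=float) * 1000.0  # J/mol
        min_t = 4 if self.fit_dcp else 3
        if np.unique(t).size < min_t:
            raise ValueError(f"need >= {min_t} distinct temperatures for this fit")
        cols = [np.ones_like(t), -t]
        if self.fit_dcp:
            cols.append(self._dcp_basis(t, self.t_ref))
        else:
            g = g - self.dcp_fixed * self._dcp_basis(t, self.t_ref)
        design = np.column_stack(cols)
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise ValueError(
                "rank-deficient van't Hoff design: "
                + ("ΔC_P unidentifiable (temperatures too clustered)" if self.fit_dcp
                   else "ΔS⁰ unidentifiable (single temperature)")
            )
        coef, *_ = np.linalg.lstsq(design, g, rcond=None)
        resid = g - design @ coef
        dof = max(t.size - design.shape[1], 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(design.T @ design)
        self.dh_ = coef[0] / 1000.0  # kJ/mol
        self.ds_ = coef[1]  # J/(mol K)
        self.dcp_ = coef[2] if self.fit_dcp else self.dcp_fixed
        self.cov_ = cov
        self.resid_kj_ = resid / 1000.0
        return self

    def predict(self, temperature):
        t = np.asarray(temperature, dtype=float)
        g = self.dh_ * 1000.0 - t * self.ds_ + self.dcp_ * self._dcp_basis(t, self.t_ref)
        return g / 1000.0


def vant_hoff_fit(temperature, dg0_kj, t_ref: float = T_REF, fit_dcp: bool = False,
                  dcp_fixed: float = 0.0) -> VantHoffRegression:
    """Fit ΔG⁰(T); with ``fit_dcp`` False, ΔC_P is held at ``dcp_fixed``."""
    return VantHoffRegression(t_ref=t_ref, fit_dcp=fit_dcp, dcp_fixed=dcp_fixed).fit(
        temperature, dg0_kj
    )


def assemble_deltas(fits: dict) -> pd.DataFrame:
    """ΔΔ quantities per concentration relative to the c=0 buffer fit.

    ``fits`` maps molality -> fitted VantHoffRegression. Variances add on
    subtraction (independent fits).
    """
    if 0.0 not in fits and not any(np.isclose(list(fits), 0.0).tolist()):
        raise ValueError("buffer (c=0) condition is required")
    c0 = min(fits, key=lambda c: abs(c))
    base = fits[c0]
    rows = []
    for c in sorted(fits):
        f = fits[c]
        ddh = f.dh_ - base.dh_
        dds = f.ds_ - base.ds_
        ddg = (f.dh_ - base.dh_) - f.t_ref * (f.ds_ - base.ds_) / 1000.0
        var_dh = f.cov_[0, 0] + base.cov_[0, 0]  # J^2
        var_ds = f.cov_[1, 1] + base.cov_[1, 1]
        rows.append({
            "molality": c,
            "ddg0_kj": ddg,
            "ddh0_kj": ddh,
            "dds0_j_k": dds,
            "t_dds0_kj": f.t_ref * dds / 1000.0,
            "ddh0_se_kj": np.sqrt(var_dh) / 1000.0,
            "dds0_se_j_k": np.sqrt(var_ds),
        })
    return pd.DataFrame(rows)


def gibbs_helmholtz_deltas(folding_df: pd.DataFrame, t_ref: float = T_REF,
                           dt: float | None = None) -> pd.DataFrame:
    """ΔΔH⁰/TΔΔS⁰ per concentration by Gibbs–Helmholtz on a ΔG⁰(c, T) surface.

    For each molality, ΔΔH⁰(T₀) = ∂(ΔΔG⁰/T)/∂(1/T) by central difference
    between the grid temperatures nearest T₀ ± dt (default: one grid step).
    Suited to densely sampled surfaces; for sparse or noisy data prefer
    per-concentration :class:`VantHoffRegression` + :func:`assemble_deltas`.
    """
    temps = np.sort(folding_df["T_K"].unique())
    if t_ref not in temps:
        raise ValueError("reference temperature must be on the grid")
    if dt is None:
        dt = float(np.min(np.diff(temps)))
    t_lo, t_hi = t_ref - dt, t_ref + dt
    for t in (t_lo, t_hi):
        if not np.isclose(temps, t).any():
            raise ValueError(f"temperature {t} K not on the grid")
    pivot = folding_df.pivot_table(index="molality", columns="T_K",
                                   values="dG0_kJ_mol")
    ddg_surface = pivot.sub(pivot.loc[0.0])  # relative to buffer, per T
    rows = []
    for c in pivot.index:
        g0 = ddg_surface.loc[c, t_ref]
        g_hi = ddg_surface.loc[c, t_hi]
        g_lo = ddg_surface.loc[c, t_lo]
        ddh = (g_hi / t_hi - g_lo / t_lo) / (1.0 / t_hi - 1.0 / t_lo)
        rows.append({"molality": c, "ddg0_kj": g0, "ddh0_kj": ddh,
                     "t_dds0_kj": ddh - g0})
    return pd.DataFrame(rows)


@dataclass
class IsodichroicResult:
    wavelength: float
    spread: float
    found: bool
    degenerate: bool = field(default=False)


def isodichroic_locate(spectra: SpectraSet, threshold: float = 500.0) -> IsodichroicResult:
    """Locate the isodichroic point: wavelength of minimal across-spectra spread.

    Returns the grid wavelength minimizing the standard deviation of MRE
    across conditions. A monotone spread profile (minimum at a grid edge)
    yields ``found=False``; identical spectra yield the degenerate flag.
    ``threshold`` is the spread below which a crossing supports two-state
    behavior (same units as MRE).
    """
    if spectra.mre.shape[1] < 3:
        raise ValueError("need at least 3 spectra")
    spread = spectra.mre.std(axis=1)
    if np.allclose(spread, 0.0):
        return IsodichroicResult(float(spectra.wavelength[0]), 0.0, found=False,
                                 degenerate=True)
    # A genuine crossing is a *prominent* interior minimum of the spread:
    # regions where the spectra merely coincide (flat far wings) give shallow
    # minima that noise shuffles around, so select by prominence, not depth.
    peaks, props = find_peaks(-spread, prominence=0.0)
    if peaks.size == 0:
        return IsodichroicResult(float(spectra.wavelength[int(np.argmin(spread))]),
                                 float(spread.min()), found=False)
    i = int(peaks[np.argmax(props["prominences"])])
    return IsodichroicResult(
        wavelength=float(spectra.wavelength[i]),
        spread=float(spread[i]),
        found=bool(spread[i] < threshold),
    )
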