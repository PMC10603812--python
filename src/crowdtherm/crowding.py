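"""Mean-field two-domain crowding model for cosolute effects on folding.

The ternary protein–cosolute–water mixture is split into a bulk domain and
a protein-surface domain, each an FH lattice solution. Folding buries ΔSASA
of protein surface and thereby

* recovers the work Π·ΔV_ex of keeping a sterically cosolute-free depletion
  shell of thickness δ = (d_S/2)(ν^{1/3} − 1) around the unfolded surface
  (the excluded-volume term; equals the Asakura–Oosawa relation),
* releases the N_buried = ΔSASA/d_S² surface lattice sites whose cosolute
  content, set by exchange equilibrium with the bulk, mixes back into a
  differently concentrated bulk (the χ nonideal-mixing term, quadratic in
  the surface–bulk concentration difference),
* removes the soft protein–cosolute contacts, each worth ε in kT (the
  ε term).

The surface volume fraction ϕ_s solves the exchange-equilibrium condition
μ̂(ϕ_s) + ν·ε = μ̂(ϕ_b), where μ̂ is the FH exchange chemical potential of
moving one cosolute from a pure-solvent reservoir into solution (per
cosolute; a surface cosolute occupies ν contact sites and thus pays ν·ε).

Because ϕ_s depends on ε, only the ε term is explicitly soft; the χ term
inherits an implicit ε dependence through ϕ_s, while the depletion-shell
ν term here depends on the bulk state only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import A3_TO_M3_PER_MOL, R, T_REF
from .binary import molality_to_composition, osmotic_pressure
from .params import CosoluteParams, ProteinCrowdingParams

__all__ = [
    "SurfaceState",
    "FreeEnergyDecomposition",
    "exchange_potential",
    "surface_composition",
    "delta_delta_g",
    "aom_free_energy",
    "preferential_hydration_change",
    "model_enthalpy_entropy",
]


@dataclass
class SurfaceState:
    """Bulk/surface cosolute partitioning at exchange equilibrium."""

    phi_b: float  # bulk cosolute volume fraction
    phi_s: float  # surface-domain cosolute volume fraction
    mu_b: float  # bulk exchange potential, kT
    m_surf: float  # surface molarity, mol/L


@dataclass
class FreeEnergyDecomposition:
    """ΔΔG⁰(c, T) and its excluded-volume / mixing / soft parts, kJ/mol."""

    c_molal: float
    temperature: float
    dg_nu: float
    dg_chi: float
    dg_eps: float

    @property
    def total(self) -> float:
        return self.dg_nu + self.dg_chi + self.dg_eps

    def per_dsasa(self, dsasa: float) -> dict:
        """Terms normalized per buried area, J/(mol·Å²)."""
        f = 1000.0 / dsasa
        return {
            "dg_nu": self.dg_nu * f,
            "dg_chi": self.dg_chi * f,
            "dg_eps": self.dg_eps * f,
            "total": self.total * f,
        }


def exchange_potential(phi, nu: float, chi: float):
    """FH exchange chemical potential μ̂ of a cosolute, in kT.

    μ̂(ϕ) = ln ϕ − ν·ln(1−ϕ) + (1−ν) + χ·ν·((1−ϕ)² − ϕ²).
    Reduces to the Langmuir form ln(ϕ/(1−ϕ)) for ν=1, χ=0.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any((phi <= 0) | (phi >= 1)):
        raise ValueError("phi must lie strictly inside (0, 1)")
    phi_s = 1.0 - phi
    out = np.log(phi) - nu * np.log(phi_s) + (1.0 - nu) + chi * nu * (phi_s**2 - phi**2)
    return float(out) if out.ndim == 0 else out


def _march_down(f, start: float, shrink: float = 0.7):
    """Bracket the first sign change of ``f`` below ``start``; None if absent."""
    f_hi = f(start)
    hi, lo = start, start * shrink
    while lo > 1e-280:
        f_lo = f(lo)
        if f_lo == 0.0 or (f_lo > 0) != (f_hi > 0):
            return lo, hi
        hi, f_hi = lo, f_lo
        lo *= shrink
    return None


def _march_up(f, start: float, shrink: float = 0.7):
    """Bracket the first sign change of ``f`` above ``start``; None if absent."""
    f_lo = f(start)
    lo, hi = start, 1.0 - (1.0 - start) * shrink
    while 1.0 - hi > 1e-14:
        f_hi = f(hi)
        if f_hi == 0.0 or (f_hi > 0) != (f_lo > 0):
            return lo, hi
        lo, f_lo = hi, f_hi
        hi = 1.0 - (1.0 - hi) * shrink
    return None


def surface_composition(phi_b: float, nu: float, chi: float, eps: float) -> SurfaceState:
    """Solve the exchange-equilibrium condition for the surface domain.

    ϕ_s satisfies μ̂(ϕ_s) + ν·ε = μ̂(ϕ_b): a repulsive surface (ε > 0)
    depletes cosolute (ϕ_s < ϕ_b), an attractive one enriches it.
    ``eps`` is the per-contact ε; the ν·ε total is applied internally.
    """
    if not 0.0 < phi_b < 1.0:
        raise ValueError("phi_b must lie strictly inside (0, 1)")
    mu_b = exchange_potential(phi_b, nu, chi)
    if eps == 0.0:
        phi_s = phi_b
    else:
        target = mu_b - nu * eps

        def f(phi):
            return exchange_potential(phi, nu, chi) - target

        # March outward from ϕ_b and take the first sign change: this selects
        # the solution branch continuous with the bulk state even where μ̂ is
        # non-monotonic (χν large enough for a miscibility gap). The starting
        # direction follows the local slope of μ̂ so that ε → 0 is continuous;
        # if that branch ends before a crossing, fall back to the other side.
        slope = 1.0 / phi_b + nu / (1.0 - phi_b) - 2.0 * chi * nu
        primary_down = (eps > 0) == (slope > 0)
        bracket = (_march_down(f, phi_b) if primary_down else _march_up(f, phi_b))
        if bracket is None:
            bracket = (_march_up(f, phi_b) if primary_down else _march_down(f, phi_b))
        if bracket is None:
            raise ValueError("equilibrium condition has no solution "
                             f"(phi_b={phi_b}, nu={nu}, chi={chi}, eps={eps})")
        phi_s = brentq(f, *bracket, xtol=1e-300, rtol=1e-14, maxiter=200)
    return SurfaceState(phi_b=phi_b, phi_s=phi_s, mu_b=mu_b, m_surf=np.nan)


def _surface_state(c_molal: float, t: float, cosolute: CosoluteParams,
                   protein: ProteinCrowdingParams) -> SurfaceState:
    comp = molality_to_composition(c_molal, cosolute)
    state = surface_composition(comp.phi_c, cosolute.nu, cosolute.chi(t), protein.eps(t))
    # surface molarity from phi_s = m_surf * nu * V̄_S (volumes in L/mol)
    state.m_surf = state.phi_s / (cosolute.nu * cosolute.vbar_s * 1e-3)
    return state


def delta_delta_g(c_molal: float, temperature: float, cosolute: CosoluteParams,
                  protein: ProteinCrowdingParams) -> FreeEnergyDecomposition:
    """Model ΔΔG⁰(c, T) decomposed into ν, χ and ε terms (kJ/mol).

    ΔΔG_ν⁰ = −Π·ΔSASA·δ       (≤ 0: depletion stabilization)
    ΔΔG_χ⁰ = +N_b·RT·χ·(ϕ_s−ϕ_b)²  (≥ 0 for χ > 0: unfavorable re-mixing)
    ΔΔG_ε⁰ = −N_b·RT·ε·ϕ_s     (sign opposite to ε)
    """
    if c_molal < 0:
        raise ValueError("concentration must be >= 0")
    if c_molal == 0:
        return FreeEnergyDecomposition(c_molal, temperature, 0.0, 0.0, 0.0)
    t = temperature
    comp = molality_to_composition(c_molal, cosolute)
    chi = cosolute.chi(t)
    eps = protein.eps(t)
    nu = cosolute.nu
    pi = osmotic_pressure(comp.phi_c, cosolute, t)  # Pa
    delta = protein.depletion_thickness(nu)  # Å
    dg_nu = -pi * protein.dsasa * delta * A3_TO_M3_PER_MOL  # J/mol
    state = surface_composition(comp.phi_c, nu, chi, eps)
    n_b = protein.n_buried()
    dg_chi = n_b * R * t * chi * (state.phi_s - comp.phi_c) ** 2
    dg_eps = -n_b * R * t * eps * state.phi_s
    return FreeEnergyDecomposition(c_molal, t, dg_nu / 1000.0, dg_chi / 1000.0,
                                   dg_eps / 1000.0)


def aom_free_energy(c_molal: float, temperature: float, cosolute: CosoluteParams,
                    protein: ProteinCrowdingParams) -> float:
    """Asakura–Oosawa baseline ΔΔG⁰_AOM = Π·ΔV_ex (kJ/mol).

    ΔV_ex = −ΔSASA·δ (folding shrinks the cosolute-excluded volume); equals
    the model's ν term by construction and is reported as the
    excluded-volume-only literature baseline.
    """
    return delta_delta_g(c_molal, temperature, cosolute, protein).dg_nu


def preferential_hydration_change(
    protein: ProteinCrowdingParams,
    cosolute: CosoluteParams,
    pi_grid: np.ndarray,
    temperature: float = T_REF,
) -> np.ndarray:
    """ΔΓ_S(Π) = (1/V̄_S)·dΔΔG⁰/dΠ along an osmotic-pressure grid.

    Computed by central differences of the model ΔΔG⁰ against Π; a more
    negative ΔΓ_S means stronger cosolute stabilization of the native
    state (it is proportional to the m-value).
    """
    pi_grid = np.asarray(pi_grid, dtype=float)
    if np.any(pi_grid <= 0) or np.any(np.diff(pi_grid) <= 0):
        raise ValueError("pi grid must be positive and strictly increasing")
    c_grid = np.array([_molality_at_pressure(p, cosolute, temperature) for p in pi_grid])
    dg = np.array([
        delta_delta_g(c, temperature, cosolute, protein).total * 1000.0  # J/mol
        for c in c_grid
    ])
    slope = np.gradient(dg, pi_grid)  # J/mol/Pa = m^3/mol
    vbar_s_m3 = cosolute.vbar_s * 1e-6
    return slope / vbar_s_m3


def _molality_at_pressure(pi: float, cosolute: CosoluteParams, t: float) -> float:
    """Invert Π(c) by bracketed root finding."""
    def f(c):
        comp = molality_to_composition(c, cosolute)
        return osmotic_pressure(comp.phi_c, cosolute, t) - pi

    hi = 1e-3
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise ValueError("osmotic pressure out of invertible range")
    return brentq(f, 0.0, hi, rtol=1e-13)


def model_enthalpy_entropy(
    c_molal: float,
    temperature: float,
    cosolute: CosoluteParams,
    protein: ProteinCrowdingParams,
    dt: float = 0.5,
) -> tuple[float, float]:
    """(ΔΔH⁰, TΔΔS⁰) of the model at (c, T), kJ/mol, via Gibbs–Helmholtz.

    ΔΔH = ∂(ΔΔG/T)/∂(1/T) by central difference with step ``dt``;
    TΔΔS = ΔΔH − ΔΔG holds exactly by construction.
    """
    t = temperature
    g_hi = delta_delta_g(c_molal, t + dt, cosolute, protein).total
    g_lo = delta_delta_g(c_molal, t - dt, cosolute, protein).total
    inv_hi, inv_lo = 1.0 / (t + dt), 1.0 / (t - dt)
    ddh = (g_hi / (t + dt) - g_lo / (t - dt)) / (inv_hi - inv_lo)
    ddg = delta_delta_g(c_molal, t, cosolute, protein).total
    return ddh, ddh - ddg
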