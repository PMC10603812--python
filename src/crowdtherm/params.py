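"""Parameter records for cosolutes and proteins.

A cosolute is characterized by its excluded-volume ratio ν = V̄_C/V̄_S and
the Flory–Huggins parameter χ(T) = a + b/T, split into an enthalpic part
χ_H(T) = b/T and an entropic part χ_TS(T) = −a, so that χ = χ_H − χ_TS.

A protein contributes the surface area buried upon folding (ΔSASA) and the
soft protein–cosolute contact parameter ε(T) = ε_h·T₀/T + ε_s in kT units,
split as ε_H(T₀) = ε_h, ε_TS(T₀) = −ε_s, so ε(T₀) = ε_H − ε_TS.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, model_validator

from .constants import M_WATER, T_REF, VBAR_WATER, site_length


class CosoluteParams(BaseModel):
    """One cosolute's size and mixing nonideality, from binary-solution data."""

    name: str
    m_c: float = Field(gt=0, description="cosolute molar mass, g/mol")
    vbar_c: float = Field(gt=0, description="cosolute partial molar volume, cm^3/mol")
    vbar_s: float = Field(default=VBAR_WATER, gt=0, description="solvent partial molar volume, cm^3/mol")
    m_s: float = Field(default=M_WATER, gt=0, description="solvent molar mass, g/mol")
    chi_a: float = Field(default=0.0, description="entropic χ coefficient (dimensionless)")
    chi_b: float = Field(default=0.0, description="enthalpic χ coefficient, K")

    @property
    def nu(self) -> float:
        """Excluded-volume ratio ν = V̄_C / V̄_S."""
        return self.vbar_c / self.vbar_s

    def chi(self, t: float) -> float:
        """χ(T) = a + b/T."""
        return self.chi_a + self.chi_b / t

    def chi_h(self, t: float) -> float:
        """Enthalpic part, χ_H(T) = b/T."""
        return self.chi_b / t

    def chi_ts(self, t: float) -> float:
        """Entropic part, χ_TS(T) = −a; χ = χ_H − χ_TS holds exactly."""
        return -self.chi_a


class ProteinCrowdingParams(BaseModel):
    """One protein's crowding-model parameters.

    ``dsasa`` is stored positive (area buried upon folding), so stabilizing
    free-energy contributions come out negative.
    """

    name: str
    dsasa: float = Field(gt=0, description="SASA buried upon folding, Å^2")
    epsilon: float = Field(default=0.0, description="soft contact parameter ε(T0), kT units")
    eps_h: float = Field(default=0.0, description="enthalpic ε coefficient")
    eps_s: float = Field(default=0.0, description="entropic ε coefficient")
    d_site: float = Field(default_factory=site_length, gt=0, description="lattice site length, Å")
    split_set: bool = Field(default=False, description="whether (eps_h, eps_s) were resolved")

    @model_validator(mode="after")
    def _check_split(self) -> "ProteinCrowdingParams":
        if self.split_set and abs((self.eps_h + self.eps_s) - self.epsilon) > 1e-9:
            raise ValueError("eps_h + eps_s must equal epsilon at the reference temperature")
        return self

    def eps(self, t: float, t_ref: float = T_REF) -> float:
        """ε(T) = ε_h·T₀/T + ε_s; falls back to the T-independent ε if no split set."""
        if not self.split_set:
            return self.epsilon
        return self.eps_h * t_ref / t + self.eps_s

    def eps_ts(self, t_ref: float = T_REF) -> float:
        """Entropic part ε_TS(T₀) = −ε_s."""
        return -self.eps_s

    def n_buried(self) -> float:
        """Number of solvent-sized lattice sites released upon folding."""
        return self.dsasa / self.d_site**2

    def depletion_thickness(self, nu: float) -> float:
        """Sterically cosolute-free shell thickness δ = (d_S/2)(ν^{1/3} − 1), Å."""
        return 0.5 * self.d_site * (nu ** (1.0 / 3.0) - 1.0)


def save_params(params: BaseModel, path: str | Path) -> None:
    Path(path).write_text(params.model_dump_json(indent=2))


def load_cosolute_params(path: str | Path) -> CosoluteParams:
    return CosoluteParams.model_validate(json.loads(Path(path).read_text()))


def load_protein_params(path: str | Path) -> ProteinCrowdingParams:
    return ProteinCrowdingParams.model_validate(json.loads(Path(path).read_text()))
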