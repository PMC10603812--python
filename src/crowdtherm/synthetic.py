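"""Synthetic study generator with known ground truth.

Emulates the full input set of a sugar/polyol protein-stabilization study:
binary-solution density and water-activity series generated from the same
FH closed forms the analysis inverts, a folding free-energy surface
ΔG⁰(c, T) built from a van't Hoff buffer baseline plus the crowding-model
ΔΔG⁰, optional two-state CD spectra constructed to share an isodichroic
point, and hydrogen-bond summary tables with a controlled perturbation
structure. Every table parses back through the package readers, and one
seed governs all tables through fixed per-table offsets, so bundles are
reproducible piecewise.

Defaults describe a trehalose-like disaccharide (ν ≈ 11.6, χ > 0 with
χ_H < 0 and χ_TS < 0) and a marginally stable 16-residue miniprotein
with a repulsive soft interaction (ε > 0, ε_H and ε_TS both positive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .binary import molality_to_composition, water_activity_fh
from .constants import M_WATER, T_REF, VBAR_WATER
from .crowding import delta_delta_g
from .folding import VantHoffRegression, fraction_from_free_energy
from .params import CosoluteParams, ProteinCrowdingParams

__all__ = [
    "GroundTruth",
    "SyntheticBundle",
    "gen_density_series",
    "gen_activity_series",
    "gen_folding_dataset",
    "gen_hbond_tables",
    "default_hbond_truth",
    "make_bundle",
    "basis_spectra",
]

# per-table seed offsets (documented contract; bundles reproduce piecewise)
SEED_DENSITY, SEED_ACTIVITY, SEED_FOLDING, SEED_SPECTRA, SEED_HBOND = 0, 1, 2, 3, 4


class GroundTruth(BaseModel):
    """All generating parameters of one synthetic study."""

    # cosolute (trehalose-like defaults)
    cosolute: str = "synthetic_disaccharide"
    m_c: float = Field(default=342.30, gt=0)  # g/mol
    vbar_c: float = Field(default=209.5, gt=0)  # cm^3/mol
    chi_a: float = 2.0  # entropic χ coefficient
    chi_b: float = -500.0  # enthalpic χ coefficient, K
    # protein (marginally stable miniprotein, repulsive soft interactions)
    protein: str = "synthetic_miniprotein"
    dsasa: float = Field(default=800.0, gt=0)  # Å^2
    epsilon: float = 0.3  # ε(T0), kT
    eps_ts: float = 1.0  # ε_TS(T0), kT
    # buffer folding baseline at T0 = 298 K
    dh0_buffer: float = -10.0  # kJ/mol
    ds0_buffer: float = -35.0  # J/(mol K)
    dcp_buffer: float = -100.0  # J/(mol K)
    t_ref: float = T_REF
    # spectra construction
    structure_class: str = "sheet"  # "helix" (two minima) or "sheet" (one)
    isodichroic_nm: float = 207.0
    # noise scales (std of additive Gaussian noise per observable)
    sigma_density: float = Field(default=5e-5, ge=0)  # g/cm^3
    sigma_activity: float = Field(default=1e-4, ge=0)
    sigma_dg: float = Field(default=0.1, ge=0)  # kJ/mol
    sigma_mre: float = Field(default=200.0, ge=0)  # deg cm^2/dmol
    seed: int = 0

    def cosolute_params(self) -> CosoluteParams:
        return CosoluteParams(name=self.cosolute, m_c=self.m_c, vbar_c=self.vbar_c,
                              vbar_s=VBAR_WATER, m_s=M_WATER,
                              chi_a=self.chi_a, chi_b=self.chi_b)

    def protein_params(self) -> ProteinCrowdingParams:
        eps_s = -self.eps_ts
        return ProteinCrowdingParams(name=self.protein, dsasa=self.dsasa,
                                     epsilon=self.epsilon,
                                     eps_h=self.epsilon - eps_s, eps_s=eps_s,
                                     split_set=True)

    @property
    def nu(self) -> float:
        return self.vbar_c / VBAR_WATER


def _rng(truth: GroundTruth, offset: int) -> np.random.Generator:
    return np.random.default_rng(truth.seed * 16 + offset)


def gen_density_series(truth: GroundTruth, molalities) -> pd.DataFrame:
    """Binary-solution densities from constant partial molar volumes.

    Per kg water: V(m) = (1000/M_S)·V̄_S + m·V̄_C, mass = 1000 + m·M_C,
    ρ = mass/V, plus additive Gaussian noise of scale ``sigma_density``.
    """
    m = np.asarray(molalities, dtype=float)
    if np.any(m < 0):
        raise ValueError("negative molality")
    volume = (1000.0 / M_WATER) * VBAR_WATER + m * truth.vbar_c
    rho = (1000.0 + m * truth.m_c) / volume
    rho = rho + _rng(truth, SEED_DENSITY).normal(0.0, truth.sigma_density, m.size)
    return pd.DataFrame({
        "cosolute": truth.cosolute, "T_K": truth.t_ref,
        "molality": m, "density_g_cm3": rho,
    })


def gen_activity_series(truth: GroundTruth, molalities, temperatures,
                        clip: bool = True) -> pd.DataFrame:
    """Water activities from the FH closed form with χ(T) = a + b/T.

    Noisy activities falling outside (0, 1] are clipped into range (and
    counted in the ``n_clipped`` attribute) when ``clip`` is set, else the
    offending draws are resampled.
    """
    t_arr = np.asarray(temperatures, dtype=float)
    if np.unique(t_arr).size < 3:
        raise ValueError("need >= 3 distinct temperatures for a van't Hoff split")
    params = truth.cosolute_params()
    rng = _rng(truth, SEED_ACTIVITY)
    rows = []
    n_clipped = 0
    for t in t_arr:
        chi = params.chi(t)
        for m in np.asarray(molalities, dtype=float):
            phi = molality_to_composition(m, params).phi_c
            a = water_activity_fh(phi, params.nu, chi)
            a_noisy = a + rng.normal(0.0, truth.sigma_activity)
            while not clip and not (0.0 < a_noisy <= 1.0):
                a_noisy = a + rng.normal(0.0, truth.sigma_activity)
            if clip and not (0.0 < a_noisy <= 1.0):
                n_clipped += 1
                a_noisy = min(max(a_noisy, 1e-12), 1.0)
            rows.append({"cosolute": truth.cosolute, "T_K": t, "molality": m,
                         "water_activity": a_noisy})
    out = pd.DataFrame(rows)
    out.attrs["n_clipped"] = n_clipped
    return out


def _baseline_dg(truth: GroundTruth, t: np.ndarray) -> np.ndarray:
    """Buffer ΔG⁰(T) in kJ/mol from the integrated van't Hoff form."""
    basis = VantHoffRegression._dcp_basis(np.asarray(t, float), truth.t_ref)
    return (truth.dh0_buffer * 1000.0 - np.asarray(t, float) * truth.ds0_buffer
            + truth.dcp_buffer * basis) / 1000.0


def gen_folding_dataset(truth: GroundTruth, molalities, temperatures,
                        with_spectra: bool = False,
                        wavelengths=None) -> pd.DataFrame | tuple:
    """ΔG⁰(c, T) surface: van't Hoff buffer baseline + crowding-model ΔΔG⁰.

    Gaussian noise of scale ``sigma_dg`` is added to ΔG⁰. With
    ``with_spectra``, two-state CD spectra f_N·MRE_N + (1−f_N)·MRE_D are
    built from synthetic basis curves crossing at ``truth.isodichroic_nm``
    and returned alongside, with MRE noise ``sigma_mre``.
    """
    cos = truth.cosolute_params()
    prot = truth.protein_params()
    rng = _rng(truth, SEED_FOLDING)
    t_arr = np.asarray(temperatures, dtype=float)
    m_arr = np.asarray(molalities, dtype=float)
    rows = []
    for m in m_arr:
        for t in t_arr:
            dg = float(_baseline_dg(truth, np.array([t]))[0])
            dg += delta_delta_g(m, t, cos, prot).total
            rows.append({"protein": truth.protein, "cosolute": truth.cosolute,
                         "molality": m, "T_K": t, "dG0_kJ_mol": dg})
    folding = pd.DataFrame(rows)
    folding["dG0_kJ_mol"] += rng.normal(0.0, truth.sigma_dg, len(folding))
    if not with_spectra:
        return folding
    if wavelengths is None:
        wavelengths = np.arange(190.0, 251.0, 1.0)
    wl = np.asarray(wavelengths, dtype=float)
    mre_n, mre_d = basis_spectra(wl, truth.structure_class, truth.isodichroic_nm)
    rng_s = _rng(truth, SEED_SPECTRA)
    spec_rows = []
    for row in rows:  # noiseless ΔG⁰ so spectra are exactly two-state
        f_n = fraction_from_free_energy(row["dG0_kJ_mol"], row["T_K"])
        mre = f_n * mre_n + (1.0 - f_n) * mre_d
        mre = mre + rng_s.normal(0.0, truth.sigma_mre, wl.size)
        for w, v in zip(wl, mre):
            spec_rows.append({"wavelength_nm": w, "T_K": row["T_K"],
                              "molality": row["molality"], "mre": v})
    return folding, pd.DataFrame(spec_rows)


def basis_spectra(wavelength, structure_class: str = "sheet",
                  isodichroic_nm: float = 207.0) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic native/denatured MRE basis curves crossing at one wavelength.

    Gaussian-mixture props shaped like the α-helix class (minima near 208
    and 222 nm) or the β-sheet class (single minimum near 215 nm), against
    a coil-like denatured curve shifted so both cross exactly at the
    configured isodichroic wavelength. Not a spectroscopic model.
    """
    wl = np.asarray(wavelength, dtype=float)

    def g(center, width, amp):
        return amp * np.exp(-0.5 * ((wl - center) / width) ** 2)

    if structure_class == "helix":
        mre_n = g(193, 5, 30000) + g(208, 6, -12000) + g(222, 7, -11000)
    elif structure_class == "sheet":
        mre_n = g(196, 5, 20000) + g(215, 8, -9000)
    else:
        raise ValueError("structure_class must be 'helix' or 'sheet'")
    # The denatured curve is the native one plus a windowed separation term
    # whose only zero is at the isodichroic wavelength, so interconverting
    # mixtures cross exactly once on the grid.
    sep = 2000.0 * (wl - isodichroic_nm) * np.exp(
        -0.5 * ((wl - isodichroic_nm) / 12.0) ** 2)
    mre_d = mre_n + sep
    return mre_n, mre_d


def default_hbond_truth(kind: str = "stabilized") -> pd.DataFrame:
    """A small H-bond truth table with a controlled perturbation structure.

    Protein–water bonds weaken upon sugar addition (ΔG̅ increases) and
    small protein–sugar terms appear; counts drop slightly. ``kind``
    selects which state is weakened more: "stabilized" weakens the
    denatured state more (ΔΔG_fold < 0), "destabilized" the native state.
    """
    if kind not in {"stabilized", "destabilized"}:
        raise ValueError("kind must be 'stabilized' or 'destabilized'")
    big, small = (0.5, 0.2) if kind == "stabilized" else (0.2, 0.5)
    rows = []
    for state, weaken in (("N", small), ("D", big)):
        base = [
            ("bb_water", "backbone", "water", 18.0, -6.0),
            ("sc_water", "side_chain", "water", 9.0, -5.0),
            ("bb_bb", "backbone", "backbone", 4.0, -8.0),
        ]
        for pair, dcls, acls, n, g in base:
            rows.append((state, "water", pair, dcls, acls, n, g))
        for pair, dcls, acls, n, g in base:
            dg = weaken if "water" in pair else 0.0
            dn = -0.7 if "water" in pair else 0.0
            rows.append((state, "sugar", pair, dcls, acls, n + dn, g + dg))
        rows.append((state, "sugar", "bb_sugarOH", "backbone", "sugar_hydroxyl",
                     1.2, -4.0))
        rows.append((state, "sugar", "sc_sugarO", "side_chain", "sugar_ether",
                     0.3, -2.0))
    return pd.DataFrame(rows, columns=["state", "condition", "pair_id",
                                       "donor_class", "acceptor_class",
                                       "n_mean", "gbar_kJ_mol"])


def gen_hbond_tables(truth_table: pd.DataFrame, protein: str = "synthetic_miniprotein",
                     sigma_n: float = 0.0, sigma_g: float = 0.0, seed: int = 0,
                     zero_fill: bool = True) -> pd.DataFrame:
    """Emit H-bond records for both states and conditions, with optional noise.

    ``truth_table`` must carry state/condition/pair_id/n_mean/gbar_kJ_mol.
    Pair sets may differ across conditions only when ``zero_fill`` is set
    (absent pairs then count as n=0 downstream, e.g. sugar partners in
    pure water).
    """
    req = {"state", "condition", "pair_id", "n_mean", "gbar_kJ_mol"}
    if not req <= set(truth_table.columns):
        raise ValueError(f"truth table needs columns {sorted(req)}")
    if not zero_fill:
        for state, grp in truth_table.groupby("state"):
            sets = [set(g["pair_id"]) for _, g in grp.groupby("condition")]
            if any(s != sets[0] for s in sets):
                raise ValueError(
                    f"pair sets differ across conditions for state {state}; "
                    "set zero_fill=True to accept"
                )
    out = truth_table.copy()
    out.insert(0, "protein", protein)
    rng = np.random.default_rng(seed * 16 + SEED_HBOND)
    out["n_mean"] = np.clip(out["n_mean"] + rng.normal(0.0, sigma_n, len(out)), 0, None)
    out["gbar_kJ_mol"] = out["gbar_kJ_mol"] + rng.normal(0.0, sigma_g, len(out))
    return out.reset_index(drop=True)


@dataclass
class SyntheticBundle:
    """All generated tables of one synthetic study plus provenance."""

    density: pd.DataFrame
    activity: pd.DataFrame
    folding: pd.DataFrame
    spectra: pd.DataFrame | None
    hbonds: pd.DataFrame
    truth: GroundTruth

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.density.to_csv(path / "density.csv", index=False)
        self.activity.to_csv(path / "activity.csv", index=False)
        self.folding.to_csv(path / "folding.csv", index=False)
        if self.spectra is not None:
            self.spectra.to_csv(path / "spectra.csv", index=False)
        self.hbonds.to_csv(path / "hbonds.csv", index=False)
        (path / "provenance.json").write_text(self.truth.model_dump_json(indent=2))

    @classmethod
    def from_dir(cls, path: str | Path) -> "SyntheticBundle":
        path = Path(path)
        spectra_path = path / "spectra.csv"
        return cls(
            density=pd.read_csv(path / "density.csv"),
            activity=pd.read_csv(path / "activity.csv"),
            folding=pd.read_csv(path / "folding.csv"),
            spectra=pd.read_csv(spectra_path) if spectra_path.exists() else None,
            hbonds=pd.read_csv(path / "hbonds.csv"),
            truth=GroundTruth.model_validate(
                json.loads((path / "provenance.json").read_text())),
        )


def make_bundle(truth: GroundTruth | None = None, molalities=None, temperatures=None,
                with_spectra: bool = True) -> SyntheticBundle:
    """Generate a complete study bundle under one seed.

    Default grids: 9 molalities 0–1.5 mol/kg and 9 temperatures 278–318 K,
    mirroring sugar-solubility and CD-accessible ranges.
    """
    truth = truth or GroundTruth()
    if molalities is None:
        molalities = np.linspace(0.0, 1.5, 9)
    if temperatures is None:
        temperatures = np.linspace(278.0, 318.0, 9)
    density = gen_density_series(truth, molalities)
    activity = gen_activity_series(truth, molalities, temperatures)
    if with_spectra:
        folding, spectra = gen_folding_dataset(truth, molalities, temperatures,
                                               with_spectra=True)
    else:
        folding, spectra = gen_folding_dataset(truth, molalities, temperatures), None
    hb = gen_hbond_tables(default_hbond_truth(), protein=truth.protein,
                          seed=truth.seed)
    return SyntheticBundle(density=density, activity=activity, folding=folding,
                           spectra=spectra, hbonds=hb, truth=truth)
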