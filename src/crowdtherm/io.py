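"""CSV readers/writers for the tabular interchange formats.

Schemas (long format, one row per observation):

* ``density.csv``  — cosolute, T_K, molality, density_g_cm3
* ``activity.csv`` — cosolute, T_K, molality, water_activity
* ``folding.csv``  — protein, cosolute, molality, T_K, dG0_kJ_mol or f_native
* ``spectra.csv``  — wavelength_nm, T_K, molality, mre
* ``hbonds.csv``   — protein, state, condition, pair_id, donor_class,
  acceptor_class, n_mean, gbar_kJ_mol
* ``md_energy.csv`` — protein, sugar, dde_el, dde_vdw, p_ddv, dde_tot
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .binary import ActivitySeries, DensitySeries
from .constants import M_WATER, R
from .folding import SpectraSet
from .hbonds import MDEnergySummary

__all__ = [
    "read_density", "read_activity", "read_folding", "read_spectra",
    "read_hbonds", "read_md_energy",
]


def _require(df: pd.DataFrame, cols: set, path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")


def read_density(path: str | Path, m_c: float = 0.0) -> dict[tuple[str, float], DensitySeries]:
    """Read density series, one per (cosolute, temperature)."""
    df = pd.read_csv(path)
    _require(df, {"cosolute", "T_K", "molality", "density_g_cm3"}, path)
    out = {}
    for (cos, t), grp in df.groupby(["cosolute", "T_K"]):
        grp = grp.sort_values("molality")
        out[(cos, float(t))] = DensitySeries(
            cosolute=cos, temperature=float(t),
            molality=grp["molality"].to_numpy(),
            density=grp["density_g_cm3"].to_numpy(),
            m_c=m_c, m_s=M_WATER,
        )
    return out


def read_activity(path: str | Path) -> dict[tuple[str, float], ActivitySeries]:
    """Read water-activity series, one per (cosolute, temperature)."""
    df = pd.read_csv(path)
    _require(df, {"cosolute", "T_K", "molality", "water_activity"}, path)
    out = {}
    for (cos, t), grp in df.groupby(["cosolute", "T_K"]):
        grp = grp.sort_values("molality")
        sig = grp["sigma"].to_numpy() if "sigma" in grp.columns else None
        out[(cos, float(t))] = ActivitySeries(
            cosolute=cos, temperature=float(t),
            molality=grp["molality"].to_numpy(),
            activity=grp["water_activity"].to_numpy(),
            sigma=sig,
        )
    return out


def read_folding(path: str | Path) -> pd.DataFrame:
    """Read folding measurements; derives dG0_kJ_mol from f_native if absent."""
    df = pd.read_csv(path)
    _require(df, {"protein", "cosolute", "molality", "T_K"}, path)
    if "dG0_kJ_mol" not in df.columns:
        if "f_native" not in df.columns:
            raise ValueError(f"{path}: need either dG0_kJ_mol or f_native")
        f = df["f_native"].to_numpy()
        df["dG0_kJ_mol"] = -R * df["T_K"].to_numpy() * np.log(f / (1 - f)) / 1000.0
    return df


def read_spectra(path: str | Path) -> SpectraSet:
    """Read long-format spectra into a wavelength × condition matrix."""
    df = pd.read_csv(path)
    _require(df, {"wavelength_nm", "T_K", "molality", "mre"}, path)
    pivot = df.pivot_table(index="wavelength_nm", columns=["T_K", "molality"],
                           values="mre")
    return SpectraSet(wavelength=pivot.index.to_numpy(),
                      mre=pivot.to_numpy(),
                      conditions=list(pivot.columns))


def read_hbonds(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, {"protein", "state", "condition", "pair_id", "n_mean",
                  "gbar_kJ_mol"}, path)
    return df


def read_md_energy(path: str | Path) -> list[MDEnergySummary]:
    df = pd.read_csv(path)
    _require(df, {"protein", "sugar", "dde_el", "dde_vdw"}, path)
    return [
        MDEnergySummary(protein=r.protein, sugar=r.sugar, dde_el=r.dde_el,
                        dde_vdw=r.dde_vdw,
                        p_ddv=getattr(r, "p_ddv", 0.0),
                        dde_tot=getattr(r, "dde_tot", float("nan")))
        for r in df.itertuples()
    ]
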