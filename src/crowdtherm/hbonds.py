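"""Hydrogen-bond network free-energy bookkeeping.

The network free energy of one protein state in one solvent condition is
the count-weighted sum over donor–acceptor pair classes, Σᵢ nᵢ·ΔG̅ᵢ. Sugar
addition perturbs it by ΔΔG_tot = Σ nᵢ'ΔG̅ᵢ' − Σ nᵢΔG̅ᵢ per state, and the
folding consequence is ΔΔG_fold = ΔΔG_tot^N − ΔΔG_tot^D: negative means
the sugar's H-bond perturbation favors folding. The perturbation splits
exactly into a strength part (count-weighted ΔG̅ changes) and a number
part (count changes weighted by perturbed ΔG̅), and rolls up by partner
class (water / sugar hydroxyl / sugar ether × backbone / side chain).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "DONOR_CLASSES",
    "ACCEPTOR_CLASSES",
    "NetworkDelta",
    "MDEnergySummary",
    "network_free_energy",
    "state_perturbation",
    "folding_perturbation",
    "strength_number_split",
    "partner_rollup",
    "nb_sum",
]

DONOR_CLASSES = frozenset({"backbone", "side_chain", "water", "sugar"})
ACCEPTOR_CLASSES = frozenset({"backbone", "side_chain", "water", "sugar_hydroxyl",
                              "sugar_ether"})

_REQUIRED = ["pair_id", "n_mean", "gbar_kJ_mol"]


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in records.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if records["pair_id"].duplicated().any():
        dups = records.loc[records["pair_id"].duplicated(), "pair_id"].tolist()
        raise ValueError(f"duplicate pair ids: {dups}")
    if (records["n_mean"] < 0).any():
        raise ValueError("mean bond counts must be >= 0")
    return records


def network_free_energy(records: pd.DataFrame, allow_empty: bool = False) -> float:
    """Total network free energy Σᵢ nᵢ·ΔG̅ᵢ (kJ/mol) for one state/condition."""
    if len(records) == 0:
        if allow_empty:
            return 0.0
        raise ValueError("no hydrogen-bond records")
    _validate(records)
    return float((records["n_mean"] * records["gbar_kJ_mol"]).sum())


def _aligned(water: pd.DataFrame, sugar: pd.DataFrame) -> pd.DataFrame:
    """Outer-join the two conditions on pair id, zero-filling absent pairs.

    Zero-filling is required: protein–sugar pairs do not exist in pure
    water. A pair absent from one condition contributes n=0 there; its ΔG̅
    is carried over from the condition where it exists (irrelevant at n=0
    but kept finite for the strength/number split).
    """
    w = _validate(water).set_index("pair_id")
    s = _validate(sugar).set_index("pair_id")
    idx = w.index.union(s.index)
    out = pd.DataFrame(index=idx)
    out["n_w"] = w["n_mean"].reindex(idx).fillna(0.0)
    out["n_s"] = s["n_mean"].reindex(idx).fillna(0.0)
    g_w = w["gbar_kJ_mol"].reindex(idx)
    g_s = s["gbar_kJ_mol"].reindex(idx)
    out["g_w"] = g_w.fillna(g_s)
    out["g_s"] = g_s.fillna(g_w)
    for col in ("donor_class", "acceptor_class"):
        if col in w.columns or col in s.columns:
            a = w[col] if col in w.columns else pd.Series(dtype=object)
            b = s[col] if col in s.columns else pd.Series(dtype=object)
            out[col] = a.reindex(idx).fillna(b.reindex(idx))
    return out


def state_perturbation(water: pd.DataFrame, sugar: pd.DataFrame) -> float:
    """ΔΔG_tot for one state upon sugar addition (kJ/mol).

    Positive values mean the state's H-bond network is destabilized by the
    sugar (e.g. weakened protein–water bonds).
    """
    a = _aligned(water, sugar)
    return float((a["n_s"] * a["g_s"] - a["n_w"] * a["g_w"]).sum())


def folding_perturbation(ddg_native: float, ddg_denatured: float) -> float:
    """ΔΔG_fold = ΔΔG_tot^N − ΔΔG_tot^D (kJ/mol).

    Negative: the denatured state is more destabilized, so the H-bond
    perturbation stabilizes folding; positive: destabilizes it.
    """
    return ddg_native - ddg_denatured


def strength_number_split(water: pd.DataFrame, sugar: pd.DataFrame) -> tuple[float, float]:
    """Exact split of the state perturbation into strength and number parts.

    strength = Σ nᵢ^w·(ΔG̅ᵢ^s − ΔG̅ᵢ^w);  number = Σ (nᵢ^s − nᵢ^w)·ΔG̅ᵢ^s.
    Their sum telescopes to :func:`state_perturbation` identically. The
    symmetric (Shapley) alternative averages this convention with its
    mirror image and is available via ``strength_number_split_symmetric``.
    """
    a = _aligned(water, sugar)
    strength = float((a["n_w"] * (a["g_s"] - a["g_w"])).sum())
    number = float(((a["n_s"] - a["n_w"]) * a["g_s"]).sum())
    return strength, number


def strength_number_split_symmetric(water: pd.DataFrame, sugar: pd.DataFrame) -> tuple[float, float]:
    """Shapley-symmetric variant: both factors evaluated at mean conditions."""
    a = _aligned(water, sugar)
    strength = float((0.5 * (a["n_w"] + a["n_s"]) * (a["g_s"] - a["g_w"])).sum())
    number = float(((a["n_s"] - a["n_w"]) * 0.5 * (a["g_w"] + a["g_s"])).sum())
    return strength, number


def partner_rollup(water: pd.DataFrame, sugar: pd.DataFrame,
                   by: tuple = ("donor_class", "acceptor_class")) -> pd.DataFrame:
    """State perturbation broken down by partner classes.

    Group contributions partition the total exactly; unknown class labels
    are rejected.
    """
    a = _aligned(water, sugar)
    for col, valid in (("donor_class", DONOR_CLASSES), ("acceptor_class", ACCEPTOR_CLASSES)):
        if col in by:
            if col not in a.columns:
                raise ValueError(f"records lack a {col} column")
            bad = set()
            for frame in (water, sugar):
                if col in frame.columns:
                    bad |= set(frame[col].dropna()) - valid
            if bad:
                raise ValueError(f"unknown {col} labels {sorted(bad)}; valid: {sorted(valid)}")
    a["contribution_kJ_mol"] = a["n_s"] * a["g_s"] - a["n_w"] * a["g_w"]
    out = a.groupby(list(by), dropna=False)["contribution_kJ_mol"].sum().reset_index()
    return out


@dataclass
class NetworkDelta:
    """Full bookkeeping for one protein/sugar pair."""

    ddg_native: float
    ddg_denatured: float
    ddg_fold: float = field(init=False)
    strength_native: float = 0.0
    number_native: float = 0.0
    strength_denatured: float = 0.0
    number_denatured: float = 0.0
    rollup_native: pd.DataFrame | None = None
    rollup_denatured: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.ddg_fold = folding_perturbation(self.ddg_native, self.ddg_denatured)


def network_delta(records: pd.DataFrame, water_label: str = "water",
                  sugar_label: str | None = None) -> NetworkDelta:
    """Run the whole bookkeeping on a long-format record table.

    ``records`` needs columns state (N/D), condition, pair_id, n_mean,
    gbar_kJ_mol and optionally the class labels.
    """
    conds = set(records["condition"].unique())
    if sugar_label is None:
        others = conds - {water_label}
        if len(others) != 1:
            raise ValueError(f"ambiguous sugar condition among {sorted(conds)}")
        sugar_label = others.pop()
    parts = {}
    for state in ("N", "D"):
        w = records.query("state == @state and condition == @water_label")
        s = records.query("state == @state and condition == @sugar_label")
        if len(w) == 0 or len(s) == 0:
            raise ValueError(f"missing records for state {state}")
        parts[state] = (w, s)
    ddg_n = state_perturbation(*parts["N"])
    ddg_d = state_perturbation(*parts["D"])
    str_n, num_n = strength_number_split(*parts["N"])
    str_d, num_d = strength_number_split(*parts["D"])
    has_classes = {"donor_class", "acceptor_class"} <= set(records.columns)
    return NetworkDelta(
        ddg_native=ddg_n, ddg_denatured=ddg_d,
        strength_native=str_n, number_native=num_n,
        strength_denatured=str_d, number_denatured=num_d,
        rollup_native=partner_rollup(*parts["N"]) if has_classes else None,
        rollup_denatured=partner_rollup(*parts["D"]) if has_classes else None,
    )


@dataclass
class MDEnergySummary:
    """Per protein/sugar nonbonded-energy summary from simulation (kJ/mol)."""

    protein: str
    sugar: str
    dde_el: float
    dde_vdw: float
    p_ddv: float = 0.0
    dde_tot: float = float("nan")

    @property
    def dde_nb(self) -> float:
        return nb_sum(self.dde_el, self.dde_vdw)


def nb_sum(dde_el: float, dde_vdw: float) -> float:
    """Nonbonded total ΔΔE_nb = ΔΔE_el + ΔΔE_vdW (kJ/mol)."""
    return dde_el + dde_vdw
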