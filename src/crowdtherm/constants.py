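"""Physical constants and solvent defaults (water at 25 °C)."""

R = 8.31446261815324  # gas constant, J / (mol K)
N_A = 6.02214076e23  # Avogadro, 1/mol

M_WATER = 18.015  # molar mass of water, g/mol
VBAR_WATER = 18.07  # partial molar volume of water, cm^3/mol
T_REF = 298.0  # reference temperature T0, K

# cm^3/mol -> m^3/mol
CM3_PER_MOL_TO_M3 = 1e-6
# A^3 (per molecule) -> m^3/mol
A3_TO_M3_PER_MOL = 1e-30 * N_A


def site_length(vbar_s: float = VBAR_WATER) -> float:
    """Lattice site edge length d_S in Å from the solvent molar volume.

    One site holds one solvent molecule: d_S = (V̄_S / N_A)^(1/3).
    """
    v_molec_cm3 = vbar_s / N_A
    return (v_molec_cm3 * 1e24) ** (1.0 / 3.0)  # cm^3 -> A^3
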