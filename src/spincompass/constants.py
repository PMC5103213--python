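"""Physical constants and unit conversions.

The Hamiltonian is stored in angular-frequency units (rad/s), which removes
hbar from the Liouvillian and keeps all reaction rate constants in s^-1.
"""

HBAR = 1.054571817e-34
"""Reduced Planck constant, J*s (CODATA 2018)."""

MU_B = 9.2740100783e-24
"""Bohr magneton, J/T (CODATA 2018)."""

G_ELECTRON_DEFAULT = 2.0
"""Isotropic electron g-value assumed identical for both radicals."""

MT_TO_TESLA = 1e-3


def gyromagnetic(g: float = G_ELECTRON_DEFAULT) -> float:
    """Electron gyromagnetic ratio g*mu_B/hbar in rad/(s*T).

    For g = 2 a field of 1 mT corresponds to ~1.7588e8 rad/s.
    """
    return g * MU_B / HBAR
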