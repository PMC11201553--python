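"""Physical constants and unit conversions.

Energies are carried in kcal/mol and coordinates in Å throughout the
package; optimizer convergence checks convert to atomic units (Hartree,
Bohr) at comparison time so thresholds can be stated exactly as the
quantum-chemistry convention prints them.
"""

from __future__ import annotations

#: 1 Hartree in kcal/mol (CODATA 2018)
HARTREE_TO_KCALMOL: float = 627.5094740631

#: 1 Bohr in Å (CODATA 2018)
BOHR_TO_ANGSTROM: float = 0.529177210903

#: Gas constant R in kcal/mol/K
GAS_CONSTANT_KCALMOL: float = 1.98720425864e-3

#: 1 Hartree/Bohr expressed in kcal/mol/Å
FORCE_AU_TO_KCALMOL_PER_A: float = HARTREE_TO_KCALMOL / BOHR_TO_ANGSTROM


def convert_force_au_to_kcalmol_per_A(f: float) -> float:
    """Convert a force from Hartree/Bohr to kcal/mol/Å."""
    return f * FORCE_AU_TO_KCALMOL_PER_A


def convert_force_kcalmol_per_A_to_au(f: float) -> float:
    """Convert a force from kcal/mol/Å to Hartree/Bohr."""
    return f / FORCE_AU_TO_KCALMOL_PER_A
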