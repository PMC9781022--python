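"""Unit conventions and conversion helpers.

The library works in reduced units: kT = 1, D0 = 1, lengths dimensionless.
The ``physical`` unit mode maps those onto the scales typical of a clay
interlayer at body temperature -- angstrom lengths, picosecond times and
kcal/mol energies at 310 K -- so that literature-style inputs (an energy
cutoff quoted in kcal/mol, an excluded region quoted in angstrom) can be
written verbatim in configuration files.  Conversion happens only at the
configuration boundary; every numerical routine sees reduced units.
"""

from __future__ import annotations

# Boltzmann constant in kcal/(mol K); kT at 310 K is then ~0.616 kcal/mol.
KB_KCAL_PER_MOL_K = 1.987204259e-3
PHYSIOLOGICAL_T_K = 310.0
KT_KCAL_PER_MOL_310K = KB_KCAL_PER_MOL_K * PHYSIOLOGICAL_T_K

#: reduced length unit expressed in angstrom under the ``physical`` mode
LENGTH_ANGSTROM = 1.0
#: reduced time unit expressed in picoseconds under the ``physical`` mode
TIME_PS = 1.0

UNIT_MODES = ("reduced", "physical")


def kcal_per_mol_to_kt(energy_kcal: float, temperature_k: float = PHYSIOLOGICAL_T_K) -> float:
    """Convert an energy in kcal/mol to multiples of kT at ``temperature_k``."""
    return energy_kcal / (KB_KCAL_PER_MOL_K * temperature_k)


def kt_to_kcal_per_mol(energy_kt: float, temperature_k: float = PHYSIOLOGICAL_T_K) -> float:
    """Convert an energy in kT units to kcal/mol at ``temperature_k``."""
    return energy_kt * KB_KCAL_PER_MOL_K * temperature_k


def angstrom_to_reduced(length_angstrom: float) -> float:
    return length_angstrom / LENGTH_ANGSTROM


def reduced_to_angstrom(length_reduced: float) -> float:
    return length_reduced * LENGTH_ANGSTROM


def ps_to_reduced(time_ps: float) -> float:
    return time_ps / TIME_PS


def reduced_to_ps(time_reduced: float) -> float:
    return time_reduced * TIME_PS
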