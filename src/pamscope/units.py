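"""Physical constants and unit conventions.

Internal units everywhere: length nm, time ps, energy kJ/mol, mass amu,
temperature K.  A convenient identity of this system: 1 amu nm^2/ps^2 is
exactly 1 kJ/mol, so sqrt(kT/lambda) with lambda in nm^2 amu is an angular
frequency in 1/ps.  Angstrom appears only at PDB and reporting boundaries,
kcal/mol only in reports.
"""

# CODATA 2018
KB = 0.008314462618  #: Boltzmann constant x Avogadro, kJ/(mol K)
R_GAS = 8.314462618  #: molar gas constant, J/(mol K)
HBAR = 0.0635077993  #: reduced Planck constant x Avogadro, kJ ps / mol
KCAL = 4.184  #: kJ per kcal

NM_PER_ANGSTROM = 0.1
ANGSTROM_PER_NM = 10.0


def kt_in_kj_per_mol(temperature: float) -> float:
    """k_B*T in kJ/mol at the given temperature in K."""
    return KB * temperature
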