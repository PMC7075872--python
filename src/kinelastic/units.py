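"""Physical constants, unit conversions and peptide-sequence utilities.

The internal unit system is GROMACS-style: kJ·mol⁻¹ (energy), nm (length),
ps (time), amu (mass).  In this system 1 kJ·mol⁻¹ = 1 amu·nm²·ps⁻², so the
equations of motion need no conversion factors.  Piconewtons and kBT are
presentation units converted at the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

# CODATA 2018 exact values
KB_J_PER_K = 1.380649e-23
AVOGADRO = 6.02214076e23

#: 1 kJ·mol⁻¹·nm⁻¹ expressed in pN (per molecule)
KJ_MOL_NM_TO_PN = 1e24 / AVOGADRO

#: Coulomb prefactor e²/(4πε₀) in kJ·mol⁻¹·nm·e⁻² (vacuum)
COULOMB_KJ_MOL_NM = 138.935458

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


def force_to_piconewton(force_kj_mol_nm: float) -> float:
    """Convert a molar force (kJ·mol⁻¹·nm⁻¹) to piconewtons per molecule.

    1300 kJ·mol⁻¹·nm⁻¹ — the strongest pulling force used in the linker
    study — comes out as ≈ 2159 pN.
    """
    return force_kj_mol_nm * KJ_MOL_NM_TO_PN


@dataclass(frozen=True)
class Thermo:
    """Thermal-energy bundle at a fixed temperature.

    Attributes
    ----------
    temperature : float
        Absolute temperature in kelvin.
    kBT_kJ_mol : float
        Thermal energy in kJ·mol⁻¹ (≈ 2.494 at 300 K).
    kBT_pN_nm : float
        Thermal energy in pN·nm (≈ 4.14 at 300 K).
    beta : float
        Inverse thermal energy in mol·kJ⁻¹, i.e. 1 / kBT_kJ_mol.
    """

    temperature: float
    kBT_kJ_mol: float
    kBT_pN_nm: float
    beta: float


def thermal_energy(temperature: float) -> Thermo:
    """Thermal energy kB·T in the package's unit systems.

    Raises
    ------
    ValueError
        If temperature is not strictly positive.
    """
    if not temperature > 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature!r}")
    kbt_kj_mol = KB_J_PER_K * AVOGADRO * temperature / 1000.0
    kbt_pn_nm = KB_J_PER_K * temperature * 1e21
    return Thermo(
        temperature=temperature,
        kBT_kJ_mol=kbt_kj_mol,
        kBT_pN_nm=kbt_pn_nm,
        beta=1.0 / kbt_kj_mol,
    )


@dataclass(frozen=True)
class PeptideSequence:
    """Validated one-letter amino-acid sequence of length ≥ 2."""

    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError("a peptide needs at least 2 residues")
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise ValueError(f"non-standard residue codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def __getitem__(self, i):
        return self.residues[i]

    def __str__(self) -> str:
        return self.residues


def substitute_residues(
    seq: PeptideSequence | str, target: str, replacement: str
) -> PeptideSequence:
    """Replace every occurrence of one residue type with another.

    This is how the alanine-scanning mutants are derived: e.g. the
    no-proline chain is ``substitute_residues(wild_type, "P", "A")``.
    Length and all other positions are unchanged.
    """
    for code, name in ((target, "target"), (replacement, "replacement")):
        if code not in STANDARD_AA:
            raise ValueError(f"{name} {code!r} is not a standard residue code")
    s = seq.residues if isinstance(seq, PeptideSequence) else str(seq)
    return PeptideSequence(s.replace(target, replacement))
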