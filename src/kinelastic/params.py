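"""Per-residue coarse-grained parameters (one bead per amino acid).

Masses are residue masses (amino acid minus water) in amu.  The attractive
Lennard-Jones well depth scales with Kyte–Doolittle hydropathy (hydrophobic
residues attract more strongly); polar side chains carry an extra
hydrogen-bond-like well depth; Lys/Arg are +1, Asp/Glu −1.  Proline beads
get a stiffer, kinked virtual-bond angle — the bead-level analog of the
ring-constrained backbone that makes proline a flexibility breaker — and
glycine a softer one.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ResidueParams:
    code: str
    mass: float  # amu
    friction: float  # ps^-1
    charge: int  # e
    lj_epsilon: float  # kJ/mol
    lj_sigma: float  # nm
    angle_k: float  # kJ/mol/rad^2
    angle_theta0: float  # rad
    hbond_epsilon: float  # kJ/mol


_KD = {  # Kyte–Doolittle hydropathy
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "E": -3.5, "Q": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

_MASS = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "E": 129.12, "Q": 128.13, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}

_CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}

_HBOND = {"N": 1.0, "Q": 1.0, "S": 0.4, "T": 0.4, "Y": 0.4, "H": 0.4, "W": 0.4}

_SIGMA = {"G": 0.45, "W": 0.55, "F": 0.55, "Y": 0.55}

DEFAULT_FRICTION = 5.0  # ps^-1
DEFAULT_ANGLE_K = 20.0  # kJ/mol/rad^2
DEFAULT_THETA0 = 2.0  # rad, ~115 deg Cα virtual angle
PRO_ANGLE_K = 60.0
PRO_THETA0 = 1.4  # kink-prone
GLY_ANGLE_K = 8.0


def _epsilon(code: str) -> float:
    # map hydropathy [-4.5, 4.5] onto [0.1, 0.9] kJ/mol
    return 0.1 + 0.8 * (_KD[code] + 4.5) / 9.0


def _build_table() -> dict[str, ResidueParams]:
    table = {}
    for code in _KD:
        angle_k, theta0 = DEFAULT_ANGLE_K, DEFAULT_THETA0
        if code == "P":
            angle_k, theta0 = PRO_ANGLE_K, PRO_THETA0
        elif code == "G":
            angle_k = GLY_ANGLE_K
        table[code] = ResidueParams(
            code=code,
            mass=_MASS[code],
            friction=DEFAULT_FRICTION,
            charge=_CHARGE.get(code, 0),
            lj_epsilon=_epsilon(code),
            lj_sigma=_SIGMA.get(code, 0.5),
            angle_k=angle_k,
            angle_theta0=theta0,
            hbond_epsilon=_HBOND.get(code, 0.0),
        )
    return table


RESIDUE_PARAMS: dict[str, ResidueParams] = _build_table()
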