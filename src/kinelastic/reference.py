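"""Published reference values used as inputs for recomputation checks.

``PUBLISHED_WORK_MOMENTS`` holds the published ensemble means and spreads
(in kBT) of the stretch and relax work distributions from all-atom
constant-force (1300 kJ·mol⁻¹·nm⁻¹, 300 K, 10⁴ runs) pulling simulations of
the kinesin neck linker, a polyalanine reference and three alanine-scanning
mutants, together with the published crossing-point ΔG.  They serve as
inputs to the crossing-point estimator: recomputing the crossing from the
printed moments reproduces the printed ΔG, which validates the estimator
independently of any simulation.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class WorkMoments:
    mu_stretch: float  # kBT
    sd_stretch: float
    mu_relax: float
    sd_relax: float
    delta_g: float  # published crossing point, kBT


PUBLISHED_WORK_MOMENTS: dict[str, WorkMoments] = {
    "neck_linker": WorkMoments(1569.9, 24.9, 1211.6, 68.2, 1462.4),
    "ala_only": WorkMoments(949.7, 23.9, 696.0, 81.5, 882.0),
    "no_asparagine": WorkMoments(733.7, 30.5, 651.0, 63.3, 690.5),
    "no_lysine": WorkMoments(985.6, 40.4, 388.0, 66.7, 752.8),
    "no_proline": WorkMoments(1056.8, 26.8, 888.0, 63.9, 997.6),
}

#: published per-mode average deformation energies (kJ/mol) of the kinesin
#: dimer elastic network: mode 16 and mode 17, around the 400 kJ/mol threshold
PUBLISHED_MODE_ENERGIES = {16: 393.03, 17: 416.98}

#: pulling force (kJ/mol/nm) used for the Table of work moments
REFERENCE_PULL_FORCE = 1300.0
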