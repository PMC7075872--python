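#!/usr/bin/env python
"""Opt-in elastic-network benchmark on the kinesin dimer structure (PDB 3kin).

The published domain analysis reports per-mode average deformation energies
of 393.03 kJ/mol (mode 16) and 416.98 kJ/mol (mode 17), with the fraction of
residues below the 400 kJ/mol threshold dropping under 90% once 17 modes are
included.  The decay length r0 of the pair force constant is not published,
so the benchmark sweeps r0 ∈ {0.3, 0.5, 0.7} nm.

This needs the 3kin structure, which is not bundled.  Supply it yourself:

    python scripts/enm_benchmark.py --pdb /path/to/3kin.pdb --out bench.json

(e.g. downloaded from https://files.rcsb.org/download/3KIN.pdb on a machine
with network access).
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from kinelastic import enm
from kinelastic.pipeline import run_mode_benchmark
from kinelastic.reference import PUBLISHED_MODE_ENERGIES


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--pdb", required=True, type=Path)
    ap.add_argument("--out", type=Path, default=Path("enm_benchmark.json"))
    ap.add_argument("--r0", type=float, nargs="+", default=[0.3, 0.5, 0.7])
    ap.add_argument("--threshold", type=float, default=400.0)
    ap.add_argument("--n-modes", type=int, default=20)
    args = ap.parse_args()

    structure = enm.read_ca_structure(args.pdb)
    print(f"{structure.N} C-alpha atoms, {len(structure.gaps)} missing residues")
    bench = run_mode_benchmark(
        structure, tuple(args.r0), threshold=args.threshold, n_modes=args.n_modes
    )
    out = {"n_atoms": structure.N, "published_mode_energies": PUBLISHED_MODE_ENERGIES}
    for r0, res in bench.items():
        e = res["avg_deformation_energy"]
        fr = res["cumulative_fraction_below_threshold"]
        out[f"r0_{r0}"] = {
            "mode16_avg_deformation_kJ_mol": e[15] if len(e) > 15 else None,
            "mode17_avg_deformation_kJ_mol": e[16] if len(e) > 16 else None,
            "n_selected_below_threshold": res["n_selected"],
            "fraction_below_threshold_17_modes": fr[16] if len(fr) > 16 else None,
            "avg_deformation_energy": e,
        }
        print(
            f"r0={r0} nm: mode16={e[15]:.2f}, mode17={e[16]:.2f} kJ/mol, "
            f"{res['n_selected']} modes below {args.threshold}, "
            f"fraction<thr at 17 modes: {fr[16]:.3f}"
        )
    args.out.write_text(json.dumps(out, indent=1))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
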