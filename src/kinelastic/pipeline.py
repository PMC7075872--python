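"""Study orchestration: domains → equilibrate → pull × relax → ΔG → stiffness.

A study runs the full factorial of sequences × pulling forces.  For each
sequence the chain is equilibrated once and a typical start conformation is
selected; for each force an ensemble of constant-force stretch runs and
paired force-off relax runs yields forward/reverse work distributions, ΔG
estimates, and finally a quadratic stiffness fit of ΔG versus fractional
extension across forces.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import elasticity, enm, work
from .simulate import (
    SimConfig,
    build_chain,
    equilibrate,
    run_relax_ensemble,
    run_stretch_ensemble,
    select_start_conformation,
)
from .units import PeptideSequence, substitute_residues

__all__ = [
    "StudyConfig",
    "StudyReport",
    "STANDIN_LINKER_SEQUENCE",
    "default_study_sequences",
    "run_domains",
    "run_pull_study",
    "make_fixtures",
]

log = logging.getLogger("kinelastic")

SCHEMA_VERSION = 1

#: Synthetic stand-in for the 19-residue kinesin-2 neck-linker segment (the
#: real sequence is not published here).  It honors the documented positional
#: constraints: Ile at position 4, Pro at positions 8 and 14, and at least
#: one Asn and one Lys.
STANDIN_LINKER_SEQUENCE = "ATSINVKPEANGSPTKNLE"

#: 18-residue polyalanine reference chain
ALA_ONLY_SEQUENCE = "A" * 18


def default_study_sequences(wild_type: str = STANDIN_LINKER_SEQUENCE) -> dict[str, str]:
    """Wild-type linker, polyalanine reference, and the three Ala-scans."""
    wt = PeptideSequence(wild_type)
    return {
        "neck_linker": str(wt),
        "ala_only": ALA_ONLY_SEQUENCE,
        "no_asparagine": str(substitute_residues(wt, "N", "A")),
        "no_lysine": str(substitute_residues(wt, "K", "A")),
        "no_proline": str(substitute_residues(wt, "P", "A")),
    }


@dataclass
class EnmConfig:
    C: float = enm.DEFAULT_C
    r0: float = enm.DEFAULT_R0
    cube_side: float = 1.2
    threshold: float = 400.0
    coarseness: float = 10.0
    n_modes: int = 20


@dataclass
class StudyConfig:
    sequences: dict[str, str] = field(default_factory=default_study_sequences)
    forces: list[float] = field(default_factory=lambda: [130.0, 400.0, 700.0, 1000.0, 1300.0])
    sim: SimConfig = field(default_factory=SimConfig)
    enm: EnmConfig = field(default_factory=EnmConfig)
    structure_path: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.forces:
            raise ValueError("forces must be non-empty")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("sequence names must be unique")
        for name, seq in self.sequences.items():
            PeptideSequence(seq)  # validates

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        version = raw.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {version}")
        known = {"sequences", "forces", "sim", "enm", "structure_path", "output_dir"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        if "sim" in raw:
            sim_raw = raw.pop("sim")
            sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
            bad = set(sim_raw) - sim_fields
            if bad:
                raise ValueError(f"unknown sim keys: {sorted(bad)}")
            kwargs["sim"] = SimConfig(**sim_raw)
        if "enm" in raw:
            enm_raw = raw.pop("enm")
            enm_fields = {f.name for f in dataclasses.fields(EnmConfig)}
            bad = set(enm_raw) - enm_fields
            if bad:
                raise ValueError(f"unknown enm keys: {sorted(bad)}")
            kwargs["enm"] = EnmConfig(**enm_raw)
        kwargs.update(raw)
        return cls(**kwargs)

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "sequences": self.sequences,
                "forces": self.forces,
                "sim": dataclasses.asdict(self.sim),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """One row per (sequence, force) plus per-sequence stiffness fits."""

    rows: list[dict]
    stiffness: dict[str, elasticity.StiffnessFit]
    failures: list[dict]
    provenance: dict

    def to_tsv(self, path: str | os.PathLike) -> None:
        cols = [
            "sequence", "force_kJ_mol_nm", "n_ensemble",
            "mean_W_stretch_kBT", "mean_W_relax_kBT",
            "delta_g_crossing_kBT", "delta_g_jarzynski_kBT",
            "ci_low_kBT", "ci_high_kBT", "fractional_extension", "cell_seed",
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in self.rows:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def _cell_seed(base_seed: int, *indices: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), *map(int, indices)])
    return int(ss.generate_state(1)[0] % 2**31)


def run_pull_study(config: StudyConfig, progress: bool = False) -> StudyReport:
    """Run the full sequences × forces pulling study.

    Cells that fail (e.g. numeric blow-up) are recorded and skipped; the
    study continues.  With an ``output_dir`` each completed cell is cached
    as JSON keyed by a content hash, making reruns resumable.
    """
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    failures: list[dict] = []
    stiffness: dict[str, elasticity.StiffnessFit] = {}
    chash = config.content_hash()

    for si, (name, seq) in enumerate(config.sequences.items()):
        chain = build_chain(seq)
        eq_cfg = dataclasses.replace(
            config.sim, base_seed=_cell_seed(config.sim.base_seed, si, 999)
        )
        eq = equilibrate(chain, eq_cfg)
        relaxed = select_start_conformation(eq)
        traj = eq.trajectories[0]
        tail = traj.end_to_end[len(traj.end_to_end) - max(1, len(traj.end_to_end) // 5):]
        relaxed_mean = float(tail.mean())
        log.info("equilibrated %s: relaxed mean e2e %.3f nm", name, relaxed_mean)

        seq_points: list[tuple[float, float]] = []
        for fi, force in enumerate(config.forces):
            cell_seed = _cell_seed(config.sim.base_seed, si, fi)
            cell_key = f"{name}_F{force:g}_{chash}_{cell_seed}"
            cache = out / f"cell_{cell_key}.json" if out else None
            if cache is not None and cache.exists():
                row = json.loads(cache.read_text())
                rows.append(row)
                seq_points.append((row["fractional_extension"], row["delta_g_crossing_kBT"]))
                continue
            cfg = dataclasses.replace(config.sim, pull_force=float(force), base_seed=cell_seed)
            try:
                stretch = run_stretch_ensemble(relaxed, chain, cfg)
                relax = run_relax_ensemble(stretch)
                wf = work.work_ensemble(stretch)
                wr = work.work_ensemble(relax)
                est = work.estimate_free_energy(wf, wr, seed=cell_seed)
                mean_final = float(np.mean([t.end_to_end[-1] for t in stretch.trajectories]))
                frac = elasticity.fractional_extension(
                    mean_final, relaxed_mean, chain.n_beads
                ).value
            except Exception as exc:  # cell-level containment
                log.warning("cell %s failed: %s", cell_key, exc)
                failures.append({"sequence": name, "force": force, "error": str(exc)})
                continue
            row = {
                "sequence": name,
                "force_kJ_mol_nm": force,
                "n_ensemble": cfg.n_ensemble,
                "mean_W_stretch_kBT": float(wf.samples.mean()),
                "mean_W_relax_kBT": float(wr.samples.mean()),
                "delta_g_crossing_kBT": est.delta_g_crossing,
                "delta_g_jarzynski_kBT": est.delta_g_jarzynski,
                "ci_low_kBT": est.ci_low,
                "ci_high_kBT": est.ci_high,
                "fractional_extension": frac,
                "cell_seed": cell_seed,
            }
            rows.append(row)
            seq_points.append((frac, est.delta_g_crossing))
            if cache is not None:
                cache.write_text(json.dumps(row, indent=1))
            log.info(
                "cell %s F=%g: dG_cross=%.1f kBT, f=%.3f",
                name, force, est.delta_g_crossing, frac,
            )
        if len(seq_points) >= 3:
            stiffness[name] = elasticity.fit_quadratic_stiffness(seq_points)

    report = StudyReport(
        rows=rows,
        stiffness=stiffness,
        failures=failures,
        provenance={
            "base_seed": config.sim.base_seed,
            "config_hash": chash,
            "n_ensemble": config.sim.n_ensemble,
            "forces": config.forces,
        },
    )
    if out:
        report.to_tsv(out / "study_report.tsv")
        stiff_rows = {
            name: {
                "quadratic_coef_kBT": fit.quadratic_coef,
                "intercept_kBT": fit.intercept,
                "r_squared": fit.r_squared,
            }
            for name, fit in stiffness.items()
        }
        (out / "stiffness.json").write_text(json.dumps(stiff_rows, indent=1))
    return report


def run_domains(config: StudyConfig, out_dir: str | os.PathLike | None = None):
    """Elastic-network domain analysis of the configured structure.

    Writes per-residue deformation energies, cumulative below-threshold
    fractions per mode count, domain labels (TSV + labelled PDB).
    """
    if not config.structure_path:
        raise ValueError("structure_path is not set; supply a PDB file")
    out = Path(out_dir or config.output_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    e = config.enm
    structure = enm.read_ca_structure(config.structure_path)
    network = enm.build_network(structure, C=e.C, r0=e.r0)
    n_modes = min(e.n_modes, 3 * structure.N - 6)
    modes = enm.compute_modes(network, structure, n_modes)
    selected, fractions = enm.mode_selection_report(modes, e.threshold)
    with open(out / "mode_report.tsv", "w") as fh:
        fh.write("mode\tavg_deformation_kJ_mol\tcumulative_fraction_below_threshold\tselected\n")
        for k in range(n_modes):
            fh.write(
                f"{k + 1}\t{modes.avg_deformation_energy[k]:.4f}\t"
                f"{fractions[k]:.4f}\t{int(k in selected)}\n"
            )
    if selected:
        profile = enm.deformation_profile(modes, selected, threshold=e.threshold)
        enm.write_deformation_tsv(structure, profile, out / "deformation.tsv")
        decomp = enm.decompose_domains(
            structure, network, modes,
            threshold=e.threshold, cube_side=e.cube_side, coarseness_c=e.coarseness,
        )
        enm.write_domain_tsv(structure, decomp, out / "domains.tsv")
        enm.write_labels_pdb(structure, decomp.residue_labels, out / "domains_labeled.pdb")
        return decomp
    import warnings

    warnings.warn("no modes below threshold; domain outputs limited to mode report")
    return None


def run_mode_benchmark(
    structure: enm.CaStructure,
    r0_values: tuple[float, ...] = (0.3, 0.5, 0.7),
    threshold: float = 400.0,
    n_modes: int = 20,
    C: float = enm.DEFAULT_C,
) -> dict[float, dict]:
    """Per-mode average deformation energies swept over the decay length r0.

    r0 is the one elastic-network parameter without an established value, so
    the benchmark reports, for each candidate r0: the per-mode average
    deformation energies (ascending), the number of modes selected below the
    threshold, and the cumulative fraction of residues below the threshold
    for every mode-count prefix.
    """
    out: dict[float, dict] = {}
    for r0 in r0_values:
        network = enm.build_network(structure, C=C, r0=r0)
        modes = enm.compute_modes(network, structure, min(n_modes, 3 * structure.N - 6))
        selected, fractions = enm.mode_selection_report(modes, threshold)
        out[r0] = {
            "avg_deformation_energy": modes.avg_deformation_energy.tolist(),
            "n_selected": len(selected),
            "cumulative_fraction_below_threshold": fractions,
        }
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def toy_helix_pdb(n_res: int = 20) -> str:
    """Ideal α-helix Cα trace as PDB text (synthetic fixture)."""
    lines = []
    for i in range(n_res):
        t = 100.0 * np.pi / 180.0 * i
        x, y, z = 2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * i
        lines.append(
            f"ATOM  {i + 1:5d}  CA  ALA A{i + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_fixtures(seed: int = 0, out_dir: str | os.PathLike = "fixtures") -> dict[str, str]:
    """Write the synthetic test fixtures: toy PDB, sequences, canned work data.

    The canned forward/reverse work pair is drawn from N(10, 2²) / N(4, 2²)
    kBT, whose equal-variance crossing point is exactly 7 kBT; the published
    work-moments table is written for crossing-point recomputation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    pdb = out / "toy_helix_synthetic.pdb"
    pdb.write_text(toy_helix_pdb())
    paths["toy_pdb"] = str(pdb)

    seqs = out / "sequences.yaml"
    seqs.write_text(yaml.safe_dump(default_study_sequences(), sort_keys=False))
    paths["sequences"] = str(seqs)

    rng = np.random.default_rng(seed)
    wf = work.WorkEnsemble("stretch", rng.normal(10.0, 2.0, 2000), 300.0)
    wr = work.WorkEnsemble("relax", rng.normal(4.0, 2.0, 2000), 300.0)
    work.write_work_tsv(wf, out / "canned_forward.tsv", {"golden_delta_g_kBT": 7.0})
    work.write_work_tsv(wr, out / "canned_reverse.tsv", {"golden_delta_g_kBT": 7.0})
    paths["canned_forward"] = str(out / "canned_forward.tsv")
    paths["canned_reverse"] = str(out / "canned_reverse.tsv")

    from .reference import PUBLISHED_WORK_MOMENTS

    moments = out / "published_work_moments.tsv"
    with open(moments, "w") as fh:
        fh.write("peptide\tmu_stretch_kBT\tsd_stretch_kBT\tmu_relax_kBT\tsd_relax_kBT\tdelta_g_kBT\n")
        for name, m in PUBLISHED_WORK_MOMENTS.items():
            fh.write(
                f"{name}\t{m.mu_stretch}\t{m.sd_stretch}\t{m.mu_relax}\t{m.sd_relax}\t{m.delta_g}\n"
            )
    paths["published_moments"] = str(moments)
    return paths
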