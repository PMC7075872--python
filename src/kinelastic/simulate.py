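"""Coarse-grained overdamped Langevin bead-spring peptide simulator.

One bead per residue.  The potential is

    E = Σ_bonds [ ½ k_b (r−b0)² + k4 (r−b0)⁴ ]
      + Σ_angles ½ k_θ (θ−θ0)²
      + Σ_{|i−j|≥3} [ 4 ε_ij ((σ/r)¹² − (σ/r)⁶) + f_C q_i q_j e^{−r/λ_D}/(ε_r r) ],

with the quartic bond term providing finite extensibility under strong
pulling.  Dynamics are overdamped Langevin (implicit solvent): each bead
moves with mobility 1/(m γ) under the systematic force plus thermal noise,
integrated by the Leimkuhler–Matthews one-step scheme (noise averaged over
consecutive steps), which samples configurations far more accurately than
plain Euler–Maruyama at the same time step.

The protocol mirrors constant-force pulling experiments: equilibrate a
chain, pick a start frame with a typical end-to-end distance, launch an
ensemble of short constant-force stretch runs from it, then relax each
final state with the force off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import RESIDUE_PARAMS, ResidueParams
from .units import COULOMB_KJ_MOL_NM, PeptideSequence, thermal_energy

__all__ = [
    "ChainModel",
    "SimConfig",
    "Trajectory",
    "TrajectoryEnsemble",
    "Conformation",
    "build_chain",
    "initial_conformation",
    "cg_energy",
    "equilibrate",
    "select_start_conformation",
    "run_stretch_ensemble",
    "run_relax_ensemble",
    "langevin_1d",
]

_PHASE_CODE = {"equil": 0, "stretch": 1, "relax": 2}
_BLOWUP_NM = 1e3


@dataclass
class ChainModel:
    """Bead-spring model bound to a specific peptide sequence."""

    sequence: PeptideSequence
    beads: list[ResidueParams]
    bond_b0: float = 0.38  # nm, Cα-Cα virtual bond
    bond_k: float = 10000.0  # kJ/mol/nm^2
    bond_k4: float = 4.0e6  # kJ/mol/nm^4, finite extensibility
    debye_length: float = 1.0  # nm
    dielectric: float = 80.0

    @property
    def n_beads(self) -> int:
        return len(self.beads)


def build_chain(
    sequence: PeptideSequence | str,
    params_table: dict[str, ResidueParams] | None = None,
    **overrides,
) -> ChainModel:
    """Bind per-residue parameters to a sequence, position by position."""
    if not isinstance(sequence, PeptideSequence):
        sequence = PeptideSequence(sequence)
    table = params_table if params_table is not None else RESIDUE_PARAMS
    beads = []
    for code in sequence:
        if code not in table:
            raise KeyError(f"residue {code!r} missing from parameter table")
        beads.append(table[code])
    return ChainModel(sequence=sequence, beads=beads, **overrides)


@dataclass
class SimConfig:
    """Simulation protocol parameters.

    ``t_pull`` must be an integral number of time steps (default 1 ps at
    dt = 2e-3 ps → 500 steps, matching the pulling protocol).
    """

    temperature: float = 300.0  # K
    dt: float = 2e-3  # ps
    n_steps_equil: int = 200_000  # 400 ps of equilibration
    n_ensemble: int = 10_000
    t_pull: float = 1.0  # ps
    pull_force: float = 1300.0  # kJ/mol/nm
    base_seed: int = 0
    sample_every: int = 10  # recording stride during equilibration

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_ensemble < 1:
            raise ValueError("n_ensemble must be >= 1")
        n = self.t_pull / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("t_pull must be an integral number of time steps")

    @property
    def n_steps_pull(self) -> int:
        return int(round(self.t_pull / self.dt))


@dataclass
class Trajectory:
    """Recorded time series of one simulation run."""

    times: np.ndarray  # ps
    end_to_end: np.ndarray  # nm, per recorded frame
    seed: int
    final_positions: np.ndarray  # (N, 3) nm
    positions: np.ndarray | None = None  # (frames, N, 3) if recorded


@dataclass
class TrajectoryEnsemble:
    phase: str  # equil | stretch | relax
    trajectories: list[Trajectory]
    config: SimConfig
    chain: ChainModel

    def end_to_end_matrix(self) -> np.ndarray:
        """(n_traj, n_frames) end-to-end distances."""
        return np.stack([t.end_to_end for t in self.trajectories])

    def mean_end_to_end(self) -> np.ndarray:
        return self.end_to_end_matrix().mean(axis=0)


@dataclass
class Conformation:
    positions: np.ndarray  # (N, 3)
    end_to_end: float
    frame_index: int


# ---------------------------------------------------------------------------
# potential energy and forces
# ---------------------------------------------------------------------------


class _ChainArrays:
    """Vectorization-ready parameter arrays for a chain."""

    def __init__(self, chain: ChainModel):
        n = chain.n_beads
        self.n = n
        self.mass = np.array([b.mass for b in chain.beads])
        self.zeta = self.mass * np.array([b.friction for b in chain.beads])
        self.b0 = chain.bond_b0
        self.kb = chain.bond_k
        self.k4 = chain.bond_k4
        self.angle_k = np.array([chain.beads[i].angle_k for i in range(1, n - 1)])
        self.theta0 = np.array([chain.beads[i].angle_theta0 for i in range(1, n - 1)])
        ii, jj = np.triu_indices(n, k=3)
        self.nb_i, self.nb_j = ii, jj
        eps = np.array([b.lj_epsilon for b in chain.beads])
        hb = np.array([b.hbond_epsilon for b in chain.beads])
        sig = np.array([b.lj_sigma for b in chain.beads])
        q = np.array([float(b.charge) for b in chain.beads])
        self.eps_ij = np.sqrt(eps[ii] * eps[jj]) + np.sqrt(hb[ii] * hb[jj])
        self.sig_ij = 0.5 * (sig[ii] + sig[jj])
        self.qq_ij = q[ii] * q[jj] * COULOMB_KJ_MOL_NM / chain.dielectric
        self.lam_d = chain.debye_length


def _energy_forces(p: _ChainArrays, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Potential energy and forces for positions of shape (..., N, 3)."""
    F = np.zeros_like(X)
    E = np.zeros(X.shape[:-2])

    # bonds
    bv = X[..., 1:, :] - X[..., :-1, :]
    r = np.linalg.norm(bv, axis=-1)
    if np.any(r < 1e-6):
        raise ValueError("overlapping bonded beads (r < 1e-6 nm)")
    d = r - p.b0
    E += (0.5 * p.kb * d**2 + p.k4 * d**4).sum(axis=-1)
    fmag = p.kb * d + 4.0 * p.k4 * d**3  # dE/dr
    fb = (fmag / r)[..., None] * bv
    F[..., :-1, :] += fb
    F[..., 1:, :] -= fb

    # angles (vertex at bead i, arms to i-1 and i+1)
    if p.n >= 3:
        u = X[..., :-2, :] - X[..., 1:-1, :]
        v = X[..., 2:, :] - X[..., 1:-1, :]
        nu = np.linalg.norm(u, axis=-1)
        nv = np.linalg.norm(v, axis=-1)
        cos_t = np.clip(np.einsum("...k,...k->...", u, v) / (nu * nv), -1.0, 1.0)
        theta = np.arccos(cos_t)
        dtheta = theta - p.theta0
        E += (0.5 * p.angle_k * dtheta**2).sum(axis=-1)
        sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 1e-12))
        coef = (p.angle_k * dtheta / sin_t)[..., None]
        dcos_du = v / (nu * nv)[..., None] - (cos_t / nu**2)[..., None] * u
        dcos_dv = u / (nu * nv)[..., None] - (cos_t / nv**2)[..., None] * v
        f_first = coef * dcos_du  # = -dE/dx_{i-1}
        f_last = coef * dcos_dv
        F[..., :-2, :] += f_first
        F[..., 2:, :] += f_last
        F[..., 1:-1, :] -= f_first + f_last

    # nonbonded |i-j| >= 3
    if len(p.nb_i):
        dv = X[..., p.nb_j, :] - X[..., p.nb_i, :]
        rr = np.linalg.norm(dv, axis=-1)
        if np.any(rr < 1e-6):
            raise ValueError("overlapping nonbonded beads (r < 1e-6 nm)")
        sr6 = (p.sig_ij / rr) ** 6
        E += (4.0 * p.eps_ij * (sr6**2 - sr6)).sum(axis=-1)
        flj = 4.0 * p.eps_ij * (12.0 * sr6**2 - 6.0 * sr6) / rr  # -dE/dr
        screen = np.exp(-rr / p.lam_d)
        E += (p.qq_ij * screen / rr).sum(axis=-1)
        fc = p.qq_ij * screen * (1.0 / rr**2 + 1.0 / (p.lam_d * rr))
        ftot = ((flj + fc) / rr)[..., None] * dv
        # force on j is +ftot (repulsive for positive ftot), on i is -ftot
        np.add.at(F, (..., p.nb_j, slice(None)), ftot)
        np.add.at(F, (..., p.nb_i, slice(None)), -ftot)

    return E, F


def cg_energy(chain: ChainModel, positions: np.ndarray) -> tuple[float, np.ndarray]:
    """Potential energy (kJ/mol) and forces (kJ/mol/nm) of one conformation."""
    X = np.asarray(positions, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite positions")
    if X.shape != (chain.n_beads, 3):
        raise ValueError(f"positions must be ({chain.n_beads}, 3)")
    E, F = _energy_forces(_ChainArrays(chain), X)
    return float(E), F


def initial_conformation(chain: ChainModel) -> np.ndarray:
    """Planar zigzag satisfying bond lengths and (approximately) angles."""
    n = chain.n_beads
    alpha = 0.5 * (np.pi - np.mean([b.angle_theta0 for b in chain.beads]))
    X = np.zeros((n, 3))
    step = chain.bond_b0 * np.array(
        [[np.cos(alpha), np.sin(alpha), 0.0], [np.cos(alpha), -np.sin(alpha), 0.0]]
    )
    for i in range(1, n):
        X[i] = X[i - 1] + step[i % 2]
    return X


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------


def _trajectory_seed(base_seed: int, phase: str, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(base_seed), _PHASE_CODE[phase], int(index)])


def _end_to_end(X: np.ndarray) -> np.ndarray:
    return np.linalg.norm(X[..., -1, :] - X[..., 0, :], axis=-1)


def _propagate(
    p: _ChainArrays,
    X0: np.ndarray,  # (M, N, 3)
    n_steps: int,
    dt: float,
    kbt: float,
    rngs: list[np.random.Generator],
    pull_force: float = 0.0,
    restrain_ends: float = 0.0,
    record_every: int = 1,
    record_positions: bool = False,
):
    """Leimkuhler–Matthews overdamped propagation of a batch of replicas.

    Each replica consumes noise from its own generator so that a trajectory
    is bit-for-bit reproducible from its seed regardless of batch layout.
    Returns (e2e (M, frames), frame times, final X, recorded positions).
    """
    M = X0.shape[0]
    X = X0.copy()
    mob = (dt / p.zeta)[:, None]  # (N, 1)
    amp = np.sqrt(2.0 * kbt * dt / p.zeta)[:, None]
    anchors = X0[:, [0, -1], :].copy()

    noise = np.empty((M, n_steps + 1, p.n, 3))
    for m, rng in enumerate(rngs):
        noise[m] = rng.standard_normal((n_steps + 1, p.n, 3))

    n_frames = n_steps // record_every + 1
    e2e = np.empty((M, n_frames))
    e2e[:, 0] = _end_to_end(X)
    rec = np.empty((M, n_frames, p.n, 3)) if record_positions else None
    if record_positions:
        rec[:, 0] = X
    times = np.arange(n_frames) * (record_every * dt)

    frame = 1
    for step in range(n_steps):
        _, F = _energy_forces(p, X)
        if pull_force != 0.0:
            axis = X[:, -1, :] - X[:, 0, :]
            axis /= np.linalg.norm(axis, axis=-1, keepdims=True)
            F[:, -1, :] += pull_force * axis
            F[:, 0, :] -= pull_force * axis
        if restrain_ends > 0.0:
            F[:, [0, -1], :] -= restrain_ends * (X[:, [0, -1], :] - anchors)
        X = X + mob * F + amp * 0.5 * (noise[:, step] + noise[:, step + 1])
        if (step + 1) % record_every == 0:
            e2e[:, frame] = _end_to_end(X)
            if record_positions:
                rec[:, frame] = X
            frame += 1
    if not np.all(np.isfinite(X)) or np.any(np.abs(X) > _BLOWUP_NM):
        raise RuntimeError(
            "simulation blew up (|x| > 1e3 nm); reduce dt or soften the potential"
        )
    return e2e, times, X, rec


def equilibrate(
    chain: ChainModel,
    config: SimConfig,
    start_positions: np.ndarray | None = None,
    restrain_ends: float = 0.0,
    record_positions: bool = True,
) -> TrajectoryEnsemble:
    """Single equilibration run at temperature T, recording end-to-end series.

    ``restrain_ends`` > 0 adds harmonic position restraints (kJ/mol/nm²) on
    the first and last beads, mimicking an equilibration with fixed termini.
    """
    p = _ChainArrays(chain)
    X0 = (start_positions if start_positions is not None else initial_conformation(chain))
    X0 = np.asarray(X0, dtype=float)[None]
    ss = _trajectory_seed(config.base_seed, "equil", 0)
    rng = np.random.Generator(np.random.PCG64(ss))
    kbt = thermal_energy(config.temperature).kBT_kJ_mol if config.temperature > 0 else 0.0
    e2e, times, Xf, rec = _propagate(
        p,
        X0,
        config.n_steps_equil,
        config.dt,
        kbt,
        [rng],
        restrain_ends=restrain_ends,
        record_every=config.sample_every,
        record_positions=record_positions,
    )
    traj = Trajectory(
        times=times,
        end_to_end=e2e[0],
        seed=0,
        final_positions=Xf[0],
        positions=rec[0] if rec is not None else None,
    )
    return TrajectoryEnsemble(phase="equil", trajectories=[traj], config=config, chain=chain)


def select_start_conformation(
    equil: TrajectoryEnsemble, window_fraction: float = 0.2
) -> Conformation:
    """Pick a start frame typical of the equilibrated chain.

    Among frames in the trailing window (last ``window_fraction`` of the
    run), return the one whose end-to-end distance is closest to the window
    mean; ties go to the latest frame.
    """
    if not equil.trajectories:
        raise ValueError("empty ensemble")
    traj = equil.trajectories[-1]
    if traj.positions is None:
        raise ValueError("equilibration was run without recorded positions")
    n = len(traj.end_to_end)
    start = n - max(1, int(np.floor(window_fraction * n)))
    window = traj.end_to_end[start:]
    if window.size == 0:
        raise ValueError("empty selection window")
    diffs = np.abs(window - window.mean())
    local = len(diffs) - 1 - int(np.argmin(diffs[::-1]))  # latest minimizer
    idx = start + local
    return Conformation(
        positions=traj.positions[idx].copy(),
        end_to_end=float(traj.end_to_end[idx]),
        frame_index=int(idx),
    )


def _run_ensemble(
    chain: ChainModel,
    config: SimConfig,
    phase: str,
    starts: np.ndarray,  # (M, N, 3) or (N, 3) shared
    pull_force: float,
    record_positions: bool = False,
    chunk: int = 512,
) -> TrajectoryEnsemble:
    p = _ChainArrays(chain)
    kbt = thermal_energy(config.temperature).kBT_kJ_mol if config.temperature > 0 else 0.0
    M = config.n_ensemble
    starts = np.asarray(starts, dtype=float)
    shared = starts.ndim == 2
    trajectories: list[Trajectory] = []
    for lo in range(0, M, chunk):
        hi = min(lo + chunk, M)
        idxs = list(range(lo, hi))
        rngs = [
            np.random.Generator(np.random.PCG64(_trajectory_seed(config.base_seed, phase, i)))
            for i in idxs
        ]
        X0 = np.broadcast_to(starts, (len(idxs), p.n, 3)).copy() if shared else starts[lo:hi].copy()
        e2e, times, Xf, rec = _propagate(
            p,
            X0,
            config.n_steps_pull,
            config.dt,
            kbt,
            rngs,
            pull_force=pull_force,
            record_every=1,
            record_positions=record_positions,
        )
        for m, i in enumerate(idxs):
            trajectories.append(
                Trajectory(
                    times=times,
                    end_to_end=e2e[m],
                    seed=i,
                    final_positions=Xf[m],
                    positions=rec[m] if rec is not None else None,
                )
            )
    return TrajectoryEnsemble(phase=phase, trajectories=trajectories, config=config, chain=chain)


def run_stretch_ensemble(
    start: Conformation,
    chain: ChainModel,
    config: SimConfig,
    record_positions: bool = False,
) -> TrajectoryEnsemble:
    """Constant-force pulling ensemble from a common start conformation.

    A force of constant magnitude acts along the instantaneous first→last
    bead axis: +F on the last bead, −F on the first, for ``t_pull``.
    Each of the ``n_ensemble`` replicas has its own noise seed.
    """
    if config.pull_force < 0:
        raise ValueError("pull_force must be non-negative")
    return _run_ensemble(
        chain, config, "stretch", start.positions, config.pull_force, record_positions
    )


def run_relax_ensemble(
    stretch: TrajectoryEnsemble,
    config: SimConfig | None = None,
    record_positions: bool = False,
) -> TrajectoryEnsemble:
    """Force-off relaxation, one run per stretch trajectory (order-preserving).

    Each relax trajectory starts from the final state of the stretch
    trajectory with the same index.
    """
    if stretch.phase != "stretch":
        raise ValueError("input ensemble must be a stretch ensemble")
    config = config if config is not None else stretch.config
    if config.n_ensemble != len(stretch.trajectories):
        raise ValueError("relax ensemble size must match the stretch ensemble")
    starts = np.stack([t.final_positions for t in stretch.trajectories])
    return _run_ensemble(stretch.chain, config, "relax", starts, 0.0, record_positions)


# ---------------------------------------------------------------------------
# 1-D toy propagator (oracles: double wells, Ornstein–Uhlenbeck checks)
# ---------------------------------------------------------------------------


def langevin_1d(
    force_fn,
    x0: float,
    n_steps: int,
    dt: float,
    kbt: float,
    zeta: float,
    seed,
    sample_every: int = 1,
) -> np.ndarray:
    """Overdamped 1-D Langevin trajectory (Leimkuhler–Matthews scheme).

    ``force_fn(x) -> F`` is the systematic force.  Returns the sampled
    positions including the initial one.
    """
    rng = np.random.default_rng(seed)
    x = float(x0)
    mob = dt / zeta
    amp = np.sqrt(2.0 * kbt * dt / zeta)
    out = [x]
    xi_prev = rng.standard_normal()
    for step in range(n_steps):
        xi = rng.standard_normal()
        x = x + mob * force_fn(x) + amp * 0.5 * (xi_prev + xi)
        xi_prev = xi
        if (step + 1) % sample_every == 0:
            out.append(x)
    return np.array(out)
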