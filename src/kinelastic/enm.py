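"""Cα elastic-network normal modes and dynamic-domain decomposition.

The model is Hinsen-style: every Cα pair interacts through a harmonic spring
whose force constant decays as a Gaussian of the reference distance,

    k(R0_ij) = C * exp(-|R0_ij|^2 / r0^2),

so the network is short-ranged and domain boundaries are not bridged.  Low
frequency normal modes of this network are decomposed into dynamic domains:
per-atom deformation energies identify rigid regions, the structure is cut
into cubes, each cube's displacement is fitted by a rigid-body motion
(translation T, rotation Ω), and cubes with similar (T, Ω) are clustered
into domains.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "CaStructure",
    "ElasticNetwork",
    "NormalModeSet",
    "DeformationProfile",
    "RigidBodyMotion",
    "Cube",
    "DomainDecomposition",
    "PDBFormatError",
    "DegenerateGeometryError",
    "DisconnectedNetworkError",
    "read_ca_structure",
    "build_network",
    "compute_modes",
    "deformation_energy",
    "deformation_profile",
    "mode_selection_report",
    "partition_cubes",
    "fit_rigid_body",
    "pair_similarity",
    "cluster_domains",
    "decompose_domains",
    "write_deformation_tsv",
    "write_domain_tsv",
    "write_labels_pdb",
]

#: default force-constant scale, kJ·mol⁻¹·nm⁻² (Amber-94-compatible choice)
DEFAULT_C = 47400.0
#: default decay length of the pair force constant, nm
DEFAULT_R0 = 0.3
#: default mode-normalization scale, nm²
DEFAULT_F = 1.0

OFF_DOMAIN = -1


class PDBFormatError(ValueError):
    """Raised when a structure file yields no usable Cα trace."""


class DegenerateGeometryError(ValueError):
    """Raised when a rigid-body fit is attempted on collinear/degenerate atoms."""


class DisconnectedNetworkError(ValueError):
    """Raised when the elastic network splits into several components."""


# ---------------------------------------------------------------------------
# structure ingestion
# ---------------------------------------------------------------------------


@dataclass
class CaStructure:
    """Cα trace of a protein: coordinates in nm plus residue identities.

    ``gaps`` records (chain, resseq) pairs where the residue numbering jumps,
    i.e. residues missing from the model; coordinates are never interpolated.
    """

    positions: np.ndarray  # (N, 3) nm
    residue_ids: list[tuple[str, int, str]]  # (chain, resseq, resname)
    gaps: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if len(self.residue_ids) != len(self.positions):
            raise ValueError("one residue id per position required")
        if self.N < 3:
            raise ValueError("need at least 3 Cα atoms")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")

    @property
    def N(self) -> int:
        return len(self.positions)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("chain\tresseq\tresname\tx_nm\ty_nm\tz_nm\n")
            for (ch, rs, rn), p in zip(self.residue_ids, self.positions):
                fh.write(f"{ch}\t{rs}\t{rn}\t{p[0]:.4f}\t{p[1]:.4f}\t{p[2]:.4f}\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "CaStructure":
        ids: list[tuple[str, int, str]] = []
        pos: list[list[float]] = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("chain"):
                raise PDBFormatError(f"unexpected header in {path}")
            for line in fh:
                ch, rs, rn, x, y, z = line.rstrip("\n").split("\t")
                ids.append((ch, int(rs), rn))
                pos.append([float(x), float(y), float(z)])
        return cls(np.array(pos), ids, gaps=_find_gaps(ids))


def _find_gaps(residue_ids: list[tuple[str, int, str]]) -> list[tuple[str, int]]:
    gaps: list[tuple[str, int]] = []
    for (c0, r0_, _), (c1, r1, _) in zip(residue_ids, residue_ids[1:]):
        if c0 == c1 and r1 > r0_ + 1:
            gaps.extend((c0, r) for r in range(r0_ + 1, r1))
    return gaps


def read_ca_structure(pdb_source) -> CaStructure:
    """Extract one Cα per residue from a PDB file, path or text.

    Alternate locations are resolved to the highest-occupancy conformer
    (first wins on ties).  Missing residues are recorded as gaps.
    """
    import gemmi

    if isinstance(pdb_source, io.IOBase):
        text = pdb_source.read()
        st = gemmi.read_pdb_string(text)
    elif isinstance(pdb_source, str) and "\nATOM" in "\n" + pdb_source:
        st = gemmi.read_pdb_string(pdb_source)
    else:
        st = gemmi.read_structure(os.fspath(pdb_source))

    if len(st) == 0:
        raise PDBFormatError("structure contains no models")
    model = st[0]
    ids: list[tuple[str, int, str]] = []
    pos: list[list[float]] = []
    for chain in model:
        for res in chain:
            cas = [a for a in res if a.name == "CA" and a.element.name != "Ca"]
            if not cas:
                continue
            best = max(cas, key=lambda a: a.occ)
            ids.append((chain.name, res.seqid.num, res.name))
            # PDB coordinates are in Å; internal unit is nm
            pos.append([best.pos.x / 10.0, best.pos.y / 10.0, best.pos.z / 10.0])
    if not ids:
        raise PDBFormatError("no Cα atoms found in structure")
    if len(ids) < 3:
        raise PDBFormatError(f"only {len(ids)} Cα atoms found; need at least 3")
    return CaStructure(np.array(pos), ids, gaps=_find_gaps(ids))


# ---------------------------------------------------------------------------
# elastic network and normal modes
# ---------------------------------------------------------------------------


@dataclass
class ElasticNetwork:
    """Pairwise springs k(R0) = C·exp(−R0²/r0²) over all retained Cα pairs."""

    C: float
    r0: float
    pairs: np.ndarray  # (M, 2) int
    pair_constants: np.ndarray  # (M,) kJ·mol⁻¹·nm⁻²
    reference_vectors: np.ndarray  # (M, 3) nm, position[j] - position[i]
    reference_distances: np.ndarray  # (M,) nm
    n_atoms: int


def build_network(
    structure: CaStructure,
    C: float = DEFAULT_C,
    r0: float = DEFAULT_R0,
    k_cutoff_frac: float = 1e-10,
) -> ElasticNetwork:
    """Build the exponential-decay spring network over a Cα structure.

    Pairs whose force constant falls below ``k_cutoff_frac * C`` are pruned;
    at the default this keeps springs out to ~4.8 r0, beyond which they are
    numerically negligible.
    """
    if C <= 0 or r0 <= 0:
        raise ValueError("C and r0 must be positive")
    X = structure.positions
    r_cut = r0 * np.sqrt(np.log(1.0 / k_cutoff_frac))
    tree = cKDTree(X)
    prs = tree.query_pairs(r_cut, output_type="ndarray")
    if prs.size == 0:
        raise DisconnectedNetworkError("no pairs within cutoff; network empty")
    vec = X[prs[:, 1]] - X[prs[:, 0]]
    dist = np.linalg.norm(vec, axis=1)
    if np.any(dist < 1e-9):
        bad = prs[dist < 1e-9][0]
        raise ValueError(f"duplicate coordinates for atoms {bad[0]} and {bad[1]}")
    k = C * np.exp(-(dist**2) / r0**2)
    return ElasticNetwork(
        C=C,
        r0=r0,
        pairs=prs,
        pair_constants=k,
        reference_vectors=vec,
        reference_distances=dist,
        n_atoms=structure.N,
    )


@dataclass
class NormalModeSet:
    """Low-frequency modes of the network, rigid-body modes removed.

    Each mode is an (N, 3) displacement field rescaled so that
    Σᵢ|dᵢ|² = f·N; eigenvalues are the Hessian eigenvalues (ascending) of
    the retained modes; ``avg_deformation_energy[m]`` is the mean over atoms
    of the per-atom deformation energy of mode m.
    """

    modes: np.ndarray  # (n_modes, N, 3)
    eigenvalues: np.ndarray  # (n_modes,)
    normalization_f: float
    avg_deformation_energy: np.ndarray  # (n_modes,)
    per_atom_energy: np.ndarray  # (n_modes, N)

    @property
    def n_modes(self) -> int:
        return len(self.modes)


def _hessian(network: ElasticNetwork) -> np.ndarray:
    """Dense 3N×3N Hessian of E = Σ ½k(|R_ij| − |R0_ij|)² at the reference."""
    N = network.n_atoms
    H = np.zeros((3 * N, 3 * N))
    u = network.reference_vectors / network.reference_distances[:, None]
    blocks = network.pair_constants[:, None, None] * (u[:, :, None] * u[:, None, :])
    for (i, j), B in zip(network.pairs, blocks):
        sl_i, sl_j = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        H[sl_i, sl_i] += B
        H[sl_j, sl_j] += B
        H[sl_i, sl_j] -= B
        H[sl_j, sl_i] -= B
    return H


def _check_connected(network: ElasticNetwork) -> None:
    N = network.n_atoms
    adj = sparse.coo_matrix(
        (np.ones(len(network.pairs)), (network.pairs[:, 0], network.pairs[:, 1])),
        shape=(N, N),
    )
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise DisconnectedNetworkError(
            f"elastic network has {n_comp} components (sizes {sizes.tolist()}); "
            "increase r0 or check the structure"
        )


def compute_modes(
    network: ElasticNetwork,
    structure: CaStructure,
    n_modes: int,
    f: float = DEFAULT_F,
) -> NormalModeSet:
    """Diagonalize the network Hessian and return the lowest non-rigid modes.

    Exactly six zero-frequency rigid-body modes are expected and removed; a
    different count signals a disconnected network (more) or degenerate
    collinear geometry (fewer).
    """
    N = network.n_atoms
    if n_modes < 1 or n_modes > 3 * N - 6:
        raise ValueError(f"n_modes must be in [1, {3 * N - 6}]")
    _check_connected(network)
    H = _hessian(network)
    evals, evecs = np.linalg.eigh(H)
    tol = max(evals[-1], 1.0) * 1e-9
    n_zero = int(np.sum(evals < tol))
    if n_zero != 6:
        raise DegenerateGeometryError(
            f"expected 6 rigid-body modes, found {n_zero} near-zero eigenvalues"
        )
    sel = slice(6, 6 + n_modes)
    modes = evecs[:, sel].T.reshape(n_modes, N, 3).copy()
    # Σ|d_i|² = f·N  (eigenvectors come unit-normalized)
    modes *= np.sqrt(f * N)
    per_atom = np.stack(
        [_per_atom_energy(network, m) for m in modes]
    )
    return NormalModeSet(
        modes=modes,
        eigenvalues=evals[sel].copy(),
        normalization_f=f,
        avg_deformation_energy=per_atom.mean(axis=1),
        per_atom_energy=per_atom,
    )


# ---------------------------------------------------------------------------
# deformation energy
# ---------------------------------------------------------------------------


@dataclass
class DeformationProfile:
    """Per-atom deformation energies of a mode (or mode-set sum)."""

    per_atom_energy: np.ndarray  # (N,) kJ·mol⁻¹
    mode_set_used: tuple[int, ...]
    threshold: float | None = None

    @property
    def fraction_below_threshold(self) -> float:
        if self.threshold is None:
            raise ValueError("no threshold set on this profile")
        return float(np.mean(self.per_atom_energy < self.threshold))


def _per_atom_energy(network: ElasticNetwork, mode: np.ndarray) -> np.ndarray:
    i, j = network.pairs[:, 0], network.pairs[:, 1]
    rel = mode[i] - mode[j]
    proj = np.einsum("md,md->m", rel, network.reference_vectors)
    e_pair = 0.5 * network.pair_constants * proj**2 / network.reference_distances**2
    E = np.zeros(network.n_atoms)
    np.add.at(E, i, e_pair)
    np.add.at(E, j, e_pair)
    return E


def deformation_energy(
    structure: CaStructure,
    network: ElasticNetwork,
    mode: np.ndarray,
    mode_index: int = 0,
    threshold: float | None = None,
) -> DeformationProfile:
    """Per-atom deformation energy E_i of a single displacement field.

    E_i = ½ Σ_j k(R0_ij) |(d_i − d_j)·R0_ij|² / |R0_ij|² — the harmonic strain
    the field puts on each atom's local springs.  Rigid fields give E_i ≡ 0.
    """
    mode = np.asarray(mode, dtype=float)
    if mode.shape != (structure.N, 3):
        raise ValueError(f"mode shape {mode.shape} != ({structure.N}, 3)")
    return DeformationProfile(
        per_atom_energy=_per_atom_energy(network, mode),
        mode_set_used=(mode_index,),
        threshold=threshold,
    )


def deformation_profile(
    modes: NormalModeSet,
    mode_indices: tuple[int, ...] | list[int],
    threshold: float | None = None,
) -> DeformationProfile:
    """Summed per-atom deformation energy over a set of modes."""
    idx = tuple(int(i) for i in mode_indices)
    if not idx:
        raise ValueError("mode_indices must be non-empty")
    return DeformationProfile(
        per_atom_energy=modes.per_atom_energy[list(idx)].sum(axis=0),
        mode_set_used=idx,
        threshold=threshold,
    )


def mode_selection_report(
    modes: NormalModeSet, threshold: float
) -> tuple[list[int], list[float]]:
    """Select modes below the deformation-energy threshold.

    Returns the maximal prefix of modes (0-based indices into the mode set)
    whose per-mode average deformation energy is strictly below the
    threshold, plus — for every cumulative prefix of k modes — the fraction
    of atoms whose summed deformation energy stays below the threshold.
    That fraction is how one judges where adding modes stops paying off:
    it shrinks as higher-energy modes are included.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if modes.n_modes == 0:
        raise ValueError("empty mode set")
    avg = modes.avg_deformation_energy
    n_sel = 0
    while n_sel < modes.n_modes and avg[n_sel] < threshold:
        n_sel += 1
    if n_sel == 0:
        import warnings

        warnings.warn("no modes below threshold; selection is empty", stacklevel=2)
    cumulative = np.cumsum(modes.per_atom_energy, axis=0)
    fractions = [float(np.mean(cumulative[k] < threshold)) for k in range(modes.n_modes)]
    return list(range(n_sel)), fractions


# ---------------------------------------------------------------------------
# cube partition, rigid-body fits, clustering
# ---------------------------------------------------------------------------


@dataclass
class Cube:
    cell: tuple[int, int, int]
    atom_indices: np.ndarray
    mean_energy: float


def partition_cubes(
    structure: CaStructure,
    profile: DeformationProfile,
    cube_side: float = 1.2,
    min_atoms: int = 3,
    threshold: float = 400.0,
) -> list[Cube]:
    """Cut space into cubes and keep the rigid, well-populated ones.

    The grid is anchored at the structure's bounding-box minimum with
    half-open intervals.  A cube is admitted iff it holds at least
    ``min_atoms`` atoms and their mean deformation energy is strictly below
    the threshold.
    """
    if cube_side <= 0 or min_atoms < 1:
        raise ValueError("cube_side must be > 0 and min_atoms >= 1")
    X = structure.positions
    cells = np.floor((X - X.min(axis=0)) / cube_side).astype(int)
    E = profile.per_atom_energy
    buckets: dict[tuple[int, int, int], list[int]] = {}
    for a, c in enumerate(map(tuple, cells)):
        buckets.setdefault(c, []).append(a)
    cubes = [
        Cube(cell=c, atom_indices=np.array(idx), mean_energy=float(E[idx].mean()))
        for c, idx in sorted(buckets.items())
        if len(idx) >= min_atoms and float(E[idx].mean()) < threshold
    ]
    if not cubes:
        import warnings

        warnings.warn("no cubes admitted at this threshold", stacklevel=2)
    return cubes


@dataclass
class RigidBodyMotion:
    """Best-fit rigid interpretation d_i = T + Ω × R_i of a displacement field.

    For a multi-mode fit T_vec and Omega are stacked (n_modes, 3) arrays;
    similarity scoring flattens them.
    """

    T_vec: np.ndarray
    Omega: np.ndarray
    residual: float


def fit_rigid_body(positions: np.ndarray, displacements: np.ndarray) -> RigidBodyMotion:
    """Least-squares (T, Ω) such that d_i ≈ T + Ω × R_i.

    Positions are referenced to their centroid before fitting.  Exactly
    rigid inputs are recovered with zero residual; collinear geometries are
    rejected because Ω is then underdetermined.
    """
    R = np.asarray(positions, dtype=float)
    d = np.asarray(displacements, dtype=float)
    if R.shape != d.shape or R.ndim != 2 or R.shape[1] != 3:
        raise ValueError("positions and displacements must both be (n, 3)")
    n = len(R)
    if n < 3:
        raise DegenerateGeometryError("need at least 3 atoms for a rigid-body fit")
    Rc = R - R.mean(axis=0)
    A = np.zeros((3 * n, 6))
    A[0::3, 0] = A[1::3, 1] = A[2::3, 2] = 1.0
    # Ω × R = -skew(R) Ω
    A[0::3, 4], A[0::3, 5] = Rc[:, 2], -Rc[:, 1]
    A[1::3, 3], A[1::3, 5] = -Rc[:, 2], Rc[:, 0]
    A[2::3, 3], A[2::3, 4] = Rc[:, 1], -Rc[:, 0]
    sol, res, rank, _ = np.linalg.lstsq(A, d.ravel(), rcond=None)
    if rank < 6:
        raise DegenerateGeometryError("collinear atoms: rotation is underdetermined")
    misfit = float(np.sum((A @ sol - d.ravel()) ** 2))
    return RigidBodyMotion(T_vec=sol[:3], Omega=sol[3:], residual=misfit)


#: quotient cap for identical motions (Eq.-6-style similarity is singular there)
S_CAP = 1e6
_DENOM_GUARD = 1e-12


def pair_similarity(a: RigidBodyMotion, b: RigidBodyMotion) -> float:
    """Rigid-motion similarity 3|Ωa+Ωb|/|Ωa−Ωb| + |Ta+Tb|/|Ta−Tb|.

    Rotations get triple weight (they discriminate domains more reliably).
    Each quotient is capped at S_CAP when its denominator vanishes, so
    identical motions score 4·S_CAP and opposite motions score 0.
    """

    def quot(u: np.ndarray, v: np.ndarray) -> float:
        num = float(np.linalg.norm((u + v).ravel()))
        den = float(np.linalg.norm((u - v).ravel()))
        if den < _DENOM_GUARD:
            return S_CAP
        return min(num / den, S_CAP)

    return 3.0 * quot(a.Omega, b.Omega) + quot(a.T_vec, b.T_vec)


@dataclass
class DomainDecomposition:
    cube_side: float
    cubes: list[Cube]
    similarities: np.ndarray  # (n_cubes, n_cubes)
    coarseness_c: float
    cube_labels: np.ndarray  # (n_cubes,) int
    residue_labels: np.ndarray  # (N,) int; OFF_DOMAIN where unassigned

    @property
    def n_domains(self) -> int:
        return int(self.cube_labels.max()) + 1 if len(self.cube_labels) else 0


def cluster_domains(
    cubes: list[Cube],
    similarities: np.ndarray,
    coarseness_c: float,
    n_atoms: int,
    cube_side: float = 1.2,
) -> DomainDecomposition:
    """Group cubes of similar rigid-body motion into dynamic domains.

    The similarity threshold is (max pairwise similarity)/c; cube pairs
    strictly above it are linked and connected components become domains.
    Larger coarseness c therefore merges more cubes: as c grows the
    decomposition coarsens monotonically toward one all-encompassing domain.
    """
    if coarseness_c <= 1:
        raise ValueError("coarseness must be > 1")
    n = len(cubes)
    S = np.asarray(similarities, dtype=float)
    if S.shape != (n, n):
        raise ValueError("similarity matrix shape mismatch")
    if n < 2:
        import warnings

        warnings.warn("fewer than 2 cubes: trivial single domain", stacklevel=2)
        labels = np.zeros(n, dtype=int)
    else:
        off = ~np.eye(n, dtype=bool)
        s_max = S[off].max()
        thr = s_max / coarseness_c
        adj = sparse.csr_matrix((S > thr) & off)
        _, labels = connected_components(adj, directed=False)
    residue_labels = np.full(n_atoms, OFF_DOMAIN, dtype=int)
    for cube, lab in zip(cubes, labels):
        residue_labels[cube.atom_indices] = lab
    return DomainDecomposition(
        cube_side=cube_side,
        cubes=cubes,
        similarities=S,
        coarseness_c=coarseness_c,
        cube_labels=np.asarray(labels, dtype=int),
        residue_labels=residue_labels,
    )


def decompose_domains(
    structure: CaStructure,
    network: ElasticNetwork,
    modes: NormalModeSet,
    threshold: float = 400.0,
    cube_side: float = 1.2,
    min_atoms: int = 3,
    coarseness_c: float = 10.0,
) -> DomainDecomposition:
    """Full decomposition: mode selection → cubes → rigid fits → clustering.

    Every admitted cube is fitted per selected mode; the per-mode (T, Ω)
    vectors are stacked before similarity scoring so all selected modes
    weigh in.  Cubes with degenerate (collinear) geometry are dropped.
    """
    selected, _ = mode_selection_report(modes, threshold)
    if not selected:
        raise ValueError("no modes below threshold; cannot decompose")
    profile = deformation_profile(modes, selected, threshold=threshold)
    cubes = partition_cubes(structure, profile, cube_side, min_atoms, threshold)
    fits: list[RigidBodyMotion] = []
    kept: list[Cube] = []
    for cube in cubes:
        R = structure.positions[cube.atom_indices]
        try:
            per_mode = [
                fit_rigid_body(R, modes.modes[m][cube.atom_indices]) for m in selected
            ]
        except DegenerateGeometryError:
            continue
        fits.append(
            RigidBodyMotion(
                T_vec=np.stack([f.T_vec for f in per_mode]),
                Omega=np.stack([f.Omega for f in per_mode]),
                residual=float(sum(f.residual for f in per_mode)),
            )
        )
        kept.append(cube)
    n = len(kept)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = pair_similarity(fits[i], fits[j])
    return cluster_domains(kept, S, coarseness_c, structure.N, cube_side)


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------


def write_deformation_tsv(
    structure: CaStructure, profile: DeformationProfile, path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tresseq\tresname\tE_kJ_mol\n")
        for (ch, rs, rn), e in zip(structure.residue_ids, profile.per_atom_energy):
            fh.write(f"{ch}\t{rs}\t{rn}\t{e:.4f}\n")


def write_domain_tsv(
    structure: CaStructure, decomposition: DomainDecomposition, path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tresseq\tresname\tdomain\n")
        for (ch, rs, rn), lab in zip(structure.residue_ids, decomposition.residue_labels):
            fh.write(f"{ch}\t{rs}\t{rn}\t{lab}\n")


def write_labels_pdb(
    structure: CaStructure, labels: np.ndarray, path: str | os.PathLike
) -> None:
    """Write the Cα trace as PDB with labels in the B-factor column.

    Handy for coloring domains in a molecular viewer.
    """
    with open(path, "w") as fh:
        for serial, ((ch, rs, rn), p, lab) in enumerate(
            zip(structure.residue_ids, structure.positions, labels), start=1
        ):
            x, y, z = p * 10.0  # nm → Å
            fh.write(
                f"ATOM  {serial:5d}  CA  {rn:<3s} {ch[:1]}{rs:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{float(lab):6.2f}"
                f"          {'C':>2s}\n"
            )
        fh.write("END\n")
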