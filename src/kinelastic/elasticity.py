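"""Conformational and elastic observables of simulated peptide chains.

End-to-end distance distributions with Gaussianity checks, ensemble-averaged
pair-distance profiles under pulling, fractional extension, quadratic
stiffness fits of ΔG versus fractional extension, and the worm-like-chain
force–extension law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .units import thermal_energy

__all__ = [
    "DistanceDistribution",
    "PairDistanceProfile",
    "WLCParams",
    "StiffnessFit",
    "FractionalExtension",
    "end_to_end_distribution",
    "pair_distance_profiles",
    "fractional_extension",
    "fit_quadratic_stiffness",
    "wlc_force",
]


@dataclass
class DistanceDistribution:
    """End-to-end samples from a frame window plus a Gaussian fit and KS test."""

    samples: np.ndarray  # nm
    window: tuple[int, int]
    mean: float
    sd: float
    ks_statistic: float
    ks_pvalue: float
    degenerate: bool = False

    def is_gaussian(self, alpha: float = 0.01) -> bool:
        """Whether the samples are consistent with the fitted normal at level alpha."""
        return not self.degenerate and self.ks_pvalue >= alpha


def end_to_end_distribution(series: np.ndarray, window: tuple[int, int] | None = None) -> DistanceDistribution:
    """Moment Gaussian fit + KS goodness-of-fit of an end-to-end series.

    ``window`` is a half-open frame-index range; default is the whole series.
    A constant series yields sd = 0 and is flagged degenerate (the KS test
    against a zero-width normal is meaningless).
    """
    x = np.asarray(series, dtype=float)
    if window is None:
        window = (0, len(x))
    lo, hi = window
    if not (0 <= lo < hi <= len(x)):
        raise ValueError(f"window {window} out of range for series of length {len(x)}")
    w = x[lo:hi]
    mean, sd = float(w.mean()), float(w.std(ddof=1)) if w.size > 1 else 0.0
    if sd == 0.0:
        return DistanceDistribution(
            samples=w, window=window, mean=mean, sd=0.0,
            ks_statistic=np.nan, ks_pvalue=np.nan, degenerate=True,
        )
    ks = stats.kstest(w, "norm", args=(mean, sd))
    return DistanceDistribution(
        samples=w, window=window, mean=mean, sd=sd,
        ks_statistic=float(ks.statistic), ks_pvalue=float(ks.pvalue),
    )


@dataclass
class PairDistanceProfile:
    """Ensemble-mean distance from a reference residue to targets, per frame."""

    reference_index: int  # 1-based residue position
    target_indices: tuple[int, ...]
    times: np.ndarray  # ps
    mean_distance_vs_time: np.ndarray  # (n_targets, n_frames) nm


def pair_distance_profiles(
    ensemble, reference_index: int = 4, target_indices=(8, 11, 14, 15)
) -> PairDistanceProfile:
    """Mean |reference→target| distances over an ensemble, frame by frame.

    Residue indices are 1-based (the conventional reference is residue 4,
    the conserved isoleucine position).  Requires trajectories recorded with
    positions.  Near neighbours of the reference stay almost constant under
    pulling while distal pairs extend — the profile makes that visible.
    """
    n = ensemble.chain.n_beads
    targets = tuple(int(t) for t in target_indices)
    for t in (reference_index, *targets):
        if not 1 <= t <= n:
            raise ValueError(f"residue index {t} outside 1..{n}")
    if reference_index in targets:
        raise ValueError("reference residue cannot be its own target")
    ref = reference_index - 1
    tgt = np.array(targets) - 1
    profiles = None
    for traj in ensemble.trajectories:
        if traj.positions is None:
            raise ValueError("ensemble trajectories lack recorded positions")
        d = np.linalg.norm(traj.positions[:, tgt, :] - traj.positions[:, [ref], :], axis=-1)
        profiles = d.T if profiles is None else profiles + d.T
    profiles /= len(ensemble.trajectories)
    return PairDistanceProfile(
        reference_index=reference_index,
        target_indices=targets,
        times=ensemble.trajectories[0].times,
        mean_distance_vs_time=profiles,
    )


@dataclass(frozen=True)
class FractionalExtension:
    """Dimensionless stretch coordinate.

    value = (current − relaxed_mean) / (Lc − relaxed_mean): 0 at the relaxed
    mean end-to-end distance, 1 at full contour length.
    """

    value: float
    relaxed_mean: float  # nm
    current: float  # nm
    Lc: float  # nm


def fractional_extension(
    current: float,
    relaxed_mean: float,
    n_residues: int,
    per_residue_contour: float = 0.4,
) -> FractionalExtension:
    """Fractional extension with contour length Lc = n_residues × 0.4 nm."""
    Lc = n_residues * per_residue_contour
    if Lc <= relaxed_mean:
        raise ValueError(
            f"contour length {Lc} nm must exceed the relaxed mean {relaxed_mean} nm"
        )
    return FractionalExtension(
        value=(current - relaxed_mean) / (Lc - relaxed_mean),
        relaxed_mean=relaxed_mean,
        current=current,
        Lc=Lc,
    )


@dataclass
class StiffnessFit:
    """Two-parameter fit ΔG = a·f² + b over (fractional extension, ΔG) points."""

    quadratic_coef: float  # kBT
    intercept: float  # kBT
    points: np.ndarray  # (n, 2)
    rss: float  # kBT²

    @property
    def r_squared(self) -> float:
        dg = self.points[:, 1]
        tss = float(np.sum((dg - dg.mean()) ** 2))
        return 1.0 - self.rss / tss if tss > 0 else float("nan")


def fit_quadratic_stiffness(points, include_linear: bool = False) -> StiffnessFit:
    """Least-squares stiffness fit of ΔG versus fractional extension.

    The default model is the pure spring form ΔG = a·f² + b (quadratic
    coefficient = effective stiffness, reported together with the
    intercept).  ``include_linear`` adds a linear term for comparison; the
    returned quadratic_coef/intercept are still a and b.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need >= 3 (fractional extension, deltaG) points")
    f, dg = pts[:, 0], pts[:, 1]
    if np.allclose(f, f[0]):
        raise ValueError("all fractional extensions identical: rank-deficient fit")
    cols = [f**2, np.ones_like(f)]
    if include_linear:
        cols.insert(1, f)
    A = np.column_stack(cols)
    sol, _, rank, _ = np.linalg.lstsq(A, dg, rcond=None)
    if rank < A.shape[1]:
        raise ValueError("rank-deficient design matrix")
    rss = float(np.sum((A @ sol - dg) ** 2))
    return StiffnessFit(
        quadratic_coef=float(sol[0]),
        intercept=float(sol[-1]),
        points=pts,
        rss=rss,
    )


@dataclass(frozen=True)
class WLCParams:
    contour_length: float  # Lc, nm
    persistence_length: float  # L, nm
    temperature: float = 300.0  # K

    def __post_init__(self) -> None:
        if self.contour_length <= 0 or self.persistence_length <= 0:
            raise ValueError("contour and persistence lengths must be positive")


def wlc_force(x: float, params: WLCParams, as_printed: bool = False) -> float:
    """Worm-like-chain force (pN) at extension x (nm).

    Standard Marko–Siggia interpolation
        F = (kBT/L) [ ¼ (1 − x/Lc)⁻² + x/Lc − ¼ ],
    which vanishes at x = 0 and diverges as x → Lc.  ``as_printed`` swaps
    the linear term to x/L (a dimensionally odd variant that appears in some
    write-ups of the formula) for comparison; it no longer vanishes at x = 0
    unless L = Lc.
    """
    Lc, L = params.contour_length, params.persistence_length
    if not 0 <= x < Lc:
        raise ValueError(f"extension must satisfy 0 <= x < Lc={Lc}")
    kbt_pn_nm = thermal_energy(params.temperature).kBT_pN_nm
    lin = x / L if as_printed else x / Lc
    return kbt_pn_nm / L * (0.25 * (1.0 - x / Lc) ** -2 + lin - 0.25)
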