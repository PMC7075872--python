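"""Work bookkeeping and free-energy estimation from pulling ensembles.

Work done by the constant pulling force on one trajectory is W = F·Δd where
d is the distance between the pulled pair (first and last residue).  Over an
ensemble of repeats the work samples feed three ΔG estimators:

* Jarzynski:   ΔG = −kBT ln ⟨e^{−βW}⟩          (exponential average)
* Gaussian:    ΔG = μ_W − σ_W²/2  (closed form of the above for normal W)
* Crooks crossing point: the work value where the forward (stretch) and
  reverse (relax) work densities intersect equals ΔG.

Also provides the occupancy-histogram estimator ΔG = −kBT ln(n_B/n_A) for
equilibrium visit counts, and percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .simulate import Trajectory
from .units import thermal_energy

__all__ = [
    "WorkEnsemble",
    "GaussianFit",
    "FreeEnergyEstimate",
    "accumulate_work",
    "work_ensemble",
    "fit_gaussian",
    "crossing_point",
    "jarzynski_estimate",
    "gaussian_jarzynski",
    "occupancy_delta_g",
    "bootstrap_ci",
    "estimate_free_energy",
    "write_work_tsv",
    "read_work_tsv",
]


@dataclass
class WorkEnsemble:
    """Per-trajectory work samples in kBT at a given temperature."""

    phase: str  # stretch | relax
    samples: np.ndarray  # kBT
    temperature: float  # K

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 1:
            raise ValueError("work ensemble needs at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite work samples")

    @property
    def n(self) -> int:
        return self.samples.size

    def samples_kj_mol(self) -> np.ndarray:
        return self.samples * thermal_energy(self.temperature).kBT_kJ_mol


@dataclass(frozen=True)
class GaussianFit:
    """Moment-matched normal fit to a work distribution (kBT units)."""

    mu: float
    sigma: float
    n: int


@dataclass
class FreeEnergyEstimate:
    """ΔG between stretched and relaxed states from one (forward, reverse) pair."""

    delta_g_crossing: float  # kBT
    delta_g_jarzynski: float  # kBT
    delta_g_gaussian: float  # kBT
    ci_low: float
    ci_high: float
    method: dict = field(default_factory=dict)


def accumulate_work(trajectory: Trajectory, force: float, phase: str, temperature: float) -> float:
    """Work (kBT) done by a constant force F over one trajectory.

    Stretch: W = F·(d_final − d_initial).  Relax: the force is physically
    off, so the reverse work is booked against the same F over the reversed
    displacement, W = F·(d_initial − d_final) — the conjugate-protocol
    convention that makes forward/reverse distributions comparable.
    """
    d0 = float(trajectory.end_to_end[0])
    d1 = float(trajectory.end_to_end[-1])
    if not (np.isfinite(d0) and np.isfinite(d1)):
        raise ValueError("non-finite end-to-end distances")
    if phase == "stretch":
        w_kj = force * (d1 - d0)
    elif phase == "relax":
        w_kj = force * (d0 - d1)
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return w_kj / thermal_energy(temperature).kBT_kJ_mol


def work_ensemble(ensemble, force: float | None = None) -> WorkEnsemble:
    """Work samples for every trajectory of a stretch or relax ensemble."""
    force = force if force is not None else ensemble.config.pull_force
    T = ensemble.config.temperature
    samples = np.array(
        [accumulate_work(t, force, ensemble.phase, T) for t in ensemble.trajectories]
    )
    return WorkEnsemble(phase=ensemble.phase, samples=samples, temperature=T)


def fit_gaussian(works: WorkEnsemble | np.ndarray) -> GaussianFit:
    """Moment-matching Gaussian fit (sample mean, unbiased SD)."""
    x = works.samples if isinstance(works, WorkEnsemble) else np.asarray(works, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to fit a Gaussian")
    return GaussianFit(mu=float(x.mean()), sigma=float(x.std(ddof=1)), n=x.size)


def crossing_point(f: GaussianFit, r: GaussianFit) -> float:
    """Work value where the two fitted normal densities intersect (= ΔG).

    Equal variances give the midpoint of the means.  Unequal variances give
    a quadratic with two roots; the physically meaningful crossing is the
    one between the two means (where the distributions overlap).
    """
    if f.sigma < 0 or r.sigma < 0:
        raise ValueError("negative sigma")
    if np.isclose(f.sigma, r.sigma):
        if f.sigma == 0 and not np.isclose(f.mu, r.mu):
            raise ValueError("degenerate distributions with distinct means never cross")
        return 0.5 * (f.mu + r.mu)
    # log N(mu_f, s_f) = log N(mu_r, s_r): quadratic a W^2 + b W + c = 0
    sf2, sr2 = f.sigma**2, r.sigma**2
    a = 1.0 / sr2 - 1.0 / sf2
    b = 2.0 * (f.mu / sf2 - r.mu / sr2)
    c = r.mu**2 / sr2 - f.mu**2 / sf2 + 2.0 * np.log(r.sigma / f.sigma)
    disc = b**2 - 4.0 * a * c
    if disc < 0:
        raise ValueError("work distributions do not cross (negative discriminant)")
    roots = np.array([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
    lo, hi = sorted((f.mu, r.mu))
    between = roots[(roots >= lo) & (roots <= hi)]
    if between.size == 0:
        raise ValueError(f"no crossing between the means; roots at {roots.tolist()}")
    return float(between[0])


def jarzynski_estimate(works: WorkEnsemble | np.ndarray) -> float:
    """ΔG (kBT) from the exponential work average, log-sum-exp stabilized."""
    w = works.samples if isinstance(works, WorkEnsemble) else np.asarray(works, dtype=float)
    if w.size == 0:
        raise ValueError("empty work ensemble")
    return float(-(logsumexp(-w) - np.log(w.size)))


def gaussian_jarzynski(fit: GaussianFit) -> float:
    """Closed-form Jarzynski ΔG = μ − σ²/2 for a normal work distribution (kBT)."""
    return fit.mu - 0.5 * fit.sigma**2


def occupancy_delta_g(
    samples: np.ndarray, region_a, region_b, temperature: float = 300.0
) -> float:
    """ΔG (kBT) between two configurational regions from visit counts.

    Regions are predicates over the sampled coordinate; the estimator is the
    Boltzmann ratio ΔG_{A→B} = −ln(n_B / n_A) in kBT.
    """
    x = np.asarray(samples, dtype=float)
    n_a = int(np.count_nonzero(region_a(x)))
    n_b = int(np.count_nonzero(region_b(x)))
    if n_a == 0 or n_b == 0:
        raise ValueError(
            f"unvisited region (n_A={n_a}, n_B={n_b}); sample longer trajectories"
        )
    return float(-np.log(n_b / n_a))


def bootstrap_ci(
    works_f: WorkEnsemble | np.ndarray,
    works_r: WorkEnsemble | np.ndarray | None,
    estimator,
    n_boot: int = 1000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI of a ΔG estimator over trajectory resampling.

    ``estimator`` takes one work array (if ``works_r`` is None) or two
    (forward, reverse).  Deterministic for a fixed seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    wf = works_f.samples if isinstance(works_f, WorkEnsemble) else np.asarray(works_f, float)
    wr = None
    if works_r is not None:
        wr = works_r.samples if isinstance(works_r, WorkEnsemble) else np.asarray(works_r, float)
    if wf.size == 1 or (wr is not None and wr.size == 1):
        warnings.warn("single-sample ensemble: zero-width interval", stacklevel=2)
        val = estimator(wf) if wr is None else estimator(wf, wr)
        return (float(val), float(val))
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        sf = wf[rng.integers(0, wf.size, wf.size)]
        if wr is None:
            stats[b] = estimator(sf)
        else:
            sr = wr[rng.integers(0, wr.size, wr.size)]
            stats[b] = estimator(sf, sr)
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def _crossing_from_samples(wf: np.ndarray, wr: np.ndarray) -> float:
    return crossing_point(fit_gaussian(wf), fit_gaussian(wr))


def estimate_free_energy(
    works_f: WorkEnsemble,
    works_r: WorkEnsemble,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> FreeEnergyEstimate:
    """All three ΔG estimators plus a bootstrap CI on the crossing point."""
    fit_f = fit_gaussian(works_f)
    fit_r = fit_gaussian(works_r)
    dg_cross = crossing_point(fit_f, fit_r)
    dg_jarz = jarzynski_estimate(works_f)
    dg_gauss = gaussian_jarzynski(fit_f)
    lo, hi = bootstrap_ci(works_f, works_r, _crossing_from_samples, n_boot=n_boot, seed=seed)
    return FreeEnergyEstimate(
        delta_g_crossing=dg_cross,
        delta_g_jarzynski=dg_jarz,
        delta_g_gaussian=dg_gauss,
        ci_low=lo,
        ci_high=hi,
        method={
            "fit_forward": (fit_f.mu, fit_f.sigma),
            "fit_reverse": (fit_r.mu, fit_r.sigma),
            "n_boot": n_boot,
            "ci": "percentile bootstrap on crossing point",
        },
    )


# ---------------------------------------------------------------------------
# IO: two-column TSV with a JSON sidecar
# ---------------------------------------------------------------------------


def write_work_tsv(works: WorkEnsemble, path: str | os.PathLike, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("trajectory_id\tW_kBT\n")
        for i, w in enumerate(works.samples):
            fh.write(f"{i}\t{w:.8g}\n")
    sidecar = dict(meta or {})
    sidecar.update({"phase": works.phase, "temperature_K": works.temperature, "n": works.n})
    with open(f"{os.fspath(path)}.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_work_tsv(path: str | os.PathLike) -> WorkEnsemble:
    with open(f"{os.fspath(path)}.json") as fh:
        meta = json.load(fh)
    samples = np.loadtxt(path, skiprows=1, usecols=1, ndmin=1)
    return WorkEnsemble(phase=meta["phase"], samples=samples, temperature=meta["temperature_K"])
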