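# Methods

## Units and constants

Internal units are GROMACS-style — kJ·mol⁻¹, nm, ps, amu — in which
1 kJ·mol⁻¹ = 1 amu·nm²·ps⁻², so the Langevin propagator needs no conversion
factors.  CODATA values kB = 1.380649×10⁻²³ J/K and
N_A = 6.02214076×10²³ mol⁻¹ are hard-coded; at 300 K,
kBT = 2.4943 kJ·mol⁻¹ = 4.1419 pN·nm, and a molar force of
1300 kJ·mol⁻¹·nm⁻¹ is 2158.7 pN per molecule.  Work is reported in kBT at
the simulation temperature.

## Elastic-network domain analysis

The model is a Hinsen-type Cα network: every pair (i, j) interacts through a
harmonic spring in the pair distance with force constant
k(R⁰) = C·exp(−|R⁰|²/r₀²).  Defaults: C = 47 400 kJ·mol⁻¹·nm⁻²
(an Amber-94-compatible scale; note the energy profile is linear in C, so C
only sets the scale on which the 400 kJ·mol⁻¹ threshold is meaningful) and
r₀ = 0.3 nm.  r₀ has no established published value for this analysis, so it
is exposed in the configuration and `scripts/enm_benchmark.py` sweeps
r₀ ∈ {0.3, 0.5, 0.7} nm; conclusions that depend on r₀ should be checked
across the sweep.  Springs with k < 10⁻¹⁰·C (pair distance beyond ≈ 4.8 r₀)
are pruned, which keeps the Hessian assembly short-ranged without measurable
effect on the low modes.

The 3N×3N Hessian of E = Σ ½k(R⁰)(|R|−|R⁰|)² at the reference structure is
the standard anisotropic-network form k·ûûᵀ per pair.  It is diagonalized
densely; exactly six near-zero eigenvalues (rigid translations/rotations) are
removed, any other count raises an error (fewer ⇒ degenerate collinear
geometry, more ⇒ disconnected network, reported with component sizes).  Each
retained mode is rescaled to Σᵢ|dᵢ|² = f·N with f = 1 nm².  With that
normalization the per-mode average deformation energy (atom mean of Eᵢ)
equals the Hessian eigenvalue — a cross-check asserted in the tests.

Mode count is chosen by a deformation-energy threshold (default
400 kJ·mol⁻¹): the maximal prefix of modes whose average deformation energy
is strictly below the threshold is selected, and the report also gives, for
every prefix, the fraction of residues whose cumulative deformation energy
stays below the threshold — the quantity whose drop signals that further
modes no longer describe rigid-body-like domain motion.  "Region" here means
an individual Cα residue.

Domains: space is cut into cubes of side 1.2 nm anchored at the bounding-box
minimum (half-open intervals, deterministic binning).  Cubes with ≥ 3 atoms
and mean deformation energy strictly below the threshold are admitted.  Each
admitted cube's displacement field is least-squares fitted per selected mode
by dᵢ = T + Ω×Rᵢ (positions referenced to the cube centroid; collinear cubes
are dropped).  The per-mode (T, Ω) vectors are stacked before similarity
scoring so every selected mode contributes.  Similarity quotients are capped
at 10⁶ when a denominator falls below 10⁻¹² (identical motions would
otherwise be singular; clustering only needs the ordering).  Cubes with
S strictly above Sᵐᵃˣ/c are linked and connected components become domains —
the reading of the published clustering rule closest to transitive closure;
a seeded single-linkage growth would differ only in ties.  Residues outside
any admitted cube are labelled off-domain (−1).  Domain count is
non-increasing in c by construction (the threshold only drops), which the
property suite asserts.

## Coarse-grained chain simulator

One bead per residue.  Potential:

* bonds: ½k_b(r−b₀)² + k₄(r−b₀)⁴ with b₀ = 0.38 nm, k_b = 10⁴ kJ·mol⁻¹·nm⁻²,
  k₄ = 4×10⁶ kJ·mol⁻¹·nm⁻⁴.  The quartic term supplies finite extensibility:
  with it, the strongest pulling force (1300 kJ·mol⁻¹·nm⁻¹) stretches the
  19-mer to ≈ 0.95 of its 7.6 nm contour length instead of past it, keeping
  fractional extension in [0, 1].
* angles: ½k_θ(θ−θ₀)² on each virtual-bond angle, parameters of the vertex
  residue.  Defaults k_θ = 20 kJ·mol⁻¹·rad⁻², θ₀ = 2.0 rad; proline gets a
  stiffer, kinked angle (60 kJ·mol⁻¹·rad⁻², 1.4 rad) as the bead-level
  analog of its ring-constrained backbone, glycine a softer one
  (8 kJ·mol⁻¹·rad⁻²).  Cis/trans proline isomerization kinetics are not
  modelled.
* nonbonded (|i−j| ≥ 3): Lennard-Jones with well depth from Kyte–Doolittle
  hydropathy mapped onto [0.1, 0.9] kJ·mol⁻¹ (hydrophobic residues attract
  more), plus an extra polar well depth (1.0 kJ·mol⁻¹ for Asn/Gln,
  0.4 for Ser/Thr/Tyr/His/Trp) combined by geometric mean — a crude
  hydrogen-bonding surrogate — and a Debye-screened Coulomb term
  (λ_D = 1 nm, ε_r = 80) between the ±1 charges of Lys/Arg and Asp/Glu.

Dynamics are overdamped Langevin with per-bead drag ζᵢ = mᵢγ (γ = 5 ps⁻¹,
residue masses in amu), integrated by the Leimkuhler–Matthews one-step
scheme x' = x + (Δt/ζ)F + √(2kBTΔt/ζ)·(ξₙ+ξₙ₊₁)/2 at Δt = 2×10⁻³ ps.  This
scheme was chosen over plain Euler–Maruyama because its configurational
sampling error is O(Δt²), which lets the equipartition and ideal-chain
checks pass honestly at this time step; cost and determinism are identical.
Analytic forces are verified against central finite differences to 10⁻⁶
relative.

Protocol, mirroring constant-force pulling experiments: (1) equilibrate a
single trajectory (default 2×10⁵ steps = 400 ps; an optional harmonic
restraint can pin the terminal beads); (2) select the frame in the trailing
20% of the run whose end-to-end distance is closest to the window mean (ties
to the latest frame); (3) run an ensemble of constant-force stretch
trajectories (default 10⁴ × 1 ps) from that common start, the force of
constant magnitude applied along the instantaneous first→last bead axis (+F
on the last bead, −F on the first); (4) relax each stretch endpoint with the
force off for the same duration, pairing 1:1 and order-preserving.
Trajectory i of phase p is seeded by SeedSequence([base_seed, p, i]), so
every trajectory is bit-for-bit reproducible regardless of batch layout.
End-to-end series are always recorded; full per-step positions only on
request (ensembles would otherwise be memory-bound).

What the generator emulates: near-Gaussian end-to-end fluctuations of an
equilibrated short chain in an energy well; stretching at a nearly constant
rate under strong constant force followed by force-off retraction; ensembles
whose forward/reverse work distributions are approximately Gaussian and
well-separated, with work values in the hundreds-of-kBT regime.  What it
does not emulate: explicit solvent and friction anisotropy, backbone
dihedral chemistry, hydrogen-bond networks, and therefore the *absolute*
free-energy differences of specific sequences — passing tests demonstrate
the estimators and the protocol, and only qualitative sequence contrasts,
not all-atom energetics.

## Work and free-energy estimators

Stretch work is W = F·(d_f − d_i) in the pulled coordinate (first↔last bead
distance).  The relaxation phase physically has the force off; its reverse
work is booked against the same F over the reversed displacement,
W = F·(d_i − d_f) — a conjugate-protocol reading that makes the forward and
reverse distributions directly comparable on one axis.  This is the one
genuinely open convention in the analysis (a force-off protocol has no
mechanical work of its own) and is flagged here deliberately.

Gaussian fits are moment-matched (sample mean, unbiased SD) rather than
histogram least-squares: bin-free and parameter-stable, and crossing points
recomputed from the published moments land within 0.7% of the published ΔG
on all five chains.  The crossing point solves equality of the two normal
log-densities; with unequal variances the quadratic has two roots and the
root between the means is returned (both appear in the error message if the
selection fails).  Equal variances reduce to the midpoint of the means.
The Jarzynski estimator uses a log-sum-exp reduction (overflow-safe for any
work scale); its Gaussian closed form is μ − σ²/2.  Occupancy free energies
use visit counts, ΔG = −kBT·ln(n_B/n_A).  Uncertainty is a percentile
bootstrap over trajectory resampling (default 1000 resamples, seeded).
The published "± 0.1" on ΔG has no stated method; the bootstrap is this
package's choice.

## Elasticity observables

End-to-end distributions get a moment Gaussian fit plus a KS test against
that fitted normal (α = 0.01) so "Gaussian in this window" is assertable
rather than visual.  Pair-distance profiles average |r_ref − r_target| over
the ensemble frame by frame (reference defaults to residue 4, the conserved
isoleucine position).  Fractional extension uses contour length 0.4 nm per
residue.  Stiffness fits use the two-parameter model ΔG = a·f² + b — the
published analysis reports exactly a quadratic coefficient and an intercept —
with an optional linear term behind a flag for comparison.  The worm-like
chain force law is implemented in the standard Marko–Siggia interpolation
with the linear term x/L_c; the variant with x/L (which appears in some
write-ups but is not a consistent interpolation: it does not vanish at
x = 0) is available behind `as_printed=True`.

## Problem sizes and tolerances

Default study scale in the tests and the acceptance script: 5 sequences ×
5 forces (130…1300 kJ·mol⁻¹·nm⁻¹), 200 trajectories per ensemble,
10⁵ equilibration steps — the package's desk-scale default; the full 10⁴
ensembles are opt-in (`kinelastic study --full`).  Stochastic physics checks
(equipartition, ideal-chain ⟨R²⟩ = (N−1)⟨r²⟩, double-well occupancy,
Ornstein–Uhlenbeck relaxation, estimator recovery on the pulled 1-D harmonic
toy with exact ΔG = −F²/2k) assert agreement within 3 standard errors,
with standard errors estimated from block means where samples are
correlated.  Deterministic algebra (Hessian eigenvalues vs a
finite-difference oracle, rigid-body fits vs normal equations, quadratic
fits on exact points) is checked to 10⁻⁶ relative or better.

## Known limitations

* The quantitative link to all-atom energetics is out of reach by design;
  CG ΔG and stiffness values are model-specific.
* The 19-residue linker sequence is a synthetic stand-in honoring the
  documented positional constraints (Ile-4, Pro-8, Pro-14, ≥1 Asn, ≥1 Lys),
  not the real kinesin-2 sequence.
* The elastic-network benchmark depends on the unpublished r₀ and on
  implementation details of the original domain-finding tool (pair-potential
  variant, cluster growth order); exact parity is not guaranteed, which is
  why the benchmark sweeps r₀ and reports rather than asserts the published
  mode energies.
* The relaxation-work convention above is an interpretation; alternative
  conventions (e.g. treating relaxation via occupancy estimators only) would
  change reverse-work numbers but not the forward Jarzynski estimate.
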