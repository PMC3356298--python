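# Methods

## Scope and model

The package analyses the energetics of successive SN2 methyl transfers
from AdoMet to a target lysine in a SET-domain methyltransferase.  It
deliberately excludes the electronic-structure/MD engine that would
produce real trajectories: its inputs are (a) labeled snapshots of the
active-site subsystem, (b) umbrella-window time series of the reaction
coordinate R = r(C_M…S_δ) − r(C_M…N_ζ), and (c) per-step barrier
tables.  A synthetic-data module generates statistically controlled
stand-ins for (a) and (b) so every stage is testable at desk scale.

Units are global: Å, kcal/mol, degrees, K, with
k_B = 1.987204259 × 10⁻³ kcal mol⁻¹ K⁻¹.  The default temperature is
283.15 K, the simulation temperature of the system this pipeline was
built around.

## Reactive geometry

θ is the angle between the lone-pair direction on N_ζ and the C_M→S_δ
vector.  The lone pair is constructed geometrically as
u = −normalize(Σᵢ normalize(pᵢ − p_N)) over the nitrogen's three
substituents.  For an ideal sp³ nitrogen this is exactly the missing
tetrahedral vertex, and it degrades gracefully under distortion; a
planar nitrogen (bond-vector sum below 1e-8) is rejected as degenerate
rather than silently assigned a direction.  An electronically derived
lone pair would differ only for strongly pyramidalized or conjugated
nitrogens, outside this system's regime.

Histogram defaults are r ∈ [2, 6] Å in 0.05 Å bins and θ ∈ [0°, 180°]
in 5° bins — chosen to match the visual granularity of typical (r, θ)
occupancy maps for these systems, and overridable in the config.  Bins
are half-open [low, high) with the last bin closed; a value exactly on
an interior edge goes up.  Zero-count cells are masked (NaN), never
given a pseudo-count; the free-energy surface is
F = −k_B·T·ln(count/count_max), so the most-populated cell sits at
exactly 0.

The hydrogen-bond criterion (the source data report occupancies but no
cutoffs) is the common geometric one: donor…acceptor ≤ 3.5 Å and, when
a hydrogen is specified, D–H…A ≥ 120°; both are configurable.

## WHAM

The bias convention is w(R) = k(R − c)² with **no ½ prefactor** — the
CHARMM umbrella convention implied by force constants quoted in
kcal mol⁻¹ Å⁻².  Every entry point accepts `half_k=True` to reinterpret
constants under ½k(R − c)²; the two conventions are never mixed
silently (the synthetic generator and the solver take the flag
separately and the equivalence k ↔ ½(2k) is covered by a test).

The solver iterates the standard self-consistency equations

    P(b) = [Σᵢ nᵢ(b)] / [Σᵢ Nᵢ exp((fᵢ − wᵢ(b))/k_BT)]
    fᵢ   = −k_BT ln Σ_b P(b) exp(−wᵢ(b)/k_BT)

as a plain fixed point (no damping — window overlap at force constants
of 50–400 kcal mol⁻¹ Å⁻² converges in a few thousand iterations),
gauge-fixed at f₁ = 0, until max|Δfᵢ| < 1e-6 kcal/mol (cap 10⁵
iterations).  All exponentials are evaluated with log-sum-exp, so
arbitrarily stiff biases cannot overflow.  Non-convergence returns a
profile flagged `converged=False` plus a warning; it is never hidden.

The default analysis grid is R ∈ [−2.5, 2.5] Å at 0.05 Å.  For barrier
work the grid should span only the sampled reaction path (for the
bundled double wells, [−1.5, 1.3] Å): bins in the far tails receive a
handful of samples from the outermost windows and their free-energy
estimates are noisy enough to masquerade as spurious minima.  The
acceptance script and the recovery tests use the path-spanning grid for
this reason.

Barrier extraction reads the profile directly (no smoothing): the TS is
the highest defined bin having strictly lower defined bins on both
sides, the reactant value is the minimum over defined bins on the
reactant side (R < R_TS by the default orientation: methyl on the
donor sulfur means r_CS < r_CN, hence R < 0).  Masked interior bins are
skipped; a gap wider than 3 bins between reactant minimum and TS
triggers a data-quality warning.  Anchoring puts the reactant-region
minimum at 0; the barrier itself is anchor-independent.

The empirical correction step only *applies* a user-supplied ΔE(R)
table (monotone cubic/PCHIP through the knots, extrapolation forbidden,
re-anchored afterwards).  Deriving such a curve — comparing a
semi-empirical QM Hamiltonian against a higher-level reference on a
small donor/acceptor model — is out of scope, and the default curve is
identically zero.  A bootstrap-over-samples PMF uncertainty (50
resamples, seeded) ships as an optional diagnostic.

## Triplets and the specificity call

Two summaries are computed from per-step barriers and always reported
together, clearly labeled, because published numbers mix them:

* the **WT-referenced triplet**: element j = ΔF‡_j(enzyme) − ΔF‡₁(WT)
  (the form in which mutant triplets are usually printed);
* the **within-enzyme deltas**: ΔF‡_j − ΔF‡₁ of the same enzyme (the
  form figure captions quote, e.g. the +3.6 kcal/mol second step of
  F1209Y).

Classification uses the within-enzyme deltas — an enzyme blocks its own
ladder relative to its own first transfer — with a default threshold of
3.0 kcal/mol.  No numeric threshold is stated in the source analysis;
recomputing from the printed barriers, all three known calls
(WT → di, F1209Y → mono, Y1124F → tri) hold simultaneously exactly for
thresholds in (2.4, 3.6] kcal/mol, and 3.0 is the midpoint of that
band.  The band itself is exposed as a diagnostic
(`threshold_consistency_band`), so the sensitivity of a call to the
threshold is always inspectable.  A missing step (an enzyme simulated
for fewer than three transfers) is carried as an explicit marker,
printed as `x`; it never silently blocks or passes, and a call derived
from an incomplete ladder carries an `undetermined_beyond` flag.

## Synthetic data

**Potentials.**  The quartic double well is constructed from
U′(R) = c(R − R_a)(R − R_t)(R − R_b): given the two minima, the barrier
height B and the reactant–product offset ΔF_rp, the TS location R_t and
the scale c are fixed by a 1-D root find on the ratio of the two
antiderivative differences (division-free residual for stability at the
interval ends), making U(R_t) − U(R_a) = B exact to machine precision.
B = 0 or ΔF_rp ≥ B violates the stationary-point ordering and is
rejected.  A harmonic form U = (κ/2)R² and a clamped-Hermite piecewise
cubic through the three stationary points are also provided.

**Umbrella samples** are i.i.d. draws from the biased Boltzmann density
∝ exp(−[U(R) + k(R − c)²]/k_BT) by inverse-CDF lookup on a 4096-point
grid over the potential's declared range.  Compared with integrating
Langevin dynamics this hits the target distribution exactly, needs no
timestep or friction choices, and is bitwise reproducible from the
seed.  The cost is the absence of autocorrelation: real umbrella
windows have correlated samples, so real-data error bars would be wider
than the i.i.d. recovery tests suggest.  Window layout spans the two
minima with 20 evenly spaced centers; force constants follow
k = 50 + 2|U′| clipped to [50, 400] kcal mol⁻¹ Å⁻² — stiff where the
mean force would drag samples off-center, soft near stationary points
where soft restraints maximize neighbour overlap.

**Frame ensembles** draw r(C_M…N_ζ), r(C_M–S_δ) and θ from truncated
normals (r > 1.5 Å, θ ∈ [0°, 180°]; a truncation keeping < 1% of the
normal mass is rejected as infeasible) and build coordinates with a
collinear S–C–N attack axis, the three N_ζ substituents in an ideal
tetrahedral arrangement whose missing-vertex direction makes exactly
the drawn θ with C_M→S_δ, at a uniformly random azimuth (the θ
statistic is azimuth-invariant).  The master invariant — the geometry
stage returns every frame's drawn values to 1e-6 — is what makes the
generator a usable oracle.  Two presets ship: `reactive_wt_like`
(mean r 3.0 Å, sd 0.15 Å; mean θ 30°, sd 12°) and
`nonreactive_wt3_like` (mean r 4.5 Å, sd 0.25 Å; mean θ 70°, sd 35°).
The means are the reported ensemble averages for those regimes; the
spreads are this package's choice of a realistic width (the source
distributions are published only as plots), so tests against the
presets validate statistical machinery, not the published spreads.

What the synthetic ensembles do **not** emulate: a real active site
(only the S–CH₃ unit and the lysine head exist, no protein or water),
bond-length/angle fluctuations beyond the drawn coordinates, any r–θ
correlation, and sampling autocorrelation.  Passing tests therefore
demonstrate correctness of the estimators and calculus, not fidelity of
any MD engine.

## Problem sizes and numerics

Recovery tests use 20 windows × 5000 samples and 10⁴-frame ensembles —
sizes at which the estimators' statistical error (≲ 0.15 kcal/mol for a
13.4 kcal/mol barrier; ≲ 0.005 Å on a mean distance) sits comfortably
inside the tolerances being asserted.  Text outputs use shortest
round-trip float formatting, so write→read cycles and staged pipeline
runs are bit-for-bit identical to in-memory ones; window-metadata CSVs
are re-read with pandas' `round_trip` float parser for the same reason.
The pipeline manifest records config, seed, warnings and SHA-256
checksums of every file; identical config + seed reproduces the output
tree byte for byte.

## Known limitations

* WHAM is 1-D; angular or 2-D reaction coordinates are out of scope.
* The fixed-point iteration has no acceleration; extremely poor window
  overlap converges slowly (and warns) rather than failing fast.
* Barrier extraction quantizes the TS and minimum to bin centers; the
  induced bias is bounded by one cell's curvature error (about
  0.03 kcal/mol for the bundled wells at 0.05 Å bins) and is part of
  the recovery tolerances.
* `compute_geometry` trusts the role map; mis-assigned substituents
  produce a well-defined but chemically meaningless θ.
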