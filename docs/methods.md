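# Methods

## The model

`aedskit` implements accelerated enveloping distribution sampling (AEDS),
a reference-state free-energy method, at desk scale. N endstate
Hamiltonians H_i (in an alchemical setting: one per ligand) are combined
into a single reference Hamiltonian

    H_R(x) = −RT · ln Σ_i exp(−(H_i(x) − ΔF_i^R)/RT),

where the per-endstate energy offsets ΔF_i^R place all endstate minima at
a common level. At the optimal offsets — equal to the endstates'
free-energy differences — the reference ensemble samples every endstate
roughly equally, and a single simulation yields free energies for all
endstates at once through Zwanzig reweighting:

    ΔG_iR = −RT · ln ⟨ exp(−(H_i − H*)/RT) ⟩.

Because barriers between the endstates' basins can still frustrate
sampling, a harmonic boosting potential acts on H_R between two
thresholds E_min < E_max:

    H* = H_R                                          H_R ≤ E_min
    H* = H_R − (H_R − E_min)²/(2(E_max − E_min))      E_min < H_R ≤ E_max
    H* = (E_min + E_max)/2                            H_R > E_max.

The middle branch pulls energy maxima down without touching energies
below E_min; the upper branch is its C¹ continuation, so H* is continuous,
once differentiable and non-decreasing in H_R, and the force on the
coordinates is the weighted endstate force scaled by dH*/dH_R (zero above
E_max, where the landscape is flat). Energies are kJ·mol⁻¹ throughout,
with RT = 0.0083145 kJ·mol⁻¹·K⁻¹ × T (2.4944 kJ·mol⁻¹ at the default
300 K).

A deliberate property of this functional form is that a *slow orthogonal
degree of freedom* — one not alchemically transformed but coupled to the
endstates, such as a binding-site side-chain rotamer — is accelerated for
free: its barrier raises H_R into the boosted band, where the landscape is
flattened, even though no collective variable was ever declared.

## Toy systems and oracles

The `toys` module generates analytic stand-ins for a cavity-binding ligand
series. Each endstate is a sum of univariate terms over two coordinates:

* binding coordinate x: a harmonic well ½k_i(x − c_i)², with staggered
  centers (spacing 2.0, giving inter-state reference barriers of roughly
  5 RT so that unboosted crossings are rare but not impossible) and a
  per-endstate depth d_i that sets the relative binding strength. Depths
  default to U(−3, 3) kJ·mol⁻¹ from the generator seed — the few-kJ·mol⁻¹
  spread typical of a congeneric ligand series — or may be supplied
  explicitly (e.g. all-zero for a "solvent" stage).
* orthogonal coordinate φ: periodic in degrees with two metastable wells
  at 180° (trans) and −60° (gauche), the χ₁ convention of a valine
  rotamer. The double well is built from von Mises-shaped bumps,
  B·(1 − e^{κ(cos(φ−180°)−1)} − e^{κ(cos(φ+60°)−1)}) with κ = 6, so B is
  the barrier measured from an unpreferred well bottom. An
  endstate-specific tilt −ε·σ_w(φ) (a tanh switch that is ±1 except near
  the inter-well midpoints, sharpness 4) deepens one well by ε ≈ 2 RT
  (default 5 kJ·mol⁻¹) essentially without reshaping it, so well
  populations follow the two-state Boltzmann ratio. The deepest ("bulky")
  endstates prefer gauche, the rest trans.

A flat-bottom restraint on x (zero over the span of the endstate minima,
harmonic with k = 10 outside) is attached by default. It is the analogue
of weak binding-site restraints, and it also matters mechanically: above
E_max the boosted landscape is force-free, and the restraint — which acts
on the sampled Hamiltonian outside the boost — keeps the walker from
diffusing away during barrier crossings. Its energy is recorded per frame
and folded into the sampled energy (H* + V_restr) before reweighting;
free energies with and without the restraint agree after this correction.

Because every term is univariate, configuration integrals factorize and
the test oracle is 1-D adaptive quadrature (`scipy.integrate.quad`,
integrand referenced to its minimum, tolerances 1e-10): exact free
energies G_i = −RT ln Z_i and exact trans/gauche populations, the latter
with basins split at the potential maxima between the wells (falling back
to the geometric midpoints when no genuine maximum exists, e.g. at zero
barrier). Integrals are taken in the coordinates' native units (degrees
for φ); the additive constant this implies is common to all endstates and
cancels in every ΔG.

What the toys deliberately do not emulate: atomistic geometry, solvent,
many coupled degrees of freedom, and rugged energy landscapes. Passing
tests therefore demonstrate the correctness of the AEDS machinery —
estimators, search logic, boost mechanics — under controlled conditions,
not force-field accuracy on real proteins.

## Dynamics

Sampling uses overdamped (position) Langevin dynamics rather than an
inertial integrator with a thermostat: only ensemble correctness matters
for the method's logic, and transition statistics are used strictly
comparatively (boosted versus baseline at equal length), never as
absolute rates. The update is the Leimkuhler–Matthews averaged-noise
discretization

    x ← x + (Δt/γ)F(x) + √(2·RT·Δt/γ)·(ξ_n + ξ_{n+1})/2,

chosen over plain Euler–Maruyama because its configurational bias is
O(Δt²) — and exactly zero for the stationary variance of a harmonic well —
so sampled ensembles can be validated against quadrature at the 1% level
without resorting to impractically small steps. One seeded NumPy
generator drives each run; identical seed and configuration give an
identical trajectory, and seeds are recorded in trajectory metadata.

Friction is per coordinate (γ = 1 for x, γ = 0.0025 for φ in degrees),
set so both coordinates relax on comparable step counts despite their
hundredfold scale difference; Δt = 0.01 in reduced units keeps
kΔt/γ ≲ 0.35 on the stiffest toy wells. Divergence (non-finite energy or
coordinate) raises an error naming the step. Energies of all endstates,
H_R, H*, the boost ΔV = H* − H_R ≤ 0 and V_restr are recorded every
`stride` steps.

## Parameter search

The search interleaves 200-step simulation segments with parameter
updates computed over a trailing memory window whose length grows
linearly from 1 000 to 10 000 samples across the run (rapid fluctuation
early, stability late). Per update:

* E_max: windowed maximum of H_R over transition frames (frames where the
  lowest offset-corrected endstate changes);
* E_min: windowed mean of the per-endstate minima of H_i − ΔF_i^R,
  restricted to endstates actually visited in the window — a
  never-visited endstate's windowed minimum measures distance, not depth,
  and would poison the mean;
* offsets: windowed Zwanzig estimates ΔG_i relative to the sampled state,
  gauged to the anchor endstate.

Raw windowed estimates oscillate (and spike when a state goes unsampled),
so the values that actually drive the simulation are *filtered running
means*: the spike-filtered average (median ± 5 scaled MADs) of the
trailing half of the instantaneous series. Three further safeguards make
the adaptation stable: thresholds are committed only while E_min < E_max
(assignment flicker near minima can transiently invert them); offset
estimates are used only when their effective sample size
(Σu)²/Σu² ≥ 8, since exponential averages supported by a handful of
frames are biased without bound; and each update moves an offset by at
most 1 kJ·mol⁻¹, so a biased estimate cannot tilt the reference state
faster than sampling can respond. The boost is off until the first
consistent threshold pair exists. A search that never observes a
transition (all-floating mode, more than one endstate) fails with advice
to extend the run.

The intended two-stage protocol mirrors standard practice: an
all-floating search on the "solvent" stage fixes E_max/E_min and a first
offset set; an offsets-only search on the "bound" stage reuses the
thresholds. `update_offsets` applies the same windowed formula to a
finished production run to repair offsets a too-short search got wrong;
an endstate never supported by the ensemble keeps its previous offset
with a warning. Search convergence is flagged when E_max and E_min drift
by <1% over the trailing fifth of the trace. Standard errors quoted for
offsets in the tests come from independent replicate searches (block
estimates within one run underestimate the error when the run holds only
a few independent memory windows).

## Estimators and diagnostics

All free energies are computed against the boosted, restraint-corrected
sampled Hamiltonian H* + V_restr via log-sum-exp; ΔG of the sampled state
with respect to itself is identically zero, and pairwise ΔΔG are
antisymmetric by construction. An endstate with literally zero ensemble
weight returns +∞ with a warning. Standard errors come from independent
replicates (default four), with no within-run autocorrelation correction
(a documented limitation). Frames are assigned to the endstate minimizing
H_i − ΔF_i^R with ties broken toward the lowest index; the softer
Boltzmann-weight fractions count frames fractionally. The
contributing-frame diagnostic counts frames whose endstate-vs-reference
gap (against the boosted sampled energy, for consistency with the
sampling) lies below ΔG_iR + RT. Observable reweighting uses
self-normalized importance weights u_i ∝ exp(−(H_i − H*)/RT); applied to
well-membership indicators it yields per-endstate trans/gauche
populations. Screening ranks endstates by sampling fraction under
deliberately unequalized (solvent-stage) offsets.

Endstate subgrouping measures the pairwise similarity of endstates as the
Bhattacharyya coefficient between histograms of H_a and H_b conditioned
on the sampled endstate (averaged over sampling states, 40 shared bins),
then applies average-linkage clustering on 1 − similarity; the endstate
most similar to all others joins every group as the shared common member
so the groups' free energies can be combined on one scale. The default
of three groups with one shared member matches the subgrouping protocol
the benchmark predictions come from.

## Benchmark statistics

Predictions arrive as ΔΔG versus an arbitrary reference state and are
anchored to experiment by a single constant, shift = mean(exp − pred),
which zeroes the mean residual and costs one degree of freedom; the RMSE
therefore divides by n − 1. Slope and R² are ordinary least squares of
prediction on experiment without a dof correction — confirmed by
arithmetic on the packaged table's printed columns, which are rounded to
one decimal, so digit equality is asserted only at printed precision.
Experimental errors are carried but not propagated. The packaged CSV
holds the 11-ligand cavity-binder benchmark (experimental binding free
energies and three prediction sets: all endstates in one run, runs split
into similarity subgroups, and a run started from a displaced-helix
conformation).

## Problem sizes and numerical choices

Tests and the acceptance script use searches of 5–8 × 10⁴ steps,
productions of 4 replicates × 6–15 × 10⁴ steps, 10-seed comparative
sweeps of 3–4 × 10⁴ steps, and quadrature tolerances of 1e-10 — sizes
chosen so each pipeline stage is statistically resolved (replicate SEs of
a few tenths of kJ·mol⁻¹) on a single CPU. Orthogonal-well barriers are
6 kJ·mol⁻¹ (≈ 2.4 RT) for solvent-stage toys and 12 RT ≈ 30 kJ·mol⁻¹ for
the slow-dihedral analogue. Known limitations: windowed Zwanzig offset
estimates carry a finite-window bias of order the replicate scatter;
all-floating searches on systems with a severe orthogonal barrier can
settle on conditional (single-well) offsets — the same failure mode the
two-stage protocol and production-run refinement exist to repair; and
reported transition counts depend on the recording stride (fast
recrossings between strides are not counted).
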