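# Methods

## Scope and strategy

`ptse` implements the free-energy and transition-state-ensemble (TSE)
analysis chain used for enzymatic phosphoryl transfer — steered
nonequilibrium estimation, umbrella sampling with WHAM, committor
shooting, TS geometry, and Eyring kinetics — on a surrogate engine:
analytic energy surfaces with Langevin dynamics.  Production QM/MM data
for such a system require cluster-scale sampling of a solvated enzyme;
none of the headline enzyme numbers (e.g. barriers of 13–34 kcal/mol, or
TSE widths of 0.30/0.13 Å) can be reproduced at desk scale.  The package
therefore treats the *methods* as the deliverable and validates every
stage against a closed form that the surrogate admits exactly.  All
validation runs use reduced units (kT = 1, unit friction, unit length);
a physical mode (kcal/mol, Å, ps, K, k_B = 0.0019872041 kcal/mol/K)
is available throughout.

## Surrogate surfaces

Four families (`ptse.potentials`):

- `flat`, `harmonic` — oracles for equipartition, restrained-window
  moments, and zero-force limits.
- `double_well_1d` — quartic double well with configurable well
  positions, barrier height `h` (default 5 kT), linear well-to-well
  asymmetry, and an optional flat saddle plateau.
- `pt_surface_2d` — a two-coordinate model of the transfer over
  (d_leave, d_attack), written in s = d_leave − d_attack (the reaction
  coordinate ξ) and q = d_leave + d_attack.  Along s it is a flat-top
  double well: s is passed through the odd, monotone shrinkage
  g(s) = s − (L/2)·tanh(2s/L) before the quartic, so minima stay exactly
  at the configured wells while the saddle acquires a plateau of length
  scale `ts_flatness` = L.  Perpendicular to s, a harmonic valley in q
  (force constant 30, s-independent) is centered on q₀(s), which
  interpolates between the well value (4.4) and a saddle value that is
  smaller for `topology="tight"` (3.6) than for `"loose"` (5.2) —
  tight/loose thus shifts the saddle along the d₁+d₂ anti-diagonal, as a
  bond-order classification of the TS would.  Because the q-valley force
  constant does not depend on s, integrating q out contributes only a
  constant, and the exact potential of mean force along ξ *is* the
  s-profile (`analytic_rc_profile`).  This choice — rather than a sum of
  Morse bond terms — was made so that saddle flatness and topology are
  controlled directly and the RC marginal stays closed-form.

## Dynamics

`ptse.langevin` provides two schemes behind one batched propagator:

- `overdamped` (default for all oracle work): the Leimkuhler–Matthews
  discretization of dx = −∇V/γ dt + √(2kT/γ) dW, which averages the
  current and previous noise increment.  For a harmonic (restrained)
  coordinate its stationary variance is exact at any dt; plain
  Euler–Maruyama inflates it at first order in k·dt/γ, which measurably
  corrupts steered work distributions at the stiff k = 300 restraints
  used here.  Steering defaults keep k·dt/γ ≤ 0.075.
- `baoab` inertial splitting, with Maxwell–Boltzmann velocity draws
  (`draw_velocities`); used where velocities are meaningful.

Restraints act on the reaction coordinate: force −k(ξ(x) − λ)·∇ξ with a
static or per-step center schedule.  All stochastic operations take
explicit seeds; a batch keyed on the full seed tuple reproduces
bit-for-bit.  Walkers leaving the declared domain raise an integration
error with the step index (single-trajectory API) or are frozen,
flagged, and excluded with a warning (steered batches).

## Steered work and free-energy estimators

Work is accumulated per integrator step as the bias-energy change under
the center move at fixed configuration,
ΔW = ½k[(ξ − λ₁)² − (ξ − λ₀)²] — the discrete protocol work for which
the nonequilibrium work identity holds exactly for the chain
"move center, then update x".  (A trapezoid in −k(ξ−λ)dλ that uses the
post-step ξ folds the current noise increment into the work; against a
quadrature oracle for the exact biased ΔG this produced an O(v·dt)
deficit of ~0.1–0.2 kT per pulled length unit at k·dt/γ ≈ 0.1, so the
exact discrete form is used.)

Estimators (`ptse.fep`):

- `jarzynski_estimate` — G(λ) = −kT·ln⟨e^{−W/kT}⟩ via log-sum-exp;
  replicate-bootstrap standard errors (200 draws default, seeded);
  the Jensen sandwich min W ≤ Ĝ ≤ mean W holds pointwise by
  construction and is asserted in tests.
- `cumulant_estimate` — ⟨W⟩ − var(W)/2kT, exact for Gaussian work, used
  as a cross-check where exponential averaging is tail-limited.
- `combine_bidirectional` — the backward profile is reflected onto the
  forward axis; the additive anchor minimizes the integrated squared
  difference over the central half of the overlap window (for symmetric
  protocols the expected dissipation biases of the two directions cancel
  in this window average), and the junction is placed where the anchored
  curves are closest, so the output keeps each direction's low-bias
  initial segment.  The junction discontinuity is reported and can be
  enforced.  In the strongly dissipative regime the splice consistently
  beats both single-direction estimates; near equilibrium, where both
  inputs are noise-limited rather than bias-limited, it matches the
  better one up to noise.
- `staged_msmd` — the RC is split into contiguous stages (10 in the
  reference configuration); each stage starts from the `n_select` = 5
  lowest-work coarse trajectories at the stage entry, re-equilibrated
  under the static entry restraint, and per-stage exponential averages
  are concatenated with continuity shifts.  Re-seeding each stage resets
  the nonequilibrium lag, so per-stage dissipation (∝ stage length)
  replaces full-pull dissipation.  Stage boundary shifts accumulate the
  per-stage estimator noise as a random walk, so stages use many more
  replicates than the coarse pass (800 vs 50 in the validation runs) —
  stages are short, so this is cheap.
- `barrier_summary` — ΔG, Δ_fG‡, Δ_bG‡ from the two minima and the
  single interior maximum (prominence-filtered; non-single-barrier
  profiles raise an error listing the extrema).  The identity
  Δ_bG‡ = Δ_fG‡ − ΔG is enforced exactly.

## Umbrella sampling and WHAM

`run_umbrella` samples the whole ladder as one batch (one walker per
center), discards equilibration strictly by time, and flags windows
whose production mean is >3 SD off-center.  Window means and variances
were verified against direct quadrature of the restrained Boltzmann
density, including the k + V″ narrowing in the wells.

`wham_solve` is a from-scratch direct self-consistent iteration in log
space, converged when max |Δf_i| < 1e−6 (energy units), with gauge
invariance (constant added to all biases) verified to 1e−6 and an
optional tracked negative log-likelihood that decreases monotonically.
Defaults: bin width 0.01 reduced units (the k = 300 bias varies steeply
across a bin, so bins are kept well below the window width), 1e5
iteration cap.  A rough per-bin stderr (kT/√counts) is attached; for
barrier-level uncertainty the tests use a split-half estimate instead,
since window-to-window matching noise accumulates along the ladder like
a random walk.

## Committor and TSE

`grid_committor_study` batches the full protocol: per grid point,
`per_point` configurations from restrained equilibration at the anchor
(k = 300), then `n_shots` unrestrained shots each, absorbed at the basin
thresholds (defaulting to the well positions).  The reference protocol
is a 0.1-spaced grid over the TS region with 20 configurations and 10
shots per configuration; validation runs use 20 shots.  (The source
protocol's "11 points … every 0.1 Å from −0.6 to 0.6 Å" is internally
inconsistent — that range contains 13 points — so the grid is fully
configurable and the validation uses the stated range and spacing.)
Undecided shots (step budget exhausted) are excluded from the committor
denominator and reported.  `committor_curve` attaches 95% Wilson score
intervals.  `committor_closed_form_1d` is the overdamped oracle
p(ξ) = ∫exp(V/kT) between the absorbing boundaries, by adaptive
quadrature with overflow shifting; velocity randomization in the
overdamped scheme means an independent noise stream per shot, which has
the same stationary law as a Maxwell–Boltzmann redraw.

`define_tse` takes the committor band [0.4, 0.6] (symmetric about the
separatrix; the band is configurable) and reports the member set, its
ξ-range and width.  For the wide-vs-narrow contrast, the three
`ts_flatness` levels (0, 1, 3) were chosen from the *closed-form*
committor so that the analytic band widths (≈0.12, 0.23, 0.28) are
separated beyond the 0.05 grid quantization; the stochastic ordering
check then has margin rather than riding a single grid point.

## Geometry

Frames are role-labeled coordinate sets (`P_T`, `O_leaving`,
`O_attacking`, `O_nb1..3`, optional `Mg`, …).  The generator
(`make_pt_frames`) builds exact in-line geometries: leaving/attacking
oxygens on the x axis at the requested donor–acceptor distance (default
4.5 Å, the compressed active-site value at which transfer becomes
feasible), P placed to realize ξ exactly, and the non-bridging ring
tilted so the improper dihedral ζ equals 180° − pyramidalization exactly
(the tilt is solved with a root finder against the analyzer itself; the
analyzer is independently checked against a textbook torsion oracle).
ζ is the 4-atom torsion over (O_nb1, O_nb2, O_nb3, P_T), with the branch
fixed so a trigonal-planar PO₃ returns exactly 180°, reported in
[0°, 360°); the convention equals the negated textbook torsion modulo
360°.  Pauling bond orders n = exp((r0 − d)/b) use r0 = 1.7 Å,
b = 0.6 Å, τ = 0.1 (configurable; no canonical constants exist for the
surrogate), giving tight (Σn > 1+τ) / loose (< 1−τ) / synchronous.
Kabsch superposition enforces a proper rotation; the ensemble width is
the mean ± SD distance of the transferring P from its average position
across aligned frames; PCA is an eigendecomposition of the flattened
coordinates of a role subset, with rank reported for degenerate
ensembles.  For width comparisons the alignment uses the two bridging
oxygens plus Mg (placed at a fixed position relative to the
donor–acceptor axis precisely so that a non-collinear alignment anchor
exists); aligning on the P–O axis atoms alone is degenerate because they
are collinear by construction.

## Kinetics

`initial_rate` fits the largest prefix window of a product time course
whose quadratic-curvature t-statistic is insignificant at α = 0.05, then
divides the linear slope (± propagated SE) by the enzyme concentration.
`eyring_fit` regresses ln(k/T) on 1/T (unweighted by default, inverse-
variance weighting optional; whether the source analysis weighted is not
documented), with transmission coefficient 1 and
k_B = 1.380649e−23 J/K, h = 6.62607015e−34 J·s,
R = 1.98720425864083e−3 kcal/mol/K.  The forward model `eyring_rate`
makes the fit round-trip exact on noiseless input; the Monte-Carlo
recovery check uses a 3 SE band because the log-space estimator is
linear in the noise and hence exactly unbiased — a 2 SE z-band would
fail ~5% of seeds with nothing to detect.

## Validation conditions (tests/test_acceptance.py, scripts/acceptance.py)

All on one CPU, reduced units, overdamped dynamics; sizes were chosen so
the full suite runs in well under a minute of simulation time:

1. Jarzynski: 5 kT double well, v = 0.05, k = 300, 200 replicates,
   dt = 2.5e−4 → barrier within 0.5 kT (typical error ≈ 0.08–0.15 kT,
   dominated by stiff-spring smoothing ≈ V″/2k at the top), Jensen
   bounds everywhere.
2. Bidirectional: asymmetric well (Δ = 2 kT), v = 4.0, 50
   replicates/direction, dt = 6.25e−5 — strongly bias-dominated so the
   splice's advantage is structural; junction gap ≤ 0.2 kT.
3. Staged: v = 2.2 (single-pass max profile error > 1 kT at 50
   replicates), 10 stages × 800 replicates, 5-lowest-work selection →
   staged error ≤ 0.5 kT (typical 0.15–0.35 kT).
4. WHAM: ladder −1.6…1.6 step 0.1, k = 300, 60 time units production
   sampled every 2.5e−3 → RMS ≤ 0.15 kT (typical ≈ 0.04 kT); gauge
   invariance to 1e−6; barrier consistent with the Jarzynski estimate
   within combined (split-half + bootstrap) errors.
5. Committor: grid −0.6…0.6 step 0.1, 400 decided shots/point →
   p̂(saddle) ∈ [0.4, 0.6], max deviation from the closed form ≤ 0.1,
   isotonic monotonicity, symmetry within binomial error.
6. Wide-vs-narrow: pt_surface_2d, barrier 7 kT, wells ±1.2, flatness
   {0, 1, 3}, fixed seeds → TSE ξ-width non-decreasing in flatness and
   P-spread largest on the flattest surface.
7. Geometry: 1000 random frames vs brute-force vector oracles to 1e−9;
   Kabsch vs a rotation-grid + simplex brute force to 1e−6; planar PO₃
   → exactly 180°; PCA variance conservation to 1e−9.
8. Eyring: exact round trip at ΔH‡ = 15.3 kcal/mol,
   ΔS‡ = −5.7 cal/mol/K over 293–333 K; unbiased recovery at 5% noise.

## What the surrogate does and does not show

Passing these checks demonstrates that the estimators, the shooting
protocol, the TSE definition, and the geometry/kinetics analyses are
implemented correctly and behave as theory predicts on landscapes where
theory is exact.  It does not validate any statement about a real
enzyme: the surrogate has no solvent, no electronic structure, no
protein degrees of freedom, a one- or two-dimensional configuration
space, and overdamped dynamics with recrossing ignored (transmission
coefficient fixed at 1).  Quantities printed in reduced units (kT,
unit lengths) are not comparable in magnitude to kcal/mol or Å values
from the enzyme system; only the qualitative structure — e.g. that a
flatter saddle yields a wider committor-defined TSE and a larger
P-atom spread — transfers.

## Known limitations

- WHAM per-bin stderr ignores sample autocorrelation and inter-window
  matching noise; use split-half or repeated-seed estimates for
  barrier-level uncertainty.
- The bidirectional anchor assumes roughly symmetric protocols; with
  grossly asymmetric speeds or replicate counts the window-average
  anchor inherits the bias difference.
- First-passage absorption in the shooting stage has O(√dt) boundary
  overshoot bias; at the dt used it is well below the binomial noise.
- PDB output is limited to the format's 3 coordinate decimals; XYZ
  round-trips at 9 decimals.
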