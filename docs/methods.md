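# Methods

## Scope and model

`powderdyn` analyses the temperature dependence of atomic motion in
solid-state (powder) protein systems. The central observable is the
mean-square fluctuation of atom *i*,

    MSF_i = (1/N_F) Σ_t | x_i(t) − ⟨x_i⟩ |²   [Å²],

computed after each protein unit, frame by frame, has been rigid-body
superposed onto its own frame-0 structure using its heavy atoms. The mean
position ⟨x_i⟩ is the post-alignment average over the analysed window, so
MSF_i is a variance, not a deviation from the reference frame. Atomic
values are mass-averaged into residue and protein-unit values; the ensemble
value is the unweighted mean over units. Standard errors come from block
averaging: the trajectory is cut into 5 contiguous equal blocks (tail
remainder dropped), the MSF recomputed per block against the global frame-0
alignment reference, and SE = sd(blocks)/√n_blocks.

Two transition temperatures are extracted from temperature series:

* **T_low** — a change of slope between two harmonic (linear) regimes of
  MSF(T), with no loss of linearity. Located by an exhaustive two-segment
  breakpoint search below a 210 K cap, by default on log MSF (the semi-log
  plotting convention for the two sub-210 K fit lines), with a linear-space
  option.
* **T_D** (protein dynamical transition) — the onset of anharmonic motion.
  Determined two ways: (i) *calorimetrically*, as the intersection of the
  two free lines of a bilinear enthalpy fit, whose slope difference is the
  heat-capacity jump ΔC_p; (ii) *dynamically*, as the first temperature at
  which MSF persistently exceeds the extrapolated upper harmonic segment.

A powder at lower hydration is prepared by Metropolis water removal: a
water chosen uniformly at random is deleted with probability
min(1, e^(−βΔU)), ΔU = U(without) − U(with), so strongly bound waters
(ΔU > 0) are preferentially retained. The relaxation between removals is a
user-supplied hook (no-op by default); a pairwise Lennard-Jones + Coulomb
toy energy (10 Å cutoff, Lorentz–Berthelot mixing) is provided for
desk-scale runs. β defaults to 300 K.

## Numerical choices

* **Breakpoint candidates** are midpoints between consecutive data
  temperatures, each segment retaining ≥ 3 points; the data grids here are
  coarse (10 K), and a continuous optimiser would claim precision the data
  cannot support. SSE ties break toward the lowest candidate. The two
  segment lines are fit independently — continuity is *not* enforced —
  because the calorimetric T_D is defined by the intersection of two free
  lines; T_low uses the same convention for consistency.
* **Two-regime significance** is a single-vs-two-line F-test (4 vs 2
  parameters), **Bonferroni-corrected by the number of candidate
  breakpoints searched**. The uncorrected sup-F statistic of a breakpoint
  search is anti-conservative (its null distribution is not F); the
  correction restores family-wise type-I control at the stated α
  (α = 0.01 for the headline enthalpy transition, α = 0.05 for the
  descriptive per-residue slope test), at a negligible power cost for the
  clearly separated regimes studied here.
* **Onset persistence rule**: T_D-from-MSF requires the excess over the
  extrapolated harmonic line to exceed k_σ·max(fit residual σ, point error)
  at the onset temperature *and at every hotter temperature* (k_σ = 3).
  A single noisy point therefore cannot declare a transition — onset
  detection is genuinely delicate in weakly hydrated systems. A relative
  noise floor of 1e−9 of the data scale keeps exact (noise-free) inputs
  from triggering on rounding error.
* **Exact-data degeneracies**: when the single-line SSE is already at
  machine level the F-test returns p = 1; numerically identical slopes in
  the per-residue slope test likewise return p = 1.
* **Alignment** is unweighted over heavy atoms (mass enters only the MSF
  averaging); a mass-weighted fit is exposed as an option. Each unit is
  made whole across periodic boundaries (minimum image about its first
  atom) before fitting; solvent never enters the MSF. Degenerate
  (coincident/collinear) point sets raise rather than return an arbitrary
  rotation.
* **Units**: Å and Å² internally; GRO files (nm) are converted on read.
  Energies kJ/mol, k_B = 0.0083145 kJ/(mol·K), Coulomb constant
  1389.35 kJ·Å/(mol·e²).

## Synthetic study conditions

The generator module emulates the statistical structure of a hydrated
Trp-cage powder study so the full pipeline is testable without molecular
dynamics:

* MSF(T): intercept 0.02 Å², harmonic slopes 1×10⁻³ and 2×10⁻³ Å²/K hinged
  at t_low = 160 K, quadratic anharmonic excess a·(T − t_d)² above
  t_d = 223 K, 1% relative multiplicative Gaussian noise on a 100–300 K,
  10 K grid. The noise level reflects block errors at or below plotting
  symbol size; the slope ratio 2 matches the designed regime change. The
  anharmonic coefficient defaults to a = 1×10⁻³ Å²/K², chosen under the
  design constraint that the excess one grid step above t_d
  (≈ 0.05 Å², some 15% of the harmonic level) must clear the 3σ detection
  band at the design noise — a smaller coefficient produces a transition
  that is undetectable on a 10 K grid *by construction*, which would make
  the designed t_d meaningless as a recovery target.
* Enthalpy(T): continuous bilinear hinge at t_d with slopes C_p,low and
  C_p,high; additive Gaussian noise.
* Methyl-hydrogen MSF: amp·e^(rate·T) below t_low (amp = 0.02 Å²,
  rate = 0.012 K⁻¹), continued linearly (value- and slope-matched) above.
* Per-residue curves share t_low/t_d; the anharmonic amplitude scales
  linearly with hydrophilicity rank (hydrated mode) or hydrophobicity rank
  (dehydrated mode) over a 1–2× range, and the chain termini get a +0.5
  bonus reflecting their weaker bonding restraints.
* Trajectories: i.i.d. Gaussian displacements with per-axis variance
  target/3 about a reproducible random reference structure, optional
  two-site hopping (occupancy variance p(1−p)d²), and per-frame random
  whole-unit rigid motion that the alignment stage must remove.

**What passing tests do and do not show.** The generators produce
uncorrelated frames and exactly piecewise-linear/bilinear curves. Real
trajectories are time-correlated (block errors then exceed the i.i.d.
value), their anharmonic onset need not be quadratic, and their harmonic
regimes are only approximately linear. Recovery of the designed
temperatures therefore validates the estimators' correctness and
calibration, not their behaviour under model misfit beyond the mild
log-space curvature discussed next.

## Known limitations

* In log space, data that are *linear* in T have within-segment curvature;
  at 1% noise the per-seed T_low breakpoint then scatters by about one to
  two grid steps even though the 20-seed mean is accurate to ≈ 1.5 K. The
  linear-space option recovers the breakpoint within ±5 K in every seed
  under the same conditions and is what the generator/detector closure test
  asserts per-seed.
* For uncorrelated frames the block standard error estimates the error of
  the full-trajectory mean and is (to leading order) *invariant* to the
  number of blocks — block variance scales as n_blocks/N_F and is divided
  by n_blocks again. It shrinks as 1/√N_F. Only for time-correlated data
  does the choice of block length matter; the 5-block convention is kept
  as the field-standard default.
* The enthalpy fit reports slopes in the input's own units; no
  per-gram normalisation is applied.
* The dehydration toy energy is a single-site water model with truncated
  interactions; it orders binding strengths but is not a force field.
  Water insertion is not supported, only removal.
* Fixed-width PDB output clamps B-factors to the two-decimal field; GRO
  velocities, forces and triclinic boxes are out of scope (powder boxes
  are orthorhombic).
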