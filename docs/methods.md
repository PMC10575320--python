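# Methods

## Model

The chain is a homopolymer of N point monomers in continuous 3D space,
in reduced units (r0 = 1, S_LJ = 1, kB = 1).  Four potentials act:

| term | form | scale | reference geometry |
|---|---|---|---|
| bond | `log[1 − ((r−r0)/R)²]` | S_FENE = −(98/5)r0²R²/2 = −1.8 | r0 = 1, finite only for \|r−r0\| < R = 3/7 |
| pair | `4[(σ/r)¹² − (σ/r)⁶] − v_c` for r < r_c, else 0 | S_LJ = 1 | minimum at r0 (σ = 2^(−1/6)), cutoff r_c = 2.5σ |
| bend | `1 − cos(θ − θ0)` | S_θ = 200 | θ0 = 1.742 rad |
| torsion | `1 − cos(τ − τ0)` | S_τ ∈ [5, 25] | τ0 = 0.873 rad |

The shift `v_c = 4[(σ/r_c)¹² − (σ/r_c)⁶]` makes the pair potential
vanish continuously at the cutoff; it and S_FENE are derived quantities,
recomputed whenever σ, r_c, r0 or R change.

Two conventions had to be fixed where the verbal model description
leaves room:

* **Bending angle.**  θ is the angle between successive *bond vectors*
  (straight chain → θ = 0), not the interior angle at the middle
  monomer.  Only this reading is self-consistent: with θ0 = 1.742 it
  produces a compact helix whose LJ energy (−38.7 for the ideal N = 30
  helix) sets the energy scale on which the model's structural
  transitions actually occur, and whose thermally relaxed single helices
  have q ≈ 0.007 and two-helix bundles q ≈ 0.35 — the documented
  signatures of the two phases.  The interior-angle reading yields a
  loose helix with LJ ≈ −7.8 that cannot reach those energies.  The
  convention is switchable by constructing `ModelParameters` with
  `theta0 = π − 1.742`.
* **Dihedral sign.**  The torsion potential is chirally asymmetric, so a
  sign convention is mandatory: the standard atan2 dihedral is used,
  right-handed helices have τ > 0, and the reference helix is
  right-handed.

The LJ sums in the Hamiltonian and in the order parameter exclude bonded
pairs (|i−j| = 1), which interact through the bond potential alone; a
switch (`include_bonded_lj`) restores them for comparison.  The order
parameter `q = Σ_{|i−j|>6} v_LJ / Σ_{2≤|i−j|≤6} v_LJ` returns 0 by
convention when the denominator magnitude is below 1e−9 (extended
chains, N ≤ 7).

## Sampling

Each replica runs Metropolis updates with a mixture of four proposal
kinds (defaults: 70% single-monomer displacement with step uniform in
[−0.3, 0.3]³; 10% rigid displacement of the tail beyond a random pivot;
10% rigid rotation of the tail about an axis through the pivot
perpendicular to its two bonds; 10% rotation of the tail about the bond
entering the pivot, i.e. a pure dihedral twist; rotation angles uniform
in ±0.5 rad).  All proposals are symmetric; any proposal that pushes a
bond outside the finite FENE domain is rejected outright.  Energy
changes are scored incrementally — a displaced monomer rescores only the
terms that touch it, a rigidly moved tail rescores only the interaction
across the pivot — and a full recomputation at every exchange interval
bounds the accumulated drift (the test suite asserts agreement with full
recomputation to 1e−8).

The replica grid spans a geometric temperature ladder (successive
temperatures differ by a constant factor) times a ladder of torsion
scales.  Every `exchange_interval` sweeps (default 10) one exchange
round runs; rounds alternate between temperature-neighbour and
S_τ-neighbour pairs with even/odd pairing alternating per round.  For
the Hamiltonian axis the cross-energies needed by the acceptance rule
follow from the cached torsion term sums alone, since the Hamiltonians
differ only in S_τ.  Every thread deposits (E, q) once per sweep after
burn-in; one histogram deposit per sweep rather than per move keeps the
bin counts closer to independent.

Reproducibility: the whole grid is a deterministic function of
(schedule, seed).  Per-thread streams are split as
`SeedSequence(seed, spawn_key=(i_T, i_Sτ, block))`; exchange decisions
and initializers draw from their own spawned streams.  Threads execute
serially; the contract for any future process-level parallelism is
bitwise identity with the serial result.

All replicas start from the ideal helix (valid FENE geometry, fast
equilibration); a random-coil initializer exists for ergodicity
cross-checks.

## Reweighting

The multiple-histogram equations are iterated entirely in log space
(log-sum-exp), starting from Z_i = 1, until the maximum change of any
log Z_i falls below 1e−8 (configurable; hard cap 100,000 iterations).
The converged log g is gauge-fixed to 0 at the most-populated bin.
Histogram inefficiency weights are deliberately not applied — the
update uses raw counts M_i.  Threads with different S_τ sample different
Hamiltonians and are reweighted separately, one density of states per
S_τ.  The 2D density of states g(E, q) reuses the converged Z_i from the
1D solve on the marginals (the reweighting factors depend on E only),
which makes the q-marginal of g(E, q) consistent with the 1D g(E) by
construction.  Empty bins keep log g = −∞; nothing is interpolated at
the reweighting stage.

Canonical back-reweighting computes normalized bin weights
∝ exp(log g − βE), the mean energy, and the specific heat as the
centred finite difference of the mean energy over the temperature grid;
the fluctuation form (⟨E²⟩−⟨E⟩²)/T² is computed alongside and a warning
is raised if the two disagree beyond differencing error.

## Microcanonical analysis

S(E) = log g(E) is analyzed on the largest contiguous run of populated
bins, after dropping bins with fewer than `min_count` aggregate samples
(default 20; the simulation criteria use 100) and `edge_trim` = 2 edge
bins: the error of log g scales like the inverse square root of the bin
count and differentiation amplifies it.  One Savitzky–Golay pass
(window 51 bins, polynomial order 4 by default; the window auto-shrinks
on short supports, and near the edges scipy's polynomial edge fit is
used) produces the smoothed S and derivatives 1–4, all from the same
operator.

Detection rules, applied lowest order first, each candidate assigned to
exactly one order:

1. backbending interval of dS/dE (d²S/dE² > 0 somewhere), located at the
   maximum of d²S/dE² inside the interval;
2. local maximum of d²S/dE² that stays below zero;
3. positive local minimum of d³S/dE³ (inverted peak);
4. sub-zero local maximum of d⁴S/dE⁴.

"Approaching zero without crossing" is operationalized as the extremum
magnitude being below 0.9 of the local baseline magnitude (the median of
the channel over ±5 window-lengths, excluding the feature core).  The
prominence screen compares the extremum's height over that baseline with
3× the local median absolute deviation of the *median-detrended*
channel: detrending separates bin-scale statistical noise from the
smooth structure of the channel, so a broad genuine feature does not
inflate its own noise estimate — a global MAD (the first design tried)
fails on realistic curves because the channel magnitude varies by orders
of magnitude across the support.  Small floors tied to the channel and
dS/dE scales keep float-level ripples on analytically smooth curves from
registering.  A higher-order candidate within five windows of an
accepted lower-order record is discarded as the flank echo of the same
feature one derivative up; candidates within one window of the support
edge are not trusted.  Optionally (`beta_range`), candidates where the
microcanonical dS/dE lies outside the simulated inverse-temperature
ladder are excluded: the density of states is an extrapolation there.

The planted-transition fixture builds transition-free backbones from a
decaying-exponential d²S/dE² (so every derivative is monotone with the
physically expected sign, all approaching zero), plants a Gaussian
feature of relative amplitude 0.8 and width 3% of the grid span in the
defining channel, and integrates down to S.  On this suite the detector
attains 100% recall and order accuracy over orders 1–4 × 50 random
placements, and returns an empty list on transition-free input.

## Structural prevalence

p(E, q) normalizes g(E, q) by its own q-marginal, so every populated
energy slice sums to exactly 1; unpopulated cells are masked, never
zero-filled.  Cross-sections extract the nearest q bin to a requested
value and report the bin center actually used.

## Synthetic data and oracles

* The ideal helix is built by sequential internal-coordinate placement
  (all bonds r0, angles θ0, dihedrals τ0); bending and torsion terms
  vanish to 1e−10 and the construction round-trips through the
  geometry code exactly.  Note that the *strictly ideal* helix has
  q = 0 — its |i−j| > 6 pairs sit just beyond the LJ cutoff — while
  thermally relaxed single helices compress slightly and show
  q ≈ 0.005–0.01.
* The two-helix template places a second ideal-helix segment
  antiparallel to the first at contact spacing (lateral offset, axial
  shift and spin chosen by a coarse scan minimizing the inter-segment
  LJ energy subject to a bridgeable end gap), bridges the gap with 2–3
  interpolated turn monomers, and relaxes the assembly with a short
  very-low-temperature Metropolis run (local moves first, so the
  topology cannot be swung apart while the turn strain releases).  It
  lands at q ≈ 0.32–0.39 and is an annealing seed, not a ground-state
  claim.
* Enumerable finite-level systems provide the independent oracle for
  the reweighting stack: exact degeneracies, closed-form Z, mean energy
  and specific heat (verified against direct summation to 1e−12), and an
  exact multinomial canonical sampler.
* `study_grids()` exposes the full-scale schedule presets (n30_full:
  16 temperatures in [0.2, 1.6] × 10 torsion scales in [5, 14], one
  million sweeps; n40_full with S_τ ∈ [5, 25]) plus reduced and smoke
  presets sized for desk-scale work.

## Problem sizes used by the test suite

The simulation-level checks run on a reduced grid — N = 30, 16
temperatures × 4 torsion scales {5, 8, 12, 14}, 80,000 sweeps per
thread (20,000 discarded) — about five minutes of CPU; the acceptance
script's annealing target uses one 16-temperature column at S_τ = 8 with
25,000 sweeps.  These sizes resolve the phase structure (helix, bundle,
coil, and the prevalence ordering) but not the subtle higher-order
derivative signals, which at full scale require orders of magnitude more
sampling.

## Known limitations and observed behaviour

* **The low-energy landscape is richer than a two-phase
  helix/bundle picture.**  With the Hamiltonian exactly as specified,
  deep annealing at S_τ ≈ 5–12 finds *end-wrapped* compact bundles —
  two-helix bundles whose chain ends wrap around the partner segment,
  q ≈ 0.45–0.6 — at energies clearly below both the relaxed single
  helix and the clean antiparallel bundle (at S_τ = 8: wrapped ≈ −57,
  best clean bundle ≈ −51, single helix ≈ −44).  Consequently the
  dominant q bin of the lowest sampled energies depends on how deeply
  the sampler has annealed: short anneals report the single-helix bin
  (≈ 0.01) or the clean-bundle band (0.31–0.43), converged ones the
  wrapped band (0.45+).  The competition between these branches also
  produces backbending in dS/dE at reduced sampling, which masks the
  subtle second- to fourth-order signals of the helix↔bundle transition.
* Microcanonical transition energies from Savitzky–Golay derivatives
  shift by roughly a bin width under different window choices; the
  window is therefore recorded in every curves table.
* The sampler is serial; the full 160-thread grids are supported by
  configuration but take days of CPU at full sweep counts.
* No autocorrelation (inefficiency) weighting in the reweighting
  equations; with one deposit per sweep and dense exchange this is a
  second-order effect at the scales tested, but it biases nothing
  toward the truth — enumerable-system tests quantify the error of the
  implemented estimator only.
* Homopolymers only; no solvent, no sequence heterogeneity, no periodic
  boundaries.
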