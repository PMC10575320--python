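# helimc

Monte Carlo simulation and microcanonical analysis of a coarse-grained
helical homopolymer.

Semiflexible polymers whose local geometry favours a preferred bending
angle and a preferred (chiral) dihedral fold into helices, and — when the
chain is long enough and the torsion stiffness low enough — into bundles
of helical segments packed against each other.  `helimc` implements a
bead–spring model of this physics and the full statistical-mechanics
pipeline needed to map its structural transitions:

1. **Model.**  N identical monomers with a FENE bond potential
   (`v_FENE(r) = log[1 − ((r−r0)/R)²]`, r0 = 1, R = 3/7), a
   truncated-shifted Lennard-Jones pair potential between non-bonded
   monomers (σ = 2^(−1/6), r_c = 2.5σ), and cosine bending/torsion
   potentials `1 − cos(θ − θ0)` and `1 − cos(τ − τ0)` with θ0 = 1.742,
   τ0 = 0.873.  The Hamiltonian is

       H(X) = S_FENE Σ v_FENE + S_LJ Σ v_LJ + S_τ Σ v_tor + S_θ Σ v_bend

   with S_FENE = −(98/5)·r0²R²/2 = −1.8, S_LJ = 1, S_θ = 200, and the
   torsion scale S_τ as the control parameter for helix-segment
   stiffness.  A bundling order parameter
   `q = Σ_{|i−j|>6} v_LJ(r_ij) / Σ_{|i−j|≤6} v_LJ(r_ij)` separates single
   helices (q ≈ 0.01) from two-helix bundles (q ≈ 0.35).

2. **Sampling.**  Metropolis Monte Carlo with four update types (local
   displacement, rigid tail displacement, bend rotation, torsion
   rotation) on a two-dimensional replica grid: a geometric temperature
   ladder × a ladder of torsion scales, with replica exchange along both
   axes (`P = min(1, exp[β_i H_i(X_i) + β_j H_j(X_j) − β_i H_i(X_j) −
   β_j H_j(X_i)])`).  The hot inner loop is compiled with numba; a pure
   NumPy reference path is cross-checked in the test suite.

3. **Reweighting.**  Multiple-histogram reweighting (iterating
   `g(E) = Σ_i h_i(E) / Σ_i M_i Z_i⁻¹ e^{−β_i E}` and
   `Z_i = Σ_E g(E) e^{−β_i E}` in log space) combines the per-thread
   energy histograms into a density of states g(E) and a joint g(E, q),
   from which canonical curves (mean energy, specific heat) are
   recovered by back-reweighting.

4. **Microcanonical inflection-point analysis.**  The entropy
   S(E) = log g(E) and its first four derivatives are estimated in one
   Savitzky–Golay pass; an n-th order transition appears as a region of
   least sensitivity in the (n−1)-th derivative (backbending of dS/dE for
   first order, a sub-zero maximum of d²S/dE² for second, a positive
   minimum of d³S/dE³ for third, a sub-zero maximum of d⁴S/dE⁴ for
   fourth).  Candidates are screened by prominence against a locally
   estimated noise level and classified lowest order first.

5. **Structural prevalence.**  `p(E, q) = g(E, q)/g(E)` gives, per
   microcanonical energy slice, the normalized distribution of structure
   types over q — the map on which helix↔bundle coexistence and the
   entropic suppression of intermediate structures are read off.

## Worked example

A reduced end-to-end run (one torsion scale, 16 temperatures, shortened
sweeps) from Python:

```python
import numpy as np
from helimc import build_schedule, run_grid, wham, wham_2d, analyze_dos
from helimc.prevalence import prevalence_field

sched = build_schedule(
    n=30, t_min=0.2, t_max=1.6, n_temperatures=16,
    s_tau_min=8.0, s_tau_max=8.0, n_s_tau=1,
    sweeps=40_000, burn_in=10_000, seed=11,
)
grid = run_grid(sched)

dos, zset, iters = wham(grid.column(0))
counts = np.sum([h.counts for h in grid.column(0)], axis=0)
curves, transitions = analyze_dos(dos, counts=counts, min_count=100,
                                  beta_range=(1/1.6, 1/0.2))
field = prevalence_field(wham_2d(grid.joint_column(0)))

rows = np.flatnonzero(field.column_populated())
j = np.argmax(field.p[rows[0]])
print("lowest sampled E bin:", field.energies[rows[0]])
print("its dominant q bin:", field.q_values[j])
for r in transitions:
    print(f"order-{r.order} transition at E = {r.energy:.1f}")
```

On the seed shown this prints

```
lowest sampled E bin: -52.95
its dominant q bin: 0.45000000000000007
order-1 transition at E = -45.8
```

meaning the lowest energies reached by this anneal are occupied by
compact two-helix structures whose long-range/short-range LJ ratio is
q ≈ 0.45 — a bundle whose chain ends have begun to wrap around the
partner segment (clean antiparallel bundles sit near q ≈ 0.35, single
helices near q ≈ 0.01).  The single backbending ("order-1") record
reflects the competition between the helix and folded branches at this
sampling depth, not a converged first-order transition; resolving the
subtle higher-order derivative signals requires substantially longer
sampling (see `docs/methods.md`).

The same pipeline from the shell:

```bash
helimc run --config run.yaml --out outdir      # simulate + reweight + analyze + prevalence
helimc simulate --config run.yaml --out outdir # histograms only
helimc reweight --histograms outdir --s-tau 8 --out dos.tsv
helimc analyze --dos dos.tsv --window 51 --order 4 --out curves.tsv transitions.json
helimc prevalence --dos2d dos2d.tsv --out prevalence.tsv
helimc fixtures --make helix --out helix.xyz
```

The full-scale study grids (160 threads for N=30: 16 temperatures in
[0.2, 1.6] × 10 torsion scales in [5, 14]; the N=40 analogue spans
S_τ ∈ [5, 25]) are available as presets
(`helimc.fixtures.study_grids()`), but runs at that scale take days of
CPU time and are not exercised by the test suite.

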