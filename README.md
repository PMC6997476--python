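# torsearch

Conformer search for flexible acyclic molecules by combined **systematic**
and **stochastic (Monte Carlo)** exploration of torsional space, plus the
**multi-structural rovibrational partition functions** (MS-HO, MS-QH,
MS-T(C)) evaluated over the located ensemble.

## The problem

A flexible chain molecule with *t* rotatable bonds (an n-alcohol, say) has
conformers — local minima of the potential energy surface — scattered over
the *t*-dimensional torus of dihedral angles **Φ** = (ϕ₁, …, ϕ_t).
Thermochemistry at elevated temperatures needs *all* of them, not just the
most stable few, because each well contributes a Boltzmann-weighted
rigid-rotor–harmonic-oscillator term to the partition function

Q^MS-QH = Σ_j w_j · Q_j^rot · Q_j^QH · e^(−U_j / k_B T),

where the sum runs over distinguishable structures that are not
conformational enantiomers, w_j = 2 when conformer *j* has a distinct
mirror image (torsions −**Φ**) and 1 when it is its own, U_j is its energy
relative to the global minimum, Q_j^rot the classical nonlinear-top
rotational partition function and Q_j^QH the harmonic vibrational function
with every frequency scaled by λ^ZPE. Per-torsion hindered-rotor factors
f_{j,η} (supplied by the caller) turn Q^MS-QH into the torsionally
anharmonic Q^MS-T(C).

The search proceeds in two phases:

1. **Systematic** — the Cartesian product of chemically intuitive angles
   per torsion (anti/gauche±: {180°, 60°, 300°} for sp³ chains), K₁ = Π P_τ
   guesses; with a molecular plane of symmetry only one representative of
   each {**Φ**, −**Φ**} pair is optimized, (K₁+1)/2 guesses.
2. **Stochastic** — batches of uniform random torsional points; a point
   falling inside the exclusion hypercube (half-edge *d* per torsion,
   circular metric) of any previously stored point is skipped, so the
   algorithm never revisits explored territory.

Every guess must pass a *connectivity test* (covalent-radius adjacency
matrix equal to the reference) and the *similarity test* before it is
optimized; every optimized structure must pass connectivity, a *redundancy
test* (not a duplicate of a known conformer) and a *Hessian test* (all
3N−6 frequencies real) — in that order, so no Hessian is ever computed for
a duplicate.

Electronic-structure surfaces are abstracted behind a small backend
contract (energy / gradient / Hessian / optimize, kcal/mol and Å); bundled
analytic toy surfaces with fully prescribed torsional profiles make the
whole pipeline runnable and testable offline, and an adapter hook is
provided for external programs.

## Worked example

```bash
python examples/two_phase_search.py
```

```
after systematic phase: [60.0, 180.0, 300.0]
after stochastic phase: [60.0, 91.0, 180.0, 300.0]

 t  K1  K1_star  J1  K2  K2_star  J2  J_LL
 1   3        3   3 150       21   1     4
```

The toy surface hides a narrow extra well near 95° between the intuitive
positions. The systematic phase (3 guesses, all accepted, 3 conformers)
cannot see it; the Monte Carlo phase generated 150 points of which 21
escaped all exclusion hypercubes and became trials, and exactly one relaxed
into the hidden well (J₂ = 1). K₁*/K₂* ≤ K₁/K₂ and the stored-pool identity
P = K₁* + K₂* + J hold throughout.

`python examples/conformer_populations.py` continues from a finished search
to populations: on the 3×3-well surface the reduced ensemble has J = 5
conformers whose weights sum to the 9 wells, χ_j sums to 1 at every
temperature, and Q^MS-QH/Q^1W-QH → 9 at high temperature — the single-well
approximation misses nearly an order of magnitude.

A thin CLI wraps the same library (`torsearch search --config run.yaml
--seed 1`, plus `systematic`, `stochastic`, `thermo`, `report`); every run
writes its conformer table (TSV), efficiency table, XYZ trajectory, event
log, JSON checkpoint and a metadata file with the config hash and seed, and
identical seed + config reproduce every output byte for byte.

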