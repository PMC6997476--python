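# Methods

## Torsional representation

A conformation is identified with its vector of target dihedral angles
**Φ** ∈ [0, 360)^t, measured with the IUPAC sign convention and stored
normalized to [0, 360). The conformational enantiomer of **Φ** is −**Φ**,
i.e. each angle replaced by 360 − ϕ; this operator is an involution and is
the basis of both the plane-of-symmetry pool reduction and the enantiomer
weights w_j ∈ {1, 2}. All angle comparisons (similarity, redundancy,
duplicate matching) use the circular distance min(|Δ|, 360 − |Δ|), so
355° and 5° are 10° apart; a linear difference would open artificial gaps
at the 0/360 seam.

Geometries are built from a Gaussian-style Z-matrix by the standard
sequential natural-extension construction; target torsions are named
dihedral variables, each of which must occupy exactly one dihedral slot
(an ambiguous declaration is a startup error, because the torsional point
of a geometry would be undefined). Non-target internal coordinates stay
frozen at their template values when building guesses; optimization then
relaxes *all* Cartesian degrees of freedom.

## Screening

* **Connectivity**: adjacency matrices from the covalent-radius rule
  — bonded iff r_ij < k_bond (R_i + R_j), Cordero radii, k_bond = 1.3 by
  default. The rule is deliberately simple; it only needs to distinguish
  "same bonding pattern as the reference" from clashes and rearrangements,
  and atoms never permute within a run, so element-wise matrix equality
  suffices (no graph isomorphism).
* **Similarity**: a guess is rejected iff some stored point's hypercube
  (half-edge d per torsion) contains it in *every* coordinate. During the
  systematic phase only equilibria are screened against — the
  preconditioned grid is spaced (120° for threefold lists) so its own
  hypercubes at the default d = 30° cannot overlap. The stochastic phase
  screens against the full stored pool (trials ∪ equilibria), since a
  random point can land in the influence region of an earlier trial.
* **Redundancy**: an optimized point duplicates a known conformer when
  every torsion is within eps_red; default eps_red = 3°, above optimizer
  convergence noise and far below the 120° well spacing. A strict
  inequality test would be meaningless in floating point.
* **Hessian**: the Cartesian Hessian is mass-weighted, the 6 rigid modes
  (5 for linear geometries, detected by a principal moment below 1e−6
  amu·Å²) are projected out with an orthonormalized translation/rotation
  basis, and the structure is accepted iff every remaining wavenumber
  exceeds −eps_freq (default 5 cm⁻¹, absorbing finite-difference noise).
  The battery order connectivity → redundancy → Hessian guarantees the
  expensive step never runs for duplicates or broken geometries.

## Search bookkeeping

Counters follow the taxonomy K₁/K₁* (systematic generated/accepted),
K₂/K₂* (stochastic, every generated point counted whether accepted or
not), J conformers, P = K₁* + K₂* + J stored points; the identity is
asserted after every event and the full event log allows exact replay.
Because the raw product Π P_τ and the enantiomer-reduced count are both
useful, the state exposes `K1_full` and `K1` (the guesses actually
generated). A trial is stored *before* optimization, so a failed or
non-convergent optimization still blocks its region from re-sampling; it
simply contributes no conformer.

Stochastic batches each carry their own cycle count and d, and batch b
draws from a generator seeded `seed + b`: a run checkpointed at a batch
boundary resumes bit-identically, and the whole run is reproducible from
(config, seed). An optional no-new-conformer-for-M-cycles early stop is
off by default, since no principled M exists a priori.

With a plane of symmetry the search keeps the lexicographically smaller
member of each {Φ, −Φ} grid pair (a deterministic, arbitrary tie-break)
and `expand_enantiomers` regenerates the mirror structures afterwards
(reflected Cartesians, identical energies, frequencies and moments).
The multi-structural sums expect this *reduced* ensemble: a conformer
with a distinct mirror image carries w = 2. Running the engine without
the symmetry flag yields both members explicitly; such an ensemble
should not be fed to the weighted sums without de-duplication, as the
mirror wells would be counted twice.

## Potential-energy backends

The backend contract fixes units (kcal/mol, Å) and four capabilities
(energy, gradient, Hessian, optimize). Local optimization is
quasi-Newton (BFGS via scipy) on all 3N Cartesian coordinates with the
backend's analytic gradient; convergence means max |∇| < 1e−6 kcal/mol/Å.
Rigid-body translations/rotations are flat directions and are left free.
Hessians default to central finite differences of the gradient (step
1e−4 Å), symmetrized as (H + Hᵀ)/2.

The bundled toy surface ties a chain template together with harmonic
restraints on every bond (300 kcal/mol/Å²), bending angle
(100 kcal/mol/rad²) and non-target dihedral (20·(1 − cos Δ) kcal/mol),
while each target torsion carries a prescribed periodic profile: cosine
terms a(1 + cos(nϕ − δ)), optional narrow von-Mises-shaped wells
−D·exp(κ(cos Δ − 1)) for planting minima between the intuitive positions,
and optional pairwise coupling cosines. Because restraints and torsional
terms act on disjoint internal coordinates, the minima of the full
Cartesian surface coincide exactly with the minima of the torsional
profile — which is what lets exhaustive grid relaxation of the profile
serve as an independent oracle for the search. With all cosine phases at
0/180° and no localized wells the surface is mirror-symmetric,
V(Φ) = V(−Φ), matching the symmetry the enantiomer machinery exploits.

The external-program adapter renders a text template, shells out and
parses stdout for an energy; it exists as an integration point and ships
no quantum-chemistry driver. Gradients/Hessians of external codes are
out of scope.

## Partition functions

Constants are CODATA (via scipy.constants), centralized in one module;
energies kcal/mol, frequencies cm⁻¹, moments amu·Å². The rotational
function is the classical nonlinear-top expression
(8π²/σ_rot)(k_BT/2πħ²)^{3/2}√(I₁I₂I₃); linear tops raise an explicit
unsupported error. Vibrational functions are ZPE-referenced products
∏ 1/(1 − e^{−βħω}), evaluated with expm1 for overflow safety; the
quasi-harmonic variant scales every frequency by λ^ZPE (so
E^QH = λ^ZPE·E^HO exactly, and λ^ZPE = 1 collapses QH to HO). The
multi-structural sums are accumulated in log space with a max-shift to
keep extreme temperatures finite.

Two printed-formula choices deserve note. The population weight uses
e^{−U_j/k_BT} — the only sign consistent with the Boltzmann factors of
the MS sums and with χ_j = w_j e^{−G_j/k_BT}/Σ under
G_j = U_j − k_BT ln(Q_j^rot Q_j^QH). And the torsional-anharmonic sum
folds in both w_j and e^{−βU_j}, so that all-unity anharmonicity factors
recover the MS-QH sum exactly; the per-torsion factors f_{j,η}
themselves are accepted as inputs (defaulting to 1), their internal
hindered-rotor construction being outside this package's scope.
Electronic degeneracy is assumed 1 (closed-shell systems).

`min_conformers_for_fraction` sorts conformers by decreasing χ_j (stable
sort; ties broken by input order) and reports the smallest head of the
list reaching the threshold, split by search provenance
(systematic/stochastic) — the quantity that tells you whether the Monte
Carlo phase mattered thermochemically at a given temperature.

## What the toy fixtures do and do not show

The fixture library (single well; 3×3 and 27-well threefold grids; the
off-grid-well surface; the shared-basin surface; phase-shifted "high
level" copies) emulates the *topology* of chain-molecule torsional
surfaces: multiple wells at intuitive positions, occasional minima away
from them, enantiomeric symmetry, basins that merge. It does not emulate
electronic-structure realism: well depths are arbitrary, frequencies
come from the restraint force constants rather than a real force field,
and connectivity failures are rarer than for a crowded all-atom
molecule. Green tests therefore certify the search logic, bookkeeping
and thermochemical algebra — not the chemistry of any particular
molecule; on real systems the backend quality decides what is found.

Problem sizes used in the default test run were chosen to keep the suite
quick while still exercising every path: toy chains of 4–9 atoms,
torsional dimensions t ≤ 3 for oracle-equivalence checks (the dense-grid
oracle grows as 36^t), stochastic batches of 20–150 cycles for discovery
tests and 2×500 cheap-optimizer cycles for the bookkeeping fuzz.

## Known limitations

* Purely torsional identity: duplicate detection never uses RMSD or atom
  permutations, so symmetric rotor tops (e.g. methyl) must simply be left
  out of the target-torsion list.
* No ring-puckering or cyclic-molecule conformers; no parallel execution.
* Rotational symmetry numbers σ_rot are user-supplied (default 1); no
  point-group detection.
* The bond-perception rule is distance-only; exotic bonding (bridged,
  metallic) would need a custom k_bond or a user-supplied reference
  adjacency.
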