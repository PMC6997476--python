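"""Model chain molecules and toy potential-energy surfaces.

The chain generator emulates the torsional skeleton of linear alcohols
and alkanes: a backbone of sp3 carbons ending in a hydroxyl (or methyl)
group, with exactly ``n_torsions`` declared target torsions along the
backbone.  Hydrogens and methyl rotors are deliberately absent: their
internal rotation only generates indistinguishable structures, so they
would never appear in the target-torsion list anyway, and omitting them
keeps the Cartesian problem small.

The toy-surface factory functions pair such templates with fully
prescribed torsional profiles (well positions and depths known in closed
form), which is what makes exhaustive grid oracles possible in tests.
"""

from __future__ import annotations

import numpy as np

from .molmodel import ZMatrix, ZMatrixRow
from .pes_backends import CosineTerm, LocalWellTerm, ToyTorsionalPES

# representative single-bond geometry parameters
CC_BOND = 1.53
CO_BOND = 1.43
OH_BOND = 0.96
CCC_ANGLE = 112.0
CCO_ANGLE = 108.0
COH_ANGLE = 107.0


def make_chain_fixture(n_torsions: int, terminal: str = "OH") -> ZMatrix:
    """An alkanol-like (or alkane-like) chain with ``n_torsions`` targets.

    ``terminal="OH"`` ends the chain C...C-O-H (the last torsion rotates
    the hydroxyl hydrogen, as in the n-alcohol series); ``terminal="CH3"``
    produces an all-carbon chain.  Torsions are named ``tor1..torN`` in
    backbone order and every one is a declared target.
    """
    if n_torsions < 1:
        raise ValueError("need at least one target torsion")
    if terminal not in ("OH", "CH3"):
        raise ValueError(f"unknown terminal {terminal!r}")
    n_atoms = n_torsions + 3
    if terminal == "OH":
        elements = ["C"] * (n_atoms - 2) + ["O", "H"]
    else:
        elements = ["C"] * n_atoms

    def geom(i):  # bond length / angle for atom i bonded to atom i-1
        if elements[i] == "H":
            return OH_BOND, COH_ANGLE
        if elements[i] == "O" or elements[i - 1] == "O":
            return CO_BOND, CCO_ANGLE
        return CC_BOND, CCC_ANGLE

    rows = [ZMatrixRow(elements[0])]
    for i in range(1, n_atoms):
        bond, angle = geom(i)
        if i == 1:
            rows.append(ZMatrixRow(elements[1], 0, bond))
        elif i == 2:
            rows.append(ZMatrixRow(elements[2], 1, bond, 0, angle))
        else:
            rows.append(ZMatrixRow(elements[i], i - 1, bond, i - 2, angle,
                                   i - 3, f"tor{i - 2}"))
    names = [f"tor{k}" for k in range(1, n_torsions + 1)]
    return ZMatrix(rows, names, np.full(n_torsions, 180.0))


# ---------------------------------------------------------------------------
# toy-surface library
# ---------------------------------------------------------------------------

def single_well_pes(amplitude: float = 2.0) -> ToyTorsionalPES:
    """One torsion, one minimum (at 180 degrees): V = a (1 + cos phi)."""
    zm = make_chain_fixture(1, "CH3")
    return ToyTorsionalPES(zm, [CosineTerm(0, amplitude, multiplicity=1)])


def threefold_pes(n_torsions: int, amplitude: float = 2.0,
                  terminal: str = "OH") -> ToyTorsionalPES:
    """Independent threefold profiles: 3^t wells at {60, 180, 300}^t.

    Mirror-symmetric (V(phi) = V(-phi)), as for a chain with a plane of
    symmetry; with t = 2 this is the 3x3 grid of wells, with t = 3 the
    27-well surface.
    """
    zm = make_chain_fixture(n_torsions, terminal)
    terms = [CosineTerm(tau, amplitude * (1.0 + 0.15 * tau)) for tau in range(n_torsions)]
    return ToyTorsionalPES(zm, terms)


def off_grid_pes(amplitude: float = 3.0, well_deg: float = 95.0,
                 depth: float = 2.5, kappa: float = 60.0) -> ToyTorsionalPES:
    """Threefold background plus a narrow extra well near ``well_deg``.

    The extra well's basin (roughly +-15 degrees) contains none of the
    preconditioned angles {60, 180, 300}, so a systematic search seeded
    with those misses it and only random sampling can land inside.
    """
    zm = make_chain_fixture(1, "OH")
    return ToyTorsionalPES(zm, [CosineTerm(0, amplitude),
                                LocalWellTerm(0, depth, well_deg, kappa)])


def shared_basin_pes(amplitude: float = 2.0) -> ToyTorsionalPES:
    """A single anti well at 180: every gauche guess slides into it, so two
    preconditioned guesses share one basin (redundancy-test exercise)."""
    zm = make_chain_fixture(1, "OH")
    return ToyTorsionalPES(zm, [CosineTerm(0, amplitude, multiplicity=1, phase_deg=180.0)])


def perturbed_pes(base: ToyTorsionalPES, phase_shift_deg: float = 8.0,
                  amplitude_scale: float = 1.15) -> ToyTorsionalPES:
    """A 'higher-level' variant of a toy surface: same topology, wells
    shifted by a few degrees and rescaled.  Used to exercise the
    low-level -> high-level refinement path, where each low-level minimum
    re-optimized on the refined surface should map onto a distinct
    refined minimum."""
    terms = []
    for t in base.terms:
        if isinstance(t, CosineTerm):
            terms.append(CosineTerm(t.torsion, t.amplitude * amplitude_scale,
                                    t.multiplicity,
                                    t.phase_deg + t.multiplicity * phase_shift_deg))
        elif isinstance(t, LocalWellTerm):
            terms.append(LocalWellTerm(t.torsion, t.depth * amplitude_scale,
                                       t.center_deg + phase_shift_deg, t.kappa))
        else:
            terms.append(t)
    return ToyTorsionalPES(base.zm, terms, base.k_bond, base.k_angle, base.k_dihedral)
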