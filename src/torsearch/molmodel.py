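"""Molecular representation in torsional internal coordinates.

A flexible acyclic molecule is described by a Z-matrix whose dihedral
entries include ``t`` named *target torsions*.  Every search object lives
in the t-dimensional torsional space: a conformation is a point
``phi = (phi_1, ..., phi_t)`` of dihedral angles in degrees, normalised
to [0, 360).  This module provides

* the :class:`ZMatrix` container and the internal -> Cartesian build,
* dihedral measurement on Cartesian geometries,
* torsional-point arithmetic (normalisation, circular distance, the
  conformational-enantiomer operator ``phi -> -phi``),
* covalent-radius bond perception (adjacency matrix) and
* principal moments of inertia.

Dihedral angles follow the IUPAC sign convention and are stored in
[0, 360), so the enantiomer of an angle ``phi`` is ``360 - phi``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants


# ---------------------------------------------------------------------------
# torsional-point arithmetic
# ---------------------------------------------------------------------------

def normalize_angles(angles) -> np.ndarray:
    """Map angles (degrees) onto [0, 360)."""
    return np.asarray(angles, dtype=float) % 360.0


def enantiomer(phi) -> np.ndarray:
    """Torsions of the conformational enantiomer: each angle ``phi`` becomes
    ``(360 - phi) mod 360``.  Applying the operator twice is the identity."""
    return (360.0 - np.asarray(phi, dtype=float)) % 360.0


def circular_distance(a, b) -> np.ndarray | float:
    """Shortest angular separation on the circle, in [0, 180] degrees.

    Works elementwise on arrays; scalars in, scalar out.
    """
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    out = np.minimum(d, 360.0 - d)
    return float(out) if out.ndim == 0 else out


def is_self_enantiomeric(phi, tol: float = 3.0) -> bool:
    """True when ``phi`` and its enantiomer coincide within ``tol`` degrees
    on every torsion (the conformer has no distinct mirror image)."""
    phi = normalize_angles(phi)
    return bool(np.all(circular_distance(phi, enantiomer(phi)) <= tol))


# ---------------------------------------------------------------------------
# Z-matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZMatrixRow:
    """One atom line of a Z-matrix.

    References are 0-based indices of previously defined atoms.  The
    dihedral value may be a float (frozen coordinate) or the name of a
    declared target torsion.
    """

    element: str
    bond_ref: int | None = None
    bond_length: float | None = None      # Angstrom
    angle_ref: int | None = None
    angle: float | None = None            # degrees, in (0, 180)
    dihedral_ref: int | None = None
    dihedral: float | str | None = None   # degrees or torsion-variable name


@dataclass
class ZMatrix:
    """Internal-coordinate template with declared target torsions.

    ``torsion_names`` is the ordered list of the ``t`` target torsions;
    each name must appear in exactly one dihedral slot so the torsional
    point of any geometry built from the template is defined without
    ambiguity.  All other internal coordinates are frozen at the values
    stored in the rows.
    """

    rows: list[ZMatrixRow]
    torsion_names: list[str] = field(default_factory=list)
    reference_torsions: np.ndarray | None = None  # phi of the reference geometry

    def __post_init__(self) -> None:
        self._torsion_atom: dict[str, int] = {}
        for i, row in enumerate(self.rows):
            if row.bond_ref is not None and row.bond_ref >= i:
                raise ValueError(f"row {i}: bond reference {row.bond_ref} is not a previous atom")
            if row.angle_ref is not None and row.angle_ref >= i:
                raise ValueError(f"row {i}: angle reference {row.angle_ref} is not a previous atom")
            if row.dihedral_ref is not None and row.dihedral_ref >= i:
                raise ValueError(f"row {i}: dihedral reference {row.dihedral_ref} is not a previous atom")
            if isinstance(row.dihedral, str):
                name = row.dihedral
                if name in self._torsion_atom:
                    raise ValueError(
                        f"torsion variable {name!r} is attached to atoms "
                        f"{self._torsion_atom[name]} and {i}: target torsions must be "
                        "defined unambiguously (exactly one dihedral slot each)"
                    )
                self._torsion_atom[name] = i
        missing = [n for n in self.torsion_names if n not in self._torsion_atom]
        if missing:
            raise ValueError(f"declared target torsions never used in a dihedral slot: {missing}")
        unused = [n for n in self._torsion_atom if n not in self.torsion_names]
        if unused:
            raise ValueError(f"dihedral variables {unused} are not declared as target torsions")
        if self.n_torsions < 1:
            raise ValueError("a ZMatrix must declare at least one target torsion")
        if self.reference_torsions is None:
            self.reference_torsions = np.full(self.n_torsions, 180.0)
        self.reference_torsions = normalize_angles(self.reference_torsions)
        if len(self.reference_torsions) != self.n_torsions:
            raise ValueError("reference torsions length does not match torsion count")

    # -- basic queries ------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.rows)

    @property
    def n_torsions(self) -> int:
        return len(self.torsion_names)

    @property
    def elements(self) -> list[str]:
        return [r.element for r in self.rows]

    @property
    def masses(self) -> np.ndarray:
        return np.array([constants.atomic_mass(r.element) for r in self.rows])

    def torsion_atom_index(self, name: str) -> int:
        """Index of the atom whose dihedral entry carries torsion ``name``."""
        return self._torsion_atom[name]

    def torsion_quadruple(self, name: str) -> tuple[int, int, int, int]:
        """Atom quadruple (i, j, k, l) whose dihedral is the named torsion."""
        i = self._torsion_atom[name]
        row = self.rows[i]
        return (i, row.bond_ref, row.angle_ref, row.dihedral_ref)


# ---------------------------------------------------------------------------
# internal <-> Cartesian
# ---------------------------------------------------------------------------

class DegenerateFrameError(ValueError):
    """Raised when reference atoms are colinear and no dihedral frame exists."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-10:
        raise DegenerateFrameError("zero-length reference vector")
    return v / n


def _place_atom(p_d: np.ndarray, p_a: np.ndarray, p_b: np.ndarray,
                r: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    """Position an atom at distance ``r`` from ``p_b``, angle ``theta`` with
    ``p_a`` and dihedral ``phi`` (new-atom, p_b, p_a, p_d quadruple).

    Natural-extension construction: the new position is expressed in the
    local frame of the last three reference atoms.
    """
    theta = np.deg2rad(theta_deg)
    phi = np.deg2rad(phi_deg)
    local = np.array([
        -r * np.cos(theta),
        r * np.sin(theta) * np.cos(phi),
        -r * np.sin(theta) * np.sin(phi),
    ])
    bc = _unit(p_b - p_a)
    n = np.cross(p_a - p_d, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise DegenerateFrameError("colinear reference atoms: dihedral frame undefined")
    n /= nn
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return p_b + frame @ local


def zmatrix_to_cartesian(zm: ZMatrix, phi=None) -> np.ndarray:
    """Build the N x 3 Cartesian geometry (Angstrom) at torsional point ``phi``.

    ``phi`` supplies the ``t`` target torsions in the order of
    ``zm.torsion_names``; omitted, the reference torsions are used.  All
    other internal coordinates take their frozen values.
    """
    if phi is None:
        phi = zm.reference_torsions
    phi = normalize_angles(phi)
    if len(phi) != zm.n_torsions:
        raise ValueError(f"expected {zm.n_torsions} torsions, got {len(phi)}")
    values = {name: phi[i] for i, name in enumerate(zm.torsion_names)}

    coords = np.zeros((zm.n_atoms, 3))
    for i, row in enumerate(zm.rows):
        if i == 0:
            continue
        if row.bond_length is None or row.bond_length <= 0:
            raise ValueError(f"row {i}: bond length must be positive")
        if i == 1:
            coords[1] = [row.bond_length, 0.0, 0.0]
            continue
        if not (0.0 < row.angle < 180.0):
            raise DegenerateFrameError(f"row {i}: bending angle {row.angle} is colinear")
        if i == 2:
            # in the xy-plane relative to atoms bond_ref / angle_ref
            b, a = coords[row.bond_ref], coords[row.angle_ref]
            theta = np.deg2rad(row.angle)
            d = _unit(a - b)
            perp = np.array([-d[1], d[0], 0.0])
            perp = _unit(perp)
            # vector b->new makes the bending angle theta with b->a
            coords[2] = b + row.bond_length * (np.cos(theta) * d + np.sin(theta) * perp)
            continue
        dih = values[row.dihedral] if isinstance(row.dihedral, str) else row.dihedral
        coords[i] = _place_atom(
            coords[row.dihedral_ref], coords[row.angle_ref], coords[row.bond_ref],
            row.bond_length, row.angle, dih,
        )
    return coords


def measure_dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed IUPAC dihedral of the quadruple (p0, p1, p2, p3), degrees in [0, 360)."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateFrameError("colinear atoms: dihedral undefined")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m @ n2
    return float(np.rad2deg(np.arctan2(y, x)) % 360.0)


def measure_torsions(cart: np.ndarray, zm: ZMatrix) -> np.ndarray:
    """Target torsions of a Cartesian geometry, in Z-matrix declaration order."""
    cart = np.asarray(cart, dtype=float)
    if cart.shape != (zm.n_atoms, 3):
        raise ValueError(f"expected geometry of shape {(zm.n_atoms, 3)}, got {cart.shape}")
    out = np.empty(zm.n_torsions)
    for k, name in enumerate(zm.torsion_names):
        i, j, a, d = zm.torsion_quadruple(name)
        # dihedral entry of atom i is the angle over (i, bond, angle, dihedral refs)
        out[k] = measure_dihedral(cart[i], cart[j], cart[a], cart[d])
    return out


# ---------------------------------------------------------------------------
# bond perception
# ---------------------------------------------------------------------------

def perceive_adjacency(cart: np.ndarray, elements: list[str], k_bond: float = 1.3) -> np.ndarray:
    """0/1 adjacency matrix from the covalent-radius criterion.

    Atoms i and j are bonded when their distance is below
    ``k_bond * (R_i + R_j)`` with Cordero covalent radii.  The matrix is
    symmetric with a zero diagonal and, for a chemically intact geometry,
    does not depend on the torsional angles.
    """
    cart = np.asarray(cart, dtype=float)
    radii = np.array([constants.covalent_radius(e) for e in elements])
    diff = cart[:, None, :] - cart[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    cutoff = k_bond * (radii[:, None] + radii[None, :])
    adj = (dist < cutoff).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return adj


# ---------------------------------------------------------------------------
# inertia
# ---------------------------------------------------------------------------

def principal_moments(cart: np.ndarray, masses) -> np.ndarray:
    """Principal moments of inertia about the centre of mass.

    Returns the three eigenvalues of the inertia tensor in amu*Angstrom^2,
    sorted ascending; tiny negative round-off is clipped to zero.
    """
    cart = np.asarray(cart, dtype=float)
    masses = np.asarray(masses, dtype=float)
    com = (masses[:, None] * cart).sum(axis=0) / masses.sum()
    r = cart - com
    r2 = (r ** 2).sum(axis=1)
    # inertia tensor: I = sum_a m_a (r^2 delta - r r^T)
    tensor = (masses[:, None, None] * (
        r2[:, None, None] * np.eye(3)[None, :, :]
        - r[:, :, None] * r[:, None, :]
    )).sum(axis=0)
    vals = np.linalg.eigvalsh(tensor)
    return np.clip(vals, 0.0, None)
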