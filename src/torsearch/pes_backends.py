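"""Potential-energy-surface backends.

The conformer search only needs four capabilities from an electronic
structure provider: single-point energies, gradients, Hessians and a
local geometry optimisation.  :class:`Backend` fixes that contract with
units of kcal/mol and Angstrom at the boundary, so the engine is agnostic
to whether the surface comes from the bundled analytic toy potentials,
or from an external quantum-chemistry program wrapped by
:class:`ExternalProgramBackend`.

The toy surface :class:`ToyTorsionalPES` is an analytic molecular
mechanics-style potential tied to a :class:`~torsearch.molmodel.ZMatrix`:
every bond, bending angle and non-target dihedral of the template is
harmonically restrained at its reference value, while each target torsion
carries a user-chosen periodic profile (cosine series, optionally sharp
localised wells and pairwise couplings).  Because the restraints and the
torsional terms act on disjoint internal coordinates, the minima of the
full Cartesian surface sit exactly at the minima of the torsional profile
— which makes the toy surface an ideal, fully controllable stand-in for a
low-level ab initio surface when exercising the search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .molmodel import ZMatrix, zmatrix_to_cartesian


class CapabilityError(NotImplementedError):
    """A backend was asked for a capability it does not provide."""


class Backend:
    """Abstract PES provider.  Energies kcal/mol, lengths Angstrom."""

    capabilities: frozenset[str] = frozenset()

    def energy(self, cart: np.ndarray) -> float:
        raise CapabilityError(f"{type(self).__name__} does not provide energies")

    def gradient(self, cart: np.ndarray) -> np.ndarray:
        raise CapabilityError(f"{type(self).__name__} does not provide gradients")

    def hessian(self, cart: np.ndarray) -> np.ndarray:
        """3N x 3N Cartesian Hessian; default central finite differences of
        the gradient (step 1e-4 Angstrom), symmetrised."""
        if "gradient" not in self.capabilities:
            raise CapabilityError(f"{type(self).__name__} cannot form a Hessian without gradients")
        cart = np.asarray(cart, dtype=float)
        n = cart.size
        h = 1e-4
        H = np.empty((n, n))
        flat = cart.ravel().copy()
        for i in range(n):
            x = flat.copy(); x[i] += h
            gp = self.gradient(x.reshape(cart.shape)).ravel()
            x = flat.copy(); x[i] -= h
            gm = self.gradient(x.reshape(cart.shape)).ravel()
            H[i] = (gp - gm) / (2.0 * h)
        return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# internal-coordinate derivatives
# ---------------------------------------------------------------------------

def _bond_grad(cart, i, j):
    v = cart[i] - cart[j]
    r = np.linalg.norm(v)
    u = v / r
    g = np.zeros_like(cart)
    g[i] = u
    g[j] = -u
    return r, g


def _angle_grad(cart, i, j, k):
    """Bending angle i-j-k (radians) and its Cartesian gradient."""
    u = cart[i] - cart[j]
    v = cart[k] - cart[j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / nu, v / nv
    c = np.clip(uh @ vh, -1.0, 1.0)
    s = np.sqrt(max(1.0 - c * c, 1e-14))
    theta = np.arccos(c)
    gi = (c * uh - vh) / (nu * s)
    gk = (c * vh - uh) / (nv * s)
    g = np.zeros_like(cart)
    g[i] = gi
    g[k] = gk
    g[j] = -(gi + gk)
    return theta, g


def _dihedral_grad(cart, i, j, k, l):
    """IUPAC dihedral over (i, j, k, l) in radians and its gradient."""
    b1 = cart[j] - cart[i]
    b2 = cart[k] - cart[j]
    b3 = cart[l] - cart[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    m = np.cross(n1, b2 / nb2)
    x = n1 @ n2
    y = m @ n2
    phi = np.arctan2(y, x)

    sq1 = n1 @ n1
    sq2 = n2 @ n2
    # signs fixed by the IUPAC convention used in measure_dihedral
    gi = nb2 / sq1 * n1
    gl = -nb2 / sq2 * n2
    c1 = (b1 @ b2) / (nb2 ** 2)
    c3 = (b3 @ b2) / (nb2 ** 2)
    gj = -(1.0 + c1) * gi + c3 * gl
    gk = c1 * gi - (1.0 + c3) * gl
    g = np.zeros_like(cart)
    g[i], g[j], g[k], g[l] = gi, gj, gk, gl
    return phi, g


# ---------------------------------------------------------------------------
# torsional profile terms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CosineTerm:
    """``a * (1 + cos(n*phi - phase))`` acting on one target torsion.

    The default (n=3, phase 0) has minima at 60/180/300 degrees — the
    gauche+/anti/gauche- wells of an sp3 chain torsion.
    """
    torsion: int
    amplitude: float          # kcal/mol
    multiplicity: int = 3
    phase_deg: float = 0.0

    def value(self, phi: np.ndarray) -> float:
        x = self.multiplicity * phi[self.torsion] - np.deg2rad(self.phase_deg)
        return self.amplitude * (1.0 + np.cos(x))

    def dvalue(self, phi: np.ndarray) -> np.ndarray:
        d = np.zeros_like(phi)
        x = self.multiplicity * phi[self.torsion] - np.deg2rad(self.phase_deg)
        d[self.torsion] = -self.amplitude * self.multiplicity * np.sin(x)
        return d


@dataclass(frozen=True)
class LocalWellTerm:
    """A narrow periodic well ``-depth * exp(kappa*(cos(phi-center)-1))``.

    Used to plant minima away from the chemically intuitive positions
    (the "off-grid well" fixtures); width ~ 1/sqrt(kappa) radians.
    """
    torsion: int
    depth: float              # kcal/mol, > 0 digs a well
    center_deg: float
    kappa: float = 60.0

    def value(self, phi: np.ndarray) -> float:
        d = phi[self.torsion] - np.deg2rad(self.center_deg)
        return -self.depth * np.exp(self.kappa * (np.cos(d) - 1.0))

    def dvalue(self, phi: np.ndarray) -> np.ndarray:
        g = np.zeros_like(phi)
        d = phi[self.torsion] - np.deg2rad(self.center_deg)
        g[self.torsion] = self.depth * self.kappa * np.sin(d) * np.exp(self.kappa * (np.cos(d) - 1.0))
        return g


@dataclass(frozen=True)
class CouplingTerm:
    """Pairwise torsional coupling ``a * cos(n1*phi_t1 + n2*phi_t2 - phase)``."""
    torsion_a: int
    torsion_b: int
    amplitude: float
    mult_a: int = 1
    mult_b: int = 1
    phase_deg: float = 0.0

    def value(self, phi: np.ndarray) -> float:
        x = self.mult_a * phi[self.torsion_a] + self.mult_b * phi[self.torsion_b] - np.deg2rad(self.phase_deg)
        return self.amplitude * np.cos(x)

    def dvalue(self, phi: np.ndarray) -> np.ndarray:
        g = np.zeros_like(phi)
        x = self.mult_a * phi[self.torsion_a] + self.mult_b * phi[self.torsion_b] - np.deg2rad(self.phase_deg)
        s = -self.amplitude * np.sin(x)
        g[self.torsion_a] += s * self.mult_a
        g[self.torsion_b] += s * self.mult_b
        return g


class ToyTorsionalPES(Backend):
    """Analytic Cartesian PES whose torsional profile is fully prescribed.

    Parameters
    ----------
    zm:
        Template defining the skeleton and the target torsions.
    terms:
        Torsional terms (cosine series / local wells / pairwise couplings)
        over the target torsions, indexed by position in ``zm.torsion_names``.
    k_bond, k_angle, k_dihedral:
        Restraint force constants (kcal/mol/A^2, kcal/mol/rad^2 and the
        amplitude of the periodic ``k*(1-cos(phi-phi0))`` dihedral
        restraint) holding all non-target internal coordinates at their
        Z-matrix reference values.

    When every term is a :class:`CosineTerm` with phase 0 or 180 degrees
    and there are no local wells or couplings with other phases, the
    surface is mirror-symmetric: V(phi) = V(-phi).
    """

    capabilities = frozenset({"energy", "gradient", "hessian", "optimize"})

    def __init__(self, zm: ZMatrix, terms, k_bond: float = 300.0,
                 k_angle: float = 100.0, k_dihedral: float = 20.0):
        self.zm = zm
        self.terms = list(terms)
        self.k_bond = k_bond
        self.k_angle = k_angle
        self.k_dihedral = k_dihedral
        for t in self.terms:
            for attr in ("torsion", "torsion_a", "torsion_b"):
                idx = getattr(t, attr, None)
                if idx is not None and not (0 <= idx < zm.n_torsions):
                    raise ValueError(f"term {t} references torsion index {idx} out of range")
        # restraint targets from the template
        self._bonds = []       # (i, j, r0)
        self._angles = []      # (i, j, k, theta0_rad)
        self._dihedrals = []   # (i, j, k, l, phi0_rad)  -- non-target only
        self._target_quads = [zm.torsion_quadruple(n) for n in zm.torsion_names]
        for i, row in enumerate(zm.rows):
            if row.bond_ref is not None:
                self._bonds.append((i, row.bond_ref, row.bond_length))
            if row.angle_ref is not None:
                self._angles.append((i, row.bond_ref, row.angle_ref, np.deg2rad(row.angle)))
            if row.dihedral_ref is not None and not isinstance(row.dihedral, str):
                self._dihedrals.append((i, row.bond_ref, row.angle_ref, row.dihedral_ref,
                                        np.deg2rad(row.dihedral)))

    # -- torsion-space view -------------------------------------------------
    def torsional_potential(self, phi_deg) -> float:
        """Profile V(phi) of the target torsions alone (restraints at rest)."""
        phi = np.deg2rad(np.asarray(phi_deg, dtype=float))
        return float(sum(t.value(phi) for t in self.terms))

    def torsional_potential_grid(self, grids) -> np.ndarray:
        """Vectorised evaluation on a meshgrid-style stack of angle arrays."""
        shape = np.broadcast(*[np.asarray(g) for g in grids]).shape if len(grids) > 1 else np.asarray(grids[0]).shape
        out = np.zeros(shape)
        rad = [np.deg2rad(np.asarray(g, dtype=float)) for g in grids]

        for t in self.terms:
            if isinstance(t, CosineTerm):
                out = out + t.amplitude * (1.0 + np.cos(t.multiplicity * rad[t.torsion] - np.deg2rad(t.phase_deg)))
            elif isinstance(t, LocalWellTerm):
                d = rad[t.torsion] - np.deg2rad(t.center_deg)
                out = out - t.depth * np.exp(t.kappa * (np.cos(d) - 1.0))
            elif isinstance(t, CouplingTerm):
                x = t.mult_a * rad[t.torsion_a] + t.mult_b * rad[t.torsion_b] - np.deg2rad(t.phase_deg)
                out = out + t.amplitude * np.cos(x)
            else:  # pragma: no cover - user-supplied exotic terms
                it = np.nditer(out, flags=["multi_index"], op_flags=["readwrite"])
                for v in it:
                    phi = np.array([r[it.multi_index] for r in rad])
                    v[...] += t.value(phi)
        return out

    # -- Cartesian view -----------------------------------------------------
    def _energy_gradient(self, cart: np.ndarray):
        cart = np.asarray(cart, dtype=float).reshape(self.zm.n_atoms, 3)
        e = 0.0
        g = np.zeros_like(cart)
        for i, j, r0 in self._bonds:
            r, dg = _bond_grad(cart, i, j)
            e += self.k_bond * (r - r0) ** 2
            g += 2.0 * self.k_bond * (r - r0) * dg
        for i, j, k, th0 in self._angles:
            th, dg = _angle_grad(cart, i, j, k)
            e += self.k_angle * (th - th0) ** 2
            g += 2.0 * self.k_angle * (th - th0) * dg
        for i, j, k, l, p0 in self._dihedrals:
            p, dg = _dihedral_grad(cart, i, j, k, l)
            e += self.k_dihedral * (1.0 - np.cos(p - p0))
            g += self.k_dihedral * np.sin(p - p0) * dg
        # target torsions
        phi = np.empty(self.zm.n_torsions)
        dphi = []
        for idx, (i, j, k, l) in enumerate(self._target_quads):
            p, dg = _dihedral_grad(cart, i, j, k, l)
            phi[idx] = p
            dphi.append(dg)
        for t in self.terms:
            e += t.value(phi)
            dv = t.dvalue(phi)
            for idx in np.nonzero(dv)[0]:
                g += dv[idx] * dphi[idx]
        return float(e), g

    def energy(self, cart: np.ndarray) -> float:
        return self._energy_gradient(cart)[0]

    def gradient(self, cart: np.ndarray) -> np.ndarray:
        return self._energy_gradient(cart)[1]


class QuadraticBackend(Backend):
    """V = 0.5 (x-x0)^T K (x-x0): a harmonic well with a known Hessian."""

    capabilities = frozenset({"energy", "gradient", "hessian"})

    def __init__(self, x0: np.ndarray, K: np.ndarray):
        self.x0 = np.asarray(x0, dtype=float).ravel()
        self.K = np.asarray(K, dtype=float)

    def energy(self, cart):
        d = np.asarray(cart, dtype=float).ravel() - self.x0
        return float(0.5 * d @ self.K @ d)

    def gradient(self, cart):
        cart = np.asarray(cart, dtype=float)
        d = cart.ravel() - self.x0
        return (self.K @ d).reshape(cart.shape)

    def hessian(self, cart):
        return self.K.copy()


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

@dataclass
class OptimizationResult:
    cart: np.ndarray
    energy: float
    converged: bool
    n_iter: int
    max_grad: float


def optimize(backend: Backend, cart: np.ndarray, grad_tol: float = 1e-6,
             max_steps: int = 2000) -> OptimizationResult:
    """Unconstrained local minimisation of all Cartesian degrees of freedom.

    Quasi-Newton (BFGS) with the backend's analytic gradient; converged
    when the largest gradient component falls below ``grad_tol``
    (kcal/mol/Angstrom).  Rigid translations/rotations are flat
    directions of every physical PES and are simply left free.
    """
    if "gradient" not in backend.capabilities:
        raise CapabilityError(f"{type(backend).__name__} cannot optimise without gradients")
    cart = np.asarray(cart, dtype=float)
    shape = cart.shape

    def f(x):
        return backend.energy(x.reshape(shape))

    def jac(x):
        return backend.gradient(x.reshape(shape)).ravel()

    res = minimize(f, cart.ravel(), jac=jac, method="BFGS",
                   options={"gtol": grad_tol, "maxiter": max_steps, "norm": np.inf})
    out = res.x.reshape(shape)
    max_grad = float(np.max(np.abs(jac(res.x))))
    return OptimizationResult(cart=out, energy=float(res.fun),
                              converged=bool(max_grad < grad_tol),
                              n_iter=int(res.nit), max_grad=max_grad)


# ---------------------------------------------------------------------------
# external-program adapter
# ---------------------------------------------------------------------------

class ExternalParseError(RuntimeError):
    def __init__(self, message: str, raw_output: str):
        super().__init__(f"{message}\n--- raw output ---\n{raw_output}")
        self.raw_output = raw_output


@dataclass
class ExternalProgramBackend(Backend):
    """Adapter hook for an external electronic-structure program.

    ``template`` is a format string receiving ``natoms``, ``elements`` and
    ``xyz_block``; the rendered input is passed to ``command`` (a list,
    run via subprocess) and ``parser`` extracts the energy in kcal/mol
    from the program's stdout.  Only single-point energies are exposed;
    gradients/Hessians of real quantum-chemistry codes are deliberately
    outside this package.
    """

    command: list[str]
    template: str
    parser: "callable"
    elements: list[str] | None = None
    capabilities: frozenset = field(default=frozenset({"energy"}))

    def render_input(self, cart: np.ndarray) -> str:
        cart = np.asarray(cart, dtype=float)
        elements = self.elements or ["X"] * len(cart)
        xyz = "\n".join(
            f"{el} {x:.10f} {y:.10f} {z:.10f}" for el, (x, y, z) in zip(elements, cart)
        )
        return self.template.format(natoms=len(cart), elements=" ".join(elements), xyz_block=xyz)

    def energy(self, cart: np.ndarray) -> float:
        import subprocess

        rendered = self.render_input(cart)
        proc = subprocess.run(self.command, input=rendered, capture_output=True,
                              text=True)
        if proc.returncode != 0:
            raise ExternalParseError(
                f"external program exited with status {proc.returncode}", proc.stdout + proc.stderr)
        try:
            return float(self.parser(proc.stdout))
        except ExternalParseError:
            raise
        except Exception as exc:
            raise ExternalParseError(f"could not parse program output: {exc}", proc.stdout) from exc


def build_reference_geometry(zm: ZMatrix) -> np.ndarray:
    """Cartesian reference geometry of the template at its declared torsions."""
    return zmatrix_to_cartesian(zm, zm.reference_torsions)
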