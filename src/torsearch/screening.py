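"""Acceptance tests applied to guess and optimized geometries.

A guess torsional point must pass two tests before it becomes a trial
geometry: the *connectivity test* (its adjacency matrix equals that of
the reference geometry, which rejects strained or rearranged structures)
and the *similarity test* (it lies outside the exclusion hypercube of
half-edge ``d`` around every stored point, so the same region of
torsional space is never visited twice).

An optimized geometry must pass three, in a fixed order chosen so that
the expensive step runs last: connectivity, then the *redundancy test*
(it coincides with no known conformer), and only then the *Hessian test*
(all 3N-6 vibrational frequencies real, i.e. a true minimum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants
from .molmodel import circular_distance, principal_moments


@dataclass(frozen=True)
class TestReport:
    test_name: str   # connectivity | similarity | redundancy | hessian
    passed: bool
    detail: str = ""

    def __post_init__(self):
        if not self.passed and not self.detail:
            raise ValueError("a failing TestReport must carry a reason")

    def __bool__(self) -> bool:  # allows `if report:` in the engine
        return self.passed


# ---------------------------------------------------------------------------

def connectivity_test(a_ref: np.ndarray, a_guess: np.ndarray) -> TestReport:
    """Pass iff the two adjacency matrices are identical element-wise."""
    a_ref = np.asarray(a_ref)
    a_guess = np.asarray(a_guess)
    if a_ref.shape != a_guess.shape:
        raise ValueError(f"adjacency shape mismatch: {a_ref.shape} vs {a_guess.shape}")
    if np.array_equal(a_ref, a_guess):
        return TestReport("connectivity", True, "same connectivity as reference")
    i, j = np.argwhere(a_ref != a_guess)[0]
    return TestReport("connectivity", False,
                      f"bond pattern differs from reference at atom pair ({i}, {j})")


def similarity_test(phi_g, stored, d: float) -> TestReport:
    """Pass iff the guess lies outside every stored point's hypercube.

    For each stored point p the guess escapes when at least one torsion
    differs by more than the half-edge ``d`` (circular distance, so 355
    and 5 degrees are 10 degrees apart).  An empty pool passes trivially.
    """
    if d <= 0:
        raise ValueError("hypercube half-edge d must be positive")
    phi_g = np.asarray(phi_g, dtype=float)
    for p, phi_p in enumerate(stored):
        if np.all(circular_distance(phi_g, phi_p) <= d):
            return TestReport("similarity", False,
                              f"inside the hypercube of stored point {p} (half-edge {d} deg)")
    return TestReport("similarity", True,
                      f"outside all {len(list(stored))} stored hypercubes")


def redundancy_test(phi_opt, equilibria, eps_red: float) -> TestReport:
    """Pass iff the optimized point coincides with no known conformer.

    Coincidence means every torsion within ``eps_red`` degrees (circular).
    Enantiomeric points are distinct and both pass.
    """
    if eps_red <= 0:
        raise ValueError("eps_red must be positive")
    phi_opt = np.asarray(phi_opt, dtype=float)
    for j, phi_j in enumerate(equilibria):
        if np.all(circular_distance(phi_opt, phi_j) <= eps_red):
            return TestReport("redundancy", False,
                              f"duplicate of equilibrium conformer {j} (within {eps_red} deg)")
    return TestReport("redundancy", True, "distinct from all known conformers")


# ---------------------------------------------------------------------------
# Hessian test
# ---------------------------------------------------------------------------

LINEAR_MOMENT_THRESHOLD = 1e-6  # amu*A^2: below this a principal moment is "zero"


def _tr_projector(cart: np.ndarray, masses: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthonormal basis of the translational + rotational subspace in
    mass-weighted coordinates; returns (3N x k matrix, k)."""
    n = len(cart)
    sq = np.sqrt(masses)
    com = (masses[:, None] * cart).sum(axis=0) / masses.sum()
    r = cart - com
    vecs = []
    for ax in range(3):
        v = np.zeros((n, 3))
        v[:, ax] = sq
        vecs.append(v.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        v = sq[:, None] * np.cross(r, e)
        vecs.append(v.ravel())
    basis = np.array(vecs).T
    q, rmat = np.linalg.qr(basis)
    keep = np.abs(np.diag(rmat)) > 1e-8
    return q[:, keep], int(keep.sum())


def vibrational_frequencies(hessian: np.ndarray, cart: np.ndarray, masses) -> np.ndarray:
    """Harmonic wavenumbers (cm^-1, ascending, signed) from a Cartesian Hessian.

    Mass-weights the Hessian, projects out rigid translations and
    rotations (6 modes, or 5 for linear geometries detected via the
    smallest principal moment) and converts the remaining eigenvalues.
    Imaginary modes come back as negative wavenumbers.
    """
    cart = np.asarray(cart, dtype=float)
    masses = np.asarray(masses, dtype=float)
    hessian = np.asarray(hessian, dtype=float)
    n3 = 3 * len(cart)
    if hessian.shape != (n3, n3):
        raise ValueError(f"Hessian must be {n3}x{n3}, got {hessian.shape}")
    if not np.allclose(hessian, hessian.T, atol=1e-8 * max(1.0, np.abs(hessian).max())):
        raise ValueError("Hessian is not symmetric")

    inv_sq = 1.0 / np.sqrt(np.repeat(masses, 3))
    h_mw = hessian * inv_sq[:, None] * inv_sq[None, :]

    moments = principal_moments(cart, masses)
    q, k = _tr_projector(cart, masses)
    n_zero = 5 if moments[0] < LINEAR_MOMENT_THRESHOLD and len(cart) > 1 else 6
    n_zero = min(n_zero, k)
    proj = np.eye(n3) - q @ q.T
    h_proj = proj @ h_mw @ proj
    eigs = np.linalg.eigvalsh(h_proj)
    # discard the n_zero eigenvalues closest to zero (the projected-out block)
    order = np.argsort(np.abs(eigs))
    vib = np.delete(eigs, order[:n_zero])
    waves = np.array([constants.omega2_to_wavenumber(e) for e in vib])
    return np.sort(waves)


def hessian_test(hessian: np.ndarray, cart: np.ndarray, masses,
                 eps_freq: float = 5.0) -> tuple[TestReport, np.ndarray | None]:
    """Pass iff every vibrational wavenumber exceeds ``-eps_freq`` cm^-1.

    The tolerance absorbs numerical noise of finite-difference Hessians.
    On pass, the 3N-6 (or 3N-5) wavenumbers are returned alongside.
    """
    waves = vibrational_frequencies(hessian, cart, masses)
    n_imag = int((waves <= -eps_freq).sum())
    if n_imag:
        return (TestReport("hessian", False,
                           f"{n_imag} imaginary frequenc{'y' if n_imag == 1 else 'ies'} "
                           f"(lowest {waves[0]:.1f} cm^-1): not a minimum"),
                None)
    return TestReport("hessian", True, f"all frequencies real (lowest {waves[0]:.1f} cm^-1)"), waves


# ---------------------------------------------------------------------------
# batteries
# ---------------------------------------------------------------------------

@dataclass
class ScreeningContext:
    """Everything the batteries need: the reference adjacency, the pools
    and the tolerances.  ``similarity_pool`` is phase-dependent: the
    systematic phase screens against equilibria only, the stochastic
    phase against the full stored pool."""

    a_ref: np.ndarray
    similarity_pool: list
    equilibria: list
    d: float = 30.0
    eps_red: float = 3.0
    eps_freq: float = 5.0


def run_guess_battery(phi_g, a_guess: np.ndarray, ctx: ScreeningContext) -> list[TestReport]:
    """Connectivity then similarity, short-circuiting on first failure."""
    reports = [connectivity_test(ctx.a_ref, a_guess)]
    if not reports[0].passed:
        return reports
    reports.append(similarity_test(phi_g, ctx.similarity_pool, ctx.d))
    return reports


def run_optimized_battery(phi_opt, a_opt: np.ndarray, hessian_fn, cart_opt, masses,
                          ctx: ScreeningContext) -> tuple[list[TestReport], np.ndarray | None]:
    """Connectivity -> redundancy -> Hessian, in that order, short-circuiting.

    ``hessian_fn`` is only invoked when the two cheap tests pass, so no
    time is spent on Hessians of duplicates or broken geometries.
    """
    reports = [connectivity_test(ctx.a_ref, a_opt)]
    if not reports[0].passed:
        return reports, None
    reports.append(redundancy_test(phi_opt, ctx.equilibria, ctx.eps_red))
    if not reports[1].passed:
        return reports, None
    report, waves = hessian_test(hessian_fn(cart_opt), cart_opt, masses, ctx.eps_freq)
    reports.append(report)
    return reports, waves
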