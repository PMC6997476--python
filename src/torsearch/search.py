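"""Systematic + stochastic (Monte Carlo) torsional conformer search.

The engine explores the t-dimensional torsional space of a Z-matrix
template in two phases:

* **systematic** — every point of the Cartesian product of the
  preconditioned (chemically intuitive) angle lists is tried; for a
  molecule with a plane of symmetry only one representative of each
  conformational-enantiomer pair {phi, -phi} is kept, reducing the pool
  from K1 to (K1+1)/2 when a single grid point is self-enantiomeric.
* **stochastic** — batches of uniformly random torsional points, each
  batch with its own exclusion half-edge ``d``; points falling inside
  the hypercube of any stored point (trials *and* equilibria) are
  skipped, so previously visited regions are never re-optimized.

Accepted guesses are relaxed on the backend surface and the optimized
geometry must pass connectivity, redundancy and Hessian screening before
it is recorded as a conformer.  The bookkeeping invariant
``P = K1* + K2* + J`` (stored points = trials + equilibria) holds after
every event.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from . import screening
from .molmodel import (
    ZMatrix,
    circular_distance,
    enantiomer,
    is_self_enantiomeric,
    measure_torsions,
    normalize_angles,
    perceive_adjacency,
    principal_moments,
    zmatrix_to_cartesian,
)
from .pes_backends import Backend, optimize

STATE_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PreconditionedAngles:
    """Per-torsion lists of intuitive guess angles (degrees).

    Only angles generating distinguishable structures belong here; for an
    sp3 chain torsion the default is (180, 60, 300) — anti, gauche+,
    gauche-.  Duplicate angles within one list are rejected.
    """

    per_torsion: list[list[float]]

    def __post_init__(self):
        cleaned = []
        for tau, lst in enumerate(self.per_torsion):
            if not lst:
                raise ValueError(f"torsion {tau}: empty preconditioned angle list")
            vals = [float(a) % 360.0 for a in lst]
            if len(set(vals)) != len(vals):
                raise ValueError(f"torsion {tau}: duplicate preconditioned angles in {lst}")
            cleaned.append(vals)
        self.per_torsion = cleaned

    @classmethod
    def sp3_chain(cls, n_torsions: int) -> "PreconditionedAngles":
        return cls([[180.0, 60.0, 300.0] for _ in range(n_torsions)])

    @property
    def p_tau(self) -> list[int]:
        return [len(lst) for lst in self.per_torsion]


@dataclass
class Conformer:
    """An accepted equilibrium structure."""

    phi_eq: np.ndarray                 # degrees, [0, 360)
    cartesian: np.ndarray              # N x 3 Angstrom
    energy_U: float                    # kcal/mol relative to ensemble minimum
    frequencies: np.ndarray            # 3N-6 wavenumbers, cm^-1, all > 0
    inertia: np.ndarray                # three principal moments, amu A^2
    sigma_rot: int = 1
    weight_w: int = 2                  # 1 iff self-enantiomeric
    provenance: str = "systematic"     # systematic | stochastic-<batch>

    def to_dict(self) -> dict:
        return {
            "phi_eq": [float(x) for x in self.phi_eq],
            "cartesian": [[float(v) for v in row] for row in self.cartesian],
            "energy_U": float(self.energy_U),
            "frequencies": [float(x) for x in self.frequencies],
            "inertia": [float(x) for x in self.inertia],
            "sigma_rot": int(self.sigma_rot),
            "weight_w": int(self.weight_w),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Conformer":
        return cls(
            phi_eq=np.array(d["phi_eq"]),
            cartesian=np.array(d["cartesian"]),
            energy_U=d["energy_U"],
            frequencies=np.array(d["frequencies"]),
            inertia=np.array(d["inertia"]),
            sigma_rot=d["sigma_rot"],
            weight_w=d["weight_w"],
            provenance=d["provenance"],
        )


@dataclass
class SearchState:
    """Evolving pools and counters of one search run.

    ``K1`` counts systematic guesses actually generated (after any
    enantiomer reduction; ``K1_full`` keeps the raw product), ``K1_star``
    those that became trials; likewise K2/K2_star for the stochastic
    phase.  ``J`` is the number of accepted conformers.  At all times
    ``P = K1_star + K2_star + J`` and the stored pool is the union of
    trial and equilibrium torsional points.
    """

    equilibria: list[Conformer] = field(default_factory=list)
    trials: list[np.ndarray] = field(default_factory=list)
    K1: int = 0
    K1_full: int = 0
    K1_star: int = 0
    K2: int = 0
    K2_star: int = 0
    events: list[dict] = field(default_factory=list)

    @property
    def J(self) -> int:
        return len(self.equilibria)

    @property
    def J1(self) -> int:
        return sum(1 for c in self.equilibria if c.provenance == "systematic")

    @property
    def J2(self) -> int:
        return self.J - self.J1

    @property
    def K_star(self) -> int:
        return self.K1_star + self.K2_star

    @property
    def P(self) -> int:
        return self.K_star + self.J

    @property
    def equilibrium_points(self) -> list[np.ndarray]:
        return [c.phi_eq for c in self.equilibria]

    @property
    def stored_points(self) -> list[np.ndarray]:
        return self.equilibrium_points + self.trials

    def check_invariants(self) -> None:
        assert self.K1_star <= self.K1 <= max(self.K1_full, self.K1)
        assert self.K2_star <= self.K2
        assert self.P == len(self.trials) + len(self.equilibria)

    def log(self, **kw) -> None:
        kw.update(K1=self.K1, K1_star=self.K1_star, K2=self.K2,
                  K2_star=self.K2_star, J=self.J, P=self.P)
        self.events.append(kw)

    # -- serialization ------------------------------------------------------
    def to_json(self, include_events: bool = True) -> str:
        payload = {
            "format_version": STATE_FORMAT_VERSION,
            "counters": {"K1": self.K1, "K1_full": self.K1_full, "K1_star": self.K1_star,
                         "K2": self.K2, "K2_star": self.K2_star},
            "trials": [[float(x) for x in t] for t in self.trials],
            "equilibria": [c.to_dict() for c in self.equilibria],
        }
        if include_events:
            payload["events"] = self.events
        return json.dumps(payload, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SearchState":
        d = json.loads(text)
        if d.get("format_version") != STATE_FORMAT_VERSION:
            raise ValueError(f"unsupported state format version {d.get('format_version')}")
        st = cls()
        c = d["counters"]
        st.K1, st.K1_full, st.K1_star = c["K1"], c["K1_full"], c["K1_star"]
        st.K2, st.K2_star = c["K2"], c["K2_star"]
        st.trials = [np.array(t) for t in d["trials"]]
        st.equilibria = [Conformer.from_dict(x) for x in d["equilibria"]]
        st.events = d.get("events", [])
        return st


@dataclass
class SearchConfig:
    """Knobs of one run (see also :mod:`torsearch.config` for file I/O)."""

    d: float = 30.0                       # systematic-phase hypercube half-edge, deg
    eps_red: float = 3.0                  # redundancy tolerance, deg
    eps_freq: float = 5.0                 # Hessian-test tolerance, cm^-1
    k_bond: float = 1.3                   # bond-perception scale factor
    grad_tol: float = 1e-6                # optimizer convergence, kcal/mol/A
    max_opt_steps: int = 2000
    has_sym_plane: bool = False
    seed: int = 0
    batches: list[dict] = field(default_factory=list)   # [{"cycles": int, "d": float}, ...]
    stop_after_no_new: int | None = None  # optional early stop per batch


# ---------------------------------------------------------------------------
# systematic pool
# ---------------------------------------------------------------------------

def canonical_representative(phi) -> np.ndarray:
    """The lexicographically smaller of {phi, -phi}, a deterministic choice
    of which member of an enantiomer pair to keep."""
    phi = normalize_angles(phi)
    mirror = enantiomer(phi)
    return phi if tuple(phi) <= tuple(mirror) else mirror


def systematic_pool(pre: PreconditionedAngles, has_sym_plane: bool = False) -> list[np.ndarray]:
    """The preconditioned guess pool.

    Full Cartesian product of the per-torsion angle lists (size
    ``K1 = prod P_tau``); with ``has_sym_plane`` one representative per
    conformational-enantiomer pair is kept (self-enantiomeric points
    once), which yields (K1+1)/2 points for symmetric 3-angle lists.
    """
    if has_sym_plane:
        for tau, lst in enumerate(pre.per_torsion):
            mirrored = {round((360.0 - a) % 360.0, 9) for a in lst}
            if mirrored != {round(a, 9) for a in lst}:
                raise ValueError(
                    f"torsion {tau}: angle list {lst} is not closed under phi -> 360-phi, "
                    "so the enantiomer of a grid point is off-grid; drop has_sym_plane "
                    "or symmetrise the list")
    pool: list[np.ndarray] = []
    seen: set[tuple] = set()
    for combo in itertools.product(*pre.per_torsion):
        phi = normalize_angles(combo)
        if has_sym_plane:
            key = tuple(np.round(canonical_representative(phi), 9))
            if key in seen:
                continue
            seen.add(key)
        pool.append(phi)
    return pool


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

class SearchEngine:
    """Binds template, backend and configuration; runs the two phases."""

    def __init__(self, zm: ZMatrix, backend: Backend, config: SearchConfig | None = None):
        self.zm = zm
        self.backend = backend
        self.config = config or SearchConfig()
        self.reference_cart = zmatrix_to_cartesian(zm, zm.reference_torsions)
        self.a_ref = perceive_adjacency(self.reference_cart, zm.elements, self.config.k_bond)
        if self.a_ref.sum() == 0 and zm.n_atoms > 1:
            raise ValueError("reference geometry has no bonds: check the template")

    # -- shared per-guess pipeline -----------------------------------------
    def _try_guess(self, state: SearchState, phi_g: np.ndarray, similarity_pool,
                   d: float, phase: str) -> bool:
        """Run one guess through tests, optimization and screening.

        Returns True when a new conformer was accepted.
        """
        cfg = self.config
        cart_g = zmatrix_to_cartesian(self.zm, phi_g)
        a_g = perceive_adjacency(cart_g, self.zm.elements, cfg.k_bond)
        ctx = screening.ScreeningContext(
            a_ref=self.a_ref, similarity_pool=similarity_pool,
            equilibria=state.equilibrium_points,
            d=d, eps_red=cfg.eps_red, eps_freq=cfg.eps_freq)
        guess_reports = screening.run_guess_battery(phi_g, a_g, ctx)
        if not all(r.passed for r in guess_reports):
            state.log(phase=phase, phi=[float(x) for x in phi_g], outcome="rejected-guess",
                      detail=guess_reports[-1].detail)
            return False

        # guess accepted: it becomes a trial and is stored immediately so the
        # same region is never visited again, whatever the optimization does
        state.trials.append(phi_g.copy())
        if phase == "systematic":
            state.K1_star += 1
        else:
            state.K2_star += 1
        state.log(phase=phase, phi=[float(x) for x in phi_g], outcome="trial-stored")

        opt = optimize(self.backend, cart_g, grad_tol=cfg.grad_tol, max_steps=cfg.max_opt_steps)
        if not opt.converged:
            state.log(phase=phase, phi=[float(x) for x in phi_g],
                      outcome="optimization-failed", detail=f"max|g|={opt.max_grad:.2e}")
            return False
        phi_opt = normalize_angles(measure_torsions(opt.cart, self.zm))
        a_opt = perceive_adjacency(opt.cart, self.zm.elements, cfg.k_bond)
        ctx.equilibria = state.equilibrium_points
        opt_reports, waves = screening.run_optimized_battery(
            phi_opt, a_opt, self.backend.hessian, opt.cart, self.zm.masses, ctx)
        if not all(r.passed for r in opt_reports):
            state.log(phase=phase, phi=[float(x) for x in phi_opt],
                      outcome="rejected-optimized", detail=opt_reports[-1].detail)
            return False

        conf = Conformer(
            phi_eq=phi_opt,
            cartesian=opt.cart,
            energy_U=opt.energy,      # re-referenced at the end of the run
            frequencies=waves,
            inertia=principal_moments(opt.cart, self.zm.masses),
            weight_w=1 if is_self_enantiomeric(phi_opt, cfg.eps_red) else 2,
            provenance=phase,
        )
        state.equilibria.append(conf)
        state.log(phase=phase, phi=[float(x) for x in phi_opt], outcome="conformer-accepted")
        return True

    # -- phases -------------------------------------------------------------
    def run_systematic(self, pre: PreconditionedAngles, state: SearchState | None = None) -> SearchState:
        """Optimize every preconditioned guess, in pool order.

        During this phase the similarity test screens against the
        equilibria only: the preconditioned grid is built so that
        hypercubes around its own points never overlap.
        """
        state = state or SearchState()
        cfg = self.config
        pool = systematic_pool(pre, cfg.has_sym_plane)
        state.K1_full = int(np.prod(pre.p_tau))
        for phi_g in pool:
            state.K1 += 1
            self._try_guess(state, phi_g, state.equilibrium_points, cfg.d, "systematic")
            state.check_invariants()
        return state

    def sample_stochastic_point(self, rng: np.random.Generator) -> np.ndarray:
        """t independent uniform draws on [0, 360)."""
        return rng.uniform(0.0, 360.0, size=self.zm.n_torsions)

    def run_stochastic(self, state: SearchState | None = None,
                       batches: list[dict] | None = None,
                       first_batch: int = 0) -> SearchState:
        """Monte Carlo batches; each batch has its own cycle count and ``d``.

        Every generated point counts toward K2 whether accepted or not.
        Here the similarity test screens against the *full* stored pool
        (trials and equilibria), because a random point may fall inside
        the influence region of an earlier trial.  Batch ``b`` draws from
        a generator seeded with ``seed + b`` so a run checkpointed at a
        batch boundary resumes identically.
        """
        state = state or SearchState()
        cfg = self.config
        batches = batches if batches is not None else cfg.batches
        for b, batch in enumerate(batches[first_batch:], start=first_batch):
            cycles = int(batch["cycles"])
            d = float(batch.get("d", cfg.d))
            rng = np.random.default_rng(cfg.seed + b)
            since_new = 0
            for _ in range(cycles):
                phi_g = self.sample_stochastic_point(rng)
                state.K2 += 1
                found = self._try_guess(state, phi_g, state.stored_points, d,
                                        f"stochastic-{b}")
                state.check_invariants()
                since_new = 0 if found else since_new + 1
                if cfg.stop_after_no_new and since_new >= cfg.stop_after_no_new:
                    state.log(phase=f"stochastic-{b}", outcome="early-stop",
                              detail=f"no new conformer for {since_new} cycles")
                    break
        return state

    # -- orchestration ------------------------------------------------------
    def run(self, pre: PreconditionedAngles | None = None,
            systematic: bool = True) -> SearchState:
        """Full run: systematic phase, then the configured stochastic batches;
        conformer energies re-referenced to the ensemble minimum at exit."""
        state = SearchState()
        if systematic:
            if pre is None:
                pre = PreconditionedAngles.sp3_chain(self.zm.n_torsions)
            self.run_systematic(pre, state)
        self.run_stochastic(state)
        rereference_energies(state)
        state.check_invariants()
        return state


def rereference_energies(state: SearchState) -> None:
    """Shift conformer energies so the global minimum sits at U = 0."""
    if not state.equilibria:
        return
    u_min = min(c.energy_U for c in state.equilibria)
    for c in state.equilibria:
        c.energy_U = c.energy_U - u_min


# ---------------------------------------------------------------------------
# enantiomer expansion
# ---------------------------------------------------------------------------

def expand_enantiomers(state: SearchState, eps_red: float = 3.0) -> list[Conformer]:
    """Full list of distinguishable structures, mirror images included.

    Every conformer with weight 2 contributes its enantiomer (torsions
    -phi, reflected Cartesian, identical energy/frequencies/inertia); the
    total is ``2 J - n_self`` where ``n_self`` counts self-enantiomeric
    conformers.
    """
    out: list[Conformer] = []
    for c in state.equilibria:
        out.append(c)
        if c.weight_w == 2:
            mirror = Conformer(
                phi_eq=enantiomer(c.phi_eq),
                cartesian=c.cartesian * np.array([1.0, 1.0, -1.0]),
                energy_U=c.energy_U,
                frequencies=c.frequencies.copy(),
                inertia=c.inertia.copy(),
                sigma_rot=c.sigma_rot,
                weight_w=2,
                provenance=c.provenance + "+mirror",
            )
            out.append(mirror)
    return out


def pairwise_min_distance(points) -> float:
    """Smallest over pairs of the largest per-torsion circular distance;
    diagnostic for the pairwise-redundancy invariant."""
    pts = [np.asarray(p, dtype=float) for p in points]
    best = np.inf
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            best = min(best, float(np.max(circular_distance(pts[i], pts[j]))))
    return best
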