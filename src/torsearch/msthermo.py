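"""Multi-structural rovibrational partition functions and populations.

Given the conformer ensemble (relative energies U_j, harmonic
frequencies, principal moments of inertia, rotational symmetry numbers
and enantiomer weights w_j), this module evaluates

* the classical rigid-rotor rotational partition function Q_rot,j,
* harmonic (HO) and quasi-harmonic (QH, frequencies scaled by lambda_ZPE)
  vibrational partition functions referenced at the zero-point energy,
* the multi-structural sums Q_MS-HO and Q_MS-QH over distinguishable
  non-enantiomeric structures, each weighted w_j * exp(-U_j/kB T),
* the torsional-anharmonic Q_MS-T(C), which multiplies each conformer's
  QH term by per-torsion factors f_{j,eta} supplied by the caller (the
  factors themselves come from a hindered-rotor treatment outside this
  package; all f = 1 recovers Q_MS-QH exactly),
* conformer populations chi_j and rovibrational Gibbs free energies
  G_j = U_j - kB T ln(Q_rot,j Q_QH,j), and the minimum number of
  conformers needed to recover a given fraction of the partition
  function.

Degenerate electronic ground states are assumed (degeneracy 1,
closed-shell molecules).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    AMUA2_TO_KGM2,
    HBAR,
    KB,
    KB_KCALMOL,
    WAVENUMBER_TO_KCALMOL,
)


# ---------------------------------------------------------------------------
# inputs
# ---------------------------------------------------------------------------

@dataclass
class ConformerThermo:
    """Per-conformer data required by the partition functions."""

    energy_U: float                  # kcal/mol, >= 0 after re-referencing
    frequencies: np.ndarray          # cm^-1, all > 0
    inertia: np.ndarray              # three principal moments, amu A^2
    sigma_rot: int = 1
    weight_w: int = 1
    label: str = ""
    provenance: str = ""

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.inertia = np.asarray(self.inertia, dtype=float)
        if np.any(self.frequencies <= 0):
            raise ValueError(f"conformer {self.label!r}: non-positive frequency")
        if self.weight_w not in (1, 2):
            raise ValueError("enantiomer weight must be 1 or 2")
        if self.sigma_rot < 1:
            raise ValueError("sigma_rot must be a positive integer")


@dataclass
class ThermoInput:
    conformers: list[ConformerThermo]
    temperatures: np.ndarray
    lambda_zpe: float = 1.0

    def __post_init__(self):
        self.temperatures = np.atleast_1d(np.asarray(self.temperatures, dtype=float))
        if np.any(self.temperatures <= 0):
            raise ValueError("temperatures must be strictly positive")
        if not (0.0 < self.lambda_zpe <= 1.2):
            raise ValueError("lambda_zpe outside the plausible (0, 1.2] range")
        if not self.conformers:
            raise ValueError("empty conformer list")
        u_min = min(c.energy_U for c in self.conformers)
        if abs(u_min) > 1e-9:
            for c in self.conformers:
                c.energy_U -= u_min


# ---------------------------------------------------------------------------
# single-conformer building blocks
# ---------------------------------------------------------------------------

def q_rot(inertia, sigma_rot: int, T: float) -> float:
    """Classical rigid-rotor partition function of a nonlinear top:

        Q_rot = (8 pi^2 / sigma) * (kB T / (2 pi hbar^2))^(3/2) * sqrt(I1 I2 I3)

    with the moments in amu*Angstrom^2 converted internally to SI.
    """
    I = np.asarray(inertia, dtype=float) * AMUA2_TO_KGM2
    if np.any(I <= 0):
        raise ValueError("linear or point-like geometry: nonlinear top required")
    pref = (KB * T / (2.0 * np.pi * HBAR ** 2)) ** 1.5
    return float(8.0 * np.pi ** 2 / sigma_rot * pref * np.sqrt(np.prod(I)))


def zpe_ho(frequencies) -> float:
    """Harmonic zero-point energy, kcal/mol: sum of hbar*omega/2."""
    nu = np.asarray(frequencies, dtype=float)
    return float(0.5 * nu.sum() * WAVENUMBER_TO_KCALMOL)


def q_ho(frequencies, T: float) -> tuple[float, float]:
    """ZPE-referenced harmonic vibrational partition function and E_HO.

    Returns (Qtilde, E_zpe): Qtilde = prod_m 1/(1 - exp(-beta hbar omega_m))
    evaluated overflow-safely, and the zero-point energy in kcal/mol.
    The full HO function is Qtilde * exp(-beta * E_zpe).
    """
    nu = np.asarray(frequencies, dtype=float)
    beta_e = nu * WAVENUMBER_TO_KCALMOL / (KB_KCALMOL * T)   # beta*hbar*omega, dimensionless
    qt = float(np.prod(1.0 / -np.expm1(-beta_e))) if nu.size else 1.0
    return qt, zpe_ho(nu)


def q_qh(frequencies, lambda_zpe: float, T: float) -> tuple[float, float]:
    """Quasi-harmonic variant: every frequency scaled by lambda_zpe, so
    E_QH = lambda_zpe * E_HO and lambda_zpe = 1 reduces to q_ho."""
    nu = lambda_zpe * np.asarray(frequencies, dtype=float)
    return q_ho(nu, T)


def _log_conformer_term(c: ConformerThermo, T: float, lambda_zpe: float) -> float:
    """log of w * Q_rot * Q_QH * exp(-U/kBT) for one conformer (stable)."""
    qt, ezpe = q_qh(c.frequencies, lambda_zpe, T)
    return (np.log(c.weight_w) + np.log(q_rot(c.inertia, c.sigma_rot, T))
            + np.log(qt) - (ezpe + c.energy_U) / (KB_KCALMOL * T))


# ---------------------------------------------------------------------------
# multi-structural sums
# ---------------------------------------------------------------------------

def q_ms(inp: ThermoInput, flavor: str = "QH") -> np.ndarray:
    """Q_MS-HO or Q_MS-QH at each temperature.

    The weighted sum over distinguishable non-enantiomeric structures,
    sum_j w_j Q_rot,j Q_vib,j exp(-U_j/kB T), equals the plain sum over
    all structures with each enantiomer pair counted twice.
    """
    if flavor not in ("HO", "QH"):
        raise ValueError("flavor must be 'HO' or 'QH'")
    lam = inp.lambda_zpe if flavor == "QH" else 1.0
    out = np.empty(len(inp.temperatures))
    for it, T in enumerate(inp.temperatures):
        logs = [_log_conformer_term(c, T, lam) for c in inp.conformers]
        m = max(logs)
        out[it] = np.exp(m) * sum(np.exp(l - m) for l in logs)
    return out


def q_mst(inp: ThermoInput, f_factors) -> np.ndarray:
    """Torsional-anharmonic Q_MS-T(C) at each temperature.

    ``f_factors[j]`` holds one positive factor per torsion for conformer
    j; the conformer's QH term is multiplied by F_j = prod_eta f_{j,eta}.
    The Boltzmann factor exp(-U_j/kB T) and the enantiomer weight w_j are
    folded in exactly as in Q_MS-QH, so that all-f=1 recovers it.
    """
    f_factors = [np.atleast_1d(np.asarray(f, dtype=float)) for f in f_factors]
    if len(f_factors) != len(inp.conformers):
        raise ValueError(f"need one factor list per conformer: got {len(f_factors)} "
                         f"for {len(inp.conformers)} conformers")
    n_tors = {f.size for f in f_factors}
    if len(n_tors) != 1:
        raise ValueError("inconsistent number of torsional factors across conformers")
    if any(np.any(f <= 0) for f in f_factors):
        raise ValueError("torsional anharmonicity factors must be positive")
    out = np.empty(len(inp.temperatures))
    for it, T in enumerate(inp.temperatures):
        logs = [_log_conformer_term(c, T, inp.lambda_zpe) + np.log(f).sum()
                for c, f in zip(inp.conformers, f_factors)]
        m = max(logs)
        out[it] = np.exp(m) * sum(np.exp(l - m) for l in logs)
    return out


# ---------------------------------------------------------------------------
# populations and free energies
# ---------------------------------------------------------------------------

def gibbs_free_energies(inp: ThermoInput, T: float) -> np.ndarray:
    """Rovibrational Gibbs free energy per conformer, kcal/mol:
    G_j = U_j - kB T ln(Q_rot,j Q_QH,j)."""
    out = np.empty(len(inp.conformers))
    for j, c in enumerate(inp.conformers):
        qt, ezpe = q_qh(c.frequencies, inp.lambda_zpe, T)
        log_q = np.log(q_rot(c.inertia, c.sigma_rot, T)) + np.log(qt) - ezpe / (KB_KCALMOL * T)
        out[j] = c.energy_U - KB_KCALMOL * T * log_q
    return out


def chi(inp: ThermoInput, T: float) -> np.ndarray:
    """Equilibrium populations chi_j = w_j e^{-G_j/kBT} / sum, normalised
    to exactly 1; order follows the input conformer list."""
    g = gibbs_free_energies(inp, T)
    logw = np.log([c.weight_w for c in inp.conformers])
    x = logw - g / (KB_KCALMOL * T)
    x -= x.max()
    e = np.exp(x)
    return e / e.sum()


def min_conformers_for_fraction(inp: ThermoInput, T: float, threshold: float = 0.9) -> dict:
    """Smallest m such that the m most populated conformers carry at least
    ``threshold`` of the partition function; split by search provenance.

    Returns ``{"m": m, "systematic": m1, "stochastic": m2}``.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    x = chi(inp, T)
    order = np.argsort(-x, kind="stable")
    cum = np.cumsum(x[order])
    m = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    m = min(m, len(x))
    chosen = order[:m]
    m1 = sum(1 for j in chosen if inp.conformers[j].provenance.startswith("systematic")
             or inp.conformers[j].provenance == "")
    return {"m": m, "systematic": m1, "stochastic": m - m1}


# ---------------------------------------------------------------------------
# tables and ratios
# ---------------------------------------------------------------------------

def one_well_input(inp: ThermoInput) -> ThermoInput:
    """The single-global-minimum (1W) ensemble: the lowest-U conformer with
    its enantiomer weight forced to 1."""
    jmin = int(np.argmin([c.energy_U for c in inp.conformers]))
    c = inp.conformers[jmin]
    solo = ConformerThermo(energy_U=0.0, frequencies=c.frequencies.copy(),
                           inertia=c.inertia.copy(), sigma_rot=c.sigma_rot,
                           weight_w=1, label=c.label, provenance=c.provenance)
    return ThermoInput([solo], inp.temperatures.copy(), inp.lambda_zpe)


def ratio_report(inp: ThermoInput, f_factors=None) -> pd.DataFrame:
    """Per-temperature ratios quantifying multi-well and torsional effects:
    Q_MS-QH/Q_1W-QH (>= 1 always), Q_MS-T(C)/Q_MS-QH and Q_MS-T(C)/Q_1W-QH.

    Without ``f_factors`` all torsional factors default to 1 and the two
    MS quantities coincide.
    """
    q_msqh = q_ms(inp, "QH")
    q_1w = q_ms(one_well_input(inp), "QH")
    if f_factors is None:
        f_factors = [np.ones(1) for _ in inp.conformers]
    q_t = q_mst(inp, f_factors)
    return pd.DataFrame({
        "T": inp.temperatures,
        "Q_MS_QH": q_msqh,
        "Q_1W_QH": q_1w,
        "Q_MS_TC": q_t,
        "MSQH_over_1WQH": q_msqh / q_1w,
        "MSTC_over_MSQH": q_t / q_msqh,
        "MSTC_over_1WQH": q_t / q_1w,
    })


def thermo_table(inp: ThermoInput, f_factors=None) -> pd.DataFrame:
    """Long-format per-(T, conformer) table: Q_rot, Q_HO, Q_QH, chi, G."""
    rows = []
    for T in inp.temperatures:
        x = chi(inp, T)
        g = gibbs_free_energies(inp, T)
        for j, c in enumerate(inp.conformers):
            qt_ho, e_ho = q_ho(c.frequencies, T)
            qt_qh, e_qh = q_qh(c.frequencies, inp.lambda_zpe, T)
            rows.append({
                "T": T, "conformer": c.label or str(j), "U": c.energy_U,
                "w": c.weight_w, "sigma_rot": c.sigma_rot,
                "Q_rot": q_rot(c.inertia, c.sigma_rot, T),
                "Q_HO_tilde": qt_ho, "E_HO": e_ho,
                "Q_QH_tilde": qt_qh, "E_QH": e_qh,
                "chi": x[j], "G": g[j],
            })
    return pd.DataFrame(rows)


def ensemble_from_search(state, temperatures, lambda_zpe: float = 1.0) -> ThermoInput:
    """Build a ThermoInput straight from a finished SearchState."""
    confs = [ConformerThermo(energy_U=c.energy_U, frequencies=c.frequencies,
                             inertia=c.inertia, sigma_rot=c.sigma_rot,
                             weight_w=c.weight_w, label=str(i), provenance=c.provenance)
             for i, c in enumerate(state.equilibria)]
    return ThermoInput(confs, np.asarray(temperatures, dtype=float), lambda_zpe)
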