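"""Tabular reports and plain-text run logs.

Two stable tables summarise a run: the *efficiency table* (per-phase
guess/trial/conformer counts) and the *minimum-conformer table* (how
many conformers, split by provenance, are needed to recover a population
threshold at each temperature).  The conformer table lists one row per
accepted conformer with its torsions, relative energy, enantiomer weight
and provenance.  Angles are printed with 2 decimals; full precision
lives in the JSON checkpoint.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .msthermo import ThermoInput, min_conformers_for_fraction
from .search import SearchState


def conformer_table(state: SearchState) -> pd.DataFrame:
    rows = []
    n_tors = len(state.equilibria[0].phi_eq) if state.equilibria else 0
    for i, c in enumerate(state.equilibria):
        row = {"id": i}
        for tau in range(n_tors):
            row[f"phi_{tau + 1}"] = round(float(c.phi_eq[tau]), 2)
        row.update(energy=round(float(c.energy_U), 6), weight=c.weight_w,
                   n_imag=0, provenance=c.provenance)
        rows.append(row)
    return pd.DataFrame(rows)


def efficiency_table(state: SearchState, t: int) -> pd.DataFrame:
    """Per-run counters: t, K1, K1*, J1, K2, K2*, J2, J_LL."""
    return pd.DataFrame([{
        "t": t, "K1": state.K1, "K1_star": state.K1_star, "J1": state.J1,
        "K2": state.K2, "K2_star": state.K2_star, "J2": state.J2,
        "J_LL": state.J,
    }])


def min_conformer_table(inp: ThermoInput, threshold: float = 0.9) -> pd.DataFrame:
    rows = []
    for T in inp.temperatures:
        r = min_conformers_for_fraction(inp, T, threshold)
        rows.append({"T": T, "threshold": threshold, "m": r["m"],
                     "J1": r["systematic"], "J2": r["stochastic"]})
    return pd.DataFrame(rows)


def events_log_text(state: SearchState) -> str:
    """One traceable line per event: phase, point, outcome, counters."""
    lines = []
    for ev in state.events:
        phi = ev.get("phi")
        phi_s = "(" + ",".join(f"{x:.2f}" for x in phi) + ")" if phi else "-"
        lines.append(
            f"{ev.get('phase', '-')}\t{phi_s}\t{ev.get('outcome', '-')}\t"
            f"K1={ev['K1']} K1*={ev['K1_star']} K2={ev['K2']} K2*={ev['K2_star']} "
            f"J={ev['J']} P={ev['P']}\t{ev.get('detail', '')}")
    return "\n".join(lines) + ("\n" if lines else "")


def write_reports(out_dir, state: SearchState, t: int,
                  thermo: ThermoInput | None = None, threshold: float = 0.9) -> dict[str, Path]:
    """Write the standard report files; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    df = conformer_table(state)
    paths["conformers"] = out / "conformers.tsv"
    df.to_csv(paths["conformers"], sep="\t", index=False)

    eff = efficiency_table(state, t)
    paths["efficiency"] = out / "efficiency.tsv"
    eff.to_csv(paths["efficiency"], sep="\t", index=False)

    paths["state"] = out / "state.json"
    paths["state"].write_text(state.to_json())

    paths["log"] = out / "events.log"
    paths["log"].write_text(events_log_text(state))

    if thermo is not None:
        mc = min_conformer_table(thermo, threshold)
        paths["min_conformers"] = out / "min_conformers.tsv"
        mc.to_csv(paths["min_conformers"], sep="\t", index=False)
    return paths
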