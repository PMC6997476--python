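"""Independent brute-force oracle: exhaustive grid relaxation of a toy
torsional profile.

Evaluates the profile on a dense periodic grid, performs discrete
steepest descent from every node to a grid-local minimum, then polishes
each distinct minimum with a continuous minimizer.  This never touches
the Cartesian search machinery, so it can arbitrate what the search
engine should have found.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize

from torsearch.molmodel import circular_distance


def grid_minima(pes, n_torsions: int, step: float = 10.0, eps: float = 3.0) -> list[np.ndarray]:
    """All distinct minima of the torsional profile, degrees in [0, 360)."""
    axes = [np.arange(0.0, 360.0, step) for _ in range(n_torsions)]
    mesh = np.meshgrid(*axes, indexing="ij")
    V = pes.torsional_potential_grid(mesh)

    # discrete steepest descent: every node walks to its lowest neighbour
    shape = V.shape
    offsets = [o for o in itertools.product((-1, 0, 1), repeat=n_torsions)
               if any(o)]
    minima_nodes = set()
    for idx in itertools.product(*(range(s) for s in shape)):
        cur = idx
        while True:
            best, best_v = cur, V[cur]
            for off in offsets:
                nb = tuple((c + o) % s for c, o, s in zip(cur, off, shape))
                if V[nb] < best_v:
                    best, best_v = nb, V[nb]
            if best == cur:
                minima_nodes.add(cur)
                break
            cur = best

    # polish each grid minimum on the continuous profile
    polished: list[np.ndarray] = []
    for node in sorted(minima_nodes):
        x0 = np.array([axes[k][node[k]] for k in range(n_torsions)])
        res = minimize(lambda x: pes.torsional_potential(x), x0, method="BFGS",
                       options={"gtol": 1e-10})
        phi = np.asarray(res.x) % 360.0
        if not any(np.all(circular_distance(phi, q) <= eps) for q in polished):
            polished.append(phi)
    return polished


def match_sets(found, expected, eps: float = 3.0) -> bool:
    """True iff the two point sets coincide one-to-one within eps degrees."""
    found = [np.asarray(p) for p in found]
    expected = [np.asarray(p) for p in expected]
    if len(found) != len(expected):
        return False
    used = set()
    for p in found:
        hit = next((i for i, q in enumerate(expected)
                    if i not in used and np.all(circular_distance(p, q) <= eps)), None)
        if hit is None:
            return False
        used.add(hit)
    return True
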