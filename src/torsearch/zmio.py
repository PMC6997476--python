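"""Z-matrix (Gaussian-style dialect) reading/writing and XYZ output.

The accepted dialect is the common cartesian-free form::

    C
    C 1 1.53
    C 2 1.53 1 112.0
    C 3 1.53 2 112.0 1 tor1

    Variables:
    tor1 180.0

Atom references are 1-based.  Values may be literal numbers or variable
names resolved in the ``Variables:`` block.  The *target torsions* are
the variables named in ``torsion_names`` (default: every variable that
sits in a dihedral slot); a torsion name appearing in two dihedral slots
is a hard error, since the torsional point would be ambiguous.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .molmodel import ZMatrix, ZMatrixRow


class ZMatrixParseError(ValueError):
    pass


def _parse_value(token: str, variables: dict[str, float], line_no: int):
    try:
        return float(token)
    except ValueError:
        pass
    name = token.lstrip("-")
    if name in variables:
        v = variables[name]
        return -v if token.startswith("-") else v
    return token  # unresolved symbol: a torsion variable


def loads_zmatrix(text: str, torsion_names: list[str] | None = None) -> ZMatrix:
    lines = text.splitlines()
    atom_lines: list[tuple[int, list[str]]] = []
    variables: dict[str, float] = {}
    in_vars = False
    for ln, raw in enumerate(lines, start=1):
        line = raw.split("!")[0].split("#")[0].strip()
        if not line:
            continue
        low = line.lower().rstrip(":")
        if low in ("variables", "constants"):
            in_vars = True
            continue
        if in_vars:
            parts = line.replace("=", " ").split()
            if len(parts) != 2:
                raise ZMatrixParseError(f"line {ln}: malformed variable assignment {raw!r}")
            try:
                variables[parts[0]] = float(parts[1])
            except ValueError:
                raise ZMatrixParseError(f"line {ln}: non-numeric variable value {raw!r}") from None
        else:
            atom_lines.append((ln, line.split()))

    rows: list[ZMatrixRow] = []
    dihedral_vars: dict[str, list[int]] = {}
    for idx, (ln, parts) in enumerate(atom_lines):
        try:
            if idx == 0:
                if len(parts) != 1:
                    raise ValueError("first atom takes no references")
                rows.append(ZMatrixRow(parts[0]))
                continue
            el = parts[0]
            bond_ref = int(parts[1]) - 1
            bond_len = _parse_value(parts[2], variables, ln)
            if isinstance(bond_len, str):
                raise ValueError(f"unresolved bond-length variable {bond_len!r}")
            if idx == 1:
                rows.append(ZMatrixRow(el, bond_ref, bond_len))
                continue
            angle_ref = int(parts[3]) - 1
            angle = _parse_value(parts[4], variables, ln)
            if isinstance(angle, str):
                raise ValueError(f"unresolved angle variable {angle!r}")
            if idx == 2:
                rows.append(ZMatrixRow(el, bond_ref, bond_len, angle_ref, angle))
                continue
            dih_ref = int(parts[5]) - 1
            # a symbolic dihedral stays symbolic here even when the variables
            # block provides its value: it may be a target torsion
            try:
                dih: float | str = float(parts[6])
            except ValueError:
                dih = parts[6]
                dihedral_vars.setdefault(dih, []).append(ln)
            rows.append(ZMatrixRow(el, bond_ref, bond_len, angle_ref, angle, dih_ref, dih))
        except (IndexError, ValueError) as exc:
            raise ZMatrixParseError(f"line {ln}: malformed Z-matrix entry {' '.join(parts)!r}: {exc}") from None

    for name, lns in dihedral_vars.items():
        if len(lns) > 1:
            raise ZMatrixParseError(
                f"torsion variable {name!r} names the dihedral of lines {lns}: "
                "each target torsion must be defined unambiguously")

    if torsion_names is None:
        torsion_names = list(dihedral_vars)
    else:
        unknown = [n for n in torsion_names if n not in dihedral_vars]
        if unknown:
            raise ZMatrixParseError(f"declared torsions {unknown} not found in any dihedral slot")
        extra = [n for n in dihedral_vars if n not in torsion_names]
        for name in extra:  # non-target dihedral variables freeze at their value
            if name not in variables:
                raise ZMatrixParseError(f"dihedral variable {name!r} has no value and is not a target torsion")
        rows = [
            ZMatrixRow(r.element, r.bond_ref, r.bond_length, r.angle_ref, r.angle,
                       r.dihedral_ref,
                       variables[r.dihedral] if isinstance(r.dihedral, str) and r.dihedral in extra
                       else r.dihedral)
            for r in rows
        ]

    reference = [variables.get(n, 180.0) for n in torsion_names]
    return ZMatrix(rows, list(torsion_names), np.array(reference, dtype=float))


def read_zmatrix(path, torsion_names: list[str] | None = None) -> ZMatrix:
    return loads_zmatrix(Path(path).read_text(), torsion_names)


def dumps_zmatrix(zm: ZMatrix) -> str:
    """Serialise back to the Gaussian-style dialect (lossless round-trip)."""
    out = []
    for i, r in enumerate(zm.rows):
        parts = [r.element]
        if i >= 1:
            parts += [str(r.bond_ref + 1), f"{r.bond_length:.10g}"]
        if i >= 2:
            parts += [str(r.angle_ref + 1), f"{r.angle:.10g}"]
        if i >= 3:
            dih = r.dihedral if isinstance(r.dihedral, str) else f"{r.dihedral:.10g}"
            parts += [str(r.dihedral_ref + 1), dih]
        out.append(" ".join(parts))
    out.append("")
    out.append("Variables:")
    for k, name in enumerate(zm.torsion_names):
        out.append(f"{name} {zm.reference_torsions[k]:.10g}")
    return "\n".join(out) + "\n"


def write_zmatrix(path, zm: ZMatrix) -> None:
    Path(path).write_text(dumps_zmatrix(zm))


# ---------------------------------------------------------------------------
# XYZ output
# ---------------------------------------------------------------------------

def xyz_frame(elements, cart, comment: str = "") -> str:
    lines = [str(len(elements)), comment.replace("\n", " ")]
    for el, (x, y, z) in zip(elements, np.asarray(cart, dtype=float)):
        lines.append(f"{el} {x:15.8f} {y:15.8f} {z:15.8f}")
    return "\n".join(lines) + "\n"


def write_xyz(path, elements, cart, comment: str = "") -> None:
    Path(path).write_text(xyz_frame(elements, cart, comment))


def write_xyz_trajectory(path, elements, frames, comments=None) -> None:
    comments = comments or ["" for _ in frames]
    with open(path, "w") as fh:
        for cart, comment in zip(frames, comments):
            fh.write(xyz_frame(elements, cart, comment))
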