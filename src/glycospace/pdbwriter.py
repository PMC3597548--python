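"""Minimal fixed-width PDB emission for glycan fragments and synthetic
fixtures.

Only the records the rest of the package consumes are written: REMARK 2
(resolution), ATOM/HETATM, CONECT and END. Writing is kept in-house so that
fixture files are byte-stable (atom ordering and CONECT layout under our
control); reading always goes through gemmi.
"""

from __future__ import annotations

import numpy as np


def _atom_name_field(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def format_pdb(atoms, coords, bonds, resolution=None, serials=None) -> str:
    """Format AtomRecord-like objects (name, element, residue_name,
    residue_id, is_hetatm) with coordinates into PDB text.

    CONECT records are emitted for every bond involving a HETATM atom, in
    both directions, four partners per line.
    """
    coords = np.asarray(coords)
    lines = []
    if resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {resolution:4.2f} ANGSTROMS.")
    if serials is None:
        serials = list(range(1, len(atoms) + 1))
    for a, s, xyz in zip(atoms, serials, coords):
        record = "HETATM" if a.is_hetatm else "ATOM  "
        chain, resnum, icode = a.residue_id
        lines.append(
            f"{record}{s:5d} {_atom_name_field(a.name, a.element)} "
            f"{a.residue_name:>3s} {str(chain)[:1]:1s}{resnum:4d}{icode or ' ':1s}   "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {a.element:>2s}"
        )
    neighbours = {}
    for i, j in bonds:
        if atoms[i].is_hetatm or atoms[j].is_hetatm:
            neighbours.setdefault(i, []).append(j)
            neighbours.setdefault(j, []).append(i)
    for i in sorted(neighbours):
        partners = sorted(neighbours[i])
        for k in range(0, len(partners), 4):
            chunk = partners[k : k + 4]
            lines.append(
                f"CONECT{serials[i]:5d}" + "".join(f"{serials[j]:5d}" for j in chunk)
            )
    lines.append("END")
    return "\n".join(lines) + "\n"
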