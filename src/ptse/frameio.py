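"""Molecular frame I/O: multi-frame XYZ and minimal PDB.

Atom-name dialects vary between packages, so role assignment is always
driven by an explicit role map supplied by the caller:

* XYZ carries only element symbols, so the map is role → atom index;
* PDB carries atom names, so the map is atom name → role.

XYZ coordinates are written with 9 decimals (lossless round trip at
that precision); PDB coordinates are limited to the format's 3
decimals.  PDB reading tolerates missing occupancy/B-factor fields.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .geometry import REQUIRED_ROLES, MolecularFrame, RoleError

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_pdb",
    "read_pdb",
    "default_pdb_names",
]

#: default PDB atom names for each role (one common dialect)
default_pdb_names: Dict[str, str] = {
    "P_T": "PT",
    "O_leaving": "O3A",
    "O_attacking": "O3B",
    "O_nb1": "O1G",
    "O_nb2": "O2G",
    "O_nb3": "O3G",
    "Mg": "MG",
    "P_alpha": "PA",
    "O3_alpha": "O3'",
    "P_beta": "PB",
    "O3_beta": "O3B'",
}


def _check_required(roles: Dict[str, int]) -> None:
    for r in REQUIRED_ROLES:
        if r not in roles:
            raise RoleError(f"role map does not cover required role {r!r}")


def write_xyz(path, frames: Sequence[MolecularFrame], comment: str = "") -> None:
    """Multi-frame XYZ; element symbols from the frame labels."""
    with open(path, "w") as fh:
        for i, fr in enumerate(frames):
            fh.write(f"{len(fr.labels)}\n{comment or f'frame {i}'}\n")
            for lab, (x, y, z) in zip(fr.labels, fr.coordinates):
                fh.write(f"{lab:<2s} {x:18.9f} {y:18.9f} {z:18.9f}\n")


def read_xyz(path, role_map: Dict[str, int]) -> List[MolecularFrame]:
    """Read multi-frame XYZ; ``role_map`` maps role → atom index."""
    _check_required(role_map)
    frames: List[MolecularFrame] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        labels, coords = [], []
        for ln in block:
            parts = ln.split()
            labels.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        if max(role_map.values()) >= n:
            raise RoleError("role map index exceeds atom count")
        frames.append(MolecularFrame(labels, np.array(coords), dict(role_map)))
        i += 2 + n
    return frames


def _pdb_names_for(frame: MolecularFrame, names_by_role: Dict[str, str]) -> List[str]:
    index_to_role = {i: r for r, i in frame.roles.items()}
    names = []
    for i, lab in enumerate(frame.labels):
        role = index_to_role.get(i)
        names.append(names_by_role.get(role, lab.upper()) if role else lab.upper())
    return names


def write_pdb(path, frames: Sequence[MolecularFrame],
              names_by_role: Dict[str, str] = default_pdb_names) -> None:
    """Minimal multi-model PDB (HETATM records, residue LIG)."""
    arrays = []
    for fr in frames:
        n = len(fr.labels)
        arr = struc.AtomArray(n)
        arr.coord = np.asarray(fr.coordinates, dtype=np.float32)
        arr.atom_name = np.array(_pdb_names_for(fr, names_by_role), dtype="U6")
        arr.element = np.array([lab.upper() for lab in fr.labels], dtype="U2")
        arr.res_name = np.full(n, "LIG", dtype="U5")
        arr.res_id = np.ones(n, dtype=int)
        arr.chain_id = np.full(n, "A", dtype="U4")
        arr.hetero = np.ones(n, dtype=bool)
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_pdb(path, role_map: Dict[str, str]) -> List[MolecularFrame]:
    """Read a (multi-model) PDB; ``role_map`` maps atom name → role.

    Raises :class:`RoleError` naming the first required role not covered
    by the mapped atoms.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    frames: List[MolecularFrame] = []
    for arr in stack:
        labels = [str(e).capitalize() for e in arr.element]
        roles: Dict[str, int] = {}
        for i, name in enumerate(arr.atom_name):
            role = role_map.get(str(name).strip())
            if role is not None:
                roles[role] = i
        _check_required(roles)
        frames.append(MolecularFrame(labels, np.asarray(arr.coord, dtype=float), roles))
    return frames
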