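"""Multi-model PDB trajectory reading and writing (biotite-backed).

One peptide chain per file; MODEL/ENDMDL blocks are frames.  The frame
spacing (ps) travels in a REMARK so a written trajectory round-trips
losslessly apart from the format's 3-decimal coordinate precision.
"""

from __future__ import annotations

from pathlib import Path

import biotite.structure as struc
import biotite.structure.io.pdb as pdb
import numpy as np

from .model import VDW_RADII, AtomRecord, Topology, Trajectory
from .sets import PeptideSequence
from .templates import ONE_LETTER, THREE_LETTER

__all__ = ["read_trajectory", "write_trajectory"]

_SPACING_REMARK = "REMARK 250 FRAME SPACING (PS):"


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    top = trajectory.topology
    n_atoms = top.n_atoms
    array = struc.AtomArrayStack(trajectory.n_frames, n_atoms)
    array.coord = np.asarray(trajectory.coords, np.float32)
    array.chain_id = np.full(n_atoms, "A")
    array.res_id = np.array([a.residue_index for a in top.atoms])
    array.res_name = np.array(
        [THREE_LETTER[top.sequence.residues[a.residue_index - 1]] for a in top.atoms]
    )
    array.atom_name = np.array([a.name for a in top.atoms])
    array.element = np.array([a.element for a in top.atoms])
    array.hetero = np.zeros(n_atoms, bool)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(array)
    pdb_file.lines = [f"{_SPACING_REMARK} {trajectory.frame_spacing:g}"] + pdb_file.lines
    pdb_file.write(str(path))


def _validate_models(lines: list[str]) -> None:
    """Reject files whose MODEL blocks disagree in atom count or ordering."""
    counts: list[tuple[int, int]] = []  # (model number, atom count)
    names: list[list[str]] = []
    current: list[str] | None = None
    model_no = 0
    for line in lines:
        rec = line[:6].strip()
        if rec == "MODEL":
            model_no = int(line.split()[1]) if len(line.split()) > 1 else model_no + 1
            current = []
        elif rec == "ENDMDL":
            if current is None:
                raise ValueError("ENDMDL without matching MODEL record")
            counts.append((model_no, len(current)))
            names.append(current)
            current = None
        elif rec in ("ATOM", "HETATM") and current is not None:
            current.append(line[12:16].strip())
    if not counts:
        return  # single implicit model
    ref_no, ref_count = counts[0]
    for (no, count), nm in zip(counts, names):
        if count != ref_count:
            raise ValueError(
                f"MODEL {no}: {count} atoms, but MODEL {ref_no} has {ref_count}"
            )
        if nm != names[0]:
            raise ValueError(f"MODEL {no}: atom ordering differs from MODEL {ref_no}")


def read_trajectory(path: str | Path, frame_spacing: float | None = None) -> Trajectory:
    """Read a multi-model PDB into a :class:`Trajectory`.

    ``frame_spacing`` overrides the value stored in the file's REMARK
    (default 0.5 ps when neither is present).
    """
    pdb_file = pdb.PDBFile.read(str(path))
    _validate_models(pdb_file.lines)
    if frame_spacing is None:
        frame_spacing = 0.5
        for line in pdb_file.lines:
            if line.startswith(_SPACING_REMARK):
                frame_spacing = float(line[len(_SPACING_REMARK):])
                break
    stack = pdb_file.get_structure(model=None)

    res_ids = stack.res_id
    order = np.unique(res_ids)
    one_letters = []
    for rid in order:
        res_name = stack.res_name[res_ids == rid][0]
        if res_name not in ONE_LETTER:
            raise ValueError(f"unsupported residue {res_name} (id {rid})")
        one_letters.append(ONE_LETTER[res_name])
    sequence = PeptideSequence(id=Path(path).stem, residues="".join(one_letters))

    rid_to_pos = {rid: i + 1 for i, rid in enumerate(order)}
    atoms: list[AtomRecord] = []
    # map hydrogens to their nitrogen: the backbone N of the same residue
    # (the model carries no O-H hydrogens)
    n_index_of_res: dict[int, int] = {}
    for i in range(stack.array_length()):
        if stack.atom_name[i] == "N":
            n_index_of_res[rid_to_pos[res_ids[i]]] = i
    for i in range(stack.array_length()):
        element = stack.element[i].capitalize()
        if element not in VDW_RADII:
            raise ValueError(f"unsupported element {element!r} for atom {stack.atom_name[i]}")
        res_pos = rid_to_pos[res_ids[i]]
        bonded_heavy = n_index_of_res.get(res_pos, -1) if element == "H" else -1
        atoms.append(
            AtomRecord(
                name=stack.atom_name[i],
                element=element,
                residue_index=res_pos,
                vdw_radius=VDW_RADII[element],
                is_polar=element in ("N", "O") or (element == "H" and bonded_heavy >= 0),
                bonded_heavy=bonded_heavy,
            )
        )
    topology = Topology(sequence, atoms)
    return Trajectory(topology, np.asarray(stack.coord, float), frame_spacing)
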