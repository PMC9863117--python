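"""Peptide coordinate construction from internal coordinates.

Chains are grown by the sequential natural-extension (NeRF) placement rule
using the bond lengths and angles of the packaged template table: standard
peptide backbone geometry, L-configured side chains, a deprotonated
(carboxylate) C-terminus and Asp/Glu side chains, and an ammonium N-terminus.
Only heavy atoms and nitrogen-bound hydrogens are built — exactly the atoms
the downstream hydrogen-bond, fluctuation, and surface stages consume.

Everything broadcasts over frames: ``build_frames`` turns an
(n_frames, n_residues, 2) array of backbone dihedrals into a whole
``Trajectory`` in one vectorised pass, which is what makes desk-scale
synthetic trajectories cheap.
"""

from __future__ import annotations

import numpy as np

from .geometry import place_atom
from .model import VDW_RADII, AtomRecord, Conformation, Topology, Trajectory
from .sets import PeptideSequence
from .templates import THREE_LETTER, load_templates

__all__ = [
    "make_topology",
    "build_conformation",
    "build_frames",
    "place_amide_hydrogen",
]


def _atom(name: str, element: str, residue_index: int, bonded_heavy: int = -1) -> AtomRecord:
    polar = element in ("N", "O") or (element == "H" and bonded_heavy >= 0)
    return AtomRecord(
        name=name,
        element=element,
        residue_index=residue_index,
        vdw_radius=VDW_RADII[element],
        is_polar=polar,
        bonded_heavy=bonded_heavy,
    )


def make_topology(sequence: PeptideSequence) -> Topology:
    """Atom list for a sequence: N CA C O (OXT) side chain, then N-bound H."""
    tpl = load_templates()
    atoms: list[AtomRecord] = []
    n_res = len(sequence)
    for i, one in enumerate(sequence, start=1):
        three = THREE_LETTER.get(one)
        if three is None:
            raise ValueError(f"unknown residue symbol {one!r} at position {i}")
        n_index = len(atoms)
        atoms.append(_atom("N", "N", i))
        atoms.append(_atom("CA", "C", i))
        atoms.append(_atom("C", "C", i))
        atoms.append(_atom("O", "O", i))
        if i == n_res:
            atoms.append(_atom("OXT", "O", i))
        for sc in tpl.sidechains[three]:
            atoms.append(_atom(sc.name, sc.element, i))
        if i == 1:
            for h in ("H1", "H2", "H3"):
                atoms.append(_atom(h, "H", i, bonded_heavy=n_index))
        else:
            atoms.append(_atom("H", "H", i, bonded_heavy=n_index))
    return Topology(sequence, atoms)


def _chi_for_residue(three: str, chi_spec, n_frames: int) -> np.ndarray:
    """Normalise a residue's chi angles to shape (n_frames, n_chi)."""
    tpl = load_templates()
    defaults = tpl.chi_defaults[three]
    if chi_spec is None:
        return np.tile(np.asarray(defaults, float), (n_frames, 1))
    arr = np.asarray(chi_spec, float)
    if arr.ndim == 1:
        arr = np.tile(arr, (n_frames, 1))
    if arr.shape != (n_frames, len(defaults)):
        raise ValueError(
            f"residue {three}: expected {len(defaults)} chi angle(s), "
            f"got shape {arr.shape}"
        )
    return arr


def build_frames(
    sequence: PeptideSequence,
    phi_psi: np.ndarray,
    chi: list | None = None,
    frame_spacing: float = 0.5,
) -> Trajectory:
    """Build a trajectory from per-frame backbone (and side-chain) dihedrals.

    Parameters
    ----------
    phi_psi
        Array of shape (n_frames, n_residues, 2) or (n_residues, 2), degrees.
        phi of the first residue is geometrically unused (there is no
        preceding carbonyl); psi of the last residue orients the C-terminal
        carboxylate.
    chi
        Optional list with one entry per residue: ``None`` (template
        rotamer), an (n_chi,) vector used for every frame, or an
        (n_frames, n_chi) array.
    """
    tpl = load_templates()
    bb = tpl.backbone
    L = len(sequence)
    phi_psi = np.asarray(phi_psi, float)
    if phi_psi.ndim == 2:
        phi_psi = phi_psi[None]
    if phi_psi.shape[1:] != (L, 2):
        raise ValueError(
            f"phi_psi shape {phi_psi.shape} does not match (n_frames, {L}, 2)"
        )
    F = phi_psi.shape[0]
    if chi is not None and len(chi) != L:
        raise ValueError(f"chi list length {len(chi)} != sequence length {L}")

    topology = make_topology(sequence)
    coords = np.empty((F, topology.n_atoms, 3))

    # backbone N/CA/C grown residue by residue, vectorised across frames
    n_xyz = np.empty((F, L, 3))
    ca_xyz = np.empty((F, L, 3))
    c_xyz = np.empty((F, L, 3))
    o_xyz = np.empty((F, L, 3))

    n_xyz[:, 0] = 0.0
    ca_xyz[:, 0] = np.array([bb["n_ca"], 0.0, 0.0])
    theta = np.deg2rad(bb["n_ca_c"])
    c_xyz[:, 0] = ca_xyz[:, 0] + bb["ca_c"] * np.array(
        [np.cos(np.pi - theta), np.sin(np.pi - theta), 0.0]
    )
    for i in range(1, L):
        psi_prev = phi_psi[:, i - 1, 1]
        n_xyz[:, i] = place_atom(
            n_xyz[:, i - 1], ca_xyz[:, i - 1], c_xyz[:, i - 1],
            bb["c_n"], bb["ca_c_n"], psi_prev,
        )
        ca_xyz[:, i] = place_atom(
            ca_xyz[:, i - 1], c_xyz[:, i - 1], n_xyz[:, i],
            bb["n_ca"], bb["c_n_ca"], bb["omega"],
        )
        c_xyz[:, i] = place_atom(
            c_xyz[:, i - 1], n_xyz[:, i], ca_xyz[:, i],
            bb["ca_c"], bb["n_ca_c"], phi_psi[:, i, 0],
        )
        # carbonyl O of residue i-1, anti to the new backbone nitrogen
        o_xyz[:, i - 1] = place_atom(
            n_xyz[:, i], ca_xyz[:, i - 1], c_xyz[:, i - 1],
            bb["c_o"], bb["ca_c_o"], 180.0,
        )
    # C-terminal carboxylate: O anti, OXT syn to psi of the last residue
    psi_last = phi_psi[:, L - 1, 1]
    o_xyz[:, L - 1] = place_atom(
        n_xyz[:, L - 1], ca_xyz[:, L - 1], c_xyz[:, L - 1],
        bb["c_oxt"], bb["ca_c_o"], psi_last + 180.0,
    )
    oxt = place_atom(
        n_xyz[:, L - 1], ca_xyz[:, L - 1], c_xyz[:, L - 1],
        bb["c_oxt"], bb["ca_c_o"], psi_last,
    )

    for i in range(L):
        r = i + 1
        coords[:, topology.index_of(r, "N")] = n_xyz[:, i]
        coords[:, topology.index_of(r, "CA")] = ca_xyz[:, i]
        coords[:, topology.index_of(r, "C")] = c_xyz[:, i]
        coords[:, topology.index_of(r, "O")] = o_xyz[:, i]
    coords[:, topology.index_of(L, "OXT")] = oxt

    # side chains from the z-matrix table
    for i, one in enumerate(sequence, start=1):
        three = THREE_LETTER[one]
        rows = tpl.sidechains[three]
        if not rows:
            continue
        chi_arr = _chi_for_residue(three, None if chi is None else chi[i - 1], F)
        placed = {
            "N": n_xyz[:, i - 1],
            "CA": ca_xyz[:, i - 1],
            "C": c_xyz[:, i - 1],
        }
        for row in rows:
            if isinstance(row.torsion, tuple):
                k, offset = row.torsion
                torsion = chi_arr[:, k - 1] + offset
            else:
                torsion = row.torsion
            pos = place_atom(
                placed[row.ref_torsion], placed[row.ref_angle], placed[row.ref_bond],
                row.bond, row.angle, torsion,
            )
            placed[row.name] = pos
            coords[:, topology.index_of(i, row.name)] = pos

    # amide hydrogens (Kabsch-Sander convention) and the N-terminal ammonium
    for i in range(2, L + 1):
        co_dir = c_xyz[:, i - 2] - o_xyz[:, i - 2]
        co_dir = co_dir / np.linalg.norm(co_dir, axis=-1, keepdims=True)
        coords[:, topology.index_of(i, "H")] = n_xyz[:, i - 1] + bb["n_h"] * co_dir
    for h_name, tors in (("H1", 60.0), ("H2", 180.0), ("H3", -60.0)):
        coords[:, topology.index_of(1, h_name)] = place_atom(
            c_xyz[:, 0], ca_xyz[:, 0], n_xyz[:, 0], bb["n_h"], bb["ca_n_h"], tors
        )

    return Trajectory(topology, coords, frame_spacing=frame_spacing)


def build_conformation(
    sequence: PeptideSequence, phi_psi: np.ndarray, chi: list | None = None
) -> Conformation:
    """Build a single conformation; see :func:`build_frames` for arguments."""
    phi_psi = np.asarray(phi_psi, float)
    if phi_psi.ndim != 2:
        raise ValueError("build_conformation expects phi_psi of shape (n_residues, 2)")
    return build_frames(sequence, phi_psi[None], chi=chi).frame(0)


def place_amide_hydrogen(conformation: Conformation, residue_index: int) -> np.ndarray:
    """Reconstruct nitrogen-bound hydrogen position(s) for one residue.

    For residues after the first, returns the single amide H placed 1.01 A
    from N along the preceding peptide bond's C=O direction (the convention
    the secondary-structure assigner uses).  For the first residue, returns
    the three tetrahedral ammonium hydrogens as a (3, 3) array.
    """
    tpl = load_templates()
    bb = tpl.backbone
    top = conformation.topology
    if residue_index < 1 or residue_index > top.n_residues:
        raise ValueError(f"residue_index {residue_index} out of range")
    if residue_index == 1:
        c = conformation.atom_coord(1, "C")
        ca = conformation.atom_coord(1, "CA")
        n = conformation.atom_coord(1, "N")
        return np.stack(
            [
                place_atom(c, ca, n, bb["n_h"], bb["ca_n_h"], tors)
                for tors in (60.0, 180.0, -60.0)
            ]
        )
    for name in ("C", "O"):
        if not top.has_atom(residue_index - 1, name):
            raise ValueError(
                f"residue {residue_index - 1} lacks backbone {name}; cannot place amide H"
            )
    c_prev = conformation.atom_coord(residue_index - 1, "C")
    o_prev = conformation.atom_coord(residue_index - 1, "O")
    n = conformation.atom_coord(residue_index, "N")
    direction = c_prev - o_prev
    direction = direction / np.linalg.norm(direction)
    return n + bb["n_h"] * direction
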