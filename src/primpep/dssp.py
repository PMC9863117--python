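"""Kabsch–Sander secondary-structure assignment.

A from-scratch implementation of the classic pattern-based assigner:
backbone hydrogen bonds are detected with the electrostatic proxy energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  [kcal/mol]

(a bond when E < -0.5 kcal/mol), n-turns at offsets 3/4/5 feed minimal
helices (G/H/I), bridge patterns feed strand labels (E/B), plus turn (T)
and bend (S).  Helical labels H, G and I together form the helix mask that
the occupancy analysis consumes — the aggregation used throughout this
package, where alpha-, 3-10- and pi-helices all count as "helix".

All pattern logic runs on boolean arrays over (frame, residue), so a whole
trajectory is assigned in a handful of numpy passes.  The amide hydrogen is
always re-derived from the preceding peptide bond's C=O direction, keeping
the energy well-defined even for input lacking explicit hydrogens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Conformation, Trajectory

__all__ = [
    "HBOND_ENERGY_CUTOFF",
    "SecondaryStructureRecord",
    "backbone_hbond_energy",
    "assign_frame",
    "assign_trajectory",
]

#: coupling constant q1*q2*f of the electrostatic H-bond model, kcal*A/mol
_Q1Q2F = 0.084 * 332.0
#: declare a backbone H-bond below this energy, kcal/mol
HBOND_ENERGY_CUTOFF = -0.5
#: minimal donor/acceptor chain separation for the energy to be evaluated
_MIN_SEPARATION = 2
#: C-alpha bend threshold for the S label, degrees
_BEND_ANGLE = 70.0

_HELIX_LABELS = ("H", "G", "I")


@dataclass
class SecondaryStructureRecord:
    """Per-frame, per-residue labels and the derived helix mask."""

    labels: np.ndarray  # (n_frames, n_residues) of unicode symbols
    helix_mask: np.ndarray  # (n_frames, n_residues) bool

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def n_residues(self) -> int:
        return self.labels.shape[1]

    def helix_occupancy(self) -> np.ndarray:
        """Fraction of frames each residue carries a helical label."""
        return self.helix_mask.mean(axis=0)

    def to_frame_table(self):
        """Label matrix as a pandas DataFrame (rows frames, columns residues)."""
        import pandas as pd

        return pd.DataFrame(
            self.labels,
            columns=[f"res{r}" for r in range(1, self.n_residues + 1)],
        )

    def occupancy_summary(self) -> dict:
        """Compact per-residue helix-occupancy mapping (JSON-serialisable)."""
        occ = self.helix_occupancy()
        return {
            "n_frames": int(self.n_frames),
            "helix_occupancy": {
                str(r + 1): round(float(occ[r]), 6) for r in range(self.n_residues)
            },
        }


def _backbone_arrays(traj: Trajectory):
    """(F, L, 3) arrays for N, CA, C, O plus the reconstructed amide H."""
    top = traj.topology
    out = {}
    for name in ("N", "CA", "C", "O"):
        idx = top.backbone_indices(name)
        if np.any(idx < 0):
            missing = int(np.nonzero(idx < 0)[0][0]) + 1
            raise ValueError(f"residue {missing} lacks backbone atom {name}")
        out[name] = traj.coords[:, idx, :]
    n, c, o = out["N"], out["C"], out["O"]
    co = c[:, :-1] - o[:, :-1]
    co = co / np.linalg.norm(co, axis=-1, keepdims=True)
    h = np.full_like(n, np.nan)
    h[:, 1:] = n[:, 1:] + 1.01 * co
    out["H"] = h
    return out


def _hbond_matrix(bb: dict[str, np.ndarray]) -> np.ndarray:
    """Boolean (F, L, L): [f, d, a] true when N-H of d bonds to C=O of a."""
    n, h, c, o = bb["N"], bb["H"], bb["C"], bb["O"]
    F, L = n.shape[:2]

    def pairwise(x, y):
        # squared-distance expansion keeps this in BLAS matmuls
        d2 = (
            np.einsum("fli,fli->fl", x, x)[:, :, None]
            + np.einsum("fli,fli->fl", y, y)[:, None, :]
            - 2.0 * (x @ y.transpose(0, 2, 1))
        )
        return np.sqrt(np.maximum(d2, 1e-18))

    energy = _Q1Q2F * (
        1.0 / pairwise(n, o)
        + 1.0 / pairwise(h, c)
        - 1.0 / pairwise(h, o)
        - 1.0 / pairwise(n, c)
    )
    donors, acceptors = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    valid = np.abs(donors - acceptors) >= _MIN_SEPARATION
    valid &= donors > 0  # first residue has no amide H
    hb = (energy < HBOND_ENERGY_CUTOFF) & valid[None]
    return hb


def backbone_hbond_energy(
    donor_residue: int, acceptor_residue: int, conformation: Conformation
) -> float:
    """Electrostatic proxy energy (kcal/mol) for one donor->acceptor pair.

    ``donor_residue`` contributes N-H, ``acceptor_residue`` C=O; residues are
    1-based.  Missing atoms yield +inf (reported as non-bonded) rather than
    an exception so a single damaged residue cannot abort a frame.
    """
    if abs(donor_residue - acceptor_residue) < _MIN_SEPARATION:
        raise ValueError("donor and acceptor must be >= 2 residues apart")
    top = conformation.topology
    needed = [
        (donor_residue, "N"),
        (acceptor_residue, "C"),
        (acceptor_residue, "O"),
        (donor_residue - 1, "C"),
        (donor_residue - 1, "O"),
    ]
    if any(not top.has_atom(r, nm) for r, nm in needed) or donor_residue == 1:
        return float("inf")
    n = conformation.atom_coord(donor_residue, "N")
    c_prev = conformation.atom_coord(donor_residue - 1, "C")
    o_prev = conformation.atom_coord(donor_residue - 1, "O")
    direction = c_prev - o_prev
    h = n + 1.01 * direction / np.linalg.norm(direction)
    c = conformation.atom_coord(acceptor_residue, "C")
    o = conformation.atom_coord(acceptor_residue, "O")

    def r(x, y):
        return max(float(np.linalg.norm(x - y)), 1e-9)

    return _Q1Q2F * (1.0 / r(n, o) + 1.0 / r(h, c) - 1.0 / r(h, o) - 1.0 / r(n, c))


def _assign_from_hbonds(hb: np.ndarray, ca: np.ndarray) -> np.ndarray:
    """Label matrix (F, L) from the H-bond tensor and C-alpha coordinates."""
    F, L = hb.shape[:2]
    labels = np.full((F, L), "-", dtype="<U1")
    if L < 3:
        return labels

    res = np.arange(L)

    def turn(nn: int) -> np.ndarray:
        """(F, L) boolean: n-turn starting at acceptor residue i."""
        t = np.zeros((F, L), bool)
        if L > nn:
            i = res[: L - nn]
            t[:, : L - nn] = hb[:, i + nn, i]
        return t

    turns = {nn: turn(nn) for nn in (3, 4, 5)}

    def minimal_helix(nn: int) -> np.ndarray:
        """Residues i..i+nn-1 where consecutive n-turns start at i-1 and i."""
        helix = np.zeros((F, L), bool)
        t = turns[nn]
        start = np.zeros((F, L), bool)
        start[:, 1:] = t[:, 1:] & t[:, :-1]  # turns at i-1 and i (index i)
        for off in range(nn):
            if off == 0:
                helix |= start
            else:
                helix[:, off:] |= start[:, : L - off]
        return helix

    helix4 = minimal_helix(4)
    helix3 = minimal_helix(3)
    helix5 = minimal_helix(5)

    # bridges (Kabsch-Sander parallel/antiparallel patterns), |i-j| >= 3
    def shift_hb(di: int, dj: int) -> np.ndarray:
        """hb[f, i+di, j+dj] aligned on (f, i, j), False out of range."""
        out = np.zeros_like(hb)
        i0, i1 = max(0, -di), min(L, L - di)
        j0, j1 = max(0, -dj), min(L, L - dj)
        out[:, i0:i1, j0:j1] = hb[:, i0 + di : i1 + di, j0 + dj : j1 + dj]
        return out

    par = (shift_hb(-1, 0) & shift_hb(0, +1).transpose(0, 2, 1)) | (
        shift_hb(0, -1).transpose(0, 2, 1) & shift_hb(+1, 0)
    )
    anti = (hb & hb.transpose(0, 2, 1)) | (
        shift_hb(-1, +1) & shift_hb(-1, +1).transpose(0, 2, 1)
    )
    ii, jj = np.meshgrid(res, res, indexing="ij")
    far = np.abs(ii - jj) >= 3
    bridge = (par | anti) & far[None]
    has_bridge = bridge.any(axis=2)
    # a bridge residue extends to strand (E) when an adjacent residue also
    # bridges to a partner adjacent to one of its own partners (a ladder)
    neighbor = np.zeros_like(bridge)
    neighbor[:, :, 1:] |= bridge[:, :, :-1]
    neighbor[:, :, :-1] |= bridge[:, :, 1:]
    ladder = np.zeros((F, L), bool)
    ladder[:, 1:] |= (bridge[:, 1:] & neighbor[:, :-1]).any(axis=2)
    ladder[:, :-1] |= (bridge[:, :-1] & neighbor[:, 1:]).any(axis=2)
    strand_e = has_bridge & ladder
    strand_b = has_bridge & ~ladder

    # turn label: residues strictly inside any n-turn
    turn_t = np.zeros((F, L), bool)
    for nn, t in turns.items():
        for off in range(1, nn):
            turn_t[:, off:] |= t[:, : L - off]

    # bend: C-alpha direction change > 70 degrees
    bend = np.zeros((F, L), bool)
    if L >= 5:
        v1 = ca[:, 2:-2] - ca[:, :-4]
        v2 = ca[:, 4:] - ca[:, 2:-2]
        cosang = np.sum(v1 * v2, axis=-1) / (
            np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
        )
        bend[:, 2:-2] = np.degrees(np.arccos(np.clip(cosang, -1, 1))) > _BEND_ANGLE

    # priority: H > E > B > G > I > T > S
    for mask, sym in (
        (bend, "S"),
        (turn_t, "T"),
        (helix5, "I"),
        (helix3, "G"),
        (strand_b, "B"),
        (strand_e, "E"),
        (helix4, "H"),
    ):
        labels[mask] = sym
    return labels


def assign_trajectory(trajectory: Trajectory) -> SecondaryStructureRecord:
    """Assign labels for every frame and derive the {H, G, I} helix mask."""
    L = trajectory.topology.n_residues
    if L < 3:
        labels = np.full((trajectory.n_frames, L), "-", dtype="<U1")
        return SecondaryStructureRecord(labels, np.zeros(labels.shape, bool))
    bb = _backbone_arrays(trajectory)
    hb = _hbond_matrix(bb)
    labels = _assign_from_hbonds(hb, bb["CA"])
    helix_mask = np.isin(labels, _HELIX_LABELS)
    return SecondaryStructureRecord(labels, helix_mask)


def assign_frame(conformation: Conformation) -> np.ndarray:
    """Per-residue labels for a single conformation."""
    traj = Trajectory(conformation.topology, conformation.coords[None], 1.0)
    return assign_trajectory(traj).labels[0]
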