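"""Molecular data model: atoms, topology, single conformations, trajectories.

The model is deliberately small: one peptide chain of the six residue types
G, A, D, V, E, L, heavy atoms plus nitrogen-bound hydrogens (backbone amides
and the N-terminal ammonium).  Coordinates live in dense numpy arrays so that
whole trajectories can be processed vectorised; ``Conformation`` is a single
frame view and ``Trajectory`` an ordered stack of frames sharing one topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sets import PeptideSequence

__all__ = ["VDW_RADII", "AtomRecord", "Topology", "Conformation", "Trajectory"]

#: Bondi van der Waals radii (Angstrom) used for surface-area work.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "H": 1.20}


@dataclass(frozen=True)
class AtomRecord:
    """Static description of one atom (coordinates live in the frame arrays)."""

    name: str
    element: str
    residue_index: int  # 1-based
    vdw_radius: float
    is_polar: bool
    #: index of the heavy atom this hydrogen is bonded to, -1 for heavy atoms
    bonded_heavy: int = -1

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name}: vdw_radius must be > 0")


class Topology:
    """Atom metadata for one peptide, shared by all frames of a trajectory."""

    def __init__(self, sequence: PeptideSequence, atoms: list[AtomRecord]):
        self.sequence = sequence
        self.atoms = list(atoms)
        self.n_atoms = len(self.atoms)
        self.n_residues = len(sequence)
        # residue (1-based) -> contiguous [start, stop) atom index range
        self.residue_ranges: dict[int, tuple[int, int]] = {}
        for i, atom in enumerate(self.atoms):
            r = atom.residue_index
            if r not in self.residue_ranges:
                self.residue_ranges[r] = (i, i + 1)
            else:
                s, _ = self.residue_ranges[r]
                self.residue_ranges[r] = (s, i + 1)
        self._name_index: dict[tuple[int, str], int] = {
            (a.residue_index, a.name): i for i, a in enumerate(self.atoms)
        }

    def index_of(self, residue_index: int, name: str) -> int:
        """Flat atom index of ``name`` in residue ``residue_index`` (1-based)."""
        return self._name_index[(residue_index, name)]

    def has_atom(self, residue_index: int, name: str) -> bool:
        return (residue_index, name) in self._name_index

    def backbone_indices(self, name: str) -> np.ndarray:
        """Per-residue flat indices of a backbone atom (-1 where absent)."""
        return np.array(
            [self._name_index.get((r, name), -1) for r in range(1, self.n_residues + 1)],
            dtype=int,
        )

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    @property
    def polar_mask(self) -> np.ndarray:
        return np.array([a.is_polar for a in self.atoms])

    def donor_pairs(self) -> list[tuple[int, int]]:
        """(heavy, hydrogen) index pairs for every N/O-bound hydrogen."""
        return [
            (a.bonded_heavy, i)
            for i, a in enumerate(self.atoms)
            if a.element == "H" and a.bonded_heavy >= 0
        ]

    def acceptor_indices(self) -> np.ndarray:
        """Indices of all N and O atoms (hydrogen-bond acceptor candidates)."""
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.element in ("N", "O")], dtype=int
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Topology)
            and self.sequence.residues == other.sequence.residues
            and [(a.name, a.residue_index) for a in self.atoms]
            == [(a.name, a.residue_index) for a in other.atoms]
        )


@dataclass
class Conformation:
    """One frame: a topology plus an (n_atoms, 3) coordinate array."""

    topology: Topology
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match topology "
                f"({self.topology.n_atoms} atoms)"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")

    def atom_coord(self, residue_index: int, name: str) -> np.ndarray:
        return self.coords[self.topology.index_of(residue_index, name)]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformation":
        return Conformation(self.topology, self.coords @ np.asarray(rotation).T + translation)


@dataclass
class Trajectory:
    """Ordered frames sharing one topology, with a fixed time spacing in ps."""

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    frame_spacing: float = 0.5

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"(n_frames, {self.topology.n_atoms}, 3)"
            )
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be > 0")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def duration_ps(self) -> float:
        return self.n_frames * self.frame_spacing

    def frame(self, i: int) -> Conformation:
        return Conformation(self.topology, self.coords[i])

    def __len__(self) -> int:
        return self.n_frames

    def ca_coords(self) -> np.ndarray:
        """(n_frames, n_residues, 3) C-alpha coordinates."""
        idx = self.topology.backbone_indices("CA")
        return self.coords[:, idx, :]

    def tail(self, n_frames: int) -> "Trajectory":
        return Trajectory(self.topology, self.coords[-n_frames:], self.frame_spacing)
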