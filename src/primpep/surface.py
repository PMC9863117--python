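"""Shrake–Rupley solvent-accessible surface area and polar surface area.

Each atom's accessible area is estimated by sampling a deterministic
golden-section spiral of points on its probe-expanded sphere and counting
the fraction not buried inside any neighbour's expanded sphere:

    area_i = 4 pi (r_i + r_probe)^2 * accessible_i / n_points

The polar surface area (PSA) sums the accessible area of polar atoms
(N, O, and N/O-bound hydrogens); PSA/SASA serves as a hydrophilicity
index.  The point lattice is fixed in the laboratory frame, so areas are
rotation-invariant only to within the sampling resolution (about 1% at
the default 960 points).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .model import Conformation, Trajectory

__all__ = ["SurfaceResult", "sphere_points", "shrake_rupley", "trajectory_surface"]

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960


@dataclass
class SurfaceResult:
    per_atom_area: np.ndarray  # A^2, one entry per atom
    sasa: float
    psa: float

    @property
    def psa_ratio(self) -> float:
        return self.psa / self.sasa if self.sasa > 0 else float("nan")


@lru_cache(maxsize=8)
def sphere_points(n_points: int) -> np.ndarray:
    """Deterministic golden-section spiral of ``n_points`` unit vectors."""
    if n_points < 64:
        raise ValueError(f"n_points must be >= 64, got {n_points}")
    i = np.arange(n_points) + 0.5
    z = 1.0 - 2.0 * i / n_points
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _per_atom_areas(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float,
    points: np.ndarray,
) -> np.ndarray:
    n_atoms = coords.shape[0]
    expanded = radii + probe_radius
    areas = np.zeros(n_atoms)

    # coincident duplicates would spuriously bury each other; keep the first
    active = np.ones(n_atoms, bool)
    for i in range(n_atoms):
        if not active[i]:
            continue
        dup = (
            active
            & (np.arange(n_atoms) > i)
            & (np.linalg.norm(coords - coords[i], axis=1) < 1e-6)
        )
        if np.any(dup):
            warnings.warn(
                f"excluding {int(dup.sum())} atom(s) coincident with atom {i} "
                "from surface computation",
                stacklevel=3,
            )
            active[dup] = False

    idx_active = np.nonzero(active)[0]
    pos = coords[idx_active]
    rad = expanded[idx_active]
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)
    neighbor = dist < (rad[:, None] + rad[None, :])

    n_points = points.shape[0]
    rad2 = rad**2
    for k, i in enumerate(idx_active):
        nb = np.nonzero(neighbor[k])[0]
        if nb.size == 0:
            accessible = n_points
        else:
            surf = coords[i] + rad[k] * points
            # squared-distance expansion keeps the inner test in BLAS
            nbpos = pos[nb]
            d2 = (
                np.einsum("pi,pi->p", surf, surf)[:, None]
                + np.einsum("ni,ni->n", nbpos, nbpos)[None, :]
                - 2.0 * (surf @ nbpos.T)
            )
            buried = np.any(d2 < rad2[nb][None, :], axis=1)
            accessible = int(np.count_nonzero(~buried))
        areas[i] = 4.0 * np.pi * rad2[k] * accessible / n_points
    return areas


def shrake_rupley(
    conformation: Conformation,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    polar_hydrogens: bool = True,
) -> SurfaceResult:
    """Accessible surface of one conformation.

    ``polar_hydrogens=False`` restricts the polar sum to heavy N/O atoms
    (the alternative reading of "polar surface area").
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    top = conformation.topology
    areas = _per_atom_areas(
        conformation.coords, top.vdw_radii, probe_radius, sphere_points(n_points)
    )
    polar = top.polar_mask
    if not polar_hydrogens:
        polar = polar & (top.elements != "H")
    return SurfaceResult(
        per_atom_area=areas, sasa=float(areas.sum()), psa=float(areas[polar].sum())
    )


def trajectory_surface(
    window: Trajectory,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    stride: int = 1,
    polar_hydrogens: bool = True,
) -> SurfaceResult:
    """Trajectory-averaged surface areas.

    SASA and PSA are arithmetic means over every ``stride``-th frame;
    the reported ratio is (mean PSA) / (mean SASA).  ``per_atom_area``
    holds the per-atom means.
    """
    frames = range(0, window.n_frames, max(1, stride))
    per_atom = np.zeros(window.topology.n_atoms)
    count = 0
    for f in frames:
        res = shrake_rupley(
            window.frame(f),
            probe_radius=probe_radius,
            n_points=n_points,
            polar_hydrogens=polar_hydrogens,
        )
        per_atom += res.per_atom_area
        count += 1
    per_atom /= count
    polar = window.topology.polar_mask
    if not polar_hydrogens:
        polar = polar & (window.topology.elements != "H")
    return SurfaceResult(
        per_atom_area=per_atom,
        sasa=float(per_atom.sum()),
        psa=float(per_atom[polar].sum()),
    )
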