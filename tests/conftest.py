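"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from primpep import PeptideSequence, build_frames
from primpep.model import Trajectory

HELIX = (-57.0, -47.0)
EXTENDED = (-135.0, 135.0)
PPII = (-75.0, 145.0)


@pytest.fixture(scope="session")
def helix_sequence() -> PeptideSequence:
    return PeptideSequence("helix20", "ADAVEALDVAVELADVAEAL", set_name="test")


@pytest.fixture(scope="session")
def helix_trajectory(helix_sequence) -> Trajectory:
    """Three identical ideal alpha-helix frames."""
    pp = np.tile(HELIX, (3, len(helix_sequence), 1))
    return build_frames(helix_sequence, pp)


@pytest.fixture(scope="session")
def extended_trajectory(helix_sequence) -> Trajectory:
    pp = np.tile(EXTENDED, (1, len(helix_sequence), 1))
    return build_frames(helix_sequence, pp)


def random_mixed_conformation(rng: np.random.Generator, length: int = 20):
    """A peptide with random helical/coil stretches and dihedral jitter."""
    seq = PeptideSequence("mixed", "".join(rng.choice(list("GADVEL"), length)))
    pp = np.empty((1, length, 2))
    state = rng.random() < 0.5
    for i in range(length):
        if rng.random() < 0.25:  # switch stretches cooperatively
            state = not state
        base = HELIX if state else (EXTENDED if rng.random() < 0.5 else PPII)
        pp[0, i] = np.asarray(base) + rng.normal(0.0, 8.0, 2)
    return build_frames(seq, pp)


def quaternion_superpose(reference: np.ndarray, mobile: np.ndarray) -> float:
    """Independent RMSD oracle: Horn's quaternion method (proper rotations).

    Builds the 4x4 key matrix from the correlation of the centred point
    sets; the largest eigenvalue gives the minimal RMSD in closed form.
    """
    ref = reference - reference.mean(axis=0)
    mob = mobile - mobile.mean(axis=0)
    m = mob.T @ ref
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    msd = (np.sum(ref**2) + np.sum(mob**2) - 2.0 * lam) / reference.shape[0]
    return float(np.sqrt(max(msd, 0.0)))


def two_sphere_area(r1: float, r2: float, d: float) -> tuple[float, float]:
    """Closed-form exposed areas of two intersecting spheres (cap formula)."""
    if d >= r1 + r2:
        return 4 * np.pi * r1**2, 4 * np.pi * r2**2
    x1 = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    h1 = r1 - x1
    h2 = r2 - (d - x1)
    a1 = 4 * np.pi * r1**2 - 2 * np.pi * r1 * h1
    a2 = 4 * np.pi * r2**2 - 2 * np.pi * r2 * h2
    return a1, a2
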