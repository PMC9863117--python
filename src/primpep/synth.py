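"""Synthetic peptide trajectories with known helix occupancy.

Stands in for long molecular-dynamics runs when exercising the analysis
pipeline: helix formation is modelled at segment level (cooperative
blocks), each segment switching between a helical and a coil state as a
two-state Markov chain with a prescribed long-run occupancy and
frame-to-frame persistence (emulating MD autocorrelation).  Helical frames
use alpha-helical backbone dihedrals (-57, -47) with Gaussian jitter; coil
frames sample beta/polyproline-II basins.  Because the secondary-structure
assigner aggregates alpha-, 3-10- and pi-helical labels into one helix
mask, a contiguous block of helical geometry is detected exactly at the
declared residues (the block edges pick up 3-10 labels where the
alpha-helical hydrogen-bond pattern cannot complete), which is what makes
the generator's ground truth exact.

The generator validates the measurement machinery; it makes no claim that
its occupancies match any force field's propensities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .builder import build_frames
from .model import Trajectory
from .sets import AminoAcidSet, PeptideSequence, generate_sequences
from .templates import THREE_LETTER, load_templates

__all__ = [
    "HELIX_PHI_PSI",
    "DEFAULT_COIL_BASINS",
    "DEFAULT_PROPENSITY",
    "HelixSegment",
    "SyntheticSpec",
    "GroundTruth",
    "synthesize_trajectory",
    "effective_sample_size",
    "experiment_specs",
    "multi_set_experiment",
]

#: canonical alpha-helix backbone dihedrals (phi, psi) in degrees
HELIX_PHI_PSI = (-57.0, -47.0)
#: coil basins as ((phi, psi), weight): beta and polyproline-II regions
DEFAULT_COIL_BASINS = (((-135.0, 135.0), 0.5), ((-75.0, 145.0), 0.5))
#: default helix propensities for the synthetic experiment: E and L high,
#: G low, with D intermediate-high and A/V intermediate-low.  The values are
#: synthetic stand-ins, not physical propensities: they were chosen by a
#: design-time power analysis so that the compositional axes separating the
#: study alphabets (the E and D shares) carry enough signal for a
#: 20-peptide experiment to rank the sets reliably.
DEFAULT_PROPENSITY = {"G": 0.05, "A": 0.15, "D": 0.40, "V": 0.15, "E": 1.0, "L": 1.0}
#: logistic mapping from mean segment propensity to helix occupancy
OCCUPANCY_MIDPOINT = 0.28
OCCUPANCY_SLOPE = 30.0


@dataclass(frozen=True)
class HelixSegment:
    """Residue range [start, stop] (1-based, inclusive) switching as a block."""

    start: int
    stop: int
    occupancy: float
    persistence: float = 0.9  # frame-to-frame state correlation

    def __post_init__(self) -> None:
        if self.stop < self.start:
            raise ValueError(f"segment [{self.start}, {self.stop}]: stop < start")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"segment occupancy {self.occupancy} outside [0, 1]")
        if not 0.0 <= self.persistence < 1.0:
            raise ValueError(f"segment persistence {self.persistence} outside [0, 1)")

    @property
    def residues(self) -> range:
        return range(self.start, self.stop + 1)


@dataclass
class SyntheticSpec:
    sequence: PeptideSequence
    segments: list[HelixSegment]
    n_frames: int
    coil_basins: tuple = DEFAULT_COIL_BASINS
    noise_sigma: float = 8.0  # degrees of jitter on all dihedrals
    frame_spacing: float = 0.5  # ps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        L = len(self.sequence)
        occupied: set[int] = set()
        for seg in self.segments:
            if seg.start < 1 or seg.stop > L:
                raise ValueError(
                    f"segment [{seg.start}, {seg.stop}] outside sequence of length {L}"
                )
            overlap = occupied & set(seg.residues)
            if overlap:
                raise ValueError(f"segments overlap at residues {sorted(overlap)}")
            occupied |= set(seg.residues)


@dataclass
class GroundTruth:
    """Exact per-residue truth accompanying a synthetic trajectory."""

    occupancy: np.ndarray  # stationary target per residue
    realized_occupancy: np.ndarray  # realised helix-state frequency
    fluctuation_class: list[str]  # "stable" / "intermediate" / "mobile"


def _markov_states(
    n_frames: int, occupancy: float, persistence: float, rng: np.random.Generator
) -> np.ndarray:
    """Two-state chain with stationary P(helix)=occupancy, given persistence."""
    if occupancy in (0.0, 1.0):
        return np.full(n_frames, bool(occupancy))
    p_stay = occupancy + persistence * (1.0 - occupancy)
    p_enter = occupancy * (1.0 - persistence)
    u = rng.random(n_frames)
    states = np.empty(n_frames, bool)
    states[0] = u[0] < occupancy
    for t in range(1, n_frames):
        states[t] = u[t] < (p_stay if states[t - 1] else p_enter)
    return states


def effective_sample_size(n_frames: int, persistence: float) -> float:
    """Frames corrected for Markov autocorrelation: n (1-rho)/(1+rho)."""
    return n_frames * (1.0 - persistence) / (1.0 + persistence)


def synthesize_trajectory(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Generate a seeded trajectory plus its exact ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    L = len(spec.sequence)
    F = spec.n_frames

    basin_centers = np.array([b[0] for b in spec.coil_basins])
    basin_weights = np.array([b[1] for b in spec.coil_basins], float)
    basin_weights /= basin_weights.sum()

    # base coil dihedrals everywhere, then overwrite helical stretches
    basin_idx = rng.choice(len(basin_centers), size=(F, L), p=basin_weights)
    phi_psi = basin_centers[basin_idx] + rng.normal(0.0, spec.noise_sigma, (F, L, 2))

    helix_state = np.zeros((F, L), bool)  # declared segment state per residue
    for seg in spec.segments:
        states = _markov_states(F, seg.occupancy, seg.persistence, rng)
        span = slice(seg.start - 1, seg.stop)
        helical = np.tile(np.array(HELIX_PHI_PSI), (F, seg.stop - seg.start + 1, 1))
        helical += rng.normal(0.0, spec.noise_sigma, helical.shape)
        phi_psi[:, span][states] = helical[states]
        helix_state[:, seg.start - 1 : seg.stop] = states[:, None]

    # side-chain rotamers: template defaults plus the same jitter
    tpl = load_templates()
    chi = []
    for one in spec.sequence:
        defaults = tpl.chi_defaults[THREE_LETTER[one]]
        if defaults:
            chi.append(
                np.asarray(defaults) + rng.normal(0.0, spec.noise_sigma, (F, len(defaults)))
            )
        else:
            chi.append(None)

    traj = build_frames(spec.sequence, phi_psi, chi=chi, frame_spacing=spec.frame_spacing)

    occupancy = np.zeros(L)
    for seg in spec.segments:
        occupancy[seg.start - 1 : seg.stop] = seg.occupancy
    realized = helix_state.mean(axis=0)
    classes = [
        "stable" if occ >= 0.8 else ("mobile" if occ <= 0.2 else "intermediate")
        for occ in occupancy
    ]
    return traj, GroundTruth(occupancy, realized, classes)


def _derived_seed(*parts: int) -> int:
    """Stable sub-stream seed below 2**31 from integer key parts."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def segment_occupancy(
    sequence: PeptideSequence,
    segment: tuple[int, int],
    propensity_map: dict[str, float],
    midpoint: float = OCCUPANCY_MIDPOINT,
    slope: float = OCCUPANCY_SLOPE,
) -> float:
    """Monotone map from mean residue propensity over the segment to occupancy.

    occupancy = logistic(slope * (mean propensity - midpoint)): a steep but
    smooth sigmoid, so windows rich in high-propensity residues switch to
    near-permanent helix while poor windows stay essentially coil.
    """
    start, stop = segment
    window = sequence.residues[start - 1 : stop]
    missing = sorted(set(window) - set(propensity_map))
    if missing:
        raise ValueError(f"propensity_map lacks entries for residues {missing}")
    mean_p = float(np.mean([propensity_map[r] for r in window]))
    return float(1.0 / (1.0 + np.exp(-slope * (mean_p - midpoint))))


def experiment_specs(
    sets: list[AminoAcidSet],
    n_peptides: int,
    n_frames: int,
    seed: int,
    propensity_map: dict[str, float] | None = None,
    length: int = 20,
    segments: tuple[tuple[int, int], ...] = ((3, 9), (12, 18)),
    persistence: float = 0.9,
    frame_spacing: float = 0.5,
) -> list[SyntheticSpec]:
    """Deterministic specs for a multi-set synthetic experiment.

    For each set, ``n_peptides`` random sequences are drawn; each sequence
    carries independent helix segments (default the two interior windows
    3-9 and 12-18) whose occupancies follow the mean helix propensity of
    their residues.  Two disjoint windows double the compositional
    information a 20-mer contributes, which is what gives a 20-peptide
    experiment its discriminating power.
    """
    if propensity_map is None:
        propensity_map = DEFAULT_PROPENSITY
    specs = []
    for s_idx, aa_set in enumerate(sets):
        seqs = generate_sequences(
            aa_set, n=n_peptides, length=length, seed=_derived_seed(seed, s_idx)
        )
        for p_idx, seq in enumerate(seqs):
            segs = [
                HelixSegment(
                    a, b, segment_occupancy(seq, (a, b), propensity_map),
                    persistence=persistence,
                )
                for a, b in segments
            ]
            specs.append(
                SyntheticSpec(
                    sequence=seq,
                    segments=segs,
                    n_frames=n_frames,
                    frame_spacing=frame_spacing,
                    seed=_derived_seed(seed, s_idx, p_idx),
                )
            )
    return specs


def multi_set_experiment(
    sets: list[AminoAcidSet],
    n_peptides: int,
    n_frames: int,
    seed: int,
    propensity_map: dict[str, float] | None = None,
    outdir: str | Path | None = None,
    **spec_kwargs,
) -> tuple[pd.DataFrame, list[tuple[SyntheticSpec, Trajectory, GroundTruth]]]:
    """Generate every trajectory of a multi-set experiment.

    Returns the manifest (one row per peptide: id, set, seed, sequence,
    segment, target occupancy) and the list of (spec, trajectory, truth).
    With ``outdir`` set, trajectories are written as multi-model PDB files
    next to ``manifest.csv`` and ``truth.json``.
    """
    from .pdbio import write_trajectory  # local import avoids a cycle

    specs = experiment_specs(
        sets, n_peptides, n_frames, seed, propensity_map, **spec_kwargs
    )
    rows = []
    results = []
    truths: dict[str, list[float]] = {}
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for spec in specs:
        traj, truth = synthesize_trajectory(spec)
        rows.append(
            {
                "id": spec.sequence.id,
                "set": spec.sequence.set_name,
                "seed": spec.seed,
                "sequence": spec.sequence.residues,
                "segments": ";".join(f"{s.start}-{s.stop}" for s in spec.segments),
                "occupancies": ";".join(f"{s.occupancy:.4f}" for s in spec.segments),
            }
        )
        truths[spec.sequence.id] = [float(x) for x in truth.occupancy]
        results.append((spec, traj, truth))
        if out is not None:
            write_trajectory(traj, out / f"{spec.sequence.id}.pdb")
    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
        (out / "truth.json").write_text(json.dumps(truths, indent=1, sort_keys=True))
    return manifest, results
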