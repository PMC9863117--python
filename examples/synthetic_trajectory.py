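"""Synthesize a trajectory with known helix occupancy and recover it.

Builds a 20-mer whose residues 6-15 switch between helix and coil as a
correlated two-state process occupying the helical state 70% of the time,
then runs the secondary-structure assigner and compares the measured
per-residue helix occupancy with the generator's ground truth.
"""

import numpy as np

from primpep import PeptideSequence, assign_trajectory, synthesize_trajectory
from primpep.synth import HelixSegment, SyntheticSpec

spec = SyntheticSpec(
    sequence=PeptideSequence("demo", "AVEADEVAAEVDAEAVADEA"),
    segments=[HelixSegment(start=6, stop=15, occupancy=0.7, persistence=0.9)],
    n_frames=2000,
    seed=7,
)
trajectory, truth = synthesize_trajectory(spec)
record = assign_trajectory(trajectory)
measured = record.helix_occupancy()

print("res  truth  measured")
for i in range(20):
    print(f"{i + 1:3d}  {truth.realized_occupancy[i]:.3f}  {measured[i]:.3f}")
print(f"\nsegment mean: truth {truth.realized_occupancy[5:15].mean():.3f}, "
      f"measured {measured[5:15].mean():.3f}")
# The assigner recovers the realised switching frequency of the segment;
# residues outside the declared segment stay at zero occupancy.
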