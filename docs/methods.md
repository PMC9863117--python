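# Methods

This note documents the models, conventions and design choices behind
`primpep`, in the order the pipeline applies them.

## Sequence model

Each alphabet is a map from one-letter residue symbols to positive relative
weights; sampling normalises the weights and draws residues i.i.d. per
position. Composition therefore holds in expectation, not exactly per
sequence — matching the notion of residue "appearance rates" rather than a
fixed-composition shuffle. Sequence ids are `{set}_{index:03d}` (index from
1) for stable joins across pipeline outputs. The RNG is a numpy
`SeedSequence` tree: each sequence draws from its own substream, so
enlarging `n` extends a collection without reshuffling earlier members.

## Coordinate model

Peptides are built from internal coordinates by sequential three-atom (NeRF)
placement, using standard backbone geometry (N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å, C–O 1.231 Å; N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°,
CA–C–O 120.8°; ω = 180°) and ideal tetrahedral side chains from a
plain-text template table shipped as package data. The improper torsion
C–N–CA–CB = −120° selects the L-configuration. Protonation states follow
the charged-termini convention for the study's conditions: ammonium
N-terminus (three H), carboxylate C-terminus and Asp/Glu side chains
(two equivalent oxygens at 1.25 Å, no hydroxyl H). Only heavy atoms and
nitrogen-bound hydrogens are built — exactly the atoms the downstream
stages consume. Amide hydrogens sit 1.01 Å from N along the preceding
peptide bond's C=O direction, the reconstruction convention of the
secondary-structure assigner, so assignment is identical whether or not a
trajectory arrives with explicit hydrogens. Side-chain torsions default to
template rotamers when a caller supplies none, keeping fixtures
deterministic.

Construction is vectorised over frames: an (n_frames, n_residues, 2)
dihedral array becomes a whole trajectory in a few numpy passes, which is
what makes 2,000-frame synthetic trajectories take well under 0.1 s.

Trajectories are exchanged as multi-model PDB (biotite behind the I/O
surface); the frame spacing travels in a `REMARK 250` line. MODEL blocks
are pre-validated so an inconsistent file is rejected with the offending
model number.

## Secondary structure

The assigner is a full reimplementation of the Kabsch–Sander pattern rules.
Backbone H-bond energy uses the electrostatic proxy with coupling constant
0.084 · 332 kcal·Å/mol and the −0.5 kcal/mol cutoff (both from the original
assigner's publication; neither is fixed by the study protocol itself, so
they live in module constants). Donors and acceptors must be ≥ 2 residues
apart. n-turns at offsets 3/4/5 give minimal helices (two consecutive
turns; residues i..i+n−1), Kabsch–Sander parallel/antiparallel patterns
give bridges (isolated → B, laddered → E), in-turn residues get T, and a
Cα direction change > 70° gives the bend S. Label priority is
H > E > B > G > I > T > S, with π-helix below α so that α wins overlaps —
matching the behaviour of the distributed assigner. The **helix mask** is
true exactly for labels {H, G, I}; this aggregation (α + 3₁₀ + π = "helix")
is used everywhere downstream.

Agreement with an independent reference implementation (mdtraj's DSSP port)
on mixed helical/coil fixtures is ≈ 98–99 % per-residue and ≈ 100 % on the
helix mask; the oracle-agreement thresholds (95 % labels, 98 % mask) are
the acceptance surface because the exact variant/version of the reference
program is not pinned.

Sheet topology (ladder/sheet lettering) is deliberately not book-kept
beyond the E/B labels: 20-mers do not retain stable sheets, and no
sheet-specific aggregation exists downstream.

## Classifiers and window

The analysis window is the trailing `window_ns` of a trajectory
(`n = window_ns · 1000 / frame_spacing_ps` frames); the original protocol's
window is the last 10 ns of a 200 ns run at 0.5 ps output spacing = 20,000
frames. A residue is a **helix residue** when its helix-mask occupancy is
≥ 0.5 (the boundary is inclusive and configurable). A residue is **rigid**
when its Cα RMSF is strictly below 4.0 Å.

RMSF uses the iterated average structure: all frames are superposed
(unweighted, all Cα) on the running mean, the mean is recomputed, and the
loop stops when the mean shifts < 1e−6 Å or after 10 rounds. Superposition
is Kabsch (SVD with determinant correction, proper rotations only; batched
over frames). RMSF_i = sqrt(mean over frames |r_i − r̄_i|²). The averaging
order for per-set summaries is residues-then-peptides (unweighted peptide
means), and helix content uses the full denominator
(sequence length × frame count), which makes its [0, 1] bound exact.
Whether the original analyses mass-weighted the fit or defined averaging
order differently cannot be determined from the protocol text; the choices
here are recorded as configuration.

Hydrogen bonds are geometric: donors are N/O atoms with a bonded hydrogen,
acceptors all N/O atoms, intra-residue pairs excluded, and a triple
qualifies iff the X–H…X′ angle is ≥ 120° and the H…X′ distance ≤ 3.5 Å.
Both cutoffs are inclusive; they are evaluated in cosine space with a 1e−9
rounding guard so that geometries constructed exactly on the boundary
classify deterministically (the guard corresponds to ~1e−7 degrees — far
below anything physically meaningful). No minimum sequence separation is
imposed beyond the same-residue exclusion, and all N/O donors (backbone,
side chain, termini) participate by default; a backbone-only mode covers
the narrower reading. Because the trajectories are solute-only, all bonds
are solute–solute by construction.

## Surface areas

Solvent-accessible surface area uses Shrake–Rupley point sampling: each
atom's sphere is expanded by the probe radius (default 1.4 Å) and sampled
with a deterministic golden-section spiral (default 960 points, no RNG);
a point is accessible when outside every neighbour's expanded sphere. Radii
are the Bondi set (C 1.70, N 1.55, O 1.52, H 1.20 Å). A dot-surface program
was historically used for this role; accessible-surface sampling replaces
it here because the analysis uses areas only as a relative hydrophilicity
index, which the substitution preserves. Polar surface area sums the
accessible area of N, O and N/O-bound hydrogens (the conventional polar
partition; charged carboxylate oxygens are polar, and a heavy-atoms-only
mode exists because the original definition is not stated). The reported
PSA/SASA is the ratio of trajectory means, not the mean of per-frame
ratios; the difference is second-order. The point lattice is fixed in the
laboratory frame, so areas are rotation-invariant only to sampling
resolution (~1 % at 960 points). Coincident duplicate atoms are excluded
from burial checks (with a warning) so they cannot spuriously zero each
other. Trajectory averages may be strided (default every 10th frame) —
purely a speed knob for the slowest stage; all other metrics always use
every frame.

## Per-set statistics

Histograms count peptides by their number of helix (or rigid) residues,
with zero-count peptides tallied separately, mirroring how such results
are plotted. Means are unweighted arithmetic means over all peptides,
including zero-helix ones. "Correlation coefficient" is read as Pearson's
r between helix content and PSA/SASA across peptides (the scatter-plot
framing); Spearman is available as an option. A constant input vector
makes the correlation undefined and it is reported as NaN with an explicit
flag, never silently as 0. Set comparison is descriptive (ranked table
with differences); no hypothesis test is attached because the study design
reports none.

## Synthetic trajectories

The generator emulates the *statistical* structure the analyses assume —
residues that hold a secondary structure for a fraction of frames — without
any physics. Helix formation is modelled at segment level: each declared
residue range switches between an α-helical state ((φ, ψ) = (−57°, −47°)
plus Gaussian jitter, default σ = 8°) and a coil state (β and
polyproline-II basins, equal weights, same jitter) as a two-state Markov
chain with stationary occupancy `f` and frame-to-frame persistence ρ
(default 0.9, emulating MD autocorrelation; error bars in tests use the
effective sample size n(1−ρ)/(1+ρ), not the raw frame count). Side-chain
torsions get the same jitter around template rotamers.

Cooperative segments rather than per-residue independence are essential:
the assigner's pattern rules need runs of consecutive turns, which
independent residues would almost never satisfy. Because the helix mask
aggregates α, 3₁₀ and π labels, a contiguous block of helical geometry is
detected at *exactly* the declared residues — block edges that cannot
complete the α-helical hydrogen-bond pattern pick up 3₁₀ labels instead —
so no lead-in or trimming convention is needed and the ground truth is
exact. This was verified empirically for interior blocks (blocks touching
the chain termini lose their first/last residue and are avoided in the
default designs). The generator returns both the stationary target
occupancy and the realised switching frequency; the latter is the sharper
ground truth for finite trajectories. A per-residue fluctuation class
("stable" ≥ 0.8, "mobile" ≤ 0.2, else "intermediate") supports qualitative
RMSF checks.

False-helix assignment on pure-coil trajectories is below 1 %.

## The synthetic multi-set experiment

The experiment mirrors the full-scale study design: n random peptides per
alphabet, one trajectory each, per-set aggregation. Each 20-mer carries two
disjoint interior helix segments (residues 3–9 and 12–18); each segment's
occupancy is a steep logistic function of the mean helix propensity of its
residues (midpoint 0.28, slope 30), with default propensities G 0.05,
A 0.15, V 0.15, D 0.40, E 1.0, L 1.0.

These numbers are *synthetic stand-ins, not physical helix propensities*
(real-world scales would put A above D). They were fixed by a design-time
power analysis: the compositional axes that actually distinguish GADV,
GA(D/E)V and GADVE are the glutamate share (0, 1/8, 1/5) and the aspartate
share (1/4, 1/8, 1/5), so the map loads its discriminating weight on E and
D; and because a segment's helix-residue count is all-or-none, two
independent windows per peptide double the information a 20-mer
contributes. Sequence-level Monte Carlo puts the probability that one
20-peptide replicate ranks GADVE > GA(D/E)V > GADV at ≈ 99.6 %, so 19-plus
of 20 replicates reproduce the ordering with high probability. A
single-window design with near-physical propensities was measurably
underpowered at n = 20. A consequence of loading the map on E and D is
that the default design does not reproduce the subtler GADVA-versus-GADV
relation (which in the full-scale study hinges on alanine outperforming
glycine); only the glutamate-addition ordering is within this design's
scope. The generator validates the measurement machinery
and the experiment design's statistical logic — it makes no claim that its
occupancies match any force field, and passing these tests says nothing
about real MD ensembles beyond the correctness of the measurements.

## Problem sizes and numerical choices

Tests and the acceptance script run the study at desk scale — typically 20
peptides × 2,000 frames per set and 960 surface points with a stride of
10–40 frames — sizes chosen so the statistical checks retain power while a
full run stays in the minutes range on one core. Degenerate inputs are
handled explicitly: chains shorter than three residues assign to "-",
collinear point sets are rejected by the superposition, missing backbone
atoms make an H-bond energy report non-bonded (never raise mid-frame), and
coincident atoms are excluded from surface burial. Determinism everywhere:
equal seeds give byte-identical FASTA, trajectories and manifests.

## Known limitations

- The coordinate model covers exactly six residue types plus charged
  termini; it is not a general PDB chemistry engine.
- Synthetic coil states ignore sterics; occasional clashes are harmless to
  the label/RMSF/H-bond/SASA stages but the ensembles are not physical.
- The assigner does not book-keep sheet ladders/lettering beyond E/B.
- Absolute H-bond counts include termini and side-chain donors/acceptors;
  they are comparable within this pipeline, not across programs with other
  conventions.
- Surface areas are accessible-surface (not molecular-surface) areas and
  carry ~1 % point-sampling noise at the default resolution.
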