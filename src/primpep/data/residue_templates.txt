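# Internal-coordinate templates for the six residue types handled by primpep
# (G, A, D, V, E, L) plus the shared backbone geometry.
#
# Format
# ------
# BACKBONE <name> <value>
#     Shared backbone bond lengths (Angstrom) and bond angles (degrees).
#
# SIDECHAIN <res> <atom> <element> <ref_bond> <ref_angle> <ref_torsion> <bond> <angle> <torsion>
#     Z-matrix row for one side-chain atom.  The atom is placed at distance
#     <bond> from <ref_bond>, with bond angle <angle> at <ref_bond> against
#     <ref_angle>, and torsion <torsion> about the <ref_angle>-<ref_bond> axis
#     measured from <ref_torsion>.  <torsion> is either a number (degrees) or
#     a symbolic expression "chiK" / "chiK+OFFSET" / "chiK-OFFSET" resolved
#     against the residue's chi angles at build time.
#
# CHI_DEFAULT <res> <chi1> [<chi2> ...]
#     Default rotamer used when the caller supplies no chi angles.
#
# Values are standard peptide geometry; side-chain bond lengths/angles match
# ideal amino-acid geometry (tetrahedral carbons, planar carboxylates).  The
# improper torsion C-N-CA-CB = -120 deg selects the L-configuration.
# Asp/Glu carboxylates are built deprotonated and symmetric (both C-O 1.25 A).

BACKBONE  n_ca        1.458
BACKBONE  ca_c        1.525
BACKBONE  c_n         1.329
BACKBONE  c_o         1.231
BACKBONE  c_oxt       1.250
BACKBONE  n_h         1.01
BACKBONE  n_ca_c      111.2
BACKBONE  ca_c_n      116.2
BACKBONE  c_n_ca      121.7
BACKBONE  ca_c_o      120.8
BACKBONE  ca_n_h      109.5
BACKBONE  omega       180.0

# CB is common to A, D, V, E, L; its torsion is the L-chirality improper.
SIDECHAIN ALA CB  C  CA N  C    1.530 109.5 -120.0
SIDECHAIN VAL CB  C  CA N  C    1.530 109.5 -120.0
SIDECHAIN VAL CG1 C  CB CA N    1.530 109.5 chi1
SIDECHAIN VAL CG2 C  CB CA N    1.530 109.5 chi1+120
SIDECHAIN ASP CB  C  CA N  C    1.530 109.5 -120.0
SIDECHAIN ASP CG  C  CB CA N    1.510 112.6 chi1
SIDECHAIN ASP OD1 O  CG CB CA   1.250 118.3 chi2
SIDECHAIN ASP OD2 O  CG CB CA   1.250 118.3 chi2+180
SIDECHAIN GLU CB  C  CA N  C    1.530 109.5 -120.0
SIDECHAIN GLU CG  C  CB CA N    1.530 114.1 chi1
SIDECHAIN GLU CD  C  CG CB CA   1.510 112.6 chi2
SIDECHAIN GLU OE1 O  CD CG CB   1.250 118.3 chi3
SIDECHAIN GLU OE2 O  CD CG CB   1.250 118.3 chi3+180
SIDECHAIN LEU CB  C  CA N  C    1.530 109.5 -120.0
SIDECHAIN LEU CG  C  CB CA N    1.530 116.3 chi1
SIDECHAIN LEU CD1 C  CG CB CA   1.530 110.7 chi2
SIDECHAIN LEU CD2 C  CG CB CA   1.530 110.7 chi2+120

CHI_DEFAULT ALA
CHI_DEFAULT GLY
CHI_DEFAULT VAL 180.0
CHI_DEFAULT ASP -60.0 -20.0
CHI_DEFAULT GLU -60.0 180.0 -20.0
CHI_DEFAULT LEU -60.0 180.0
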