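"""Miniature version of the five-alphabet structure-formation comparison.

Runs the synthetic experiment for GADV, GA(D/E)V and GADVE (8 peptides x
800 frames each, for speed), aggregates per-set statistics, and ranks the
sets by mean helix-forming residues.
"""

from primpep import (
    compare_sets,
    get_builtin_set,
    peptide_metrics,
    summarize_set,
    synthesize_trajectory,
)
from primpep.synth import experiment_specs

sets = [get_builtin_set(n) for n in ("GADV", "GA(D/E)V", "GADVE")]
summaries = []
for aa_set in sets:
    specs = experiment_specs([aa_set], n_peptides=8, n_frames=800, seed=11)
    metrics = []
    for spec in specs:
        traj, _ = synthesize_trajectory(spec)
        metrics.append(peptide_metrics(traj, surface_stride=40))
    summaries.append(summarize_set(metrics, aa_set.name))

print(compare_sets(summaries).to_string(index=False))
# Under the default propensity map (glutamate strongly helix-forming,
# glycine helix-breaking) the five-residue alphabet GADVE ranks above the
# codon-ratio set GA(D/E)V, which ranks above plain GADV — the qualitative
# ordering the full-scale study reports.
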