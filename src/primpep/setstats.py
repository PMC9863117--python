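"""Per-set aggregation: histograms, zero-count tallies, means, correlations.

A "set" is the collection of (typically 100) random peptides drawn from one
amino-acid alphabet.  Histograms count peptides by their number of helix or
rigid residues, with peptides that have none tallied separately — matching
how such results are usually plotted.  The helix-content versus PSA/SASA
relationship is summarised by Pearson's r (Spearman available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import PeptideMetrics

__all__ = ["SetSummary", "summarize_set", "compare_sets", "summary_table"]


@dataclass
class SetSummary:
    set_name: str
    n_peptides: int
    helix_hist: dict[int, int]  # n_helix_residues (>=1) -> peptide count
    n_zero_helix: int
    rigid_hist: dict[int, int]
    n_zero_rigid: int
    mean_helix_residues: float
    mean_rigid_residues: float
    mean_hbonds: float
    mean_rmsf_ca: float
    mean_helix_content: float
    mean_psa_ratio: float
    corr_helix_psa: float  # NaN when undefined
    corr_defined: bool = True

    def __post_init__(self) -> None:
        for hist, zero in ((self.helix_hist, self.n_zero_helix),
                           (self.rigid_hist, self.n_zero_rigid)):
            if zero + sum(hist.values()) != self.n_peptides:
                raise ValueError("histogram counts do not sum to n_peptides")


def _hist(values: list[int]) -> tuple[dict[int, int], int]:
    nonzero = [v for v in values if v >= 1]
    hist: dict[int, int] = {}
    for v in sorted(nonzero):
        hist[v] = hist.get(v, 0) + 1
    return hist, len(values) - len(nonzero)


def summarize_set(
    metrics: list[PeptideMetrics],
    set_name: str | None = None,
    correlation: str = "pearson",
) -> SetSummary:
    """Aggregate one set's peptide metrics.

    Means are unweighted arithmetic means over all peptides (zero-helix
    peptides included).  A constant helix-content or PSA/SASA vector makes
    the correlation undefined; it is then reported as NaN with
    ``corr_defined=False``, never silently as 0.
    """
    if not metrics:
        raise ValueError("metrics must be non-empty")
    names = {m.set_name for m in metrics}
    if len(names) > 1:
        raise ValueError(f"metrics mix sets: {sorted(names)}")
    if set_name is None:
        set_name = metrics[0].set_name

    helix_hist, n_zero_helix = _hist([m.n_helix_residues for m in metrics])
    rigid_hist, n_zero_rigid = _hist([m.n_rigid_residues for m in metrics])

    hc = np.array([m.helix_content for m in metrics])
    pr = np.array([m.psa_ratio for m in metrics])
    corr = float("nan")
    defined = False
    usable = np.isfinite(hc) & np.isfinite(pr)
    if usable.sum() >= 3 and np.ptp(hc[usable]) > 0 and np.ptp(pr[usable]) > 0:
        if correlation == "pearson":
            corr = float(sps.pearsonr(hc[usable], pr[usable]).statistic)
        elif correlation == "spearman":
            corr = float(sps.spearmanr(hc[usable], pr[usable]).statistic)
        else:
            raise ValueError(f"unknown correlation {correlation!r}")
        defined = True

    return SetSummary(
        set_name=set_name,
        n_peptides=len(metrics),
        helix_hist=helix_hist,
        n_zero_helix=n_zero_helix,
        rigid_hist=rigid_hist,
        n_zero_rigid=n_zero_rigid,
        mean_helix_residues=float(np.mean([m.n_helix_residues for m in metrics])),
        mean_rigid_residues=float(np.mean([m.n_rigid_residues for m in metrics])),
        mean_hbonds=float(np.mean([m.mean_hbonds for m in metrics])),
        mean_rmsf_ca=float(np.mean([m.mean_rmsf_ca for m in metrics])),
        mean_helix_content=float(np.mean(hc)),
        mean_psa_ratio=float(np.nanmean(pr)) if np.isfinite(pr).any() else float("nan"),
        corr_helix_psa=corr,
        corr_defined=defined,
    )


def summary_table(summaries: list[SetSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": s.set_name,
                "n_peptides": s.n_peptides,
                "n_zero_helix": s.n_zero_helix,
                "n_zero_rigid": s.n_zero_rigid,
                "mean_helix_residues": s.mean_helix_residues,
                "mean_rigid_residues": s.mean_rigid_residues,
                "mean_hbonds": s.mean_hbonds,
                "mean_rmsf_ca": s.mean_rmsf_ca,
                "mean_helix_content": s.mean_helix_content,
                "mean_psa_ratio": s.mean_psa_ratio,
                "corr_helix_psa": s.corr_helix_psa,
            }
            for s in summaries
        ]
    )


def compare_sets(summaries: list[SetSummary]) -> pd.DataFrame:
    """Rank sets by mean helix residues (then rigid residues, H-bonds).

    Returns the ranked table with pairwise differences in mean helix
    residues against the top-ranked set.  No hypothesis test is attached —
    the comparison is descriptive.
    """
    if len(summaries) < 2:
        raise ValueError("compare_sets needs at least two summaries")
    table = summary_table(summaries).sort_values(
        ["mean_helix_residues", "mean_rigid_residues", "mean_hbonds"],
        ascending=False,
        kind="mergesort",
    )
    table = table.reset_index(drop=True)
    table.insert(1, "rank", np.arange(1, len(table) + 1))
    for _, row in table.iterrows():
        table[f"diff_helix_vs_{row['set']}"] = (
            table["mean_helix_residues"] - row["mean_helix_residues"]
        )
    return table
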