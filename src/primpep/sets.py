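"""Restricted amino-acid alphabets and seeded random peptide generation.

A handful of "primitive" alphabets built from glycine, alanine, aspartate,
valine — the classic GADV set thought to resemble the earliest proteins —
plus variants that add glutamate or leucine as a fifth residue, double the
alanine share, or weight residues by their codon multiplicity in the GNN
block of the genetic code (G:A:D:V:E = 2:2:1:2:1).  Sequences are sampled
i.i.d. per position with probabilities proportional to the set weights, so
composition holds in expectation rather than exactly per sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AminoAcidSet",
    "PeptideSequence",
    "builtin_sets",
    "get_builtin_set",
    "generate_sequences",
    "write_fasta",
    "read_fasta",
]

_KNOWN_RESIDUES = frozenset("GADVEL")


@dataclass(frozen=True)
class AminoAcidSet:
    """A named alphabet with positive relative residue weights."""

    name: str
    frequencies: dict[str, float]

    def __post_init__(self) -> None:
        if not self.frequencies:
            raise ValueError(f"set {self.name!r}: frequencies must be non-empty")
        for res, w in self.frequencies.items():
            if res not in _KNOWN_RESIDUES:
                raise ValueError(
                    f"set {self.name!r}: unsupported residue symbol {res!r} "
                    f"(supported: {''.join(sorted(_KNOWN_RESIDUES))})"
                )
            if not w > 0:
                raise ValueError(f"set {self.name!r}: weight for {res} must be > 0")

    @property
    def residues(self) -> tuple[str, ...]:
        return tuple(self.frequencies)

    def probabilities(self) -> dict[str, float]:
        """Weights normalised to sum to one."""
        total = sum(self.frequencies.values())
        return {r: w / total for r, w in self.frequencies.items()}

    @classmethod
    def from_json(cls, path: str | Path) -> "AminoAcidSet":
        spec = json.loads(Path(path).read_text())
        return cls(name=spec["name"], frequencies=dict(spec["frequencies"]))


@dataclass(frozen=True)
class PeptideSequence:
    """One random peptide: an id, its residues, and the originating set name."""

    id: str
    residues: str
    set_name: str = ""

    def __post_init__(self) -> None:
        bad = set(self.residues) - _KNOWN_RESIDUES
        if bad:
            raise ValueError(f"sequence {self.id!r}: unsupported residues {sorted(bad)}")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)


def builtin_sets() -> list[AminoAcidSet]:
    """The five study alphabets with their relative residue frequencies."""
    return [
        AminoAcidSet("GADV", {"G": 1, "A": 1, "D": 1, "V": 1}),
        AminoAcidSet("GADVA", {"G": 1, "A": 2, "D": 1, "V": 1}),
        AminoAcidSet("GADVE", {"G": 1, "A": 1, "D": 1, "V": 1, "E": 1}),
        AminoAcidSet("GADVL", {"G": 1, "A": 1, "D": 1, "V": 1, "L": 1}),
        AminoAcidSet("GA(D/E)V", {"G": 2, "A": 2, "D": 1, "V": 2, "E": 1}),
    ]


def get_builtin_set(name: str) -> AminoAcidSet:
    for s in builtin_sets():
        if s.name == name:
            return s
    names = ", ".join(s.name for s in builtin_sets())
    raise KeyError(f"unknown builtin set {name!r}; available: {names}")


def generate_sequences(
    aa_set: AminoAcidSet, n: int, length: int = 20, seed: int = 0
) -> list[PeptideSequence]:
    """Draw ``n`` i.i.d. random peptides of ``length`` residues.

    Residues are sampled independently per position with probability
    proportional to the set weights.  Each sequence uses its own RNG
    substream spawned from the master seed, so enlarging ``n`` extends the
    collection without reshuffling earlier sequences.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    symbols = list(aa_set.frequencies)
    probs = np.array([aa_set.probabilities()[s] for s in symbols])
    children = np.random.SeedSequence(seed).spawn(n)
    out = []
    for i, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        residues = "".join(rng.choice(symbols, size=length, p=probs))
        out.append(
            PeptideSequence(id=f"{aa_set.name}_{i:03d}", residues=residues, set_name=aa_set.name)
        )
    return out


def write_fasta(sequences: list[PeptideSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=f"set={s.set_name}")
        for s in sequences
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> list[PeptideSequence]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        set_name = ""
        for token in rec.description.split():
            if token.startswith("set="):
                set_name = token[4:]
        out.append(PeptideSequence(id=rec.id, residues=str(rec.seq), set_name=set_name))
    return out
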