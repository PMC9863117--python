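"""Parser for the plain-text residue template table shipped as package data."""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

__all__ = ["SidechainAtom", "ResidueTemplates", "load_templates", "THREE_LETTER"]

#: one-letter -> PDB residue name for the supported alphabet
THREE_LETTER = {"G": "GLY", "A": "ALA", "D": "ASP", "V": "VAL", "E": "GLU", "L": "LEU"}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}

_CHI_RE = re.compile(r"^chi(\d+)([+-]\d+(?:\.\d+)?)?$")


@dataclass(frozen=True)
class SidechainAtom:
    name: str
    element: str
    ref_bond: str
    ref_angle: str
    ref_torsion: str
    bond: float
    angle: float
    # either a fixed torsion in degrees, or (chi_index, offset_degrees)
    torsion: float | tuple[int, float]

    def resolve_torsion(self, chi: list[float]) -> float:
        if isinstance(self.torsion, tuple):
            k, offset = self.torsion
            return chi[k - 1] + offset
        return self.torsion


@dataclass(frozen=True)
class ResidueTemplates:
    backbone: dict[str, float]
    sidechains: dict[str, list[SidechainAtom]]  # keyed by three-letter name
    chi_defaults: dict[str, list[float]]

    def n_chi(self, three_letter: str) -> int:
        return len(self.chi_defaults[three_letter])


def _parse_torsion(token: str) -> float | tuple[int, float]:
    m = _CHI_RE.match(token)
    if m:
        return int(m.group(1)), float(m.group(2) or 0.0)
    return float(token)


@lru_cache(maxsize=1)
def load_templates() -> ResidueTemplates:
    text = (resources.files("primpep") / "data" / "residue_templates.txt").read_text()
    backbone: dict[str, float] = {}
    sidechains: dict[str, list[SidechainAtom]] = {t: [] for t in THREE_LETTER.values()}
    chi_defaults: dict[str, list[float]] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        kind = fields[0]
        if kind == "BACKBONE":
            backbone[fields[1]] = float(fields[2])
        elif kind == "SIDECHAIN":
            res, name, element, rb, ra, rt, bond, angle, torsion = fields[1:10]
            sidechains[res].append(
                SidechainAtom(
                    name=name,
                    element=element,
                    ref_bond=rb,
                    ref_angle=ra,
                    ref_torsion=rt,
                    bond=float(bond),
                    angle=float(angle),
                    torsion=_parse_torsion(torsion),
                )
            )
        elif kind == "CHI_DEFAULT":
            chi_defaults[fields[1]] = [float(x) for x in fields[2:]]
        else:
            raise ValueError(f"unknown template record {kind!r}")
    return ResidueTemplates(backbone=backbone, sidechains=sidechains, chi_defaults=chi_defaults)
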