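"""Single-point mutant libraries.

Two generators: saturation knockouts of annotated active/binding-site
positions (the artificial no-activity penalty group, 19 variants per site)
and the full nonsynonymous single-mutant library of a parent (19 x L
variants), both in a fixed (position, then mutant residue A->Y) order so
downstream rankings break ties reproducibly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

from .seqio import CANONICAL_AA, SequenceRecord

__all__ = [
    "SiteAnnotation",
    "Variant",
    "site_knockout_variants",
    "full_single_mutant_library",
    "read_site_annotations",
]


@dataclass(frozen=True)
class SiteAnnotation:
    """1-based active/binding-site positions of a parent sequence."""

    parent_id: str
    positions: tuple[int, ...]

    def __post_init__(self):
        pos = self.positions
        if len(set(pos)) != len(pos):
            raise ValueError("site positions must be unique")
        if any(p < 1 for p in pos):
            raise ValueError("site positions are 1-based and must be >= 1")
        if tuple(sorted(pos)) != pos:
            object.__setattr__(self, "positions", tuple(sorted(pos)))


@dataclass(frozen=True)
class Variant:
    """A single-point mutant named in the <wt><pos><mut> convention."""

    parent_id: str
    position: int          # 1-based
    wt_aa: str
    mut_aa: str
    sequence: str

    @property
    def name(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


def _mutate(parent: SequenceRecord, position: int) -> list[Variant]:
    if not 1 <= position <= parent.length:
        raise ValueError(
            f"position {position} outside parent {parent.record_id} "
            f"(length {parent.length})")
    wt = parent.sequence[position - 1]
    out = []
    for aa in CANONICAL_AA:
        if aa == wt:
            continue
        seq = parent.sequence[:position - 1] + aa + parent.sequence[position:]
        out.append(Variant(parent.record_id, position, wt, aa, seq))
    return out


def site_knockout_variants(parent: SequenceRecord,
                           sites: SiteAnnotation) -> list[Variant]:
    """All 19 substitutions at every annotated site (19 x |positions|)."""
    if sites.parent_id != parent.record_id:
        raise ValueError("site annotation does not belong to this parent")
    variants: list[Variant] = []
    for pos in sites.positions:
        variants.extend(_mutate(parent, pos))
    return variants


def full_single_mutant_library(parent: SequenceRecord) -> list[Variant]:
    """All nonsynonymous single-point mutants of the parent (19 x L)."""
    variants: list[Variant] = []
    for pos in range(1, parent.length + 1):
        variants.extend(_mutate(parent, pos))
    return variants


def read_site_annotations(handle, parent_id: str) -> SiteAnnotation:
    """Read a (parent_id, position, feature_type) TSV; positions are unioned."""
    positions = set()
    for row in csv.DictReader(handle, delimiter="\t"):
        if row["parent_id"] == parent_id:
            positions.add(int(row["position"]))
    return SiteAnnotation(parent_id, tuple(sorted(positions)))
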