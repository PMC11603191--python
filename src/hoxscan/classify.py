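"""Orthology-group assignment, duplication calls, and complement tables.

A locus is assigned to its best-scoring group only when the score margin
over the runner-up group exceeds ``margin_delta`` bits; otherwise it stays
ambiguous. The complement table is the species-by-group multiplicity
matrix: 0 marks an absent orthologue, 2 a duplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .profiles import ORTHOLOGY_GROUPS
from .scan import HoxLocus

DEFAULT_MARGIN_DELTA = 3.0  # bits
DEFAULT_MIN_SEPARATION = 5_000  # nt; matches the scanner's merge max_gap


def assign_group(locus: HoxLocus, margin_delta: float = DEFAULT_MARGIN_DELTA) -> HoxLocus:
    """Resolve a locus status: assigned iff margin >= margin_delta."""
    if not locus.group_scores:
        raise ValueError(f"locus {locus.locus_id} has no group scores")
    status = "assigned" if locus.margin >= margin_delta else "ambiguous"
    return replace(locus, status=status)


def assign_all(loci: Sequence[HoxLocus], margin_delta: float = DEFAULT_MARGIN_DELTA) -> list[HoxLocus]:
    return [assign_group(l, margin_delta) for l in loci]


def call_duplications(
    loci: Sequence[HoxLocus],
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> dict[str, int]:
    """Per-group multiplicity for one species.

    Assigned loci of one group count separately only when their pairwise
    genomic distance exceeds ``min_separation``; co-located loci (within
    it, on the same scaffold) collapse to a single copy. Loci on different
    scaffolds never collapse.
    """
    out: dict[str, int] = {}
    by_group: dict[str, list[HoxLocus]] = {}
    for l in loci:
        if l.status == "assigned":
            by_group.setdefault(l.best_group, []).append(l)
    for group, members in by_group.items():
        members.sort(key=lambda l: (l.scaffold, l.nt_start))
        copies = 0
        prev: HoxLocus | None = None
        for l in members:
            if (
                prev is None
                or l.scaffold != prev.scaffold
                or l.nt_start - prev.nt_end > min_separation
            ):
                copies += 1
            prev = l
        out[group] = copies
    return out


@dataclass
class ComplementTable:
    """Species-by-orthology-group locus counts plus ambiguous tallies."""

    species: list[str]
    counts: dict[str, dict[str, int]]  # species -> group -> count
    ambiguous: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species names")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [[self.counts[s].get(g, 0) for g in ORTHOLOGY_GROUPS] for s in self.species],
            index=pd.Index(self.species, name="species"),
            columns=list(ORTHOLOGY_GROUPS),
            dtype=int,
        )
        df["ambiguous"] = [self.ambiguous.get(s, 0) for s in self.species]
        return df

    def to_long(self) -> pd.DataFrame:
        rows = []
        for s in self.species:
            for g in ORTHOLOGY_GROUPS:
                n = self.counts[s].get(g, 0)
                rows.append(
                    {
                        "species": s,
                        "group": g,
                        "count": n,
                        "status": "absent" if n == 0 else ("duplicated" if n >= 2 else "present"),
                    }
                )
        return pd.DataFrame(rows, columns=["species", "group", "count", "status"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ComplementTable":
        df = pd.read_csv(path, sep="\t", index_col="species", comment="#")
        species = [str(s) for s in df.index]
        counts = {
            s: {g: int(df.loc[s, g]) for g in ORTHOLOGY_GROUPS if g in df.columns}
            for s in species
        }
        ambiguous = (
            {s: int(df.loc[s, "ambiguous"]) for s in species}
            if "ambiguous" in df.columns
            else {}
        )
        return cls(species=species, counts=counts, ambiguous=ambiguous)

    def presence(self) -> pd.DataFrame:
        """Binary presence matrix (multiplicity >= 1) for loss mapping."""
        df = self.to_frame()[list(ORTHOLOGY_GROUPS)]
        return (df >= 1).astype(int)


def build_complement(
    per_species: Mapping[str, Sequence[HoxLocus]],
) -> ComplementTable:
    """Assemble the complement matrix from per-species assigned loci.

    Counts tally assigned loci per group (so the per-species totals equal
    assigned + ambiguous locus counts); use :func:`call_duplications` for
    separation-aware copy numbers.
    """
    species = list(per_species)
    if len(set(species)) != len(species):
        raise ValueError("duplicate species names")
    counts: dict[str, dict[str, int]] = {}
    ambiguous: dict[str, int] = {}
    for s, loci in per_species.items():
        row: dict[str, int] = {}
        amb = 0
        for l in loci:
            if l.status == "assigned":
                row[l.best_group] = row.get(l.best_group, 0) + 1
            else:
                amb += 1
        counts[s] = row
        ambiguous[s] = amb
    return ComplementTable(species=species, counts=counts, ambiguous=ambiguous)
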