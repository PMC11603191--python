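"""Seeded synthetic genomes, annotations and presence matrices with truth.

The generator emulates the study substrate end-to-end: multi-scaffold
nucleotide genomes with implanted homeodomain-encoding genes (one or more
per orthology group, at controlled amino-acid divergence, optional single
intron with canonical GT..AG ends, known strand and coordinates), decoy
non-Hox genes whose proteins are composition-preserving shuffles of
homeodomain consensi (destroying the positional signal), implanted ~22 nt
mature miRNAs, and a truth manifest mirroring the emitted GFF3 exactly.

Everything is deterministic given the config seed. Background composition
defaults to GC 0.42, a typical nematode-like value; no repeat or isochore
structure is simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .profiles import (
    AA_RESIDUES,
    LabelledAlignment,
    ORTHOLOGY_GROUPS,
    background_from_alignment,
    build_profile,
)
from .seqio import CODON_TABLE, GeneFeature, SeqRecord, revcomp

DEFAULT_GC = 0.42
HOMEODOMAIN_LEN = 60

# alphabetically first codon per residue (deterministic back-translation)
BACKTRANSLATE: dict[str, str] = {}
for _codon in sorted(CODON_TABLE):
    _aa = CODON_TABLE[_codon]
    BACKTRANSLATE.setdefault(_aa, _codon)

_NON_STOP_CODONS = sorted(c for c, a in CODON_TABLE.items() if a != "*")


def mutate_protein(aa: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitution at ``rate``, uniform over the 19 alternatives."""
    if not (0 <= rate <= 1):
        raise ValueError("rate must be in [0, 1]")
    out = list(aa)
    for i, ch in enumerate(out):
        if rng.random() < rate:
            alternatives = [a for a in AA_RESIDUES if a != ch]
            out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def backtranslate(aa: str, rng: np.random.Generator | None = None) -> str:
    """aa -> nt; first codon alphabetically, or seeded uniform codon choice."""
    if rng is None:
        return "".join(BACKTRANSLATE[ch] for ch in aa)
    codons_for: dict[str, list[str]] = {}
    for codon, res in CODON_TABLE.items():
        codons_for.setdefault(res, []).append(codon)
    out = []
    for ch in aa:
        options = sorted(codons_for[ch])
        out.append(options[rng.integers(len(options))])
    return "".join(out)


def simulate_reference_alignment(
    seed: int,
    groups: Sequence[str] = ORTHOLOGY_GROUPS,
    n_per_group: int = 8,
    length: int = HOMEODOMAIN_LEN,
    within_divergence: float = 0.05,
) -> LabelledAlignment:
    """A labelled homeodomain-style reference alignment with ground truth.

    Each group gets a random ungapped consensus; members are seeded
    mutants of it, so groups are mutually distinguishable while rows
    within a group vary as a curated ingroup/outgroup set would.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in groups:
        consensus = "".join(
            AA_RESIDUES[i] for i in rng.integers(len(AA_RESIDUES), size=length)
        )
        for k in range(n_per_group):
            member = consensus if k == 0 else mutate_protein(consensus, within_divergence, rng)
            rows.append((group, f"{group.replace('-', '_')}_m{k}", member))
    return LabelledAlignment(rows=rows)


def group_consensi(
    alignment: LabelledAlignment, alpha: float = 1.0
) -> dict[str, str]:
    """Per-group profile consensus windows used as implant sources."""
    q = background_from_alignment(alignment)
    return {
        g: build_profile(alignment.subset(g), q=q, alpha=alpha).consensus()
        for g in alignment.groups()
    }


# ---------------------------------------------------------------------------
# Config


@dataclass
class Implant:
    group: str
    scaffold: str
    nt_start: int
    strand: str
    aa_divergence: float = 0.0
    intron: tuple[int, int] | None = None  # (offset_aa, length_nt)


@dataclass
class MirnaImplant:
    mirna_id: str
    scaffold: str
    position: int
    strand: str
    n_mismatches: int = 0


@dataclass
class SimConfig:
    seed: int
    reference_alignment: LabelledAlignment
    n_scaffolds: int = 1
    scaffold_len: int = 1_000_000
    gc: float = DEFAULT_GC
    implants: list[Implant] = field(default_factory=list)
    n_decoys: int = 0
    decoy_len: int = 3 * HOMEODOMAIN_LEN
    mirna_implants: list[MirnaImplant] = field(default_factory=list)
    mirna_len: int = 22

    def scaffold_names(self) -> list[str]:
        return [f"scaffold_{i + 1}" for i in range(self.n_scaffolds)]


def _random_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


class PlacementError(ValueError):
    pass


def _claim(
    occupied: dict[str, list[tuple[int, int, str]]],
    scaffold: str,
    start: int,
    end: int,
    label: str,
    scaffold_len: int,
) -> None:
    if start < 0 or end > scaffold_len:
        raise PlacementError(f"{label}: interval [{start}, {end}) outside {scaffold}")
    for s, e, other in occupied.setdefault(scaffold, []):
        if start < e and end > s:
            raise PlacementError(
                f"{label} at {scaffold}:[{start}, {end}) collides with "
                f"{other} at [{s}, {e})"
            )
    occupied[scaffold].append((start, end, label))


def simulate_genome(
    config: SimConfig,
) -> tuple[list[SeqRecord], list[GeneFeature], dict]:
    """Emit (genome records, truth features, manifest) for a config.

    The manifest echoes the config and records every realized interval;
    it is guaranteed to agree with the truth GFF3 features.
    """
    rng = np.random.default_rng(config.seed)
    names = config.scaffold_names()
    seqs = {name: list(_random_nt(rng, config.scaffold_len, config.gc)) for name in names}
    occupied: dict[str, list[tuple[int, int, str]]] = {}
    features: list[GeneFeature] = []
    manifest: dict = {
        "config": {
            "seed": config.seed,
            "n_scaffolds": config.n_scaffolds,
            "scaffold_len": config.scaffold_len,
            "gc": config.gc,
            "n_decoys": config.n_decoys,
            "decoy_len": config.decoy_len,
            "mirna_len": config.mirna_len,
        },
        "implants": [],
        "decoys": [],
        "mirnas": [],
    }
    consensi = group_consensi(config.reference_alignment)

    # --- Hox implants at stated coordinates
    for k, imp in enumerate(config.implants):
        if imp.scaffold not in seqs:
            raise PlacementError(f"implant {k}: unknown scaffold {imp.scaffold}")
        consensus = consensi[imp.group]
        aa = mutate_protein(consensus, imp.aa_divergence, rng)
        realized_div = sum(a != b for a, b in zip(aa, consensus)) / len(consensus)
        cds = backtranslate(aa)
        if imp.intron is not None:
            off_aa, intron_len = imp.intron
            if intron_len < 4:
                raise ValueError("intron length must be >= 4 (GT..AG)")
            intron = "GT" + _random_nt(rng, intron_len - 4, config.gc) + "AG"
            cds = cds[: 3 * off_aa] + intron + cds[3 * off_aa :]
        gene = cds if imp.strand == "+" else revcomp(cds)
        start, end = imp.nt_start, imp.nt_start + len(gene)
        label = f"hox_implant_{k + 1}"
        _claim(occupied, imp.scaffold, start, end, label, config.scaffold_len)
        seqs[imp.scaffold][start:end] = list(gene)
        features.append(
            GeneFeature(
                feature_id=label,
                scaffold=imp.scaffold,
                start=start,
                end=end,
                strand=imp.strand,
                kind="gene",
                attributes={"ID": label, "group": imp.group, "truth": "hox"},
            )
        )
        manifest["implants"].append(
            {
                "id": label,
                "group": imp.group,
                "scaffold": imp.scaffold,
                "start": start,
                "end": end,
                "strand": imp.strand,
                "aa_divergence_requested": imp.aa_divergence,
                "aa_divergence_realized": realized_div,
                "protein": aa,
                "intron": list(imp.intron) if imp.intron else None,
            }
        )

    # --- decoys at random free positions (seeded)
    group_list = sorted(consensi)
    for k in range(config.n_decoys):
        src = consensi[group_list[int(rng.integers(len(group_list)))]]
        shuffled = "".join(np.array(list(src))[rng.permutation(len(src))])
        decoy_nt = backtranslate(shuffled)
        if config.decoy_len > len(decoy_nt):
            n_pad = (config.decoy_len - len(decoy_nt) + 2) // 3
            decoy_nt += "".join(
                _NON_STOP_CODONS[int(rng.integers(len(_NON_STOP_CODONS)))]
                for _ in range(n_pad)
            )
        label = f"decoy_{k + 1}"
        placed = False
        for _attempt in range(1000):
            scaffold = names[int(rng.integers(len(names)))]
            start = int(rng.integers(0, config.scaffold_len - len(decoy_nt)))
            try:
                _claim(occupied, scaffold, start, start + len(decoy_nt), label,
                       config.scaffold_len)
            except PlacementError:
                continue
            placed = True
            break
        if not placed:
            raise PlacementError(f"could not place {label} after 1000 attempts")
        strand = "+" if rng.random() < 0.5 else "-"
        gene = decoy_nt if strand == "+" else revcomp(decoy_nt)
        seqs[scaffold][start : start + len(gene)] = list(gene)
        features.append(
            GeneFeature(
                feature_id=label,
                scaffold=scaffold,
                start=start,
                end=start + len(gene),
                strand=strand,
                kind="gene",
                attributes={"ID": label, "truth": "decoy"},
            )
        )
        manifest["decoys"].append(
            {"id": label, "scaffold": scaffold, "start": start,
             "end": start + len(gene), "strand": strand}
        )

    # --- mature miRNA implants
    mirna_seqs: dict[str, str] = {}
    for mi in config.mirna_implants:
        if mi.mirna_id not in mirna_seqs:
            mirna_seqs[mi.mirna_id] = _random_nt(rng, config.mirna_len, 0.5)
        query = mirna_seqs[mi.mirna_id]
        implanted = list(query)
        if mi.n_mismatches:
            pos = rng.choice(len(query), size=mi.n_mismatches, replace=False)
            for p in pos:
                alternatives = [c for c in "ACGT" if c != implanted[p]]
                implanted[p] = alternatives[int(rng.integers(3))]
        implanted_s = "".join(implanted)
        if mi.strand == "-":
            implanted_s = revcomp(implanted_s)
        start, end = mi.position, mi.position + len(implanted_s)
        label = f"mirna_{mi.mirna_id}_{start}"
        _claim(occupied, mi.scaffold, start, end, label, config.scaffold_len)
        seqs[mi.scaffold][start:end] = list(implanted_s)
        features.append(
            GeneFeature(
                feature_id=label,
                scaffold=mi.scaffold,
                start=start,
                end=end,
                strand=mi.strand,
                kind="mirna",
                attributes={"ID": label, "mirna": mi.mirna_id,
                            "mismatches": str(mi.n_mismatches), "truth": "mirna"},
            )
        )
        manifest["mirnas"].append(
            {
                "id": label,
                "mirna_id": mi.mirna_id,
                "query_seq": query,
                "scaffold": mi.scaffold,
                "start": start,
                "end": end,
                "strand": mi.strand,
                "n_mismatches": mi.n_mismatches,
            }
        )

    genome = [
        SeqRecord(id=name, description=name, seq="".join(seqs[name])) for name in names
    ]
    return genome, features, manifest


def mirna_queries(manifest: dict) -> list[SeqRecord]:
    """The unmutated miRNA query sequences recorded in a manifest."""
    seen: dict[str, str] = {}
    for m in manifest["mirnas"]:
        seen[m["mirna_id"]] = m["query_seq"]
    return [SeqRecord(id=mid, description=mid, seq=s) for mid, s in seen.items()]


def write_manifest(path: str | Path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Presence-matrix simulation


def simulate_presence_matrix(tree, scenarios: dict[str, tuple[str | None, set[str]]]):
    """Leaf presence states from explicit per-group (gain, losses) scenarios.

    ``scenarios`` maps group -> (gain edge child-node label or None, set of
    loss edge labels). Losses must lie strictly below the gain edge.
    """
    import pandas as pd

    labels = {node.label for node in tree.preorder_node_iter()}
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    data: dict[str, list[int]] = {}
    for group, (gain, losses) in scenarios.items():
        if gain is not None and gain not in labels:
            raise ValueError(f"{group}: gain edge {gain!r} not in tree")
        for e in losses:
            if e not in labels:
                raise ValueError(f"{group}: loss edge {e!r} not in tree")
        if gain is not None:
            gain_node = next(
                n for n in tree.preorder_node_iter() if n.label == gain
            )
            below = {n.label for n in gain_node.preorder_iter()}
            bad = set(losses) - (below - {gain})
            if bad:
                raise ValueError(f"{group}: losses {sorted(bad)} not below gain {gain!r}")
        states: dict[str, int] = {}

        def walk(node, state: int) -> None:
            if gain is not None and node.label == gain:
                state = 1
            if node.label in losses:
                state = 0
            if node.is_leaf():
                states[node.taxon.label] = state
            for child in node.child_nodes():
                walk(child, state)

        walk(tree.seed_node, 0)
        data[group] = [states[l] for l in leaves]
    return pd.DataFrame(data, index=pd.Index(leaves, name="species"))


# ---------------------------------------------------------------------------
# Convenience configs


def hox_cluster_config(
    seed: int,
    reference_alignment: LabelledAlignment,
    groups: Sequence[str] = ("HOX1", "HOX3", "HOX4", "HOX6-8_ftz"),
    divergence: float = 0.05,
    scaffold_len: int = 1_000_000,
    window: tuple[int, int] | None = None,
    n_decoys: int = 10,
    strand_pattern: Sequence[str] = ("+", "-"),
) -> SimConfig:
    """One clustered implant per group, evenly spaced inside ``window``.

    The default window is a centred 250 kb region (shrunk proportionally
    on scaffolds too small to hold it).
    """
    if window is None:
        width = min(250_000, int(scaffold_len * 0.6))
        lo = (scaffold_len - width) // 2
        window = (lo, lo + width)
    lo, hi = window
    n = len(groups)
    step = (hi - lo) // n
    implants = [
        Implant(
            group=g,
            scaffold="scaffold_1",
            nt_start=lo + i * step,
            strand=strand_pattern[i % len(strand_pattern)],
            aa_divergence=divergence,
        )
        for i, g in enumerate(groups)
    ]
    return SimConfig(
        seed=seed,
        reference_alignment=reference_alignment,
        n_scaffolds=1,
        scaffold_len=scaffold_len,
        implants=implants,
        n_decoys=n_decoys,
    )
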