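"""Sequence and annotation I/O with coordinate-safe six-frame translation.

All coordinates are 0-based half-open internally; GFF3 files (1-based,
inclusive) are converted at the read/write boundary. Nucleotide sequences
are restricted to the closed alphabet {A, C, G, T, N}; amino-acid sequences
to the 20 standard residues plus X (unknown) and * (stop).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

logger = logging.getLogger("hoxscan")

NT_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")
AA_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"  # canonical order used throughout

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"


@dataclass
class SeqRecord:
    """A named sequence; ``seq`` is uppercase and alphabet-checked on read."""

    id: str
    description: str
    seq: str


@dataclass
class GeneFeature:
    """A gene-level annotation interval (0-based, half-open)."""

    feature_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    kind: str  # "gene" or "mirna"
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.feature_id}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id}: bad strand {self.strand!r}")


@dataclass
class TranslatedFrame:
    """One reading frame of a scaffold.

    ``origin_map(i)`` returns the forward-strand nt interval (start, end,
    strand) of the codon that produced ``aa_seq[i]``; intervals are always
    expressed in the forward coordinate system, also for minus frames.
    """

    frame_id: int  # one of +1, +2, +3, -1, -2, -3
    aa_seq: str
    origin_map: Callable[[int], tuple[int, int, str]]


# ---------------------------------------------------------------------------
# FASTA


def _check_alphabet(rec_id: str, seq: str, alphabet: Literal["nt", "aa"]) -> None:
    allowed = NT_ALPHABET if alphabet == "nt" else AA_ALPHABET
    for pos, ch in enumerate(seq):
        if ch not in allowed:
            raise ValueError(
                f"record {rec_id}: illegal {alphabet} residue {ch!r} at position {pos}"
            )


def read_fasta(path: str | Path, alphabet: Literal["nt", "aa"]) -> list[SeqRecord]:
    """Read a FASTA file, uppercasing sequences and validating the alphabet.

    Raises ``ValueError`` on duplicate record ids, empty sequences, or
    residues outside the declared alphabet.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id}: empty sequence")
        _check_alphabet(rec.id, seq, alphabet)
        records.append(SeqRecord(id=rec.id, description=rec.description, seq=seq))
    return records


def write_fasta(path: str | Path, records: Iterable[SeqRecord], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_GFF_KINDS = {"gene": "gene", "mirna": "mirna", "miRNA": "mirna", "miRNA_gene": "mirna"}


def read_gff3(path: str | Path) -> list[GeneFeature]:
    """Read gene-level features from GFF3.

    Only ``gene`` and ``mirna`` feature types are retained; other types are
    skipped (their count is logged). GFF3 1-based inclusive coordinates are
    converted to 0-based half-open.
    """
    feats: list[GeneFeature] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"line {lineno}: expected 9 GFF3 columns, got {len(cols)}")
            scaffold, _src, ftype, start_s, end_s, _score, strand, _phase, attrs_s = cols
            start1, end1 = int(start_s), int(end_s)
            if start1 > end1:
                raise ValueError(f"line {lineno}: start {start1} > end {end1}")
            if ftype not in _GFF_KINDS:
                skipped += 1
                continue
            attributes: dict[str, str] = {}
            for item in attrs_s.split(";"):
                if "=" in item:
                    key, value = item.split("=", 1)
                    attributes[key.strip()] = value.strip()
            feature_id = attributes.get("ID", f"feature_{lineno}")
            feats.append(
                GeneFeature(
                    feature_id=feature_id,
                    scaffold=scaffold,
                    start=start1 - 1,
                    end=end1,
                    strand=strand if strand in ("+", "-") else "+",
                    kind=_GFF_KINDS[ftype],
                    attributes=attributes,
                )
            )
    if skipped:
        logger.info("read_gff3: skipped %d non-gene/mirna features in %s", skipped, path)
    return feats


def write_gff3(path: str | Path, features: Iterable[GeneFeature], source: str = "hoxscan") -> None:
    """Write gene-level features as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = dict(f.attributes)
            attrs.setdefault("ID", f.feature_id)
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{f.scaffold}\t{source}\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attr_s}\n"
            )


# ---------------------------------------------------------------------------
# Translation


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# codon -> aa lookup over base-5 digit encoding (A,C,G,T,N -> 0..4);
# any codon containing N maps to X
_NT_CODE = np.full(128, -1, dtype=np.int8)
for _i, _base in enumerate("ACGTN"):
    _NT_CODE[ord(_base)] = _i
_CODON_AA = np.full(125, ord("X"), dtype=np.uint8)
for _c1 in "ACGT":
    for _c2 in "ACGT":
        for _c3 in "ACGT":
            _idx = 25 * _NT_CODE[ord(_c1)] + 5 * _NT_CODE[ord(_c2)] + _NT_CODE[ord(_c3)]
            _CODON_AA[_idx] = ord(CODON_TABLE[_c1 + _c2 + _c3])


def translate_nt(seq: str) -> str:
    """Translate an in-frame nt string: standard code, N-codons -> X, stops kept."""
    n = len(seq) - len(seq) % 3
    if n == 0:
        return ""
    codes = _NT_CODE[np.frombuffer(seq[:n].encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        pos = int(np.argmax(codes < 0))
        raise ValueError(f"illegal nucleotide {seq[pos]!r} at position {pos}")
    triplets = codes.reshape(-1, 3).astype(np.int32)
    idx = 25 * triplets[:, 0] + 5 * triplets[:, 1] + triplets[:, 2]
    return _CODON_AA[idx].tobytes().decode("ascii")


def six_frame_translate(record: SeqRecord) -> list[TranslatedFrame]:
    """Translate a nucleotide record in all six frames.

    Stops remain in the translations as '*'; trailing partial codons are
    dropped. For minus frames the origin map reports forward-strand
    coordinates: aa index ``i`` of frame ``-(k+1)`` was read from forward
    interval ``[n - k - 3(i+1), n - k - 3i)``.
    """
    _check_alphabet(record.id, record.seq, "nt")
    n = len(record.seq)
    rc = revcomp(record.seq)
    frames: list[TranslatedFrame] = []
    for offset in range(3):
        aa_fwd = translate_nt(record.seq[offset:])

        def fwd_map(i: int, _off: int = offset) -> tuple[int, int, str]:
            start = _off + 3 * i
            return (start, start + 3, "+")

        frames.append(TranslatedFrame(frame_id=offset + 1, aa_seq=aa_fwd, origin_map=fwd_map))

        aa_rev = translate_nt(rc[offset:])

        def rev_map(i: int, _off: int = offset) -> tuple[int, int, str]:
            end = n - _off - 3 * i
            return (end - 3, end, "-")

        frames.append(TranslatedFrame(frame_id=-(offset + 1), aa_seq=aa_rev, origin_map=rev_map))
    return frames


# ---------------------------------------------------------------------------
# Newick


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted newick tree; duplicate leaf labels are an error.

    Unlabelled internal nodes get deterministic labels (``node_<k>`` in
    post-order) so that edges can be named by their child node downstream.
    """
    with open(path) as fh:
        return parse_newick(fh.read())


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a rooted newick string (same validation as :func:`read_newick`)."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises reader-specific classes
        if "duplicate" in str(exc).lower() or "Multiple occurrences" in str(exc):
            raise ValueError("duplicate leaf labels") from exc
        raise
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {lab for lab in labels if labels.count(lab) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
    k = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label
        elif not node.label:
            node.label = f"node_{k}"
            k += 1
    return tree
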