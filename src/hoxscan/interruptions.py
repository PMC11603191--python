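"""Non-Hox gene interruptions and mature-miRNA content of Hox clusters.

Interruptions are protein-coding genes overlapping the cluster hull
[first Hox start, last Hox end) by at least one nucleotide. Mature miRNAs
(~22 nt) are located by exact k-mer seeding on both strands followed by
ungapped extension over the full query, filtered on identity and query
coverage — thresholds chosen so an exact match always passes and four or
more mismatches in a 22-mer never do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .clusters import ClusterReport
from .seqio import GeneFeature, SeqRecord, revcomp

DEFAULT_SEED_K = 9
DEFAULT_MIN_IDENTITY = 0.85
DEFAULT_MIN_COVERAGE = 0.9


@dataclass
class InterruptionReport:
    cluster_id: str
    scaffold: str
    start: int
    end: int
    non_hox_ids: list[str] = field(default_factory=list)

    @property
    def n_non_hox(self) -> int:
        return len(self.non_hox_ids)


@dataclass
class MirnaHit:
    mirna_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    identity: float
    coverage: float


def count_non_hox(
    cluster: ClusterReport,
    annotation: Sequence[GeneFeature],
    hox_ids: set[str],
) -> InterruptionReport:
    """Count non-Hox genes overlapping the cluster hull by >= 1 nt.

    Only ``kind == "gene"`` features count; features whose id is in
    ``hox_ids`` are the cluster's own genes and are excluded. A non-empty
    annotation with no feature on the cluster's scaffold indicates a
    coordinate-system mismatch and is an error.
    """
    start, end = cluster.start, cluster.end
    on_scaffold = [f for f in annotation if f.scaffold == cluster.scaffold]
    if annotation and not on_scaffold:
        raise ValueError(
            f"annotation has no features on scaffold {cluster.scaffold}; "
            "scaffold mismatch?"
        )
    ids = []
    for f in on_scaffold:
        if f.kind != "gene" or f.feature_id in hox_ids:
            continue
        if f.start < end and f.end > start:  # >= 1 nt overlap with the hull
            ids.append(f.feature_id)
    return InterruptionReport(
        cluster_id=cluster.cluster_id,
        scaffold=cluster.scaffold,
        start=start,
        end=end,
        non_hox_ids=sorted(ids),
    )


def _ungapped_hits(
    target: str,
    query: str,
    k: int,
    region: tuple[int, int],
) -> list[tuple[int, int, float, float]]:
    """All distinct ungapped placements of ``query`` on ``target`` sharing
    an exact k-mer with it; returns (start, end, identity, coverage)."""
    qlen = len(query)
    lo = max(0, region[0] - qlen)
    hi = min(len(target), region[1] + qlen)
    window = target[lo:hi]
    starts: set[int] = set()
    for q_off in range(qlen - k + 1):
        seed = query[q_off : q_off + k]
        pos = window.find(seed)
        while pos != -1:
            starts.add(lo + pos - q_off)
            pos = window.find(seed, pos + 1)
    out = []
    for a_start in sorted(starts):
        t0 = max(a_start, 0)
        t1 = min(a_start + qlen, len(target))
        aligned = t1 - t0
        if aligned <= 0:
            continue
        matches = sum(
            1 for i in range(t0, t1) if target[i] == query[i - a_start]
        )
        out.append((t0, t1, matches / aligned, aligned / qlen))
    return out


def find_mirnas(
    scaffold_seq: SeqRecord,
    interval: tuple[int, int],
    mirnas: Sequence[SeqRecord],
    k: int = DEFAULT_SEED_K,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[MirnaHit]:
    """Locate mature miRNAs within a cluster interval, both strands.

    Overlapping placements of one query are deduplicated to the best
    identity (ties: leftmost, then '+' strand).
    """
    hits: list[MirnaHit] = []
    for q in mirnas:
        if len(q.seq) < k:
            raise ValueError(f"miRNA query {q.id} shorter than seed length {k}")
        candidates: list[MirnaHit] = []
        for strand, qseq in (("+", q.seq), ("-", revcomp(q.seq))):
            for start, end, ident, cov in _ungapped_hits(
                scaffold_seq.seq, qseq, k, interval
            ):
                if ident < min_identity or cov < min_coverage:
                    continue
                if start >= interval[1] or end <= interval[0]:
                    continue  # outside the cluster interval
                candidates.append(
                    MirnaHit(
                        mirna_id=q.id,
                        scaffold=scaffold_seq.id,
                        start=start,
                        end=end,
                        strand=strand,
                        identity=ident,
                        coverage=cov,
                    )
                )
        # deduplicate overlapping placements of this query: keep best identity
        candidates.sort(key=lambda h: (-h.identity, h.start, h.strand))
        kept: list[MirnaHit] = []
        for h in candidates:
            if all(h.start >= x.end or h.end <= x.start for x in kept):
                kept.append(h)
        hits.extend(sorted(kept, key=lambda h: h.start))
    return hits


def mirna_hits_to_features(hits: Sequence[MirnaHit]) -> list[GeneFeature]:
    return [
        GeneFeature(
            feature_id=f"{h.mirna_id}_{h.start}",
            scaffold=h.scaffold,
            start=h.start,
            end=h.end,
            strand=h.strand,
            kind="mirna",
            attributes={
                "ID": f"{h.mirna_id}_{h.start}",
                "mirna": h.mirna_id,
                "identity": f"{h.identity:.3f}",
                "coverage": f"{h.coverage:.3f}",
            },
        )
        for h in hits
    ]
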