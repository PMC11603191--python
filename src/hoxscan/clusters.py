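"""Hox cluster detection and architecture metrics.

A cluster is four or more Hox genes on one scaffold within a bounded span
(default 0.3 Mb). For each cluster we report the span, the genomic order of
canonical ranks, transcriptional orientations, and a Kendall-style
collinearity statistic tau = (C - D) / (C + D) over rank-distinct gene
pairs, where C counts pairs whose genomic order matches the canonical
HOX1 -> HOX9-13 order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .profiles import GROUP_RANK
from .scan import HoxLocus

DEFAULT_MIN_GENES = 4
DEFAULT_MAX_SPAN = 300_000  # nt


@dataclass
class ClusterReport:
    scaffold: str
    members: list[HoxLocus]  # ordered by nt_start
    span: int
    order_ranks: list[int]
    strands: list[str]
    tau: float | None
    tau_rev: float | None
    discordant_pairs: int
    modal_strand: str
    orientation_consistency: float
    flipped_members: list[str]
    min_genes: int
    max_span: int
    cluster_id: str = ""

    @property
    def start(self) -> int:
        return min(l.nt_start for l in self.members)

    @property
    def end(self) -> int:
        return max(l.nt_end for l in self.members)


@dataclass
class LociSpanReport:
    scaffold: str
    n_hox: int
    span: int  # hull of all Hox loci on the scaffold, no max_span constraint


def _window_span(members: Sequence[HoxLocus]) -> int:
    return max(l.nt_end for l in members) - min(l.nt_start for l in members)


def collinearity_stats(
    ranks_in_genomic_order: Sequence[int],
) -> tuple[float | None, float | None, int]:
    """(tau, tau_rev, discordant) over pairs with distinct canonical ranks."""
    c = d = 0
    n = len(ranks_in_genomic_order)
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = ranks_in_genomic_order[i], ranks_in_genomic_order[j]
            if ri < rj:
                c += 1
            elif ri > rj:
                d += 1
    if c + d == 0:
        return None, None, 0
    tau = (c - d) / (c + d)
    return tau, -tau, d


def _make_report(
    members: list[HoxLocus], min_genes: int, max_span: int
) -> ClusterReport:
    members = sorted(members, key=lambda l: (l.nt_start, l.nt_end))
    ranks = [GROUP_RANK[l.best_group] for l in members]
    strands = [l.strand for l in members]
    tau, tau_rev, discordant = collinearity_stats(ranks)
    modal, consistency, flipped = orientation_stats(members)
    return ClusterReport(
        scaffold=members[0].scaffold,
        members=members,
        span=_window_span(members),
        order_ranks=ranks,
        strands=strands,
        tau=tau,
        tau_rev=tau_rev,
        discordant_pairs=discordant,
        modal_strand=modal,
        orientation_consistency=consistency,
        flipped_members=flipped,
        min_genes=min_genes,
        max_span=max_span,
    )


def collinearity(cluster: ClusterReport) -> tuple[float | None, int]:
    return cluster.tau, cluster.discordant_pairs


def orientation_stats(members: Sequence[HoxLocus]) -> tuple[str, float, list[str]]:
    """Modal strand (tie -> '+'), consistency fraction, flipped member ids."""
    if not members:
        raise ValueError("empty cluster")
    n_plus = sum(1 for l in members if l.strand == "+")
    modal = "+" if n_plus >= len(members) - n_plus else "-"
    on_modal = sum(1 for l in members if l.strand == modal)
    flipped = [l.locus_id for l in members if l.strand != modal]
    return modal, on_modal / len(members), flipped


def orientation_profile(cluster: ClusterReport) -> tuple[str, float, list[str]]:
    return cluster.modal_strand, cluster.orientation_consistency, cluster.flipped_members


def _best_window(
    loci: list[HoxLocus], min_genes: int, max_span: int
) -> tuple[int, int] | None:
    """Best qualifying contiguous window: max members, then min span, then
    leftmost start. Returns (i, j) inclusive indices or None."""
    best: tuple[int, int, int, int] | None = None  # (-count, span, start, i) key + j
    best_ij = None
    n = len(loci)
    for i in range(n):
        for j in range(i + min_genes - 1, n):
            members = loci[i : j + 1]
            span = _window_span(members)
            if span > max_span:
                break  # loci sorted by start: extending only grows the hull
            key = (-(j - i + 1), span, loci[i].nt_start)
            if best is None or key < best[:3]:
                best = (*key, j)
                best_ij = (i, j)
    return best_ij


def detect_clusters(
    loci: Sequence[HoxLocus],
    min_genes: int = DEFAULT_MIN_GENES,
    max_span: int = DEFAULT_MAX_SPAN,
    include_ambiguous: bool = False,
) -> list[ClusterReport]:
    """Find Hox clusters per scaffold.

    Among all contiguous runs (in genomic order) whose coordinate hull is
    <= ``max_span`` (boundary inclusive) and size >= ``min_genes``, the
    best window (most members, then smallest span, then leftmost) is taken
    first; remaining loci on either side are re-examined. Each locus joins
    at most one cluster. Ambiguous loci are excluded unless requested.
    """
    pool = [
        l for l in loci if include_ambiguous or l.status == "assigned"
    ]
    by_scaffold: dict[str, list[HoxLocus]] = {}
    for l in pool:
        by_scaffold.setdefault(l.scaffold, []).append(l)
    reports: list[ClusterReport] = []
    for scaffold in sorted(by_scaffold):
        segs = [sorted(by_scaffold[scaffold], key=lambda l: (l.nt_start, l.nt_end))]
        while segs:
            seg = segs.pop()
            if len(seg) < min_genes:
                continue
            ij = _best_window(seg, min_genes, max_span)
            if ij is None:
                continue
            i, j = ij
            reports.append(_make_report(seg[i : j + 1], min_genes, max_span))
            segs.append(seg[:i])
            segs.append(seg[j + 1 :])
    reports.sort(key=lambda r: (r.scaffold, r.start))
    for k, r in enumerate(reports, start=1):
        r.cluster_id = f"cluster_{k}"
    return reports


def loci_span(loci: Sequence[HoxLocus]) -> list[LociSpanReport]:
    """Per-scaffold hull of all Hox loci, regardless of clustering."""
    by_scaffold: dict[str, list[HoxLocus]] = {}
    for l in loci:
        by_scaffold.setdefault(l.scaffold, []).append(l)
    out = []
    for scaffold in sorted(by_scaffold):
        members = by_scaffold[scaffold]
        out.append(
            LociSpanReport(
                scaffold=scaffold,
                n_hox=len(members),
                span=_window_span(members),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Export


def cluster_table(
    clusters: Sequence[ClusterReport],
    spans: Sequence[LociSpanReport] = (),
    non_hox: dict[str, int] | None = None,
    taxon: str = "",
) -> pd.DataFrame:
    """Architecture summary table (one row per cluster)."""
    span_by_scaffold = {s.scaffold: s for s in spans}
    rows = []
    for c in clusters:
        s = span_by_scaffold.get(c.scaffold)
        rows.append(
            {
                "taxon": taxon,
                "cluster_id": c.cluster_id,
                "scaffold": c.scaffold,
                "hox_loci": len(c.members),
                "genomic_loci_size": s.span if s else c.span,
                "cluster_size": c.span,
                "n_non_hox": non_hox.get(c.cluster_id) if non_hox else None,
                "order": ",".join(l.best_group for l in c.members),
                "strands": "".join(c.strands),
                "tau": None if c.tau is None else round(c.tau, 4),
                "orientation_consistency": round(c.orientation_consistency, 4),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "taxon", "cluster_id", "scaffold", "hox_loci", "genomic_loci_size",
            "cluster_size", "n_non_hox", "order", "strands", "tau",
            "orientation_consistency",
        ],
    )


def clusters_to_bed(clusters: Sequence[ClusterReport], path: str | Path) -> None:
    """Per-member BED (0-based half-open) for genome-browser loading."""
    with open(path, "w") as fh:
        for c in clusters:
            for l in c.members:
                fh.write(
                    f"{l.scaffold}\t{l.nt_start}\t{l.nt_end}\t"
                    f"{c.cluster_id}.{l.locus_id}.{l.best_group}\t"
                    f"{int(min(l.score, 1000))}\t{l.strand}\n"
                )
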