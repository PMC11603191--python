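"""Homeodomain locus detection in genomes (six-frame) and proteomes.

The scanner slides every profile over every reading frame, converts window
scores to E-values under each profile's calibrated null, maps significant
windows back to forward-strand nucleotide coordinates, and merges nearby
windows into loci. The two-round search folds accepted round-1 windows
back into the profiles (recalibrating) before a second pass, mirroring the
iterative profile-augmentation strategy used for divergent family members.

E-values share a single m = total number of windows scanned genome-wide
across all six frames (per profile; no further cross-profile correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .profiles import GroupProfile, augment_profile, encode_aa
from .seqio import GeneFeature, SeqRecord, TranslatedFrame, six_frame_translate

DEFAULT_THRESHOLD_E = 1e-5
DEFAULT_MAX_GAP = 5_000  # nt; bridges a single intron splitting the domain


@dataclass
class WindowHit:
    """A single significant profile window in one reading frame."""

    scaffold: str
    frame_id: int
    aa_start: int
    nt_start: int
    nt_end: int
    strand: str
    group: str
    score: float
    evalue: float
    window: str = ""  # the aa window itself, kept for round-2 augmentation


@dataclass
class HoxLocus:
    """A merged homeodomain locus with per-group best scores.

    ``margin`` is the gap in bits between the best and second-best group;
    +inf when only one group scored. ``aa_space`` marks proteome-mode loci
    whose coordinates are aa indices within the protein named by
    ``scaffold``.
    """

    locus_id: str
    scaffold: str
    nt_start: int
    nt_end: int
    strand: str
    best_group: str
    score: float
    margin: float
    status: str  # "assigned" or "ambiguous"
    group_scores: dict[str, float] = field(default_factory=dict)
    aa_space: bool = False


def _score_cutoff(profile: GroupProfile, threshold_E: float, m: int) -> float:
    """Smallest score with E(S, m) <= threshold_E under the fitted Gumbel."""
    p = threshold_E / m
    if p >= 1.0:
        return -math.inf
    return profile.mu - profile.lam * math.log(-math.log1p(-p))


def _window_scores(matrix: np.ndarray, codes: np.ndarray, L: int) -> np.ndarray:
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for i in range(L):
        scores += matrix[i, codes[i : i + n]]
    return scores


def scan_frame(
    profiles: Sequence[GroupProfile],
    frame: TranslatedFrame,
    threshold_E: float,
    m: int,
    scaffold: str,
) -> list[WindowHit]:
    """Score every window of one frame against every profile.

    Windows containing a stop score -inf and are never reported. Reported
    nt coordinates are the forward-strand hull of the window's codons.
    All profiles are scored in one batched pass over the frame.
    """
    lengths = {p.L for p in profiles}
    if len(lengths) > 1:
        raise ValueError(f"profiles have differing window lengths {sorted(lengths)}")
    if m < 1:
        raise ValueError("m must be >= 1")
    L = lengths.pop()
    for prof in profiles:
        if not prof.calibrated:
            raise ValueError(f"profile {prof.group} is not calibrated")
    codes = encode_aa(frame.aa_seq)
    n = len(codes) - L + 1
    if n <= 0:
        return []
    mats = np.stack([p.matrix for p in profiles], axis=-1)  # (L, 22, G)
    acc = np.zeros((n, len(profiles)))
    for i in range(L):
        acc += mats[i, codes[i : i + n], :]
    hits: list[WindowHit] = []
    for g, prof in enumerate(profiles):
        scores = acc[:, g]
        cutoff = _score_cutoff(prof, threshold_E, m)
        for j in np.flatnonzero(scores >= cutoff):
            j = int(j)
            s = float(scores[j])
            first = frame.origin_map(j)
            last = frame.origin_map(j + L - 1)
            nt_start = min(first[0], last[0])
            nt_end = max(first[1], last[1])
            hits.append(
                WindowHit(
                    scaffold=scaffold,
                    frame_id=frame.frame_id,
                    aa_start=j,
                    nt_start=nt_start,
                    nt_end=nt_end,
                    strand=first[2],
                    group=prof.group,
                    score=s,
                    evalue=prof.evalue(s, m),
                    window=frame.aa_seq[j : j + L],
                )
            )
    return hits


def merge_hits(
    hits: Sequence[WindowHit],
    max_gap: int = DEFAULT_MAX_GAP,
    aa_space: bool = False,
) -> list[HoxLocus]:
    """Merge window hits on the same scaffold and strand into loci.

    Hits whose intervals overlap or lie within ``max_gap`` are chained;
    the locus takes the coordinate hull, and group_scores keeps the best
    window score per group.
    """
    by_key: dict[tuple[str, str], list[WindowHit]] = {}
    for h in hits:
        by_key.setdefault((h.scaffold, h.strand), []).append(h)
    loci: list[HoxLocus] = []
    for (scaffold, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: (h.nt_start, h.nt_end))
        chain: list[WindowHit] = []
        chain_end = -1
        for h in group + [None]:  # type: ignore[list-item]
            if h is not None and (not chain or h.nt_start - chain_end <= max_gap):
                chain.append(h)
                chain_end = max(chain_end, h.nt_end)
                continue
            if chain:
                loci.append(_locus_from_chain(chain, aa_space))
            if h is not None:
                chain = [h]
                chain_end = h.nt_end
    loci.sort(key=lambda l: (l.scaffold, l.nt_start, l.strand))
    for k, locus in enumerate(loci, start=1):
        locus.locus_id = f"hox_{k:04d}"
    return loci


def _locus_from_chain(chain: list[WindowHit], aa_space: bool) -> HoxLocus:
    group_scores: dict[str, float] = {}
    for h in chain:
        if h.score > group_scores.get(h.group, -math.inf):
            group_scores[h.group] = h.score
    best_group = max(group_scores, key=lambda g: (group_scores[g], g))
    score = group_scores[best_group]
    others = [v for g, v in group_scores.items() if g != best_group]
    margin = score - max(others) if others else math.inf
    return HoxLocus(
        locus_id="",
        scaffold=chain[0].scaffold,
        nt_start=min(h.nt_start for h in chain),
        nt_end=max(h.nt_end for h in chain),
        strand=chain[0].strand,
        best_group=best_group,
        score=score,
        margin=margin,
        status="ambiguous",
        group_scores=group_scores,
        aa_space=aa_space,
    )


def scan_genome(
    profiles: Sequence[GroupProfile],
    genome: Sequence[SeqRecord],
    threshold_E: float = DEFAULT_THRESHOLD_E,
    max_gap: int = DEFAULT_MAX_GAP,
    rounds: int = 2,
    seed: int = 0,
    n_windows: int = 10_000,
    return_profiles: bool = False,
):
    """Six-frame scan of a genome, optionally with profile augmentation.

    Round 1 translates and scans every scaffold; with ``rounds=2`` the
    accepted round-1 hit windows are added to their matched profiles
    (weight 1 each), the null is re-fitted, and the scan is repeated. The
    final loci come from the last round. Deterministic given ``seed``.
    """
    if rounds not in (1, 2):
        raise ValueError("rounds must be 1 or 2")
    frames_by_scaffold = [(rec.id, six_frame_translate(rec)) for rec in genome]
    lengths = {p.L for p in profiles}
    if len(lengths) > 1:
        raise ValueError(f"profiles have differing window lengths {sorted(lengths)}")
    L = lengths.pop() if lengths else 0
    m = sum(
        max(0, len(f.aa_seq) - L + 1)
        for _sid, frames in frames_by_scaffold
        for f in frames
    )
    m = max(m, 1)

    def one_round(profs: Sequence[GroupProfile]) -> list[WindowHit]:
        hits: list[WindowHit] = []
        for sid, frames in frames_by_scaffold:
            for fr in frames:
                hits.extend(scan_frame(profs, fr, threshold_E, m, scaffold=sid))
        return hits

    hits = one_round(profiles)
    used = list(profiles)
    if rounds == 2 and hits:
        windows_by_group: dict[str, list[str]] = {}
        for h in hits:
            windows_by_group.setdefault(h.group, []).append(h.window)
        used = [
            augment_profile(
                p,
                windows_by_group.get(p.group, []),
                weight=1.0,
                n_windows=n_windows,
                seed=seed,
            )
            if p.group in windows_by_group
            else p
            for p in profiles
        ]
        hits = one_round(used)
    loci = merge_hits(hits, max_gap=max_gap)
    if return_profiles:
        return loci, used
    return loci


def scan_proteome(
    profiles: Sequence[GroupProfile],
    proteins: Sequence[SeqRecord],
    threshold_E: float = DEFAULT_THRESHOLD_E,
) -> list[HoxLocus]:
    """Scan a proteome; loci carry aa-space coordinates (strand fixed '+')."""
    for rec in proteins:
        if set(rec.seq) <= set("ACGTN"):
            raise ValueError(
                f"record {rec.id} looks like a nucleotide sequence; "
                "proteome mode needs amino acids"
            )
    lengths = {p.L for p in profiles}
    if len(lengths) > 1:
        raise ValueError(f"profiles have differing window lengths {sorted(lengths)}")
    L = lengths.pop() if lengths else 0
    m = max(1, sum(max(0, len(rec.seq) - L + 1) for rec in proteins))
    hits: list[WindowHit] = []
    for rec in proteins:
        frame = TranslatedFrame(
            frame_id=1,
            aa_seq=rec.seq,
            origin_map=lambda i: (i, i + 1, "+"),
        )
        hits.extend(scan_frame(profiles, frame, threshold_E, m, scaffold=rec.id))
    return merge_hits(hits, max_gap=0, aa_space=True)


# ---------------------------------------------------------------------------
# Export


def loci_to_features(loci: Sequence[HoxLocus]) -> list[GeneFeature]:
    feats = []
    for l in loci:
        feats.append(
            GeneFeature(
                feature_id=l.locus_id,
                scaffold=l.scaffold,
                start=l.nt_start,
                end=l.nt_end,
                strand=l.strand,
                kind="gene",
                attributes={
                    "ID": l.locus_id,
                    "group": l.best_group,
                    "score": f"{l.score:.3f}",
                    "margin": "inf" if math.isinf(l.margin) else f"{l.margin:.3f}",
                    "status": l.status,
                },
            )
        )
    return feats


def read_loci_table(path) -> list[HoxLocus]:
    """Load loci back from the TSV written by :func:`loci_table`.

    Per-group window scores are not serialized; group_scores is rebuilt
    with the best group only, which preserves score/margin semantics.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    loci = []
    for _idx, row in df.iterrows():
        margin = float(row["margin"]) if str(row["margin"]) != "inf" else math.inf
        loci.append(
            HoxLocus(
                locus_id=str(row["locus_id"]),
                scaffold=str(row["scaffold"]),
                nt_start=int(row["start"]),
                nt_end=int(row["end"]),
                strand=str(row["strand"]),
                best_group=str(row["group"]),
                score=float(row["score"]),
                margin=margin,
                status=str(row["status"]),
                group_scores={str(row["group"]): float(row["score"])},
                aa_space=row.get("coordinate_space", "nt") == "aa",
            )
        )
    return loci


def loci_table(loci: Sequence[HoxLocus]):
    """Loci as a pandas DataFrame (stable column order, TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "locus_id": l.locus_id,
                "scaffold": l.scaffold,
                "start": l.nt_start,
                "end": l.nt_end,
                "strand": l.strand,
                "group": l.best_group,
                "score": round(l.score, 3),
                "margin": l.margin if math.isinf(l.margin) else round(l.margin, 3),
                "status": l.status,
                "coordinate_space": "aa" if l.aa_space else "nt",
            }
            for l in loci
        ],
        columns=[
            "locus_id", "scaffold", "start", "end", "strand",
            "group", "score", "margin", "status", "coordinate_space",
        ],
    )
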