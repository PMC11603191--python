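"""Per-orthology-group log-odds profiles for homeodomain detection.

A profile is a position-specific scoring matrix over the ~60-column
homeodomain core, built from a labelled reference alignment (ingroup plus
outgroup rows tagged with their orthology group). Column probabilities use
background-mixed pseudocounts,

    p_i(a) = (n_i(a) + alpha * q(a)) / (N_i + alpha),

and the matrix holds M[a][i] = log2(p_i(a) / q(a)) in bits. Significance is
assigned by an empirical null: scores of random windows drawn from the
background are fitted to a Gumbel distribution by method of moments, and
E(S, m) = m * P_null(score >= S) for m windows scanned.

There are no insert/delete states: the homeodomain core is treated as a
fixed-length ungapped window after gap-column filtering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import AA_RESIDUES, SeqRecord, read_fasta

# The nine orthology groups recognised across Nematoda + Nematomorpha.
# The three HOX6-8 subtypes are distinct groups for detection and
# classification but share a single rank for collinearity.
ORTHOLOGY_GROUPS: tuple[str, ...] = (
    "HOX1",
    "HOX2",
    "HOX3",
    "HOX4",
    "HOX5",
    "HOX6-8_ftz",
    "HOX6-8_Antp",
    "HOX6-8_UbxAbdA",
    "HOX9-13",
)

GROUP_RANK: dict[str, int] = {
    "HOX1": 1,
    "HOX2": 2,
    "HOX3": 3,
    "HOX4": 4,
    "HOX5": 5,
    "HOX6-8_ftz": 6,
    "HOX6-8_Antp": 6,
    "HOX6-8_UbxAbdA": 6,
    "HOX9-13": 7,
}

N_AA = 20
_AA_INDEX = {a: i for i, a in enumerate(AA_RESIDUES)}
# extended encoding used by the scanner: X -> 20 (neutral), * -> 21 (reject)
X_CODE = 20
STOP_CODE = 21

GAP_CHARS = frozenset("-.")

EULER_GAMMA = 0.5772156649015329

PROFILE_FORMAT_VERSION = 1


_AA_LOOKUP = np.full(128, -1, dtype=np.int8)
for _ch, _i in _AA_INDEX.items():
    _AA_LOOKUP[ord(_ch)] = _i
_AA_LOOKUP[ord("X")] = X_CODE
_AA_LOOKUP[ord("*")] = STOP_CODE


def encode_aa(seq: str) -> np.ndarray:
    """Encode an aa string to integer codes (20 residues, X=20, *=21)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if raw.size and raw.max() >= 128:
        raise ValueError("illegal non-ASCII amino-acid residue")
    codes = _AA_LOOKUP[raw]
    if (codes < 0).any():
        pos = int(np.argmax(codes < 0))
        raise ValueError(f"illegal amino-acid residue {seq[pos]!r} at position {pos}")
    return codes


@dataclass
class LabelledAlignment:
    """Gapped aa alignment rows tagged with orthology group and member id."""

    rows: list[tuple[str, str, str]]  # (group, member_id, aa_row)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        lengths = {len(r[2]) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        for group, member_id, _row in self.rows:
            if group not in ORTHOLOGY_GROUPS:
                raise ValueError(f"unknown orthology group {group!r} for {member_id}")

    @property
    def L(self) -> int:
        return len(self.rows[0][2])

    def groups(self) -> list[str]:
        return sorted({g for g, _m, _r in self.rows}, key=ORTHOLOGY_GROUPS.index)

    def subset(self, group: str) -> "LabelledAlignment":
        rows = [r for r in self.rows if r[0] == group]
        if not rows:
            raise ValueError(f"no rows for group {group}")
        return LabelledAlignment(rows=rows)


def read_labelled_alignment(path: str | Path) -> LabelledAlignment:
    """Read a reference alignment from aa FASTA with ``group=<name>`` tags."""
    rows = []
    for rec in read_fasta_gapped(path):
        group = None
        for token in rec.description.split():
            if token.startswith("group="):
                group = token[len("group=") :]
        if group is None:
            raise ValueError(f"record {rec.id}: missing group=<name> tag")
        rows.append((group, rec.id, rec.seq))
    return LabelledAlignment(rows=rows)


def read_fasta_gapped(path: str | Path) -> list[SeqRecord]:
    """aa FASTA reader that additionally admits gap characters ('-', '.')."""
    from Bio import SeqIO

    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq):
            if ch not in _AA_INDEX and ch != "X" and ch != "*" and ch not in GAP_CHARS:
                raise ValueError(f"record {rec.id}: illegal residue {ch!r} at position {pos}")
        records.append(SeqRecord(id=rec.id, description=rec.description, seq=seq))
    return records


def background_from_alignment(alignment: LabelledAlignment) -> np.ndarray:
    """Pooled residue composition over all rows and groups, smoothed.

    One pseudo-observation per residue keeps every q(a) > 0 so the log-odds
    stay finite even when a residue never occurs in the reference set.
    """
    counts = np.ones(N_AA)
    for _g, _m, row in alignment.rows:
        for ch in row:
            if ch in _AA_INDEX:
                counts[_AA_INDEX[ch]] += 1
    return counts / counts.sum()


@dataclass
class GroupProfile:
    """Calibrated log-odds matrix for one orthology group.

    ``counts`` holds the raw residue counts per column (so the profile can
    be augmented with round-1 hits and rebuilt exactly); ``matrix`` is the
    (L, 22) scoring matrix in bits with the X (neutral, 0) and * (-inf)
    rows appended.
    """

    group: str
    L: int
    counts: np.ndarray  # (L, 20) float
    q: np.ndarray  # (20,) background
    alpha: float
    matrix: np.ndarray = field(init=False)  # (L, 22) bits
    mu: float | None = None
    lam: float | None = None  # Gumbel scale
    threshold_E: float = 1e-5

    def __post_init__(self) -> None:
        if self.group not in ORTHOLOGY_GROUPS:
            raise ValueError(f"unknown orthology group {self.group!r}")
        if not np.isclose(self.q.sum(), 1.0):
            raise ValueError("background q must sum to 1")
        if np.any(self.q <= 0):
            raise ValueError("background q must be strictly positive")
        self._rebuild_matrix()

    def _rebuild_matrix(self) -> None:
        n_col = self.counts.sum(axis=1, keepdims=True)  # N_i, non-gap counts
        p = (self.counts + self.alpha * self.q) / (n_col + self.alpha)
        core = np.log2(p / self.q)  # (L, 20)
        self.matrix = np.hstack(
            [core, np.zeros((self.L, 1)), np.full((self.L, 1), -np.inf)]
        )

    @property
    def probabilities(self) -> np.ndarray:
        """Reconstructed per-column probability model p_i(a), rows sum to 1."""
        n_col = self.counts.sum(axis=1, keepdims=True)
        return (self.counts + self.alpha * self.q) / (n_col + self.alpha)

    @property
    def calibrated(self) -> bool:
        return self.mu is not None and self.lam is not None

    def consensus(self) -> str:
        """Per-column argmax of the scoring matrix (the top-scoring window)."""
        idx = np.argmax(self.matrix[:, :N_AA], axis=1)
        return "".join(AA_RESIDUES[i] for i in idx)

    def evalue(self, score: float, m: int) -> float:
        """E(S, m) = m * (1 - GumbelCDF(S)) under the fitted null."""
        if not self.calibrated:
            raise ValueError(f"profile {self.group} is not calibrated")
        if np.isneginf(score):
            return float(m)
        z = (score - self.mu) / self.lam
        # survival 1 - exp(-exp(-z)), numerically = -expm1(-exp(-z));
        # exp(-z) overflow for deeply negative scores saturates to E = m
        with np.errstate(over="ignore"):
            return float(m) * float(-np.expm1(-np.exp(-z)))


def build_profile(
    alignment: LabelledAlignment,
    q: np.ndarray | None = None,
    alpha: float = 1.0,
    gap_max: float = 0.5,
) -> GroupProfile:
    """Build an uncalibrated profile from the rows of a single group.

    Columns whose gap fraction is >= ``gap_max`` are dropped, shrinking L.
    """
    groups = {g for g, _m, _r in alignment.rows}
    if len(groups) != 1:
        raise ValueError(f"alignment mixes groups {sorted(groups)}; restrict to one")
    if not (0 <= gap_max < 1):
        raise ValueError("gap_max must be in [0, 1)")
    group = groups.pop()
    if q is None:
        q = background_from_alignment(alignment)
    n_rows = len(alignment.rows)
    L_full = alignment.L
    counts_full = np.zeros((L_full, N_AA))
    gaps = np.zeros(L_full)
    for _g, _m, row in alignment.rows:
        for i, ch in enumerate(row):
            if ch in GAP_CHARS:
                gaps[i] += 1
            elif ch in _AA_INDEX:
                counts_full[i, _AA_INDEX[ch]] += 1
            # X contributes to neither counts nor gaps (unknown residue)
    keep = gaps / n_rows < gap_max
    if not keep.any():
        raise ValueError("all columns dropped by gap filtering")
    counts = counts_full[keep]
    return GroupProfile(group=group, L=int(keep.sum()), counts=counts, q=q, alpha=alpha)


def calibrate_profile(
    profile: GroupProfile,
    null_model: np.ndarray | None = None,
    n_windows: int = 10_000,
    seed: int = 0,
    threshold_E: float | None = None,
) -> GroupProfile:
    """Fit the null score distribution and return a calibrated copy.

    ``n_windows`` i.i.d. windows of length L are drawn from ``null_model``
    (default: the profile's background q), scored, and fitted to a Gumbel
    by method of moments: scale = sqrt(6 Var) / pi, location = mean -
    gamma * scale. Deterministic given ``seed``.
    """
    if n_windows < 1000:
        raise ValueError("n_windows must be >= 1000 for a stable fit")
    null = profile.q if null_model is None else np.asarray(null_model, dtype=float)
    rng = np.random.default_rng(seed)
    windows = rng.choice(N_AA, size=(n_windows, profile.L), p=null)
    scores = profile.matrix[np.arange(profile.L), windows].sum(axis=1)
    var = float(scores.var())
    if np.sqrt(var) < 1e-9 * (1.0 + abs(float(scores.mean()))):
        raise ValueError("degenerate null: zero score variance")
    lam = float(np.sqrt(6.0 * var) / np.pi)
    mu = float(scores.mean() - EULER_GAMMA * lam)
    out = replace(
        profile,
        counts=profile.counts.copy(),
        mu=None,
        lam=None,
        threshold_E=threshold_E if threshold_E is not None else profile.threshold_E,
    )
    out.mu = mu
    out.lam = lam
    return out


def score_window(profile: GroupProfile, window: str) -> float:
    """Score one aa window of length L: sum of per-column log-odds in bits.

    X scores 0 at every column; a window containing '*' scores -inf.
    """
    if len(window) != profile.L:
        raise ValueError(f"window length {len(window)} != profile L {profile.L}")
    codes = encode_aa(window)
    return float(profile.matrix[np.arange(profile.L), codes].sum())


def augment_profile(
    profile: GroupProfile,
    new_members: Sequence[str],
    weight: float = 1.0,
    recalibrate: bool = True,
    n_windows: int = 10_000,
    seed: int = 0,
) -> GroupProfile:
    """Add fixed-length hit windows to the profile counts and rebuild.

    Implements the second search round: accepted round-1 hit windows are
    folded into the count matrix at ``weight`` observations each, the
    log-odds matrix is recomputed, and the null is re-fitted.
    """
    counts = profile.counts.copy()
    for win in new_members:
        if len(win) != profile.L:
            raise ValueError(f"window length {len(win)} != profile L {profile.L}")
        codes = encode_aa(win)
        for i, c in enumerate(codes):
            if c < N_AA:
                counts[i, c] += weight
    out = replace(profile, counts=counts, mu=None, lam=None)
    if recalibrate:
        out = calibrate_profile(out, n_windows=n_windows, seed=seed,
                                threshold_E=profile.threshold_E)
    return out


# ---------------------------------------------------------------------------
# Serialization (versioned structured text; JSON container)


def save_profiles(path: str | Path, profiles: Sequence[GroupProfile]) -> None:
    payload = {
        "format": "hoxscan-profiles",
        "version": PROFILE_FORMAT_VERSION,
        "profiles": [
            {
                "group": p.group,
                "L": p.L,
                "alpha": p.alpha,
                "q": [round(float(x), 6) for x in p.q],
                "counts": [[round(float(x), 6) for x in row] for row in p.counts],
                "mu": p.mu,
                "lam": p.lam,
                "threshold_E": p.threshold_E,
            }
            for p in profiles
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_profiles(path: str | Path) -> list[GroupProfile]:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "hoxscan-profiles":
        raise ValueError(f"{path}: not a hoxscan profile file")
    if payload.get("version") != PROFILE_FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported profile format version")
    out = []
    for d in payload["profiles"]:
        q = np.asarray(d["q"], dtype=float)
        q = q / q.sum()  # re-normalise after 6-decimal rounding
        p = GroupProfile(
            group=d["group"],
            L=d["L"],
            counts=np.asarray(d["counts"], dtype=float),
            q=q,
            alpha=d["alpha"],
            threshold_E=d["threshold_E"],
        )
        p.mu = d["mu"]
        p.lam = d["lam"]
        out.append(p)
    return out


def build_all_profiles(
    alignment: LabelledAlignment,
    q: np.ndarray | None = None,
    alpha: float = 1.0,
    gap_max: float = 0.5,
    n_windows: int = 10_000,
    seed: int = 0,
    threshold_E: float = 1e-5,
) -> list[GroupProfile]:
    """Build and calibrate one profile per group present in the alignment.

    The background q is pooled over all groups (shared across profiles)
    unless given explicitly.
    """
    if q is None:
        q = background_from_alignment(alignment)
    out = []
    for group in alignment.groups():
        prof = build_profile(alignment.subset(group), q=q, alpha=alpha, gap_max=gap_max)
        out.append(
            calibrate_profile(prof, n_windows=n_windows, seed=seed, threshold_E=threshold_E)
        )
    return out
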