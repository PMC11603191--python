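# Methods

This note documents the models and procedures implemented in `hoxscan`,
the parameters that matter, the numerical choices behind them, and what
the synthetic validation does and does not establish.

## Homeodomain profiles

Each orthology group (HOX1, HOX2, HOX3, HOX4, HOX5, the three HOX6-8
subtypes ftz/Antp/UbxAbdA, and HOX9-13) is modelled as a position-specific
log-odds matrix over the homeodomain core. The model is deliberately
simpler than a full profile HMM: after gap-column filtering the
homeodomain is treated as a fixed-length ungapped window (typically 60
columns), so there are no insert/delete states. For a discriminative
detect-and-classify task on a domain this strongly conserved in length,
indel states add parameters without adding separation; the cost is that a
homeodomain with an internal indel relative to the reference alignment
would score as two partial windows rather than one full one.

Column probabilities mix observed counts with the background:
p_i(a) = (n_i(a) + α·q(a)) / (N_i + α), with α = 1 by default
(Laplace-style, background-weighted). The matrix stores
M[a][i] = log₂(p_i(a)/q(a)) in bits. Unknown residues (X) score 0 at
every column; a stop (*) anywhere in a window scores −∞, which silently
rejects windows straddling reading-frame stops.

The background q defaults to the residue composition pooled over the
whole reference alignment, smoothed with one pseudo-observation per
residue so that q(a) > 0 for all twenty residues (a residue absent from
the reference would otherwise make the log-odds undefined). Supplying an
explicit q overrides this.

Gap-heavy columns (gap fraction ≥ 0.5 by default) are dropped before any
scoring; the profile length L shrinks accordingly and all windows are
scored at that L.

## E-value calibration

Significance uses an empirical null rather than analytic extreme-value
theory for gapped search: 10,000 i.i.d. windows are drawn from q, scored,
and fitted to a Gumbel by method of moments (scale λ = √(6·Var)/π,
location μ = mean − γ·λ, γ the Euler–Mascheroni constant). Then
E(S, m) = m·(1 − F(S)) with m the number of windows actually scanned
genome-wide across all six frames — the same m for every profile, which
shares the multiple-testing burden Bonferroni-style without an additional
cross-profile correction. The fit is deterministic given the seed.

The method-of-moments Gumbel is a pragmatic choice: the null score is a
sum of ~60 bounded per-column terms and is therefore close to normal, so
the fitted Gumbel's heavier right tail over-estimates tail probability.
E-values at the 10⁻⁵ operating point are conservative (fewer reported
false positives than nominal), which the null-genome tests confirm.

## Scanning and the two-round search

Genome mode translates every scaffold in all six frames (stops retained,
trailing partial codons dropped) and scores every window of every frame
against every profile in a single batched matrix pass. Each hit is mapped
back to forward-strand nucleotide coordinates through the frame's origin
map, so minus-strand hits carry forward coordinates and strand "−".
Proteome mode scans each protein as a single frame; its loci carry
amino-acid coordinates and a flag distinguishing them from genomic loci.

Hits on one scaffold and strand whose intervals overlap or fall within
max_gap = 5,000 nt merge into one locus (coordinate hull; best window
score per group retained). The gap default is sized to bridge a single
intron of ≤ 2 kb splitting the homeodomain between two partial-window
hits; the synthetic generator's intron option and the scanner's merge are
tested as a pair. With default thresholds a domain split near its centre
can fall below the window significance cutoff — a known limitation of
fixed-length-window scanning, shared with any single-window method.

The search runs two rounds by default. Accepted round-1 hit windows are
added to their matched profile's count matrix at weight 1 each, the
log-odds and calibration are recomputed, and the scan repeats. On genomes
with no round-1 hits the second round is skipped (it would be identical).
Round two widens each profile toward the family actually present in the
genome, helping at higher divergence; it is deterministic given the seed.

## Classification, duplications, complements

A merged locus keeps the best score per group. It is "assigned" to its
best group when the margin over the runner-up exceeds margin_delta = 3
bits, otherwise "ambiguous"; a locus only one group scored has infinite
margin. The margin rule replaces tree-based orthology assignment, which
is outside this package's scope; within HOX6-8 the three subtypes are
classified as separate groups but share a single rank for collinearity.

Duplication multiplicity counts assigned same-group loci whose pairwise
separation exceeds min_separation (default 5 kb, matching the merge gap
so that merging and duplication calls cannot disagree). The complement
table is the species × group count matrix; 0 renders an absence, 2 a
duplication.

## Cluster architecture

A cluster is ≥ min_genes (4) assigned Hox loci on one scaffold whose
coordinate hull is ≤ max_span, boundary inclusive. max_span defaults to
300,000 nt (0.3 Mb). Among all qualifying contiguous windows, the
selection maximises member count, then minimises span, then takes the
leftmost start — a total order, so detection is deterministic; chosen
loci are removed and the remainder re-examined, and each locus joins at
most one cluster. Ambiguous loci are excluded by default. Implementation
is exhaustive window enumeration, which is exact and cheap at realistic
per-scaffold Hox counts (tens at most).

Collinearity: over member pairs with distinct canonical ranks, C counts
pairs whose genomic order (ascending coordinate) agrees with rank order
and D the rest; τ = (C − D)/(C + D), undefined when all ranks tie (the
reversed-cluster value −τ is also reported). Orientation: modal strand by
majority with ties broken to "+", consistency = fraction of members on
the modal strand. The per-scaffold Hox hull (no span constraint) is
reported separately, so dispersed complements like the > 4 Mb C. elegans
arrangement are still summarised.

## Interruptions and miRNAs

Non-Hox interruptions are annotated protein-coding genes (GFF3 kind
"gene", not among the Hox locus ids) overlapping the cluster hull
[first Hox start, last Hox end) by at least one nucleotide. Hull-overlap
is the reproducible operationalisation of "between Hox loci"; genes
straddling a boundary count.

Mature miRNA search is exact k-mer seed (k = 9) on both strands followed
by ungapped extension across the full query, keeping hits with identity
≥ 0.85 and query coverage ≥ 0.9 that overlap the cluster interval;
overlapping placements of one query collapse to the best identity. The
thresholds are set so an exact 22-mer always passes and ≥ 4 substitutions
(18/22 ≈ 0.82) never do. As in any seeded search, a placement sharing no
exact 9-mer with the query is unreachable regardless of its identity;
with ≤ 2 substitutions in a 22-mer an intact seed usually survives, so
the operating behaviour matches a word-size-9 ungapped BLASTN-style
search. Gapped alignment and E-value statistics are deliberately not used
for 22 nt queries.

## Dollo loss mapping

Presence (multiplicity ≥ 1) per group is reconstructed on a rooted
species tree under Dollo parsimony: one gain on the edge above the LCA of
all retaining species, plus the minimal loss set — the maximal all-absent
subtrees within the gain clade — found in one post-order pass.
Polytomies are supported; each all-absent polytomy child is a separate
loss. Minimality among single-gain scenarios is verified in the tests by
exhaustive enumeration on small trees. An optional Fitch mode (gains
allowed anywhere) is exposed for comparison only. Species whose only loci
are ambiguous count as absent; there is no "unknown" leaf state, so
assembly-gap absences are indistinguishable from true losses — a known
limitation.

## Synthetic data

The generator emulates the study substrate: i.i.d. background sequence at
GC 0.42 (nematode-like; no repeats or isochores), homeodomain implants
built from each group's profile consensus mutated at a controlled per-site
amino-acid divergence (uniform over the 19 alternatives), back-translated
(alphabetically first codon by default — codon usage is irrelevant to
amino-acid-space scanning — or seeded-uniform on request), optionally
split by one GT..AG intron, and placed at stated coordinates on either
strand. Decoy genes are composition-preserving shuffles of homeodomain
consensi (destroying positional signal) padded with random non-stop
codons; ~22 nt miRNA implants carry a stated number of substitutions.
Every run emits FASTA + truth GFF3 + a JSON manifest that are mutually
consistent by construction, byte-identical under one seed.

Reference alignments for testing are themselves synthetic: one random
60-residue consensus per group with seeded 5% within-group variation
across 8 rows. Random consensi are far more separable than real
homeodomain groups, which share deep similarity — so passing recovery
tests demonstrates the machinery (coordinates, merging, calibration,
classification bookkeeping) is correct, not that margin-based
classification resolves real mab-5 vs ant-1 boundaries. Real-data use
should start from a curated homeodomain alignment and may need a smaller
margin_delta.

## Problem sizes and determinism

The validation suite uses 1 Mb single-scaffold genomes (ten seeds) for
recovery, twenty 1 Mb null genomes for false-positive control, a
divergence sweep 0–0.4 in 0.05 steps with 20 implants per step on 360 kb
genomes, exhaustive Dollo checks on all presence patterns over sampled
trees of up to 7 leaves, and 100 random 10-leaf gain/loss scenarios.
Every stochastic component takes an explicit seed; identical seeds give
byte-identical outputs end to end.
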