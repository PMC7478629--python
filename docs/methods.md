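# Methods

This note documents the models and procedures behind each stage, the
parameters that matter, the numerical choices, and what the synthetic
fixtures do and do not demonstrate.

## Coordinates and sequence alphabet

All coordinates at package surfaces (inputs, outputs, logs, dataclasses)
are 1-based inclusive, the GenBank/GFF3 convention; half-open arithmetic
exists only inside functions. Sequences are uppercased on load; any
character outside {A,C,G,T} is treated as N, and N never matches anything
in repeat, overlap, or segment detection — draft assemblies contain gap
characters and those must not manufacture evidence.

## Maximal repeat detection

A repeat pair is two equal-length, non-overlapping arms, direct
(same-strand copy) or inverted (arm2 matches the reverse complement of
arm1). Identity is ungapped Hamming identity over the aligned arms. We
deliberately do not model gapped arms: the repeats this tool is built to
recover (TIRs of linear plasmids, integration-boundary DRs, circularity
overlaps) are recent, 99–100% identical copies, and a gapped model adds
parameters without adding recoverable signal.

A pair is *maximal* when extending both arms one base leftward or
rightward — staying inside the sequence and keeping arms disjoint — drops
identity below the threshold. Every direct pair lies on one diagonal
(fixed arm offset) and every inverted pair on one anti-diagonal (fixed
sum of paired coordinates), so the search reduces to finding maximal
above-threshold windows over per-diagonal 0/1 match arrays. Candidate
diagonals come from exact k-mer seeds with k capped by a pigeonhole
bound: an arm of length L with at most m mismatches contains an exact run
of ceil((L−m)/(m+1)) bases, so choosing k at or below the minimum of that
bound over qualifying lengths guarantees every qualifying repeat seeds at
least one candidate diagonal. The search is therefore exhaustive at the
declared thresholds, not heuristic, and the test suite holds it equal to
a brute-force enumeration oracle.

Identity comparisons use exact integer arithmetic (matches·10⁵ ≥
round(identity·10³)·length), so no float tolerance can flip a window.

Determinism and output hygiene: pairs are sorted by length descending
then arm1 start; when two pairs overlap on both arms the longer (then
leftmost) is kept, which collapses the one-base-shifted families that
arise below 100% identity; arm-separation-capped direct windows (arms
about to touch) report their leftmost placement only. Tandem/self-overlap
detection is out of scope.

Defaults: `min_len` 100 for genome-wide scans (the conventional minimum
reported repeat size at this scale), 50 for TIR scans to catch short
termini; `max_offset` 100 bp for how far from the contig ends TIR arms
may sit, because assembly ends are ragged. All are exposed.

## Topology calling

Three independent evidence channels:

1. **Terminal redundancy** — the largest L in [`min_overlap`,
   `max_overlap`] with prefix(L) exactly equal to suffix(L), capped at
   half the contig so the copies are disjoint. Exact match only:
   assembler-duplicated termini are exact, and mismatch tolerance would
   need an alignment model with no principled parameterization here.
2. **Spanning read pairs** — pairs with one mate in the first
   `end_window` bases on the minus strand and the other in the last
   `end_window` bases on the plus strand, i.e. both mates reading
   outward, which is how an insert across the circular junction maps
   after linearization. Mate order in the file is irrelevant.
3. **TIR** — the longest inverted pair pinned to both ends. The default
   TIR scan is at 100% identity: TIRs are near-perfect, and a permissive
   floor would let the maximal window dilute a perfect TIR with flanking
   chance matches (a 145 bp perfect TIR scanned at 90% reports ~160 bp at
   ~90%). Degraded TIRs are still found — as their longest perfect run at
   the default, or exactly when the configurable floor is lowered
   (e.g. 99% recovers a planted 101 bp / 99% TIR at exactly 101 bp,
   because the flanking mismatch pushes any extension below 99%).

Verdict: circular when redundancy ≥ `min_overlap` (20) **or** spanning
pairs ≥ 3; linear when a TIR exists and circular evidence is below
threshold; unresolved otherwise. A TIR alongside above-threshold circular
evidence yields *circular* with the conflict recorded in the evidence
notes — read-pair evidence is physical, and circular molecules can
contain inverted repeats. No published threshold exists for these
quantities; the defaults are liberal (suited to the plasmid-scale contigs
this targets) and all sit in `TopologyParams`.

## ESX locus calling and typing

Locus calling operates on the controlled domain-tag vocabulary, never on
free-text products (a keyword helper can derive tags from products, but
explicit tags always win). Core-tagged genes are clustered by single
linkage along the replicon with a `max_gap` of 6 kb between consecutive
genes; clusters of ≥ 4 core genes become loci. The 6 kb default is sized
from the spacing of described loci and is configurable; the published
criterion is only qualitative ("close to each other").

eccA frequently sits well downstream of the rest of the locus. A lone
distal eccA within `eccA_reach` (20 kb, sized from the ~17 kb case in
described elements) of a called cluster is appended to the nearest such
cluster, marked `-//-` in the signature. The marker is purely display
convention; no fixed distance is implied. No two loci may share a member.

Typing is token-level Levenshtein distance between the locus signature
and a bundled reference table, evaluated in both reading directions
(locus orientation in a contig is arbitrary); nearest wins, ties or
distance > 2 are `untyped` — a truncated core order equidistant from two
references is deliberately not guessed. Duplicate core genes are distinct
tokens; the double eccD is exactly what separates ESX-4-bis from ESX-4.
The bundled table carries the two mobile-element signatures plus
canonical chromosomal ESX-1/ESX-3/ESX-4 orders from the T7SS literature,
and is a plain dict users can extend.

## Element profile and classification

Each backbone flag is true iff ≥ 1 feature carries the corresponding tag.
`t7ss` is true iff ESX loci were called (never from tags alone);
`trna_genes` counts tRNA features; the toxin–antitoxin flag requires a
Toxin- and an Antitoxin-tagged feature with at most one intervening gene
— an adjacency heuristic, explicitly weaker than dedicated TA finders,
and flagged as such in the report notes.

The cascade (first match wins):

1. `putative_ICE` — relaxase ∧ (virB4 ∨ virD4) ∧ (integrase ∨
   transposase) ∧ ¬repA
2. `conjugative_plasmid` — (repA ∨ helicase) ∧ relaxase ∧ (virB4 ∨ virD4)
3. `cryptic_plasmid` — (repA ∨ helicase) ∧ ¬relaxase
4. `unclassified`

A DnaB-like replicative helicase is accepted as the replication marker
for repA-less plasmids. One consequence is deliberate: a replicon with
VirB4 but no relaxase has T4SS-like machinery and no mobilization
function, lands in `cryptic_plasmid`, and the report notes the
incomplete conjugation module rather than promoting it. There is no
quantitative published boundary between an ICE and an integrated
conjugative-plasmid remnant; this cascade is our operationalization and
is a pure function of the flag vector.

Integrated-region calls: one per direct repeat pair at ≥ 99% identity
whose inter-arm region (inner edge to inner edge, never into the arms)
contains ≥ 1 CDS; the nearest transposase/IS-tagged feature within 1 kb
of either arm is attached ("adjacent" is not quantified in the
literature; 1 kb is our recorded choice).

## Shared segments

Exact k-mer anchors (k = 21, both strands of B) are clustered into
near-diagonal chains (diagonal band 200 bp absorbing indel drift, anchor
gaps ≤ 2 kb), continued across chain breaks when collinear. Chain edges
stop at the outermost exact anchors, which under-reaches diverged ends,
so both ends are extended by ungapped X-drop (match +1, mismatch −3,
drop 30): inside homology the score climbs, in background it collapses
within a few bases, so edges land within a handful of bases of the true
boundary. Each chain's identity is then computed by a global edlib
alignment over the chained spans — library-backed and indel-robust,
which we prefer over summing anchor coverage. Chains overlapping in A are
resolved greedily by anchor score, so reported segments are
non-overlapping in A and "coverage of A" is well defined; B-side
intervals are merged before B coverage. Sized for 80–100% nucleotide
identity (homologous plasmid/ICE backbones); this is not a remote-
homology or protein-level comparator.

## Synthetic data

The generator is the package's study-condition bench: PCG64 (numpy),
integer seeds, byte-identical output per seed on any platform.
Backgrounds are composition-exact (GC within rounding of the target) and
rejection-sampled so that no repeat ≥ 50 bp at 100% identity exists
outside the planted coordinates; the verification scan runs for fixtures
up to 50 kb (beyond that the chance of a spurious 50 bp exact repeat is
negligible and the scan cost is not). Planted repeat arms get their
flanking bases adjusted so the planted pair is exactly maximal — without
this, one-in-four chance flank matches would extend a planted 145 bp TIR
to 146 and planted-truth recovery would be flaky. Degraded arms receive
an exact substitution count (round(L·(1−id/100))), and the truth records
the resulting exact identity, so tests compare against bookkeeping, not
expectation.

Planted architectures mirror the elements this tool targets: a 21.6 kb
cryptic linear plasmid with a 489 bp perfect TIR; a 101 bp / 99% internal
inverted-repeat pair flanking a tRNA array with transposases at the
flanks inside a larger linear plasmid; circular plasmids with a 77 bp
duplicated terminus and 30 outward-oriented spanning mate pairs (5%
mispairing noise available); a ~100 kb ICE with a 167 bp DR pair around a
40 kb ESX-4-bis cargo (IS transposase 200 bp outside one arm), a second
648 bp DR pair bracketing the conjugation module, both described ESX
gene orders with the distal eccA 17 kb downstream, and the
relaxase/VirD4/VirB4/TcpC/helicase/TA/transposase backbone. Gene models
are simple (1.2–1.4 kb CDS on the plus strand with fixed spacing) and
annotations are synthesized directly with domain tags, so no gene caller
sits in the test loop.

What passing on these fixtures does **not** show: robustness to
annotation noise (mis-tagged or missed genes), gapped/degenerate repeat
arms, assembly chimerism, real read-mapping artifacts beyond the
abstracted mispairing model, or compositional heterogeneity (fixtures
are i.i.d. backgrounds at a fixed GC). The deposited-record tests exist
precisely to anchor the same code against real sequences when the
records are available locally.

## Problem sizes in the shipped suites

The default test and acceptance runs use fixtures between 3 kb and
100 kb, oracle comparisons on ~420 bp sequences (the brute-force oracle
is cubic-ish and exact), 50 + 50 replicons for the clean topology sweep,
and 20 seeds for the noisy-recall measurement; the sharing benchmark
plants 28 kb of a 40 kb element (70%) at 90% identity in a 96 kb
partner. These sizes exercise every code path at full fidelity while
keeping the whole suite in the minutes range on one core.

## Known limitations

* Repeat arms are ungapped; an indel inside a repeat splits it into two
  reported pairs rather than one gapped pair.
* Low-complexity sequence can inflate the seed candidate set (quadratic
  in per-k-mer occurrences); fine for the intended inputs, unguarded for
  pathological ones.
* The TA call is keyword/tag adjacency only.
* Read-pair evidence arrives as a documented TSV; SAM/BAM conversion is
  the user's one-liner, not ours.
* Typing knows only the bundled signature table; novel locus orders come
  out `untyped` by design.
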