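# Methods

This note documents the models and procedures implemented in `its2delim`,
the parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## ITS2 excision and the B9 stem

Boundaries are found by scanning position-weight profiles of the conserved
3' tail of the 5.8S gene and 5' head of the 28S gene within a window
(`search_window`, default 60 nt) from each end of the amplicon, accepting
hits with at most `max_mismatch` (default 3) mismatches to the profile
consensus.  The shipped profiles are plain-majority approximations of the
Viridiplantae flank consensus written for this package — they are *not* the
profile HMMs used by the ITS2 database annotation tool, and should be
overridden for taxa with divergent flanks.  Among equal-scoring hits the
combination maximising the reconstructed B9 stem is preferred, then the
5'-most; this reflects the biological requirement that the true boundaries
leave the 5.8S/28S hybridisation stem intact.

B9 reconstruction hybridises the two flanks antiparallel and reports the
longest contiguous duplex (Watson–Crick + G·U wobble).  Runs shorter than
2 bp are rejected (warning, length 0).

## Folding model

Structures are predicted by weighted base-pair maximisation over nested
structures: pair weights GC=3, AU=2, GU=1, minimum hairpin loop 3 nt, and by
default a no-lonely-pair rule (every helix run ≥ 2 directly stacked pairs),
implemented exactly via a stacked-run recursion:

    W(i,j) = max( W(i+1,j), max_k H(i,k) + W(k+1,j) )
    H(i,j) = max_{L≥2} [ Σ_{t<L} s(i+t, j-t) ] + W(i+L, j-L)

This is a deliberate substitution for a thermodynamic model.  The design
rationale: downstream analysis never trusts the single best fold — the
biologically meaningful structure is chosen among near-optimal candidates by
hallmark content and cross-strain comparison, so the scoring model only has
to keep the annotated topology within reach, and a pair-maximisation model
is exactly testable (the DP is verified against brute-force enumeration over
all valid pair sets for every random sequence up to 16 nt; the enumeration
oracle applies the same loop and lonely-pair rules).  Temperature is not
modeled.  IUPAC ambiguity codes are never paired.  A hook to an external
thermodynamic folder (`fold_external`, e.g. RNAfold) exists but nothing
requires it.

Determinism: traceback prefers pairing the left end with its smallest
admissible partner, and pairing over leaving it unpaired when co-optimal.
Suboptimal enumeration is best-first over an admissible bound (partial score
plus DP optima of unexpanded intervals), so candidates emerge in
non-increasing score order; output is deduplicated, sorted (score
descending, then lexicographic dot-bracket) and capped at `max_candidates`.
Note one falsifiable-looking symmetry does *not* hold in this model:
folding scores are invariant under reverse complement only when wobble
pairs are excluded, since G·U maps to C·A.

## Hallmarks and structure assignment

Helix segmentation groups stacked pairs across internal loops of at most
`bulge_tol` (default 2) unpaired nt per side, so the helix II
pyrimidine-mismatch does not split the helix.  The four longest root-level
segments are labelled I–IV in 5'→3' order; when the helix III multiloop
contains more than one child stem, the shortest child is the lateral helix
IIIa.  Hallmark checks: a 1×1 pyrimidine×pyrimidine internal loop in helix
II (reported with its actual bases, e.g. U×U or C×U); the first YRRY window
on the 5' side of helix III (e.g. UGGU, UAAU); spacer lengths I–II and
II–III against configured expectations (defaults 4 and 5 nt, overridable —
the conserved first-two-base-pair identities per helix are recorded but not
asserted, and the AGG motif at the helix IV base is checked but never
scored).  The aggregate score is 4·(four helices) + 2·(Y–Y) + 2·(YRRY) +
1 per correct spacer; weights are configuration, with topology dominant by
default.

Per-dataset structure assignment works the way ITS2 structures are curated
in practice: every sequence is folded; the sequence whose optimal fold shows
the fullest hallmark content anchors the dataset (among hallmark-ties, the
anchor is the one whose structure transfers best onto everyone else,
measured by retained pairs and hallmark content of the transferred
structures); the anchor structure is then mapped onto each sequence by
homology transfer — align, copy every pair whose residues still legally
pair, drop pairs violating the hairpin minimum, prune lonely pairs.  A
sequence falls back to its own optimal fold only if transfer loses hallmark
content.  This cross-strain step is what suppresses the idiosyncratic
rearrangements that single point mutations induce in single-sequence
pair-maximisation folding; without it, per-strain structure recovery on the
synthetic benchmark drops from ~97% to ~60%.

## Sequence+structure alignment

Residues are encoded over a 12-letter alphabet (4 bases × unpaired/
opening/closing).  Substitution score: +2 base match, −1 base mismatch,
further −1 if the pairing states differ; affine gaps −3/−1.  Pairwise
alignment is Gotoh three-state DP with deterministic traceback (diagonal,
then up, then left).  The MSA is progressive: guide tree from neighbor
joining on p-distances of pairwise sequence-only alignments (structure
penalty zero), profile–profile merges along the tree with column scores
`P₁ S P₂ᵀ`.  Columns are never re-folded after alignment; structures are
fixed inputs (fold-then-align).  A user-supplied Newick guide tree is
accepted; unknown leaves are an error.

## Conserved pairs and CBC counting

CBC counting is phenetic (direct pairwise comparison, no ancestral-state
reconstruction).  The "conserved regions of helices I–III" are
operationalised as alignment column pairs that (a) are paired identically in
≥ `min_frac` (default 0.9) of rows, (b) pass a base-conservation filter at
`conservation` (default 0.7) on both columns, and (c) carry a majority helix
label in {I, II, III} (helix IV and IIIa are excluded by convention).  When
a lineage grouping is available the conservation criterion is applied
*within each lineage* — this is the convention of lineage-level consensus
structures, and it is essential: a position that diagnostically separates
two lineages is ~50% conserved globally yet 100% conserved within each
lineage.  Crossing column pairs are resolved by support then 5' position;
surviving pairs are numbered 1..K in 5'→3' order.  These bp IDs are this
package's own numbering of its own alignment and are not expected to
coincide with any external numbering.

Classification at a pair of columns: gaps/ambiguity → not comparable
(excluded from counts); two valid pairs differing on both sides → CBC, one
side → hCBC; otherwise non-CBC.  Clade-level matrix cells compare
majority-consensus rows per clade.  Lineage-diagnostic positions are those
where every member of one group differs from every member of the other by a
CBC.

## Distances and trees

p-distances use complete deletion by default (all columns containing any
gap or ambiguity removed once, globally) to match the convention under
which the comparison numbers in this literature are computed; pairwise
deletion is available behind a flag with a warning.  Between-group distance
is the unweighted mean over cross pairs; the maximum is also exposed because
"divergence as high as X%" statements refer to it.  Neighbor joining is
standard, with Q-criterion ties broken on the lowest taxon-index pair and
negative branch lengths clamped to zero; it exists as alignment
infrastructure (guide trees) and a convenience output, not as a phylogeny
engine — an independent implementation (scikit-bio) is used as a
cross-check in the test suite.

## Delimitation rule

`distinct` iff ≥ 1 CBC; `same` only for identical ITS2 (zero distance, no
hCBC); everything else `not-separable-by-CBC` with hCBC counts and
distances reported as notes.  No distance threshold is applied to call
species: the evidence model is CBC presence, and distances corroborate.

## Synthetic benchmark: what it emulates, and what it does not

`make_template` builds a consensus ITS2 with helices I (9 bp), II (9 bp
with a planted U×U mismatch after the 4th pair), III (5 bp basal + 7 bp
distal whose 5' arm begins UGGU, with a 3 bp lateral IIIa), IV (6 bp),
spacers I–II = 4 nt and II–III = 5 nt, flanks hybridising into an 8 bp B9
stem.  Stems are sampled from G/C pairs (the basal helix III arm resampled
so no spurious YRRY window precedes the planted box) and unpaired regions
are poly-A.  `simulate` derives 2 lineages × 3 clades × 4 strains (all
configurable): three lineage-level CBCs in helices II/III (one in II, two
in the distal III stem), clade-level hCBCs in helix I, strain-level wobble
toggles in stems (rate 0.02 per pair) and free point mutations in loops
(rate 0.02 per site), clade-level ±2 nt length variation in the apical
regions, a 7–9 nt poly-A insertion 3' of helix III carried by lineage B
only (length drawn per clade), and one flank substitution per strain
outside the B9 octamer.  RNG streams are keyed by (seed, lineage, clade,
strain), so adding strains never changes existing ones; every edit is
recorded in a ledger whose replay reproduces each strain exactly.

The idealisations are deliberate and worth stating: G/C-dominated stems and
poly-A loops make the planted topology the unambiguous folding optimum,
mutation rates are uniform and small, indels are confined to declared
variable regions, and there is no rate heterogeneity, recombination or
intragenomic ITS variation.  Passing the benchmark therefore demonstrates
that the *machinery* — excision, structure assignment, alignment, CBC
classification, distance and delimitation logic — is correct and recovers
planted signal through the entire pipe; it does not demonstrate that a
thermodynamic folder would recover the right structure for an arbitrary
real ITS2, nor that real alignments are unambiguous.  On real data the
structure-assignment and alignment stages are the ones expected to need
expert attention, which is why curated structures (Vienna files) and
curated alignments can be supplied to the pipeline in place of the
automatic stages, and why the folder exposes near-optimal candidates rather
than a single answer.

Within the benchmark, mutation noise still produces the natural analogues
of real-data exceptions (e.g. an occasional strain whose Y–Y mismatch reads
C×U rather than U×U because a loop mutation hit the unpaired site), which
is why feature frequencies in the acceptance outputs are a few percent
below 100 rather than exact.

## Problem sizes and tolerances

Default validation runs use ITS2 sequences of ~130–150 nt, 24 strains per
dataset, 20 replicate datasets, 500 random sequences (≤ 16 nt) for the
folding oracle, and 15–20 random additive trees (6–10 taxa) for NJ — sizes
chosen so the full suite exercises every code path in well under a minute
of compute while keeping the brute-force oracles exhaustive.  Exactness is
asserted wherever an oracle exists (folding scores, truth table, NJ path
lengths to 1e-6, ledger replay byte-exact); statistical assertions
(planted-change recovery ≥ 19/20 seeds, hallmark frequencies ≥ 0.9,
alignment column recovery ≥ 0.98 outside homopolymer runs) use thresholds
stated next to the test.
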