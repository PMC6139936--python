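# Methods

This note records the models behind each stage, the defaults and why
they were chosen, and what the synthetic benchmark does and does not
establish about real data.

## Reference-anchored alignment

Every element is aligned independently to a reference consensus with
Biopython's `PairwiseAligner` (global mode, free end gaps on both
sequences), replacing a joint multiple alignment. Scoring defaults are
match +1, mismatch −2, gap open −6, gap extend −1 (a gap of length L
costs 6 + (L−1)); copies within a retrotransposon family are typically
>90% identical to their consensus, so any standard affine scheme
recovers the same variants, and the values are exposed in
`ScoringParams`. Reference positions outside the aligned span are
*missing* (never deleted), internal gaps in the element are deletion
calls, and N/IUPAC bases are missing so that ambiguity can never create
a diagnostic. An element is *unalignable* when alignment identity falls
below 0.6 or when fewer than 30% of its bases are aligned — the second
condition matters because an overlap alignment of two unrelated
sequences degenerates to a short high-identity sliver; the reverse
complement is tried whenever the forward orientation fails these
checks. Elements covering less than half of the reference are excluded
from sorting (boundary inclusive: exactly half is kept).

Two caveats follow from alignment theory rather than implementation: the
in-alignment position of a deletion is ambiguous when its flanks are
locally repetitive (the deleted *sequence* is not), so deletion events
are compared by decoded sequence where exactness matters; and a 20 bp
deletion is only recovered as such when the element anchors the
reference on both sides with more aligned positions than the gap
penalty — true for real SVA copies, not for toy sequences a few dozen
bases long.

## Subfamily sorting

Sorting operates on a call matrix (elements × reference positions with
states A/C/G/T/deleted/missing) restricted to a window — by default the
SINE-R domain, the region classically used for SVA subfamily
definition. The restriction is not cosmetic: 5' structural variation
(truncation, VNTR length turnover, captured exon blocks that partially
glue onto the reference during alignment) otherwise leaks shared
artifacts into the candidate variants.

The greedy step finds the variant pair with the largest joint carrier
set (exact for the ≥2-shared criterion, since adding variants only
shrinks carrier sets), extends it with every variant strictly carried by
the same carriers, and forms a subfamily when membership reaches
`min_members` (default 10; a signature whitelist exempts named groups).
Nested subfamilies need only one additional diagnostic, root-level
groups two. A subfamily's consensus is its parent consensus with the
diagnostics applied, which guarantees the invariant that consensus and
parent differ exactly at the diagnostic positions; the independent
majority-rule builder (`build_consensus`, ties to the parent state,
deletion as a votable state) is used for reporting and cross-checking.
Membership tolerates missing data — all covered diagnostics must match
and at least min(2, n) be covered — mirroring how truncated elements are
handled in manual sorting. Deletion events count as single diagnostics
(the 20 bp SINE-R and 11 bp Alu-like hallmark deletions are
subfamily-defining); insertions are recorded but excluded by default,
and when enabled enter as exact (anchor, sequence) characters that
cannot be expressed in a consensus vector. Ties break on (carrier
count, variant count, lowest positions), making the tree a pure function
of its inputs.

`sequentiality_check` flags any parent→child edge whose child consensus
restores the root-reference state at a position where the parent was
already derived — the back-mutation signature that disqualifies a
claimed ancestry under the source-element model.
`cosegregation_scan` partitions variants shared by ≥2 consensuses into
groups with identical carrier sets, which is how hallmark co-segregating
substitution pairs are found.

## Median-joining networks

`condense_characters` keeps variable columns, merges identical columns
with summed weight, collapses identical sequences, and treats the gap as
a fifth state. `median_joining` iterates: build the ε-relaxed minimum
spanning network (an edge enters iff its weight is within ε of the
minimax path weight between its endpoints; ε = 0 gives the union of all
minimum spanning trees); generate quasi-median vectors from each
network link plus a third node (per-column majority where one exists,
otherwise all combinations of observed states, capped at three
unresolved columns); add the candidate vectors that most reduce the
spanning cost of the node set (all ties at once — tied medians act as
mutual stepping stones); when no single candidate reduces the cost,
purge obsolete medians and retry, then attempt a bounded two-median
lookahead; stop at the fixed point. The purge keeps the median subset
minimizing spanning cost — exactly (subset enumeration) up to 12
medians, by steepest-descent elimination beyond. A hard cap of 10,000
median vectors fails loudly. The pure "generate the full quasi-median
closure" variant is exponential on incompatible data and was rejected;
the cost-reduction criterion keeps the node set near-minimal at every
step. On compatible binary characters the output is the perfect
phylogeny; on small binary instances its cost matches exhaustive
minimum-Steiner-tree enumeration (both verified against brute-force
oracles in the test suite).

`mp_postprocess` enumerates median subsets (guarded at 16) and keeps
exactly the links and median vectors lying on at least one
minimum-length tree spanning the sampled haplotypes; sampled nodes are
never removed and the spanning length is unchanged. `root_network` marks
the node carrying the outgroup label and annotates weighted distances
and link orientations toward the root without touching the topology.

## Orthology from flanks

Whether two species share an insertion is decided from 50 nt flanks
(k-mer seeded, k = 16): a cross-species pair matches when both flanks
align at ≥90% identity and each locus is the other's unique best hit in
that species (reciprocal best hit, ambiguity flagged as unresolvable
rather than guessed). The signed insertion-point offset is read from
the junction-side end of the 5'-flank alignment; clusters are the
transitive closure of offset-0 matches, so loci displaced by a single
nucleotide are reported as *distinct* integration sites — the
discriminating observation in the master-element question. The offset
tolerance is configurable but defaults to 0. TSD sequence is
deliberately not required to match across species: the two copies mutate
independently after insertion. Presence histories follow a Dollo-style
rule on the fixed tree ((hs, pt), gg): presence spanning the root means
an ancestral hominine insertion, absence below such a gain is loss or
incomplete lineage sorting in that lineage, single-species presence is
lineage-specific.

Identical flanks in a homopolymer-rich context would make a 1-nt offset
undetectable in principle; the simulator's decoy loci use random flank
frames where the shift is unambiguous, so the decoy-splitting results
bound the pipeline's behavior on informative flanks only.

## TSD forensics

`extract_tsd` takes the longest suffix of the 5' flank matching a
prefix of the 3' flank within a mismatch budget (default lengths 5–30,
≤1 mismatch; ties to longer, then cleaner). `compare_tsd` is
end-gap-tolerant: a terminal length difference (the human TSD is one nt
shorter than the inferred ancestral site) is reported separately and the
terminal-gap placement minimizing substitutions is chosen, so a
length-15 vs length-16 comparison can still report a single internal
mutation. A single extra base inside a homopolymer run is flagged as
replication slippage rather than aligned as substitutions. Positions
are 1-based from the TSD 5' end. `detect_untemplated_g` counts leading
element G's not accounted for by trailing G's of the resolved target
site (undetermined when the TSD is unresolved) — the RNA-cap signature.
`a_tract_distance` reports the distance from the 3' end of the nearest
upstream A-tract (≥6 A's, 3' end within a 50 nt window) to the
insertion point, 0 meaning directly adjacent.

## Exon capture

Domains are annotated by local alignment of Alu-like and SINE-R
consensuses (identity ≥0.6; the SINE-R hit must cover ≥40% of its
reference, the Alu-like hit ≥25%, which suppresses random short local
hits), hexamers as ≥2 tandem TCTCCC-like units (≤1 mismatch each), the
VNTR as the region between Alu-like and SINE-R, polyA as the first A-run
3' of the SINE-R. No SINE-R hit means the sequence is not called an
SVA. A 5' block of ≥30 nt upstream of the first recognizable domain
anchor that fails to align to the canonical 5' sequence (hexamers +
Alu-like + VNTR) is flagged foreign. Donor attribution requires the
block's 3' end to coincide with a library exon's 3' end within ±2 nt
(the splice criterion; exact junction bases are not demanded because the
acceptor cannot generally be reconstructed from the consensus). Because
local domain hits place the junction only approximately, the block is
padded by 25 nt before donor alignment and the exon-end criterion pins
the boundary. Acquired length is the matched exon suffix; segment
sequence 5' of the exon match is reported as an additional upstream
transduction; equally scoring donors yield an ambiguous call; a CATG
tetranucleotide near the 5' end is reported as an observation, never
used as a criterion. Length histograms deduplicate identical acquired
lengths. One ambiguity is irreducible: an untemplated cap G immediately
5' of a captured exon suffix is indistinguishable from one more exonic
base when that base is G; the simulator's truth table records both
acceptable lengths for such copies.

## The simulator

`simulate_expansion` is a forward simulation on the fixed hominine tree.
Source lineages are a plan of (name, parent, branch, copy count,
diagnostics, optional hallmark deletion, age, optional capture); each
source inherits its parent's variants and adds its own at unused
positions inside the SINE-R window (sequential acquisition, no
reversion, one position per event simulation-wide). Copies carry
Poisson(age × rate × length) random substitutions; ages are relative
units, so divergence per copy is age × rate. The default plan has 15
lineages with 30–200 copies each, ages 1–4 at rate 0.005/site/unit
(0.5–2% divergence), 20% of canonical copies 5'-truncated to keep
55–95% of their length, TSDs of 8–16 nt drawn A-rich and duplicated
exactly at insertion (the two copies then mutate independently with
age), an A-tract planted 0–2 nt upstream of the target site, a 30%
untemplated-G probability, 10% per-lineage loss of pre-split insertions
(the incomplete-lineage-sorting proxy), five 1-nt-offset decoy locus
pairs, and two capture lineages (donor exons GC-rich, acquired lengths
80–250 nt). The structured reference is an SVA-like composite
(4 hexamer units, 250 nt Alu-like, 5×37 nt VNTR, 400 nt SINE-R, 15 nt
polyA; ~874 nt total). A single master seed feeds named substreams
(sequence, diagnostics, mutation, placement, truncation, loss) so stages
can be varied independently; identical configs give byte-identical
output.

What the simulator does *not* emulate: genome-scale flank context and
segmental duplication (flanks are unique by construction, so orthology
accuracy here is an upper bound), CpG hypermutability (not modeled by
default), VNTR subunit evolution, selection, and calibrated ages in
years. Passing the benchmark therefore shows the algorithms implement
the source-element model correctly, not that real-genome accuracy will
match these numbers.

`hallmark_consensus_set` is a synthetic stand-in for a published
consensus alignment set: randomly generated sequences constructed to
carry the documented relationships (DR = D1 + 3 substitutions, D2 = D1
with a 20 bp deletion, four subfamilies sharing co-segregating
substitutions at positions 228→A and 242→G relative to DR, each with a
private diagnostic). It tests the forensic operations, not the
published sequences themselves.

## Scoring and benchmark sizes

Partition recovery is scored by the adjusted Rand index
(scikit-learn's implementation, cross-checked against a permutation
null) over elements passing the coverage filter, plus per-lineage
precision/recall against the best-overlapping cluster; consensus
recovery compares decoded sequences over the sorting window. Presence
calls count a planted locus as correct only when all and only its
species instances form one cluster. The default benchmark sizes — one
~1,500-element simulation per noise condition, 100 random compatible
matrices (≤12 taxa, ≤20 characters), 40 random binary haplotype sets
(≤5 sequences, ≤8 characters) against exact Steiner enumeration
(Dreyfus–Wagner), 20 multistate sets for the spanning-structure bound —
keep a full run of the suite and of `scripts/acceptance.py` to a few
minutes while the properties they probe are size-independent.

## Known limitations

- The sorting is greedy; pathological variant configurations could in
  principle mask a subfamily behind a larger overlapping carrier set.
  Under the source-element model (nested carrier sets) the greedy choice
  is exact.
- Strict membership (all covered diagnostics must match) places copies
  with a chance hit at a diagnostic position one level too high; at 2%
  divergence this costs a few percent of assignments, which is the gap
  between the observed ARI (~0.91–0.93) and 1.
- Median-joining with cost-reduction additions is still a heuristic for
  the NP-hard Steiner problem; optimality is verified only at the tested
  sizes. Parsimony post-processing is exact but exponential in the
  median count (guarded at 16).
- `assign_exon_source` assumes the donor library contains the true exon;
  it reports the best-scoring library hit or none.
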