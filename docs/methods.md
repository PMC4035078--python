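# Methods

## Scope and data model

The package analyses gene-order rearrangement on circular mitochondrial
genomes at the level of annotated elements: genes (tRNA, rRNA,
protein-coding), control regions (CR), and noncoding remnants. No
nucleotide sequences are consumed or produced; sequence-level quantities
(feature coordinates, spacer lengths) live in the annotation layer only.

Elements are identified by `(label, copy_tag)`. The vocabulary follows
compact mitochondrial naming (`trnF`, `rrnS`, `ND1`, `COI`, `CR`, `NC`),
with serine/leucine paralogs resolved by anticodon: `trnL1` = Leu(TAA),
`trnL2` = Leu(TAG), `trnS1` = Ser(TGA), `trnS2` = Ser(GCT). This is the
convention of the *S. latus* annotation; cross-species imports must map
anticodons, not one-letter names, because the S1/S2 convention varies
across the literature. The typical vertebrate order is numbered
1 (*trnF*) … 38 (CR) and that number is carried as an element's
*ancestral index*.

Circular orders compare equal under rotation; the canonical rotation
starts at `trnF` when present, else at the lexicographically smallest
identity. Internally indexing is 0-based; all user-facing coordinates are
1-based, matching annotation-table conventions.

## The DRRL model as implemented

A DRRL event is parameterized by an insertion edge, a loss assignment, and
three CR fates.

**Duplication–translocation** copies a contiguous segment and inserts the
copy (tagged `'`) at an adjacency outside the segment. The mechanism of
this initial duplication is deliberately left open — it is modelled as a
primitive, not attributed to TDRL or recombination.

**Double replication** requires exactly two CRs. Replication direction is
fixed as the forward direction of the order from CRI: the elements
strictly between CRI and CRII are duplicated, giving
`upstream + CRI + block₁ + CRII + block₂ + CRIII`, where CRIII, a copy of
CRI, arises at the distal end of the second copy. This placement is the
only one that puts CRIII's remnant at the typical CR position of the
genome (between the block's last gene and the upstream run), which is
where the observed NC fragment sits in *S. latus*. The strand-replacement
narrative of the underlying replication mechanism is treated as mechanism
prose: the simulator operates on element orders, not strands of nascent
DNA, and no replication-fork kinetics are modelled.

**Random loss** resolves each duplicated pair to one survivor —
independently fair per gene by default (seeded), or by explicit
assignment. CR fates: `functional` keeps a CR element; `remnant`
degenerates CRII into a CR-remnant element between the survivor runs and
CRIII into an `NC` element; `lost` removes the CR. Remnant elements carry
no length — the observed lengths of such residues (e.g. an 86-bp spacer,
a 376-bp NC) are annotation-layer data, not simulated. At least one CR
must stay functional. DRRL and TDRL never invert strands.

## Inference

One-step derivability reduces to a permutation property: for a candidate
insertion edge, the duplicated block is the run of genes from the edge
forward to the CR, and the observed arrangement of those genes must be a
concatenation of two subsequences each strictly increasing in ancestral
rank. The arrangement's *descents* decide everything: two or more descents
— no explanation; exactly one — a unique split; none — every split is
valid and all are reported (explanation multiplicity is never collapsed;
the single-descent case of *S. latus* is unambiguous). The split
reconstructs the loss assignment.

Candidate edges are enumerated over the whole ancestral circle. When the
upstream (single-copy) run is non-empty it anchors the circular alignment
between ancestral and observed; with an empty upstream every rotation of
the observed circle is tried and duplicate explanations are removed by
their `(edge, survivor-set)` key. Output order is deterministic.

**Remnant support.** An event with the functional/remnant/remnant fate
pattern predicts CR-derived elements at three junctions: the functional
CRI ahead of the first survivor run, the CRII residue between the runs,
and the CRIII residue at the typical CR position. An explanation has full
remnant support when observed CR/remnant elements occupy every predicted
junction (positional matching only — lengths are annotation data). Because
residues erode — in *S. latus* the CRII residue survives only as an 86-bp
spacer, below the element scale — explanations also carry a
`remnant_matches` count so partially supported explanations can be ranked.
`require_remnants` defaults to off: the observed remnants are treated as
corroborating rather than required evidence. Events whose block would wrap
past the original CR are not representable and hence never inferred.

**Recent-duplication reduction.** Labels present twice (e.g. CR/CR',
trnC/trnC') betray a very recent duplication–translocation. Each maximal
repeated segment yields two reductions (remove either copy, untag the
survivor); the caller scores them by downstream derivability. For
*S. latus* exactly one reduction — removing CR2-trnC'-trnY' — is one-step
derivable, which is what identifies CR1-trnC-trnY as the original template
and the other fragment as the translocated copy.

**Oracle.** `brute_force_explanations` exhaustively replays every
insertion edge and every `2^block` loss assignment through the forward
simulator and keeps the parameter sets whose replay matches. It shares no
code path with the descent-based enumeration and serves as the independent
reference in tests: the two agree on every arrangement of circles of up to
6 genes (exhaustive over permutations, reachable or not) and on 200 seeded
random cases with blocks up to 10 genes.

**Block-membership convention.** The block is defined as all genes
strictly between CRI and CRII, so in the *S. latus* reconstruction *trnP*
(37) belongs to the block and the raw survivor clusters are 11 and 18.
Because *trnP* occupies the block's distal end in both the ancestral and
the observed order, it is also reported separately: cluster sizes
"excluding trailing genes in typical position" are 11 and 17, with *trnP*
flagged. Both readings are exposed (`cluster_sizes()` and
`cluster_sizes(exclude_trailing=True)`).

## Annotation statistics

Coordinates are 1-based inclusive; the spacer between consecutive features
is `next.start − prev.end − 1`, computed circularly for the last→first
pair — the only convention that reproduces a standard mitogenome
organization table's intergenic column, including negative values for
overlaps. The genome length is the last feature's end. When a table
carries a printed intergenic column it is cross-checked against the
recomputation; on mismatch a warning is raised and the recomputed value
wins. The count of "intergenic regions" is the number of strictly positive
spacers anywhere on the circle (a zero-length wrap is reported but not
counted). Thresholds are parameters with defaults of 50 bp for long
spacers and 300 bp for large noncoding regions. CR and NC rows participate
in spacer computation as ordinary features. Origin-spanning features are
not supported (none occur in the packaged data).

The packaged fixture transcribes the *S. latus* genome-organization table:
42 features (24 tRNA, 2 rRNA, 13 CDS, 2 CR, 1 NC) over 18,706 bp, with
anticodons, start/stop codons and the printed intergenic column. The two
CR copies are printed as 893 and 899 bp; the package records both numbers
and asserts nothing about their equality, since the discrepancy cannot be
resolved at the annotation level. One printed start codon (COI) did not
survive transcription of the source table legibly and is left blank;
codon columns are pass-through data with no effect on any statistic.

## Residue consistency

The reconstruction exposes the set of *residue-marked adjacencies*:
junctions where the event chain deleted at least one gene copy or left a
CR-derived residue. Marks propagate through the final
duplication–translocation (an insertion into a marked junction leaves both
new junctions marked, since the residue sequence is split, not removed)
and through the erosion of the CRII remnant (its neighbours inherit the
mark). The package verifies that every spacer over 50 bp in the observed
annotation lies on a marked adjacency — consistent with long intergenic
regions being decay products of lost duplicates. The converse is not
asserted: a marked adjacency may have eroded to nothing.

## Synthetic cases and what tests show

`random_drrl_case` draws the insertion edge uniformly over the ancestral
circle, the surviving copy of each gene as an independent fair coin (the
loss model of the simulator's default), and fixes the CR fates to
functional/remnant/remnant — the fate pattern of the *S. latus* chain,
which leaves maximal evidence. Ancestral toys use generic labels with
seeded random strands and arrangement. All generators are pure functions
of their seed; there is no global RNG state.

Synthetic annotations draw feature lengths from bounded uniform ranges per
element class (tRNA 65–75 bp, rRNA 900–1750, CDS 160–1900, CR 800–950,
remnant 80–400 — spanning the ranges seen in fish mitogenomes) and spacers
from a bounded model with a parameterized overlap probability; explicit
spacer lists are accepted for designed cases. Overlaps are clamped so
starts remain strictly increasing.

Passing round-trip tests therefore show that the inference recovers events
*whose remnants are still visible as elements*. Real genomes differ in
ways the generator does not emulate: residues erode (handled by the
`remnant_matches` ranking, exercised by the *S. latus* case itself),
multiple successive events may overprint each other (out of scope — no
multi-event search), and annotation noise may misplace boundaries.

## Problem sizes and numerical choices

Exhaustive oracle comparisons run on circles of up to 6 genes (all
permutations) and 200 seeded random cases with blocks up to 10 genes —
sizes at which the `edges × 2^block` replay stays exact and fast; the
descent-based enumeration itself is polynomial and handles the 37-gene
vertebrate circle directly. Round-trip recovery uses 1,000 seeded cases of
3–16 genes. All computations are integer/combinatorial; there are no
numerical tolerances. Ties in canonical rotation are broken
lexicographically; explanation lists are sorted by (edge, split) and
deduplicated by survivor set.

## Known limitations

- Single-event inference only: no minimum-event distances, no multi-event
  search, no phylogenetic placement, and no probabilistic choice between
  DRRL and TDRL when both fit.
- No inversions, recombination, non-random-loss, or miss-priming models;
  inversion-bearing inputs are detected and rejected with a diagnostic
  rather than explained.
- Remnant evidence is positional, not length-based; two remnants in one
  junction are counted, not distinguished.
- Annotation arithmetic assumes features do not span the origin.
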