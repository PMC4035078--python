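# drrl — mitogenome rearrangement under Double Replications and Random Loss

`drrl` is a Python toolkit for analysing genome-scale gene-order
rearrangements in circular mitochondrial genomes under the **Double
Replications and Random Loss (DRRL)** model, built around the rearranged
mitogenome of the flatfish *Samariscus latus*. It provides:

- a data model for circular, stranded gene orders (genes, control regions,
  noncoding remnants), with the typical vertebrate order numbered
  1 (*tRNA-Phe*) … 38 (CR);
- forward simulators for DRRL and for the classic Tandem Duplication and
  Random Loss (TDRL) model;
- an inference engine that decides whether an observed order is one-step
  derivable from an ancestral order, enumerates every explanation, and
  scores each against the positions of observed CR remnants;
- annotation-table statistics for circular genomes (feature sizes,
  intergenic spacers and overlaps, large noncoding regions), with the
  *S. latus* genome-organization table packaged as a fixture;
- seeded synthetic-case generators for round-trip testing, and a CLI.

It is aimed at researchers studying mitochondrial gene-order evolution who
want to test duplication–loss mechanisms against annotated gene orders.

## The model

A DRRL event transforms a circular order in three steps:

1. **CR duplication and translocation.** The control region is duplicated;
   one copy (CRI) moves to a new position, leaving the original (CRII) in
   place. Both copies carry a heavy-strand replication origin.
2. **Double replication.** A replication fires from CRI's origin and, after
   it passes CRII, a second fires from CRII; both terminate back at CRI.
   The net product is a genome in which the block of genes strictly between
   CRI and CRII (in replication direction) appears twice, with a third
   control region (CRIII) at the distal end of the second copy.
3. **Random loss.** One copy of each duplicated gene pair is lost; each CR
   independently stays functional, degenerates into a noncoding remnant, or
   disappears.

Writing the duplicated block as ranks `1..m`, the surviving arrangement is
always a concatenation of two strictly increasing subsequences — so an
observed order is one-step DRRL-derivable if and only if, for some CR
insertion edge, the observed block arrangement has at most one *descent*
(a position where the ancestral rank drops). The split at the descent
recovers which copy of each gene survived. Unlike TDRL, DRRL pins the
duplicated region between two replication origins, so the model predicts
CR-derived elements at three specific junctions; the inference engine
checks observed CR/remnant elements against those predictions.

## Worked example

```python
from drrl import *

# the observed S. latus order, bridged from the annotation table
features = table1_fixture()
summary = summarize_annotation(features)
print(summary.genome_length, summary.n_positive_spacers, summary.n_long_spacers)
# 18706 19 9

observed = order_from_annotation(features)

# strip the recent CR-trnC-trnY duplication; exactly one reduction stays
# one-step derivable from the typical vertebrate order
canon = canonical_vertebrate_order()
reduced = next(r for _seg, r in reduce_recent_duplications(observed)
               if is_drrl_derivable(canon, r))

best = max(explain_drrl(canon, reduced),
           key=lambda e: e.remnant_matches[0])
print(best.event.insertion_edge)          # (('trnQ', None), ('trnM', None))
print(len(best.event.duplicated_block))   # 29
print(best.cluster_sizes(exclude_trailing=True))  # (11, 17)
```

The numbers say: the genome is 18,706 bp with 19 intergenic spacers (nine
over 50 bp); the translocated CR inserted between *tRNA-Gln* and
*tRNA-Met*; double replication duplicated the 29 genes from *tRNA-Met* to
*tRNA-Pro*; and the survivors form an 11-gene and a 17-gene cluster, each
preserving the typical relative order, with *tRNA-Pro* keeping its typical
position beside the degenerated CR.

The same reconstruction is available from the shell:

```bash
drrl demo slatus
drrl annstats src/drrl/data/table1_slatus.tsv --json
drrl simulate drrl --edge trnQ,trnM --seed 7
```

## Layout

- `src/drrl/orders.py` — circular gene orders, parsing, comparison
- `src/drrl/annotation.py` — annotation tables, spacers, summaries
- `src/drrl/simulate.py` — DRRL / TDRL forward simulators
- `src/drrl/infer.py` — derivability, explanations, oracle, reconstruction
- `src/drrl/synth.py` — seeded generators + packaged fixture
- `src/drrl/cli.py` — `drrl` command-line interface
- `docs/methods.md` — model details, conventions, and limitations
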