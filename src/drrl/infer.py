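"""Inference of rearrangement events from observed gene orders.

An observed circular gene order is one-step derivable from an ancestral
order under DRRL iff, for some insertion edge of the translocated CR, the
genes of the implied duplicated block appear as at most two runs each
preserving the ancestral relative order — equivalently, the block
arrangement has at most one *descent* in ancestral rank.  The split at the
descent reconstructs which copy of each duplicated gene survived.

``explain_drrl`` and ``explain_tdrl`` enumerate all one-step explanations;
``brute_force_explanations`` is an independent oracle that exhaustively
replays every parameter set through the forward simulator.
``reconstruct_slatus`` replays the inferred event chain for the S. latus
mitogenome stage by stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from . import genes as _genes
from .orders import PRIME, GeneElement, GeneOrder, canonical_vertebrate_order
from .simulate import (
    COPY1,
    COPY2,
    DEFAULT_CR_FATES,
    DrrlEvent,
    double_replication,
    duplicate_translocate,
    random_loss,
    simulate_drrl,
)

Identity = tuple[str, str | None]


class GeneContentError(ValueError):
    """Observed and ancestral orders do not carry the same genes."""


class InversionError(ValueError):
    """Observed strands differ from ancestral ones; neither DRRL nor TDRL
    can invert a gene, so such inputs are flagged rather than explained."""


@dataclass(frozen=True)
class TdrlEvent:
    """Parameters of one classic TDRL event."""

    block: tuple[str, ...]
    loss_assignment: dict[str, str]
    seed: int | None = None

    @property
    def copy1_survivors(self) -> frozenset[str]:
        return frozenset(g for g, c in self.loss_assignment.items() if c == COPY1)

    def to_json(self) -> dict:
        return {"block": list(self.block),
                "loss_assignment": dict(self.loss_assignment),
                "seed": self.seed}


@dataclass(frozen=True)
class Explanation:
    """One inferred event mapping an ancestral order onto an observed one.

    ``split_position`` is the index in the observed block arrangement where
    the first survivor run (copy 1) ends; ``arrangement`` is the observed
    ordering of the block genes.  ``remnant_support`` records whether
    observed CR/remnant elements occupy every position at which the event
    predicts one (the functional CRI plus the CRII/CRIII residues);
    ``remnant_matches`` counts satisfied predicted positions so partially
    eroded evidence (a residue degenerated below the annotation scale) can
    still be ranked.
    """

    mechanism: str  # "DRRL" | "TDRL"
    event: DrrlEvent | TdrlEvent
    split_position: int
    arrangement: tuple[str, ...]
    remnant_support: bool = False
    remnant_matches: tuple[int, int] = (0, 0)

    @property
    def copy1_size(self) -> int:
        return self.split_position

    @property
    def copy2_size(self) -> int:
        return len(self.arrangement) - self.split_position

    @property
    def trailing_typical(self) -> int:
        """Length of the longest common suffix of the arrangement and the
        block: genes at the block's distal end that kept their typical
        position (e.g. trnP next to the degenerated CR in S. latus)."""
        block = (self.event.duplicated_block
                 if isinstance(self.event, DrrlEvent) else self.event.block)
        t = 0
        while (t < min(len(block), len(self.arrangement))
               and self.arrangement[-1 - t] == block[-1 - t]):
            t += 1
        return t

    def cluster_sizes(self, exclude_trailing: bool = False) -> tuple[int, int]:
        """Sizes of the two survivor clusters.

        With ``exclude_trailing`` the genes that retained their typical
        position at the block end are not counted in the second cluster —
        the convention that yields 11 and 17 for S. latus, with trnP set
        aside.
        """
        c1, c2 = self.copy1_size, self.copy2_size
        if exclude_trailing:
            t = min(self.trailing_typical, c2)
            c2 -= t
        return c1, c2

    def key(self) -> tuple:
        ev = self.event
        if isinstance(ev, DrrlEvent):
            return ("DRRL", ev.insertion_edge, tuple(sorted(ev.copy1_survivors)))
        return ("TDRL", ev.block, tuple(sorted(ev.copy1_survivors)))


# ---------------------------------------------------------------------------
# Permutation primitives


def descents(seq) -> list[int]:
    """Positions ``i`` where ``seq[i+1] < seq[i]``."""
    return [i for i in range(len(seq) - 1) if seq[i + 1] < seq[i]]


def two_increasing_split(seq) -> list[int]:
    """All split positions dividing ``seq`` into two strictly increasing runs.

    A sequence with two or more descents has no such split; one descent
    forces the unique split right after it; a strictly increasing sequence
    admits every one of the ``len(seq) + 1`` splits.
    """
    d = descents(seq)
    if len(d) >= 2:
        return []
    if len(d) == 1:
        return [d[0] + 1]
    return list(range(len(seq) + 1))


# ---------------------------------------------------------------------------
# Alignment helpers


def _gene_idents(order: GeneOrder) -> list[Identity]:
    return [el.identity for el in order.genes()]


def _validate_content(ancestral: GeneOrder, observed: GeneOrder) -> None:
    anc = {el.identity: el for el in ancestral.genes()}
    obs = {el.identity: el for el in observed.genes()}
    if set(anc) != set(obs):
        missing = sorted(set(anc) - set(obs))
        extra = sorted(set(obs) - set(anc))
        raise GeneContentError(
            f"gene content mismatch: missing {missing}, extra {extra}")
    flipped = sorted(i for i in anc if anc[i].strand != obs[i].strand)
    if flipped:
        raise InversionError(
            f"strand inversion detected for {flipped}; DRRL/TDRL events "
            "never invert strands")


def _forward_from_cr(ancestral: GeneOrder) -> tuple[GeneElement, list[GeneElement]]:
    crs = [el for el in ancestral.elements if el.element_class == "CR"]
    if len(crs) != 1:
        raise ValueError(
            f"the ancestral order must carry exactly one CR, found {len(crs)}")
    rot = ancestral.rotate(ancestral.index_of(*crs[0].identity))
    return crs[0], [el for el in rot.elements[1:] if el.is_gene]


def _rotations_with_prefix(obs: list[Identity], prefix: list[Identity]) -> list[int]:
    n = len(obs)
    if not prefix:
        return list(range(n))
    return [r for r in range(n)
            if all(obs[(r + i) % n] == prefix[i] for i in range(len(prefix)))]


def _observed_gaps(observed: GeneOrder) -> dict[tuple[Identity, Identity], int]:
    """Non-gene element counts between consecutive genes on the circle."""
    els = observed.elements
    n = len(els)
    gene_pos = [i for i, el in enumerate(els) if el.is_gene]
    gaps: dict[tuple[Identity, Identity], int] = {}
    for j, p in enumerate(gene_pos):
        q = gene_pos[(j + 1) % len(gene_pos)]
        count = (q - p - 1) % n
        gaps[(els[p].identity, els[q].identity)] = count
    return gaps


def _predicted_cr_gaps(upstream: list[Identity], a: list[Identity],
                       split: int) -> dict[tuple[Identity, Identity], int]:
    """Gaps (flanking gene pair -> CR-element count) where the event leaves
    its three CRs — the functional CRI plus the CRII / CRIII residues — on
    the predicted post-event circle
    ``upstream + [CRI] + copy1 + [CRII] + copy2 + [CRIII]``."""
    copy1, copy2 = a[:split], a[split:]
    seq: list[Identity | str] = list(upstream) + ["CRI"] + list(copy1) \
        + ["CRII"] + list(copy2) + ["CRIII"]
    genes_at = [i for i, x in enumerate(seq) if not isinstance(x, str)]
    if not genes_at:
        return {}
    gaps: dict[tuple[Identity, Identity], int] = {}
    m = len(seq)
    for j, p in enumerate(genes_at):
        q = genes_at[(j + 1) % len(genes_at)]
        between = [seq[(p + i) % m] for i in range(1, (q - p) % m or m)]
        crs = [x for x in between if isinstance(x, str)]
        if crs:
            gaps[(seq[p], seq[q])] = len(crs)
    return gaps


def _remnant_matches(observed_gaps: dict, upstream, a, split) -> tuple[int, int]:
    """(satisfied, total) over the gaps where the event predicts CR-derived
    elements: a gap is satisfied when the observed order carries at least
    the predicted number of CR/remnant elements between the same genes."""
    predicted = _predicted_cr_gaps(upstream, a, split)
    sat = sum(1 for pair, need in predicted.items()
              if observed_gaps.get(pair, 0) >= need)
    return sat, len(predicted)


# ---------------------------------------------------------------------------
# One-step explanation enumeration


def explain_drrl(ancestral: GeneOrder, observed: GeneOrder,
                 require_remnants: bool = False) -> list[Explanation]:
    """Enumerate every one-step DRRL explanation of ``observed``.

    For each candidate insertion edge on the ancestral circle the implied
    duplicated block is the run of genes from the edge forward to the CR.
    The observed arrangement of those genes must decompose into two runs
    that each preserve ancestral order; every valid (edge, split) pair
    yields one :class:`Explanation`, with the loss assignment reconstructed
    from the split.  With ``require_remnants``, explanations whose predicted
    CRII/CRIII remnant positions lack an observed CR/remnant element are
    discarded.
    """
    _validate_content(ancestral, observed)
    cr, genes_fwd = _forward_from_cr(ancestral)
    g = [el.identity for el in genes_fwd]
    n = len(g)
    obs = _gene_idents(observed)
    obs_gaps = _observed_gaps(observed)
    found: dict[tuple, Explanation] = {}
    for k in range(n + 1):
        upstream, block = g[:k], g[k:]
        left = g[k - 1] if k > 0 else cr.identity
        right = g[k] if k < n else cr.identity
        rank = {ident: i for i, ident in enumerate(block)}
        for r in _rotations_with_prefix(obs, upstream):
            a = [obs[(r + k + i) % n] for i in range(n - k)]
            ranks = [rank[x] for x in a]
            for split in two_increasing_split(ranks):
                assignment = {lbl: COPY1 for lbl, _tag in a[:split]}
                assignment.update({lbl: COPY2 for lbl, _tag in a[split:]})
                sat, total = _remnant_matches(obs_gaps, upstream, a, split)
                support = sat == total
                if require_remnants and not support:
                    continue
                event = DrrlEvent(
                    insertion_edge=(left, right),
                    duplicated_block=tuple(lbl for lbl, _t in block),
                    loss_assignment=assignment,
                    cr_fates=dict(DEFAULT_CR_FATES),
                )
                exp = Explanation(
                    mechanism="DRRL", event=event, split_position=split,
                    arrangement=tuple(lbl for lbl, _t in a),
                    remnant_support=support,
                    remnant_matches=(sat, total),
                )
                found.setdefault((k, exp.key()), exp)
    return sorted(found.values(),
                  key=lambda e: (len(g) - len(e.event.duplicated_block),
                                 e.split_position, e.key()))


def explain_tdrl(ancestral: GeneOrder, observed: GeneOrder) -> list[Explanation]:
    """Enumerate every one-step TDRL explanation of ``observed``.

    Analogous to :func:`explain_drrl` but over all contiguous gene blocks:
    a one-step TDRL explanation exists iff the rearranged region admits a
    two-increasing split.  TDRL carries no CR bookkeeping, so explanations
    never have remnant support.
    """
    _validate_content(ancestral, observed)
    anc_genes = [el.identity for el in ancestral.genes()]
    n = len(anc_genes)
    obs = _gene_idents(observed)
    found: dict[tuple, Explanation] = {}
    for start in range(n):
        for m in range(1, n + 1):
            block = [anc_genes[(start + i) % n] for i in range(m)]
            upstream = [anc_genes[(start + m + i) % n] for i in range(n - m)]
            rank = {ident: i for i, ident in enumerate(block)}
            for r in _rotations_with_prefix(obs, upstream):
                a = [obs[(r + (n - m) + i) % n] for i in range(m)]
                ranks = [rank.get(x) for x in a]
                if None in ranks:
                    continue
                for split in two_increasing_split(ranks):
                    assignment = {lbl: COPY1 for lbl, _t in a[:split]}
                    assignment.update({lbl: COPY2 for lbl, _t in a[split:]})
                    event = TdrlEvent(
                        block=tuple(lbl for lbl, _t in block),
                        loss_assignment=assignment)
                    exp = Explanation(
                        mechanism="TDRL", event=event, split_position=split,
                        arrangement=tuple(lbl for lbl, _t in a))
                    found.setdefault(exp.key(), exp)
    return sorted(found.values(),
                  key=lambda e: (len(e.event.block), e.event.block,
                                 e.split_position, e.key()))


def is_drrl_derivable(ancestral: GeneOrder, observed: GeneOrder) -> bool:
    """True iff one DRRL event maps ``ancestral`` onto ``observed``
    (gene arrangement only; remnants not required)."""
    try:
        return bool(explain_drrl(ancestral, observed))
    except (GeneContentError, InversionError):
        return False


# ---------------------------------------------------------------------------
# Brute-force oracle


def _gene_signature(order: GeneOrder) -> tuple:
    """Rotation-invariant signature of the gene arrangement (strand-aware)."""
    sig = [(el.label, el.copy_tag, el.strand) for el in order.genes()]
    if not sig:
        return ()
    if not order.circular:
        return tuple(sig)
    start = min(range(len(sig)), key=lambda i: sig[i])
    return tuple(sig[start:] + sig[:start])


def brute_force_explanations(ancestral: GeneOrder, observed: GeneOrder,
                             max_block: int = 10,
                             require_remnants: bool = False) -> list[Explanation]:
    """Exhaustive one-step DRRL search by forward replay.

    Every insertion edge and every loss assignment (``2^block`` of them) is
    replayed through :func:`drrl.simulate.simulate_drrl`; parameter sets
    whose replay reproduces the observed gene arrangement (or, with
    ``require_remnants``, the full observed order including remnants) are
    returned.  Intended as a testing oracle; blocks larger than
    ``max_block`` raise an error.
    """
    _validate_content(ancestral, observed)
    cr, genes_fwd = _forward_from_cr(ancestral)
    g = [el.identity for el in genes_fwd]
    n = len(g)
    if n > max_block:
        raise ValueError(
            f"{n} genes imply blocks up to {n} > max_block={max_block}")
    target = _gene_signature(observed)
    results: list[Explanation] = []
    for k in range(n + 1):
        block = [lbl for lbl, _t in g[k:]]
        left = g[k - 1] if k > 0 else cr.identity
        right = g[k] if k < n else cr.identity
        for mask in range(1 << len(block)):
            assignment = {lbl: (COPY1 if mask >> i & 1 else COPY2)
                          for i, lbl in enumerate(block)}
            derived, event = simulate_drrl(ancestral, (left, right), assignment)
            if require_remnants:
                ok = derived == observed
            else:
                ok = _gene_signature(derived) == target
            if ok:
                copy1 = [el.label for el in derived.genes()
                         if assignment.get(el.label) == COPY1]
                copy2 = [el.label for el in derived.genes()
                         if assignment.get(el.label) == COPY2]
                results.append(Explanation(
                    mechanism="DRRL", event=event,
                    split_position=len(copy1),
                    arrangement=tuple(copy1 + copy2),
                    remnant_support=derived == observed))
    dedup = {e.key(): e for e in results}
    return sorted(dedup.values(),
                  key=lambda e: (n - len(e.event.duplicated_block),
                                 e.split_position, e.key()))


# ---------------------------------------------------------------------------
# Recent-duplication reduction


def reduce_recent_duplications(observed: GeneOrder
                               ) -> list[tuple[tuple[GeneElement, ...], GeneOrder]]:
    """Candidate reductions of a very recent segment duplication.

    Labels present twice (e.g. CR/CR', trnC/trnC') betray a recent
    duplication-translocation.  For each maximal repeated segment the two
    possible reductions — remove either copy, untag the survivor — are
    returned; the caller scores them by downstream derivability.
    """
    els = observed.elements
    n = len(els)
    by_label: dict[str, list[int]] = {}
    for i, el in enumerate(els):
        by_label.setdefault(el.label, []).append(i)
    twin = {}
    for label, pos in by_label.items():
        if len(pos) == 2:
            twin[pos[0]] = pos[1]
            twin[pos[1]] = pos[0]
    segments: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    covered: set[int] = set()
    for i in range(n):
        if i in covered or i not in twin:
            continue
        run = [i]
        partners = [twin[i]]
        j = i + 1
        while j < n and j in twin and j not in covered and twin[j] == partners[-1] + 1:
            run.append(j)
            partners.append(twin[j])
            j += 1
        covered.update(run)
        covered.update(partners)
        segments.append((tuple(run), tuple(partners)))
    out: list[tuple[tuple[GeneElement, ...], GeneOrder]] = []
    for run, partners in segments:
        for removed, kept in ((run, partners), (partners, run)):
            removed_set = set(removed)
            new = []
            for idx, el in enumerate(els):
                if idx in removed_set:
                    continue
                if idx in kept:
                    el = replace(el, copy_tag=None)
                new.append(el)
            out.append((tuple(els[idx] for idx in removed),
                        replace(observed, elements=tuple(new))))
    return out


# ---------------------------------------------------------------------------
# The S. latus reconstruction


#: Ancestral indices (typical-order positions) of the genes whose first
#: copy survived random loss in the S. latus event chain; the second copy
#: survived for all other duplicated genes, including trnP (37).
SLATUS_COPY1_INDICES = frozenset({14, 15, 17, 20, 26, 30, 32, 33, 34, 35, 36})


def slatus_loss_assignment() -> dict[str, str]:
    """The loss assignment of the S. latus event chain, by gene label."""
    out = {}
    for idx in range(9, 38):
        label = _genes.BY_INDEX[idx].label
        out[label] = COPY1 if idx in SLATUS_COPY1_INDICES else COPY2
    return out


def reconstruct_slatus() -> list[tuple[str, GeneOrder]]:
    """Replay the six-stage rearrangement from the typical vertebrate order
    to the S. latus mitogenome.

    A: the typical order (37 genes + CR).
    B: the CR duplicated; the copy (CRI) translocated between trnQ and trnM.
    C: same arrangement as B — the stage at which the two replications fire
       from the two CRs' origins.
    D: after double replication — 29 genes (trnM..trnP) in two copies, with
       three CRs.
    E: after random loss — the two survivor clusters separated by the CRII
       remnant, NC at the typical CR position.
    F: CR-trnC-trnY duplicated once more, the copy translocated between
       trnL2 and trnP; the CRII remnant, by now eroded to an 86-bp spacer,
       drops below the element scale.  Stage F equals the observed order.
    """
    a = canonical_vertebrate_order()
    b = duplicate_translocate(a, [("CR", None)], (("trnQ", None), ("trnM", None)))
    c = b
    state = double_replication(b, origin1=("CR", PRIME))
    d = state.order
    e, _event = random_loss(state, slatus_loss_assignment(),
                            cr_fates=dict(DEFAULT_CR_FATES))
    f_full = duplicate_translocate(
        e, [("CR", None), ("trnC", None), ("trnY", None)],
        (("trnL2", None), ("trnP", None)))
    f = replace(f_full, elements=tuple(
        el for el in f_full.elements if el.label != _genes.CR_REMNANT_LABEL))
    return [("A", a), ("B", b), ("C", c), ("D", d), ("E", e), ("F", f)]


def slatus_residue_adjacencies() -> set[frozenset]:
    """Feature adjacencies at which the S. latus event chain left residue.

    An adjacency is marked when at least one duplicated gene copy was
    deleted between the two flanking elements, or a CR degenerated there.
    Marks survive the final duplication-translocation (the insertion splits
    a marked junction into two marked junctions) and the erosion of the
    CRII remnant (its neighbours inherit the mark).  Long intergenic
    spacers in the observed genome are expected to lie on marked
    adjacencies only.
    """
    stages = dict(reconstruct_slatus())
    b = stages["B"]
    state = double_replication(b, origin1=("CR", PRIME))
    d_els = state.order.elements
    e, _ = random_loss(state, slatus_loss_assignment(),
                       cr_fates=dict(DEFAULT_CR_FATES))
    # replay the loss to tag each stage-D element kept / lost, with the
    # identity it carries in stage E
    assignment = slatus_loss_assignment()
    kept: list[tuple] = []  # (E identity, is_remnant)
    lost_since_last: list[int] = []
    seq: list[tuple | None] = []
    for el in d_els:
        if el.element_class == "CR":
            name = "CR" + (el.copy_tag or "")
            fate = DEFAULT_CR_FATES.get(name, "functional")
            if fate == "functional":
                seq.append((("CR", None), False))
            elif fate == "remnant":
                lbl = (_genes.NC_LABEL if name == "CRIII"
                       else _genes.CR_REMNANT_LABEL)
                seq.append(((lbl, None), True))
            else:
                seq.append(None)
        elif el.copy_tag in ("1", "2"):
            want = "1" if assignment[el.label] == COPY1 else "2"
            seq.append(((el.label, None), False) if el.copy_tag == want else None)
        else:
            seq.append((el.identity, False))
    marks: set[frozenset] = set()
    kept_items = [(i, s) for i, s in enumerate(seq) if s is not None]
    nk = len(kept_items)
    for j in range(nk):
        (i1, (id1, rem1)) = kept_items[j]
        (i2, (id2, rem2)) = kept_items[(j + 1) % nk]
        n_lost = ((i2 - i1) % len(seq)) - 1
        if n_lost > 0:
            marks.add(frozenset((id1, id2)))
    # remnant elements are residue themselves: mark their flanks and the
    # gene-gene adjacency that appears once the remnant erodes away
    for j in range(nk):
        (_, (ident, is_rem)) = kept_items[j]
        if is_rem:
            prev_id = kept_items[(j - 1) % nk][1][0]
            next_id = kept_items[(j + 1) % nk][1][0]
            marks.add(frozenset((prev_id, ident)))
            marks.add(frozenset((ident, next_id)))
            marks.add(frozenset((prev_id, next_id)))
    # final duplication-translocation: the insertion at trnL2|trnP splits
    # that junction; both new junctions inherit its mark
    edge = frozenset(((("trnL2", None)), ("trnP", None)))
    if edge in marks:
        marks.add(frozenset((("trnL2", None), ("CR", PRIME))))
        marks.add(frozenset((("trnY", PRIME), ("trnP", None))))
    return marks
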