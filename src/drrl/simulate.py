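"""Forward simulators for mitogenome rearrangement events.

The Double Replications and Random Loss (DRRL) model rearranges a circular
mitogenome in three steps:

1. the control region (CR) is duplicated and one copy translocated to a new
   position (``duplicate_translocate``);
2. two successive replications start from the two CRs' heavy-strand origins;
   the genes strictly between the translocated CR (CRI) and the original CR
   (CRII), in the direction of replication, end up duplicated, and a third
   CR (CRIII) is created at the far end of the second copy
   (``double_replication``);
3. one copy of each duplicated gene pair is lost, at random or by a given
   assignment, and each of the three CRs either stays functional,
   degenerates into a noncoding remnant, or is lost (``random_loss``).

``simulate_drrl`` composes the three steps.  ``simulate_tdrl`` implements
the classic Tandem Duplication and Random Loss model for comparison: a
contiguous block is duplicated in place, with no CR bookkeeping.

Neither model ever changes an element's strand: rearrangements that involve
inversions are outside both models.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from . import genes as _genes
from .orders import PRIME, GeneElement, GeneOrder

COPY1 = "copy1"
COPY2 = "copy2"
FUNCTIONAL = "functional"
REMNANT = "remnant"
LOST = "lost"

#: CR fates of the S. latus reconstruction: the translocated CR stays
#: functional while the original CR and the newly created one degenerate.
DEFAULT_CR_FATES = {"CRI": FUNCTIONAL, "CRII": REMNANT, "CRIII": REMNANT}

_REMNANT_LABELS = {"CRI": "CRI-remnant", "CRII": _genes.CR_REMNANT_LABEL,
                   "CRIII": _genes.NC_LABEL}


@dataclass(frozen=True)
class DrrlEvent:
    """Full parameterization of one DRRL event.

    ``insertion_edge`` names the adjacent pair of elements between which the
    translocated CR (CRI) was inserted.  ``duplicated_block`` lists, in
    replication order, the labels of the genes strictly between CRI and the
    original CR (CRII).  ``loss_assignment`` records which copy of each
    duplicated gene survived, and ``cr_fates`` what became of the three CRs.
    """

    insertion_edge: tuple[tuple[str, str | None], tuple[str, str | None]] | None
    duplicated_block: tuple[str, ...]
    loss_assignment: dict[str, str]
    cr_fates: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CR_FATES))
    seed: int | None = None

    def __post_init__(self) -> None:
        if set(self.loss_assignment) != set(self.duplicated_block):
            missing = set(self.duplicated_block) - set(self.loss_assignment)
            extra = set(self.loss_assignment) - set(self.duplicated_block)
            raise ValueError(
                f"loss_assignment must cover exactly the duplicated block; "
                f"missing {sorted(missing)}, extra {sorted(extra)}")
        if FUNCTIONAL not in self.cr_fates.values():
            raise ValueError("at least one CR must remain functional")

    @property
    def copy1_survivors(self) -> frozenset[str]:
        return frozenset(g for g, c in self.loss_assignment.items() if c == COPY1)

    def to_json(self) -> dict:
        return {
            "insertion_edge": [list(e) for e in self.insertion_edge]
            if self.insertion_edge else None,
            "duplicated_block": list(self.duplicated_block),
            "loss_assignment": dict(self.loss_assignment),
            "cr_fates": dict(self.cr_fates),
            "seed": self.seed,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "DrrlEvent":
        edge = obj.get("insertion_edge")
        return cls(
            insertion_edge=tuple(tuple(e) for e in edge) if edge else None,
            duplicated_block=tuple(obj["duplicated_block"]),
            loss_assignment=dict(obj["loss_assignment"]),
            cr_fates=dict(obj.get("cr_fates", DEFAULT_CR_FATES)),
            seed=obj.get("seed"),
        )


@dataclass(frozen=True)
class DuplicatedState:
    """A genome caught after double replication, before any loss.

    The order reads: upstream single-copy genes, CRI, block copy 1 (tag
    ``1``), CRII, block copy 2 (tag ``2``), CRIII — circularly back to the
    upstream genes.  Every duplicated gene appears exactly twice, in the
    same relative order in both copies.
    """

    order: GeneOrder
    block: tuple[str, ...]  # labels in replication order
    upstream: tuple[str, ...]


def _find_identity(order: GeneOrder, ident) -> int:
    label, tag = ident if isinstance(ident, tuple) else (ident, None)
    return order.index_of(label, tag)


def duplicate_translocate(order: GeneOrder, segment, insertion_edge) -> GeneOrder:
    """Duplicate a contiguous segment and insert the copy at an edge.

    ``segment`` is a list of element identities (labels, or (label,
    copy_tag) pairs) forming a contiguous run in ``order``; ``insertion_edge``
    is an adjacent pair of identities between which the copy (tagged with a
    prime) is placed.  The original segment is untouched.  Inserting at the
    edge immediately following the segment gives a tandem duplication.
    """
    n = len(order.elements)
    seg_idx = [_find_identity(order, s) for s in segment]
    for a, b in zip(seg_idx, seg_idx[1:]):
        if b != (a + 1) % n:
            raise ValueError("segment is not contiguous in the order")
    left = _find_identity(order, insertion_edge[0])
    right = _find_identity(order, insertion_edge[1])
    if right != (left + 1) % n:
        raise ValueError(
            f"insertion edge {insertion_edge!r} is not an adjacency of the order")
    if left in seg_idx and right in seg_idx:
        raise ValueError("insertion edge lies inside the duplicated segment")
    copy = tuple(replace(order.elements[i], copy_tag=PRIME) for i in seg_idx)
    for el in copy:
        if el.identity in {e.identity for e in order.elements}:
            raise ValueError(f"copy of {el.label} collides with an existing "
                             "prime-tagged element")
    new = order.elements[: left + 1] + copy + order.elements[left + 1:]
    return replace(order, elements=new)


def double_replication(order: GeneOrder, origin1=None) -> DuplicatedState:
    """Duplicate the genes between two CRs by two successive replications.

    ``order`` must contain exactly two CR-class elements.  ``origin1`` names
    the CR whose origin fires first (CRI); by default the prime-tagged copy
    (as produced by :func:`duplicate_translocate`) is CRI.  Replication runs
    in the forward direction of the order: the elements strictly between CRI
    and the other CR (CRII) are duplicated, and a third CR (CRIII, a copy of
    CRI) is created at the distal end of the second copy.  Genes upstream of
    CRI (between CRII and CRI) stay single-copy.
    """
    crs = [el for el in order.elements if el.element_class == "CR"]
    if len(crs) != 2:
        raise ValueError(f"double replication needs exactly 2 CRs, found {len(crs)}")
    if origin1 is None:
        tagged = [el for el in crs if el.copy_tag is not None]
        if len(tagged) != 1:
            raise ValueError("origin1 is ambiguous: name the CR that fires first")
        origin1 = tagged[0].identity
    i1 = _find_identity(order, origin1)
    if order.elements[i1].element_class != "CR":
        raise ValueError(f"origin1 {origin1!r} is not a CR element")
    n = len(order.elements)
    rot = order.rotate(i1)  # CRI first
    cri = rot.elements[0]
    i2 = next(i for i, el in enumerate(rot.elements)
              if i > 0 and el.element_class == "CR")
    crii = rot.elements[i2]
    block = rot.elements[1:i2]
    upstream = rot.elements[i2 + 1:]
    labels = [el.label for el in block]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicated block contains repeated labels")
    new_elements = (
        upstream
        + (replace(cri, copy_tag="I"),)
        + tuple(replace(el, copy_tag="1") for el in block)
        + (replace(crii, copy_tag="II"),)
        + tuple(replace(el, copy_tag="2") for el in block)
        + (replace(cri, copy_tag="III"),)
    )
    return DuplicatedState(
        order=replace(order, elements=new_elements),
        block=tuple(labels),
        upstream=tuple(el.label for el in upstream),
    )


def _cr_element(state_cr: GeneElement, name: str, fate: str,
                n_functional: int) -> GeneElement | None:
    if fate == LOST:
        return None
    if fate == FUNCTIONAL:
        # a single surviving functional CR drops its roman tag; with several,
        # tags are kept so identities stay unique
        tag = None if n_functional == 1 else state_cr.copy_tag
        return replace(state_cr, copy_tag=tag)
    if fate == REMNANT:
        return GeneElement(label=_REMNANT_LABELS[name], strand=state_cr.strand,
                           element_class="remnant")
    raise ValueError(f"unknown CR fate {fate!r} for {name}")


def random_loss(state: DuplicatedState, loss_assignment: dict[str, str] | None = None,
                seed: int | None = None,
                cr_fates: dict[str, str] | None = None
                ) -> tuple[GeneOrder, DrrlEvent]:
    """Resolve a duplicated state by losing one copy of each gene pair.

    When ``loss_assignment`` is absent, each gene's surviving copy is drawn
    independently with probability 1/2 from ``seed`` (which is then
    mandatory).  CRs follow ``cr_fates``: a functional CR keeps its label, a
    remnant degenerates into a noncoding element (CRII into a CR remnant
    between the two survivor runs, CRIII into NC at the typical CR
    position), and a lost CR disappears.
    """
    fates = dict(DEFAULT_CR_FATES if cr_fates is None else cr_fates)
    if loss_assignment is None:
        if seed is None:
            raise ValueError("either loss_assignment or seed is required")
        rng = random.Random(seed)
        loss_assignment = {g: (COPY1 if rng.random() < 0.5 else COPY2)
                           for g in state.block}
    if set(loss_assignment) != set(state.block):
        missing = set(state.block) - set(loss_assignment)
        extra = set(loss_assignment) - set(state.block)
        raise ValueError(f"incomplete loss assignment: missing {sorted(missing)}, "
                         f"extra {sorted(extra)}")
    bad = {g: c for g, c in loss_assignment.items() if c not in (COPY1, COPY2)}
    if bad:
        raise ValueError(f"loss assignment values must be copy1/copy2: {bad}")

    order = state.order
    crs = {el.copy_tag: el for el in order.elements if el.element_class == "CR"}
    n_functional = sum(1 for f in fates.values() if f == FUNCTIONAL)
    out: list[GeneElement] = []
    for el in order.elements:
        if el.element_class == "CR" and el.copy_tag in ("I", "II", "III"):
            name = "CR" + el.copy_tag
            kept = _cr_element(el, name, fates.get(name, FUNCTIONAL), n_functional)
            if kept is not None:
                out.append(kept)
        elif el.copy_tag in ("1", "2") and el.label in loss_assignment:
            wanted = "1" if loss_assignment[el.label] == COPY1 else "2"
            if el.copy_tag == wanted:
                out.append(replace(el, copy_tag=None))
        else:
            out.append(el)
    event = DrrlEvent(insertion_edge=None, duplicated_block=state.block,
                      loss_assignment=dict(loss_assignment), cr_fates=fates,
                      seed=seed)
    return replace(order, elements=tuple(out)), event


def simulate_drrl(order: GeneOrder, insertion_edge,
                  loss_assignment: dict[str, str] | None = None,
                  seed: int | None = None,
                  cr_fates: dict[str, str] | None = None
                  ) -> tuple[GeneOrder, DrrlEvent]:
    """Apply one full DRRL event to an order with a single CR.

    Composition of CR duplication/translocation to ``insertion_edge``,
    double replication, and random loss.  Returns the derived order and the
    fully parameterized event.
    """
    crs = [el for el in order.elements if el.element_class == "CR"]
    if len(crs) != 1:
        raise ValueError(f"DRRL starts from an order with one CR, found {len(crs)}")
    with_cri = duplicate_translocate(order, [crs[0].identity], insertion_edge)
    state = double_replication(with_cri, origin1=("CR", PRIME))
    derived, event = random_loss(state, loss_assignment, seed, cr_fates)
    edge = (_as_identity(insertion_edge[0]), _as_identity(insertion_edge[1]))
    event = replace(event, insertion_edge=edge)
    return derived, event


def _as_identity(x) -> tuple[str, str | None]:
    return x if isinstance(x, tuple) else (x, None)


def simulate_tdrl(order: GeneOrder, block,
                  loss_assignment: dict[str, str] | None = None,
                  seed: int | None = None) -> GeneOrder:
    """Apply one classic TDRL event: tandem-duplicate ``block``, then keep
    one copy of each element per ``loss_assignment`` (or a fair coin draw
    from ``seed``).  No CR bookkeeping is performed.
    """
    n = len(order.elements)
    idx = [_find_identity(order, b) for b in block]
    for a, b in zip(idx, idx[1:]):
        if b != (a + 1) % n:
            raise ValueError("TDRL block is not contiguous in the order")
    labels = [order.elements[i].label for i in idx]
    if loss_assignment is None:
        if seed is None:
            raise ValueError("either loss_assignment or seed is required")
        rng = random.Random(seed)
        loss_assignment = {g: (COPY1 if rng.random() < 0.5 else COPY2)
                           for g in labels}
    if set(loss_assignment) != set(labels):
        raise ValueError("incomplete loss assignment for TDRL block")
    rot = order.rotate(idx[0])  # block first, then the rest
    m = len(idx)
    blk, rest = rot.elements[:m], rot.elements[m:]
    copy1 = tuple(el for el in blk if loss_assignment[el.label] == COPY1)
    copy2 = tuple(el for el in blk if loss_assignment[el.label] == COPY2)
    return replace(order, elements=copy1 + copy2 + rest)
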