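"""Circular gene orders for mitogenome rearrangement analysis.

A :class:`GeneOrder` is an ordered collection of labelled, stranded elements
on a (usually circular) mitogenome: genes, control regions (CRs), and
remnants of degenerated features.  Circular orders compare equal under
rotation; the canonical rotation starts at trnF when present.

Elements are identified by ``(label, copy_tag)``.  Copy tags distinguish
duplicates: ``'`` marks a recent duplicate (e.g. trnC' / trnY'), ``1`` / ``2``
mark the two copies of a duplicated block, and ``I`` / ``II`` / ``III`` mark
the control regions of a genome caught between duplication and loss.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

from . import genes as _genes

PRIME = "'"

#: Remnant-class labels that are part of the vocabulary (not warnings).
_KNOWN_REMNANTS = {_genes.NC_LABEL, _genes.CR_REMNANT_LABEL, "CRI-remnant"}


@dataclass(frozen=True)
class GeneElement:
    """One element of a gene order: a gene, a CR, or a remnant."""

    label: str
    strand: str = "H"
    element_class: str = "remnant"
    copy_tag: str | None = None
    ancestral_index: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be H or L, got {self.strand!r}")
        if self.element_class not in ("tRNA", "rRNA", "CDS", "CR", "remnant"):
            raise ValueError(f"unknown element class {self.element_class!r}")
        if self.ancestral_index is not None and not 1 <= self.ancestral_index <= 38:
            raise ValueError("ancestral_index must be in [1, 38]")
        if self.element_class == "CR" and not self.label.startswith("CR"):
            raise ValueError("CR-class elements must be labelled CR")

    @property
    def identity(self) -> tuple[str, str | None]:
        return (self.label, self.copy_tag)

    @property
    def is_gene(self) -> bool:
        return self.element_class in ("tRNA", "rRNA", "CDS")

    def token(self) -> str:
        """Render as a text token (``-`` prefix = L strand, ``'`` = prime)."""
        tag = ""
        if self.copy_tag == PRIME:
            tag = PRIME
        elif self.copy_tag is not None:
            tag = "." + self.copy_tag
        sign = "-" if self.strand == "L" else ""
        return f"{sign}{self.label}{tag}"


def element_for(label: str, copy_tag: str | None = None,
                strand: str | None = None) -> GeneElement:
    """Build an element from a vocabulary label, filling class/strand/index."""
    info = _genes.BY_LABEL.get(label)
    if info is not None:
        return GeneElement(
            label=info.label,
            strand=strand or info.strand,
            element_class=info.element_class,
            copy_tag=copy_tag,
            ancestral_index=info.ancestral_index,
        )
    if label in _KNOWN_REMNANTS:
        return GeneElement(label=label, strand=strand or "H",
                           element_class="remnant", copy_tag=copy_tag)
    raise KeyError(f"unknown label {label!r}")


@dataclass(frozen=True)
class GeneOrder:
    """An ordered, optionally circular, sequence of genome elements."""

    elements: tuple[GeneElement, ...]
    circular: bool = True

    def __post_init__(self) -> None:
        seen: set[tuple[str, str | None]] = set()
        for el in self.elements:
            if el.identity in seen:
                raise ValueError(
                    f"duplicate element {el.token()!r}: (label, copy_tag) "
                    "pairs must be unique within an order"
                )
            seen.add(el.identity)

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def genes(self) -> tuple[GeneElement, ...]:
        """Gene elements only (CRs and remnants dropped)."""
        return tuple(el for el in self.elements if el.is_gene)

    def labels(self) -> tuple[str, ...]:
        return tuple(el.label for el in self.elements)

    def index_of(self, label: str, copy_tag: str | None = None) -> int:
        for i, el in enumerate(self.elements):
            if el.identity == (label, copy_tag):
                return i
        raise KeyError(f"element ({label!r}, {copy_tag!r}) not in order")

    def rotate(self, start: int) -> "GeneOrder":
        if not self.circular:
            raise ValueError("cannot rotate a linear order")
        n = len(self.elements)
        start %= n
        return replace(self, elements=self.elements[start:] + self.elements[:start])

    def without_remnants(self) -> "GeneOrder":
        return replace(self, elements=tuple(
            el for el in self.elements if el.element_class != "remnant"))

    # -- equality under rotation ----------------------------------------
    def _signature(self) -> tuple:
        return tuple((el.label, el.copy_tag, el.strand, el.element_class)
                     for el in canonical_rotation(self).elements)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneOrder):
            return NotImplemented
        if self.circular != other.circular:
            return False
        return self._signature() == other._signature()

    def __hash__(self) -> int:
        return hash((self.circular, self._signature()))

    # -- serialization ---------------------------------------------------
    def to_json(self) -> dict:
        return {
            "circular": self.circular,
            "elements": [
                {
                    "label": el.label,
                    "strand": el.strand,
                    "class": el.element_class,
                    "copy_tag": el.copy_tag,
                    "ancestral_index": el.ancestral_index,
                }
                for el in self.elements
            ],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "GeneOrder":
        els = tuple(
            GeneElement(
                label=e["label"],
                strand=e.get("strand", "H"),
                element_class=e.get("class", "remnant"),
                copy_tag=e.get("copy_tag"),
                ancestral_index=e.get("ancestral_index"),
            )
            for e in obj["elements"]
        )
        return cls(elements=els, circular=obj.get("circular", True))

    def dumps(self) -> str:
        return json.dumps(self.to_json(), ensure_ascii=False)


# ---------------------------------------------------------------------------
# Reference orders


def canonical_vertebrate_order() -> GeneOrder:
    """The typical vertebrate mitogenome order: 37 genes + CR, numbered 1-38.

    Position 1 is trnF and position 38 the control region; strands follow
    the vertebrate consensus (ND6 and the tRNAs Q, A, N, C, Y, S1, E, P on
    the light strand).
    """
    return GeneOrder(tuple(element_for(g.label) for g in _genes.CANONICAL_TABLE))


#: The observed S. latus order as (label, copy_tag) pairs, top-to-bottom of
#: the genome annotation: the first eight genes keep their typical position,
#: then CR1, an 11-gene cluster, a 17-gene cluster, the translocated
#: CR2-trnC'-trnY' copy, trnP, and the NC remnant at the typical CR position.
_SLATUS_SEQUENCE: tuple[tuple[str, str | None], ...] = (
    ("trnF", None), ("rrnS", None), ("trnV", None), ("rrnL", None),
    ("trnL1", None), ("ND1", None), ("trnI", None), ("trnQ", None),
    ("CR", None),
    ("trnC", None), ("trnY", None), ("trnS1", None), ("trnK", None),
    ("trnR", None), ("trnS2", None), ("ND5", None), ("ND6", None),
    ("trnE", None), ("CYTB", None), ("trnT", None),
    ("trnM", None), ("ND2", None), ("trnW", None), ("trnA", None),
    ("trnN", None), ("COI", None), ("trnD", None), ("COII", None),
    ("ATP8", None), ("ATP6", None), ("COIII", None), ("trnG", None),
    ("ND3", None), ("ND4L", None), ("ND4", None), ("trnH", None),
    ("trnL2", None),
    ("CR", PRIME), ("trnC", PRIME), ("trnY", PRIME),
    ("trnP", None), ("NC", None),
)


def samariscus_latus_order() -> GeneOrder:
    """The observed S. latus mitogenome gene order (42 elements).

    Relative to the typical vertebrate order the genome carries a duplicated,
    translocated control region: CR1 sits between trnQ and trnC, the genes
    between the two CRs fall into two clusters each preserving the typical
    relative order, CR2-trnC'-trnY' is a recent duplicate of CR1-trnC-trnY
    inserted between trnL2 and trnP, and a 376-bp noncoding remnant (NC)
    occupies the typical CR position between trnP and trnF.
    """
    return GeneOrder(tuple(element_for(lbl, tag) for lbl, tag in _SLATUS_SEQUENCE))


# ---------------------------------------------------------------------------
# Parsing and formatting


def _parse_token(token: str) -> GeneElement:
    raw = token
    strand_override = None
    if token.startswith("-"):
        strand_override = "L"
        token = token[1:]
    copy_tag = None
    if token.endswith(("'", "′")):
        copy_tag = PRIME
        token = token.rstrip("'′")
    elif "." in token:
        token, _, tag = token.partition(".")
        copy_tag = tag
    if not token:
        raise ValueError(f"empty label in token {raw!r}")
    label = _genes.resolve_label(token)
    if token.upper() in _genes.DUPLICATE_CR_ALIASES:
        label, copy_tag = "CR", PRIME
    if label is not None:
        return element_for(label, copy_tag, strand_override)
    if token in _KNOWN_REMNANTS or token.upper() == "NC":
        lbl = _genes.NC_LABEL if token.upper() == "NC" else token
        return element_for(lbl, copy_tag, strand_override)
    warnings.warn(f"unknown label {token!r}: keeping it as a remnant element",
                  stacklevel=3)
    return GeneElement(label=token, strand=strand_override or "H",
                       element_class="remnant", copy_tag=copy_tag)


def parse_gene_order(text: str, circular: bool = True) -> GeneOrder:
    """Parse a token string into a :class:`GeneOrder`.

    Tokens are whitespace- or comma-separated.  A leading ``-`` marks the
    light strand, a trailing ``'`` (or prime) marks a duplicate copy, and
    ``#`` starts a comment.  Unknown labels are kept as remnant elements
    with a warning.
    """
    tokens: list[str] = []
    for line in text.splitlines() or [text]:
        line = line.split("#", 1)[0]
        tokens.extend(t for t in line.replace(",", " ").split() if t)
    if not tokens:
        raise ValueError("empty gene-order input")
    elements = []
    seen: set[tuple[str, str | None]] = set()
    for tok in tokens:
        el = _parse_token(tok)
        if el.identity in seen:
            raise ValueError(f"duplicate element for token {tok!r}")
        seen.add(el.identity)
        elements.append(el)
    return GeneOrder(tuple(elements), circular=circular)


def format_gene_order(order: GeneOrder) -> str:
    """Render an order as a single line of tokens (inverse of parsing)."""
    return " ".join(el.token() for el in order.elements)


# ---------------------------------------------------------------------------
# Rotation and comparison


def canonical_rotation(order: GeneOrder) -> GeneOrder:
    """Rotate a circular order to its canonical start.

    The canonical start is trnF (untagged) when present, otherwise the
    element with the smallest ``(label, copy_tag)``.  Linear orders are
    returned unchanged.  Idempotent; two circular orders are equal iff
    their canonical rotations are element-wise equal.
    """
    if not order.circular or not order.elements:
        return order
    try:
        start = order.index_of("trnF")
    except KeyError:
        start = min(range(len(order.elements)),
                    key=lambda i: (order.elements[i].label,
                                   order.elements[i].copy_tag or ""))
    return order.rotate(start)


def _adjacency_set(order: GeneOrder) -> set[frozenset]:
    els = order.genes()
    if len(els) < 2:
        return set()
    pairs = zip(els, els[1:] + (els[:1] if order.circular else ()))
    return {frozenset((a.identity, b.identity)) for a, b in pairs}


def shared_adjacencies(a: GeneOrder, b: GeneOrder) -> int:
    """Count gene-gene adjacencies present in both orders.

    CR and remnant elements are ignored, so the count reflects conserved
    gene neighborhoods only.  Symmetric; for a circular order compared with
    itself it equals the number of genes.
    """
    return len(_adjacency_set(a) & _adjacency_set(b))
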