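"""Seeded generators of synthetic gene orders, events, and annotations.

Every generator is a pure function of its arguments and seed: the same
seed always reproduces the same case.  ``random_drrl_case`` produces a
ground-truth triple (ancestral, event, derived) suitable for round-trip
tests of the inference engine, mirroring the study conditions of the
S. latus event chain: a uniformly random insertion edge, a fair coin per
duplicated gene pair, and CR fates functional / remnant / remnant.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources

from .annotation import FeatureRecord, read_annotation_table
from .orders import GeneElement, GeneOrder
from .simulate import DEFAULT_CR_FATES, DrrlEvent, simulate_drrl


@dataclass(frozen=True)
class SyntheticCase:
    """A ground-truth rearrangement case: replaying ``event`` on
    ``ancestral`` yields ``derived`` exactly (up to rotation)."""

    ancestral: GeneOrder
    event: DrrlEvent
    derived: GeneOrder
    seed: int


def random_gene_order(n_genes: int, seed: int) -> GeneOrder:
    """A circular order of ``n_genes`` generic genes (g1..gn) plus one CR,
    with seeded random strands and gene arrangement."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = random.Random(seed)
    labels = [f"g{i}" for i in range(1, n_genes + 1)]
    rng.shuffle(labels)
    elements = [
        GeneElement(label=lbl, strand=rng.choice("HL"), element_class="CDS")
        for lbl in labels
    ]
    elements.append(GeneElement(label="CR", strand="H", element_class="CR"))
    return GeneOrder(tuple(elements))


def random_drrl_case(n_genes: int, seed: int) -> SyntheticCase:
    """A seeded DRRL case with known ground truth.

    The insertion edge is uniform over the ancestral circle, each gene's
    surviving copy is a fair coin, and the CR fates follow the pattern of
    the S. latus chain (CRI functional, CRII and CRIII remnants).
    """
    rng = random.Random(seed)
    ancestral = random_gene_order(n_genes, rng.randrange(2**31))
    n = len(ancestral.elements)
    i = rng.randrange(n)
    edge = (ancestral.elements[i].identity,
            ancestral.elements[(i + 1) % n].identity)
    derived, event = simulate_drrl(
        ancestral, edge, seed=rng.randrange(2**31),
        cr_fates=dict(DEFAULT_CR_FATES))
    return SyntheticCase(ancestral=ancestral, event=event,
                         derived=derived, seed=seed)


@dataclass(frozen=True)
class LengthModel:
    """Bounded uniform feature-length distributions by element class (bp)."""

    ranges: dict = None

    _DEFAULT = {
        "tRNA": (65, 75),
        "rRNA": (900, 1750),
        "CDS": (160, 1900),
        "CR": (800, 950),
        "remnant": (80, 400),
    }

    def draw(self, rng: random.Random, element_class: str) -> int:
        lo, hi = (self.ranges or self._DEFAULT).get(
            element_class, self._DEFAULT["CDS"])
        return rng.randint(lo, hi)


@dataclass(frozen=True)
class SpacerModel:
    """Intergenic spacer distribution with a parameterized overlap rate."""

    lo: int = 0
    hi: int = 90
    p_overlap: float = 0.0
    max_overlap: int = 10

    def draw(self, rng: random.Random) -> int:
        if self.p_overlap and rng.random() < self.p_overlap:
            return -rng.randint(1, self.max_overlap)
        return rng.randint(self.lo, self.hi)


def synthetic_annotation(order: GeneOrder,
                         gene_length_model: LengthModel | None = None,
                         spacer_model=None,
                         seed: int = 0) -> list[FeatureRecord]:
    """Coordinate-level annotation emulating a mitogenome table.

    Feature sizes are drawn from ``gene_length_model`` and the spacer ahead
    of each feature from ``spacer_model`` (a :class:`SpacerModel`, or an
    explicit list of spacer lengths, one per internal junction).  Negative
    spacers (overlaps) are clamped so starts stay strictly increasing.  The
    genome length is the last feature's end, so the wrap spacer is zero.
    """
    rng = random.Random(seed)
    lengths = gene_length_model or LengthModel()
    if spacer_model is None:
        spacer_model = SpacerModel()
    explicit = list(spacer_model) if isinstance(spacer_model, (list, tuple)) \
        else None
    records: list[FeatureRecord] = []
    pos = 0  # end of previous feature
    for i, el in enumerate(order.elements):
        if i == 0:
            spacer = 0
        elif explicit is not None:
            spacer = explicit[(i - 1) % len(explicit)]
        else:
            spacer = spacer_model.draw(rng)
        if spacer < 0:
            spacer = max(spacer, -(records[-1].size - 1))
        size = lengths.draw(rng, el.element_class)
        cls = el.element_class
        if cls == "remnant":
            cls = "NC"
        start = pos + 1 + spacer
        records.append(FeatureRecord(
            name=el.token().lstrip("-"), start=start, end=start + size - 1,
            strand=el.strand, element_class=cls,
            intergenic_printed=None))
        pos = start + size - 1
    return records


def table1_fixture() -> list[FeatureRecord]:
    """The packaged transcription of the S. latus genome-organization
    table: 42 features (24 tRNA, 2 rRNA, 13 protein-coding, 2 CRs, 1 NC)
    with 1-based coordinates and the printed intergenic column."""
    ref = resources.files("drrl").joinpath("data/table1_slatus.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return read_annotation_table(fh)
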