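"""Annotation tables and circular-genome organization statistics.

Reads tab-separated feature tables with 1-based inclusive coordinates (the
layout of a mitogenome organization table: name, from, to, strand, class,
optional anticodon/codon columns and a printed intergenic column), computes
intergenic spacers and overlaps around the circle, and summarizes genome
organization.  The spacer between consecutive features is
``next.start - prev.end - 1``; a negative value is an overlap.  The wrap
spacer between the last and first feature closes the circle.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import genes as _genes
from .orders import GeneOrder, _parse_token

_REQUIRED = ("name", "from", "to", "strand", "class")
_CLASSES = {"tRNA", "rRNA", "CDS", "CR", "NC"}


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated feature with 1-based inclusive coordinates."""

    name: str
    start: int
    end: int
    strand: str
    element_class: str
    anticodon: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None
    intergenic_printed: int | None = None  # as printed in the source table

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SpacerRecord:
    """Intergenic spacer between two consecutive features; negative length
    denotes an overlap."""

    upstream: str
    downstream: str
    length: int
    wrap: bool = False  # the circular last-to-first pair


@dataclass
class AnnotationSummary:
    """Genome-organization statistics for a circular annotation."""

    genome_length: int
    counts_by_class: dict[str, int]
    counts_by_strand: dict[str, int]
    l_strand_features: list[str]
    spacers: list[SpacerRecord]
    spacer_threshold: int
    nc_threshold: int
    n_positive_spacers: int = 0
    n_long_spacers: int = 0
    n_overlaps: int = 0
    large_noncoding: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "genome_length": self.genome_length,
            "counts_by_class": dict(self.counts_by_class),
            "counts_by_strand": dict(self.counts_by_strand),
            "l_strand_features": list(self.l_strand_features),
            "n_positive_spacers": self.n_positive_spacers,
            "n_spacers_over_threshold": self.n_long_spacers,
            "spacer_threshold": self.spacer_threshold,
            "n_overlaps": self.n_overlaps,
            "large_noncoding": list(self.large_noncoding),
            "nc_threshold": self.nc_threshold,
            "spacers": [
                {"upstream": s.upstream, "downstream": s.downstream,
                 "length": s.length, "wrap": s.wrap}
                for s in self.spacers
            ],
        }


def read_annotation_table(source) -> list[FeatureRecord]:
    """Read a TSV annotation table into feature records, in file order.

    ``source`` may be a path or an open text stream.  Required columns:
    name, from, to, strand, class; recognized extras: anticodon,
    start_codon, stop_codon, intergenic.  File order must equal coordinate
    order; coordinate problems are reported with their row number.
    """
    if isinstance(source, (str, Path)) and "\t" not in str(source):
        df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    else:
        text = source if isinstance(source, str) else source.read()
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str,
                         keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table lacks required columns: {missing}")
    records: list[FeatureRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = 1
        row = dict(zip(df.columns, row))
        try:
            start, end = int(row["from"]), int(row["to"])
        except ValueError as exc:
            raise ValueError(f"row {i}: non-numeric coordinates "
                             f"({row['from']!r}, {row['to']!r})") from exc
        if start > end:
            raise ValueError(f"row {i} ({row['name']}): start {start} > end {end}")
        if start < 1:
            raise ValueError(f"row {i} ({row['name']}): coordinates are 1-based")
        strand = row["strand"].strip()
        if strand not in ("H", "L"):
            raise ValueError(f"row {i} ({row['name']}): unknown strand {strand!r}")
        cls = row["class"].strip()
        if cls not in _CLASSES:
            raise ValueError(f"row {i} ({row['name']}): unknown class {cls!r}")
        printed = row.get("intergenic", "").strip()
        records.append(FeatureRecord(
            name=row["name"].strip(),
            start=start, end=end, strand=strand, element_class=cls,
            anticodon=row.get("anticodon", "").strip() or None,
            start_codon=row.get("start_codon", "").strip() or None,
            stop_codon=row.get("stop_codon", "").strip() or None,
            intergenic_printed=int(printed) if printed not in ("", "NA") else None,
        ))
    return records


def compute_spacers(features: list[FeatureRecord],
                    genome_length: int | None = None,
                    circular: bool = True) -> list[SpacerRecord]:
    """One spacer per adjacent feature pair, plus the circular wrap pair.

    Requires features sorted by start.  When the table carries a printed
    intergenic column it is cross-checked against the recomputed value; on
    mismatch a warning is issued and the recomputed value wins.
    """
    if not features:
        return []
    for a, b in zip(features, features[1:]):
        if b.start < a.start:
            raise ValueError(
                f"features not sorted by start: {b.name} ({b.start}) follows "
                f"{a.name} ({a.start})")
    if genome_length is None:
        genome_length = max(f.end for f in features)
    spacers = []
    pairs = list(zip(features, features[1:]))
    for up, down in pairs:
        spacers.append(SpacerRecord(up.name, down.name,
                                    down.start - up.end - 1))
    if circular:
        first, last = features[0], features[-1]
        spacers.append(SpacerRecord(
            last.name, first.name,
            first.start + genome_length - last.end - 1, wrap=True))
    for feat, spacer in zip(features, spacers):
        if feat.intergenic_printed is not None \
                and feat.intergenic_printed != spacer.length:
            warnings.warn(
                f"printed intergenic value for {feat.name} "
                f"({feat.intergenic_printed}) disagrees with recomputed "
                f"{spacer.length}; using the recomputed value", stacklevel=2)
    return spacers


def summarize_annotation(features: list[FeatureRecord],
                         genome_length: int | None = None,
                         spacer_threshold: int = 50,
                         nc_threshold: int = 300) -> AnnotationSummary:
    """Genome organization summary: class/strand composition, intergenic
    spacers above a threshold, overlaps, and large noncoding regions."""
    if genome_length is None:
        genome_length = max(f.end for f in features)
    spacers = compute_spacers(features, genome_length)
    counts_by_class: dict[str, int] = {}
    counts_by_strand: dict[str, int] = {"H": 0, "L": 0}
    for f in features:
        counts_by_class[f.element_class] = counts_by_class.get(f.element_class, 0) + 1
        counts_by_strand[f.strand] += 1
    return AnnotationSummary(
        genome_length=genome_length,
        counts_by_class=counts_by_class,
        counts_by_strand=counts_by_strand,
        l_strand_features=[f.name for f in features if f.strand == "L"],
        spacers=spacers,
        spacer_threshold=spacer_threshold,
        nc_threshold=nc_threshold,
        n_positive_spacers=sum(1 for s in spacers if s.length > 0),
        n_long_spacers=sum(1 for s in spacers if s.length > spacer_threshold),
        n_overlaps=sum(1 for s in spacers if s.length < 0),
        large_noncoding=[f.name for f in features
                         if f.element_class in ("CR", "NC")
                         and f.size > nc_threshold],
    )


def order_from_annotation(features: list[FeatureRecord]) -> GeneOrder:
    """Bridge an annotation table to a :class:`GeneOrder`.

    Element labels are resolved against the gene vocabulary (CR1/CR2 map to
    the untagged and prime-tagged CR, primes mark duplicate copies) and
    strands are taken from the table, so the resulting order mirrors the
    file top to bottom.
    """
    elements = []
    for f in features:
        el = _parse_token(f.name)
        elements.append(el.__class__(
            label=el.label, strand=f.strand, element_class=el.element_class,
            copy_tag=el.copy_tag, ancestral_index=el.ancestral_index))
    return GeneOrder(tuple(elements), circular=True)


def features_from_genbank(source) -> list[FeatureRecord]:
    """Map an INSDC/GenBank flat file's feature table onto FeatureRecords.

    tRNA, rRNA, CDS and D-loop/misc_feature entries are kept; names come
    from gene/product qualifiers.  Coordinates are converted to 1-based
    inclusive.  Only simple (non-compound, non-origin-spanning) locations
    are supported.
    """
    from Bio import SeqIO

    record = next(SeqIO.parse(source, "genbank"))
    out: list[FeatureRecord] = []
    for feat in record.features:
        if feat.type not in ("tRNA", "rRNA", "CDS", "D-loop", "misc_feature"):
            continue
        cls = {"D-loop": "CR", "misc_feature": "NC"}.get(feat.type, feat.type)
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("product") or [feat.type])[0]
        out.append(FeatureRecord(
            name=name,
            start=int(feat.location.start) + 1,
            end=int(feat.location.end),
            strand="L" if feat.location.strand == -1 else "H",
            element_class=cls,
            anticodon=(quals.get("anticodon") or [None])[0],
        ))
    out.sort(key=lambda f: f.start)
    return out
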