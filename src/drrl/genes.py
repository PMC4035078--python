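"""Controlled vocabulary for vertebrate mitochondrial gene names.

The typical vertebrate mitogenome carries 37 genes (13 protein-coding, 22
tRNAs, 2 rRNAs) plus one major noncoding control region (CR).  Positions in
the typical order are numbered 1 (trnF) through 38 (CR); that numbering is
used throughout this package as the "ancestral index" of an element.

Serine and leucine tRNA paralogs follow the anticodon convention used for
flatfish mitogenomes: trnL1 = Leu(TAA), trnL2 = Leu(TAG), trnS1 = Ser(TGA),
trnS2 = Ser(GCT).  Cross-species imports must map anticodons, not letters.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GeneInfo:
    """Static description of one vocabulary entry."""

    label: str
    letter: str  # one-letter / compact name used in figures and tables
    ancestral_index: int  # 1..38 position in the typical vertebrate order
    element_class: str  # tRNA | rRNA | CDS | CR
    strand: str  # canonical strand, H or L


#: The typical vertebrate order, index 1..38.  Strand follows the vertebrate
#: consensus: ND6 and eight tRNAs (Q, A, N, C, Y, S1, E, P) sit on the
#: light strand; everything else on the heavy strand.
CANONICAL_TABLE: tuple[GeneInfo, ...] = (
    GeneInfo("trnF", "F", 1, "tRNA", "H"),
    GeneInfo("rrnS", "12S", 2, "rRNA", "H"),
    GeneInfo("trnV", "V", 3, "tRNA", "H"),
    GeneInfo("rrnL", "16S", 4, "rRNA", "H"),
    GeneInfo("trnL1", "L1", 5, "tRNA", "H"),
    GeneInfo("ND1", "ND1", 6, "CDS", "H"),
    GeneInfo("trnI", "I", 7, "tRNA", "H"),
    GeneInfo("trnQ", "Q", 8, "tRNA", "L"),
    GeneInfo("trnM", "M", 9, "tRNA", "H"),
    GeneInfo("ND2", "ND2", 10, "CDS", "H"),
    GeneInfo("trnW", "W", 11, "tRNA", "H"),
    GeneInfo("trnA", "A", 12, "tRNA", "L"),
    GeneInfo("trnN", "N", 13, "tRNA", "L"),
    GeneInfo("trnC", "C", 14, "tRNA", "L"),
    GeneInfo("trnY", "Y", 15, "tRNA", "L"),
    GeneInfo("COI", "COI", 16, "CDS", "H"),
    GeneInfo("trnS1", "S1", 17, "tRNA", "L"),
    GeneInfo("trnD", "D", 18, "tRNA", "H"),
    GeneInfo("COII", "COII", 19, "CDS", "H"),
    GeneInfo("trnK", "K", 20, "tRNA", "H"),
    GeneInfo("ATP8", "ATP8", 21, "CDS", "H"),
    GeneInfo("ATP6", "ATP6", 22, "CDS", "H"),
    GeneInfo("COIII", "COIII", 23, "CDS", "H"),
    GeneInfo("trnG", "G", 24, "tRNA", "H"),
    GeneInfo("ND3", "ND3", 25, "CDS", "H"),
    GeneInfo("trnR", "R", 26, "tRNA", "H"),
    GeneInfo("ND4L", "ND4L", 27, "CDS", "H"),
    GeneInfo("ND4", "ND4", 28, "CDS", "H"),
    GeneInfo("trnH", "H", 29, "tRNA", "H"),
    GeneInfo("trnS2", "S2", 30, "tRNA", "H"),
    GeneInfo("trnL2", "L2", 31, "tRNA", "H"),
    GeneInfo("ND5", "ND5", 32, "CDS", "H"),
    GeneInfo("ND6", "ND6", 33, "CDS", "L"),
    GeneInfo("trnE", "E", 34, "tRNA", "L"),
    GeneInfo("CYTB", "CYTB", 35, "CDS", "H"),
    GeneInfo("trnT", "T", 36, "tRNA", "H"),
    GeneInfo("trnP", "P", 37, "tRNA", "L"),
    GeneInfo("CR", "CR", 38, "CR", "H"),
)

BY_LABEL: dict[str, GeneInfo] = {g.label: g for g in CANONICAL_TABLE}
BY_INDEX: dict[int, GeneInfo] = {g.ancestral_index: g for g in CANONICAL_TABLE}

#: Accepted aliases, mapped onto vocabulary labels.  Letters, common
#: annotation spellings, and the numbered control regions all resolve here.
ALIASES: dict[str, str] = {}
for _g in CANONICAL_TABLE:
    ALIASES[_g.label.upper()] = _g.label
    ALIASES[_g.letter.upper()] = _g.label
ALIASES.update(
    {
        "12SRRNA": "rrnS",
        "16SRRNA": "rrnL",
        "RRN12": "rrnS",
        "RRN16": "rrnL",
        "S-RRNA": "rrnS",
        "L-RRNA": "rrnL",
        "COX1": "COI",
        "COX2": "COII",
        "COX3": "COIII",
        "CO1": "COI",
        "CO2": "COII",
        "CO3": "COIII",
        "NAD1": "ND1",
        "NAD2": "ND2",
        "NAD3": "ND3",
        "NAD4": "ND4",
        "NAD4L": "ND4L",
        "NAD5": "ND5",
        "NAD6": "ND6",
        "COB": "CYTB",
        "CYB": "CYTB",
        "D-LOOP": "CR",
        "OH": "CR",
        "CR1": "CR",
        "CRI": "CR",
    }
)
# CR2 / CRII denote the second (duplicated) control region copy.
DUPLICATE_CR_ALIASES = {"CR2", "CRII"}

#: Labels of remnant-class noncoding elements produced by CR degeneration.
NC_LABEL = "NC"
CR_REMNANT_LABEL = "CRII-remnant"


def resolve_label(token: str) -> str | None:
    """Map a raw token to a vocabulary label, or None if unknown."""
    return ALIASES.get(token.upper())
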