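"""Protein-level consequence of an exon-inclusion event.

Rebuilds the transcript with the extra exon spliced in, re-scans the open
reading frame from the original start codon, locates any premature
termination codon (PTC), applies the classical 50-nt rule (a stop codon
more than 50 nt upstream of the last exon-exon junction triggers
nonsense-mediated decay), and computes in-silico RT-PCR product lengths in
spliced coordinates so isoform-diagnostic assays can be designed.

Transcript coordinates are 0-based in transcription orientation; reported
PTC exon indices are 1-based over the modified exon chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .simulate import STOPS, revcomp

logger = logging.getLogger(__name__)

DEFAULT_RULE_DISTANCE = 50


@dataclass
class TranscriptModel:
    """An annotated transcript: ordered genomic exons plus a CDS given in
    transcript coordinates (start of ATG, end just past the stop codon)."""

    gene: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genomic 0-based half-open, sorted
    cds_start: int  # transcript coordinates
    cds_end: int

    def __post_init__(self):
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError("exons overlap")
            if e1 <= s1 or e2 <= s2:
                raise ValueError("empty exon")
        self.exons = ex
        tlen = sum(e - s for s, e in ex)
        if not (0 <= self.cds_start < self.cds_end <= tlen):
            raise ValueError("CDS outside transcript")
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError("CDS length not divisible by 3")

    @property
    def exons_tx_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        seq = "".join(genome[self.chrom][s:e] for s, e in self.exons)
        return seq if self.strand == "+" else revcomp(seq)

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class IsoformVariant:
    base: TranscriptModel
    inserted_exon: tuple[int, int] | None
    exons: list[tuple[int, int]]  # modified chain, genomic sorted
    spliced_sequence: str
    cds_start: int  # transcript coordinates in the modified isoform
    frame_shifted: bool
    ptc_transcript_pos: int | None = None
    ptc_exon_index: int | None = None  # 1-based, transcription order
    nmd_predicted: bool = False
    nonstop: bool = False
    last_junction_distance: int | None = None

    @property
    def strand(self) -> str:
        return self.base.strand

    @property
    def exons_tx_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    def transcript_pos_to_exon_index(self, tpos: int) -> int:
        cum = 0
        for i, (s, e) in enumerate(self.exons_tx_order, 1):
            cum += e - s
            if tpos < cum:
                return i
        raise ValueError(f"transcript position {tpos} outside transcript")


# --------------------------------------------------------------------------- splicing


def splice_isoform(
    model: TranscriptModel,
    insert: tuple[int, int] | None,
    genome: dict[str, str],
) -> IsoformVariant:
    """Insert an (unannotated) exon strictly inside one intron of the model.

    A zero-length or None insert reproduces the base transcript. The CDS
    start shifts by the insert length when the insert lands upstream of it
    in transcription order.
    """
    if insert is not None and insert[1] <= insert[0]:
        insert = None
    if insert is None:
        seq = model.spliced_sequence(genome)
        return IsoformVariant(
            model, None, list(model.exons), seq, model.cds_start, False
        )
    s, e = insert
    for xs, xe in model.exons:
        if s < xe and e > xs:
            raise ValueError(
                f"insert {insert} overlaps exon ({xs}, {xe}) of {model.gene}"
            )
    if not any(is_ < s and e < ie for is_, ie in model.introns()):
        raise ValueError(f"insert {insert} is not strictly inside one intron")
    exons = sorted(model.exons + [insert])
    chain = exons if model.strand == "+" else exons[::-1]
    seq = "".join(genome[model.chrom][a:b] for a, b in exons)
    if model.strand == "-":
        seq = revcomp(seq)
    # transcript offset of the insert in the modified chain
    off = 0
    for a, b in chain:
        if (a, b) == insert:
            break
        off += b - a
    ins_len = e - s
    cds_start = model.cds_start + (ins_len if off <= model.cds_start else 0)
    return IsoformVariant(
        model, insert, exons, seq, cds_start, ins_len % 3 != 0
    )


# --------------------------------------------------------------------------- PTC / NMD


def find_ptc(variant: IsoformVariant) -> IsoformVariant:
    """Scan the modified ORF from the original start codon.

    The first in-frame stop upstream of the original stop position (shifted
    by the insert length when the insert precedes it) is the PTC. If no stop
    occurs before the transcript end the variant is flagged nonstop.
    """
    seq = variant.spliced_sequence
    ins_len = (
        variant.inserted_exon[1] - variant.inserted_exon[0]
        if variant.inserted_exon
        else 0
    )
    base_stop = variant.base.cds_end - 3  # start of the annotated stop codon
    # position of the annotated stop in the modified transcript
    if variant.inserted_exon is not None:
        chain = variant.exons_tx_order
        off = 0
        for a, b in chain:
            if (a, b) == variant.inserted_exon:
                break
            off += b - a
        expected_stop = base_stop + (ins_len if off <= base_stop else 0)
    else:
        expected_stop = base_stop
    pos = variant.cds_start
    stop_at = None
    while pos + 3 <= len(seq):
        if seq[pos : pos + 3] in STOPS:
            stop_at = pos
            break
        pos += 3
    if stop_at is None:
        variant.nonstop = True
        variant.ptc_transcript_pos = None
        variant.ptc_exon_index = None
        return variant
    if stop_at >= expected_stop:
        variant.ptc_transcript_pos = None
        variant.ptc_exon_index = None
        return variant
    variant.ptc_transcript_pos = stop_at
    variant.ptc_exon_index = variant.transcript_pos_to_exon_index(stop_at)
    return variant


def predict_nmd(
    variant: IsoformVariant, rule_distance: int = DEFAULT_RULE_DISTANCE
) -> bool:
    """50-nt rule: NMD iff the PTC lies strictly more than ``rule_distance``
    nt upstream of the last exon-exon junction (measured from the start of
    the stop codon). Single-exon transcripts never trigger NMD."""
    if variant.ptc_transcript_pos is None:
        variant.nmd_predicted = False
        return False
    chain = variant.exons_tx_order
    if len(chain) < 2:
        variant.nmd_predicted = False
        variant.last_junction_distance = None
        return False
    tlen = len(variant.spliced_sequence)
    last_junction = tlen - (chain[-1][1] - chain[-1][0])
    dist = last_junction - variant.ptc_transcript_pos
    variant.last_junction_distance = dist
    variant.nmd_predicted = dist > rule_distance
    return variant.nmd_predicted


def analyze_inclusion(
    model: TranscriptModel,
    insert: tuple[int, int],
    genome: dict[str, str],
    rule_distance: int = DEFAULT_RULE_DISTANCE,
) -> IsoformVariant:
    """Full consequence chain: splice in the exon, find the PTC, apply NMD."""
    variant = splice_isoform(model, insert, genome)
    find_ptc(variant)
    predict_nmd(variant, rule_distance)
    return variant


# --------------------------------------------------------------------------- PCR


@dataclass
class PcrResult:
    isoform: str
    product_length: int | None
    reason: str = ""


def _map_interval(variant_exons_tx, strand, interval) -> tuple[int, int] | None:
    """Genomic interval -> transcript interval; None unless fully exonic in
    one exon (a primer spanning a junction has no contiguous genomic site)."""
    s, e = interval
    cum = 0
    for a, b in variant_exons_tx:
        L = b - a
        if a <= s and e <= b:
            if strand == "+":
                return (cum + (s - a), cum + (e - a))
            return (cum + (b - e), cum + (b - s))
        cum += L
    return None


def insilico_pcr(
    isoforms: dict[str, IsoformVariant],
    fwd_primer: tuple[int, int],
    rev_primer: tuple[int, int],
) -> dict[str, PcrResult]:
    """Product length per isoform for a primer pair.

    Primers are transcript-anchored genomic intervals. The product length is
    the inclusive spliced-coordinate distance from the forward primer's 5'
    end to the reverse primer's 5' end; isoforms lacking either site (or
    with the primers in the wrong orientation) yield no product.
    """
    out = {}
    for name, iso in isoforms.items():
        chain = iso.exons_tx_order
        fwd = _map_interval(chain, iso.strand, fwd_primer)
        rev = _map_interval(chain, iso.strand, rev_primer)
        if fwd is None or rev is None:
            out[name] = PcrResult(name, None, "primer site absent")
            continue
        if rev[0] <= fwd[0]:
            logger.info("primers in wrong orientation for isoform %s", name)
            out[name] = PcrResult(name, None, "wrong orientation")
            continue
        out[name] = PcrResult(name, rev[1] - fwd[0])
    return out
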