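"""Transcript annotation model and interval lookup.

Loads a GTF (gene/transcript/exon/CDS features with ``gene_id`` and
``transcript_id`` attributes) into lightweight gene/transcript records with
0-based half-open coordinates, and provides the strand-aware positional
queries used by cluster annotation and event discovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gffutils
from intervaltree import IntervalTree

#: Feature categories in decreasing annotation priority.
CATEGORY_PRIORITY = ("CDS", "5'UTR", "3'UTR", "noncoding_exon", "intron", "intergenic")
_PRIORITY_RANK = {c: i for i, c in enumerate(CATEGORY_PRIORITY)}


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # genomic, sorted
    cds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def classify_position(self, pos: int) -> str | None:
        """Category of a genomic position within this transcript, or None."""
        if not (self.start <= pos < self.end):
            return None
        for s, e in self.cds:
            if s <= pos < e:
                return "CDS"
        for s, e in self.exons:
            if s <= pos < e:
                if not self.cds:
                    return "noncoding_exon"
                cds_lo, cds_hi = self.cds[0][0], self.cds[-1][1]
                if pos < cds_lo:
                    return "5'UTR" if self.strand == "+" else "3'UTR"
                if pos >= cds_hi:
                    return "3'UTR" if self.strand == "+" else "5'UTR"
                return "noncoding_exon"  # exonic gap inside CDS span (unusual)
        return "intron"


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: dict[str, Transcript] = field(default_factory=dict)


class Annotation:
    """Gene models plus per-(chrom, strand) interval indexes."""

    def __init__(self, genes: dict[str, Gene]):
        self.genes = genes
        self._gene_index: dict[tuple[str, str], IntervalTree] = {}
        for g in genes.values():
            tree = self._gene_index.setdefault((g.chrom, g.strand), IntervalTree())
            if g.end > g.start:
                tree.addi(g.start, g.end, g.gene_id)

    @classmethod
    def from_gtf(cls, path: str) -> "Annotation":
        db = gffutils.create_db(
            str(path),
            ":memory:",
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        genes: dict[str, Gene] = {}
        transcripts: dict[str, Transcript] = {}
        for feat in db.all_features():
            gid = feat.attributes.get("gene_id", [None])[0]
            if feat.featuretype == "gene":
                genes[gid] = Gene(gid, feat.seqid, feat.strand, feat.start - 1, feat.end)
            elif feat.featuretype == "transcript":
                tid = feat.attributes["transcript_id"][0]
                transcripts[tid] = Transcript(tid, gid, feat.seqid, feat.strand)
            elif feat.featuretype in ("exon", "CDS"):
                tid = feat.attributes["transcript_id"][0]
                tx = transcripts.setdefault(
                    tid, Transcript(tid, gid, feat.seqid, feat.strand)
                )
                ival = (feat.start - 1, feat.end)
                (tx.exons if feat.featuretype == "exon" else tx.cds).append(ival)
        for tx in transcripts.values():
            tx.exons.sort()
            tx.cds.sort()
            gene = genes.get(tx.gene_id)
            if gene is None:
                gene = Gene(tx.gene_id, tx.chrom, tx.strand, tx.start, tx.end)
                genes[tx.gene_id] = gene
            gene.start = min(gene.start, tx.start)
            gene.end = max(gene.end, tx.end)
            gene.transcripts[tx.transcript_id] = tx
        return cls(genes)

    # ------------------------------------------------------------------ queries

    def genes_at(self, chrom: str, strand: str, pos: int) -> list[Gene]:
        tree = self._gene_index.get((chrom, strand))
        if tree is None:
            return []
        return [self.genes[iv.data] for iv in tree.at(pos)]

    def assign_gene(
        self, chrom: str, strand: str, start: int, end: int
    ) -> str | None:
        """Gene containing the interval midpoint on the same strand.

        Ties broken by longest overlap with [start, end), then gene_id.
        """
        mid = (start + end) // 2
        hits = self.genes_at(chrom, strand, mid)
        if not hits:
            return None
        def key(g: Gene):
            overlap = min(end, g.end) - max(start, g.start)
            return (-overlap, g.gene_id)
        return sorted(hits, key=key)[0].gene_id

    def classify_position(self, chrom: str, strand: str, pos: int) -> str:
        """Highest-priority feature category at a position (CDS > 5'UTR >
        3'UTR > noncoding_exon > intron > intergenic)."""
        if (chrom, strand) not in self._gene_index:
            warnings.warn(f"position on unknown chromosome/strand {chrom}{strand}")
            return "intergenic"
        best = "intergenic"
        for gene in self.genes_at(chrom, strand, pos):
            for tx in gene.transcripts.values():
                cat = tx.classify_position(pos)
                if cat is not None and _PRIORITY_RANK[cat] < _PRIORITY_RANK[best]:
                    best = cat
        return best

    def annotated_junctions(self) -> set[tuple[str, str, int, int]]:
        """All (chrom, strand, intron_start, intron_end) implied by exon chains."""
        out = set()
        for gene in self.genes.values():
            for tx in gene.transcripts.values():
                for s, e in tx.introns:
                    out.add((gene.chrom, gene.strand, s, e))
        return out
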