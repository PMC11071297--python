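"""PAR-CLIP binding-site calling from T-to-C conversion evidence.

The 4SU crosslinking chemistry leaves a diagnostic T-to-C substitution in
reads at protein-RNA contact sites. In transcript orientation that is a
reference-T read-C mismatch; for genes transcribed from the minus strand the
same event appears as reference-A read-G on the forward reference. All
counting here is strand-aware in that sense.

A binding site ("cluster") is a maximal run of overlapping same-strand reads
with enough read support, enough total T-to-C conversions, and a minimum
conversion specificity (conversions per covered T opportunity). This is a
deliberately simple, fully re-checkable replacement for kernel-density CLIP
peak callers: every emitted cluster satisfies its thresholds exactly, which
is what the downstream binding/expression/splicing integration needs.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import Annotation
from .simulate import revcomp

DEFAULT_MIN_BASE_QUALITY = 20
DEFAULT_MIN_READS = 5
DEFAULT_MIN_T2C = 2
# conversions per covered-T opportunity: true sites convert one T out of the
# ~8 a read covers, so even a fully converted site scores ~ rate/8; the
# default sits about twice above the spurious-conversion floor
# (background conversion + sequencing error / 3).
DEFAULT_MIN_SPECIFICITY = 0.01


@dataclass
class AlignedRead:
    """Gapless-per-block alignment with per-base reference context."""

    chrom: str
    strand: str
    start: int
    end: int
    seq: str
    # (query_pos, ref_pos, ref_base) for aligned (M) bases
    pairs: list[tuple[int, int, str]] = field(repr=False, default_factory=list)
    quals: list[int] = field(repr=False, default_factory=list)


@dataclass
class Cluster:
    chrom: str
    strand: str
    start: int
    end: int
    n_reads: int
    t2c_total: int
    conversion_specificity: float
    gene: str | None = None
    category: str | None = None
    sequence: str | None = None


@dataclass
class KmerStat:
    kmer: str
    target_freq: float
    background_freq: float
    log2_enrichment: float
    p_value: float
    q_value: float = 1.0


class ConversionProfile:
    """Per-position coverage and transcript-orientation T-to-C counts."""

    def __init__(self):
        # (chrom, strand) -> pos -> [coverage, t2c]
        self.counts: dict[tuple[str, str], dict[int, list[int]]] = defaultdict(
            lambda: defaultdict(lambda: [0, 0])
        )
        # positions whose transcript-orientation reference base is T
        self.t_positions: dict[tuple[str, str], set[int]] = defaultdict(set)

    def add(self, chrom, strand, pos, is_t, is_t2c) -> None:
        rec = self.counts[(chrom, strand)][pos]
        rec[0] += 1
        rec[1] += int(is_t2c)
        if is_t:
            self.t_positions[(chrom, strand)].add(pos)

    def coverage(self, chrom, strand, pos) -> int:
        return self.counts[(chrom, strand)].get(pos, [0, 0])[0]

    def t2c(self, chrom, strand, pos) -> int:
        return self.counts[(chrom, strand)].get(pos, [0, 0])[1]

    def region_stats(self, chrom, strand, start, end) -> tuple[int, int]:
        """(t2c_total, covered-T opportunities) over [start, end)."""
        d = self.counts[(chrom, strand)]
        tset = self.t_positions[(chrom, strand)]
        t2c = 0
        opp = 0
        for pos in range(start, end):
            rec = d.get(pos)
            if rec is None:
                continue
            t2c += rec[1]
            if pos in tset:
                opp += rec[0]
        return t2c, opp

    def gene_t2c_totals(self, annotation: Annotation) -> pd.Series:
        """Per-gene sum of T-to-C conversions (strand-matched containment)."""
        totals: dict[str, int] = defaultdict(int)
        for (chrom, strand), d in self.counts.items():
            for pos, (_, t2c) in d.items():
                if not t2c:
                    continue
                for gene in annotation.genes_at(chrom, strand, pos):
                    totals[gene.gene_id] += t2c
        return pd.Series(totals, dtype=float)


# --------------------------------------------------------------------------- reading


def read_alignments(
    sam_path,
    genome: dict[str, str] | None = None,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    dedup: bool = True,
) -> list[AlignedRead]:
    """Load mapped reads; PCR duplicates (same chrom/strand/start/sequence)
    are collapsed when ``dedup`` is set."""
    reads = []
    seen = set()
    with pysam.AlignmentFile(str(sam_path), "r") as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            strand = "-" if rec.is_reverse else "+"
            key = (rec.reference_name, strand, rec.reference_start, rec.query_sequence)
            if dedup:
                if key in seen:
                    continue
                seen.add(key)
            pairs = _aligned_pairs(rec, genome)
            quals = (
                list(rec.query_qualities)
                if rec.query_qualities is not None
                else [255] * len(rec.query_sequence)
            )
            keep = [
                (q, r, b) for q, r, b in pairs if quals[q] >= min_base_quality
            ]
            reads.append(
                AlignedRead(
                    rec.reference_name,
                    strand,
                    rec.reference_start,
                    rec.reference_end,
                    rec.query_sequence,
                    keep,
                    quals,
                )
            )
    return reads


def _aligned_pairs(rec, genome) -> list[tuple[int, int, str]]:
    try:
        raw = rec.get_aligned_pairs(matches_only=True, with_seq=True)
        return [(q, r, b.upper()) for q, r, b in raw]
    except ValueError:
        if genome is None:
            raise ValueError(
                f"read {rec.query_name} lacks an MD tag and no genome was "
                "supplied; cannot recover reference bases"
            ) from None
        ref = genome[rec.reference_name]
        return [
            (q, r, ref[r])
            for q, r in rec.get_aligned_pairs(matches_only=True)
        ]


def build_conversion_profile(
    source,
    genome: dict[str, str] | None = None,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> ConversionProfile:
    """Strand-aware conversion profile from a SAM path or AlignedRead list."""
    if not isinstance(source, list):
        source = read_alignments(source, genome, min_base_quality)
    profile = ConversionProfile()
    for read in source:
        t_ref, c_read = ("T", "C") if read.strand == "+" else ("A", "G")
        for q, r, ref_base in read.pairs:
            is_t = ref_base == t_ref
            is_t2c = is_t and read.seq[q] == c_read
            profile.add(read.chrom, read.strand, r, is_t, is_t2c)
    return profile


# --------------------------------------------------------------------------- calling


def call_clusters(
    profile: ConversionProfile,
    reads: list[AlignedRead],
    min_reads: int = DEFAULT_MIN_READS,
    min_t2c: int = DEFAULT_MIN_T2C,
    min_specificity: float = DEFAULT_MIN_SPECIFICITY,
) -> list[Cluster]:
    """Emit maximal read-overlap regions passing all three thresholds.

    Regions separated by at least one uncovered base are distinct; reads
    sharing only a boundary (zero uncovered bases between them) fall in the
    same region. Input read order does not matter.
    """
    clusters = []
    by_key: dict[tuple[str, str], list[AlignedRead]] = defaultdict(list)
    for read in reads:
        by_key[(read.chrom, read.strand)].append(read)
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda r: (r.start, r.end))
        cur: list[AlignedRead] = []
        cur_end = -1
        for read in group + [None]:
            if read is not None and (not cur or read.start <= cur_end):
                cur.append(read)
                cur_end = max(cur_end, read.end)
                continue
            if cur:
                start = cur[0].start
                t2c, opp = profile.region_stats(chrom, strand, start, cur_end)
                spec = t2c / opp if opp else 0.0
                if len(cur) >= min_reads and t2c >= min_t2c and spec >= min_specificity:
                    clusters.append(
                        Cluster(chrom, strand, start, cur_end, len(cur), t2c, spec)
                    )
            if read is not None:
                cur = [read]
                cur_end = read.end
    return clusters


def annotate_clusters(
    clusters: list[Cluster],
    annotation: Annotation,
    genome: dict[str, str] | None = None,
) -> tuple[list[Cluster], dict[str, float]]:
    """Assign each cluster a gene and one feature category by its midpoint.

    Categories follow the fixed priority CDS > 5'UTR > 3'UTR >
    noncoding_exon > intron > intergenic, so fractions over all clusters sum
    to one. If a genome is given, cluster sequences (transcript orientation)
    are attached for k-mer analysis.
    """
    frac: dict[str, float] = defaultdict(float)
    for cl in clusters:
        mid = (cl.start + cl.end) // 2
        cl.category = annotation.classify_position(cl.chrom, cl.strand, mid)
        cl.gene = annotation.assign_gene(cl.chrom, cl.strand, cl.start, cl.end)
        if genome is not None:
            seq = genome[cl.chrom][cl.start : cl.end]
            cl.sequence = seq if cl.strand == "+" else revcomp(seq)
        frac[cl.category] += 1
    if clusters:
        for k in frac:
            frac[k] /= len(clusters)
    return clusters, dict(frac)


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "gene": c.gene,
                "score": c.t2c_total,
                "strand": c.strand,
                "n_reads": c.n_reads,
                "specificity": round(c.conversion_specificity, 4),
                "category": c.category,
            }
            for c in clusters
        ]
    )


# --------------------------------------------------------------------------- replicates


def replicate_correlation(
    profiles: list[ConversionProfile], annotation: Annotation
) -> pd.DataFrame:
    """Pairwise Spearman rho between replicates on per-gene T-to-C totals."""
    if len(profiles) < 2:
        raise ValueError("need at least two replicate profiles")
    mat = pd.DataFrame(
        {i + 1: p.gene_t2c_totals(annotation) for i, p in enumerate(profiles)}
    ).fillna(0.0)
    if (mat.sum(axis=1) > 0).sum() < 2:
        raise ValueError("fewer than two genes with nonzero conversion counts")
    rows = []
    for a, b in itertools.combinations(mat.columns, 2):
        rho, p = stats.spearmanr(mat[a], mat[b])
        rows.append({"rep_a": a, "rep_b": b, "rho": rho, "p_value": p})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- k-mers


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erikson shuffle preserving exact dinucleotide counts."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    vertices = [v for v in edges if v != last]
    # choose a random last-edge per vertex forming a tree into the final vertex
    for _ in range(200):
        last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        if _reaches_all(last_edge, last):
            break
    else:  # pragma: no cover - tiny alphabets converge fast
        return seq
    out = [seq[0]]
    remaining: dict[str, list[str]] = {}
    for v, targets in edges.items():
        pool = list(targets)
        if v in last_edge:
            pool.remove(last_edge[v])
        rng.shuffle(pool)
        if v in last_edge:
            pool.append(last_edge[v])
        remaining[v] = pool
    cur = seq[0]
    while remaining.get(cur):
        nxt = remaining[cur].pop(0)
        out.append(nxt)
        cur = nxt
    return "".join(out)


def _reaches_all(last_edge: dict[str, str], sink: str) -> bool:
    for v in last_edge:
        seen = set()
        cur = v
        while cur != sink:
            if cur in seen or cur not in last_edge:
                return False
            seen.add(cur)
            cur = last_edge[cur]
    return True


def _kmer_counts(seqs: list[str], k: int) -> tuple[dict[str, int], int, int]:
    counts: dict[str, int] = defaultdict(int)
    total = 0
    skipped = 0
    for s in seqs:
        if len(s) < k:
            skipped += 1
            continue
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if "N" in kmer:
                continue
            counts[kmer] += 1
            total += 1
    return counts, total, skipped


def kmer_enrichment(
    clusters: list[Cluster],
    genome: dict[str, str] | None = None,
    k: int = 5,
    background: str = "shuffled",
    n_shuffles: int = 20,
    flank: int = 200,
    seed: int = 0,
) -> tuple[list[KmerStat], int]:
    """k-mer enrichment of cluster sequences against a matched background.

    Background is either each cluster sequence dinucleotide-shuffled
    ``n_shuffles`` times (default) or same-length flanking sequence. Each
    k-mer's target count is tested against the background frequency with a
    two-sided binomial tail test (2 x min tail, capped at 1), BH-corrected,
    sorted by decreasing enrichment. Returns (stats, n_skipped_short).
    """
    rng = np.random.default_rng(seed)
    seqs = []
    for cl in clusters:
        if cl.sequence is None:
            if genome is None:
                raise ValueError("clusters lack sequences and no genome given")
            s = genome[cl.chrom][cl.start : cl.end]
            cl.sequence = s if cl.strand == "+" else revcomp(s)
        seqs.append(cl.sequence)
    if background == "shuffled":
        bg_seqs = [
            dinucleotide_shuffle(s, rng) for s in seqs for _ in range(n_shuffles)
        ]
    elif background == "flanking":
        if genome is None:
            raise ValueError("flanking background requires a genome")
        bg_seqs = []
        for cl in clusters:
            chromseq = genome[cl.chrom]
            left = chromseq[max(0, cl.start - flank) : cl.start]
            right = chromseq[cl.end : cl.end + flank]
            s = left + right
            bg_seqs.append(s if cl.strand == "+" else revcomp(s))
    else:
        raise ValueError(f"unknown background {background!r}")

    tgt, tgt_total, skipped = _kmer_counts(seqs, k)
    bg, bg_total, _ = _kmer_counts(bg_seqs, k)
    if tgt_total == 0:
        return [], skipped
    kmers = sorted(set(tgt) | set(bg))
    x = np.array([tgt.get(km, 0) for km in kmers])
    p0 = np.array(
        [
            min(max(bg.get(km, 0) / bg_total if bg_total else 0.0, 0.5 / (bg_total + 1)), 1.0 - 1e-12)
            for km in kmers
        ]
    )
    upper = stats.binom.sf(x - 1, tgt_total, p0)
    lower = stats.binom.cdf(x, tgt_total, p0)
    pvals = np.minimum(1.0, 2.0 * np.minimum(upper, lower))
    stats_out = []
    eps = 0.5 / tgt_total
    for km, xi, pi, pv in zip(kmers, x, p0, pvals):
        tf = xi / tgt_total
        bf = bg.get(km, 0) / bg_total if bg_total else 0.0
        stats_out.append(
            KmerStat(km, tf, bf, math.log2((tf + eps) / (bf + eps)), float(pv))
        )
    qvals = multipletests([s.p_value for s in stats_out], method="fdr_bh")[1]
    for s, q in zip(stats_out, qvals):
        s.q_value = max(float(q), s.p_value)
    stats_out.sort(key=lambda s: (-s.log2_enrichment, s.kmer))
    return stats_out, skipped
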