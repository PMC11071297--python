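"""Junction-based alternative-splicing analysis.

Junctions are extracted from spliced (N-containing CIGAR) alignments with a
minimum anchor on both sides, pooled across samples, and combined with the
annotation to discover and classify events: skipped exons (SE, including
*novel* exons implied by a pair of unannotated junctions strictly inside an
annotated intron), retained introns (RI), mutually exclusive exons (MXE) and
alternative 5'/3' splice sites (A5SS/A3SS). Inclusion levels (PSI) come from
junction counts; differential inclusion between conditions is a two-sided
Fisher exact test on pooled inclusion/skipping counts with BH correction — a
deliberately simple, exact replacement for replicate-aware likelihood
models, adequate at the scale this package targets.

Coordinates are genomic 0-based half-open; a junction's ``donor`` and
``acceptor`` are the left and right intron boundaries on the forward strand
(biological donor/acceptor swap roles on minus-strand genes, which the
A5SS/A3SS classification accounts for).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pysam
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import Annotation

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERHANG = 6
DEFAULT_MIN_JUNCTION_COUNT = 2
DEFAULT_MAX_Q = 0.05
DEFAULT_MIN_DELTA_PSI = 0.1

#: inclusion / skipping junction multiplicities per event type, used to
#: normalize PSI (an SE inclusion is supported by two junctions, etc.)
EVENT_JUNCTION_ARITY = {
    "SE": (2, 1),
    "RI": (2, 1),
    "MXE": (2, 2),
    "A5SS": (1, 1),
    "A3SS": (1, 1),
}


@dataclass
class Junction:
    chrom: str
    strand: str
    donor: int  # intron start (genomic left)
    acceptor: int  # intron end (genomic right)
    counts: dict[str, int] = field(default_factory=dict)
    annotated: bool = False

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class SpliceEvent:
    event_type: str
    gene: str | None
    chrom: str
    strand: str
    region: tuple[int, int]  # alternative exon / intron / extension
    inclusion_junctions: list[tuple[int, int]]
    skipping_junctions: list[tuple[int, int]]
    inclusion_counts: dict[str, int] = field(default_factory=dict)
    skipping_counts: dict[str, int] = field(default_factory=dict)
    psi: dict[str, float | None] = field(default_factory=dict)
    delta_psi: float | None = None
    p_value: float | None = None
    q_value: float | None = None
    novel: bool = False
    flank_upstream: tuple[int, int] | None = None  # transcription order
    flank_downstream: tuple[int, int] | None = None

    @property
    def exon_length(self) -> int:
        return self.region[1] - self.region[0]


# --------------------------------------------------------------------------- extraction


def extract_junctions(
    sam_path, min_overhang: int = DEFAULT_MIN_OVERHANG
) -> Counter:
    """Junction counts for one sample.

    Keys are (chrom, strand, donor, acceptor). A read supports a junction
    only if the aligned blocks on both sides of the gap are at least
    ``min_overhang`` nt long.
    """
    counts: Counter = Counter()
    with pysam.AlignmentFile(str(sam_path), "r") as fh:
        for rec in fh:
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            strand = "-" if rec.is_reverse else "+"
            pos = rec.reference_start
            blocks = []  # (op, ref_len)
            for op, ln in rec.cigartuples:
                if op in (0, 7, 8):  # M/=/X
                    blocks.append(("M", pos, pos + ln))
                    pos += ln
                elif op == 3:  # N
                    blocks.append(("N", pos, pos + ln))
                    pos += ln
                elif op == 2:  # D
                    pos += ln
            for i, (op, s, e) in enumerate(blocks):
                if op != "N":
                    continue
                left = blocks[i - 1][2] - blocks[i - 1][1] if i > 0 else 0
                right = (
                    blocks[i + 1][2] - blocks[i + 1][1]
                    if i + 1 < len(blocks)
                    else 0
                )
                if left >= min_overhang and right >= min_overhang:
                    counts[(rec.reference_name, strand, s, e)] += 1
    return counts


def merge_junctions(
    per_sample: dict[str, Counter], annotation: Annotation | None = None
) -> list[Junction]:
    """Combine per-sample junction counts into Junction records."""
    annotated = annotation.annotated_junctions() if annotation else set()
    merged: dict[tuple, Junction] = {}
    for sample, counts in per_sample.items():
        for key, n in counts.items():
            j = merged.get(key)
            if j is None:
                chrom, strand, d, a = key
                j = Junction(chrom, strand, d, a, {}, key in annotated)
                merged[key] = j
            j.counts[sample] = j.counts.get(sample, 0) + n
    for j in merged.values():
        for sample in per_sample:
            j.counts.setdefault(sample, 0)
    return sorted(
        merged.values(), key=lambda j: (j.chrom, j.strand, j.donor, j.acceptor)
    )


# --------------------------------------------------------------------------- discovery


def _is_canonical(genome, chrom, strand, donor, acceptor) -> bool:
    """GT..AG intron dinucleotides in transcript orientation."""
    seq = genome[chrom]
    if strand == "+":
        return seq[donor : donor + 2] == "GT" and seq[acceptor - 2 : acceptor] == "AG"
    return seq[acceptor - 2 : acceptor] == "AC" and seq[donor : donor + 2] == "CT"


def discover_events(
    junctions: list[Junction],
    annotation: Annotation,
    genome: dict[str, str] | None = None,
    samples: dict[str, str] | None = None,
    min_count: int = DEFAULT_MIN_JUNCTION_COUNT,
) -> list[SpliceEvent]:
    """Classify splicing events from junction evidence plus the annotation.

    ``samples`` (sample name -> SAM path) enables retained-intron detection,
    which needs intron-body coverage and unspliced boundary-spanning read
    counts in addition to junctions. When a genome is supplied, novel-exon
    calls additionally require canonical GT-AG dinucleotides on both implied
    introns.
    """
    jn = [j for j in junctions if j.total >= min_count]
    by_key = defaultdict(list)
    for j in jn:
        by_key[(j.chrom, j.strand)].append(j)
    events: list[SpliceEvent] = []
    for (chrom, strand), group in sorted(by_key.items()):
        jset = {(j.donor, j.acceptor): j for j in group}
        events += _find_se(chrom, strand, jset, annotation, genome)
        events += _find_mxe(chrom, strand, jset, annotation)
        events += _find_alt_ss(chrom, strand, jset, annotation)
    if samples:
        events += _find_ri(junctions, annotation, samples, min_count)
    sample_names = set()
    for j in junctions:
        sample_names.update(j.counts)
    for ev in events:
        _fill_counts(ev, junctions, sample_names)
        ev.psi = compute_psi(ev)
        _orient_flanks(ev, annotation)
    events.sort(key=lambda e: (e.chrom, e.strand, e.region))
    return events


def _exon_catalog(annotation, chrom, strand):
    exons = set()
    introns = []
    for gene in annotation.genes.values():
        if gene.chrom != chrom or gene.strand != strand:
            continue
        for tx in gene.transcripts.values():
            exons.update(tx.exons)
            introns.extend(tx.introns)
    return exons, introns


def _find_se(chrom, strand, jset, annotation, genome):
    exons, introns = _exon_catalog(annotation, chrom, strand)
    events = []
    seen = set()
    for (d, a), skip in jset.items():
        # annotated-exon skipping: junctions d->xs and xe->a around exon (xs, xe)
        for xs, xe in exons:
            if d < xs and xe < a and (d, xs) in jset and (xe, a) in jset:
                key = ("SE", xs, xe)
                if key in seen:
                    continue
                seen.add(key)
                events.append(
                    SpliceEvent(
                        "SE",
                        annotation.assign_gene(chrom, strand, xs, xe),
                        chrom,
                        strand,
                        (xs, xe),
                        [(d, xs), (xe, a)],
                        [(d, a)],
                    )
                )
    # novel exon: unannotated junction pair implying an exon inside an intron
    unann = [
        (d, a) for (d, a), j in jset.items() if not j.annotated
    ]
    for d1, a1 in unann:
        for d2, a2 in unann:
            if (d1, a1) == (d2, a2) or d2 <= a1:
                continue
            xs, xe = a1, d2
            if xe - xs <= 0:
                logger.warning(
                    "discarding junction pair with non-positive implied exon "
                    "length at %s:%d-%d",
                    chrom,
                    a1,
                    d2,
                )
                continue
            if (xs, xe) in exons:
                continue
            hosted = any(i_s < xs and xe < i_e for i_s, i_e in introns)
            if not hosted:
                continue
            if genome is not None and not (
                _is_canonical(genome, chrom, strand, d1, a1)
                and _is_canonical(genome, chrom, strand, d2, a2)
            ):
                continue
            key = ("SE", xs, xe)
            if key in {("SE", e.region[0], e.region[1]) for e in events}:
                continue
            events.append(
                SpliceEvent(
                    "SE",
                    annotation.assign_gene(chrom, strand, xs, xe),
                    chrom,
                    strand,
                    (xs, xe),
                    [(d1, a1), (d2, a2)],
                    [(d1, a2)],
                    novel=True,
                )
            )
    return events


def _find_mxe(chrom, strand, jset, annotation):
    events = []
    by_donor = defaultdict(list)
    by_acceptor = defaultdict(list)
    for d, a in jset:
        by_donor[d].append(a)
        by_acceptor[a].append(d)
    seen = set()
    for d, accs in by_donor.items():
        for s1 in sorted(accs):
            for s2 in sorted(accs):
                if s2 <= s1:
                    continue
                # exon 1 = (s1, e1) with junction (e1, a); exon 2 = (s2, e2), (e2, a)
                cands1 = [(dd, aa) for (dd, aa) in jset if s1 < dd < s2 and aa > s2]
                for e1, a in cands1:
                    cands2 = [
                        (dd, aa)
                        for (dd, aa) in jset
                        if dd >= s2 and dd < a and aa == a
                    ]
                    for e2, _ in cands2:
                        if e2 <= s2 or e2 >= a:
                            continue
                        if (d, a) in jset or (e1, s2) in jset:
                            continue  # skip-junction or X1->X2: not mutually exclusive
                        key = (d, s1, e1, s2, e2, a)
                        if key in seen:
                            continue
                        seen.add(key)
                        events.append(
                            SpliceEvent(
                                "MXE",
                                annotation.assign_gene(chrom, strand, s1, e2),
                                chrom,
                                strand,
                                (s1, e1),
                                [(d, s1), (e1, a)],
                                [(d, s2), (e2, a)],
                                flank_upstream=None,
                            )
                        )
    return events


def _find_alt_ss(chrom, strand, jset, annotation):
    events = []
    by_acceptor = defaultdict(list)
    by_donor = defaultdict(list)
    for d, a in jset:
        by_acceptor[a].append(d)
        by_donor[d].append(a)
    # shared acceptor (right edge), alternative left boundary
    for a, donors in by_acceptor.items():
        donors = sorted(donors)
        for i in range(len(donors) - 1):
            d1, d2 = donors[i], donors[i + 1]
            # an exon between d1 and d2 means SE, not an alternative boundary
            if any(d1 <= aa <= d2 for (dd, aa) in jset if dd <= d1):
                continue
            etype = "A5SS" if strand == "+" else "A3SS"
            events.append(
                SpliceEvent(
                    etype,
                    annotation.assign_gene(chrom, strand, d1, d2),
                    chrom,
                    strand,
                    (d1, d2),
                    [(d2, a)],  # longer exon, shorter intron = inclusion
                    [(d1, a)],
                )
            )
    # shared donor (left edge), alternative right boundary
    for d, accs in by_donor.items():
        accs = sorted(accs)
        for i in range(len(accs) - 1):
            a1, a2 = accs[i], accs[i + 1]
            if any(a1 <= dd <= a2 for (dd, aa) in jset if aa >= a2):
                continue
            etype = "A3SS" if strand == "+" else "A5SS"
            events.append(
                SpliceEvent(
                    etype,
                    annotation.assign_gene(chrom, strand, a1, a2),
                    chrom,
                    strand,
                    (a1, a2),
                    [(d, a1)],
                    [(d, a2)],
                )
            )
    return events


def _find_ri(junctions, annotation, samples, min_count, cov_ratio=0.5):
    """Retained introns: annotated intron with a spliced junction whose body
    coverage reaches ``cov_ratio`` of flanking-exon coverage in >=1 sample."""
    candidates = []
    jmap = {(j.chrom, j.strand, j.donor, j.acceptor): j for j in junctions}
    for gene in annotation.genes.values():
        for tx in gene.transcripts.values():
            for k, (d, a) in enumerate(tx.introns):
                j = jmap.get((gene.chrom, gene.strand, d, a))
                if j is None or j.total < min_count:
                    continue
                candidates.append(
                    (gene, (d, a), tx.exons[k], tx.exons[k + 1], j)
                )
    if not candidates:
        return []
    # per-sample coverage + unspliced boundary-spanning counts
    stats_per = {
        name: _scan_retention(
            path, [(c[0].chrom, c[1], c[2], c[3]) for c in candidates]
        )
        for name, path in samples.items()
    }
    events = []
    seen = set()
    for gene, intron, exl, exr, j in candidates:
        if intron in seen:
            continue
        seen.add(intron)
        retained = False
        boundary_counts = {}
        for name in samples:
            span, intron_cov, flank_cov = stats_per[name][intron]
            boundary_counts[name] = span
            if flank_cov > 0 and intron_cov >= cov_ratio * flank_cov:
                retained = True
        if not retained:
            continue
        ev = SpliceEvent(
            "RI",
            gene.gene_id,
            gene.chrom,
            gene.strand,
            intron,
            [],  # inclusion evidence is unspliced boundary reads
            [intron],
        )
        ev.inclusion_counts = boundary_counts
        events.append(ev)
    return events


def _scan_retention(sam_path, candidates, min_overhang=DEFAULT_MIN_OVERHANG):
    """For each (chrom, intron, left_exon, right_exon): (#unspliced reads
    spanning a boundary, median intron coverage, median flanking-exon
    coverage)."""
    candidates = sorted(set(candidates))
    out = {}
    cov: dict[str, np.ndarray] = {}
    spans = Counter()
    boundaries = [iv for _, iv, _, _ in candidates]
    with pysam.AlignmentFile(str(sam_path), "r") as fh:
        for name, length in zip(fh.references, fh.lengths):
            cov[name] = np.zeros(length + 1, dtype=np.int32)
        for rec in fh:
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            diff = cov[rec.reference_name]
            pos = rec.reference_start
            for op, ln in rec.cigartuples:
                if op in (0, 7, 8):
                    diff[pos] += 1  # difference array; prefix-summed below
                    diff[pos + ln] -= 1
                    for d, a in boundaries:
                        for b in (d, a):
                            if pos + min_overhang <= b <= pos + ln - min_overhang:
                                spans[(d, a)] += 1
                    pos += ln
                elif op in (2, 3):
                    pos += ln
    cov = {name: np.cumsum(diff)[:-1] for name, diff in cov.items()}
    for chrom, (d, a), exl, exr in candidates:
        c = cov[chrom]
        intron_cov = float(np.median(c[d:a]))
        flank = np.concatenate([c[s:e] for s, e in (exl, exr)])
        flank_cov = float(np.median(flank))
        out[(d, a)] = (spans[(d, a)], intron_cov, flank_cov)
    return out


def _fill_counts(ev: SpliceEvent, junctions, sample_names) -> None:
    jmap = {(j.chrom, j.strand, j.donor, j.acceptor): j for j in junctions}
    for sample in sample_names:
        inc = sum(
            jmap.get((ev.chrom, ev.strand, d, a), Junction(ev.chrom, ev.strand, d, a))
            .counts.get(sample, 0)
            for d, a in ev.inclusion_junctions
        )
        skip = sum(
            jmap.get((ev.chrom, ev.strand, d, a), Junction(ev.chrom, ev.strand, d, a))
            .counts.get(sample, 0)
            for d, a in ev.skipping_junctions
        )
        if ev.event_type == "RI":
            ev.inclusion_counts.setdefault(sample, 0)
        else:
            ev.inclusion_counts[sample] = inc
        ev.skipping_counts[sample] = skip


def _orient_flanks(ev: SpliceEvent, annotation: Annotation) -> None:
    """Attach the transcription-order upstream/downstream neighbor exons."""
    if ev.gene is None:
        return
    gene = annotation.genes.get(ev.gene)
    if gene is None:
        return
    exons = sorted({e for tx in gene.transcripts.values() for e in tx.exons})
    left = [e for e in exons if e[1] <= ev.region[0]]
    right = [e for e in exons if e[0] >= ev.region[1]]
    g_left = left[-1] if left else None
    g_right = right[0] if right else None
    if ev.strand == "+":
        ev.flank_upstream, ev.flank_downstream = g_left, g_right
    else:
        ev.flank_upstream, ev.flank_downstream = g_right, g_left


# --------------------------------------------------------------------------- psi / testing


def compute_psi(ev: SpliceEvent) -> dict[str, float | None]:
    """Per-sample PSI from junction counts.

    Inclusion counts are divided by the number of supporting junctions (two
    for SE/RI/MXE inclusion) so that one included molecule contributes one
    unit of evidence: psi = (I/n_i) / (I/n_i + S/n_s). Undefined (None) when
    there is no evidence at all.
    """
    n_i, n_s = EVENT_JUNCTION_ARITY[ev.event_type]
    psi = {}
    for sample in sorted(set(ev.inclusion_counts) | set(ev.skipping_counts)):
        i = ev.inclusion_counts.get(sample, 0) / n_i
        s = ev.skipping_counts.get(sample, 0) / n_s
        psi[sample] = i / (i + s) if (i + s) > 0 else None
    return psi


def test_differential(
    events: list[SpliceEvent],
    condition_map: dict[str, str],
    max_q: float = DEFAULT_MAX_Q,
    min_delta_psi: float = DEFAULT_MIN_DELTA_PSI,
) -> list[SpliceEvent]:
    """Fisher exact test (KO vs WT pooled counts) per event, BH-corrected.

    delta_psi is KO minus WT pooled PSI. Returns the input events with
    p_value, q_value and delta_psi filled in.
    """
    conds = set(condition_map.values())
    if conds != {"ko", "wt"}:
        raise ValueError(f"condition map must assign 'ko'/'wt', got {conds}")
    pvals = []
    for ev in events:
        n_i, n_s = EVENT_JUNCTION_ARITY[ev.event_type]
        pooled = {}
        for cond in ("ko", "wt"):
            names = [s for s, c in condition_map.items() if c == cond]
            i = sum(ev.inclusion_counts.get(s, 0) for s in names)
            k = sum(ev.skipping_counts.get(s, 0) for s in names)
            pooled[cond] = (i, k)
        table = [list(pooled["ko"]), list(pooled["wt"])]
        if sum(pooled["ko"]) + sum(pooled["wt"]) == 0:
            ev.p_value = 1.0
        else:
            ev.p_value = float(stats.fisher_exact(table, "two-sided")[1])
        psis = {}
        for cond, (i, k) in pooled.items():
            i_n, k_n = i / n_i, k / n_s
            psis[cond] = i_n / (i_n + k_n) if (i_n + k_n) > 0 else None
        if psis["ko"] is not None and psis["wt"] is not None:
            ev.delta_psi = psis["ko"] - psis["wt"]
        pvals.append(ev.p_value)
    if events:
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for ev, q in zip(events, qvals):
            ev.q_value = max(float(q), ev.p_value) if ev.p_value is not None else None
    return events


def significant_events(
    events: list[SpliceEvent],
    max_q: float = DEFAULT_MAX_Q,
    min_delta_psi: float = DEFAULT_MIN_DELTA_PSI,
) -> list[SpliceEvent]:
    return [
        ev
        for ev in events
        if ev.q_value is not None
        and ev.q_value < max_q
        and ev.delta_psi is not None
        and abs(ev.delta_psi) >= min_delta_psi
    ]


def event_census(events: list[SpliceEvent]) -> dict[str, int]:
    census = Counter(ev.event_type for ev in events)
    return dict(sorted(census.items()))
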