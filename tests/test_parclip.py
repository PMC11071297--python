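"""Cluster-calling tests: conversion profiling against a naive recount,
threshold gates, annotation categories, replicate statistics and k-mer
enrichment."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clipsplice.parclip as pc
from clipsplice.parclip import (
    AlignedRead,
    ConversionProfile,
    build_conversion_profile,
    call_clusters,
    dinucleotide_shuffle,
    kmer_enrichment,
    read_alignments,
    replicate_correlation,
)


def _make_read(chrom, strand, start, seq, ref):
    pairs = [(i, start + i, ref[i]) for i in range(len(seq))]
    return AlignedRead(chrom, strand, start, start + len(seq), seq, pairs, [40] * len(seq))


def _write_sam(path, chrom_len, records):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "c1", "LN": chrom_len}]}
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, (flag, pos, cigar, seq, md) in enumerate(records):
            a = pysam.AlignedSegment(header)
            a.query_name = f"r{i}"
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 255
            a.cigarstring = cigar
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.set_tags([("MD", md)])
            out.write(a)


def test_profile_counts_direct_fixture(tmp_path):
    """10 reads over one position, 7 carrying T->C: coverage 10, t2c 7."""
    sam = tmp_path / "t.sam"
    recs = []
    for i in range(10):
        seq = "ACTG"
        md = "4"
        if i < 7:
            seq = "ACCG"  # position 2 is ref T read C
            md = "2T1"
        recs.append((0, 100, "4M", seq, md))
    _write_sam(sam, 1000, recs)
    profile = build_conversion_profile(read_alignments(str(sam), dedup=False))
    assert profile.coverage("c1", "+", 102) == 10
    assert profile.t2c("c1", "+", 102) == 7
    # identical reads collapse to two distinct molecules under the PCR guard
    dedup = build_conversion_profile(str(sam))
    assert dedup.coverage("c1", "+", 102) == 2


def test_minus_strand_a_to_g_counts_as_t2c(tmp_path):
    sam = tmp_path / "t.sam"
    # reference AATA, read AGTA at pos 1: ref A -> read G on a reverse read
    _write_sam(sam, 1000, [(16, 50, "4M", "AGTA", "1A2")])
    profile = build_conversion_profile(str(sam))
    assert profile.t2c("c1", "-", 51) == 1
    assert profile.t2c("c1", "+", 51) == 0


def test_missing_md_without_genome_is_hard_error(tmp_path):
    sam = tmp_path / "t.sam"
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "c1", "LN": 100}]}
    )
    with pysam.AlignmentFile(str(sam), "w", header=header) as out:
        a = pysam.AlignedSegment(header)
        a.query_name = "orphan"
        a.flag = 0
        a.reference_id = 0
        a.reference_start = 10
        a.mapping_quality = 255
        a.cigarstring = "4M"
        a.query_sequence = "ACGT"
        a.query_qualities = pysam.qualitystring_to_array("IIII")
        out.write(a)
    with pytest.raises(ValueError, match="orphan"):
        read_alignments(str(sam), genome=None)
    genome = {"c1": "A" * 100}
    assert len(read_alignments(str(sam), genome=genome)) == 1


def test_profile_matches_naive_recount_on_simulated_reads(sim_bundle, genome):
    """Totals equal an independent per-read recount that parses the SAM text
    directly and compares read bases to the genome."""
    sam_path = sim_bundle["files"]["parclip"][0]
    naive_cov = {}
    naive_t2c = {}
    seen = set()
    for line in open(sam_path):
        if line.startswith("@"):
            continue
        f = line.split("\t")
        flag, chrom, pos, seq = int(f[1]), f[2], int(f[3]) - 1, f[9]
        strand = "-" if flag & 16 else "+"
        key = (chrom, strand, pos, seq)
        if key in seen:  # same dedup rule as the reader
            continue
        seen.add(key)
        want_ref, want_read = ("T", "C") if strand == "+" else ("A", "G")
        for i, b in enumerate(seq):
            p = pos + i
            naive_cov[(strand, p)] = naive_cov.get((strand, p), 0) + 1
            if genome[chrom][p] == want_ref and b == want_read:
                naive_t2c[(strand, p)] = naive_t2c.get((strand, p), 0) + 1
    profile = build_conversion_profile(str(sam_path), genome, min_base_quality=0)
    for (strand, p), n in naive_t2c.items():
        assert profile.t2c("chrS", strand, p) == n
    total_naive = sum(naive_t2c.values())
    total = sum(
        rec[1] for d in profile.counts.values() for rec in d.values()
    )
    assert total == total_naive


def _two_site_reads(rng, ref):
    reads = []
    for site in (600, 1100):
        for _ in range(50):
            start = site - int(rng.integers(0, 30))
            seq = list(ref[start : start + 30])
            if rng.random() < 0.5:
                seq[site - start] = "C"
            reads.append(_make_read("c1", "+", start, "".join(seq), ref[start : start + 30]))
    return reads


def test_two_separated_sites_give_two_clusters_containing_them():
    rng = np.random.default_rng(0)
    ref = "".join(rng.choice(list("ACGT"), size=2000))
    ref = ref[:600] + "T" + ref[601:1100] + "T" + ref[1101:]
    reads = _two_site_reads(rng, ref)
    profile = build_conversion_profile(reads)
    clusters = call_clusters(profile, reads, 5, 2, 0.01)
    assert len(clusters) == 2
    spans = sorted((c.start, c.end) for c in clusters)
    assert spans[0][0] <= 600 < spans[0][1]
    assert spans[1][0] <= 1100 < spans[1][1]
    for c in clusters:
        assert c.n_reads >= 5 and c.t2c_total >= 2
        assert c.conversion_specificity >= 0.01


def test_no_conversions_means_no_clusters():
    rng = np.random.default_rng(1)
    ref = "".join(rng.choice(list("ACGT"), size=500))
    reads = [
        _make_read("c1", "+", 100 + i, ref[100 + i : 130 + i], ref[100 + i : 130 + i])
        for i in range(20)
    ]
    profile = build_conversion_profile(reads)
    assert call_clusters(profile, reads, 5, 1, 0.0) == []


def test_cluster_calling_invariant_to_read_order():
    rng = np.random.default_rng(2)
    ref = "".join(rng.choice(list("ACGT"), size=2000))
    ref = ref[:600] + "T" + ref[601:1100] + "T" + ref[1101:]
    reads = _two_site_reads(rng, ref)
    profile = build_conversion_profile(reads)
    a = call_clusters(profile, reads, 5, 2, 0.01)
    shuffled = list(reads)
    rng.shuffle(shuffled)
    b = call_clusters(profile, shuffled, 5, 2, 0.01)
    assert [(c.start, c.end, c.n_reads, c.t2c_total) for c in a] == [
        (c.start, c.end, c.n_reads, c.t2c_total) for c in b
    ]


def test_emitted_clusters_satisfy_thresholds_exactly(called_clusters):
    profile = called_clusters["profile"]
    for c in called_clusters["clusters"]:
        t2c, opp = profile.region_stats(c.chrom, c.strand, c.start, c.end)
        assert t2c == c.t2c_total
        assert c.n_reads >= pc.DEFAULT_MIN_READS
        assert t2c >= pc.DEFAULT_MIN_T2C
        assert c.conversion_specificity >= pc.DEFAULT_MIN_SPECIFICITY
        assert c.conversion_specificity == pytest.approx(t2c / opp)


def test_per_replicate_cluster_jaccard(sim_bundle, genome, parclip_reads):
    """Replicates called independently agree (interval Jaccard >= 0.8)."""
    per_rep = []
    for reads in parclip_reads[:2]:
        profile = build_conversion_profile(reads)
        cls = call_clusters(profile, reads)
        per_rep.append({(c.strand, c.start // 50) for c in cls})
    a, b = per_rep
    jac = len(a & b) / len(a | b)
    assert jac >= 0.8


def test_category_priority_and_fractions(called_clusters, sim_bundle, annotation):
    fractions = called_clusters["fractions"]
    assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-9)
    # cluster intron fraction tracks the planted site categories
    site_cats = [
        annotation.classify_position(c, s, p)
        for c, p, s in sim_bundle["truth"].crosslink_sites
    ]
    planted_intron = site_cats.count("intron") / len(site_cats)
    assert abs(fractions.get("intron", 0.0) - planted_intron) < 0.15


def test_midpoint_category_rules(annotation, sim_bundle):
    gene = sim_bundle["sim"].genes[0]
    intron = gene.introns[0]
    mid = sum(intron) // 2
    assert annotation.classify_position("chrS", gene.strand, mid) == "intron"
    cds_mid = sum(gene.cds[1]) // 2
    assert annotation.classify_position("chrS", gene.strand, cds_mid) == "CDS"


def test_unknown_chromosome_is_intergenic_with_warning(annotation):
    with pytest.warns(UserWarning):
        assert annotation.classify_position("chrZ", "+", 5) == "intergenic"


def _profile_from_gene_counts(annotation, counts):
    """Synthetic profile with one converted position per gene."""
    profile = ConversionProfile()
    for gene_id, n in counts.items():
        g = annotation.genes[gene_id]
        pos = (g.start + g.end) // 2
        for _ in range(int(n)):
            profile.add(g.chrom, g.strand, pos, True, True)
    return profile


def test_replicate_correlation_limits(annotation):
    genes = sorted(annotation.genes)[:5]
    up = {g: 10 * (i + 1) for i, g in enumerate(genes)}
    down = {g: 10 * (5 - i) for i, g in enumerate(genes)}
    same = replicate_correlation(
        [_profile_from_gene_counts(annotation, up)] * 2, annotation
    )
    assert same["rho"].iloc[0] == pytest.approx(1.0)
    rev = replicate_correlation(
        [
            _profile_from_gene_counts(annotation, up),
            _profile_from_gene_counts(annotation, down),
        ],
        annotation,
    )
    assert rev["rho"].iloc[0] == pytest.approx(-1.0)


def test_replicate_correlation_matches_naive_rank_oracle(annotation):
    rng = np.random.default_rng(3)
    genes = sorted(annotation.genes)
    a = {g: int(rng.integers(0, 50)) for g in genes}
    b = {g: int(rng.integers(0, 50)) for g in genes}
    out = replicate_correlation(
        [
            _profile_from_gene_counts(annotation, a),
            _profile_from_gene_counts(annotation, b),
        ],
        annotation,
    )

    def midranks(vals):
        order = sorted(range(len(vals)), key=lambda i: vals[i])
        ranks = [0.0] * len(vals)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and vals[order[j + 1]] == vals[order[i]]:
                j += 1
            for k in range(i, j + 1):
                ranks[order[k]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    # zero-count genes do not appear in profiles; restrict to observed genes
    used = [g for g in genes if a[g] > 0 or b[g] > 0]
    va = [a[g] for g in used]
    vb = [b[g] for g in used]
    ra, rb = midranks(va), midranks(vb)
    expected = float(np.corrcoef(ra, rb)[0, 1])
    assert out["rho"].iloc[0] == pytest.approx(expected, abs=1e-12)


def test_replicate_correlation_needs_two_informative_genes(annotation):
    single = _profile_from_gene_counts(annotation, {sorted(annotation.genes)[0]: 5})
    with pytest.raises(ValueError):
        replicate_correlation([single, single], annotation)


def test_polyt_clusters_rank_polyt_kmer_first():
    clusters = [
        pc.Cluster("c1", "+", 0, 8, 5, 3, 0.1, sequence="TTTTTTTT")
        for _ in range(5)
    ]
    out, skipped = kmer_enrichment(clusters, None, k=5, seed=0)
    assert out[0].kmer == "TTTTT"
    assert skipped == 0


def test_kmer_null_when_background_equals_target(monkeypatch):
    monkeypatch.setattr(pc, "dinucleotide_shuffle", lambda s, rng: s)
    rng = np.random.default_rng(4)
    clusters = [
        pc.Cluster(
            "c1", "+", 0, 40, 5, 3, 0.1,
            sequence="".join(rng.choice(list("ACGT"), size=40)),
        )
        for _ in range(20)
    ]
    out, _ = kmer_enrichment(clusters, None, k=5, seed=0)
    for s in out:
        assert s.log2_enrichment == pytest.approx(0.0, abs=1e-12)
        assert s.p_value > 0.3
        assert s.q_value >= s.p_value


def test_planted_pyrimidine_motif_recovered_in_top3(called_clusters, genome):
    out, _ = kmer_enrichment(called_clusters["clusters"], genome, seed=1)
    top3 = [s.kmer for s in out[:3]]
    assert any(set(k) <= set("CT") for k in top3)
    assert "TTTCT" in top3 or "TTCTC" in top3


def test_short_clusters_are_skipped_and_counted():
    clusters = [
        pc.Cluster("c1", "+", 0, 3, 5, 3, 0.1, sequence="TTT"),
        pc.Cluster("c1", "+", 0, 9, 5, 3, 0.1, sequence="TTTTTTTTT"),
    ]
    out, skipped = kmer_enrichment(clusters, None, k=5, seed=0)
    assert skipped == 1
    assert out


@given(st.text(alphabet="ACGT", min_size=3, max_size=60), st.integers(0, 10_000))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_dinucleotide_shuffle_preserves_dinucleotide_counts(seq, seed):
    rng = np.random.default_rng(seed)
    out = dinucleotide_shuffle(seq, rng)
    assert len(out) == len(seq)
    assert out[0] == seq[0] and out[-1] == seq[-1]

    def dinucs(s):
        c = {}
        for a, b in zip(s, s[1:]):
            c[a + b] = c.get(a + b, 0) + 1
        return c

    assert dinucs(out) == dinucs(seq)
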