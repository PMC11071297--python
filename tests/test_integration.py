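"""Integration tests: normalization/fold change, bin partition, KS oracle,
metagene geometry, cross-platform correlation, GSEA oracle, prioritization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from clipsplice.integration import (
    bin_label,
    build_gene_summaries,
    cdf_by_bins,
    gsea_preranked,
    ks_statistic,
    ks_test,
    metagene_profile,
    normalize_and_logfc,
    prioritize_candidates,
    spearman_cross_platform,
)
from clipsplice.parclip import Cluster
from clipsplice.splicing import SpliceEvent

# ------------------------------------------------------------------- logFC


def _tables(rng, n_genes=200, logfc=None, reps=3, mean=300.0, disp=0.02):
    genes = [f"g{i:04d}" for i in range(n_genes)]
    logfc = logfc if logfc is not None else np.zeros(n_genes)
    tables = {}
    cmap = {}
    for cond in ("wt", "ko"):
        for r in range(reps):
            mu = mean * (2.0 ** logfc if cond == "ko" else 1.0)
            size = 1.0 / disp
            counts = rng.negative_binomial(size, size / (size + mu))
            name = f"{cond}{r + 1}"
            tables[name] = pd.Series(counts, index=genes)
            cmap[name] = cond
    return tables, cmap


def test_identical_tables_give_zero_logfc():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(50)]
    base = pd.Series(rng.integers(10, 500, size=50), index=genes)
    tables = {"wt1": base, "wt2": base, "ko1": base, "ko2": base}
    cmap = {s: ("ko" if s.startswith("ko") else "wt") for s in tables}
    out = normalize_and_logfc(tables, cmap)
    assert np.allclose(out["log2fc"], 0.0)


def test_size_factor_recovered_for_scaled_sample():
    rng = np.random.default_rng(1)
    genes = [f"g{i}" for i in range(100)]
    base = pd.Series(rng.integers(50, 500, size=100), index=genes)
    tables = {"wt1": base, "wt2": base * 2, "ko1": base, "ko2": base}
    cmap = {s: ("ko" if s.startswith("ko") else "wt") for s in tables}
    out = normalize_and_logfc(tables, cmap)
    sf = out.attrs["size_factors"]
    assert sf["wt2"] / sf["wt1"] == pytest.approx(2.0, rel=1e-6)
    assert np.allclose(out["log2fc"], 0.0, atol=1e-9)


def test_planted_logfc_recovered_within_015():
    rng = np.random.default_rng(2)
    logfc = np.zeros(200)
    logfc[:30] = -1.0
    tables, cmap = _tables(rng, logfc=logfc, mean=300.0, reps=3)
    out = normalize_and_logfc(tables, cmap)
    est = out["log2fc"].to_numpy()[:30]
    # the planted-group estimate is tight; one-directional DE shifts the
    # median-of-ratios baseline slightly, so per-gene scatter stays wider
    assert abs(est.mean() + 1.0) < 0.15
    assert np.all(np.abs(est + 1.0) < 0.8)
    null = out["log2fc"].to_numpy()[30:]
    assert abs(null.mean()) < 0.1


def test_all_zero_sample_rejected():
    tables = {
        "wt1": pd.Series([1, 2], index=["a", "b"]),
        "ko1": pd.Series([0, 0], index=["a", "b"]),
    }
    with pytest.raises(ValueError, match="all-zero"):
        normalize_and_logfc(tables, {"wt1": "wt", "ko1": "ko"})


# ------------------------------------------------------------------- bins


@pytest.mark.parametrize(
    "n,label",
    [(0, "0"), (1, "1-9"), (9, "1-9"), (10, "10-29"), (29, "10-29"), (30, ">=30"), (120, ">=30")],
)
def test_bin_partition_matches_printed_edges(n, label):
    assert bin_label(n) == label


# ------------------------------------------------------------------- KS


def _brute_ks(x, y):
    d = 0.0
    for t in list(x) + list(y):
        fx = sum(v <= t for v in x) / len(x)
        fy = sum(v <= t for v in y) / len(y)
        d = max(d, abs(fx - fy))
    return d


def test_ks_statistic_equals_brute_force_and_scipy():
    rng = np.random.default_rng(3)
    for _ in range(40):
        n, m = rng.integers(2, 50, size=2)
        x = rng.normal(size=n)
        y = rng.normal(loc=rng.normal(), size=m)
        d = ks_statistic(x, y)
        assert d == pytest.approx(_brute_ks(x, y), abs=1e-12)
        assert d == pytest.approx(sstats.ks_2samp(x, y).statistic, abs=1e-12)


def test_ks_identical_samples():
    x = np.arange(10.0)
    d, p = ks_test(x, x)
    assert d == 0.0
    assert p == pytest.approx(1.0)


def test_cdf_by_bins_reports_counts_and_shift():
    rng = np.random.default_rng(4)
    rows = []
    for i in range(200):
        rows.append({"log2fc": rng.normal(), "n_clusters": 0})
    for i in range(100):
        rows.append({"log2fc": rng.normal(loc=-0.5), "n_clusters": 5})
    df = pd.DataFrame(rows, index=[f"g{i}" for i in range(300)])
    df["bin"] = [bin_label(n) for n in df["n_clusters"]]
    ecdf, ks = cdf_by_bins(df)
    row = ks[ks["bin"] == "1-9"].iloc[0]
    assert row["n"] == 100 and row["n_unbound"] == 200
    assert row["ks_d"] > 0
    assert row["median_shift"] < 0
    # stochastic dominance: bound ECDF lies left of (above) the unbound ECDF
    bound = np.sort(df.loc[df["bin"] == "1-9", "log2fc"])
    unbound = np.sort(df.loc[df["bin"] == "0", "log2fc"])
    grid = np.linspace(-2, 2, 41)
    fb = np.searchsorted(bound, grid, side="right") / len(bound)
    fu = np.searchsorted(unbound, grid, side="right") / len(unbound)
    assert np.all(fb >= fu - 0.05)


# ------------------------------------------------------------------- metagene


def _cluster(gene, start, end, strand="+"):
    return Cluster("c1", strand, start, end, 10, 5, 0.1, gene=gene)


def _event(gene, region, dpsi, strand="+", flanks=((None), (None))):
    ev = SpliceEvent("SE", gene, "c1", strand, region, [], [])
    ev.delta_psi = dpsi
    ev.q_value = 0.001
    ev.flank_upstream, ev.flank_downstream = flanks
    return ev


def test_metagene_indicator_geometry():
    ev = _event("g1", (1000, 1100), 0.5, flanks=((500, 600), (1500, 1600)))
    clusters = [_cluster("g1", 1000, 1100)]
    out = metagene_profile(clusters, [ev], window=200)
    target = {m.event_class: m for m in out}["included_in_KO:target"]
    # exon center 1050; cluster spans center-50 .. center+50
    assert target.value[200] == 1.0
    assert target.value[200 - 50] == 1.0
    assert target.value[200 - 51] == 0.0
    assert target.value[200 + 49] == 1.0
    assert target.value[200 + 50] == 0.0
    up = {m.event_class: m for m in out}["included_in_KO:upstream_exon"]
    assert up.value.max() == 0.0


def test_metagene_minus_strand_orientation_flips():
    ev = _event("g1", (1000, 1100), 0.5, strand="-")
    # cluster downstream in transcription = genomically left of center
    clusters = [_cluster("g1", 940, 990, strand="-")]
    out = metagene_profile(clusters, [ev], window=200)
    target = out[0].value
    # genomic offsets [-110, -60) map to (+60, +110] after the flip
    assert target[200 + 61] == 1.0
    assert target[200 + 110] == 1.0
    assert target[200 + 111] == 0.0
    assert target[200 - 61] == 0.0


def test_metagene_without_clusters_is_zero():
    ev = _event("g1", (1000, 1100), -0.4, flanks=((500, 600), (1500, 1600)))
    out = metagene_profile([], [ev], window=100)
    for m in out:
        assert m.event_class.startswith("excluded_in_KO")
        assert np.all(m.value == 0.0)


# ------------------------------------------------------------------- Spearman


def test_cross_platform_spearman_limits_and_oracle():
    a = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
    assert spearman_cross_platform(a, a)[0] == pytest.approx(1.0)
    assert spearman_cross_platform(a, -a)[0] == pytest.approx(-1.0)
    rng = np.random.default_rng(5)
    b = pd.Series(rng.normal(size=10), index=a.index)
    rho, _, n = spearman_cross_platform(a, b)
    ra = a.rank().to_numpy()
    rb = b.rank().to_numpy()
    assert rho == pytest.approx(float(np.corrcoef(ra, rb)[0, 1]), abs=1e-12)
    assert n == 10
    with pytest.raises(ValueError):
        spearman_cross_platform(a.iloc[:2], b.iloc[:2])


# ------------------------------------------------------------------- GSEA


def _naive_es(ranked: pd.Series, members: set[str]) -> float:
    """Plain-loop weighted KS running sum, maximum deviation from zero."""
    items = sorted(ranked.items(), key=lambda kv: -kv[1])
    total_hit = sum(abs(v) for g, v in items if g in members)
    n_miss = sum(1 for g, _ in items if g not in members)
    run = 0.0
    best = 0.0
    for g, v in items:
        if g in members:
            run += abs(v) / total_hit
        else:
            run -= 1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best


def test_top_block_set_scores_high():
    ranked = pd.Series(np.linspace(3, -3, 100), index=[f"g{i}" for i in range(100)])
    sets = {"TOP10": [f"g{i}" for i in range(10)]}
    out = gsea_preranked(ranked, sets, n_perm=200, seed=0)
    assert out[0].es > 0.8
    assert out[0].p_value < 0.05


def test_es_matches_naive_running_sum_for_every_set():
    rng = np.random.default_rng(6)
    genes = [f"g{i}" for i in range(80)]
    ranked = pd.Series(rng.normal(size=80), index=genes)
    sets = {
        f"S{k}": list(rng.choice(genes, size=rng.integers(5, 30), replace=False))
        for k in range(10)
    }
    out = gsea_preranked(ranked, sets, n_perm=100, seed=1)
    for r in out:
        assert r.es == pytest.approx(_naive_es(ranked, set(sets[r.gene_set])), abs=1e-12)


def test_all_gene_set_es_is_zero():
    ranked = pd.Series(np.linspace(1, -1, 30), index=[f"g{i}" for i in range(30)])
    out = gsea_preranked(ranked, {"ALL": list(ranked.index)}, n_perm=100, seed=0)
    assert out[0].es == 0.0


def test_small_sets_skipped_and_seed_deterministic():
    ranked = pd.Series(np.linspace(1, -1, 40), index=[f"g{i}" for i in range(40)])
    sets = {"TINY": ["g0", "g1"], "OK": [f"g{i}" for i in range(8)]}
    a = gsea_preranked(ranked, sets, n_perm=150, seed=3)
    b = gsea_preranked(ranked, sets, n_perm=150, seed=3)
    assert [r.gene_set for r in a] == ["OK"]
    assert a[0].p_value == b[0].p_value and a[0].nes == b[0].nes


def test_nonfinite_scores_rejected():
    ranked = pd.Series([1.0, np.nan], index=["a", "b"])
    with pytest.raises(ValueError):
        gsea_preranked(ranked, {"S": ["a"]}, n_perm=100, seed=0)


# ------------------------------------------------------------------- prioritization


def _summary_frame(rows):
    df = pd.DataFrame(rows).set_index("gene")
    df["bin"] = [bin_label(n) for n in df["n_clusters"]]
    return df


def test_prioritization_filters_and_ranks():
    df = _summary_frame(
        [
            dict(gene="ee", log2fc=-2.0, n_clusters=3, has_included_exon_in_ko=True),
            dict(gene="mid", log2fc=-1.0, n_clusters=1, has_included_exon_in_ko=True),
            dict(gene="no_ev", log2fc=-3.0, n_clusters=5, has_included_exon_in_ko=False),
            dict(gene="up", log2fc=1.5, n_clusters=2, has_included_exon_in_ko=True),
            dict(gene="unbound", log2fc=-2.5, n_clusters=0, has_included_exon_in_ko=True),
        ]
    )
    out = prioritize_candidates(df)
    assert list(out.index) == ["ee", "mid"]
    assert list(out["priority_rank"]) == [1, 2]


def test_prioritization_tie_breaks_and_rbp_exclusion():
    df = _summary_frame(
        [
            dict(gene="b", log2fc=-1.0, n_clusters=2, has_included_exon_in_ko=True),
            dict(gene="a", log2fc=-1.0, n_clusters=2, has_included_exon_in_ko=True),
            dict(gene="c", log2fc=-1.0, n_clusters=7, has_included_exon_in_ko=True),
            dict(gene="rbp", log2fc=-9.0, n_clusters=9, has_included_exon_in_ko=True),
        ]
    )
    out = prioritize_candidates(df, exclude_gene="rbp")
    assert list(out.index) == ["c", "a", "b"]


def test_empty_events_give_empty_candidates():
    logfc = pd.DataFrame(
        {"mean_wt": [10.0], "mean_ko": [5.0], "log2fc": [-1.0]}, index=["g1"]
    )
    summaries = build_gene_summaries(logfc, [_cluster("g1", 0, 50)], events=[])
    out = prioritize_candidates(summaries)
    assert out.empty
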