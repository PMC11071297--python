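"""Integration of binding, expression and splicing.

This module links the three data layers: per-gene fold changes from count
tables (median-of-ratios normalization), binding-site counts per gene binned
as 0 / 1-9 / 10-29 / >=30 with two-sided Kolmogorov-Smirnov tests of the
fold-change ECDF shift of each bound bin against unbound genes, metagene
binding profiles in a +/-0.5 kb window around the centers of differentially
included/excluded exons, cross-platform Spearman correlation, preranked
gene-set enrichment (weighted KS running sum with gene-label permutation),
and the final candidate prioritization: bound genes, down-regulated in the
knockout, with at least one exon included in the knockout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .parclip import Cluster
from .splicing import SpliceEvent

logger = logging.getLogger(__name__)

#: printed bin partition over per-gene binding-site counts
DEFAULT_BIN_EDGES = (0, 1, 10, 30)
BIN_LABELS = ("0", "1-9", "10-29", ">=30")


def bin_label(n_clusters: int, edges=DEFAULT_BIN_EDGES) -> str:
    labels = _labels_for(edges)
    idx = 0
    for i, lo in enumerate(edges):
        if n_clusters >= lo:
            idx = i
    return labels[idx]


def _labels_for(edges) -> tuple[str, ...]:
    if tuple(edges) == DEFAULT_BIN_EDGES:
        return BIN_LABELS
    out = []
    for i, lo in enumerate(edges):
        if i + 1 < len(edges):
            hi = edges[i + 1] - 1
            out.append(str(lo) if hi == lo else f"{lo}-{hi}")
        else:
            out.append(f">={lo}")
    return tuple(out)


# --------------------------------------------------------------------------- logFC


def normalize_and_logfc(
    count_tables: dict[str, pd.Series],
    condition_map: dict[str, str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Median-of-ratios size factors, normalized means, log2 KO/WT.

    Size factor per sample = median over genes of count / geometric mean
    across samples; genes with a zero in any sample are excluded from factor
    estimation. Returns a frame indexed by gene with mean_wt, mean_ko,
    log2fc columns.
    """
    mat = pd.DataFrame(count_tables).fillna(0.0)
    if (mat.sum(axis=0) == 0).any():
        bad = mat.columns[mat.sum(axis=0) == 0].tolist()
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    log_mat = np.log(mat.where(mat > 0))
    log_geo = log_mat.mean(axis=1)
    usable = log_mat.notna().all(axis=1)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ratios = np.log(mat.loc[usable]).sub(log_geo[usable], axis=0)
    size_factors = np.exp(ratios.median(axis=0))
    norm = mat.div(size_factors, axis=1)
    out = pd.DataFrame(index=mat.index)
    for cond in ("wt", "ko"):
        cols = [s for s in mat.columns if condition_map[s] == cond]
        if not cols:
            raise ValueError(f"no samples for condition {cond!r}")
        out[f"mean_{cond}"] = norm[cols].mean(axis=1)
    out["log2fc"] = np.log2(
        (out["mean_ko"] + pseudocount) / (out["mean_wt"] + pseudocount)
    )
    out.attrs["size_factors"] = size_factors.to_dict()
    return out


def build_gene_summaries(
    logfc: pd.DataFrame,
    clusters: list[Cluster],
    events: list[SpliceEvent] | None = None,
    max_q: float = 0.05,
    min_delta_psi: float = 0.1,
    edges=DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Per-gene summary: logFC, cluster count, bin, included-exon flag."""
    counts: dict[str, int] = {}
    for cl in clusters:
        if cl.gene is not None:
            counts[cl.gene] = counts.get(cl.gene, 0) + 1
    included = set()
    for ev in events or []:
        if (
            ev.gene is not None
            and ev.q_value is not None
            and ev.q_value < max_q
            and ev.delta_psi is not None
            and ev.delta_psi > 0
            and abs(ev.delta_psi) >= min_delta_psi
        ):
            included.add(ev.gene)
    out = logfc.copy()
    out["n_clusters"] = [counts.get(g, 0) for g in out.index]
    out["bin"] = [bin_label(n, edges) for n in out["n_clusters"]]
    out["has_included_exon_in_ko"] = [g in included for g in out.index]
    return out


# --------------------------------------------------------------------------- KS / ECDF


def ks_statistic(x, y) -> float:
    """Two-sample KS D: max absolute ECDF difference."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    grid = np.concatenate([x, y])
    fx = np.searchsorted(x, grid, side="right") / len(x)
    fy = np.searchsorted(y, grid, side="right") / len(y)
    return float(np.max(np.abs(fx - fy)))


def ks_test(x, y) -> tuple[float, float]:
    """Two-sided two-sample KS with the asymptotic Kolmogorov p-value."""
    d = ks_statistic(x, y)
    n, m = len(x), len(y)
    en = n * m / (n + m)
    p = float(stats.kstwobign.sf(np.sqrt(en) * d))
    return d, min(max(p, 0.0), 1.0)


def cdf_by_bins(
    summaries: pd.DataFrame, edges=DEFAULT_BIN_EDGES
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin fold-change ECDFs and KS tests of each bound bin vs bin 0.

    Returns (ecdf_frame, ks_frame); ecdf_frame holds the sorted log2fc values
    and cumulative fraction per bin, ks_frame one row per nonzero bin with D,
    the asymptotic p, and per-bin transcript counts.
    """
    labels = _labels_for(edges)
    groups = {
        lab: summaries.loc[summaries["bin"] == lab, "log2fc"].to_numpy()
        for lab in labels
    }
    ecdf_rows = []
    for lab in labels:
        vals = np.sort(groups[lab])
        for i, v in enumerate(vals, 1):
            ecdf_rows.append({"bin": lab, "log2fc": v, "cum_frac": i / len(vals)})
    base = groups[labels[0]]
    ks_rows = []
    for lab in labels[1:]:
        vals = groups[lab]
        if len(vals) == 0 or len(base) == 0:
            logger.warning("empty bin %s skipped in KS comparison", lab)
            continue
        d, p = ks_test(vals, base)
        ks_rows.append(
            {
                "bin": lab,
                "n": len(vals),
                "n_unbound": len(base),
                "ks_d": d,
                "p_value": p,
                "median_shift": float(np.median(vals) - np.median(base)),
            }
        )
    return pd.DataFrame(ecdf_rows), pd.DataFrame(ks_rows)


# --------------------------------------------------------------------------- metagene


@dataclass
class Metagene:
    event_class: str  # e.g. "included_in_KO:target"
    positions: np.ndarray  # -window .. +window, transcription orientation
    value: np.ndarray  # mean cluster-overlap indicator, in [0, 1]
    n_events: int


def metagene_profile(
    clusters: list[Cluster],
    events: list[SpliceEvent],
    window: int = 500,
) -> list[Metagene]:
    """Mean binding indicator around centers of regulated exons.

    For every significant event direction (included/excluded in KO) and
    panel (the regulated exon itself, its upstream and its downstream
    neighbor), each position in a +/-``window`` nt window around the exon
    center gets the binary indicator "a cluster of this event's gene
    overlaps this genomic position", averaged over events. The x-axis is
    oriented so positive offsets are downstream in transcription direction.
    Only exon-skipping events are summarized: the window is anchored on an
    alternative exon's center.
    """
    by_gene: dict[str, list[Cluster]] = {}
    for cl in clusters:
        if cl.gene is not None:
            by_gene.setdefault(cl.gene, []).append(cl)
    panels: dict[str, list[np.ndarray]] = {}
    positions = np.arange(-window, window + 1)
    for ev in events:
        if ev.event_type != "SE":  # exon-centered summary only
            continue
        if ev.delta_psi is None or ev.gene is None:
            continue
        direction = "included_in_KO" if ev.delta_psi > 0 else "excluded_in_KO"
        anchors = {
            "target": ev.region,
            "upstream_exon": ev.flank_upstream,
            "downstream_exon": ev.flank_downstream,
        }
        for panel, iv in anchors.items():
            if iv is None:
                continue
            center = (iv[0] + iv[1]) // 2
            track = np.zeros(2 * window + 1)
            for cl in by_gene.get(ev.gene, []):
                lo = max(cl.start - center + window, 0)
                hi = min(cl.end - center + window, 2 * window + 1)
                if hi > lo:
                    track[lo:hi] = 1.0
            if ev.strand == "-":
                track = track[::-1]
            panels.setdefault(f"{direction}:{panel}", []).append(track)
    out = []
    for name in sorted(panels):
        tracks = panels[name]
        out.append(
            Metagene(name, positions, np.mean(tracks, axis=0), len(tracks))
        )
    return out


# --------------------------------------------------------------------------- cross-platform


def spearman_cross_platform(a: pd.Series, b: pd.Series) -> tuple[float, float, int]:
    """Spearman rho on the shared genes of two per-gene measurements."""
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need at least 3")
    rho, p = stats.spearmanr(a.loc[shared], b.loc[shared])
    return float(rho), float(p), len(shared)


# --------------------------------------------------------------------------- GSEA


@dataclass
class EnrichmentResult:
    gene_set: str
    es: float
    nes: float
    p_value: float
    q_value: float
    size: int


def _enrichment_score(order: np.ndarray, weights: np.ndarray, member: np.ndarray) -> float:
    """Weighted KS running-sum enrichment score (weight exponent 1).

    ``order`` indexes genes by decreasing score; ``member`` flags set
    membership per gene; returns the maximum deviation from zero.
    """
    w = np.abs(weights[order])
    hit = member[order]
    w_hit = np.where(hit, w, 0.0)
    total_hit = w_hit.sum()
    n_miss = (~hit).sum()
    if total_hit == 0 or n_miss == 0:
        return 0.0
    p_hit = np.cumsum(w_hit) / total_hit
    p_miss = np.cumsum(~hit) / n_miss
    running = p_hit - p_miss
    return float(running[np.argmax(np.abs(running))])


def gsea_preranked(
    ranked: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
) -> list[EnrichmentResult]:
    """Preranked GSEA: weighted KS running sum with gene-label permutation.

    NES = ES divided by the mean |null ES| of the same sign; permutation p
    is one-sided on the same-sign null. Sets with fewer than ``min_size``
    members after intersection with the ranking are skipped.
    """
    if not np.isfinite(ranked.to_numpy(dtype=float)).all():
        raise ValueError("ranked scores must be finite")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    order = np.argsort(-scores, kind="stable")
    results = []
    for name, members in gene_sets.items():
        member = np.isin(genes, list(members))
        size = int(member.sum())
        if size < min_size:
            logger.info("gene set %s skipped (%d members < %d)", name, size, min_size)
            continue
        es = _enrichment_score(order, scores, member)
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = np.zeros(len(genes), dtype=bool)
            perm[rng.choice(len(genes), size=size, replace=False)] = True
            null[i] = _enrichment_score(order, scores, perm)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same_sign) == 0:
            p = 1.0 / (n_perm + 1)
            nes = 0.0
        else:
            p = (np.sum(np.abs(same_sign) >= abs(es)) + 1) / (len(same_sign) + 1)
            denom = float(np.mean(np.abs(same_sign)))
            nes = es / denom if denom > 0 else 0.0
        results.append(EnrichmentResult(name, es, float(nes), float(p), 1.0, size))
    if results:
        qvals = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qvals):
            r.q_value = max(float(q), r.p_value)
    results.sort(key=lambda r: r.p_value)
    return results


# --------------------------------------------------------------------------- prioritization


def prioritize_candidates(
    summaries: pd.DataFrame,
    exclude_gene: str | None = None,
) -> pd.DataFrame:
    """Rank mis-splicing candidates.

    Keeps genes that are bound (>=1 cluster), have an exon included in KO
    (delta_psi > 0 at q < 0.05), and are down-regulated (log2fc < 0); sorts
    ascending by log2fc (most down-regulated first), ties broken by more
    clusters then gene id. The perturbed RBP's own gene can be excluded.
    """
    sel = summaries[
        (summaries["n_clusters"] >= 1)
        & summaries["has_included_exon_in_ko"]
        & (summaries["log2fc"] < 0)
    ].copy()
    if exclude_gene is not None:
        sel = sel[sel.index != exclude_gene]
    sel = sel.iloc[
        np.lexsort(
            (
                sel.index.to_numpy(),
                -sel["n_clusters"].to_numpy(),
                sel["log2fc"].to_numpy(),
            )
        )
    ]
    sel["priority_rank"] = np.arange(1, len(sel) + 1)
    return sel
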