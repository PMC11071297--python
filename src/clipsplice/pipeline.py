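"""End-to-end driver: binding-site calling -> splicing-event discovery ->
binding/expression/splicing integration -> NMD consequence prediction.

``run_synthetic`` generates a synthetic dataset and pushes it through the
full chain; ``run_from_files`` runs the same chain on existing files. Both
return a :class:`PipelineResult`; ``write_outputs`` serializes every table
plus a manifest with parameters and content hashes so a rerun with the same
configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import Annotation, Gene
from .integration import (
    Metagene,
    build_gene_summaries,
    cdf_by_bins,
    gsea_preranked,
    metagene_profile,
    normalize_and_logfc,
    prioritize_candidates,
    spearman_cross_platform,
)
from .io import read_count_matrix, read_counts, read_fasta, read_gmt
from .nmd import IsoformVariant, TranscriptModel, analyze_inclusion
from .parclip import (
    annotate_clusters,
    build_conversion_profile,
    call_clusters,
    clusters_to_frame,
    kmer_enrichment,
    read_alignments,
    replicate_correlation,
)
from .simulate import SimConfig, Simulator
from .splicing import (
    discover_events,
    event_census,
    extract_junctions,
    merge_junctions,
    test_differential,
)


@dataclass
class PipelineParams:
    min_reads: int = 5
    min_t2c: int = 2
    min_specificity: float = 0.01
    min_base_quality: int = 20
    kmer_k: int = 5
    max_q: float = 0.05
    min_delta_psi: float = 0.1
    gsea_permutations: int = 500
    exclude_gene: str | None = None
    seed: int = 0
    #: skip the descriptive layers (k-mers, metagene, GSEA, cross-platform,
    #: replicate correlation) and keep only the prioritization chain
    minimal: bool = False


@dataclass
class PipelineResult:
    clusters: pd.DataFrame
    category_fractions: dict[str, float]
    replicate_rho: pd.DataFrame | None
    kmers: pd.DataFrame
    events: list
    census: dict[str, int]
    summaries: pd.DataFrame
    ecdf: pd.DataFrame
    ks: pd.DataFrame
    metagene: list[Metagene]
    candidates: pd.DataFrame
    variants: dict[str, IsoformVariant]
    enrichment: pd.DataFrame | None = None
    cross_platform: tuple[float, float, int] | None = None
    params: PipelineParams = field(default_factory=PipelineParams)


def transcript_model(gene: Gene) -> TranscriptModel:
    """Build the NMD-module transcript model from the first coding isoform."""
    tx = next(
        (t for t in gene.transcripts.values() if t.cds), None
    )
    if tx is None:
        raise ValueError(f"gene {gene.gene_id} has no coding transcript")
    order = tx.exons if gene.strand == "+" else tx.exons[::-1]
    cds_pos = []
    cum = 0
    for s, e in order:
        for cs, ce in tx.cds:
            if cs < e and ce > s:
                lo, hi = max(cs, s), min(ce, e)
                if gene.strand == "+":
                    cds_pos.append((cum + lo - s, cum + hi - s))
                else:
                    cds_pos.append((cum + e - hi, cum + e - lo))
        cum += e - s
    cds_start = min(p[0] for p in cds_pos)
    cds_end = max(p[1] for p in cds_pos)
    return TranscriptModel(
        gene.gene_id, gene.chrom, gene.strand, list(tx.exons), cds_start, cds_end
    )


def run_from_files(
    genome_fa,
    gtf,
    parclip_sams: list,
    rnaseq_sams: dict[str, str],
    condition_map: dict[str, str],
    count_tables: dict[str, str],
    gmt: str | None = None,
    crossplatform: str | None = None,
    params: PipelineParams | None = None,
) -> PipelineResult:
    params = params or PipelineParams()
    genome = read_fasta(genome_fa)
    annotation = Annotation.from_gtf(gtf)

    # ---- binding sites
    per_rep_reads = [
        read_alignments(p, genome, params.min_base_quality) for p in parclip_sams
    ]
    profiles = [build_conversion_profile(r) for r in per_rep_reads]
    pooled_reads = [r for rep in per_rep_reads for r in rep]
    pooled_profile = build_conversion_profile(pooled_reads)
    clusters = call_clusters(
        pooled_profile,
        pooled_reads,
        params.min_reads,
        params.min_t2c,
        params.min_specificity,
    )
    clusters, fractions = annotate_clusters(clusters, annotation, genome)
    rho = None
    kmer_df = pd.DataFrame()
    if not params.minimal:
        if len(profiles) > 1:
            rho = replicate_correlation(profiles, annotation)
        kmers, _ = kmer_enrichment(clusters, genome, k=params.kmer_k, seed=params.seed)
        kmer_df = pd.DataFrame([dataclasses.asdict(s) for s in kmers])

    # ---- splicing
    junctions = merge_junctions(
        {name: extract_junctions(path) for name, path in rnaseq_sams.items()},
        annotation,
    )
    events = discover_events(junctions, annotation, genome, samples=rnaseq_sams)
    events = test_differential(
        events, condition_map, params.max_q, params.min_delta_psi
    )
    census = event_census(events)

    # ---- integration
    tables = {name: read_counts(path) for name, path in count_tables.items()}
    logfc = normalize_and_logfc(tables, condition_map)
    summaries = build_gene_summaries(
        logfc, clusters, events, params.max_q, params.min_delta_psi
    )
    ecdf, ks = cdf_by_bins(summaries)
    meta = [] if params.minimal else metagene_profile(
        clusters,
        [
            e
            for e in events
            if e.q_value is not None
            and e.q_value < params.max_q
            and e.delta_psi is not None
            and abs(e.delta_psi) >= params.min_delta_psi
        ],
    )
    candidates = prioritize_candidates(summaries, params.exclude_gene)

    enrichment = None
    if gmt is not None and not params.minimal:
        results = gsea_preranked(
            summaries["log2fc"],
            read_gmt(gmt),
            n_perm=params.gsea_permutations,
            seed=params.seed,
        )
        enrichment = pd.DataFrame([dataclasses.asdict(r) for r in results])
    cross = None
    if crossplatform is not None and not params.minimal:
        other = read_count_matrix(crossplatform)
        other_tables = {c: other[c].astype(int) for c in other.columns}
        cmap = {c: ("ko" if c.startswith("ko") else "wt") for c in other.columns}
        other_fc = normalize_and_logfc(other_tables, cmap)
        cross = spearman_cross_platform(summaries["log2fc"], other_fc["log2fc"])

    # ---- consequence prediction for candidates with a novel included exon
    variants: dict[str, IsoformVariant] = {}
    for ev in events:
        if not ev.novel or ev.gene is None or ev.gene not in candidates.index:
            continue
        if ev.delta_psi is None or ev.delta_psi <= 0:
            continue
        model = transcript_model(annotation.genes[ev.gene])
        variants[ev.gene] = analyze_inclusion(model, ev.region, genome)

    return PipelineResult(
        clusters=clusters_to_frame(clusters),
        category_fractions=fractions,
        replicate_rho=rho,
        kmers=kmer_df,
        events=events,
        census=census,
        summaries=summaries,
        ecdf=ecdf,
        ks=ks,
        metagene=meta,
        candidates=candidates,
        variants=variants,
        enrichment=enrichment,
        cross_platform=cross,
        params=params,
    )


def run_synthetic(
    config: SimConfig, outdir, params: PipelineParams | None = None
) -> tuple[PipelineResult, dict]:
    """Generate a synthetic dataset under ``outdir`` and analyze it."""
    outdir = Path(outdir)
    sim = Simulator(config)
    sim.make_genome()
    files = sim.write_all(outdir / "data")
    names = [f"{c}{r}" for c in ("wt", "ko") for r in range(1, config.n_replicates_per_condition + 1)]
    rnaseq = {n: str(p) for n, p in zip(names, files["sam"])}
    counts = {n: str(p) for n, p in zip(names, files["counts"])}
    condition_map = {n: ("ko" if n.startswith("ko") else "wt") for n in names}
    params = params or PipelineParams(seed=config.seed)
    result = run_from_files(
        files["fasta"],
        files["gtf"],
        [str(p) for p in files["parclip"]],
        rnaseq,
        condition_map,
        counts,
        gmt=str(files["gene_sets"]),
        crossplatform=str(files["crossplatform"]),
        params=params,
    )
    return result, files


# --------------------------------------------------------------------------- output


def events_to_frame(events) -> pd.DataFrame:
    rows = []
    for ev in events:
        row = {
            "event_type": ev.event_type,
            "gene": ev.gene,
            "chrom": ev.chrom,
            "strand": ev.strand,
            "region_start": ev.region[0],
            "region_end": ev.region[1],
            "novel": ev.novel,
            "delta_psi": ev.delta_psi,
            "p_value": ev.p_value,
            "q_value": ev.q_value,
        }
        for sample in sorted(ev.psi):
            row[f"psi_{sample}"] = ev.psi[sample]
            row[f"inc_{sample}"] = ev.inclusion_counts.get(sample, 0)
            row[f"skip_{sample}"] = ev.skipping_counts.get(sample, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def metagene_to_frame(meta: list[Metagene]) -> pd.DataFrame:
    rows = []
    for m in meta:
        for pos, val in zip(m.positions, m.value):
            rows.append(
                {
                    "event_class": m.event_class,
                    "position": int(pos),
                    "value": float(val),
                    "n_events": m.n_events,
                }
            )
    return pd.DataFrame(rows)


def write_outputs(result: PipelineResult, outdir) -> dict:
    """Write every result table plus a manifest of hashes and parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, index=False):
        path = outdir / name
        df.to_csv(path, sep="\t", index=index)
        written[name] = path

    emit("clusters.tsv", result.clusters)
    emit(
        "category_fractions.tsv",
        pd.DataFrame(
            sorted(result.category_fractions.items()),
            columns=["category", "fraction"],
        ),
    )
    if result.replicate_rho is not None:
        emit("replicate_correlation.tsv", result.replicate_rho)
    emit("kmer_enrichment.tsv", result.kmers)
    emit("events.tsv", events_to_frame(result.events))
    emit(
        "event_census.tsv",
        pd.DataFrame(sorted(result.census.items()), columns=["event_type", "n"]),
    )
    emit("gene_summaries.tsv", result.summaries, index=True)
    emit("ecdf_by_bin.tsv", result.ecdf)
    emit("ks_by_bin.tsv", result.ks)
    emit("metagene.tsv", metagene_to_frame(result.metagene))
    emit("candidates.tsv", result.candidates, index=True)
    if result.enrichment is not None:
        emit("gsea.tsv", result.enrichment)
    nmd_rows = []
    for gene, var in result.variants.items():
        nmd_rows.append(
            {
                "gene": gene,
                "insert_start": var.inserted_exon[0],
                "insert_end": var.inserted_exon[1],
                "insert_length": var.inserted_exon[1] - var.inserted_exon[0],
                "frame_shifted": var.frame_shifted,
                "ptc_transcript_pos": var.ptc_transcript_pos,
                "ptc_exon_index": var.ptc_exon_index,
                "nmd_predicted": var.nmd_predicted,
                "last_junction_distance": var.last_junction_distance,
            }
        )
    emit("nmd_report.tsv", pd.DataFrame(nmd_rows))
    manifest = {
        "version": __version__,
        "params": dataclasses.asdict(result.params),
        "files": {
            name: hashlib.sha256(path.read_bytes()).hexdigest()
            for name, path in sorted(written.items())
        },
    }
    if result.cross_platform is not None:
        rho, p, n = result.cross_platform
        manifest["cross_platform"] = {"rho": rho, "p_value": p, "n_genes": n}
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    written["manifest.json"] = mpath
    return manifest
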