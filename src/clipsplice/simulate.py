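"""Synthetic data generator with planted ground truth.

Builds a toy multi-gene genome and emits everything the downstream pipeline
consumes: a FASTA genome, a GTF annotation, PAR-CLIP SAM replicates whose
reads carry T-to-C conversions at planted crosslink sites, two-condition
RNA-seq SAM files with junction reads at planted inclusion levels,
negative-binomial gene-count tables, an optional cross-platform count table
and a GMT gene-set file.

One designated gene carries an unannotated internal ("erroneous") exon whose
length is not divisible by three: present in the genome sequence, flanked by
canonical AG / GT dinucleotides, absent from the GTF, and spliced in only in
the knockout condition. Its inclusion shifts the reading frame so that the
first stop codon of the shifted frame falls two exons downstream — the
planted analogue of a frameshifting cryptic-exon inclusion that creates a
premature termination codon.

All coordinates are 0-based half-open. Every output file draws from its own
RNG stream derived from the global seed, so regenerating one file never
perturbs another, and the same configuration reproduces all files
byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import textwrap
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
NONSTOP_CODONS = [
    a + b + c for a in BASES for b in BASES for c in BASES if a + b + c not in STOPS
]
# codons without T cannot form a stop in any reading frame (all stops start with T)
TFREE_CODONS = [a + b + c for a in "ACG" for b in "ACG" for c in "ACG"]
# pyrimidine context written around each crosslink site; the site sits over
# the central T (index 2). All-pyrimidine with a C after every trailing T so
# the write can never create a stop codon inside a coding exon.
SITE_MOTIF = "TTTCTC"
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# --------------------------------------------------------------------------- config


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Probabilities are per-event; depths are reads per gene (PAR-CLIP, RNA-seq
    body) or reads per planted event (junction reads). ``planted_logfc`` is
    the log2 KO/WT fold change assigned to bound target genes (negative:
    bound targets are down-regulated in KO); the erroneous-exon gene gets the
    stronger ``ee_logfc``.
    """

    seed: int = 1
    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_len: tuple[int, int] = (90, 180)
    intron_len: tuple[int, int] = (250, 450)
    n_crosslink_sites: int = 120
    conversion_rate: float = 0.5
    background_conversion_rate: float = 0.005
    seq_error_rate: float = 0.001
    parclip_depth: int = 40
    rnaseq_depth: int = 100
    junction_depth: int = 100
    n_parclip_replicates: int = 3
    n_replicates_per_condition: int = 2
    psi_wt: float = 0.25
    psi_ko: float = 0.75
    ee_psi_wt: float = 0.0
    ee_psi_ko: float = 0.85
    ee_length: int = 53
    ee_n_exons: int = 10
    nb_mean: float = 200.0
    nb_dispersion: float = 0.05
    planted_logfc: float = -0.4
    ee_logfc: float = -2.0
    parclip_read_len: int = 30
    rnaseq_read_len: int = 75
    frac_intronic_sites: float = 0.8
    chrom: str = "chrS"

    def validate(self) -> None:
        for name in (
            "conversion_rate",
            "background_conversion_rate",
            "seq_error_rate",
            "psi_wt",
            "psi_ko",
            "ee_psi_wt",
            "ee_psi_ko",
            "frac_intronic_sites",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.exon_len[0] < 1 or self.intron_len[0] < 1:
            raise ValueError("exon/intron lengths must be >= 1")
        if self.exon_len[0] < self.rnaseq_read_len:
            raise ValueError(
                "minimum exon length must accommodate an RNA-seq read "
                f"({self.rnaseq_read_len} nt)"
            )
        if self.ee_n_exons < 2:
            raise ValueError(
                "the erroneous-exon gene needs at least one intron to host "
                "the planted exon"
            )
        if self.ee_length % 3 == 0:
            raise ValueError("planted erroneous-exon length must not be divisible by 3")
        # the host intron holds: GT..AG, the exon, GT..AG, plus filler margins
        if self.intron_len[0] < self.ee_length + 8 + 40:
            raise ValueError(
                "intron too short to host the planted exon plus splice sites"
            )
        if self.n_genes < 6:
            raise ValueError("need at least 6 genes to assign all planted roles")


# --------------------------------------------------------------------------- truth


@dataclass
class EventTruth:
    gene: str
    event_type: str  # SE / RI / MXE / A5SS / A3SS / novel_SE
    psi_wt: float
    psi_ko: float
    region: tuple[int, int]  # genomic interval of the alternative exon/intron
    novel: bool = False


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside the synthetic data."""

    crosslink_sites: list[tuple[str, int, str]]
    event_truth: list[EventTruth]
    logfc_truth: dict[str, float]
    ee_gene: str
    ee_interval: tuple[str, int, int, str]
    bound_genes: list[str]

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        d["event_truth"] = [EventTruth(**e) for e in d["event_truth"]]
        d["crosslink_sites"] = [tuple(s) for s in d["crosslink_sites"]]
        d["ee_interval"] = tuple(d["ee_interval"])
        return cls(**d)


# --------------------------------------------------------------------------- gene model


@dataclass
class _Isoform:
    """Exon chain (genomic, sorted) of one simulated isoform."""

    exons: list[tuple[int, int]]

    def junctions(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class _Event:
    event_type: str
    inclusion: _Isoform
    exclusion: _Isoform
    psi_wt: float
    psi_ko: float
    region: tuple[int, int]
    novel: bool = False


@dataclass
class _GeneSim:
    gene_id: str
    strand: str
    start: int = 0
    end: int = 0
    exons: list[tuple[int, int]] = field(default_factory=list)  # annotated, genomic
    cds: list[tuple[int, int]] = field(default_factory=list)
    annotated_isoforms: list[list[tuple[int, int]]] = field(default_factory=list)
    event: _Event | None = None
    ee: tuple[int, int] | None = None
    sites: list[int] = field(default_factory=list)
    bound: bool = False
    logfc: float = 0.0
    base_mean: float = 0.0

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


# --------------------------------------------------------------------------- simulator


class Simulator:
    """Builds the genome in memory and writes all synthetic data files."""

    def __init__(self, config: SimConfig):
        config.validate()
        self.config = config
        self.genes: list[_GeneSim] = []
        self.genome: str = ""
        self.truth: SimTruth | None = None
        self._built = False

    # ------------------------------------------------------------ genome

    def make_genome(self) -> SimTruth:
        """Construct genome sequence, gene models and planted truth."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        roles = self._assign_roles()
        chrom_parts: list[str] = []
        cursor = 0
        for i, role in enumerate(roles):
            spacer = "".join(rng.choice(list(BASES), size=300))
            chrom_parts.append(spacer)
            cursor += 300
            gene = self._build_gene(f"g{i + 1:03d}", role, cursor, rng)
            seq_local, length = gene.pop("_seq"), gene.pop("_len")
            gs = gene.pop("_obj")
            if gs.strand == "-":
                chrom_parts.append(revcomp(seq_local))
            else:
                chrom_parts.append(seq_local)
            cursor += length
            self.genes.append(gs)
        chrom_parts.append("".join(rng.choice(list(BASES), size=300)))
        self.genome = "".join(chrom_parts)
        self._plant_sites(rng)
        self._draw_expression(rng)
        self._verify_orfs()
        self.truth = self._collect_truth()
        self._built = True
        return self.truth

    def _assign_roles(self) -> list[str]:
        n = self.config.n_genes
        roles = ["ee"]
        roles += ["se_incl"] * min(4, max(1, (n - 6) // 6))
        roles += ["se_excl"] * min(4, max(1, (n - 6) // 6))
        for r in ("ri", "mxe", "a5ss", "a3ss"):
            if len(roles) < n - 2:
                roles.append(r)
        remaining = n - len(roles)
        roles += ["bound"] * (remaining // 2)
        roles += ["unbound"] * (n - len(roles))
        return roles

    def _build_gene(self, gene_id: str, role: str, offset: int, rng) -> dict:
        cfg = self.config
        if role == "ee":
            n_exons = cfg.ee_n_exons
        elif role == "mxe":
            n_exons = max(5, rng.integers(*cfg.exons_per_gene, endpoint=True))
        else:
            n_exons = max(4, rng.integers(*cfg.exons_per_gene, endpoint=True))
        exon_lens = [
            int(rng.integers(*cfg.exon_len, endpoint=True)) for _ in range(n_exons)
        ]
        intron_lens = [
            int(rng.integers(*cfg.intron_len, endpoint=True))
            for _ in range(n_exons - 1)
        ]
        strand = "+" if rng.random() < 0.5 else "-"

        # --- spliced CDS layout (transcript orientation, local coordinates)
        total_exonic = sum(exon_lens)
        u5 = 30
        cds_len = total_exonic - 60
        cds_len -= cds_len % 3
        u3 = total_exonic - u5 - cds_len
        n_codons = cds_len // 3 - 2

        utr5 = "".join(rng.choice(list(BASES), size=u5))
        utr3 = "".join(rng.choice(list(BASES), size=u3))
        codons = list(rng.choice(NONSTOP_CODONS, size=n_codons))
        if codons and codons[0] == "ATG":
            pass
        spliced = utr5 + "ATG" + "".join(codons) + "TAA" + utr3

        # spliced offsets of each exon
        ex_spl = []
        p = 0
        for L in exon_lens:
            ex_spl.append((p, p + L))
            p += L

        ee_local = None
        ee_seq = None
        host_intron = None
        if role == "ee":
            host_intron = 4  # between exon 5 and exon 6 (0-based intron index)
            # T-free codons downstream of the host intron so the only stop in
            # the shifted frame is the one we plant (in original exon 7)
            p6 = ex_spl[host_intron + 1][0]
            first = max(0, (p6 - (u5 + 3) + 2) // 3 - 1)  # codon touching exon 6
            for ci in range(first, n_codons):
                codons[ci] = str(rng.choice(TFREE_CODONS))
            spliced = utr5 + "ATG" + "".join(codons) + "TAA" + utr3
            ee_seq = "".join(rng.choice(["C", "T"], size=cfg.ee_length - 1)) + "C"
            spliced = self._plant_ptc(spliced, ex_spl, host_intron, u5, cds_len, rng)

        # --- assemble unspliced gene sequence with GT..AG introns
        parts = []
        exon_local = []
        pos = 0
        ee_interval_local = None
        for i, L in enumerate(exon_lens):
            s, e = ex_spl[i]
            parts.append(spliced[s:e])
            exon_local.append((pos, pos + L))
            pos += L
            if i < n_exons - 1:
                ilen = intron_lens[i]
                if role == "ee" and i == host_intron:
                    fill = ilen - cfg.ee_length - 8
                    f1 = fill // 2
                    f2 = fill - f1
                    up = "GT" + "".join(rng.choice(list(BASES), size=f1)) + "AG"
                    dn = "GT" + "".join(rng.choice(list(BASES), size=f2)) + "AG"
                    parts.append(up)
                    ee_interval_local = (pos + len(up), pos + len(up) + cfg.ee_length)
                    parts.append(ee_seq)
                    parts.append(dn)
                    pos += ilen
                else:
                    mid = "".join(rng.choice(list(BASES), size=ilen - 4))
                    parts.append("GT" + mid + "AG")
                    pos += ilen
        seq_local = "".join(parts)
        length = len(seq_local)

        def g(iv: tuple[int, int]) -> tuple[int, int]:
            if strand == "+":
                return (offset + iv[0], offset + iv[1])
            return (offset + length - iv[1], offset + length - iv[0])

        exons_g = sorted(g(iv) for iv in exon_local)
        gs = _GeneSim(gene_id, strand, offset, offset + length, exons_g)
        gs.cds = self._cds_genomic(exon_local, u5, cds_len, g)
        gs.ee = g(ee_interval_local) if ee_interval_local else None
        gs.event = self._plant_event(role, gs, exon_local, g, rng)
        gs.annotated_isoforms = self._annotated_isoforms(role, gs)
        gs.bound = role in ("ee", "se_incl", "se_excl", "bound")
        if role == "ee":
            gs.logfc = cfg.ee_logfc
        elif gs.bound:
            gs.logfc = cfg.planted_logfc
        return {"_obj": gs, "_seq": seq_local, "_len": length}

    def _plant_ptc(self, spliced, ex_spl, host_intron, u5, cds_len, rng) -> str:
        """Write a TAA at a shifted-frame codon start inside original exon 7."""
        cfg = self.config
        cds_start = u5
        # variant spliced coordinates: EE inserted after exon (host_intron)
        ins_at = ex_spl[host_intron][1]
        target_exon = host_intron + 2  # original exon 7 (0-based index 6)
        v7s = ex_spl[target_exon][0] + cfg.ee_length
        t = v7s + 40
        t += (3 - (t - cds_start) % 3) % 3
        orig = t - cfg.ee_length  # back to canonical spliced coordinate
        assert ex_spl[target_exon][0] <= orig and orig + 3 <= ex_spl[target_exon][1]
        assert ins_at < orig
        return spliced[:orig] + "TAA" + spliced[orig + 3 :]

    @staticmethod
    def _cds_genomic(exon_local, u5, cds_len, g) -> list[tuple[int, int]]:
        out = []
        spl = 0
        cds_lo, cds_hi = u5, u5 + cds_len
        for s, e in exon_local:
            L = e - s
            a = max(cds_lo, spl)
            b = min(cds_hi, spl + L)
            if b > a:
                out.append(g((s + (a - spl), s + (b - spl))))
            spl += L
        return sorted(out)

    def _plant_event(self, role, gs: _GeneSim, exon_local, g, rng) -> _Event | None:
        cfg = self.config
        exons = gs.exons
        n = len(exons)
        if role == "ee":
            return _Event(
                "novel_SE",
                _Isoform(sorted(set(exons) | {gs.ee})),
                _Isoform(exons),
                cfg.ee_psi_wt,
                cfg.ee_psi_ko,
                gs.ee,
                novel=True,
            )
        if role in ("se_incl", "se_excl"):
            alt = n // 2  # internal exon
            excl = exons[:alt] + exons[alt + 1 :]
            psi_wt, psi_ko = (
                (cfg.psi_wt, cfg.psi_ko) if role == "se_incl" else (cfg.psi_ko, cfg.psi_wt)
            )
            return _Event(
                "SE", _Isoform(exons), _Isoform(excl), psi_wt, psi_ko, exons[alt]
            )
        if role == "ri":
            k = (n - 1) // 2
            intr = gs.introns[k]
            merged = exons[: k] + [(exons[k][0], exons[k + 1][1])] + exons[k + 2 :]
            return _Event(
                "RI", _Isoform(merged), _Isoform(exons), cfg.psi_wt, cfg.psi_ko, intr
            )
        if role == "mxe":
            # two adjacent internal exons used mutually exclusively
            k = n // 2
            iso1 = exons[: k] + exons[k + 1 :]  # uses exon k-? keep M1 = exons[k-?]
            m1, m2 = exons[k - 1], exons[k]
            iso1 = [e for e in exons if e != m2]
            iso2 = [e for e in exons if e != m1]
            return _Event(
                "MXE", _Isoform(iso1), _Isoform(iso2), cfg.psi_wt, cfg.psi_ko, m1
            )
        if role in ("a5ss", "a3ss"):
            k = n // 2
            shift = 45
            s, e = exons[k]
            # extended-exon isoform moves one boundary into the intron
            if role == "a5ss":
                left_edge = gs.strand == "+"
            else:
                left_edge = gs.strand == "-"
            if left_edge:
                # alternative right boundary of exon k (donor on +, acceptor on -)
                long_ex = (s, e + shift)
            else:
                long_ex = (s - shift, e)
            iso_long = [long_ex if ex == exons[k] else ex for ex in exons]
            return _Event(
                role.upper(),
                _Isoform(iso_long),
                _Isoform(exons),
                cfg.psi_wt,
                cfg.psi_ko,
                long_ex,
            )
        return None

    def _annotated_isoforms(self, role, gs: _GeneSim) -> list[list[tuple[int, int]]]:
        isoforms = [list(gs.exons)]
        if role in ("mxe", "a5ss", "a3ss") and gs.event is not None:
            isoforms.append(list(gs.event.inclusion.exons))
        return isoforms

    # ------------------------------------------------------------ crosslink sites

    def _plant_sites(self, rng) -> None:
        cfg = self.config
        budget = cfg.n_crosslink_sites
        placed: list[tuple[_GeneSim, int]] = []

        def place_at(gene: _GeneSim, pos: int) -> None:
            pos = self._write_motif(gene, pos)
            gene.sites.append(pos)
            placed.append((gene, pos))

        # binding concentrated at exons included in KO (and the planted EE)
        for gene in self.genes:
            if gene.ee is not None:
                place_at(gene, (gene.ee[0] + gene.ee[1]) // 2)
            elif (
                gene.event is not None
                and gene.event.event_type == "SE"
                and gene.event.psi_ko > gene.event.psi_wt
                and gene.bound
            ):
                s, e = gene.event.region
                place_at(gene, (s + e) // 2 - 20)
                place_at(gene, (s + e) // 2 + 20)
        # remaining sites over the other bound genes, mostly intronic
        others = [
            gn
            for gn in self.genes
            if gn.bound
            and gn.ee is None
            and not (
                gn.event is not None
                and gn.event.event_type == "SE"
                and gn.event.psi_ko > gn.event.psi_wt
            )
        ]
        # skewed per-gene quotas so binding-site counts span the analysis bins
        weights = [(i % 4 + 1) ** 2 for i in range(len(others))]
        remaining = max(0, budget - len(placed))
        quotas = [round(remaining * w / sum(weights)) for w in weights]
        for gene, quota in zip(others, quotas):
            avoid = gene.event.region if gene.event else None
            guard = 0
            while (
                sum(1 for gn, _ in placed if gn is gene) < quota and guard < quota * 20
            ):
                guard += 1
                if rng.random() < cfg.frac_intronic_sites and gene.introns:
                    s, e = gene.introns[int(rng.integers(len(gene.introns)))]
                    pos = int(rng.integers(s + 20, e - 20))
                else:
                    cand = [
                        ex
                        for ex in gene.exons[1:-1]
                        if ex != avoid and ex[1] - ex[0] > 60
                    ] or gene.exons[1:-1]
                    s, e = cand[int(rng.integers(len(cand)))]
                    pos = int(rng.integers(s + 20, e - 20))
                if all(abs(pos - p) >= 100 for gn, p in placed if gn is gene):
                    place_at(gene, pos)

    def _write_motif(self, gene: _GeneSim, pos: int) -> int:
        """Write the pyrimidine site motif into the genome around pos.

        The motif is written in transcript orientation; the site itself sits
        over the motif's central T. Returns the genomic site position.
        """
        k = len(SITE_MOTIF)
        if gene.strand == "+":
            motif, start = SITE_MOTIF, pos - 2
        else:
            motif, start = revcomp(SITE_MOTIF), pos - (k - 3)
        self.genome = self.genome[:start] + motif + self.genome[start + k :]
        return pos

    def _draw_expression(self, rng) -> None:
        for gene in self.genes:
            gene.base_mean = float(
                self.config.nb_mean * rng.lognormal(0.0, 0.6)
            )

    def _verify_orfs(self) -> None:
        """Generation-time check: canonical ORFs are clean and the EE variant
        truncates where designed."""
        for gene in self.genes:
            cds = self._spliced_cds(gene)
            assert cds[:3] == "ATG" and cds[-3:] in STOPS
            for i in range(0, len(cds) - 3, 3):
                assert cds[i : i + 3] not in STOPS, gene.gene_id

    def _spliced_cds(self, gene: _GeneSim) -> str:
        chunks = [self.genome[s:e] for s, e in gene.cds]
        seq = "".join(chunks)
        return seq if gene.strand == "+" else revcomp(seq)

    def _collect_truth(self) -> SimTruth:
        cfg = self.config
        sites = []
        for gene in self.genes:
            for pos in gene.sites:
                sites.append((cfg.chrom, pos, gene.strand))
        events = []
        ee_gene = ""
        ee_iv = None
        for gene in self.genes:
            if gene.event is not None:
                et = gene.event
                events.append(
                    EventTruth(
                        gene.gene_id,
                        et.event_type,
                        et.psi_wt,
                        et.psi_ko,
                        et.region,
                        et.novel,
                    )
                )
            if gene.ee is not None:
                ee_gene = gene.gene_id
                ee_iv = (cfg.chrom, gene.ee[0], gene.ee[1], gene.strand)
        return SimTruth(
            crosslink_sites=sites,
            event_truth=events,
            logfc_truth={g.gene_id: g.logfc for g in self.genes},
            ee_gene=ee_gene,
            ee_interval=ee_iv,
            bound_genes=[g.gene_id for g in self.genes if g.bound],
        )

    # ------------------------------------------------------------ writers

    def write_genome(self, outdir: str | Path) -> dict[str, Path]:
        self._require_built()
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "genome.fa"
        with open(fasta, "w") as fh:
            fh.write(f">{self.config.chrom}\n")
            fh.write(textwrap.fill(self.genome, 60) + "\n")
        gtf = outdir / "annotation.gtf"
        self._write_gtf(gtf)
        truth_path = outdir / "truth.json"
        self.truth.to_json(truth_path)
        return {"fasta": fasta, "gtf": gtf, "truth": truth_path}

    def _write_gtf(self, path: Path) -> None:
        chrom = self.config.chrom
        lines = []

        def rec(feature, s, e, gid, tid=None, frame="."):
            attrs = f'gene_id "{gid}";'
            if tid:
                attrs += f' transcript_id "{tid}";'
            lines.append(
                f"{chrom}\tclipsplice_sim\t{feature}\t{s + 1}\t{e}\t.\t"
                f"{strand}\t{frame}\t{attrs}"
            )

        for gene in self.genes:
            strand = gene.strand
            rec("gene", gene.start, gene.end, gene.gene_id)
            for ti, chain in enumerate(gene.annotated_isoforms, 1):
                tid = f"{gene.gene_id}.t{ti}"
                rec("transcript", chain[0][0], chain[-1][1], gene.gene_id, tid)
                for s, e in chain:
                    rec("exon", s, e, gene.gene_id, tid)
                if ti == 1:
                    cds_order = gene.cds if strand == "+" else gene.cds[::-1]
                    phase = 0
                    for s, e in cds_order:
                        rec("CDS", s, e, gene.gene_id, tid, frame=str(phase))
                        phase = (3 - ((e - s - phase) % 3)) % 3
        Path(path).write_text("\n".join(lines) + "\n")

    def _sam_header(self):
        return pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "unsorted"},
                "SQ": [{"SN": self.config.chrom, "LN": len(self.genome)}],
            }
        )

    def write_parclip(self, outdir: str | Path) -> list[Path]:
        """One SAM per PAR-CLIP replicate."""
        self._require_built()
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for rep in range(1, self.config.n_parclip_replicates + 1):
            rng = np.random.default_rng(self.config.seed + 100 + rep)
            path = outdir / f"parclip_rep{rep}.sam"
            self._write_parclip_one(path, rng, rep)
            paths.append(path)
        return paths

    def _write_parclip_one(self, path: Path, rng, rep: int) -> None:
        cfg = self.config
        R = cfg.parclip_read_len
        header = self._sam_header()
        qn = 0
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for gene in self.genes:
                starts = []
                # parclip_depth reads per crosslink site + scattered background
                n_bg = max(1, round(0.2 * cfg.parclip_depth))
                for _ in range(n_bg):
                    starts.append(int(rng.integers(gene.start, gene.end - R)))
                if gene.bound and gene.sites:
                    for site in gene.sites:
                        lo = max(gene.start, site - R + 1)
                        hi = min(gene.end - R, site)
                        for _ in range(cfg.parclip_depth):
                            starts.append(int(rng.integers(lo, hi + 1)))
                for start in starts:
                    qn += 1
                    self._emit_parclip_read(out, header, gene, start, rng, qn, rep)

    def _emit_parclip_read(self, out, header, gene, start, rng, qn, rep) -> None:
        cfg = self.config
        R = cfg.parclip_read_len
        ref = self.genome[start : start + R]
        read = list(ref)
        # T (transcript orientation) appears as ref T on + genes, ref A on -
        t_ref, c_read = ("T", "C") if gene.strand == "+" else ("A", "G")
        site_set = {s for s in gene.sites if start <= s < start + R}
        for i, b in enumerate(ref):
            gpos = start + i
            if b != t_ref:
                continue
            # crosslink-induced and spurious conversions are independent
            p = cfg.background_conversion_rate
            if gpos in site_set:
                p = 1.0 - (1.0 - cfg.conversion_rate) * (1.0 - p)
            if rng.random() < p:
                read[i] = c_read
        for i in np.nonzero(rng.random(R) < cfg.seq_error_rate)[0]:
            read[i] = BASES[(BASES.index(read[i]) + 1 + int(rng.integers(3))) % 4]
        seq = "".join(read)
        a = pysam.AlignedSegment(header)
        a.query_name = f"pc{rep}_{qn}"
        a.flag = 0 if gene.strand == "+" else 16
        a.reference_id = 0
        a.reference_start = start
        a.mapping_quality = 255
        a.cigarstring = f"{R}M"
        a.query_sequence = seq
        a.query_qualities = pysam.qualitystring_to_array("I" * R)
        md, nm = _md_tag(ref, seq)
        a.set_tags([("MD", md), ("NM", nm)])
        out.write(a)

    def write_rnaseq(self, outdir: str | Path) -> dict[str, list[Path]]:
        """SAM + gene-count TSV per sample (wt_1.., ko_1..)."""
        self._require_built()
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sams, counts = [], []
        idx = 0
        for cond in ("wt", "ko"):
            for rep in range(1, self.config.n_replicates_per_condition + 1):
                idx += 1
                rng = np.random.default_rng(self.config.seed + 200 + idx)
                sam = outdir / f"rnaseq_{cond}{rep}.sam"
                self._write_rnaseq_one(sam, cond, rng)
                sams.append(sam)
                crng = np.random.default_rng(self.config.seed + 300 + idx)
                tsv = outdir / f"counts_{cond}{rep}.tsv"
                self._write_counts(tsv, cond, crng)
                counts.append(tsv)
        return {"sam": sams, "counts": counts}

    def _write_rnaseq_one(self, path: Path, cond: str, rng) -> None:
        cfg = self.config
        R = cfg.rnaseq_read_len
        header = self._sam_header()
        qn = 0
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for gene in self.genes:
                # exon-internal coverage reads
                exlens = np.array([e - s for s, e in gene.exons], dtype=float)
                ok = exlens >= R
                w = np.where(ok, exlens - R + 1, 0.0)
                w /= w.sum()
                for _ in range(cfg.rnaseq_depth):
                    k = int(rng.choice(len(gene.exons), p=w))
                    s, e = gene.exons[k]
                    start = int(rng.integers(s, e - R + 1))
                    qn += 1
                    self._emit_rna_read(out, header, gene, start, f"{R}M", rng, qn)
                if gene.event is not None:
                    psi = gene.event.psi_ko if cond == "ko" else gene.event.psi_wt
                    qn = self._emit_event_reads(out, header, gene, psi, rng, qn)

    def _emit_event_reads(self, out, header, gene, psi, rng, qn) -> int:
        cfg = self.config
        R = cfg.rnaseq_read_len
        ev = gene.event
        inc_j = ev.inclusion.junctions()
        exc_j = ev.exclusion.junctions()
        if ev.event_type == "RI":
            # a retained molecule spans both intron boundaries unspliced
            s, e = ev.region
            only_exc = [j for j in exc_j if j not in inc_j]
            n_fill = int(round(psi * cfg.junction_depth))
            for _ in range(n_fill):  # intron-body coverage for RI detection
                start = int(rng.integers(s, max(s + 1, e - R)))
                qn += 1
                self._emit_rna_read(out, header, gene, start, f"{R}M", rng, qn)
            for _ in range(cfg.junction_depth):
                if rng.random() < psi:
                    for b in (s, e):
                        qn += 1
                        m1 = int(rng.integers(6, R - 5))
                        self._emit_rna_read(
                            out, header, gene, b - m1, f"{R}M", rng, qn
                        )
                else:
                    j = only_exc[int(rng.integers(len(only_exc)))]
                    qn += 1
                    self._emit_junction_read(out, header, gene, j, rng, qn)
            return qn
        only_inc = [j for j in inc_j if j not in exc_j]
        only_exc = [j for j in exc_j if j not in inc_j]
        for _ in range(cfg.junction_depth):
            # each molecule evidences every junction distinctive of its isoform
            pool = only_inc if rng.random() < psi else only_exc
            for j in pool:
                qn += 1
                self._emit_junction_read(out, header, gene, j, rng, qn)
        return qn

    def _emit_junction_read(self, out, header, gene, junction, rng, qn) -> None:
        cfg = self.config
        R = cfg.rnaseq_read_len
        gd, ga = junction
        # flanking segment lengths; clamp so the read stays inside its exons
        left_len = self._flank_len(gene, gd, left=True)
        right_len = self._flank_len(gene, ga, left=False)
        lo = max(6, R - right_len)
        hi = min(R - 6, left_len)
        m1 = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        m2 = R - m1
        cigar = f"{m1}M{ga - gd}N{m2}M"
        self._emit_rna_read(out, header, gene, gd - m1, cigar, rng, qn)

    def _flank_len(self, gene, boundary, left: bool) -> int:
        best = 10**9
        for iso in (gene.event.inclusion, gene.event.exclusion):
            for s, e in iso.exons:
                if left and e == boundary:
                    return e - s
                if not left and s == boundary:
                    return e - s
        return best

    def _emit_rna_read(self, out, header, gene, start, cigar, rng, qn) -> None:
        cfg = self.config
        # reference bases under M operations
        ref_parts = []
        pos = start
        num = ""
        for ch in cigar:
            if ch.isdigit():
                num += ch
                continue
            n = int(num)
            num = ""
            if ch == "M":
                ref_parts.append(self.genome[pos : pos + n])
                pos += n
            elif ch == "N":
                pos += n
        ref = "".join(ref_parts)
        read = list(ref)
        for i in np.nonzero(rng.random(len(read)) < cfg.seq_error_rate)[0]:
            read[i] = BASES[(BASES.index(read[i]) + 1 + int(rng.integers(3))) % 4]
        seq = "".join(read)
        a = pysam.AlignedSegment(header)
        a.query_name = f"rna_{qn}"
        a.flag = 0 if gene.strand == "+" else 16
        a.reference_id = 0
        a.reference_start = start
        a.mapping_quality = 255
        a.cigarstring = cigar
        a.query_sequence = seq
        a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        md, nm = _md_tag(ref, seq)
        a.set_tags([("MD", md), ("NM", nm)])
        out.write(a)

    def _write_counts(self, path: Path, cond: str, rng) -> None:
        cfg = self.config
        lines = ["gene_id\tcount"]
        for gene in self.genes:
            mean = gene.base_mean * (2.0 ** gene.logfc if cond == "ko" else 1.0)
            r = 1.0 / cfg.nb_dispersion
            p = r / (r + mean)
            c = int(rng.negative_binomial(r, p))
            lines.append(f"{gene.gene_id}\t{c}")
        path.write_text("\n".join(lines) + "\n")

    def write_crossplatform(self, outdir: str | Path) -> Path:
        """Cross-platform (probe-hybridization-style) count table: a gene
        subset re-measured from the same planted means with independent
        noise, one column per sample."""
        self._require_built()
        cfg = self.config
        outdir = Path(outdir)
        rng = np.random.default_rng(cfg.seed + 400)
        subset = self.genes[:: max(1, len(self.genes) // 20)]
        cols = [
            f"{cond}{rep}"
            for cond in ("wt", "ko")
            for rep in range(1, cfg.n_replicates_per_condition + 1)
        ]
        lines = ["gene_id\t" + "\t".join(cols)]
        for gene in subset:
            vals = []
            for col in cols:
                mean = gene.base_mean * (
                    2.0 ** gene.logfc if col.startswith("ko") else 1.0
                )
                r = 1.0 / cfg.nb_dispersion
                c = int(rng.negative_binomial(r, r / (r + mean)))
                vals.append(str(c))
            lines.append(gene.gene_id + "\t" + "\t".join(vals))
        path = outdir / "crossplatform_counts.tsv"
        path.write_text("\n".join(lines) + "\n")
        return path

    def write_gene_sets(self, outdir: str | Path) -> Path:
        """GMT file: the planted bound-target set plus random decoys."""
        self._require_built()
        rng = np.random.default_rng(self.config.seed + 500)
        all_ids = [g.gene_id for g in self.genes]
        lines = [
            "BOUND_TARGETS\tplanted\t"
            + "\t".join(g.gene_id for g in self.genes if g.bound)
        ]
        for i in range(1, 4):
            pick = sorted(
                rng.choice(all_ids, size=min(8, len(all_ids) // 2), replace=False)
            )
            lines.append(f"RANDOM_SET_{i}\trandom\t" + "\t".join(pick))
        path = Path(outdir) / "gene_sets.gmt"
        path.write_text("\n".join(lines) + "\n")
        return path

    def write_all(self, outdir: str | Path) -> dict:
        """Generate genome (if needed) and write every output file."""
        if not self._built:
            self.make_genome()
        outdir = Path(outdir)
        files = self.write_genome(outdir)
        files["parclip"] = self.write_parclip(outdir)
        files.update(self.write_rnaseq(outdir))
        files["crossplatform"] = self.write_crossplatform(outdir)
        files["gene_sets"] = self.write_gene_sets(outdir)
        return files

    def _require_built(self) -> None:
        if not self._built:
            raise RuntimeError("call make_genome() first")


# --------------------------------------------------------------------------- helpers


def _md_tag(ref: str, read: str) -> tuple[str, int]:
    """MD string and NM count for a gapless-per-block alignment."""
    out = []
    run = 0
    nm = 0
    for r, q in zip(ref, read):
        if r == q:
            run += 1
        else:
            out.append(str(run))
            out.append(r)
            run = 0
            nm += 1
    out.append(str(run))
    return "".join(out), nm


def simulate(config: SimConfig, outdir: str | Path) -> tuple[SimTruth, dict]:
    """Convenience wrapper: build and write the full synthetic dataset."""
    sim = Simulator(config)
    truth = sim.make_genome()
    files = sim.write_all(outdir)
    return truth, files
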