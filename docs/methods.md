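# Methods

`clipsplice` implements the inference chain that connects an RNA-binding
protein's (RBP's) direct transcriptome contacts to a mis-splicing consequence
in its knockout: PAR-CLIP binding-site calling, junction-based
splicing-event discovery (including unannotated exons), integration of
binding with expression and inclusion changes, and prediction of whether an
aberrant inclusion creates a premature termination codon (PTC) that triggers
nonsense-mediated decay (NMD). Every stage is exercised end-to-end on
synthetic data with planted ground truth, so all statistical behavior
documented below is measured, not assumed.

## Synthetic data generator

The generator (`clipsplice.simulate`) builds a single toy chromosome of
protein-coding genes (default 30 genes, 4–8 exons of 90–180 nt, introns of
250–450 nt, random strands) and emits the full input set: genome FASTA,
GTF, PAR-CLIP SAM replicates, two-condition RNA-seq SAM files, per-sample
gene-count TSVs, a cross-platform count table, a GMT gene-set file, and a
JSON record of the planted truth. All coordinates are 0-based half-open
internally; GTF output is 1-based inclusive as the format requires.

**Gene architecture.** Each gene carries a clean open reading frame: 30-nt
UTRs, an ATG, stop-free random codons, and a terminal stop, laid across all
exons. Introns begin `GT` and end `AG` in transcript orientation.

**The erroneous-exon gene.** One designated 10-exon gene carries a 53-nt
unannotated exon inside the intron between exons 5 and 6, flanked by its own
`AG…GT` splice sites and absent from the GTF. Its length mod 3 = 2, so
inclusion shifts the downstream reading frame. The downstream coding
sequence is constructed from T-free codons (no stop can form in any frame,
since all stop codons begin with T) with a single `TAA` written at a
shifted-frame codon position inside original exon 7 — exon 8 of the modified
chain. The exon itself is pyrimidine-only (ending in C), which both mimics
the pyrimidine-rich binding context of the modeled RBP and guarantees the
planted stop is the first one reached. Generation-time assertions verify
every canonical ORF is stop-free and the variant truncates where designed.

**Crosslink sites.** Sites sit over a transcript-orientation T; a 6-nt
pyrimidine context (`TTTCTC`, site over the central T) is written into the
genome at each site, emulating the pyrimidine preference seen in CLIP data
for this protein family without being able to create a stop codon inside a
coding exon. Binding is concentrated on the exons included in the knockout
(the regulated targets), with the remaining sites spread over the other
bound genes, 80% intronic, with skewed per-gene quotas so per-gene site
counts span the 1–9 / 10–29 / ≥30 analysis bins. At the default scale the
≥30 bin is usually empty and is skipped with a warning; the binned-ECDF
machinery is calibrated separately on constructed data.

**PAR-CLIP reads.** 30-nt single-end reads; `parclip_depth` (default 40)
reads per crosslink site plus 20% scattered background per gene. A read
covering a site carries the diagnostic conversion with probability
`conversion_rate` (default 0.5); every covered T converts spuriously at
`background_conversion_rate` (0.005), independent of the crosslink process;
all bases err at `seq_error_rate` (0.001). On minus-strand genes the
conversion appears as A→G on the forward reference; FLAG bits, MD and NM
tags are emitted so conversions are recoverable without the genome.

**RNA-seq reads.** 75-nt reads in two layers: exon-internal coverage reads
(`rnaseq_depth` per gene, default 100) and event-specific junction reads
(`junction_depth` molecules per planted event and sample, default 100). Each
simulated molecule evidences every junction distinctive of its isoform —
an included skipped exon contributes one read on each of its two flanking
junctions — which makes the halved-inclusion PSI estimator unbiased.
Retained-intron molecules contribute unspliced boundary-spanning reads plus
intron-body coverage. Junction reads keep at least 6 nt on each side of the
gap, matching the extraction filter.

**Planted events.** One gene each: novel-exon inclusion (PSI 0 → 0.85,
KO-only), retained intron, mutually exclusive exons, alternative 5' and 3'
splice sites, plus several annotated skipped exons included (0.25 → 0.75) or
excluded (0.75 → 0.25) in KO. MXE/A5SS/A3SS genes are annotated with two
transcripts; SE genes with the inclusion isoform only.

**Counts.** Per-gene baselines are log-normal around `nb_mean` (200);
samples draw NB(mean·2^(logfc·[KO]), dispersion 0.05). Dispersion 0.05
represents well-measured bulk RNA-seq of moderately expressed genes. Bound
target genes are down-regulated at −0.4 log2 units — a modest shift, which
is what the binding-bin ECDF comparison visualizes — while the
erroneous-exon gene, whose transcript is degraded by NMD, is planted at −2
(the "most down-regulated bound target"). Planting strong fold changes on
all bound genes would both be biologically implausible and bias
median-of-ratios normalization, whose size factors assume most genes are
unchanged.

**Determinism.** Each output file draws from its own RNG stream
(`seed + file-index` offsets), so adding a file never perturbs the others
and a configuration reproduces every file byte-identically; the end-to-end
driver writes a manifest of SHA-256 hashes to make this checkable.

## Binding-site calling

Reads are PCR-deduplicated on (chrom, strand, start, sequence); bases below
quality 20 are ignored. The conversion profile counts, per strand-aware
position, coverage and transcript-orientation T-to-C mismatches (A→G on the
reference for minus-strand reads). A cluster is a maximal run of overlapping
same-strand reads; regions separated by one or more uncovered bases are
distinct. A region is emitted iff

* `n_reads ≥ 5`,
* total T-to-C conversions ≥ 2, and
* conversion specificity ≥ 0.01, where specificity = conversions per
  covered-T opportunity (the sum of coverage over reference-T positions in
  the region).

The specificity default deserves a note: a 30-nt read covers ~8 Ts but a
crosslink converts only the site T, so even a perfectly converted site
scores ≈ rate/8 ≈ 0.06; the spurious floor (background conversion plus a
third of sequencing errors) is ≈ 0.006. The 0.01 default sits between the
two. Thresholds demanding per-read conversion fractions (e.g. 0.2) are
incompatible with this per-opportunity definition and would reject every
true site. All three gates are CLI-overridable and re-checkable from the
profile.

This caller is deliberately simpler than kernel-density peak callers
(no sub-peak splitting, no half-site smoothing): the downstream statistics
consume per-gene cluster counts and cluster-exon overlaps, for which
contiguous read-overlap regions are sufficient and fully testable.

Clusters are annotated by their midpoint with the fixed priority
CDS > 5'UTR > 3'UTR > noncoding exon > intron > intergenic, which guarantees
one category per cluster and fractions that sum to 1. Gene assignment takes
the same-strand gene span containing the midpoint, ties broken by longest
overlap then lexicographic id. Replicate agreement is summarized as pairwise
Spearman correlation of per-gene conversion totals (mid-ranks for ties).

**k-mer enrichment.** Cluster sequences (transcript orientation) are
compared to a dinucleotide-preserving shuffle of themselves (Altschul–
Erikson; 20 shuffles per cluster by default) or to flanking sequence. Each
5-mer's target count is tested against the background frequency with a
two-sided binomial tail test (twice the smaller tail, capped at 1),
BH-corrected. Clusters shorter than k are skipped and counted.

## Splicing events

Junctions are read from N-containing CIGARs with ≥ 6 nt aligned on both
sides of the gap, counted per sample, and flagged as annotated when the
intron matches an annotated exon chain. Event classification works on
junction geometry per (chrom, strand), requiring a pooled count ≥ 2:

* **SE** — a skip junction (d, a) together with junctions (d, xs) and
  (xe, a) around an annotated exon (xs, xe).
* **Novel SE** — a pair of unannotated junctions implying an exon strictly
  inside an annotated intron; when the genome is available both implied
  introns must have canonical GT–AG (transcript-orientation) dinucleotides.
  Implied non-positive exon lengths are discarded with a log message.
* **MXE** — two internal exons sharing both flank junctions with no
  direct skip junction and no junction connecting them.
* **A5SS / A3SS** — two junctions sharing one intron boundary, provided no
  junction lands between the alternative boundaries (which would indicate a
  skipped exon instead); the 5'/3' label follows the strand.
* **RI** — an annotated intron with a spliced junction whose median
  intron-body coverage reaches 0.5× the median flanking-exon coverage in at
  least one sample; inclusion evidence is the count of unspliced reads
  spanning either intron boundary with 6 nt on both sides.

**PSI.** Inclusion evidence is divided by the number of supporting
junctions (two for SE/RI/MXE, one for A5SS/A3SS) so one molecule contributes
one unit: psi = (I/nᵢ) / (I/nᵢ + S/nₛ); undefined (None) without evidence.

**Differential test.** Counts are pooled within condition and tested with a
two-sided Fisher exact test on the 2×2 inclusion/skipping × KO/WT table,
BH-corrected across events; significance defaults to q < 0.05 with
|ΔPSI| ≥ 0.1. This replaces replicate-aware likelihood models (rMATS-style)
with an exact, dependency-free test appropriate at this scale; pooling
ignores between-replicate overdispersion, which is the main caveat when
replicates disagree. Measured on synthetic data: type-I error ≤ 0.05 at
q < 0.05 over 1,000 null events (Fisher is conservative), power ≥ 0.9 at
ΔPSI = 0.6 with 100 molecules per condition, and PSI recovery within ±0.05
at ≥ 200 molecules per junction.

## Integration

**Fold changes.** Median-of-ratios normalization (size factor = median of
count/geometric-mean over genes nonzero in all samples), then
log2((mean_KO + 0.5)/(mean_WT + 0.5)). The pseudocount keeps ratios finite
and symmetric. With strongly asymmetric differential expression the median
shifts slightly — visible in tests as a small positive bias on null genes —
which is inherent to this normalization family.

**Binding bins and ECDFs.** Genes are binned by cluster count exactly as
0 / 1–9 / 10–29 / ≥30 (CLI-overridable edges); each bound bin's log2FC ECDF
is compared to the unbound bin with the two-sample KS statistic
(exact max-|ΔECDF|) and the asymptotic Kolmogorov p-value. The asymptotic p
is standard practice at these sample sizes; the statistic itself is verified
against brute force. Empty bins are skipped with a warning.

**Metagene.** For each significant skipped-exon event direction (included/
excluded in KO) and panel (target exon, upstream and downstream neighbor),
the profile is the mean over events of the binary indicator "a cluster of
this gene overlaps this position" in ±500 nt around the exon center,
flipped on minus-strand genes so +x is downstream in transcription. The
binary (depth-free) summary matches "arbitrary relative units" and is robust
to coverage differences between events. Only exon-skipping events enter:
the window is anchored on an exon center, which other event classes lack.

**Preranked gene-set enrichment.** Weighted KS running sum with weight
|score| (exponent 1), ES = maximum deviation from zero; null by gene-label
permutation of set membership (the input is already a ranked list, so
phenotype permutation is unavailable); p is one-sided on the same-sign null
with the (r+1)/(n+1) estimator; NES divides ES by the mean |null ES| of the
same sign; BH across sets. Sets with fewer than 5 ranked members are
skipped. The vectorized running sum is tested against a plain-loop
recomputation for every set, and permutation p-values are verified uniform
under random sets.

**Prioritization.** Candidates are genes with ≥ 1 cluster, an exon included
in KO (ΔPSI > 0 at q < 0.05), and log2FC < 0, sorted ascending by log2FC
with ties broken by more clusters then gene id; the perturbed RBP's own gene
can be excluded. For candidates whose included exon is novel, the isoform is
rebuilt and the NMD call attached.

## NMD prediction

The modified isoform splices the new exon into its host intron (an insert
overlapping an exon, or not strictly inside one intron, is an error; a
zero-length insert is the identity). The ORF is re-scanned from the original
start codon; the first in-frame stop upstream of the (insert-shifted)
annotated stop is the PTC, reported with its 1-based exon index in the
modified chain; a missing stop flags the variant nonstop. The 50-nt rule is
applied strictly: NMD iff the PTC start lies more than 50 nt upstream of
the last exon–exon junction in transcript coordinates; a PTC exactly 50 nt
upstream, or in the last exon, or any single-exon transcript, is negative.
`frame_shifted` is true iff the insert length is not divisible by 3
(checked exhaustively for lengths 1–100).

**In-silico RT-PCR.** Primers are transcript-anchored genomic intervals; a
primer site exists in an isoform only if its interval is fully exonic there
(a junction-spanning primer has no contiguous genomic site). The product
length is the inclusive spliced-coordinate distance from the forward
primer's 5' end to the reverse primer's 5' end; missing sites or inverted
orientation give no product. The product difference between the
exon-included and canonical isoforms equals the exon length for any primer
pair flanking the insertion, which is a property test.

## Problem sizes and calibration checks

Tests and the acceptance script run at desk scale by design: the default
genome is 30 genes (~90 kb), three PAR-CLIP replicates at 40 reads per site,
two RNA-seq replicates per condition at 100 coverage reads per gene and 100
junction molecules per event. Measured under those conditions: crosslink-
site recall and precision ≥ 0.9 pooled over 20 seeded runs (conversion 0.5,
30 reads/site); the planted erroneous-exon gene is the top-ranked candidate
and NMD-predicted in ≥ 95 of 100 seeded end-to-end runs; KS null rejection
sits at the nominal 5%; GSEA permutation p-values are uniform under random
sets.

## Known limitations

* The cluster caller does not separate adjacent crosslink sites closer than
  a read length; they merge into one cluster (site-level recall is still
  counted per site).
* Pooled-count Fisher testing ignores replicate structure.
* RI PSI uses boundary-spanning read counts, which intron-body reads can
  inflate slightly relative to the molecule-level inclusion rate.
* The generator produces uniform read starts, flat quality, no GC or
  fragment-length bias, no multimapping, and exact splice alignments, so
  passing tests demonstrate algorithmic correctness on idealized data, not
  robustness to alignment artifacts in real libraries.
* The asymptotic KS p-value is slightly conservative below ~20 samples per
  bin.
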