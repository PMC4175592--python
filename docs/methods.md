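# Methods

This note documents the models, estimators and numerical choices behind
`clipscreen`, and what the synthetic-data validation does and does not show
about real data.

## Coordinates and data model

All genomic coordinates are 0-based, half-open (BED convention). An iCLIP
read truncates at the protein–RNA crosslink, so after barcode removal the
crosslink site of a mapped tag `[s, e)` is `s − 1` on the + strand and `e`
on the − strand (the nucleotide immediately 5′ of the tag start in
transcript orientation). Sites that would fall off a chromosome edge are
dropped and counted rather than clamped. The unit of evidence everywhere is
the **unique cDNA**: mapped tags collapsed by (strand-aware start position,
strand, chromosome, random barcode). The tag *end* is deliberately not part
of the key — the truncation point defines the cDNA identity, so two PCR
copies trimmed to different lengths still collapse. Deduplication runs per
replicate (library), and replicates are pooled afterwards for site calling;
both behaviours are available in the library API.

Reads whose insert is shorter than 11 nt after barcode removal are
discarded (an insert of exactly 11 nt is kept). Experiment barcodes must
match a configured sample sheet exactly; mismatches are counted and
dropped.

## Randomization null and site FDR

For each gene independently, the observed cDNA total N is placed uniformly
at random over the gene's permissible positions (full gene span by
default; a region-restricted span can be supplied) R times, as a single
multinomial draw per randomization, so every randomization conserves N
exactly. For an observed height h:

    FDR(h) = mean_r[ #positions with randomized height ≥ h ]
             ─────────────────────────────────────────────
             #observed sites with height ≥ h

clamped to [0, 1]. The raw ratio is not guaranteed monotone, so a running
minimum over ascending h enforces that a taller site never receives a
larger FDR than a shorter one. Sites with FDR < α (default 0.05) are
significant; significant sites within 15 nt of each other (boundary
inclusive, measured between crosslink positions) merge greedily into
clusters, whose reported FDR is the minimum member FDR. An optional second
stage compares each cluster's height sum against the maximal sliding
16-nt-window sum per randomization (`cluster_window_fdr`); the site-level
route is the default because it is the simpler reading of the protocol and
is what the tests validate. No cross-gene multiplicity correction is
applied; the protocol this follows applies none.

On genes small enough to enumerate (span 10, ≤ 5 cDNAs), the Monte-Carlo
FDR is tested against the exact average over all L^N placements and agrees
within two Monte-Carlo standard errors at R = 5000.

## Pentamer enrichment

k-mers (k = 5) are counted on the annotated strand in windows of ±30 nt
around each crosslink site (windows trimmed at chromosome ends). Counting
is exact and vectorised: the genome is integer-encoded once and each
window contributes a slice of precomputed rolling base-4 codes (forward or
reverse-complement for − strand windows). The null repeats the counting at
R sets of positions drawn uniformly within the same genes (site count per
gene preserved); z = (obs − null mean)/null sd, with sd = 0 reported as
z = 0 plus a flag. The top-n ranking breaks ties lexicographically so runs
are reproducible.

The choice of R trades speed against the tail accuracy of z: with R
randomizations the statistic is t-like with R − 1 df, so small R inflates
extreme |z|. Enrichment *ranking* is stable at R ≈ 50–100; tail
*calibration* statements (e.g. "max |z| over all 1024 pentamers stays
below 4 under the null") need near-exact null moments and are evaluated at
R = 500. Even with exact moments, the maximum of ~1024 standard-normal
scores exceeds 4 in about 6% of draws, so occasional max-|z| values just
above 4 under the null are expected behaviour, not miscalibration.

Binding-site density of an exon is the percentage of its nucleotides
covered by at least one occurrence of any top-10 k-mer (union coverage;
occurrences may overlap). An exon shorter than the shortest k-mer gets
density 0 with a flag. Group densities are compared with a two-sided
equal-variance two-sample t-test (df = nA + nB − 2); Welch is available by
flag. Two zero-variance identical groups return t = 0, p = 1.

## Region assignment

cDNAs are assigned by crosslink position (a single nucleotide, not the
read span) to one of {5′UTR, ORF, 3′UTR, intron, ncRNA, intergenic}.
Overlaps resolve by the precedence ncRNA > 3′UTR > 5′UTR > ORF > intron >
intergenic (configurable); annotation is read from GTF via pyranges.
Size correction divides each class count by the class's nucleotide size
and renormalises the densities to 100%, which is scale-invariant in the
sizes. Raw and normalised percentage vectors each sum to 100 ± 0.01 by
construction.

## Exon screen

A candidate exon's window is its span extended by 300 nt on each side
(half-open, so a tag exactly 300 nt beyond either splice site still
counts), clipped to the gene span. The enrichment score is window cDNA
count / gene cDNA count; ranking is by score, then raw window count, then
coordinate, so ties resolve deterministically. A per-nucleotide-normalised
variant (window density over gene density) is available behind a flag.
Windows of neighbouring exons may overlap; tags in the overlap count for
both. **Limitation:** the raw count ratio is noisy for genes with very few
tags — a gene with 4–5 tags that all happen to fall inside the window
scores 1.0 and can outrank genuinely enriched exons; on the synthetic
benchmark this caps planted-vs-background AUC around 0.87–1.0 depending on
seed. Downstream users should treat low-coverage candidates with caution
(the raw window and gene counts are always reported alongside the score).

## Splicing response

PSI = 100·included/(included + skipped) per sample; capillary-style
readouts are assumed already molarity-corrected. Per exon, condition means
are contrasted against control with equal-variance two-sample t-tests
(two-sided, df = n1 + n2 − 2); contrasts with fewer than two replicates on
a side are skipped with a warning. No multiple-testing correction is
applied by default (per-exon p values are reported); Benjamini–Hochberg is
available by flag. Classes, driven by the joint-depletion contrast:
responsive if |ΔPSI(double)| > 15 points and p < 0.05; strong additionally
if > 40 (strong ⇒ responsive); constitutive-like if control PSI ≥ 95;
fully-constitutive at exactly 100; otherwise non-responder. The
compensation test computes the buffering score
S = |ΔPSI(double)| − max(|ΔPSI(α)|, |ΔPSI(β)|) and flags an exon
paralog-compensated when S > 15 and both single-knockdown effects stay
below 10 points; both thresholds are configurable.

## Synthetic-data generator

The generator is the package's validation instrument; its defaults define
the benchmark conditions and are fixed.

**Genome and genes.** One chromosome carrying `n_genes` (default 50)
three-exon genes (flank exons 100–140 nt, cassette exon 140–180 nt,
introns 350–450 nt, 200 nt intergenic spacers), random strand, one
transcript per gene. Coding genes get a 30 nt 5′UTR / CDS / 40 nt 3′UTR
partition that tiles the exonic span exactly; 10% of genes are ncRNA.
A fixed fraction (default 0.4, i.e. exactly 20 of 50 genes) carries one
60 nt motif region centred in the cassette exon, written on the transcript
strand. Motif regions are built from a pentamer vocabulary in which every
word contains AGAA or GAA (core words AGAAG/GAAGA/AAGAA sampled 3× more
often than ten auxiliary words), with 2–3 random bases between words. The
spacers matter: a pure tandem repeat exposes only three distinct
pentamers, whereas islands with randomized junctions let the whole planted
vocabulary — and nothing systematic besides it — rise in the enrichment
ranking, matching the qualitative structure of real AGAA/GAA-rich binding
maps.

**iCLIP reads.** Per-gene expression weights are lognormal (σ = 0.75).
The crosslink propensity of position x is
expression × (b0 + w·motif(x)) with background rate b0 = 0.05/nt and
motif weight w = 50, so ~95% of a motif gene's crosslinks fall inside its
planted region. Each molecule draws a crosslink position, an insert length
uniform on 20–40 nt, and a random barcode; the read starts one nucleotide
downstream of the crosslink in transcript orientation. The read layout
follows the barcode mask (default `NNNXXXXNN`, a common iCLIP layout: the
random barcode split around a 4 nt experiment barcode); three replicates
get distinct experiment barcodes. PCR duplication re-emits a molecule
(same position and barcode) with probability ρ = 0.15 per copy,
geometrically. Reads, true alignments (BED) and a full provenance table
(read → molecule → crosslink) are emitted; sequencing errors and aligner
behaviour are deliberately not modelled, so preprocessing tests validate
bookkeeping, not mapping robustness.

**Feedback model.** Baselines E_α = 0.1 ≪ E_β = 1.0. Knockdowns are
remaining-activity fractions k ∈ [0, 1] (default single/double knockdowns
leave 5%). Effective activities use rational de-repression:

    e_α = k_α·E_α·(1 + γ·E_β)/(1 + γ·k_β·E_β)
    e_β = k_β·E_β·(1 + γ_r·E_α)/(1 + γ_r·k_α·E_α)

with γ = 15 (strong repression of α by β) and γ_r = 0.5 (weak reverse
direction). This functional form is a modelling choice made to encode the
qualitative biology — it is not taken from any measured dose–response. It
yields the observed asymmetry (β-knockdown de-represses α strongly, α-
knockdown barely moves β) and near-perfect buffering of single knockdowns:
at γ = 15, β-knockdown raises e_α from 0.1 to ≈ 0.91, keeping total
activity at ≈ 88% of baseline. True inclusion is logistic,
PSI = 100·expit(θ0 + d_e·(e_α + e_β)) with θ0 = −2; exons of motif genes
get dependence d_e ~ U(3, 6), others d_e = 0, so dependent exons sit at
78–99% control inclusion and collapse to ~12–20% only under joint
depletion. Replicate PSI adds Gaussian noise (σ_rep = 3 PSI points)
clipped to [0, 100], and is emitted as included/skipped quantities of a
100-unit total per sample. The clipping makes extreme-inclusion exons'
replicate noise slightly asymmetric; with the default dependence range the
effect on ΔPSI estimates is < 0.1 PSI point except within ~1 point of the
bounds.

**What passing tests show.** Recovery of planted clusters/motifs/exons
demonstrates the estimators' correctness and calibration under the
generative assumptions (uniform background within genes, exact single-hit
alignments, motif-driven binding). They do not demonstrate robustness to
mapping artefacts, crosslinking sequence bias, expression-dependent
background structure, or partial knockdowns with off-target effects — all
properties of real data the generator intentionally omits.

## Problem sizes and determinism

Default validation sizes: 50-gene genome (~75 kb), 20,000 molecules across
three replicates; cluster null R = 100; enrichment null R = 100 (ranking)
or 500 (tail calibration); 50 motif-free simulations (5 genes, 1,200
molecules each) for null calibration; 1,000–2,000 simulated exons for
t-test calibration and ΔPSI-recovery checks. These sizes make every
statistical check stable while keeping a full validation run in the
single-digit minutes on one core. All randomness flows through
`numpy.random.default_rng` with explicit stage-tagged seed sequences
(per-gene streams keyed by CRC32 of the gene id), so identical configs
give byte-identical outputs; the run manifest records parameters, seeds
and input checksums.
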