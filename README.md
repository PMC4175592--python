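# clipscreen

`clipscreen` is a pipeline for finding exons that are jointly controlled by a
pair of paralogous splicing factors, of the kind exemplified by the human
Tra2α/Tra2β pair. The two paralogs bind the same AGAA/GAA-rich RNA motifs and
cross-regulate each other asymmetrically (the dominant paralog represses the
other via poison-exon inclusion), so depleting either protein alone is
buffered by de-repression of its partner, and only joint depletion reveals
the shared target exons. The package implements the computational route from
raw iCLIP reads to a classified list of knockdown-responsive exons:

1. **Preprocessing** — experiment/random barcode extraction, length
   filtering, collapse of mapped tags to unique cDNAs by
   (truncation position, strand, random barcode), and crosslink-site calling
   at the nucleotide immediately 5′ of each tag start.
2. **Cluster calling** — per-gene randomization null: the gene's cDNA total
   is redistributed uniformly over the gene span R times, and a site of
   height *h* gets FDR(h) = E_null[#positions ≥ h] / #observed ≥ h.
   Significant sites within 15 nt merge into clusters.
3. **Motif analysis** — pentamer counting in ±30 nt windows around crosslink
   sites, z-scores against position-randomized nulls, top-10 k-mer
   extraction, and per-exon binding-site density (% of exon nucleotides
   covered by top-k-mer occurrences).
4. **Region mapping** — assignment of cDNAs to
   5′UTR/ORF/3′UTR/intron/ncRNA/intergenic classes, raw and
   region-size-corrected percentages.
5. **Exon screen** — exons ranked by iCLIP tag count in the exon ±300 nt
   window relative to total gene coverage.
6. **Splicing response** — PSI = 100·included/(included+skipped) from
   replicate isoform measurements; ΔPSI contrasts vs control with
   equal-variance two-sample t-tests; response classes
   (responsive > 15 PSI points on joint depletion, strong > 40,
   constitutive-like ≥ 95% control inclusion) and a paralog-compensation
   flag for exons whose joint-depletion effect exceeds both single-depletion
   effects.

A first-class synthetic-data module (`clipscreen.synthgen`) generates a toy
genome with planted AGAA/GAA motif regions, crosslink-biased truncated reads
with PCR duplicates and random barcodes, and replicate PSI measurements from
an explicit asymmetric-feedback model — with full ground truth — so every
stage can be validated as a recovery problem without any external data.

## Worked example

```python
from clipscreen import (SimConfig, FeedbackModel, KnockdownDesign,
                        generate_genome, simulate_iclip, simulate_splicing,
                        GeneSpan, call_clusters, deduplicate,
                        call_crosslink_sites, kmer_counts, kmer_zscores,
                        top_kmers, delta_psi, classify_response,
                        compensation_test)

cfg = SimConfig(seed=1, n_genes=20, n_reads=6000)
genome, genes, truth = generate_genome(cfg)
sim = simulate_iclip(genome, genes, cfg, truth)

cdnas = deduplicate(sim.alignments)
sites, _ = call_crosslink_sites(cdnas)
spans = [GeneSpan.from_gene(g) for g in genes]
_, clusters = call_clusters(sites, spans, R=100, alpha=0.05, seed=1)

obs = kmer_counts(sites, genome, flank=30, k=5)
scores = kmer_zscores(obs, sites, spans, genome, R=100, seed=1)
print(len(cdnas), "unique cDNAs;", len(clusters), "clusters;",
      "top pentamers:", top_kmers(scores, n_top=5))

meas, _ = simulate_splicing(genes, FeedbackModel(), KnockdownDesign(), cfg,
                            truth=truth)
for r in delta_psi(meas):
    if r.exon_id in ("G000.cas", "G003.cas"):
        classify_response(r); compensation_test(r)
        print(r.exon_id, round(r.delta_psi["kd_double"], 1), r.classes,
              r.compensated)
```

prints

```
5951 unique cDNAs; 8 clusters; top pentamers: ['AAGAA', 'GAAGA', 'AGAAG', 'AGAAT', 'TAGAA']
G000.cas -1.8 ['non-responder'] False
G003.cas -76.3 ['responsive', 'strong'] True
```

All 8 planted motif regions are recovered as significant clusters, the top
pentamers are the planted AGAA/GAA vocabulary, and the motif-dependent exon
`G003.cas` shows the diagnostic compensation signature: small single-knockdown
shifts (−5.7/−7.6 PSI points) but a −76-point collapse on joint depletion.

## Command line

```bash
clipscreen all --outdir run1 --seed 1       # simulate + full pipeline
clipscreen simulate --config cfg.yaml       # individual stages:
clipscreen preprocess | clusters | kmers | density | regions | screen | psi | report
```

Every stage writes plain-text outputs (FASTA/GTF/FASTQ/BED/TSV) plus a run
manifest with parameters, seeds and input checksums. Exit codes: 0 ok,
2 configuration error, 3 data error.

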