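"""End-to-end orchestration: simulate -> preprocess -> clusters -> kmers ->
density -> regions -> screen -> psi -> report.

Every stage writes plain-text outputs into the run directory and the run
manifest records parameters, seeds and input checksums so a rerun with
the same config is byte-identical for deterministic stages.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from . import io as cio
from . import __version__
from .config import PipelineConfig, FeedbackModel, KnockdownDesign
from .clustercall import GeneSpan, call_clusters, clusters_to_bed
from .errors import ConfigurationError, DataError
from .exonscreen import candidates_table, rank_candidates, score_exons
from .motifscan import (GenomeKmerIndex, binding_density, kmer_counts,
                        kmer_zscores, top_kmers)
from .preprocess import (call_crosslink_sites, deduplicate, extract_barcodes,
                         sites_to_bed)
from .regionmap import assign_tags, build_region_index, size_normalize
from .report import candidate_report, replicate_counts
from .spliceresp import (classify_response, compensation_test, delta_psi,
                         responses_table)
from .synthgen import (ToyGenome, generate_genome, revcomp, simulate_iclip,
                       simulate_splicing)

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "clusters", "kmers", "density",
          "regions", "screen", "psi", "report")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_genome(path: str) -> ToyGenome:
    fa = Fasta(path)
    names = list(fa.keys())
    if not names:
        raise DataError(f"no sequences in {path}")
    name = names[0]
    return ToyGenome(name, str(fa[name][:]).upper())


class PipelineRun:
    """Stateful runner; stages can be run individually or via run_all()."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.outdir = config.outdir
        os.makedirs(self.outdir, exist_ok=True)
        self.paths: Dict[str, str] = {}
        self._timings: Dict[str, float] = {}

    def _out(self, name: str) -> str:
        p = os.path.join(self.outdir, name)
        return p

    def __getattr__(self, name: str):
        """Lazily reload stage artifacts from the run directory so stages
        can also be invoked individually across processes."""
        loaders = {
            "reads": lambda: cio.read_fastq(self.cfg.fastq),
            "cdnas": lambda: cio.read_bed(self._out("unique_cdnas.bed")),
            "sites": self._load_sites,
            "kmer_scores": lambda: cio.read_tsv(self._out("kmer_scores.tsv")),
            "top": lambda: top_kmers(self.kmer_scores,
                                     n_top=self.cfg.params.n_top_kmers),
            "candidates": lambda: cio.read_tsv(self._out("exon_candidates.tsv")),
            "responses": lambda: cio.read_tsv(self._out("splicing_responses.tsv")),
            "densities": lambda: cio.read_tsv(self._out("binding_density.tsv")),
        }
        if name in loaders:
            try:
                value = loaders[name]()
            except Exception as exc:  # noqa: BLE001
                raise DataError(f"stage input {name!r} unavailable: "
                                f"run the producing stage first ({exc})") from exc
            setattr(self, name, value)
            return value
        raise AttributeError(name)

    def _load_sites(self) -> pd.DataFrame:
        bed = cio.read_bed(self._out("crosslink_sites.bed"))
        return pd.DataFrame({"chrom": bed["chrom"], "strand": bed["strand"],
                             "position": bed["start"], "height": bed["score"]})

    # -- stages -------------------------------------------------------

    def simulate(self) -> None:
        t0 = time.time()
        cfg = self.cfg.sim
        genome, genes, truth = generate_genome(cfg)
        sim = simulate_iclip(genome, genes, cfg, truth)
        meas, psi_truth = simulate_splicing(genes, FeedbackModel(),
                                            KnockdownDesign(), cfg, truth=truth)
        cio.write_fasta(genome, self._out("genome.fa"))
        cio.write_gtf(genes, self._out("genes.gtf"))
        cio.write_fastq(sim.reads, self._out("reads.fastq"))
        cio.write_bed(sim.alignments, self._out("alignments.bed"))
        cio.write_tsv(truth.planted_clusters, self._out("truth_planted_clusters.tsv"))
        cio.write_tsv(truth.provenance, self._out("truth_provenance.tsv"))
        cio.write_tsv(psi_truth, self._out("truth_psi.tsv"))
        cio.write_tsv(meas, self._out("psi_measurements.tsv"))
        self.paths.update(genome=self._out("genome.fa"), gtf=self._out("genes.gtf"),
                          fastq=self._out("reads.fastq"), bed=self._out("alignments.bed"),
                          psi_table=self._out("psi_measurements.tsv"))
        self.cfg.genome = self.cfg.genome or self.paths["genome"]
        self.cfg.gtf = self.cfg.gtf or self.paths["gtf"]
        self.cfg.fastq = self.cfg.fastq or self.paths["fastq"]
        self.cfg.bed = self.cfg.bed or self.paths["bed"]
        self.cfg.psi_table = self.cfg.psi_table or self.paths["psi_table"]
        self._timings["simulate"] = time.time() - t0

    def _require(self, *attrs: str) -> None:
        for a in attrs:
            val = getattr(self.cfg, a)
            if not val:
                raise ConfigurationError(f"config is missing required path: {a}")
            if not os.path.exists(val):
                raise ConfigurationError(f"{a} path does not exist: {val}")

    def preprocess(self) -> None:
        t0 = time.time()
        self._require("fastq", "bed", "genome")
        p = self.cfg.params
        reads = cio.read_fastq(self.cfg.fastq)
        extraction = extract_barcodes(reads, self.cfg.sim.barcode_mask,
                                      min_len=p.min_insert_length)
        rep_of = {r.read_id: r.experiment_barcode for r in extraction.reads}
        tags = cio.read_bed(self.cfg.bed)
        tags = tags[tags["name"].str.rsplit(":", n=1).str[0].isin(rep_of)].copy()
        tags["replicate"] = tags["name"].str.rsplit(":", n=1).str[0].map(rep_of)
        # deduplicate per replicate, then pool for downstream calls
        cdnas = pd.concat([deduplicate(grp) for _, grp in
                           tags.groupby("replicate", sort=True)], ignore_index=True)
        genome = _load_genome(self.cfg.genome)
        sites, n_edge = call_crosslink_sites(
            cdnas, chrom_sizes={genome.chrom_name: genome.length})
        self.cdnas = cdnas
        self.sites = sites
        self.reads = reads
        cio.write_bed(cdnas, self._out("unique_cdnas.bed"))
        cio.write_bed(sites_to_bed(sites), self._out("crosslink_sites.bed"))
        stats = pd.DataFrame([{
            "n_raw_reads": len(reads),
            "n_rejected_short": extraction.n_rejected_short,
            "n_rejected_barcode": extraction.n_rejected_barcode,
            "n_mapped_tags": len(tags),
            "n_unique_cdnas": len(cdnas),
            "n_crosslink_sites": len(sites),
            "n_edge_discarded": n_edge,
        }])
        cio.write_tsv(stats, self._out("preprocess_stats.tsv"))
        self._timings["preprocess"] = time.time() - t0

    def _spans(self) -> List[GeneSpan]:
        self._require("gtf")
        return [GeneSpan.from_gene(g) for g in cio.read_gene_models(self.cfg.gtf)]

    def clusters(self) -> None:
        t0 = time.time()
        p = self.cfg.params
        sites_fdr, clusters = call_clusters(
            self.sites, self._spans(), R=p.n_randomizations,
            alpha=p.cluster_alpha, max_gap=p.cluster_max_gap, seed=self.cfg.seed)
        self.sites_fdr = sites_fdr
        self.cluster_calls = clusters
        cio.write_tsv(sites_fdr, self._out("sites_fdr.tsv"))
        bed = clusters_to_bed(clusters)
        bed.to_csv(self._out("clusters.bed"), sep="\t", header=False, index=False)
        self._timings["clusters"] = time.time() - t0

    def kmers(self) -> None:
        t0 = time.time()
        self._require("genome")
        p = self.cfg.params
        genome = _load_genome(self.cfg.genome)
        spans = self._spans()
        observed = kmer_counts(self.sites, genome, flank=p.kmer_flank, k=p.kmer_k)
        scores = kmer_zscores(observed, self.sites, spans, genome,
                              R=max(10, p.n_randomizations // 2),
                              seed=self.cfg.seed, flank=p.kmer_flank, k=p.kmer_k)
        self.kmer_scores = scores
        self.top = top_kmers(scores, n_top=p.n_top_kmers)
        cio.write_tsv(scores, self._out("kmer_scores.tsv"))
        self._timings["kmers"] = time.time() - t0

    def density(self) -> None:
        t0 = time.time()
        self._require("genome", "gtf")
        genome = _load_genome(self.cfg.genome)
        rows = []
        for g in cio.read_gene_models(self.cfg.gtf):
            for i, ((a, b), cls) in enumerate(zip(g.exons, g.exon_classes)):
                if cls != "cassette":
                    continue
                seq = genome.sequence[a:b]
                if g.strand == "-":
                    seq = revcomp(seq)
                d = binding_density(seq, self.top, exon_id=f"{g.gene_id}.cas")
                rows.append({"exon_id": d.exon_id, "length": d.length,
                             "covered": d.covered, "density_pct": d.density})
        self.densities = pd.DataFrame(rows)
        cio.write_tsv(self.densities, self._out("binding_density.tsv"))
        self._timings["density"] = time.time() - t0

    def regions(self) -> None:
        t0 = time.time()
        self._require("gtf", "genome")
        genome = _load_genome(self.cfg.genome)
        index = build_region_index(self.cfg.gtf, {genome.chrom_name: genome.length})
        dist = size_normalize(assign_tags(self.cdnas, index), index)
        self.region_dist = dist.table
        cio.write_tsv(dist.table, self._out("region_distribution.tsv"))
        self._timings["regions"] = time.time() - t0

    def screen(self) -> None:
        t0 = time.time()
        self._require("gtf")
        p = self.cfg.params
        genes = cio.read_gene_models(self.cfg.gtf)
        cands = rank_candidates(score_exons(self.cdnas, genes, flank=p.screen_flank))
        self.candidates = candidates_table(cands)
        cio.write_tsv(self.candidates, self._out("exon_candidates.tsv"))
        self._timings["screen"] = time.time() - t0

    def psi(self) -> None:
        t0 = time.time()
        self._require("psi_table")
        p = self.cfg.params
        meas = cio.read_tsv(self.cfg.psi_table)
        responses = delta_psi(meas)
        for r in responses:
            if "kd_double" in r.delta_psi:
                classify_response(r, responsive_threshold=p.responsive_delta_psi,
                                  strong_threshold=p.strong_delta_psi,
                                  constitutive_psi=p.constitutive_psi,
                                  alpha=p.test_alpha)
            compensation_test(r, min_gain=p.compensation_min_gain,
                              max_single=p.compensation_max_single)
        self.responses = responses_table(responses)
        cio.write_tsv(self.responses, self._out("splicing_responses.tsv"))
        self._timings["psi"] = time.time() - t0

    def report(self) -> None:
        t0 = time.time()
        counts = replicate_counts(self.reads, self.cdnas, self.sites)
        cio.write_tsv(counts, self._out("report_counts.tsv"))
        def _maybe(name):
            try:
                return getattr(self, name)
            except DataError:
                log.warning("report: section %s missing", name)
                return None

        cands = _maybe("candidates")
        cands = cands if cands is not None else pd.DataFrame()
        resp = _maybe("responses")
        dens = _maybe("densities")
        if not cands.empty:
            cio.write_tsv(candidate_report(cands, resp, dens),
                          self._out("report_candidates.tsv"))
        manifest = {
            "version": __version__,
            "seed": self.cfg.seed,
            "parameters": self.cfg.to_dict(),
            "timings_s": {k: round(v, 3) for k, v in self._timings.items()},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "input_checksums": {
                k: _sha256(getattr(self.cfg, k))
                for k in ("genome", "gtf", "fastq", "bed", "psi_table")
                if getattr(self.cfg, k) and os.path.exists(getattr(self.cfg, k))
            },
        }
        with open(self._out("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        self._timings["report"] = time.time() - t0

    def run_all(self) -> Dict[str, str]:
        for stage in STAGES:
            log.info("stage %s ...", stage)
            try:
                getattr(self, stage)()
            except Exception as exc:
                raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
        return {name: self._out(name) for name in sorted(os.listdir(self.outdir))}


def run_pipeline(config: PipelineConfig) -> Dict[str, str]:
    """Validate the config, run every stage, return the output file map."""
    config.sim.validate()
    return PipelineRun(config).run_all()
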