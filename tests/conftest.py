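"""Shared fixtures: one full-size simulation with preprocessing and
cluster/kmer calls, reused by the recovery and acceptance tests."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from clipscreen.config import SimConfig
from clipscreen.clustercall import GeneSpan, call_clusters
from clipscreen.motifscan import kmer_counts, kmer_zscores, top_kmers
from clipscreen.preprocess import call_crosslink_sites, deduplicate
from clipscreen.synthgen import generate_genome, simulate_iclip

SIM_SEED = 1


def preprocess_simulation(sim):
    """Alignments -> per-replicate dedup -> pooled crosslink sites."""
    tags = sim.alignments.merge(
        sim.truth.provenance[["read_id", "replicate"]],
        left_on=sim.alignments["name"].str.rsplit(":", n=1).str[0],
        right_on="read_id")
    cdnas = pd.concat([deduplicate(g) for _, g in tags.groupby("replicate")],
                      ignore_index=True)
    sites, _ = call_crosslink_sites(cdnas)
    return cdnas, sites


@pytest.fixture(scope="session")
def sim50():
    """The study-scale simulation: 50 genes, 20 planted motif regions,
    strong motif crosslink bias, three replicates with PCR duplicates."""
    config = SimConfig(seed=SIM_SEED)
    genome, genes, truth = generate_genome(config)
    sim = simulate_iclip(genome, genes, config, truth)
    cdnas, sites = preprocess_simulation(sim)
    return {"config": config, "genome": genome, "genes": genes,
            "truth": truth, "sim": sim, "cdnas": cdnas, "sites": sites}


@pytest.fixture(scope="session")
def sim50_clusters(sim50):
    spans = [GeneSpan.from_gene(g) for g in sim50["genes"]]
    sites_fdr, clusters = call_clusters(sim50["sites"], spans, R=100,
                                        alpha=0.05, max_gap=15, seed=SIM_SEED)
    return {"spans": spans, "sites_fdr": sites_fdr, "clusters": clusters}


@pytest.fixture(scope="session")
def sim50_kmers(sim50, sim50_clusters):
    observed = kmer_counts(sim50["sites"], sim50["genome"], flank=30, k=5)
    scores = kmer_zscores(observed, sim50["sites"], sim50_clusters["spans"],
                          sim50["genome"], R=50, seed=SIM_SEED, flank=30, k=5)
    return {"observed": observed, "scores": scores,
            "top": top_kmers(scores, n_top=10)}
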