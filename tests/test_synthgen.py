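"""Generator behaviour: determinism, planted-motif bookkeeping, crosslink
bias, duplication, and the paralog feedback model."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clipscreen.config import FeedbackModel, KnockdownDesign, SimConfig
from clipscreen.errors import ConfigurationError
from clipscreen.synthgen import (generate_genome, revcomp, simulate_iclip,
                                 simulate_splicing, true_psi)
from clipscreen import io as cio


def small_config(**kw):
    defaults = dict(seed=7, n_genes=3, n_reads=600, n_replicates=2)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestGenerateGenome:
    def test_minimal_single_gene(self, tmp_path):
        cfg = SimConfig(seed=1, n_genes=1, motif_fraction=0.0, ncrna_fraction=0.0)
        genome, genes, truth = generate_genome(cfg)
        assert len(genes) == 1
        g = genes[0]
        assert len(g.exons) == 3 and g.exon_classes[1] == "cassette"
        gtf = tmp_path / "g.gtf"
        cio.write_gtf(genes, str(gtf))
        exon_lines = [l for l in gtf.read_text().splitlines()
                      if l.split("\t")[2] == "exon"]
        assert len(exon_lines) == 3

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        files = []
        for run in ("a", "b"):
            cfg = small_config()
            genome, genes, truth = generate_genome(cfg)
            sim = simulate_iclip(genome, genes, cfg, truth)
            fa = tmp_path / f"{run}.fa"
            gtf = tmp_path / f"{run}.gtf"
            fq = tmp_path / f"{run}.fastq"
            cio.write_fasta(genome, str(fa))
            cio.write_gtf(genes, str(gtf))
            cio.write_fastq(sim.reads, str(fq))
            files.append((fa.read_bytes(), gtf.read_bytes(), fq.read_bytes()))
        assert files[0] == files[1]

    def test_motif_fraction_gives_exact_planted_count(self):
        cfg = SimConfig(seed=3, n_genes=50, motif_fraction=0.4)
        _, _, truth = generate_genome(cfg)
        assert len(truth.planted_clusters) == 20

    def test_planted_region_is_motif_rich_on_transcript_strand(self):
        cfg = SimConfig(seed=5, n_genes=10, motif_fraction=1.0)
        genome, genes, truth = generate_genome(cfg)
        by_id = {g.gene_id: g for g in genes}
        for row in truth.planted_clusters.itertuples(index=False):
            seq = genome.sequence[row.start:row.end]
            if by_id[row.gene_id].strand == "-":
                seq = revcomp(seq)
            assert seq.count("GAA") >= 5   # islands every ~8 nt

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_genome(SimConfig(n_genes=0))
        with pytest.raises(ConfigurationError):
            generate_genome(SimConfig(pcr_duplication_rate=1.0))
        with pytest.raises(ConfigurationError):
            generate_genome(SimConfig(barcode_mask="III"))


class TestSimulateIclip:
    def test_uniform_crosslinks_when_motif_weight_zero(self):
        cfg = SimConfig(seed=2, n_genes=1, n_reads=4000, motif_fraction=1.0,
                        motif_weight=0.0)
        genome, genes, truth = generate_genome(cfg)
        sim = simulate_iclip(genome, genes, cfg, truth)
        g = genes[0]
        pos = sim.truth.provenance.drop_duplicates("molecule_id")["crosslink_pos"]
        counts, _ = np.histogram(pos, bins=20, range=(g.start, g.end))
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_no_duplication_means_reads_equal_molecules(self):
        cfg = small_config(pcr_duplication_rate=0.0)
        genome, genes, truth = generate_genome(cfg)
        sim = simulate_iclip(genome, genes, cfg, truth)
        prov = sim.truth.provenance
        assert len(sim.reads) == prov["molecule_id"].nunique()
        assert prov["duplicate_of"].isna().all()

    def test_strong_motif_weight_concentrates_crosslinks(self):
        cfg = SimConfig(seed=4, n_genes=1, n_reads=2000, motif_fraction=1.0,
                        motif_weight=50.0)
        genome, genes, truth = generate_genome(cfg)
        sim = simulate_iclip(genome, genes, cfg, truth)
        region = truth.planted_clusters.iloc[0]
        pos = sim.truth.provenance.drop_duplicates("molecule_id")["crosslink_pos"]
        inside = ((pos >= region.start - 5) & (pos < region.end + 5)).mean()
        assert inside >= 0.80

    def test_provenance_conservation(self):
        cfg = small_config(pcr_duplication_rate=0.4)
        genome, genes, truth = generate_genome(cfg)
        sim = simulate_iclip(genome, genes, cfg, truth)
        assert len(sim.truth.provenance) == len(sim.reads) == len(sim.alignments)
        assert sim.truth.provenance["read_id"].is_unique

    def test_read_starts_one_nt_downstream_of_crosslink(self):
        cfg = small_config()
        genome, genes, truth = generate_genome(cfg)
        sim = simulate_iclip(genome, genes, cfg, truth)
        joined = sim.alignments.assign(
            read_id=sim.alignments["name"].str.rsplit(":", n=1).str[0]
        ).merge(sim.truth.provenance, on="read_id")
        plus = joined[joined["strand_x"] == "+"]
        minus = joined[joined["strand_x"] == "-"]
        assert (plus["start"] == plus["crosslink_pos"] + 1).all()
        assert (minus["end"] == minus["crosslink_pos"]).all()


class TestFeedbackModel:
    def test_hand_computed_derepression_psi(self):
        # beta knockdown with k_beta = 0.05: alpha is de-repressed
        fb = FeedbackModel(E_alpha=0.1, E_beta=1.0, gamma=10.0, gamma_rev=0.5,
                           theta0=-2.0, sigma_rep=0.0)
        e_a, e_b = fb.activities(k_alpha=1.0, k_beta=0.05)
        e_a_hand = 1.0 * 0.1 * (1 + 10 * 1.0) / (1 + 10 * 0.05 * 1.0)
        e_b_hand = 0.05 * 1.0 * (1 + 0.5 * 0.1) / (1 + 0.5 * 1.0 * 0.1)
        assert abs(e_a - e_a_hand) < 1e-12
        assert abs(e_b - e_b_hand) < 1e-12
        assert e_a > fb.E_alpha            # de-repression
        d = 4.0
        psi_hand = 100.0 / (1.0 + math.exp(-(-2.0 + d * (e_a_hand + e_b_hand))))
        assert abs(true_psi(fb, d, 1.0, 0.05) - psi_hand) < 1e-9

    def test_asymmetry_beta_kd_raises_alpha_more(self):
        fb = FeedbackModel()
        e_a_beta_kd, _ = fb.activities(1.0, 0.05)
        _, e_b_alpha_kd = fb.activities(0.05, 1.0)
        gain_alpha = e_a_beta_kd - fb.E_alpha
        gain_beta = e_b_alpha_kd - fb.E_beta
        assert gain_alpha > gain_beta > 0

    def test_no_knockdown_is_identity(self):
        fb = FeedbackModel()
        e_a, e_b = fb.activities(1.0, 1.0)
        assert abs(e_a - fb.E_alpha) < 1e-12 and abs(e_b - fb.E_beta) < 1e-12


class TestSimulateSplicing:
    def test_dependence_free_exon_flat_across_conditions(self):
        cfg = small_config()
        genome, genes, truth = generate_genome(cfg)
        fb = FeedbackModel(sigma_rep=2.0)
        meas, psi = simulate_splicing(genes, fb, KnockdownDesign(n_replicates=30),
                                      cfg, d_e={"e0": 0.0})
        means = meas.groupby("condition")["included"].mean()
        deltas = (means - means["control"]).drop("control").abs()
        assert (deltas < fb.sigma_rep).all()
        assert psi["true_psi"].nunique() == 1

    def test_compensation_single_vs_double_on_truth(self):
        cfg = small_config()
        _, genes, _ = generate_genome(cfg)
        fb = FeedbackModel(sigma_rep=0.0)
        d_e = {f"e{i}": d for i, d in enumerate([0.5, 1, 2, 3, 4, 5, 6, 8])}
        _, psi = simulate_splicing(genes, fb, KnockdownDesign(), cfg, d_e=d_e)
        wide = psi.pivot(index="exon_id", columns="condition", values="true_psi")
        for _, row in wide.iterrows():
            d_alpha = abs(row["kd_alpha"] - row["control"])
            d_beta = abs(row["kd_beta"] - row["control"])
            d_double = abs(row["kd_double"] - row["control"])
            assert max(d_alpha, d_beta) < d_double

    def test_psi_bounds_and_quantities(self):
        cfg = small_config()
        genome, genes, truth = generate_genome(cfg)
        meas, psi = simulate_splicing(genes, FeedbackModel(), KnockdownDesign(),
                                      cfg, truth=truth)
        assert psi["true_psi"].between(0, 100).all()
        assert (meas["included"] >= 0).all() and (meas["skipped"] >= 0).all()
        back = 100 * meas["included"] / (meas["included"] + meas["skipped"])
        assert back.between(0, 100).all()
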