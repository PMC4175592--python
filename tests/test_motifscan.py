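"""k-mer counting (with a brute-force string oracle), enrichment z-scores,
top-k-mer selection, binding density and density comparison."""
import numpy as np
import pandas as pd
import pytest

from clipscreen.clustercall import GeneSpan
from clipscreen.errors import ConfigurationError, DataError
from clipscreen.motifscan import (GenomeKmerIndex, all_kmers, binding_density,
                                  compare_density, kmer_counts, kmer_zscores,
                                  top_kmers)
from clipscreen.synthgen import ToyGenome, revcomp


def brute_force_counts(genome_seq, sites, flank, k):
    """Independent string-based window k-mer counting."""
    counts = {}
    L = len(genome_seq)
    for _, s in sites.iterrows():
        a = max(0, s.position - flank)
        b = min(L, s.position + flank + 1)
        window = genome_seq[a:b]
        if s.strand == "-":
            window = revcomp(window)
        for i in range(len(window) - k + 1):
            w = window[i:i + k]
            counts[w] = counts.get(w, 0) + 1
    return counts


def to_dict(count_vector, k):
    names = all_kmers(k)
    return {names[i]: int(c) for i, c in enumerate(count_vector) if c}


class TestKmerCounts:
    def test_single_window_exact(self):
        genome = ToyGenome("c", "TTAGAAATT")
        sites = pd.DataFrame([{"chrom": "c", "strand": "+", "position": 4}])
        counts = kmer_counts(sites, genome, flank=2, k=5)
        assert to_dict(counts, 5) == {"AGAAA": 1}

    def test_minus_strand_counts_transcript_kmers(self):
        genome = ToyGenome("c", "TT" + revcomp("AGAAA") + "TT")
        sites = pd.DataFrame([{"chrom": "c", "strand": "-", "position": 4}])
        counts = kmer_counts(sites, genome, flank=2, k=5)
        assert to_dict(counts, 5) == {"AGAAA": 1}

    def test_empty_sites_all_zero(self):
        genome = ToyGenome("c", "ACGTACGTAC")
        counts = kmer_counts(pd.DataFrame(columns=["chrom", "strand", "position"]),
                             genome, flank=2, k=3)
        assert counts.sum() == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        genome = ToyGenome("c", seq)
        sites = pd.DataFrame({
            "chrom": "c",
            "strand": rng.choice(["+", "-"], size=25),
            "position": rng.choice(300, size=25, replace=False),
        })
        counts = kmer_counts(sites, genome, flank=12, k=3)
        assert to_dict(counts, 3) == brute_force_counts(seq, sites, 12, 3)

    def test_count_conservation_without_trimming(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        genome = ToyGenome("c", seq)
        flank, k, n = 10, 5, 30
        sites = pd.DataFrame({"chrom": "c", "strand": "+",
                              "position": rng.integers(flank, 500 - flank, n)})
        counts = kmer_counts(sites, genome, flank=flank, k=k)
        assert counts.sum() == n * (2 * flank + 1 - k + 1)

    def test_k_larger_than_window_rejected(self):
        genome = ToyGenome("c", "ACGTACGT")
        with pytest.raises(ConfigurationError):
            kmer_counts(pd.DataFrame(columns=["chrom", "strand", "position"]),
                        genome, flank=1, k=5)


class TestKmerZscores:
    def test_uniform_sites_show_no_extreme_enrichment(self):
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        genome = ToyGenome("c", seq)
        span = GeneSpan("g", "c", "+", [(0, 4000)])
        sites = pd.DataFrame({"chrom": "c", "strand": "+",
                              "position": rng.choice(4000, 150, replace=False)})
        observed = kmer_counts(sites, genome, flank=20, k=5)
        scores = kmer_zscores(observed, sites, [span], genome, R=40, seed=2,
                              flank=20, k=5)
        assert scores["z"].abs().max() < 4

    def test_planted_motif_pentamers_recovered(self, sim50_kmers):
        top = sim50_kmers["top"]
        n_motif = sum(("AGAA" in k) or ("GAA" in k) for k in top)
        assert n_motif >= 8
        assert "AGAAG" in top

    def test_requires_enough_randomizations(self, sim50):
        with pytest.raises(ConfigurationError):
            kmer_zscores(np.zeros(4 ** 5), pd.DataFrame(), [], sim50["genome"], R=5)


class TestTopKmers:
    def _frame(self, kmers, zs):
        return pd.DataFrame({"kmer": kmers, "z": zs,
                             "sd_zero": [False] * len(kmers)})

    def test_distinct_z_ordering(self):
        scores = self._frame(["AAAAA", "CCCCC", "GGGGG"], [1.0, 3.0, 2.0])
        assert top_kmers(scores, n_top=2) == ["CCCCC", "GGGGG"]

    def test_tie_broken_lexicographically(self):
        scores = self._frame(["TTTTT", "AAAAA", "GGGGG"], [2.0, 2.0, 5.0])
        assert top_kmers(scores, n_top=2) == ["GGGGG", "AAAAA"]

    def test_fewer_than_requested_returns_all(self):
        scores = self._frame(["AAAAA"], [1.0])
        assert top_kmers(scores, n_top=10) == ["AAAAA"]


class TestBindingDensity:
    def test_single_occurrence(self):
        d = binding_density("CAGAAGTTTT", ["AGAAG"])
        assert (d.length, d.covered, d.density) == (10, 5, 50.0)

    def test_no_occurrence(self):
        assert binding_density("CCCCCCCC", ["AGAAG"]).density == 0.0

    def test_overlapping_occurrences_union(self):
        d = binding_density("AGAAGAAG", ["AGAAG"])
        assert (d.covered, d.density) == (8, 100.0)

    def test_exon_shorter_than_kmer_flagged(self):
        d = binding_density("AGA", ["AGAAG"])
        assert d.density == 0.0 and d.too_short

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(3)
        exon = "".join(rng.choice(list("ACGT"), size=120))
        kmers = ["AGAAG", "GAAGA", "TTTCT"]
        d1 = binding_density(exon, kmers)
        d2 = binding_density(revcomp(exon), [revcomp(m) for m in kmers])
        assert d1.covered == d2.covered and d1.density == d2.density


class TestCompareDensity:
    def test_identical_groups(self):
        r = compare_density([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert r.t == 0.0 and r.p == 1.0

    def test_matches_pooled_variance_hand_computation(self):
        a, b = [10.0, 12.0, 14.0], [1.0, 2.0, 3.0]
        r = compare_density(a, b)
        ma, mb = np.mean(a), np.mean(b)
        sp2 = (np.sum((a - ma) ** 2) + np.sum((b - mb) ** 2)) / (3 + 3 - 2)
        t_hand = (ma - mb) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        from scipy.stats import t as tdist
        p_hand = 2 * tdist.sf(abs(t_hand), df=4)
        assert abs(r.t - t_hand) < 1e-9 and abs(r.p - p_hand) < 1e-9

    def test_group_size_guard(self):
        with pytest.raises(DataError):
            compare_density([1.0], [2.0, 3.0])

    def test_planted_density_difference_detected(self, sim50, sim50_kmers):
        # responsive (motif-planted) cassette exons have higher top-kmer
        # density than non-planted ones
        genome, genes = sim50["genome"], sim50["genes"]
        planted = set(sim50["truth"].planted_clusters.gene_id)
        top = sim50_kmers["top"]
        groups = {True: [], False: []}
        for g in genes:
            a, b = g.cassette_exons()[0]
            seq = genome.sequence[a:b]
            if g.strand == "-":
                seq = revcomp(seq)
            groups[g.gene_id in planted].append(binding_density(seq, top).density)
        r = compare_density(groups[True][:20], groups[False][:20])
        assert r.p < 0.01 and r.mean_a > r.mean_b
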