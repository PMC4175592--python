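"""Pentamer enrichment around crosslink sites and binding-site density.

k-mer counting is done on integer-encoded sequence: each k-mer maps to a
base-4 code, so counting a window is an ``np.add.at`` over precomputed
rolling codes.  Windows are taken on the annotated strand (crosslinking
is to the transcript), so minus-strand windows count reverse-complement
codes.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError
from .clustercall import GeneSpan, assign_sites_to_genes
from .synthgen import ToyGenome

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def all_kmers(k: int) -> List[str]:
    return ["".join(p) for p in product("ACGT", repeat=k)]


class GenomeKmerIndex:
    """Rolling k-mer codes of a genome, forward and reverse-complement."""

    def __init__(self, genome: ToyGenome, k: int = 5):
        if k < 1:
            raise ConfigurationError("k must be >= 1")
        self.k = k
        self.length = genome.length
        codes = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.int64)
        for b, v in _CODE.items():
            lut[ord(b)] = v
        c = lut[codes]
        n = self.length - k + 1
        if n < 1:
            raise ConfigurationError("genome shorter than k")
        fwd = np.zeros(n, dtype=np.int64)
        rc = np.zeros(n, dtype=np.int64)
        for j in range(k):
            fwd = fwd * 4 + c[j:j + n]
            rc = rc * 4 + (3 - c[k - 1 - j:k - 1 - j + n])
        self.fwd = fwd
        self.rc = rc


def _window_bounds(position: int, flank: int, length: int, k: int) -> Optional[Tuple[int, int]]:
    """Genomic k-mer start range for the window [position-flank, position+flank]."""
    a = max(0, position - flank)
    b = min(length, position + flank + 1)   # half-open window end
    if b - a < k:
        return None
    return a, b - k + 1


def kmer_counts(sites: pd.DataFrame, genome: ToyGenome, flank: int = 30,
                k: int = 5, index: Optional[GenomeKmerIndex] = None) -> np.ndarray:
    """Count every overlapping k-mer on the site strand within +-flank nt.

    Returns a vector of length 4**k indexed by base-4 k-mer code.  Windows
    are trimmed at chromosome bounds.  An empty site list yields all-zero
    counts.
    """
    if 2 * flank + 1 < k:
        raise ConfigurationError("k exceeds the window length")
    idx = index or GenomeKmerIndex(genome, k)
    counts = np.zeros(4 ** k, dtype=np.int64)
    for strand in ("+", "-"):
        pos = sites.loc[sites["strand"] == strand, "position"].to_numpy()
        _count_windows(counts, pos, strand, idx, flank, k, genome.length)
    return counts


def _count_windows(counts: np.ndarray, positions: np.ndarray, strand: str,
                   idx: GenomeKmerIndex, flank: int, k: int, length: int) -> None:
    codes = idx.fwd if strand == "+" else idx.rc
    for p in positions:
        bounds = _window_bounds(int(p), flank, length, k)
        if bounds is None:
            continue
        a, b = bounds
        np.add.at(counts, codes[a:b], 1)


def kmer_zscores(observed: np.ndarray, sites: pd.DataFrame,
                 spans: Sequence[GeneSpan], genome: ToyGenome,
                 R: int = 100, seed: int = 0, flank: int = 30,
                 k: int = 5) -> pd.DataFrame:
    """z-scores of observed k-mer counts against within-gene randomizations.

    The null repeats the same counting at R sets of positions drawn
    uniformly within each gene's span (site count per gene preserved,
    strand kept).  A k-mer whose null sd is zero gets z = 0 and
    ``sd_zero`` flagged.  Requires R >= 10.
    """
    if R < 10:
        raise ConfigurationError("R must be >= 10 for stable null moments")
    idx = GenomeKmerIndex(genome, k)
    labelled = assign_sites_to_genes(sites, spans)
    labelled = labelled[~labelled["gene_id"].isna()]
    per_gene = labelled.groupby("gene_id").size()
    span_by_id = {s.gene_id: s for s in spans}

    rng = np.random.default_rng([7, seed])
    null_counts = np.zeros((R, 4 ** k), dtype=np.int64)
    for gid, n_sites in per_gene.items():
        span = span_by_id[gid]
        pos_pool = span.positions
        for r in range(R):
            draw = pos_pool[rng.integers(0, pos_pool.size, size=n_sites)]
            _count_windows(null_counts[r], draw, span.strand, idx, flank, k,
                           genome.length)

    mean = null_counts.mean(axis=0)
    sd = null_counts.std(axis=0, ddof=1)
    z = np.zeros_like(mean)
    ok = sd > 0
    z[ok] = (observed[ok] - mean[ok]) / sd[ok]
    df = pd.DataFrame({
        "kmer": all_kmers(k),
        "observed": observed,
        "null_mean": mean,
        "null_sd": sd,
        "z": z,
        "sd_zero": ~ok,
    })
    df = df.sort_values(["z", "kmer"], ascending=[False, True]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def top_kmers(scores: pd.DataFrame, n_top: int = 10) -> List[str]:
    """The n_top highest-z k-mers; ties broken lexicographically."""
    usable = scores[~scores["sd_zero"]]
    ordered = usable.sort_values(["z", "kmer"], ascending=[False, True])
    if len(ordered) < n_top:
        return ordered["kmer"].tolist()
    return ordered["kmer"].head(n_top).tolist()


@dataclass
class BindingDensity:
    """Fraction of an exon's nucleotides covered by top-k-mer occurrences."""

    exon_id: str
    length: int
    covered: int
    density: float       # percent
    too_short: bool = False


def binding_density(exon_seq: str, kmers: Iterable[str],
                    exon_id: str = "") -> BindingDensity:
    """Percentage of exon nucleotides under any occurrence of any k-mer.

    Occurrences may overlap; coverage is the union.  An exon shorter than
    the shortest k-mer has density 0 and is flagged.
    """
    kmers = list(kmers)
    n = len(exon_seq)
    if not kmers or n < min(len(m) for m in kmers):
        return BindingDensity(exon_id, n, 0, 0.0, too_short=True)
    covered = np.zeros(n, dtype=bool)
    for m in kmers:
        start = exon_seq.find(m)
        while start != -1:
            covered[start:start + len(m)] = True
            start = exon_seq.find(m, start + 1)
    c = int(covered.sum())
    return BindingDensity(exon_id, n, c, 100.0 * c / n)


@dataclass
class DensityComparison:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    t: float
    p: float


def compare_density(a: Sequence[float], b: Sequence[float],
                    labels: Tuple[str, str] = ("A", "B"),
                    equal_var: bool = True) -> DensityComparison:
    """Two-sided independent two-sample t-test on density groups.

    Equal-variance (pooled, df = nA + nB - 2) by default; Welch via
    ``equal_var=False``.  Two identical zero-variance groups give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("each group needs n >= 2")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return DensityComparison(labels[0], labels[1], a.mean(), b.mean(), 0.0, 1.0)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return DensityComparison(labels[0], labels[1], float(a.mean()), float(b.mean()),
                             float(t), float(p))
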