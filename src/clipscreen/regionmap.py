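"""Genomic-region assignment of unique cDNAs and size-normalized distributions.

Each cDNA is assigned, by its crosslink position, to exactly one of
{ncRNA, 3'UTR, 5'UTR, ORF, intron, intergenic} (that order is the overlap
precedence; configurable).  Raw percentages divide counts by the total;
size-corrected percentages divide each class count by the class's
nucleotide size and renormalize, mirroring the "relative size of that
region within the genome" correction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pyranges as pr
from intervaltree import IntervalTree

from .errors import DataError, FormatError

REGION_CLASSES = ("5'UTR", "ORF", "3'UTR", "intron", "ncRNA", "intergenic")
DEFAULT_PRECEDENCE = ("ncRNA", "3'UTR", "5'UTR", "ORF", "intron", "intergenic")

_FEATURE_TO_CLASS = {
    "five_prime_utr": "5'UTR",
    "three_prime_utr": "3'UTR",
    "CDS": "ORF",
}


@dataclass
class RegionIndex:
    """Interval trees per region class plus per-class nucleotide sizes."""

    trees: Dict[str, Dict[str, IntervalTree]]     # class -> chrom -> tree
    sizes: Dict[str, int]
    precedence: Tuple[str, ...] = DEFAULT_PRECEDENCE

    def classify(self, chrom: str, position: int) -> str:
        for cls in self.precedence:
            if cls == "intergenic":
                continue
            tree = self.trees.get(cls, {}).get(chrom)
            if tree is not None and tree.overlaps_point(position):
                return cls
        return "intergenic"


def build_region_index(gtf_path: str, chrom_sizes: Dict[str, int],
                       precedence: Tuple[str, ...] = DEFAULT_PRECEDENCE
                       ) -> RegionIndex:
    """Build the class interval index from a GTF annotation.

    Coding genes contribute 5'UTR/ORF/3'UTR from their UTR/CDS features
    and introns from the gene span minus its exons; ncRNA genes
    contribute their exons to the ncRNA class (their introns stay
    introns).  Intergenic size is whatever no gene covers.
    """
    try:
        ann = pr.read_gtf(gtf_path).df
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse GTF {gtf_path}: {exc}") from exc
    required = {"Feature", "Chromosome", "Start", "End", "gene_id"}
    if not required <= set(ann.columns):
        raise FormatError(f"{gtf_path}: missing GTF fields {required - set(ann.columns)}")

    intervals: Dict[str, List[Tuple[str, int, int]]] = {c: [] for c in REGION_CLASSES}

    genes = ann[ann.Feature == "gene"]
    biotype = dict(zip(genes.gene_id, genes.get("gene_biotype", "coding")))
    for _, g in genes.iterrows():
        gid = g.gene_id
        gene_exons = ann[(ann.Feature == "exon") & (ann.gene_id == gid)]
        exonic = sorted(zip(gene_exons.Start, gene_exons.End))
        # introns: gene span minus exons
        cursor = g.Start
        for a, b in exonic:
            if cursor < a:
                intervals["intron"].append((g.Chromosome, cursor, a))
            cursor = max(cursor, b)
        if cursor < g.End:
            intervals["intron"].append((g.Chromosome, cursor, g.End))
        if biotype.get(gid, "coding") == "coding":
            for feat, cls in _FEATURE_TO_CLASS.items():
                sub = ann[(ann.Feature == feat) & (ann.gene_id == gid)]
                for _, r in sub.iterrows():
                    if r.End > r.Start:   # zero-length UTR annotations allowed
                        intervals[cls].append((r.Chromosome, r.Start, r.End))
        else:
            for a, b in exonic:
                intervals["ncRNA"].append((g.Chromosome, a, b))

    trees: Dict[str, Dict[str, IntervalTree]] = {}
    sizes: Dict[str, int] = {}
    for cls in REGION_CLASSES:
        if cls == "intergenic":
            continue
        per_chrom: Dict[str, IntervalTree] = {}
        size = 0
        for chrom, a, b in intervals[cls]:
            per_chrom.setdefault(chrom, IntervalTree()).addi(a, b)
            size += b - a
        trees[cls] = per_chrom
        sizes[cls] = size
    genic = 0
    for _, g in genes.iterrows():
        genic += g.End - g.Start
    sizes["intergenic"] = max(0, sum(chrom_sizes.values()) - genic)
    return RegionIndex(trees=trees, sizes=sizes, precedence=precedence)


@dataclass
class RegionDistribution:
    """Raw and (optionally) size-normalized per-class tag distribution."""

    table: pd.DataFrame   # columns: region, count, raw_pct [, norm_pct]


def assign_tags(cdnas: pd.DataFrame, index: RegionIndex) -> RegionDistribution:
    """Count unique cDNAs per region class by crosslink position.

    ``cdnas`` is the unique-cDNA table (chrom, strand, start, end); the
    crosslink position (start-1 on +, end on -) is the assigned point.
    """
    if cdnas.empty:
        raise DataError("no tags to assign")
    pos = cdnas["start"].where(cdnas["strand"] == "+", cdnas["end"]).copy()
    pos.loc[cdnas["strand"] == "+"] -= 1
    counts = {c: 0 for c in REGION_CLASSES}
    for chrom, p in zip(cdnas["chrom"], pos):
        counts[index.classify(chrom, int(p))] += 1
    total = sum(counts.values())
    df = pd.DataFrame({"region": list(REGION_CLASSES),
                       "count": [counts[c] for c in REGION_CLASSES]})
    df["raw_pct"] = 100.0 * df["count"] / total
    return RegionDistribution(df)


def size_normalize(dist: RegionDistribution, index: RegionIndex) -> RegionDistribution:
    """Add size-corrected percentages: density_c = count_c / size_c,
    normalized so the densities sum to 100%."""
    df = dist.table.copy()
    sizes = df["region"].map(index.sizes).astype(float)
    if ((df["count"] > 0) & (sizes <= 0)).any():
        raise DataError("tags assigned to a zero-size region class")
    density = np.where(sizes > 0, df["count"] / np.where(sizes > 0, sizes, 1.0), 0.0)
    total = density.sum()
    if total <= 0:
        raise DataError("no density mass to normalize")
    df["norm_pct"] = 100.0 * density / total
    return RegionDistribution(df)
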