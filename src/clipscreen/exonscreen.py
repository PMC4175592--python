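"""Rank candidate target exons by iCLIP tag enrichment within their gene.

An exon's window is its span extended by ``flank`` nt on both sides
(boundary inclusive) and clipped to the gene span; its enrichment score
is the fraction of the gene's unique cDNAs whose crosslink position falls
in the window.  Exons are ranked by score, then raw window count, then
genomic coordinate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .synthgen import GeneModel

log = logging.getLogger(__name__)


@dataclass
class ExonCandidate:
    gene_id: str
    exon_id: str
    chrom: str
    strand: str
    start: int
    end: int
    window_count: int
    gene_count: int
    score: float
    rank: int = 0


def _crosslink_positions(cdnas: pd.DataFrame) -> pd.Series:
    pos = cdnas["start"].where(cdnas["strand"] == "+", cdnas["end"]).copy()
    pos.loc[cdnas["strand"] == "+"] -= 1
    return pos


def score_exons(cdnas: pd.DataFrame, genes: Sequence[GeneModel],
                flank: int = 300, cassette_only: bool = True,
                per_nt: bool = False) -> List[ExonCandidate]:
    """Score exons by window tag count relative to gene-wide coverage.

    ``per_nt`` switches to a per-nucleotide normalized variant
    (window density over gene density) for the ambiguous reading of
    gene-wide coverage; the default is the raw count ratio.  Genes
    without tags are skipped and logged.  Windows of two exons may
    overlap; tags in the overlap count for both.
    """
    pos = _crosslink_positions(cdnas)
    out: List[ExonCandidate] = []
    for g in genes:
        in_gene = ((cdnas["chrom"] == g.chrom) & (cdnas["strand"] == g.strand)
                   & (pos >= g.start) & (pos < g.end))
        gene_pos = pos[in_gene]
        gene_total = int(in_gene.sum())
        if gene_total == 0:
            log.info("gene %s has no tags; skipped", g.gene_id)
            continue
        exon_list = list(zip(g.exons, g.exon_classes))
        for i, ((a, b), cls) in enumerate(exon_list):
            if cassette_only and cls != "cassette":
                continue
            if not (g.start <= a < b <= g.end):
                raise DataError(f"exon {a}-{b} outside gene span of {g.gene_id}")
            # half-open window [wa, wb): a tag exactly flank nt from either
            # splice site is still counted (boundary inclusive)
            wa = max(g.start, a - flank)
            wb = min(g.end, b + flank)
            w_count = int(((gene_pos >= wa) & (gene_pos < wb)).sum())
            if per_nt:
                score = (w_count / (wb - wa)) / (gene_total / g.span)
            else:
                score = w_count / gene_total
            out.append(ExonCandidate(g.gene_id, f"{g.gene_id}.exon{i}", g.chrom,
                                     g.strand, a, b, w_count, gene_total, score))
    return out


def rank_candidates(candidates: Sequence[ExonCandidate],
                    top_n: Optional[int] = None) -> List[ExonCandidate]:
    """Descending by score; ties by raw window count, then coordinate."""
    ordered = sorted(candidates,
                     key=lambda c: (-c.score, -c.window_count, c.chrom, c.start))
    for i, c in enumerate(ordered, start=1):
        c.rank = i
    return ordered[:top_n] if top_n else ordered


def candidates_table(candidates: Sequence[ExonCandidate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": c.gene_id, "exon_id": c.exon_id, "chrom": c.chrom,
        "strand": c.strand, "start": c.start, "end": c.end,
        "window_count": c.window_count, "gene_count": c.gene_count,
        "score": c.score, "rank": c.rank,
    } for c in candidates])
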