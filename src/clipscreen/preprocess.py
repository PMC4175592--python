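"""Barcode extraction, unique-cDNA deduplication and crosslink-site calling.

An iCLIP read truncates at the protein-RNA crosslink, so after removing
the experiment and random barcodes the crosslink site is the nucleotide
immediately 5' (in transcript orientation) of the mapped tag start.  Reads
sharing a strand-aware start position and random barcode are PCR copies of
one cDNA and are collapsed before any counting.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .errors import DataError, FormatError

log = logging.getLogger(__name__)


@dataclass
class BarcodedRead:
    read_id: str
    experiment_barcode: str
    random_barcode: str
    insert_seq: str

    @property
    def insert_len(self) -> int:
        return len(self.insert_seq)


@dataclass
class ExtractionResult:
    reads: List[BarcodedRead]
    n_rejected_short: int
    n_rejected_barcode: int

    @property
    def n_rejected(self) -> int:
        return self.n_rejected_short + self.n_rejected_barcode


def extract_barcodes(reads: pd.DataFrame, barcode_mask: str,
                     min_len: int = 11,
                     expected_experiment_barcodes: Optional[Iterable[str]] = None
                     ) -> ExtractionResult:
    """Register and remove barcodes from raw reads; drop short inserts.

    ``reads`` needs columns ``read_id`` and ``sequence``.  Inserts shorter
    than ``min_len`` after trimming are rejected and counted (an insert of
    exactly ``min_len`` is retained).  If
    ``expected_experiment_barcodes`` is given, reads whose experiment
    barcode is not an exact member are rejected and counted separately.
    """
    n_pos = [i for i, c in enumerate(barcode_mask) if c == "N"]
    x_pos = [i for i, c in enumerate(barcode_mask) if c == "X"]
    i_pos = [i for i, c in enumerate(barcode_mask) if c == "I"]
    expected = set(expected_experiment_barcodes) if expected_experiment_barcodes else None

    out: List[BarcodedRead] = []
    n_short = 0
    n_badbc = 0
    for row in reads.itertuples(index=False):
        seq = row.sequence
        if set(seq) - set("ACGTN"):
            raise FormatError(f"read {row.read_id}: non-ACGTN characters")
        if len(seq) < len(barcode_mask):
            n_short += 1
            continue
        rand_bc = "".join(seq[i] for i in n_pos)
        exp_bc = "".join(seq[i] for i in x_pos)
        insert = "".join(seq[i] for i in i_pos) + seq[len(barcode_mask):]
        if len(insert) < min_len:
            n_short += 1
            continue
        if expected is not None and exp_bc not in expected:
            n_badbc += 1
            continue
        out.append(BarcodedRead(row.read_id, exp_bc, rand_bc, insert))
    return ExtractionResult(out, n_short, n_badbc)


def deduplicate(tags: pd.DataFrame) -> pd.DataFrame:
    """Collapse mapped tags to unique cDNAs.

    ``tags`` is a BED-like frame with columns chrom, start, end, strand and
    either a ``random_barcode`` column or BED names of the form
    ``read_id:barcode``.  The cDNA identity is the triple (strand-aware
    start position, strand, random barcode): the truncation point defines
    the cDNA, so the tag end does not enter the key.  The first-seen tag's
    interval represents each cDNA.
    """
    if tags.empty:
        return tags.assign(random_barcode=pd.Series(dtype=str)) if "random_barcode" not in tags else tags
    tags = tags.copy()
    if "random_barcode" not in tags.columns:
        if "name" not in tags.columns:
            raise DataError("tags need a random_barcode column or read_id:barcode names")
        parts = tags["name"].str.rsplit(":", n=1)
        if parts.str.len().min() < 2:
            raise DataError("tag names must carry read_id:barcode")
        tags["read_id"] = parts.str[0]
        tags["random_barcode"] = parts.str[1]
    if tags["random_barcode"].isna().any() or (tags["random_barcode"] == "").any():
        raise DataError("missing random barcode on mapped tags")
    five_prime = tags["start"].where(tags["strand"] == "+", tags["end"])
    tags = tags.assign(_key5=five_prime)
    dedup = tags.drop_duplicates(subset=["chrom", "strand", "_key5", "random_barcode"],
                                 keep="first").drop(columns="_key5")
    return dedup.reset_index(drop=True)


def call_crosslink_sites(cdnas: pd.DataFrame,
                         chrom_sizes: Optional[Dict[str, int]] = None
                         ) -> Tuple[pd.DataFrame, int]:
    """Aggregate unique cDNAs into crosslink sites with heights.

    The site is one nucleotide upstream of the tag in transcript
    orientation: ``start - 1`` on the + strand, ``end`` on the - strand.
    Sites falling off the chromosome (start-of-chromosome + tags; past-the-
    end - tags when ``chrom_sizes`` is given) are discarded and counted.
    Returns ``(sites, n_discarded)`` where sites has columns chrom, strand,
    position, height and the heights sum to the number of surviving cDNAs.
    """
    if cdnas.empty:
        return (pd.DataFrame(columns=["chrom", "strand", "position", "height"]), 0)
    pos = cdnas["start"].where(cdnas["strand"] == "+", cdnas["end"]).copy()
    pos.loc[cdnas["strand"] == "+"] -= 1
    df = pd.DataFrame({"chrom": cdnas["chrom"], "strand": cdnas["strand"],
                       "position": pos})
    keep = df["position"] >= 0
    if chrom_sizes is not None:
        limits = df["chrom"].map(chrom_sizes)
        keep &= df["position"] < limits
    n_discard = int((~keep).sum())
    if n_discard:
        log.warning("discarded %d crosslink sites at chromosome edges", n_discard)
    df = df[keep]
    sites = (df.groupby(["chrom", "strand", "position"], as_index=False)
               .size().rename(columns={"size": "height"})
               .sort_values(["chrom", "strand", "position"])
               .reset_index(drop=True))
    return sites, n_discard


def sites_to_bed(sites: pd.DataFrame) -> pd.DataFrame:
    """Crosslink sites as BED6 with score = height."""
    return pd.DataFrame({
        "chrom": sites["chrom"],
        "start": sites["position"],
        "end": sites["position"] + 1,
        "name": "xl",
        "score": sites["height"],
        "strand": sites["strand"],
    })
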