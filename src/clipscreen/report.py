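"""Summary tables for an end-to-end run.

The report mirrors the shape of published iCLIP run statistics: a per-
replicate counts table (total reads, unique cDNAs, crosslink sites) and a
candidate-exon table joining enrichment scores, dPSI contrasts, response
classes and binding-site densities.
"""
from __future__ import annotations

from typing import Dict, Optional

import pandas as pd


def replicate_counts(reads: pd.DataFrame, cdnas: pd.DataFrame,
                     sites: pd.DataFrame,
                     read_replicates: Optional[pd.Series] = None) -> pd.DataFrame:
    """Per-replicate totals.  ``cdnas`` must carry a ``replicate`` column
    (experiment barcode or replicate label); sites are pooled, so the
    site count is repeated only on the pooled row."""
    rows = []
    if "replicate" in cdnas.columns:
        groups = sorted(cdnas["replicate"].unique())
        for rep in groups:
            n_reads = None
            if read_replicates is not None:
                n_reads = int((read_replicates == rep).sum())
            rows.append({"replicate": str(rep), "n_reads": n_reads,
                         "n_unique_cdnas": int((cdnas["replicate"] == rep).sum()),
                         "n_crosslink_sites": None})
    rows.append({"replicate": "pooled",
                 "n_reads": int(len(reads)),
                 "n_unique_cdnas": int(len(cdnas)),
                 "n_crosslink_sites": int(len(sites))})
    return pd.DataFrame(rows)


def candidate_report(candidates: pd.DataFrame,
                     responses: Optional[pd.DataFrame] = None,
                     densities: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Join the exon screen with splicing responses and densities.

    Missing sections are simply absent columns; the report stays valid
    with partial inputs.
    """
    out = candidates.copy()
    if responses is not None and not responses.empty:
        resp = responses.copy()
        resp["gene_id"] = resp["exon_id"].str.split(".").str[0]
        out = out.merge(resp.drop(columns=["exon_id"]), on="gene_id", how="left")
    if densities is not None and not densities.empty:
        out = out.merge(densities, on="exon_id", how="left")
    return out
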