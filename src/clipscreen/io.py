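"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; BED and TSV through pandas.  GTF output
is 1-based inclusive per the format; everything in memory is 0-based
half-open.
"""
from __future__ import annotations

from typing import Iterable, List, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError
from .synthgen import ToyGenome, GeneModel

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_fasta(genome: ToyGenome, path: str) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.chrom_name, description="")
    SeqIO.write([rec], path, "fasta")


def write_fastq(reads: pd.DataFrame, path: str) -> None:
    """Write reads (columns read_id, sequence, quality) as FASTQ."""
    with open(path, "w") as fh:
        for row in reads.itertuples(index=False):
            fh.write(f"@{row.read_id}\n{row.sequence}\n+\n{row.quality}\n")


def read_fastq(path: str) -> pd.DataFrame:
    rows = []
    for rec in SeqIO.parse(path, "fastq"):
        rows.append((rec.id, str(rec.seq)))
    return pd.DataFrame(rows, columns=["read_id", "sequence"])


def write_gtf(genes: Sequence[GeneModel], path: str, source: str = "clipscreen") -> None:
    """Emit gene/transcript/exon/CDS/UTR features with gene_id, transcript_id,
    gene_biotype and (on exons) exon_class attributes."""
    lines: List[str] = []

    def feat(chrom, ftype, start, end, strand, attrs):
        astr = " ".join(f'{k} "{v}";' for k, v in attrs.items())
        lines.append(f"{chrom}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{astr}")

    for g in genes:
        tid = f"{g.gene_id}.t1"
        base = {"gene_id": g.gene_id, "gene_biotype": g.biotype}
        feat(g.chrom, "gene", g.start, g.end, g.strand, base)
        feat(g.chrom, "transcript", g.start, g.end, g.strand, {**base, "transcript_id": tid})
        for (a, b), cls in zip(g.exons, g.exon_classes):
            feat(g.chrom, "exon", a, b, g.strand,
                 {**base, "transcript_id": tid, "exon_class": cls})
        for ftype, ivs in (("five_prime_utr", g.utr5), ("CDS", g.cds),
                           ("three_prime_utr", g.utr3)):
            for a, b in ivs:
                feat(g.chrom, ftype, a, b, g.strand, {**base, "transcript_id": tid})
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gene_models(gtf_path: str) -> List[GeneModel]:
    """Reconstruct GeneModel objects (exons, classes, UTR/CDS partition)
    from a GTF written by :func:`write_gtf` or any annotation carrying
    gene_id / gene_biotype / exon_class attributes."""
    import pyranges as pr

    try:
        ann = pr.read_gtf(gtf_path).df
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse GTF {gtf_path}: {exc}") from exc
    genes: List[GeneModel] = []
    for _, g in ann[ann.Feature == "gene"].iterrows():
        sub = ann[ann.gene_id == g.gene_id]
        exon_rows = sub[sub.Feature == "exon"].sort_values("Start")
        exons = [(int(a), int(b)) for a, b in zip(exon_rows.Start, exon_rows.End)]
        classes = [str(c) if isinstance(c, str) else "constitutive"
                   for c in exon_rows.get("exon_class", ["constitutive"] * len(exons))]
        biotype = g.get("gene_biotype", "coding")
        model = GeneModel(
            gene_id=g.gene_id, chrom=str(g.Chromosome), strand=str(g.Strand),
            exons=exons, exon_classes=classes,
            biotype=biotype if isinstance(biotype, str) else "coding")
        for feat, attr in (("five_prime_utr", "utr5"), ("CDS", "cds"),
                           ("three_prime_utr", "utr3")):
            rows = sub[sub.Feature == feat].sort_values("Start")
            setattr(model, attr, [(int(a), int(b)) for a, b in zip(rows.Start, rows.End)])
        genes.append(model)
    return genes


def write_bed(df: pd.DataFrame, path: str) -> None:
    df.loc[:, BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=BED6_COLUMNS, dtype={"chrom": str, "name": str})
    except Exception as exc:  # noqa: BLE001 - normalised to a format error
        raise FormatError(f"cannot parse BED file {path}: {exc}") from exc
    if df.empty:
        return df
    if not (df.start < df.end).all():
        raise FormatError(f"{path}: BED intervals must satisfy start < end")
    return df


def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
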