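"""Synthetic genome, iCLIP reads and knockdown splicing measurements.

The generator emulates the statistical structure the analysis assumes:

* a toy multi-gene genome in which a configurable subset of genes carries
  a planted AGAA/GAA-rich motif region inside its cassette exon;
* crosslink-biased truncated reads: a molecule's crosslink position is
  drawn with probability proportional to
  ``expression * (b0 + w * motif_indicator)`` and the read starts one
  nucleotide downstream of the crosslink in transcript orientation, with
  a per-molecule random barcode and PCR duplicates that copy barcode and
  position;
* replicate percent-spliced-in (PSI) measurements under control, single-
  and double-knockdown conditions, generated from an asymmetric paralog
  feedback model (see :class:`clipscreen.config.FeedbackModel`).

Ground truth (planted motif regions, read provenance, true PSI) is
returned in :class:`SimTruth` so downstream stages can be tested as
recovery problems.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import SimConfig, FeedbackModel, KnockdownDesign
from .errors import ConfigurationError, GenerationError, DesignError

BASES = np.array(list("ACGT"))

# Pentamer vocabulary used to build planted motif regions.  Every word
# contains AGAA or GAA; the three core words are the canonical binding
# pentamers and are sampled more often.  Words are planted as short
# islands separated by 2-3 random bases so that junction k-mers are
# gene-specific and do not accumulate across genes.
MOTIF_CORE_WORDS = ("AGAAG", "GAAGA", "AAGAA")
MOTIF_AUX_WORDS = ("AGAAA", "GAAAG", "TGAAG", "CGAAG", "GGAAG",
                   "AGAAC", "AGAAT", "CAGAA", "TAGAA", "AGGAA")
MOTIF_CORE_WEIGHT = 3.0


@dataclass
class ToyGenome:
    chrom_name: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 1 or set(self.sequence) - set("ACGT"):
            raise ConfigurationError("genome sequence must be non-empty ACGT")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A single-transcript gene: exons, exon classes and a UTR/CDS partition.

    ``exons`` are 0-based half-open genomic intervals in genomic order;
    ``exon_classes`` labels each exon ``constitutive`` or ``cassette``.
    ``utr5``/``cds``/``utr3`` are genomic interval lists that tile the
    exonic span exactly (empty for ncRNA genes).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    exon_classes: List[str]
    biotype: str = "coding"
    utr5: List[Tuple[int, int]] = field(default_factory=list)
    cds: List[Tuple[int, int]] = field(default_factory=list)
    utr3: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> int:
        return self.end - self.start

    def cassette_exons(self) -> List[Tuple[int, int]]:
        return [iv for iv, c in zip(self.exons, self.exon_classes) if c == "cassette"]

    def validate(self) -> None:
        for (a, b) in self.exons:
            if not a < b:
                raise ConfigurationError(f"{self.gene_id}: empty exon {a}-{b}")
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if not b <= c:
                raise ConfigurationError(f"{self.gene_id}: exons overlap or are unsorted")
        for i, cls in enumerate(self.exon_classes):
            if cls == "cassette" and (i == 0 or i == len(self.exons) - 1):
                raise ConfigurationError(f"{self.gene_id}: cassette exon lacks a flanking exon")
        if self.biotype == "coding":
            pieces = sorted(self.utr5 + self.cds + self.utr3)
            exonic = sorted(self.exons)
            merged: List[List[int]] = []
            for a, b in pieces:
                if merged and merged[-1][1] == a:
                    merged[-1][1] = b
                else:
                    merged.append([a, b])
            if [tuple(m) for m in merged] != exonic:
                raise ConfigurationError(f"{self.gene_id}: UTR/CDS partition does not tile exons")


@dataclass
class SimTruth:
    """Ground truth tables for recovery tests.

    planted_clusters: per planted motif region -- gene, genomic interval
        and the expected share of the gene's crosslinks it should attract.
    provenance: one row per emitted FASTQ read (including PCR duplicates).
    true_psi: noise-free PSI per exon x condition.
    """

    planted_clusters: pd.DataFrame
    provenance: Optional[pd.DataFrame] = None
    true_psi: Optional[pd.DataFrame] = None


def _build_motif_region(length: int, rng: np.random.Generator) -> str:
    words = list(MOTIF_CORE_WORDS) + list(MOTIF_AUX_WORDS)
    weights = np.array([MOTIF_CORE_WEIGHT] * len(MOTIF_CORE_WORDS)
                       + [1.0] * len(MOTIF_AUX_WORDS))
    weights /= weights.sum()
    out: List[str] = []
    n = 0
    while n < length:
        w = words[rng.choice(len(words), p=weights)]
        spacer = "".join(BASES[rng.integers(0, 4, size=rng.integers(2, 4))])
        out.append(w + spacer)
        n += len(w) + len(spacer)
    return "".join(out)[:length]


def generate_genome(config: SimConfig) -> Tuple[ToyGenome, List[GeneModel], SimTruth]:
    """Build the toy genome, gene models and planted-motif truth table.

    Deterministic for a given ``config.seed``.  Exactly
    ``round(n_genes * motif_fraction)`` genes carry one planted motif
    region centred in their cassette exon.
    """
    config.validate()
    rng = np.random.default_rng([1, config.seed])

    n_motif = int(round(config.n_genes * config.motif_fraction))
    n_ncrna = int(round(config.n_genes * config.ncrna_fraction))
    motif_genes = set(rng.choice(config.n_genes, size=n_motif, replace=False).tolist())
    ncrna_genes = set(rng.choice(config.n_genes, size=n_ncrna, replace=False).tolist())

    seq_parts: List[str] = []
    genes: List[GeneModel] = []
    planted: List[dict] = []
    cursor = 0

    def _rand_seq(n: int) -> str:
        return "".join(BASES[rng.integers(0, 4, size=n)])

    for gi in range(config.n_genes):
        gap = config.intergenic_length
        seq_parts.append(_rand_seq(gap))
        cursor += gap

        e1 = int(rng.integers(*config.flank_exon_range, endpoint=True))
        e2 = int(rng.integers(*config.cassette_exon_range, endpoint=True))
        e3 = int(rng.integers(*config.flank_exon_range, endpoint=True))
        i1 = int(rng.integers(*config.intron_range, endpoint=True))
        i2 = int(rng.integers(*config.intron_range, endpoint=True))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"G{gi:03d}"

        gstart = cursor
        exons = [(gstart, gstart + e1),
                 (gstart + e1 + i1, gstart + e1 + i1 + e2),
                 (gstart + e1 + i1 + e2 + i2, gstart + e1 + i1 + e2 + i2 + e3)]
        gene_len = e1 + i1 + e2 + i2 + e3
        gene_seq = list(_rand_seq(gene_len))

        if gi in motif_genes:
            region = _build_motif_region(config.motif_region_length, rng)
            cs, ce = exons[1]
            off = (cs - gstart) + (e2 - len(region)) // 2
            # the motif lives on the transcript strand
            planted_seq = region if strand == "+" else revcomp(region)
            gene_seq[off:off + len(region)] = list(planted_seq)
            mstart = gstart + off
            planted.append({"gene_id": gene_id, "chrom": config.chrom_name,
                            "start": mstart, "end": mstart + len(region),
                            "strand": strand})

        seq_parts.append("".join(gene_seq))
        cursor += gene_len

        biotype = "ncRNA" if gi in ncrna_genes else "coding"
        gene = GeneModel(gene_id=gene_id, chrom=config.chrom_name, strand=strand,
                         exons=exons, exon_classes=["constitutive", "cassette", "constitutive"],
                         biotype=biotype)
        if biotype == "coding":
            _partition_utrs(gene, config.utr5_length, config.utr3_length)
        gene.validate()
        genes.append(gene)

    seq_parts.append(_rand_seq(config.intergenic_length))
    genome = ToyGenome(config.chrom_name, "".join(seq_parts))

    planted_df = pd.DataFrame(planted, columns=["gene_id", "chrom", "start", "end", "strand"])
    # expected within-gene tag share of each planted region
    shares = []
    by_id = {g.gene_id: g for g in genes}
    for _, row in planted_df.iterrows():
        g = by_id[row.gene_id]
        rlen = row.end - row.start
        region_prop = rlen * (config.background_rate + config.motif_weight)
        bg_prop = (g.span - rlen) * config.background_rate
        shares.append(region_prop / (region_prop + bg_prop))
    planted_df["expected_tag_share"] = shares
    return genome, genes, SimTruth(planted_clusters=planted_df)


def _partition_utrs(gene: GeneModel, utr5_len: int, utr3_len: int) -> None:
    """Tile the exonic span into 5'UTR / CDS / 3'UTR in transcript order."""
    exons = gene.exons if gene.strand == "+" else gene.exons[::-1]
    total = sum(b - a for a, b in gene.exons)
    if utr5_len + utr3_len >= total:
        raise ConfigurationError(f"{gene.gene_id}: UTRs exceed exonic span")
    # transcript-order offsets for each class
    bounds = [(0, utr5_len, "utr5"),
              (utr5_len, total - utr3_len, "cds"),
              (total - utr3_len, total, "utr3")]
    out = {"utr5": [], "cds": [], "utr3": []}
    toff = 0
    for a, b in exons:
        elen = b - a
        for lo, hi, cls in bounds:
            s = max(lo, toff)
            e = min(hi, toff + elen)
            if s < e:
                if gene.strand == "+":
                    out[cls].append((a + (s - toff), a + (e - toff)))
                else:
                    out[cls].append((b - (e - toff), b - (s - toff)))
        toff += elen
    gene.utr5 = sorted(out["utr5"])
    gene.cds = sorted(out["cds"])
    gene.utr3 = sorted(out["utr3"])


# ---------------------------------------------------------------------------
# iCLIP read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedIclip:
    """In-memory result of the iCLIP read simulation."""

    reads: pd.DataFrame        # read_id, sequence, quality, replicate
    alignments: pd.DataFrame   # BED6 columns of the true insert placements
    truth: SimTruth

    @property
    def n_reads(self) -> int:
        return len(self.reads)


_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _replicate_barcodes(n: int, width: int, rng: np.random.Generator) -> List[str]:
    codes: List[str] = []
    while len(codes) < n:
        c = "".join(BASES[rng.integers(0, 4, size=width)])
        if c not in codes:
            codes.append(c)
    return codes


def simulate_iclip(genome: ToyGenome, genes: Sequence[GeneModel],
                   config: SimConfig, truth: SimTruth) -> SimulatedIclip:
    """Draw crosslinked molecules, emit truncated reads and true alignments.

    Each molecule's crosslink position is drawn from the propensity field
    ``expression * (b0 + w * motif_indicator)``; its read starts one
    nucleotide downstream of the crosslink in transcript orientation.
    PCR duplicates re-emit the same position and random barcode.
    """
    config.validate()
    rng = np.random.default_rng([2, config.seed])

    n_N = config.barcode_mask.count("N")
    n_X = config.barcode_mask.count("X")
    exp_barcodes = _replicate_barcodes(config.n_replicates, n_X, rng)
    expr = rng.lognormal(mean=0.0, sigma=config.expression_sigma, size=len(genes))

    # propensity field over all gene positions (transcript-orientation
    # last position of each gene excluded: a read cannot start beyond it)
    positions: List[np.ndarray] = []
    props: List[np.ndarray] = []
    gene_idx: List[np.ndarray] = []
    planted = truth.planted_clusters
    for i, g in enumerate(genes):
        pos = np.arange(g.start, g.end)
        p = np.full(g.span, config.background_rate)
        sel = planted[planted.gene_id == g.gene_id]
        for _, row in sel.iterrows():
            p[row.start - g.start:row.end - g.start] += config.motif_weight
        # exclude the position with no room for a downstream read start
        if g.strand == "+":
            p[-1] = 0.0
        else:
            p[0] = 0.0
        positions.append(pos)
        props.append(expr[i] * p)
        gene_idx.append(np.full(g.span, i))
    all_pos = np.concatenate(positions)
    all_prop = np.concatenate(props)
    all_gene = np.concatenate(gene_idx)
    total = all_prop.sum()
    if total <= 0:
        raise GenerationError("zero total crosslink propensity")
    prob = all_prop / total

    seq = genome.sequence
    reads: List[tuple] = []
    aligns: List[tuple] = []
    prov: List[tuple] = []
    mask = config.barcode_mask
    read_no = 0

    n_per_rep = config.n_reads // config.n_replicates
    remainder = config.n_reads - n_per_rep * config.n_replicates
    for rep in range(config.n_replicates):
        n_mol = n_per_rep + (1 if rep < remainder else 0)
        draw = rng.choice(all_pos.size, size=n_mol, p=prob)
        for j in draw:
            x = int(all_pos[j])
            g = genes[int(all_gene[j])]
            L = int(rng.integers(config.read_length_min, config.read_length_max,
                                 endpoint=True))
            if g.strand == "+":
                s = x + 1
                e = min(s + L, g.end)
                insert = seq[s:e]
            else:
                e = x
                s = max(e - L, g.start)
                insert = revcomp(seq[s:e])
            barcode = "".join(BASES[rng.integers(0, 4, size=n_N)])
            mol_id = f"r{read_no:07d}"
            emit = [(mol_id, None)]
            while rng.random() < config.pcr_duplication_rate and len(emit) < 10:
                read_no_dup = read_no + len(emit)
                emit.append((f"r{read_no_dup:07d}", mol_id))
            read_no += len(emit)
            for rid, dup_of in emit:
                fastq_seq = _layout_read(mask, barcode, exp_barcodes[rep], insert)
                reads.append((rid, fastq_seq, "I" * len(fastq_seq), rep))
                aligns.append((genome.chrom_name, s, e, f"{rid}:{barcode}", 1, g.strand))
                prov.append((rid, mol_id, x, g.strand, g.gene_id, rep, dup_of, barcode))

    reads_df = pd.DataFrame(reads, columns=["read_id", "sequence", "quality", "replicate"])
    aligns_df = pd.DataFrame(aligns, columns=["chrom", "start", "end", "name", "score", "strand"])
    prov_df = pd.DataFrame(prov, columns=["read_id", "molecule_id", "crosslink_pos",
                                          "strand", "gene_id", "replicate",
                                          "duplicate_of", "random_barcode"])
    truth.provenance = prov_df
    return SimulatedIclip(reads=reads_df, alignments=aligns_df, truth=truth)


def _layout_read(mask: str, random_bc: str, exp_bc: str, insert: str) -> str:
    """Interleave barcodes and insert bases according to the mask."""
    out: List[str] = []
    ni = xi = ii = 0
    for c in mask:
        if c == "N":
            out.append(random_bc[ni]); ni += 1
        elif c == "X":
            out.append(exp_bc[xi]); xi += 1
        else:  # I: insert base inside the prefix
            out.append(insert[ii] if ii < len(insert) else "A"); ii += 1
    out.append(insert[ii:])
    return "".join(out)


# ---------------------------------------------------------------------------
# splicing simulation
# ---------------------------------------------------------------------------

def dependence_from_truth(genes: Sequence[GeneModel], truth: SimTruth,
                          low: float = 3.0, high: float = 6.0,
                          seed: int = 0) -> Dict[str, float]:
    """Assign each cassette exon a Tra2-dependence coefficient d_e.

    Exons of motif-planted genes get d_e ~ U(low, high); others 0.
    Exon ids are ``<gene_id>.cas``.
    """
    rng = np.random.default_rng([3, seed])
    motif = set(truth.planted_clusters.gene_id)
    out: Dict[str, float] = {}
    for g in genes:
        if g.cassette_exons():
            out[f"{g.gene_id}.cas"] = float(rng.uniform(low, high)) if g.gene_id in motif else 0.0
    return out


def true_psi(feedback: FeedbackModel, d_e: float, k_alpha: float, k_beta: float) -> float:
    """Noise-free PSI of an exon with dependence d_e under a knockdown."""
    e_a, e_b = feedback.activities(k_alpha, k_beta)
    return 100.0 * float(expit(feedback.theta0 + d_e * (e_a + e_b)))


def simulate_splicing(genes: Sequence[GeneModel], feedback: FeedbackModel,
                      design: KnockdownDesign, config: SimConfig,
                      d_e: Optional[Dict[str, float]] = None,
                      truth: Optional[SimTruth] = None) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate isoform quantities per exon x condition, plus true PSI.

    Returns ``(measurements, true_psi_table)``.  Measurements carry
    included/skipped molar quantities; replicate PSI is the true PSI plus
    Gaussian noise (sd ``feedback.sigma_rep``), clipped to [0, 100].
    """
    feedback.validate()
    design.validate()
    rng = np.random.default_rng([4, config.seed])
    if d_e is None:
        if truth is None:
            raise DesignError("need either d_e or truth to assign dependence")
        d_e = dependence_from_truth(genes, truth, seed=config.seed)

    rows: List[tuple] = []
    truths: List[tuple] = []
    for exon_id, dep in d_e.items():
        for cond, (ka, kb) in design.conditions.items():
            psi_t = true_psi(feedback, dep, ka, kb)
            truths.append((exon_id, cond, psi_t))
            for rep in range(design.n_replicates):
                psi = psi_t + rng.normal(0.0, feedback.sigma_rep) if feedback.sigma_rep > 0 else psi_t
                psi = float(np.clip(psi, 0.0, 100.0))
                inc = design.total_quantity * psi / 100.0
                rows.append((exon_id, f"{cond}_rep{rep + 1}", cond, rep + 1,
                             inc, design.total_quantity - inc))
    meas = pd.DataFrame(rows, columns=["exon_id", "sample_id", "condition",
                                       "replicate", "included", "skipped"])
    psi_df = pd.DataFrame(truths, columns=["exon_id", "condition", "true_psi"])
    if truth is not None:
        truth.true_psi = psi_df
    return meas, psi_df
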