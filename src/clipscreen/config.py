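"""Configuration objects for the simulator and the pipeline.

All genomic coordinates in this package are 0-based, half-open (BED
convention).  The barcode mask describes the read prefix: ``N`` positions
hold the random (molecule) barcode, ``X`` positions the experiment barcode,
``I`` positions are genomic insert bases that happen to sit inside the
prefix.  The default ``NNNXXXXNN`` is a common iCLIP layout (3+2 random
nucleotides split around a 4-nt experiment barcode).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from .errors import ConfigurationError

VALID_CONDITIONS = ("control", "kd_alpha", "kd_beta", "kd_double")


@dataclass
class SimConfig:
    """Parameters of the synthetic iCLIP / splicing experiment.

    Crosslink propensity at a genomic position inside a gene is
    ``expression * (background_rate + motif_weight * motif_indicator)``,
    so ``motif_weight`` is the fold-boost a planted AGAA/GAA motif
    position receives over the per-nucleotide background.
    """

    seed: int = 0
    n_genes: int = 50
    motif_fraction: float = 0.4
    ncrna_fraction: float = 0.1
    expression_sigma: float = 0.75    # lognormal sd of per-gene expression weights
    motif_weight: float = 50.0        # w: propensity multiplier on planted motif positions
    background_rate: float = 0.05     # b0: per-nucleotide background propensity
    n_reads: int = 20_000             # molecules across all replicates (before PCR duplication)
    read_length_min: int = 20         # insert length range, nt
    read_length_max: int = 40
    pcr_duplication_rate: float = 0.15
    barcode_mask: str = "NNNXXXXNN"
    n_replicates: int = 3
    chrom_name: str = "chrS"
    # gene geometry (nt)
    flank_exon_range: tuple = (100, 140)
    cassette_exon_range: tuple = (140, 180)
    intron_range: tuple = (350, 450)
    intergenic_length: int = 200
    utr5_length: int = 30
    utr3_length: int = 40
    motif_region_length: int = 60

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if not (0.0 <= self.motif_fraction <= 1.0):
            raise ConfigurationError("motif_fraction must be in [0, 1]")
        if not (0.0 <= self.ncrna_fraction <= 1.0):
            raise ConfigurationError("ncrna_fraction must be in [0, 1]")
        if self.background_rate <= 0:
            raise ConfigurationError("background_rate must be > 0")
        if self.motif_weight < 0:
            raise ConfigurationError("motif_weight must be >= 0")
        if not (0.0 <= self.pcr_duplication_rate < 1.0):
            raise ConfigurationError("pcr_duplication_rate must be in [0, 1)")
        if self.n_reads < 1:
            raise ConfigurationError("n_reads must be >= 1")
        if not (0 < self.read_length_min <= self.read_length_max):
            raise ConfigurationError("read length range must satisfy 0 < min <= max")
        mask = set(self.barcode_mask)
        if not mask <= {"N", "X", "I"}:
            raise ConfigurationError("barcode_mask may contain only N, X, I")
        if "N" not in mask or "X" not in mask:
            raise ConfigurationError("barcode_mask needs >= 1 N and >= 1 X position")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.motif_region_length > self.cassette_exon_range[0]:
            raise ConfigurationError("motif region must fit inside the smallest cassette exon")


@dataclass
class FeedbackModel:
    """Asymmetric cross-regulation between two paralogous splicing factors.

    The beta paralog is expressed well above alpha (``E_beta >> E_alpha``)
    and represses alpha via poison-exon inclusion with gain ``gamma``;
    the reverse repression is much weaker (``gamma_rev``).  Knockdowns
    are expressed as remaining-activity fractions ``k`` in [0, 1];
    depleting beta de-represses alpha:

        e_alpha = k_a * E_alpha * (1 + gamma * E_beta) / (1 + gamma * k_b * E_beta)
        e_beta  = k_b * E_beta * (1 + gamma_rev * E_alpha) / (1 + gamma_rev * k_a * E_alpha)

    True exon inclusion follows a logistic dose-response in total activity:
    ``PSI = 100 * logistic(theta0 + d_e * (e_alpha + e_beta))`` where
    ``d_e >= 0`` is the exon's dependence on the shared factor pool.
    """

    E_alpha: float = 0.1
    E_beta: float = 1.0
    gamma: float = 15.0
    gamma_rev: float = 0.5
    theta0: float = -2.0
    sigma_rep: float = 3.0   # replicate PSI noise, PSI points

    def validate(self) -> None:
        if not (self.E_beta > self.E_alpha >= 0):
            raise ConfigurationError("requires E_beta > E_alpha >= 0")
        if self.gamma < 0 or self.gamma_rev < 0:
            raise ConfigurationError("feedback gains must be >= 0")
        if self.sigma_rep < 0:
            raise ConfigurationError("sigma_rep must be >= 0")

    def activities(self, k_alpha: float, k_beta: float) -> tuple:
        """Effective (e_alpha, e_beta) under remaining-activity fractions."""
        for k in (k_alpha, k_beta):
            if not (0.0 <= k <= 1.0):
                raise ConfigurationError("knockdown remaining fractions must be in [0, 1]")
        e_alpha = (k_alpha * self.E_alpha
                   * (1.0 + self.gamma * self.E_beta)
                   / (1.0 + self.gamma * k_beta * self.E_beta))
        e_beta = (k_beta * self.E_beta
                  * (1.0 + self.gamma_rev * self.E_alpha)
                  / (1.0 + self.gamma_rev * k_alpha * self.E_alpha))
        return e_alpha, e_beta


@dataclass
class KnockdownDesign:
    """Conditions, their remaining-activity fractions and replication."""

    conditions: dict = field(default_factory=lambda: {
        "control": (1.0, 1.0),
        "kd_alpha": (0.05, 1.0),
        "kd_beta": (1.0, 0.05),
        "kd_double": (0.05, 0.05),
    })
    n_replicates: int = 3
    total_quantity: float = 100.0   # molar units per sample (included + skipped)

    def validate(self) -> None:
        from .errors import DesignError
        for name, (ka, kb) in self.conditions.items():
            if name not in VALID_CONDITIONS:
                raise DesignError(f"unknown condition label: {name!r}")
            if not (0.0 <= ka <= 1.0 and 0.0 <= kb <= 1.0):
                raise DesignError(f"remaining fractions for {name!r} must be in [0, 1]")
        if self.n_replicates < 1:
            raise DesignError("n_replicates must be >= 1")


# -- pipeline-wide constants surfaced as named parameters -------------------

@dataclass
class PipelineParams:
    """Stage parameters; defaults follow the published protocol values."""

    min_insert_length: int = 11      # reads with shorter inserts are ignored
    cluster_max_gap: int = 15        # nt window for merging significant sites
    cluster_alpha: float = 0.05      # site-level FDR threshold
    n_randomizations: int = 100      # within-gene randomizations for the null
    kmer_k: int = 5                  # pentamers
    kmer_flank: int = 30             # nt of sequence each side of a crosslink site
    n_top_kmers: int = 10
    screen_flank: int = 300          # nt around either splice site
    responsive_delta_psi: float = 15.0
    strong_delta_psi: float = 40.0
    constitutive_psi: float = 95.0
    compensation_min_gain: float = 15.0
    compensation_max_single: float = 10.0
    test_alpha: float = 0.05


@dataclass
class PipelineConfig:
    """Paths plus stage parameters for an end-to-end run."""

    outdir: str = "clipscreen_out"
    genome: Optional[str] = None
    gtf: Optional[str] = None
    fastq: Optional[str] = None
    bed: Optional[str] = None
    psi_table: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"
    sim: SimConfig = field(default_factory=SimConfig)
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        sim = SimConfig(**sim_raw)
        params = PipelineParams(**raw.pop("params", {}))
        known = {f for f in cls.__dataclass_fields__ if f not in ("sim", "params")}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(sim=sim, params=params, **raw)
        if "seed" not in sim_raw:
            cfg.sim.seed = cfg.seed
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)
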