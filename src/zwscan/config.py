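"""Configuration for the synthetic ZW-system generator and the analysis stages.

The chromosome layout mirrors a young female-heterogametic (ZW) system: a
pseudo-autosomal region (PAR) that still recombines, and two evolutionary
strata (S2 younger, S1 older) that stopped recombining at different times and
therefore carry different levels of W-Z divergence. Default divergence and
loss-of-function settings follow the per-region statistics of a recently
described halfbeak ZW system, scaled down to a 2 Mb desk-size chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

REGIONS = ("PAR", "S2", "S1")

#: LoF class order used for class-weight vectors.
LOF_CLASSES = ("sequence_loss", "exon_loss", "orf_disrupt", "splice")


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


@dataclass
class SimConfig:
    # chromosome layout (1-based inclusive coordinates, VCF/GFF convention)
    chrom_length: int = 2_000_000
    par_end: int = 700_000
    s2_end: int = 1_400_000
    autosome_length: int = 500_000

    # per-region divergence model
    ds_true: dict = field(default_factory=lambda: {"PAR": 0.016, "S2": 0.020, "S1": 0.035})
    omega: dict = field(default_factory=lambda: {"PAR": 0.31, "S2": 0.45, "S1": 0.50})

    # gene models
    n_genes: dict = field(default_factory=lambda: {"PAR": 20, "S2": 20, "S1": 20})
    gene_length_range: tuple = (600, 1500)  # CDS bp, forced to a multiple of 3
    exons_per_gene_range: tuple = (2, 6)

    # W-allele loss of function
    lof_prob: dict = field(default_factory=lambda: {"PAR": 0.0, "S2": 0.271, "S1": 0.544})
    # (sequence_loss, exon_loss, orf_disrupt, splice); defaults are the observed
    # class proportions (80, 30, 151, 71)/332 in the study system
    lof_class_weights: tuple = (80 / 332, 30 / 332, 151 / 332, 71 / 332)
    n_large_w_deletions: int = 1
    large_w_deletion_bp: int = 120_000  # spans >= 1 full coverage window

    # cohort
    n_females: int = 12
    n_males: int = 12
    missing_rate: float = 0.02
    genotype_error_rate: float = 0.005

    # coverage & polymorphism
    depth_mean: float = 10.0
    cov_window_bp: int = 50_000
    par_diversity: float = 0.005  # per-site heterozygosity in recombining regions
    read_length: int = 150

    # expression
    expr_baseline: float = 200.0
    nb_size: float = 10.0
    compensated_fraction: float = 0.1
    n_expr_females: int = 2
    n_expr_males: int = 2

    # gene trees (ZW-sister, W-loss, Z-loss planted counts)
    gene_tree_counts: tuple = (164, 20, 6)

    seed: int = 1

    # -- validation ---------------------------------------------------------
    def validate(self) -> "SimConfig":
        if not (1 <= self.par_end < self.s2_end < self.chrom_length):
            raise ConfigError(
                "boundaries: need 1 <= par_end < s2_end < chrom_length, got "
                f"par_end={self.par_end}, s2_end={self.s2_end}, "
                f"chrom_length={self.chrom_length}"
            )
        for name in ("missing_rate", "genotype_error_rate", "compensated_fraction",
                     "par_diversity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: probability must be in [0, 1], got {v}")
        for name in ("ds_true", "omega", "lof_prob", "n_genes"):
            d = getattr(self, name)
            missing = [r for r in REGIONS if r not in d]
            if missing:
                raise ConfigError(f"{name}: missing regions {missing}")
        for r, p in self.lof_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"lof_prob[{r}]: must be in [0, 1], got {p}")
        for r, v in self.ds_true.items():
            if v < 0:
                raise ConfigError(f"ds_true[{r}]: must be >= 0, got {v}")
        for r, v in self.omega.items():
            if v < 0:
                raise ConfigError(f"omega[{r}]: must be >= 0, got {v}")
        w = self.lof_class_weights
        if len(w) != 4 or any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-8:
            raise ConfigError(
                f"lof_class_weights: need 4 non-negative weights summing to 1, got {w}"
            )
        lo, hi = self.exons_per_gene_range
        if lo < 2:
            raise ConfigError(f"exons_per_gene_range: minimum exon count is 2, got {lo}")
        if self.gene_length_range[0] < 9:
            raise ConfigError("gene_length_range: CDS must hold start+body+stop (>=9 bp)")
        if self.n_females < 1 or self.n_males < 1:
            raise ConfigError("n_females/n_males: need at least one individual per sex")
        if any(c < 0 for c in self.gene_tree_counts):
            raise ConfigError(f"gene_tree_counts: counts must be >= 0, got {self.gene_tree_counts}")
        if self.depth_mean <= 0:
            raise ConfigError(f"depth_mean: must be > 0, got {self.depth_mean}")
        return self

    # -- (de)serialisation --------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("gene_length_range", "exons_per_gene_range", "lof_class_weights",
                    "gene_tree_counts"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()

    def region_of(self, pos: int) -> str:
        """Region label for a 1-based Z-chromosome position."""
        if pos <= self.par_end:
            return "PAR"
        if pos <= self.s2_end:
            return "S2"
        return "S1"

    def region_interval(self, region: str) -> tuple:
        """1-based inclusive (start, end) of a region on the Z."""
        return {
            "PAR": (1, self.par_end),
            "S2": (self.par_end + 1, self.s2_end),
            "S1": (self.s2_end + 1, self.chrom_length),
        }[region]
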