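"""Configuration objects for simulation and pipeline runs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Optional


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic trio-cohort generator.

    The generator draws founder haplotypes at the stated allele frequencies
    with blockwise-equicorrelated LD, transmits one haplotype per parent per
    LD block to each child, assigns a liability built from the child's own
    polygenic value (direct effect) and the summed parental polygenic value
    (genetic nurture), ascertains case families through a liability threshold,
    and imposes phenotype-dependent parent-DNA missingness.

    Parameters
    ----------
    n_variants : int
        Number of biallelic autosomal variants.
    n_ld_blocks : int
        Number of LD blocks; variants are split as evenly as possible.
    maf_range : (float, float)
        Lower/upper bounds of the uniform allele-frequency distribution,
        each in (0, 0.5].
    n_trio_families : int
        Number of ascertained case families retained.
    n_controls : int
        Size of the unscreened population control pool.
    h2_direct : float
        Fraction of liability variance explained by the child's own true
        polygenic value.
    b_nurture : float
        Liability effect (per SD) of the standardized sum of both parents'
        polygenic values; carries the nontransmitted half, so it models
        genetic nurture.
    prevalence : float
        Population case fraction defining the liability threshold.
    missing_beta_severity, missing_beta_ses : float
        Log-odds effects of child symptom severity (per SD) and of low
        family SES on trio incompleteness.
    missing_intercept : float
        Baseline log-odds of incompleteness.
    seed : int
        Root seed; all stage-local streams are derived from it.
    """

    n_variants: int = 2000
    n_ld_blocks: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_trio_families: int = 328
    n_controls: int = 5081
    h2_direct: float = 0.3
    b_nurture: float = 0.0
    prevalence: float = 0.05
    missing_beta_severity: float = math.log(1.3)
    missing_beta_ses: float = math.log(2.35)
    missing_intercept: float = -0.15
    seed: int = 0

    # generator internals (documented defaults, rarely changed)
    within_block_r: float = 0.8
    n_base_families: Optional[int] = None  # None -> sized from prevalence
    genotyping_fail_rate: float = 0.045
    father_missing_frac: float = 0.97
    mother_missing_frac: float = 0.41
    multi_proband_prob: float = 0.0
    gwas_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(
                f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}"
            )
        if not 0 <= self.h2_direct <= 1:
            raise ConfigurationError("h2_direct must lie in [0, 1]")
        if not 0 < self.prevalence <= 1:
            raise ConfigurationError("prevalence must lie in (0, 1]")
        if self.liability_noise_var < -1e-12:
            raise ConfigurationError(
                "h2_direct plus implied nurture variance exceeds 1 "
                f"(total {1 - self.liability_noise_var:.3f})"
            )
        if not 0 <= self.within_block_r < 1:
            raise ConfigurationError("within_block_r must lie in [0, 1)")
        for name in ("n_variants", "n_ld_blocks", "n_trio_families", "n_controls"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    @property
    def direct_coef(self) -> float:
        """Liability coefficient on the child's standardized polygenic value."""
        return math.sqrt(self.h2_direct)

    @property
    def liability_noise_var(self) -> float:
        """Residual liability variance after direct and nurture components.

        With a = sqrt(h2_direct) on the child value and b_nurture on the
        standardized midparent sum (correlation 1/sqrt(2) with the child
        value), total explained variance is a^2 + b^2 + sqrt(2)*a*b.
        """
        a, b = self.direct_coef, self.b_nurture
        return 1.0 - (a * a + b * b + math.sqrt(2.0) * a * b)

    def base_families(self) -> int:
        """Number of families simulated before case ascertainment."""
        if self.n_base_families is not None:
            return self.n_base_families
        if self.prevalence >= 1.0:
            return self.n_trio_families
        return int(math.ceil(self.n_trio_families / self.prevalence * 1.4)) + 50

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(d["maf_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class PrsConfig:
    """LD-clumping and scoring parameters.

    Defaults follow common practice: 250 kb clumping window at r^2 = 0.1 and
    seven p-value thresholds spanning genome-wide significance to 0.5.
    """

    thresholds: tuple[float, ...] = (5e-8, 1e-5, 1e-3, 0.01, 0.05, 0.1, 0.5)
    clump_r2: float = 0.1
    clump_kb: float = 250.0
    n_ancestry_pcs: int = 10

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(d["thresholds"])
        return d


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings: simulation, scoring, comparisons."""

    sim: SimConfig = field(default_factory=SimConfig)
    prs: PrsConfig = field(default_factory=PrsConfig)
    outdir: str = "triopgs_out"
    apply_fdr: bool = True  # replication-style runs set this False
    mendel_threshold: float = 0.01
    stages: tuple[str, ...] = ("simulate", "qc", "nt", "prs", "ptdt", "compare")
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "prs": self.prs.to_dict(),
            "outdir": self.outdir,
            "apply_fdr": self.apply_fdr,
            "mendel_threshold": self.mendel_threshold,
            "stages": list(self.stages),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimConfig.from_dict(d["sim"])
        if "prs" in d:
            prs = dict(d["prs"])
            if "thresholds" in prs:
                prs["thresholds"] = tuple(prs["thresholds"])
            d["prs"] = PrsConfig(**prs)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def digest(self) -> str:
        """Hash of the scientific settings (paths excluded)."""
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:12]
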