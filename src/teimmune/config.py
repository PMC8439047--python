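"""Configuration objects for the synthetic-data generators and the pipeline.

The simulation parameters mirror the design of the underlying study: four
natural populations genotyped for TE presence/absence, three biological
replicates per pyrosequencing assay, survival assays run in vials of ten
flies monitored on a discrete time grid, and qPCR quantities observed as
cycle thresholds normalised against a housekeeping gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

__all__ = ["FreqMixture", "SimConfig", "PipelineConfig"]


@dataclass(frozen=True)
class FreqMixture:
    """Mixture over per-TE population frequencies.

    A polymorphic TE is either rare (most insertions, which are deleterious
    or neutral and kept at low frequency by purifying selection and drift),
    at intermediate/high frequency (the candidate-adaptive class, >= 0.10),
    or fixed. Default masses follow the proportions observed in the
    annotated D. melanogaster reference set: roughly 29% fixed and 13% at
    high but unfixed frequency.
    """

    p_low: float = 0.58
    p_high: float = 0.135
    p_fixed: float = 0.285
    low_range: tuple[float, float] = (0.005, 0.095)
    high_range: tuple[float, float] = (0.10, 0.60)

    def __post_init__(self) -> None:
        total = self.p_low + self.p_high + self.p_fixed
        if not abs(total - 1.0) < 1e-9:
            raise ValueError(f"mixture masses must sum to 1, got {total}")
        for p in (self.p_low, self.p_high, self.p_fixed):
            if not 0.0 <= p <= 1.0:
                raise ValueError("mixture masses must lie in [0, 1]")

    @property
    def probs(self) -> tuple[float, float, float]:
        return (self.p_low, self.p_high, self.p_fixed)


# category fractions of the reference TE annotation: INE-1, repeat-flanked /
# nested / segmental-duplication, and zero-recombination insertions out of
# the 5416 annotated elements
_DEFAULT_TE_COUNT = 5416
_DEFAULT_FRAC_INE1 = 2234 / 5416
_DEFAULT_FRAC_REPEAT = 1561 / 5416
_DEFAULT_FRAC_ZERO = 813 / 5416


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Parameters
    ----------
    seed
        Global seed. Every generator derives its own deterministic
        substream from this value, so a fixed seed reproduces the whole
        cohort bit for bit.
    n_strains_per_pop
        Inbred strains genotyped per population.
    populations
        Population labels (default: the four panels of the study design).
    te_count, frac_ine1, frac_repeat_flanked, frac_zero_recomb
        Size of the TE annotation and the mutually exclusive exclusion
        categories (INE-1; repeat-flanked/nested; zero-recombination
        region). Fractions must sum to <= 1.
    freq_distribution
        :class:`FreqMixture` for true population frequencies.
    missing_call_rate
        Probability that a presence/absence call is missing.
    cis_effect_log2
        Default cis-regulatory effect beta: log2 fold-change of the
        TE-allele expression relative to the non-TE allele.
    amplification_bias
        Multiplicative PCR amplification bias b between the two alleles,
        shared by the cDNA and gDNA assays of a cross.
    pyro_read_depth
        Reads per pyrosequencing assay (not reported by the study;
        a realistic default is used).
    replicates
        Biological replicates per assay.
    hazard_scale, hazard_shape
        Weibull baseline for death times (hours).
    genotype_hazard_ratio, treatment_hazard_ratio
        Multiplicative hazard effects of genotype and of infection.
    monitoring_times
        Strictly increasing monitoring grid (hours); deaths are recorded
        at the first grid point after the true death time.
    flies_per_vial, vials_per_group
        Survival assay layout.
    ct_baseline, ct_noise_sd
        Ct model: Ct = baseline - log2(quantity) + N(0, sd).
    chip_enrichment_log2
        Default log2 H3K9me3 enrichment at a simulated TE flank.
    genome_zero_frac
        Fraction of each chromosome arm (proximal end) assigned
        recombination rate 0 in the emitted maps.
    gdna_per_replicate
        If True, an independent gDNA measurement is simulated for each
        cDNA replicate; otherwise the gDNA assay is measured once per
        cross (pooled heterozygous females) and shared.
    """

    seed: int = 0
    n_strains_per_pop: int = 60
    populations: Sequence[str] = ("DGRP", "Zambia", "Sweden", "Italy")
    te_count: int = _DEFAULT_TE_COUNT
    frac_ine1: float = _DEFAULT_FRAC_INE1
    frac_repeat_flanked: float = _DEFAULT_FRAC_REPEAT
    frac_zero_recomb: float = _DEFAULT_FRAC_ZERO
    freq_distribution: FreqMixture = field(default_factory=FreqMixture)
    missing_call_rate: float = 0.05
    cis_effect_log2: float = 1.0
    amplification_bias: float = 1.0
    pyro_read_depth: int = 2000
    replicates: int = 3
    hazard_scale: float = 60.0
    hazard_shape: float = 2.0
    genotype_hazard_ratio: float = 2.0
    treatment_hazard_ratio: float = 8.0
    monitoring_times: Sequence[float] = (12, 24, 36, 48, 60, 72, 96, 120, 168)
    flies_per_vial: int = 10
    vials_per_group: int = 8
    ct_baseline: float = 22.0
    ct_noise_sd: float = 0.2
    chip_enrichment_log2: float = 1.0
    genome_zero_frac: float = 0.2
    gdna_per_replicate: bool = False

    def __post_init__(self) -> None:
        self.populations = tuple(self.populations)
        self.monitoring_times = tuple(float(t) for t in self.monitoring_times)
        if isinstance(self.freq_distribution, dict):
            self.freq_distribution = FreqMixture(**self.freq_distribution)
        self.validate()

    def validate(self) -> None:
        for name in ("frac_ine1", "frac_repeat_flanked", "frac_zero_recomb",
                     "missing_call_rate", "genome_zero_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        cat_sum = self.frac_ine1 + self.frac_repeat_flanked + self.frac_zero_recomb
        if cat_sum > 1.0 + 1e-12:
            raise ValueError(
                "mutually exclusive category fractions sum to "
                f"{cat_sum:.4f} > 1")
        if self.te_count < 1:
            raise ValueError("te_count must be >= 1")
        for name in ("pyro_read_depth", "replicates", "n_strains_per_pop",
                     "flies_per_vial", "vials_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.amplification_bias <= 0:
            raise ValueError("amplification_bias must be > 0")
        for name in ("hazard_scale", "hazard_shape", "genotype_hazard_ratio",
                     "treatment_hazard_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if len(self.monitoring_times) == 0:
            raise ValueError("monitoring grid must be non-empty")
        times = list(self.monitoring_times)
        if any(b <= a for a, b in zip(times, times[1:])) or times[0] <= 0:
            raise ValueError("monitoring times must be positive and strictly increasing")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["populations"] = list(self.populations)
        d["monitoring_times"] = list(self.monitoring_times)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings: thresholds and output locations.

    Thresholds default to the screening values used throughout: candidate
    frequency 0.10, gene window 1000 bp, BH FDR 0.05, odds-ratio mortality
    threshold 0.50 (per-comparison overrides allowed).
    """

    sim: SimConfig = field(default_factory=SimConfig)
    frequency_threshold: float = 0.10
    window_bp: int = 1000
    fdr: float = 0.05
    mortality_threshold: float = 0.50
    mortality_overrides: dict = field(default_factory=dict)
    zero_recomb_rule: str = "either"
    outdir: str = "teimmune_out"

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if not 0.0 < self.frequency_threshold <= 1.0:
            raise ValueError("frequency_threshold must be in (0, 1]")
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must be in (0, 1)")
        if not 0.0 < self.mortality_threshold <= 1.0:
            raise ValueError("mortality_threshold must be in (0, 1]")
        if self.zero_recomb_rule not in ("either", "both"):
            raise ValueError("zero_recomb_rule must be 'either' or 'both'")
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
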