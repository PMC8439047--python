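"""Synthetic cohort generators.

Every generator derives its own deterministic random substream from the
single ``SimConfig.seed``, so a fixed seed reproduces the whole cohort
exactly. True parameters (population frequencies, cis effects, hazard
ratios, Ct-model quantities) are always emitted alongside the data as
sidecar tables, giving every downstream stage a recovery oracle.

What is emulated, statistically:

* TE presence/absence genotypes: Bernoulli draws at per-population true
  frequencies from a three-component mixture (rare / high / fixed), with
  calls masked at a missing rate.
* Pyrosequencing allele counts: exchangeable reads with a multiplicative
  allele-amplification bias b shared between the cDNA and gDNA assays of
  a cross, and a cis effect beta acting on cDNA only —
  gDNA ~ Binomial(depth, b/(b+1)),
  cDNA ~ Binomial(depth, b*2^beta/(b*2^beta+1)).
* Infection survival: Weibull death times with multiplicative
  genotype x treatment hazard effects, observed by interval monitoring
  (death times are ceiled to the next monitoring time; flies alive past
  the last check are censored there).
* qPCR: Ct = baseline - log2(quantity) + Gaussian noise; a housekeeping
  reference with fixed quantity; ChIP designs emit paired IP and input
  Cts per TE flank per strain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import SimConfig
from .screen import GenotypeMatrix, RecombinationMap, TECatalog, TE_CLASSES

__all__ = [
    "CHROM_LENGTHS", "GroupSpec", "ExpressionDesign", "ChipDesign",
    "simulate_te_catalog", "simulate_genotypes", "simulate_nonreference_counts",
    "simulate_pyro_counts", "simulate_survival", "simulate_ct",
]

# chromosome arm lengths (bp), roughly the euchromatic reference arms
CHROM_LENGTHS = {
    "2L": 23_500_000, "2R": 25_300_000, "3L": 28_100_000,
    "3R": 32_100_000, "X": 23_500_000,
}

_FAMILIES = {
    "DNA": ["pogo", "S", "1360", "hobo"],
    "LTR": ["roo", "297", "invader4", "mdg1", "Burdock", "Transpac"],
    "non-LTR": ["Doc", "BS", "Juan", "G5", "jockey"],
}

# substream ids, one per generator
_STREAM_CATALOG = 1
_STREAM_GENOTYPES = 2
_STREAM_NONREF = 3
_STREAM_PYRO = 4
_STREAM_SURVIVAL = 5
_STREAM_CT = 6


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _zero_boundary(chrom: str, config: SimConfig) -> int:
    """First position (1-based) of the proximal zero-recombination block."""
    length = CHROM_LENGTHS[chrom]
    return int(length * (1.0 - config.genome_zero_frac)) + 1


def _build_map(config: SimConfig, rng: np.random.Generator, dialect: str,
               tile: int) -> RecombinationMap:
    rows = []
    for chrom, length in CHROM_LENGTHS.items():
        zstart = _zero_boundary(chrom, config)
        # tile boundaries split at the zero-region edge so no interval
        # straddles it
        bounds = sorted({*range(1, length + 1, tile), zstart, length + 1})
        for start, end in zip(bounds, bounds[1:]):  # half-open
            rate = 0.0 if start >= zstart else float(
                rng.lognormal(mean=np.log(2.0), sigma=0.5))
            rows.append((chrom, start, end, rate))
    return RecombinationMap(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "rate"]),
        dialect=dialect)


def simulate_te_catalog(config: SimConfig,
                        category_counts: tuple[int, int, int] | None = None,
                        ) -> tuple[TECatalog, tuple[RecombinationMap, RecombinationMap]]:
    """Simulate a TE annotation plus two recombination-map dialects.

    Each TE belongs to exactly one cascade category — INE-1,
    repeat-flanked/nested, zero-recombination, or clean — drawn
    multinomially from the config fractions, or fixed exactly with
    ``category_counts=(n_ine1, n_repeat, n_zero)``. Zero-category TEs are
    placed inside the rate-0 proximal block of an arm; all others outside
    it, so cascade step counts equal category counts.
    """
    n = config.te_count
    if n < 1:
        raise ValueError("te_count must be >= 1")
    rng = _rng(config, _STREAM_CATALOG)

    if category_counts is not None:
        n_ine1, n_repeat, n_zero = (int(c) for c in category_counts)
        if n_ine1 + n_repeat + n_zero > n:
            raise ValueError("category counts exceed te_count")
        cats = np.array([0] * n_ine1 + [1] * n_repeat + [2] * n_zero
                        + [3] * (n - n_ine1 - n_repeat - n_zero))
        rng.shuffle(cats)
    else:
        p = [config.frac_ine1, config.frac_repeat_flanked,
             config.frac_zero_recomb]
        p.append(1.0 - sum(p))
        cats = rng.choice(4, size=n, p=p)

    chrom_names = list(CHROM_LENGTHS)
    weights = np.array([CHROM_LENGTHS[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    chroms = rng.choice(chrom_names, size=n, p=weights)

    lengths = np.clip(rng.lognormal(mean=6.5, sigma=1.2, size=n).astype(int),
                      30, 12_000)
    starts = np.empty(n, dtype=np.int64)
    for i in range(n):
        zstart = _zero_boundary(chroms[i], config)
        if cats[i] == 2:  # zero-recombination region
            lo, hi = zstart, CHROM_LENGTHS[chroms[i]] - int(lengths[i])
        else:
            lo, hi = 1, zstart - int(lengths[i]) - 1
        starts[i] = rng.integers(lo, max(lo + 1, hi))

    te_class = rng.choice(TE_CLASSES, size=n, p=[0.25, 0.40, 0.35])
    # INE-1 is its own (DNA) family
    families = np.array([
        "INE-1" if cats[i] == 0 else rng.choice(_FAMILIES[te_class[i]])
        for i in range(n)
    ])
    te_class = np.where(cats == 0, "DNA", te_class)
    completeness = rng.choice(["full-length", "truncated"], size=n,
                              p=[0.3, 0.7])

    df = pd.DataFrame({
        "id": [f"te{i:05d}" for i in range(n)],
        "family": families,
        "te_class": te_class,
        "chrom": chroms,
        "start": starts,
        "end": starts + lengths - 1,
        "length_bp": lengths,
        "completeness": completeness,
        "is_reference": True,
        "is_ine1": cats == 0,
        "repeat_flanked_or_nested": cats == 1,
    })
    map_a = _build_map(config, rng, "map_A", tile=500_000)
    map_b = _build_map(config, rng, "map_B", tile=250_000)
    return TECatalog(df), (map_a, map_b)


def simulate_genotypes(catalog: TECatalog, config: SimConfig,
                       ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate presence/absence calls and return (matrix, truth sidecar).

    A mixture component (rare / high / fixed) is drawn per TE; the true
    frequency is then drawn per population within the component's range
    (fixed => 1 everywhere), strains are Bernoulli draws at that
    frequency, and calls are masked at ``missing_call_rate``.
    """
    rng = _rng(config, _STREAM_GENOTYPES)
    mix = config.freq_distribution
    te_ids = catalog.df["id"].tolist()
    pops = list(config.populations)
    n_te = len(te_ids)

    comp = rng.choice(3, size=n_te, p=mix.probs)
    true = np.empty((n_te, len(pops)))
    for j in range(len(pops)):
        low = rng.uniform(*mix.low_range, size=n_te)
        high = rng.uniform(*mix.high_range, size=n_te)
        true[:, j] = np.where(comp == 0, low, np.where(comp == 1, high, 1.0))

    strains, strain_to_pop = [], {}
    for pop in pops:
        for k in range(config.n_strains_per_pop):
            name = f"{pop}_{k:03d}"
            strains.append(name)
            strain_to_pop[name] = pop

    calls = np.empty((n_te, len(strains)), dtype="<U1")
    for j, pop in enumerate(pops):
        cols = [i for i, s in enumerate(strains) if strain_to_pop[s] == pop]
        present = rng.random((n_te, len(cols))) < true[:, [j]]
        calls[:, cols] = np.where(present, GenotypeMatrix.PRESENT,
                                  GenotypeMatrix.ABSENT)
    missing = rng.random(calls.shape) < config.missing_call_rate
    calls[missing] = GenotypeMatrix.MISSING

    matrix = GenotypeMatrix(
        pd.DataFrame(calls, index=pd.Index(te_ids, name="te"),
                     columns=strains),
        strain_to_pop)
    truth = pd.DataFrame(true, index=pd.Index(te_ids, name="te"),
                         columns=pops)
    truth.insert(0, "component",
                 np.array(["low", "high", "fixed"])[comp])
    return matrix, truth


def simulate_nonreference_counts(config: SimConfig, n_te: int = 30,
                                 panel_size: int = 177,
                                 verified_rate: float = 0.9) -> pd.DataFrame:
    """Simulate a de novo insertion panel-count table for the pre-filter."""
    rng = _rng(config, _STREAM_NONREF)
    freq = rng.beta(0.8, 6.0, size=n_te)
    counts = rng.binomial(panel_size, freq)
    return pd.DataFrame({
        "te": [f"tdn{i + 1}" for i in range(n_te)],
        "count": counts,
        "verified": rng.random(n_te) < verified_rate,
        "true_frequency": freq,
    })


def simulate_pyro_counts(crosses: Iterable, config: SimConfig,
                         effects: Mapping | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate replicate pyrosequencing allele counts for ASE crosses.

    ``crosses`` is an iterable of :class:`teimmune.ase.CrossDesign` (or
    anything with ``te``, ``gene`` and ``background`` attributes).
    ``effects`` optionally maps ``(te, condition)`` or ``te`` to the true
    cis effect beta (log2); otherwise ``config.cis_effect_log2`` applies
    everywhere. The gDNA assay is measured once per cross (shared across
    conditions and replicates) unless ``config.gdna_per_replicate``.

    Returns (measurements, truth sidecar).
    """
    if config.pyro_read_depth <= 0:
        raise ValueError("pyro_read_depth must be > 0")
    rng = _rng(config, _STREAM_PYRO)
    depth = config.pyro_read_depth
    b = config.amplification_bias
    rows, truth_rows = [], []
    for cross in crosses:
        gshared = rng.binomial(depth, b / (b + 1.0))
        for condition in ("non-infected", "infected"):
            beta = config.cis_effect_log2
            if effects is not None:
                key = (getattr(cross, "te"), condition)
                if key in effects:
                    beta = effects[key]
                elif getattr(cross, "te") in effects:
                    beta = effects[getattr(cross, "te")]
            p_cdna = b * 2.0 ** beta / (b * 2.0 ** beta + 1.0)
            truth_rows.append({
                "te": cross.te, "gene": cross.gene,
                "background": cross.background, "condition": condition,
                "beta_log2": beta, "amplification_bias": b,
            })
            for rep in range(1, config.replicates + 1):
                gdna_te = (rng.binomial(depth, b / (b + 1.0))
                           if config.gdna_per_replicate else gshared)
                cdna_te = rng.binomial(depth, p_cdna)
                rows.append({
                    "te": cross.te, "gene": cross.gene,
                    "background": cross.background, "condition": condition,
                    "replicate": rep,
                    "cdna_te": int(cdna_te), "cdna_ref": int(depth - cdna_te),
                    "gdna_te": int(gdna_te), "gdna_ref": int(depth - gdna_te),
                })
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class GroupSpec:
    """One survival-assay arm: a genotype under one treatment."""

    label: str
    treatment: str  # "infected" or "non-infected"
    genotype_hazard_ratio: float = 1.0
    n_vials: int | None = None
    flies_per_vial: int | None = None

    def __post_init__(self) -> None:
        if self.treatment not in ("infected", "non-infected"):
            raise ValueError("treatment must be 'infected' or 'non-infected'")
        if self.genotype_hazard_ratio <= 0:
            raise ValueError("hazard ratios must be > 0")


def simulate_survival(groups: Sequence[GroupSpec],
                      config: SimConfig) -> pd.DataFrame:
    """Simulate per-fly interval-monitored survival records.

    Death times follow a Weibull with survival
    S(t) = exp(-r (t/scale)^shape) where
    r = genotype_hazard_ratio x (treatment_hazard_ratio if infected).
    Observed times are ceiled to the monitoring grid; flies alive after
    the last check are censored there.
    """
    grid = np.asarray(config.monitoring_times, dtype=float)
    if grid.size == 0:
        raise ValueError("monitoring grid must be non-empty")
    rng = _rng(config, _STREAM_SURVIVAL)
    rows = []
    fly = 0
    for g in groups:
        r = g.genotype_hazard_ratio * (
            config.treatment_hazard_ratio if g.treatment == "infected" else 1.0)
        n_vials = g.n_vials or config.vials_per_group
        per_vial = g.flies_per_vial or config.flies_per_vial
        for vial in range(1, n_vials + 1):
            u = rng.random(per_vial)
            t_true = config.hazard_scale * (-np.log(u) / r) ** (
                1.0 / config.hazard_shape)
            idx = np.searchsorted(grid, t_true, side="left")
            for t, i in zip(t_true, idx):
                fly += 1
                if i >= grid.size:
                    rows.append({"fly": f"fly{fly:05d}",
                                 "vial": f"{g.label}_v{vial}",
                                 "group": g.label, "treatment": g.treatment,
                                 "time": float(grid[-1]), "event": 0})
                else:
                    rows.append({"fly": f"fly{fly:05d}",
                                 "vial": f"{g.label}_v{vial}",
                                 "group": g.label, "treatment": g.treatment,
                                 "time": float(grid[i]), "event": 1})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExpressionDesign:
    """qPCR expression design: true log2 expression per group x treatment.

    ``cells`` maps (group, treatment) -> true log2 relative expression of
    the target gene (0 = same quantity as the implicit baseline).
    """

    target: str
    cells: Mapping[tuple[str, str], float] = field(default_factory=dict)


@dataclass(frozen=True)
class ChipDesign:
    """ChIP-qPCR design: true log2 enrichment per (locus, flank, strain).

    Control loci are appended automatically: an 18S-like locus expected
    enriched (+2 log2) and an Rpl32-like locus expected depleted
    (-2 log2) in every strain.
    """

    cells: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    control_enriched_log2: float = 2.0
    control_depleted_log2: float = -2.0


def simulate_ct(design, config: SimConfig) -> pd.DataFrame:
    """Simulate Ct tables for an expression or ChIP design.

    Ct = ct_baseline - log2(quantity) + Normal(0, ct_noise_sd). For an
    :class:`ExpressionDesign` the reference (housekeeping) Ct comes from
    a fixed quantity; for a :class:`ChipDesign` paired IP and input Cts
    are emitted per locus flank per strain, the input carrying quantity 1
    and the IP carrying 2^enrichment.
    """
    rng = _rng(config, _STREAM_CT)
    sd = config.ct_noise_sd
    rows = []

    def ct_of(quantity: float) -> float:
        if quantity <= 0:
            raise ValueError("quantity must be > 0")
        return config.ct_baseline - np.log2(quantity) + (
            rng.normal(0.0, sd) if sd > 0 else 0.0)

    if isinstance(design, ExpressionDesign):
        for (group, treatment), log2_expr in design.cells.items():
            for rep in range(1, config.replicates + 1):
                rows.append({
                    "sample": f"{group}_{treatment}_r{rep}",
                    "group": group, "treatment": treatment,
                    "target": design.target, "replicate": rep,
                    "ct_target": ct_of(2.0 ** log2_expr),
                    # housekeeping (Act5c-like) reference at fixed quantity 1
                    "ct_reference": ct_of(1.0),
                })
        return pd.DataFrame(rows)

    if isinstance(design, ChipDesign):
        cells = dict(design.cells)
        strains = sorted({s for (_, _, s) in cells})
        for strain in strains:
            cells[("18S", "control", strain)] = design.control_enriched_log2
            cells[("Rpl32", "control", strain)] = design.control_depleted_log2
        for (locus, flank, strain), enr in sorted(cells.items()):
            for rep in range(1, config.replicates + 1):
                rows.append({
                    "locus": locus, "flank": flank, "strain": strain,
                    "replicate": rep,
                    "ct_ip": ct_of(2.0 ** enr),
                    "ct_input": ct_of(1.0),
                })
        return pd.DataFrame(rows)

    raise TypeError("design must be ExpressionDesign or ChipDesign")
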