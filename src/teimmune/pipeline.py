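"""End-to-end pipeline: simulate -> screen -> ASE -> survival -> expression/ChIP.

Runs every stage on a synthetic cohort (or user-supplied tables), writes
every intermediate as TSV, and produces a :class:`RunReport` whose counts
are cross-consistent: TEs with ASE <= TEs analysed <= candidates <=
catalog size. Re-running with the same config reproduces identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ase import ASEExperiment, CrossDesign
from .config import PipelineConfig, SimConfig
from .expression import ChipEnrichmentModel, RelativeExpressionModel
from .screen import (GeneRecord, apply_exclusion_cascade, assign_genes_all,
                     intersect_immune, population_frequency, select_candidates,
                     screen_nonreference)
from .simulate import (ChipDesign, ExpressionDesign, GroupSpec,
                       simulate_ct, simulate_genotypes,
                       simulate_nonreference_counts, simulate_pyro_counts,
                       simulate_survival, simulate_te_catalog)
from .survival import InfectionSurvivalModel

logger = logging.getLogger(__name__)

__all__ = ["RunReport", "run_pipeline", "build_fig2_table", "simulate_genes"]

_STREAM_GENES = 7


def simulate_genes(catalog, config: SimConfig, gene_rate: float = 0.5,
                   immune_rate: float = 0.25) -> list[GeneRecord]:
    """Place synthetic genes near a fraction of catalog TEs (plumbing).

    For each selected TE a single-transcript gene is placed within 1 kb
    (or, for a fraction, a few kb away so the nearest-gene fallback is
    exercised); ``immune_rate`` of genes get the immune flag with a
    random evidence class.
    """
    rng = np.random.default_rng([int(config.seed), _STREAM_GENES])
    genes: list[GeneRecord] = []
    evidence_classes = ["expression", "survival", "pathway"]
    for i, te in catalog.df.iterrows():
        if rng.random() > gene_rate:
            continue
        near = rng.random() < 0.8
        gap = int(rng.integers(1, 1000)) if near else int(rng.integers(1500, 5000))
        length = int(rng.integers(1000, 8000))
        start = int(te["end"]) + gap + 1
        end = start + length - 1
        strand = "+" if rng.random() < 0.5 else "-"
        cds_lo = start + int(0.1 * length)
        cds_hi = end - int(0.1 * length)
        immune = bool(rng.random() < immune_rate)
        genes.append(GeneRecord(
            gene_id=f"gene_{te['id']}",
            symbol=f"CG{i + 10000}",
            chrom=te["chrom"], start=start, end=end, strand=strand,
            transcripts={f"tr_{te['id']}": [(cds_lo, cds_hi)]},
            immune_flag=immune,
            evidence=frozenset(
                rng.choice(evidence_classes,
                           size=int(rng.integers(1, 3)),
                           replace=False).tolist()) if immune else frozenset(),
        ))
    return genes


def build_fig2_table(ase_results: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Condition x gene x background matrix of ASE directions.

    Cells hold an arrow (up/down for a significant TE-higher/TE-lower
    effect, '.' otherwise); the counts dict tallies genes significant per
    condition, genes significant in both conditions, and TEs with any
    effect. Returns (matrix, counts).
    """
    if ase_results.empty:
        return pd.DataFrame(), {
            "genes_with_ase_per_condition": {},
            "genes_both_conditions": 0,
            "tes_with_ase_any_condition": 0,
        }
    arrow = {"TE-higher": "up", "TE-lower": "down", "none": "."}
    piv = ase_results.pivot_table(
        index="gene", columns=["condition", "background"],
        values="direction", aggfunc=lambda d: arrow[d.iloc[0]]).fillna(".")

    sig = ase_results[ase_results["significant"]]
    per_cond = {
        cond: int(sub["gene"].nunique())
        for cond, sub in sig.groupby("condition")
    }
    genes_by_cond = {cond: set(sub["gene"])
                     for cond, sub in sig.groupby("condition")}
    both = set.intersection(*genes_by_cond.values()) if len(
        genes_by_cond) == 2 else set()
    counts = {
        "genes_with_ase_per_condition": per_cond,
        "genes_both_conditions": len(both),
        "tes_with_ase_any_condition": int(sig["te"].nunique()),
    }
    return piv, counts


@dataclass
class RunReport:
    """Aggregated pipeline outputs and their counts."""

    version: str
    config_hash: str
    cascade: pd.DataFrame = None
    candidate_counts: dict = field(default_factory=dict)
    ase_counts: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)

    def validate(self) -> None:
        cc = self.candidate_counts
        ac = self.ase_counts
        if not cc:
            return
        chain = [
            ("tes_with_ase", ac.get("tes_with_ase_any_condition", 0)),
            ("tes_analyzed", ac.get("tes_analyzed",
                                    ac.get("tes_with_ase_any_condition", 0))),
            ("candidates", cc.get("candidates", 0)),
            ("catalog", cc.get("catalog", 0)),
        ]
        for (na, va), (nb, vb) in zip(chain, chain[1:]):
            if va > vb:
                raise AssertionError(
                    f"count inconsistency: {na}={va} > {nb}={vb}")
        if cc.get("immune_candidates", 0) > cc.get("candidates", 0):
            raise AssertionError("immune candidates exceed candidates")

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "config_hash": self.config_hash,
            "cascade": self.cascade.to_dict(orient="records")
            if self.cascade is not None else None,
            "candidate_counts": self.candidate_counts,
            "ase_counts": self.ase_counts,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = [f"teimmune v{self.version}  (config {self.config_hash[:12]})"]
        if self.cascade is not None:
            lines.append("exclusion cascade:")
            for _, r in self.cascade.iterrows():
                lines.append(f"  - {r['step']}: excluded {r['excluded']}, "
                             f"remaining {r['remaining']}")
        for k, v in self.candidate_counts.items():
            lines.append(f"{k}: {v}")
        for k, v in self.ase_counts.items():
            lines.append(f"{k}: {v}")
        return "\n".join(lines)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps({**config.sim.to_dict(),
                       "frequency_threshold": config.frequency_threshold,
                       "window_bp": config.window_bp, "fdr": config.fdr,
                       "mortality_threshold": config.mortality_threshold,
                       "zero_recomb_rule": config.zero_recomb_rule},
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir=None,
                 explicit_candidates=None,
                 n_ase_tes: int = 14, true_effect_fraction: float = 0.5,
                 ) -> RunReport:
    """Run every stage on a synthetic cohort and write intermediates.

    ``explicit_candidates`` disables the screening stage and runs ASE on
    the given TE ids instead. Of the TEs entering ASE,
    ``true_effect_fraction`` receive the config's true cis effect and the
    rest beta = 0, recorded in the truth sidecar.
    """
    sim = config.sim
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, config_hash=_config_hash(config))

    # --- screen stage -------------------------------------------------
    catalog, maps = simulate_te_catalog(sim)
    catalog.to_tsv(outdir / "catalog.tsv")
    catalog.to_bed(outdir / "catalog.bed")
    maps[0].to_tsv(outdir / "recomb_map_A.tsv")
    maps[1].to_tsv(outdir / "recomb_map_B.tsv")

    retained, cascade = apply_exclusion_cascade(
        catalog, maps, zero_recomb_rule=config.zero_recomb_rule)
    report.cascade = cascade.to_frame()
    report.cascade.to_csv(outdir / "cascade_report.tsv", sep="\t", index=False)
    logger.info("cascade: %d -> %d TEs", len(catalog), len(retained))

    genotypes, truth_freq = simulate_genotypes(retained, sim)
    genotypes.to_tsv(outdir / "genotypes.tsv", outdir / "strain_populations.tsv")
    truth_freq.to_csv(outdir / "true_frequencies.tsv", sep="\t")
    freqs = population_frequency(genotypes)
    freqs.to_tsv(outdir / "population_frequencies.tsv")

    if explicit_candidates is None:
        candidates = select_candidates(freqs, config.frequency_threshold)
    else:
        candidates = pd.DataFrame({"te": list(explicit_candidates)})
    candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)

    nonref = screen_nonreference(simulate_nonreference_counts(sim),
                                 threshold=config.frequency_threshold)
    nonref.to_csv(outdir / "nonreference_candidates.tsv", sep="\t", index=False)

    genes = simulate_genes(retained, sim)
    cand_catalog = retained.subset(
        retained.df["id"].isin(set(candidates["te"])).to_numpy())
    associations = assign_genes_all(cand_catalog, genes, config.window_bp)
    associations.to_csv(outdir / "gene_associations.tsv", sep="\t", index=False)
    immune = intersect_immune(candidates, associations)
    immune.to_csv(outdir / "immune_candidates.tsv", sep="\t", index=False)

    report.candidate_counts = {
        "catalog": len(catalog),
        "retained_after_cascade": len(retained),
        "candidates": len(candidates),
        "nonreference_candidates": len(nonref),
        "immune_candidates": int(immune["te"].nunique()) if len(immune) else 0,
    }

    # --- ASE stage ----------------------------------------------------
    ase_tes = (immune["te"].unique().tolist() if len(immune)
               else candidates["te"].head(n_ase_tes).tolist())[:n_ase_tes]
    gene_of = (dict(immune.groupby("te")["gene_id"].first())
               if len(immune) else {})
    crosses = [
        CrossDesign(te=te, gene=gene_of.get(te, f"gene_{te}"), background=bg)
        for te in ase_tes for bg in ("I", "II")
    ]
    n_true = int(round(true_effect_fraction * len(ase_tes)))
    effects = {te: (sim.cis_effect_log2 if i < n_true else 0.0)
               for i, te in enumerate(ase_tes)}
    pyro, pyro_truth = simulate_pyro_counts(crosses, sim, effects=effects)
    pyro.to_csv(outdir / "pyro_counts.tsv", sep="\t", index=False)
    pyro_truth.to_csv(outdir / "pyro_truth.tsv", sep="\t", index=False)

    if len(pyro):
        ase_res = ASEExperiment(pyro).fit(fdr=config.fdr)
        ase_res.to_tsv(outdir / "ase_results.tsv")
        fig2, ase_counts = build_fig2_table(ase_res.results)
        fig2.to_csv(outdir / "fig2_table.tsv", sep="\t")
        ase_counts["tes_analyzed"] = len(ase_tes)
        ase_counts["genes_analyzed"] = int(ase_res.results["gene"].nunique())
        report.ase_counts = ase_counts
        report.tables["ase"] = ase_res.results
    else:
        report.ase_counts = {"tes_analyzed": 0,
                             "tes_with_ase_any_condition": 0}

    # --- survival stage ----------------------------------------------
    groups = [
        GroupSpec("mutant", "infected", sim.genotype_hazard_ratio),
        GroupSpec("wild-type", "infected", 1.0),
        GroupSpec("mutant", "non-infected", sim.genotype_hazard_ratio,
                  n_vials=max(1, sim.vials_per_group // 2)),
        GroupSpec("wild-type", "non-infected", 1.0,
                  n_vials=max(1, sim.vials_per_group // 2)),
    ]
    records = simulate_survival(groups, sim)
    records.to_csv(outdir / "survival_records.tsv", sep="\t", index=False)
    surv = (InfectionSurvivalModel(records)
            .add_comparison("mutant", "wild-type", "infected",
                            threshold=config.mortality_overrides.get(
                                "mutant", config.mortality_threshold))
            .fit())
    surv.to_tsv(outdir / "survival_results.tsv")
    report.tables["survival"] = surv.results

    # --- expression / ChIP stage -------------------------------------
    interaction = sim.cis_effect_log2
    design = ExpressionDesign(target="Bin1-like", cells={
        ("TE-present", "non-infected"): 0.0,
        ("TE-absent", "non-infected"): 0.0,
        ("TE-present", "infected"): 1.0 + interaction,
        ("TE-absent", "infected"): 1.0,
    })
    ct = simulate_ct(design, sim)
    ct.to_csv(outdir / "ct_expression.tsv", sep="\t", index=False)
    expr = RelativeExpressionModel(ct).fit()
    expr.to_tsv(outdir / "expression_results.tsv")
    report.tables["expression"] = expr.cells

    chip_design = ChipDesign(cells={
        ("te_locus", flank, strain): (
            sim.chip_enrichment_log2 if strain == "TE-present" else 0.0)
        for flank in ("left", "right")
        for strain in ("TE-present", "TE-absent")
    })
    chip_ct = simulate_ct(chip_design, sim)
    chip_ct.to_csv(outdir / "ct_chip.tsv", sep="\t", index=False)
    chip = ChipEnrichmentModel(chip_ct).fit("TE-present", "TE-absent")
    chip.to_tsv(outdir / "chip_results.tsv")
    report.tables["chip"] = chip.results

    report.validate()
    (outdir / "report.json").write_text(report.to_json())
    (outdir / "report.txt").write_text(report.to_text())
    return report
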