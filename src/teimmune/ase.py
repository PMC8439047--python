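"""Allele-specific expression (ASE) from pyrosequencing allele counts.

In a fly heterozygous for a TE insertion, both alleles of the nearby gene
share one cellular environment, so a difference in allelic expression is
evidence of a cis-regulatory difference. Reads are assigned to alleles at
a diagnostic synonymous coding SNP; the cDNA allele ratio is normalised
by the gDNA allele ratio of the same cross to cancel PCR amplification
bias; the log2 normalised ratios of the biological replicates are tested
against 0 with a one-sample two-tailed t-test and corrected with the
Benjamini-Hochberg FDR.

The model-style entry point is :class:`ASEExperiment` whose
:meth:`~ASEExperiment.fit` returns an :class:`ASEResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CrossDesign", "HaplotypePanel", "select_diagnostic_snp",
    "normalized_allele_ratio", "ase_test", "fdr_adjust", "ase_summary",
    "ase_prevalence_test", "ASEExperiment", "ASEResults",
]


@dataclass(frozen=True)
class CrossDesign:
    """One ASE cross: TE-bearing x TE-free strain in one genetic background."""

    te: str
    gene: str
    background: str  # "I" or "II"
    strain_with_te: str = ""
    strain_without_te: str = ""
    diagnostic_snp: tuple | None = None  # (chrom, pos, te_allele, ref_allele)


class HaplotypePanel:
    """Strain haplotypes used to pick a diagnostic SNP and screen confounders.

    Parameters
    ----------
    te_presence
        Boolean Series indexed by strain: does the strain carry the TE?
    alleles
        DataFrame indexed by SNP id, one column per strain, values 0/1
        (allele codes) or -1 for a missing call.
    annotations
        DataFrame indexed by SNP id with boolean columns:
        ``coding`` (SNP in a coding region), ``in_cds_all_transcripts``,
        ``synonymous_all_transcripts``, ``nonsynonymous_any`` and
        ``conserved_flank`` (SNP in a conserved ±1 kb TE flank region).
    """

    REQUIRED = ("coding", "in_cds_all_transcripts",
                "synonymous_all_transcripts", "nonsynonymous_any",
                "conserved_flank")

    def __init__(self, te_presence: pd.Series, alleles: pd.DataFrame,
                 annotations: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in annotations.columns]
        if missing:
            raise ValueError(f"annotations missing columns: {missing}")
        if not alleles.index.equals(annotations.index):
            raise ValueError("alleles and annotations must share SNP index")
        unknown = set(alleles.columns) - set(te_presence.index)
        if unknown:
            raise ValueError(f"strains without TE call: {sorted(unknown)[:5]}")
        self.te_presence = te_presence.astype(bool)
        self.alleles = alleles
        self.annotations = annotations

    def perfectly_associated(self, snp: str) -> bool:
        """Is the SNP in perfect association with TE presence panel-wide?

        True when, over all strains with a non-missing call, the allele
        vector equals the TE-presence vector or its complement.
        """
        row = self.alleles.loc[snp]
        ok = row != -1
        if ok.sum() == 0:
            return False
        a = row[ok].astype(int).to_numpy()
        t = self.te_presence[row.index[ok]].astype(int).to_numpy()
        return bool(np.all(a == t) or np.all(a == 1 - t))


def select_diagnostic_snp(panel: HaplotypePanel, strain_a: str, strain_b: str,
                          ) -> tuple[str | None, str, pd.DataFrame]:
    """Pick a diagnostic SNP for a cross and report linked confounders.

    The diagnostic SNP must be (a) synonymous in every transcript, (b) in
    the coding region of every alternative transcript, and (c) carry
    different alleles in the two crossed strains. Among qualifying SNPs,
    those *not* in panel-wide perfect association with the TE are
    preferred (population-wide linkage would make the SNP itself a
    candidate causal variant); ties break by SNP id.

    The confounder report lists nonsynonymous coding SNPs and
    conserved-flank SNPs in perfect panel-wide association with TE
    presence — variants that could explain an allelic expression
    difference instead of the TE.

    Returns ``(snp_id or None, reason, confounder_table)``.
    """
    for s in (strain_a, strain_b):
        if s not in panel.alleles.columns:
            raise ValueError(f"strain {s!r} not in panel")
    ann = panel.annotations
    qual = []
    for snp in panel.alleles.index:
        a, b = panel.alleles.loc[snp, strain_a], panel.alleles.loc[snp, strain_b]
        if a == -1 or b == -1 or a == b:
            continue
        if not (ann.loc[snp, "synonymous_all_transcripts"]
                and ann.loc[snp, "in_cds_all_transcripts"]):
            continue
        qual.append(snp)

    conf_rows = []
    for snp in panel.alleles.index:
        if not panel.perfectly_associated(snp):
            continue
        if ann.loc[snp, "coding"] and ann.loc[snp, "nonsynonymous_any"]:
            conf_rows.append({"snp": snp, "kind": "nonsynonymous_coding"})
        elif ann.loc[snp, "conserved_flank"]:
            conf_rows.append({"snp": snp, "kind": "conserved_flank"})
    confounders = pd.DataFrame(conf_rows, columns=["snp", "kind"])

    if not qual:
        return None, "no synonymous coding SNP differs between the crossed strains", confounders
    unlinked = [s for s in qual if not panel.perfectly_associated(s)]
    chosen = sorted(unlinked or qual)[0]
    reason = "ok" if unlinked else \
        "only SNPs in panel-wide perfect association with the TE qualify"
    return chosen, reason, confounders


def normalized_allele_ratio(cdna_te: float, cdna_ref: float,
                            gdna_te: float, gdna_ref: float,
                            pseudocount: bool = False) -> float:
    """gDNA-normalised allelic expression ratio.

    ratio = (cdna_te / cdna_ref) / (gdna_te / gdna_ref). The gDNA of a
    heterozygote carries the two alleles 1:1, so its measured ratio is a
    direct estimate of the allele-amplification bias, which cancels here.
    Zero counts raise by default; ``pseudocount=True`` adds 0.5 to all
    four counts (Haldane).
    """
    counts = [cdna_te, cdna_ref, gdna_te, gdna_ref]
    if any(c < 0 for c in counts):
        raise ValueError("allele counts must be >= 0")
    if pseudocount:
        counts = [c + 0.5 for c in counts]
    elif any(c == 0 for c in counts):
        names = ["cdna_te", "cdna_ref", "gdna_te", "gdna_ref"]
        zeros = [n for n, c in zip(names, counts) if c == 0]
        raise ValueError(
            f"zero allele count in {zeros}; pass pseudocount=True to add 0.5")
    ct, cr, gt, gr = counts
    return (ct / cr) / (gt / gr)


def ase_test(ratios: Sequence[float]) -> dict:
    """One-sample two-tailed t-test of log2 normalised ratios against 0.

    Returns mean_log2, t, p, n and a ``degenerate`` flag. With zero
    replicate variance the t statistic is undefined; the test then
    reports p = 0 for a nonzero mean (infinitely concentrated evidence)
    and p = 1 for a zero mean, flagged as degenerate.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.ndim != 1 or ratios.size < 2:
        raise ValueError("need >= 2 replicate ratios")
    if np.any(ratios <= 0):
        raise ValueError("ratios must be > 0")
    logs = np.log2(ratios)
    mean = float(logs.mean())
    sd = float(logs.std(ddof=1))
    if sd == 0.0:
        return {"mean_log2": mean, "t": np.inf if mean != 0 else 0.0,
                "p": 0.0 if mean != 0 else 1.0, "n": int(logs.size),
                "degenerate": True}
    t, p = stats.ttest_1samp(logs, popmean=0.0)
    return {"mean_log2": mean, "t": float(t), "p": float(p),
            "n": int(logs.size), "degenerate": False}


def fdr_adjust(p_values: Sequence[float], q: float = 0.05,
               ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance flags.

    q-value_i = min over j >= rank(i) of p_(j) * m / j, capped at 1;
    significant iff q-value < ``q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, qvals < q


def ase_prevalence_test(k: int, n: int, reference_k: int, reference_n: int,
                        ) -> float:
    """Two-sided Fisher exact p comparing two ASE prevalences.

    Tests the 2x2 table [[k, n-k], [reference_k, reference_n-reference_k]]
    (genes with ASE vs without, this study vs a reference study).
    """
    for v in (k, n, reference_k, reference_n):
        if v < 0:
            raise ValueError("counts must be >= 0")
    if k > n or reference_k > reference_n:
        raise ValueError("successes cannot exceed totals")
    table = [[k, n - k], [reference_k, reference_n - reference_k]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _direction(mean_log2: float, significant: bool) -> str:
    if not significant or mean_log2 == 0:
        return "none"
    return "TE-higher" if mean_log2 > 0 else "TE-lower"


def ase_summary(results: pd.DataFrame) -> dict:
    """Summarise per-assay ASE results across backgrounds and conditions.

    ``results`` needs columns te, gene, background, condition, mean_log2,
    significant. Returns a dict with:

    * ``gene_condition`` — per gene x condition: significant-in->=1-
      background flag, per-background directions, concordance class in
      {same-direction, opposite-direction, single-background};
    * ``gene`` — per gene: significant in both conditions?
    * ``counts`` — genes with ASE per condition, genes significant in
      both conditions, TEs with ASE in >=1 condition.
    """
    rows = []
    for (gene, condition), sub in results.groupby(["gene", "condition"]):
        if sub["background"].nunique() > 2:
            raise ValueError(f"more than two backgrounds for {gene}")
        dirs = {bg: _direction(r["mean_log2"], r["significant"])
                for bg, r in sub.set_index("background").iterrows()}
        signs = np.sign(sub["mean_log2"].to_numpy())
        if len(sub) < 2:
            concordance = "single-background"
        elif signs[0] == signs[1] and signs[0] != 0:
            concordance = "same-direction"
        else:
            concordance = "opposite-direction"
        sig_any = bool(sub["significant"].any())
        # direction reported for the gene: that of the significant assays
        sig_means = sub.loc[sub["significant"], "mean_log2"]
        rows.append({
            "gene": gene, "condition": condition,
            "te": sub["te"].iloc[0],
            "significant_any_background": sig_any,
            "significant_both_backgrounds": bool(
                len(sub) == 2 and sub["significant"].all()),
            "directions": dirs,
            "direction": _direction(float(sig_means.mean()), True)
            if sig_any else "none",
            "concordance": concordance,
        })
    gc = pd.DataFrame(rows)

    gene_rows = []
    for gene, sub in gc.groupby("gene"):
        by_cond = sub.set_index("condition")["significant_any_background"]
        gene_rows.append({
            "gene": gene,
            "significant_both_conditions": all(
                bool(by_cond.get(cond, False))
                for cond in ("non-infected", "infected")),
        })
    per_gene = pd.DataFrame(gene_rows)

    counts = {
        "genes_with_ase_per_condition": {
            cond: int(sub["significant_any_background"].sum())
            for cond, sub in gc.groupby("condition")
        },
        "genes_both_conditions": int(
            per_gene["significant_both_conditions"].sum()),
        "tes_with_ase_any_condition": int(
            gc.loc[gc["significant_any_background"], "te"].nunique()),
        "genes_analyzed": int(gc["gene"].nunique()),
        "tes_analyzed": int(gc["te"].nunique()),
    }
    return {"gene_condition": gc, "gene": per_gene, "counts": counts}


class ASEExperiment:
    """Allele-specific expression experiment (model object).

    Built from a tidy measurement table with columns te, gene,
    background, condition, replicate, cdna_te, cdna_ref, gdna_te,
    gdna_ref (one row per cDNA replicate; the gDNA columns may repeat the
    shared cross-level measurement).
    """

    REQUIRED = ("te", "gene", "background", "condition", "replicate",
                "cdna_te", "cdna_ref", "gdna_te", "gdna_ref")

    def __init__(self, measurements: pd.DataFrame, pseudocount: bool = False):
        missing = [c for c in self.REQUIRED if c not in measurements.columns]
        if missing:
            raise ValueError(f"measurements missing columns: {missing}")
        self.measurements = measurements.reset_index(drop=True)
        self.pseudocount = pseudocount

    @classmethod
    def from_tsv(cls, path, **kw) -> "ASEExperiment":
        return cls(pd.read_csv(path, sep="\t"), **kw)

    def fit(self, fdr: float = 0.05,
            fdr_family: str = "condition") -> "ASEResults":
        """Compute per-assay normalised ratios, t-tests and BH correction.

        ``fdr_family`` controls the multiple-testing family: within each
        ``condition`` (default, matching how the two conditions are
        summarised separately) or ``all`` tests jointly.
        """
        if fdr_family not in ("condition", "all"):
            raise ValueError("fdr_family must be 'condition' or 'all'")
        rows = []
        keys = ["te", "gene", "background", "condition"]
        for key, sub in self.measurements.groupby(keys, sort=True):
            ratios = [
                normalized_allele_ratio(r.cdna_te, r.cdna_ref, r.gdna_te,
                                        r.gdna_ref, self.pseudocount)
                for r in sub.itertuples()
            ]
            res = ase_test(ratios)
            rows.append(dict(zip(keys, key)) | {
                "n_replicates": res["n"],
                "mean_ratio": float(np.mean(ratios)),
                "mean_log2": res["mean_log2"],
                "sem_log2": float(np.std(np.log2(ratios), ddof=1)
                                  / np.sqrt(len(ratios))),
                "t": res["t"], "p": res["p"],
                "degenerate": res["degenerate"],
            })
        table = pd.DataFrame(rows)
        table["q"] = np.nan
        table["significant"] = False
        if len(table):
            if fdr_family == "condition":
                for _, idx in table.groupby("condition").groups.items():
                    qv, sig = fdr_adjust(table.loc[idx, "p"], q=fdr)
                    table.loc[idx, "q"] = qv
                    table.loc[idx, "significant"] = sig
            else:
                qv, sig = fdr_adjust(table["p"], q=fdr)
                table["q"], table["significant"] = qv, sig
        table["direction"] = [
            _direction(m, s)
            for m, s in zip(table["mean_log2"], table["significant"])
        ]
        return ASEResults(self, table, fdr=fdr, fdr_family=fdr_family)


class ASEResults:
    """Fitted ASE results: per-assay statistics plus summaries."""

    def __init__(self, model: ASEExperiment, results: pd.DataFrame,
                 fdr: float, fdr_family: str):
        self.model = model
        self.results = results
        self.fdr = fdr
        self.fdr_family = fdr_family

    def gene_summary(self) -> dict:
        return ase_summary(self.results)

    def summary(self) -> str:
        s = self.gene_summary()
        lines = [
            "Allele-specific expression results",
            f"  assays: {len(self.results)}   FDR {self.fdr:g} "
            f"(family: per {self.fdr_family})",
        ]
        for cond, k in sorted(
                s["counts"]["genes_with_ase_per_condition"].items()):
            lines.append(f"  genes with ASE ({cond}): {k} / "
                         f"{s['counts']['genes_analyzed']}")
        lines.append(f"  genes with ASE in both conditions: "
                     f"{s['counts']['genes_both_conditions']}")
        lines.append(f"  TEs with ASE in >=1 condition: "
                     f"{s['counts']['tes_with_ase_any_condition']} / "
                     f"{s['counts']['tes_analyzed']}")
        cols = ["te", "gene", "background", "condition", "mean_ratio",
                "mean_log2", "p", "q", "direction"]
        with pd.option_context("display.width", 120):
            lines.append(self.results[cols].round(4).to_string(index=False))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.results.to_csv(path, sep="\t", index=False)

    def plot(self, ax=None):
        """Dot plot of mean ratios per gene/background, split by condition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        colors = {"non-infected": "tab:green", "infected": "tab:purple"}
        genes = sorted(self.results["gene"].unique())
        xpos = {g: i for i, g in enumerate(genes)}
        for _, r in self.results.iterrows():
            off = -0.15 if r["background"] == "I" else 0.15
            off += -0.05 if r["condition"] == "non-infected" else 0.05
            ax.errorbar(xpos[r["gene"]] + off, r["mean_ratio"],
                        yerr=2 ** r["sem_log2"] - 1,
                        fmt="o", color=colors.get(r["condition"], "k"),
                        alpha=1.0 if r["significant"] else 0.35)
        ax.axhline(1.0, color="grey", lw=0.8)
        ax.set_xticks(range(len(genes)), genes, rotation=90)
        ax.set_ylabel("TE / non-TE allele expression ratio")
        return ax
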