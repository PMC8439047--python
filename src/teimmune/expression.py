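"""qPCR relative expression (dCT) and ChIP-qPCR enrichment analysis.

Relative expression is 2^-(Ct_target - Ct_reference) against a
housekeeping gene; inferential tests run on log2 relative quantities
(variance stabilising for multiplicative qPCR noise). The factorial
analysis is a 2x2 genotype x treatment ANOVA with interaction. ChIP
enrichment normalises each immunoprecipitation against its own input
chromatin by the same dCT arithmetic, optionally scaled to
percent-of-input, with enriched/depleted control loci as QC.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

__all__ = [
    "dct_relative_expression", "expression_contrast", "factorial_analysis",
    "te_transcript_contribution", "chip_enrichment", "chip_strain_contrast",
    "RelativeExpressionModel", "ExpressionResults",
    "ChipEnrichmentModel", "ChipResults",
]


def dct_relative_expression(ct_target: float, ct_reference: float) -> float:
    """Relative quantity 2^-(ct_target - ct_reference)."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValueError("both Ct values must be finite")
    return float(2.0 ** -(ct_target - ct_reference))


def expression_contrast(rel_a, rel_b, kind: str | None = None,
                        equal_var: bool = False) -> dict:
    """Fold change and Welch t between two groups of relative expressions.

    fold_change = mean(rel_a) / mean(rel_b); the t-test runs on log2
    relative expression (Welch by default). ``kind`` may be "knockdown"
    (expected fold < 1) or "overexpression" (expected > 1); a
    ``direction_ok`` flag then reports whether the estimate agrees.
    """
    a = np.asarray(rel_a, dtype=float)
    b = np.asarray(rel_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per group")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("relative expressions must be > 0")
    fold = float(a.mean() / b.mean())
    t, p = stats.ttest_ind(np.log2(a), np.log2(b), equal_var=equal_var)
    out = {"fold_change": fold, "t": float(t), "p": float(p)}
    if kind is not None:
        if kind not in ("knockdown", "overexpression"):
            raise ValueError("kind must be 'knockdown' or 'overexpression'")
        out["direction_ok"] = fold < 1.0 if kind == "knockdown" else fold > 1.0
    return out


def factorial_analysis(df: pd.DataFrame, value: str = "rel_expression",
                       genotype: str = "group",
                       treatment: str = "treatment") -> dict:
    """2x2 genotype x treatment ANOVA with interaction on log2 quantities.

    Requires a complete 2x2 design with >= 2 replicates per cell. Returns
    genotype, treatment and interaction p-values (F tests). With zero
    residual variance the F statistics are undefined: p is reported as 1
    when the effect sum-of-squares is also ~0 and as 0 otherwise, with a
    ``degenerate`` flag.
    """
    for col in (value, genotype, treatment):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    g_levels = sorted(df[genotype].unique())
    t_levels = sorted(df[treatment].unique())
    if len(g_levels) != 2 or len(t_levels) != 2:
        raise ValueError("factorial analysis requires a 2x2 design")
    counts = df.groupby([genotype, treatment]).size()
    if len(counts) < 4 or (counts < 2).any():
        raise ValueError("every cell needs >= 2 replicates")
    if (df[value] <= 0).any():
        raise ValueError("relative quantities must be > 0")

    work = df[[genotype, treatment, value]].copy()
    work.columns = ["g", "t", "y"]
    work["y"] = np.log2(work["y"])
    model = smf.ols("y ~ C(g, Sum) * C(t, Sum)", data=work).fit()
    tbl = sm.stats.anova_lm(model, typ=2)

    resid_ss = float(tbl.loc["Residual", "sum_sq"])
    effects = {"genotype": "C(g, Sum)", "treatment": "C(t, Sum)",
               "interaction": "C(g, Sum):C(t, Sum)"}
    out: dict = {"degenerate": False}
    scale = max(float(np.abs(work["y"]).max()), 1.0)
    tol = 1e-12 * scale
    for name, key in effects.items():
        if resid_ss <= tol:
            out["degenerate"] = True
            out[f"{name}_p"] = 1.0 if tbl.loc[key, "sum_sq"] <= tol else 0.0
            out[f"{name}_F"] = np.nan
        else:
            out[f"{name}_p"] = float(tbl.loc[key, "PR(>F)"])
            out[f"{name}_F"] = float(tbl.loc[key, "F"])
    return out


def te_transcript_contribution(total_expression: float,
                               te_transcript_expression: float,
                               tolerance: float = 0.20) -> dict:
    """Percent of total gene expression contributed by TE-initiated transcripts.

    100 * te / total. Both quantities must be positive; because the two
    are measured in separate qPCR assays, the TE-transcript quantity may
    overshoot the total by measurement noise — overshoot within
    ``tolerance`` (relative) is capped at 100% with a flag, larger
    overshoot raises.
    """
    if total_expression <= 0:
        raise ValueError("total expression must be > 0")
    if te_transcript_expression < 0:
        raise ValueError("TE-transcript expression must be >= 0")
    pct = 100.0 * te_transcript_expression / total_expression
    if pct > 100.0 * (1.0 + tolerance):
        raise ValueError(
            f"TE-transcript expression exceeds total by more than "
            f"{tolerance:.0%} ({pct:.1f}%)")
    if pct > 100.0:
        return {"percent": 100.0, "capped": True}
    return {"percent": float(pct), "capped": False}


def chip_enrichment(ct_ip: float, ct_input: float,
                    input_fraction: float = 1.0) -> float:
    """Input-normalised ChIP enrichment.

    The input Ct is first adjusted to the full chromatin amount
    (ct_input + log2(input_fraction), since the input aliquot held only
    that fraction of the material), then
    enrichment = 2^-(ct_ip - adjusted_input). With ``input_fraction=1``
    this is plain dCT against the input; with the true aliquot fraction
    it is the percent-of-input form (x100 for a percentage).
    """
    if not 0.0 < input_fraction <= 1.0:
        raise ValueError("input_fraction must be in (0, 1]")
    if not (np.isfinite(ct_ip) and np.isfinite(ct_input)):
        raise ValueError("paired IP and input Cts required")
    adjusted_input = ct_input + np.log2(input_fraction)
    return float(2.0 ** -(ct_ip - adjusted_input))


def chip_strain_contrast(enrich_with, enrich_without,
                         equal_var: bool = False) -> dict:
    """Welch t on log2 enrichment: strain with TE vs strain without."""
    res = expression_contrast(enrich_with, enrich_without,
                              equal_var=equal_var)
    return {"log2_contrast": float(np.log2(res["fold_change"])),
            "t": res["t"], "p": res["p"]}


class RelativeExpressionModel:
    """qPCR expression model built from a tidy Ct table.

    Columns: sample, group, treatment, target, replicate, ct_target,
    ct_reference. ``fit`` computes per-cell relative expression and, when
    the design is a complete 2x2, the factorial decomposition; pairwise
    contrasts are available on the results object.
    """

    REQUIRED = ("group", "treatment", "target", "replicate",
                "ct_target", "ct_reference")

    def __init__(self, measurements: pd.DataFrame,
                 ct_bounds: tuple[float, float] = (5.0, 40.0)):
        missing = [c for c in self.REQUIRED if c not in measurements.columns]
        if missing:
            raise ValueError(f"measurements missing columns: {missing}")
        df = measurements.reset_index(drop=True).copy()
        if df[["ct_target", "ct_reference"]].isna().any().any():
            raise ValueError("missing Ct values")
        lo, hi = ct_bounds
        oob = ((df[["ct_target", "ct_reference"]] < lo)
               | (df[["ct_target", "ct_reference"]] > hi)).any(axis=1)
        if oob.any():
            logger.warning("%d Ct observations outside QC bounds (%g, %g)",
                           int(oob.sum()), lo, hi)
        df["rel_expression"] = 2.0 ** -(df["ct_target"] - df["ct_reference"])
        self.measurements = df

    @classmethod
    def from_tsv(cls, path, **kw) -> "RelativeExpressionModel":
        return cls(pd.read_csv(path, sep="\t"), **kw)

    def fit(self) -> "ExpressionResults":
        cells = (self.measurements
                 .groupby(["target", "group", "treatment"])["rel_expression"]
                 .agg(mean_rel="mean",
                      sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)),
                      n="size")
                 .reset_index())
        factorial = {}
        for target, sub in self.measurements.groupby("target"):
            try:
                factorial[target] = factorial_analysis(sub)
            except ValueError:
                pass  # not a complete 2x2 design for this target
        return ExpressionResults(self, cells, factorial)


class ExpressionResults:
    """Per-cell relative expression, factorial tests and contrasts."""

    def __init__(self, model: RelativeExpressionModel, cells: pd.DataFrame,
                 factorial: dict):
        self.model = model
        self.cells = cells
        self.factorial = factorial

    def contrast(self, group_a: str, group_b: str, target: str,
                 treatment: str | None = None,
                 kind: str | None = None) -> dict:
        df = self.model.measurements
        df = df[df["target"] == target]
        if treatment is not None:
            df = df[df["treatment"] == treatment]
        a = df.loc[df["group"] == group_a, "rel_expression"]
        b = df.loc[df["group"] == group_b, "rel_expression"]
        return expression_contrast(a, b, kind=kind)

    def summary(self) -> str:
        lines = ["Relative expression (2^-dCT, reference-normalised)"]
        with pd.option_context("display.width", 120):
            lines.append(self.cells.round(4).to_string(index=False))
        for target, fa in self.factorial.items():
            lines.append(
                f"  {target}: two-way ANOVA genotype p = "
                f"{fa['genotype_p']:.4g}, treatment p = "
                f"{fa['treatment_p']:.4g}, interaction p = "
                f"{fa['interaction_p']:.4g}"
                + ("  [degenerate]" if fa["degenerate"] else ""))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.cells.to_csv(path, sep="\t", index=False)


class ChipEnrichmentModel:
    """ChIP-qPCR model from paired IP/input Ct observations.

    Columns: locus, flank, strain, replicate, ct_ip, ct_input. The fit
    contrasts each (locus, flank) between a strain with the TE insertion
    and a strain without it, and checks the immunoprecipitation controls
    (an 18S-like locus expected enriched above an Rpl32-like locus).
    """

    REQUIRED = ("locus", "flank", "strain", "replicate", "ct_ip", "ct_input")

    def __init__(self, measurements: pd.DataFrame,
                 input_fraction: float = 1.0):
        missing = [c for c in self.REQUIRED if c not in measurements.columns]
        if missing:
            raise ValueError(f"measurements missing columns: {missing}")
        df = measurements.reset_index(drop=True).copy()
        if df[["ct_ip", "ct_input"]].isna().any().any():
            raise ValueError("unpaired measurement: missing IP or input Ct")
        df["enrichment"] = [
            chip_enrichment(ip, inp, input_fraction)
            for ip, inp in zip(df["ct_ip"], df["ct_input"])
        ]
        self.measurements = df
        self.input_fraction = input_fraction

    @classmethod
    def from_tsv(cls, path, **kw) -> "ChipEnrichmentModel":
        return cls(pd.read_csv(path, sep="\t"), **kw)

    def qc(self, strain: str | None = None,
           control_enriched: str = "18S",
           control_depleted: str = "Rpl32") -> dict:
        """Control-locus check: mean 18S-like enrichment above Rpl32-like."""
        df = self.measurements
        if strain is not None:
            df = df[df["strain"] == strain]
        hi = df.loc[df["locus"] == control_enriched, "enrichment"]
        lo = df.loc[df["locus"] == control_depleted, "enrichment"]
        if hi.empty or lo.empty:
            return {"available": False, "passed": None}
        passed = bool(hi.mean() > lo.mean())
        if not passed:
            logger.warning(
                "ChIP QC FAILURE: control locus %s not enriched above %s",
                control_enriched, control_depleted)
        return {"available": True, "passed": passed,
                "enriched_mean": float(hi.mean()),
                "depleted_mean": float(lo.mean())}

    def fit(self, strain_with: str, strain_without: str) -> "ChipResults":
        qc = self.qc()
        rows = []
        df = self.measurements
        test_loci = df[~df["locus"].isin(["18S", "Rpl32"])]
        for (locus, flank), sub in test_loci.groupby(["locus", "flank"]):
            w = sub.loc[sub["strain"] == strain_with, "enrichment"]
            wo = sub.loc[sub["strain"] == strain_without, "enrichment"]
            if len(w) < 2 or len(wo) < 2:
                continue
            contrast = chip_strain_contrast(w, wo)
            rows.append({
                "locus": locus, "flank": flank,
                "enrichment_with": float(w.mean()),
                "enrichment_without": float(wo.mean()),
                **contrast,
            })
        return ChipResults(self, pd.DataFrame(rows), qc,
                           strain_with=strain_with,
                           strain_without=strain_without)


class ChipResults:
    """Per-flank enrichment contrasts and control QC."""

    def __init__(self, model: ChipEnrichmentModel, results: pd.DataFrame,
                 qc: dict, strain_with: str, strain_without: str):
        self.model = model
        self.results = results
        self.qc = qc
        self.strain_with = strain_with
        self.strain_without = strain_without

    def summary(self) -> str:
        lines = [
            f"ChIP-qPCR enrichment: {self.strain_with} (TE+) vs "
            f"{self.strain_without} (TE-)",
            f"  control QC passed: {self.qc.get('passed')}",
        ]
        with pd.option_context("display.width", 120):
            lines.append(self.results.round(4).to_string(index=False))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.results.to_csv(path, sep="\t", index=False)
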