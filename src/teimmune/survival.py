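"""Infection-survival analysis: Kaplan-Meier, log-rank, and the
odds-ratio-at-mortality-threshold effect size.

Survival assays compare a genotype of interest against a control after
oral bacterial infection. Curves are compared with the two-group
log-rank test; when the difference is significant, the effect size is
the odds ratio of death from the 2x2 dead/alive table taken at the first
monitoring time at which the more susceptible group reaches a stated
cumulative mortality (50% by default, with per-comparison overrides),
with a Woolf (log) 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "km_estimate", "logrank_test", "odds_ratio_at_mortality",
    "InfectionSurvivalModel", "SurvivalResults",
]

_REQ = ("fly", "vial", "group", "treatment", "time", "event")


def _check_records(records: pd.DataFrame) -> None:
    missing = [c for c in _REQ if c not in records.columns]
    if missing:
        raise ValueError(f"survival records missing columns: {missing}")
    if len(records) and (records["time"] <= 0).any():
        raise ValueError("times must be > 0")


def km_estimate(records: pd.DataFrame, group: str) -> pd.DataFrame:
    """Product-limit survival curve for one group.

    Returns a DataFrame with time, survival, at_risk and deaths; censored
    records reduce the risk set without a survival drop.
    """
    _check_records(records)
    sub = records[records["group"] == group]
    if sub.empty:
        raise ValueError(f"no records for group {group!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], event_observed=sub["event"])
    tbl = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame({
        "time": tbl.index.to_numpy(dtype=float),
        "survival": surv.reindex(tbl.index).to_numpy(),
        "at_risk": tbl["at_risk"].to_numpy(dtype=int),
        "deaths": tbl["observed"].to_numpy(dtype=int),
    })
    return out[out["time"] > 0].reset_index(drop=True)


def logrank_test(records: pd.DataFrame, group_a: str, group_b: str) -> dict:
    """Two-group log-rank test (observed-minus-expected formulation).

    Returns chi2, p, and a ``no_events`` flag; with no deaths in either
    group the curves are indistinguishable and p is reported as 1.
    """
    _check_records(records)
    a = records[records["group"] == group_a]
    b = records[records["group"] == group_b]
    if a.empty or b.empty:
        raise ValueError("both groups must be non-empty")
    if a["event"].sum() == 0 and b["event"].sum() == 0:
        return {"chi2": 0.0, "p": 1.0, "no_events": True}
    res = _ll_logrank(a["time"], b["time"],
                      event_observed_A=a["event"],
                      event_observed_B=b["event"])
    return {"chi2": float(res.test_statistic), "p": float(res.p_value),
            "no_events": False}


def _mortality_table(sub: pd.DataFrame, t_star: float) -> tuple[int, int]:
    """(dead, alive) at t*; flies censored strictly before t* are excluded."""
    dead = int(((sub["event"] == 1) & (sub["time"] <= t_star)).sum())
    lost = int(((sub["event"] == 0) & (sub["time"] < t_star)).sum())
    alive = len(sub) - dead - lost
    return dead, alive


def odds_ratio_at_mortality(records: pd.DataFrame, group_a: str,
                            group_b: str, threshold: float = 0.50,
                            susceptible: str | None = None) -> dict:
    """Odds ratio of death at the susceptible group's mortality threshold.

    The susceptible group defaults to the one with lower Kaplan-Meier
    survival at the last time common to both groups (override with
    ``susceptible``). t* is the earliest observed time at which that
    group's cumulative mortality (1 - KM) reaches ``threshold``. The 2x2
    (dead, alive) x (group_a, group_b) table at t* gives
    OR = (a*d)/(b*c), oriented as odds of death in ``group_a`` over
    ``group_b``, with the Woolf interval
    exp(ln OR +/- 1.96*sqrt(1/a+1/b+1/c+1/d)); any zero cell receives the
    Haldane +0.5 correction (flagged).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    _check_records(records)
    curves = {g: km_estimate(records, g) for g in (group_a, group_b)}
    if susceptible is None:
        t_common = min(c["time"].max() for c in curves.values())
        last_surv = {}
        for g, c in curves.items():
            upto = c.loc[c["time"] <= t_common, "survival"]
            last_surv[g] = float(upto.iloc[-1]) if len(upto) else 1.0
        susceptible = min(last_surv, key=last_surv.get)
    elif susceptible not in (group_a, group_b):
        raise ValueError("susceptible must be one of the two groups")

    sus = curves[susceptible]
    mortality = 1.0 - sus["survival"]
    hit = sus["time"][mortality >= threshold - 1e-12]
    if hit.empty:
        raise ValueError(
            f"susceptible group {susceptible!r} never reaches mortality "
            f"{threshold:.0%}; max reached {mortality.max():.1%}")
    t_star = float(hit.iloc[0])

    a_dead, a_alive = _mortality_table(records[records["group"] == group_a],
                                       t_star)
    b_dead, b_alive = _mortality_table(records[records["group"] == group_b],
                                       t_star)
    cells = np.array([a_dead, a_alive, b_dead, b_alive], dtype=float)
    haldane = bool((cells == 0).any())
    if haldane:
        cells = cells + 0.5
    a, b, c, d = cells
    odds_ratio = (a * d) / (b * c)
    se = np.sqrt((1.0 / cells).sum())
    lo, hi = np.exp(np.log(odds_ratio) + np.array([-1.96, 1.96]) * se)
    return {
        "threshold": threshold, "threshold_time": t_star,
        "susceptible_group": susceptible,
        "table": {"dead": [a_dead, b_dead], "alive": [a_alive, b_alive]},
        "odds_ratio": float(odds_ratio),
        "ci95": (float(lo), float(hi)),
        "haldane_corrected": haldane,
    }


@dataclass
class _Comparison:
    group_a: str
    group_b: str
    treatment: str | None = None
    threshold: float = 0.50
    susceptible: str | None = None


class InfectionSurvivalModel:
    """Survival-assay model built from per-fly time-to-event records.

    ``records`` is a tidy table with columns fly, vial, group, treatment,
    time (hours) and event (1 = death, 0 = censored). Comparisons are
    declared with :meth:`add_comparison` and evaluated by :meth:`fit`.
    The log-rank test treats flies as independent; an optional
    vial-permutation p-value is available as a clustering robustness
    check.
    """

    def __init__(self, records: pd.DataFrame):
        _check_records(records)
        self.records = records.reset_index(drop=True)
        self.comparisons: list[_Comparison] = []

    @classmethod
    def from_tsv(cls, path) -> "InfectionSurvivalModel":
        return cls(pd.read_csv(path, sep="\t"))

    def add_comparison(self, group_a: str, group_b: str,
                       treatment: str | None = "infected",
                       threshold: float = 0.50,
                       susceptible: str | None = None) -> "InfectionSurvivalModel":
        self.comparisons.append(
            _Comparison(group_a, group_b, treatment, threshold, susceptible))
        return self

    def km(self, group: str, treatment: str | None = None) -> pd.DataFrame:
        rec = self.records
        if treatment is not None:
            rec = rec[rec["treatment"] == treatment]
        return km_estimate(rec, group)

    def fit(self, alpha: float = 0.05,
            permute_vials: int = 0, seed: int = 0) -> "SurvivalResults":
        """Run every declared comparison.

        The odds ratio is only computed when the log-rank test is
        significant at ``alpha`` (the effect size accompanies a detected
        difference). ``permute_vials`` > 0 adds a vial-label permutation
        p-value with that many permutations.
        """
        if not self.comparisons:
            raise ValueError("no comparisons declared; call add_comparison")
        rows = []
        for cmp_ in self.comparisons:
            rec = self.records
            if cmp_.treatment is not None:
                rec = rec[rec["treatment"] == cmp_.treatment]
            lr = logrank_test(rec, cmp_.group_a, cmp_.group_b)
            row = {
                "group_a": cmp_.group_a, "group_b": cmp_.group_b,
                "treatment": cmp_.treatment, "chi2": lr["chi2"],
                "logrank_p": lr["p"], "no_events": lr["no_events"],
                "or_threshold": cmp_.threshold,
            }
            if lr["p"] < alpha:
                orr = odds_ratio_at_mortality(
                    rec, cmp_.group_a, cmp_.group_b,
                    threshold=cmp_.threshold, susceptible=cmp_.susceptible)
                row.update({
                    "threshold_time": orr["threshold_time"],
                    "odds_ratio": orr["odds_ratio"],
                    "ci_low": orr["ci95"][0], "ci_high": orr["ci95"][1],
                    "susceptible_group": orr["susceptible_group"],
                    "haldane_corrected": orr["haldane_corrected"],
                })
            if permute_vials:
                row["vial_permutation_p"] = self._vial_permutation_p(
                    rec, cmp_.group_a, cmp_.group_b, permute_vials, seed)
            rows.append(row)
        return SurvivalResults(self, pd.DataFrame(rows), alpha=alpha)

    @staticmethod
    def _vial_permutation_p(records: pd.DataFrame, group_a: str,
                            group_b: str, n_perm: int, seed: int) -> float:
        """Permute whole vials between the groups to respect clustering."""
        rec = records[records["group"].isin([group_a, group_b])]
        obs = logrank_test(rec, group_a, group_b)["chi2"]
        vials = rec[["vial", "group"]].drop_duplicates()
        labels = vials["group"].to_numpy().copy()
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            rng.shuffle(labels)
            perm_map = dict(zip(vials["vial"], labels))
            perm = rec.assign(group=rec["vial"].map(perm_map))
            if perm["group"].nunique() < 2:
                chi2 = 0.0
            else:
                chi2 = logrank_test(perm, group_a, group_b)["chi2"]
            hits += chi2 >= obs
        return (hits + 1) / (n_perm + 1)


class SurvivalResults:
    """Fitted survival comparisons: log-rank and OR effect sizes."""

    def __init__(self, model: InfectionSurvivalModel, results: pd.DataFrame,
                 alpha: float):
        self.model = model
        self.results = results
        self.alpha = alpha

    def summary(self) -> str:
        lines = [f"Infection survival comparisons (alpha = {self.alpha:g})"]
        for _, r in self.results.iterrows():
            line = (f"  {r['group_a']} vs {r['group_b']}"
                    f" [{r['treatment']}]: log-rank chi2 = {r['chi2']:.3f},"
                    f" p = {r['logrank_p']:.4g}")
            if "odds_ratio" in r and pd.notna(r.get("odds_ratio", np.nan)):
                line += (f"; OR = {r['odds_ratio']:.2f} "
                         f"(95% CI {r['ci_low']:.2f}-{r['ci_high']:.2f}) at "
                         f"{r['or_threshold']:.0%} mortality of "
                         f"{r['susceptible_group']} (t* = "
                         f"{r['threshold_time']:g} h)")
            lines.append(line)
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.results.to_csv(path, sep="\t", index=False)

    def plot(self, treatment: str = "infected", ax=None):
        """Kaplan-Meier curves for every group under one treatment."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        rec = self.model.records
        rec = rec[rec["treatment"] == treatment]
        for group in sorted(rec["group"].unique()):
            curve = km_estimate(rec, group)
            ax.step(np.r_[0, curve["time"]], np.r_[1.0, curve["survival"]],
                    where="post", label=group)
        ax.set_xlabel("hours post exposure")
        ax.set_ylabel("survival")
        ax.set_ylim(0, 1.02)
        ax.legend(fontsize=8)
        return ax
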