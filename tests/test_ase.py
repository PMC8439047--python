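"""Allele-specific expression: ratio arithmetic, t-test, BH, SNP selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from teimmune import (ASEExperiment, HaplotypePanel, ase_prevalence_test,
                      ase_summary, ase_test, fdr_adjust,
                      normalized_allele_ratio, select_diagnostic_snp)


class TestNormalizedRatio:
    @pytest.mark.parametrize("cdna,gdna,expected", [
        ((60, 40), (50, 50), 1.5),
        ((60, 40), (60, 40), 1.0),   # shared bias cancels
        ((30, 10), (40, 20), 1.5),
    ])
    def test_forced_by_formula(self, cdna, gdna, expected):
        assert normalized_allele_ratio(*cdna, *gdna) == pytest.approx(expected)

    def test_zero_count_raises_naming_the_count(self):
        with pytest.raises(ValueError, match="gdna_te"):
            normalized_allele_ratio(10, 10, 0, 10)

    def test_pseudocount_option(self):
        assert normalized_allele_ratio(10, 10, 0, 10, pseudocount=True) == \
            pytest.approx((10.5 / 10.5) / (0.5 / 10.5))


class TestAseTest:
    def test_constant_unit_ratios(self):
        res = ase_test([1.0, 1.0, 1.0])
        assert res["mean_log2"] == 0.0
        assert res["p"] == 1.0
        assert res["degenerate"]

    def test_matches_textbook_t(self):
        ratios = [1.8, 2.1, 2.4]
        logs = np.log2(ratios)
        m, s, n = logs.mean(), logs.std(ddof=1), len(logs)
        t_hand = m / (s / np.sqrt(n))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=n - 1)
        res = ase_test(ratios)
        assert res["t"] == pytest.approx(t_hand)
        assert res["p"] == pytest.approx(p_hand)
        assert res["mean_log2"] == pytest.approx(m)

    def test_degenerate_nonzero_mean(self):
        res = ase_test([2.0, 2.0, 2.0])
        assert res["p"] == 0.0 and res["degenerate"]

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            ase_test([1.5])


def bh_bruteforce(p):
    """Step-up definition: q_i = min_{j >= rank(i)} p_(j) * m / j, capped."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for k in range(m - 1, -1, -1):
        running = min(running, p[order[k]] * m / (k + 1))
        q[order[k]] = running
    return q


class TestFdrAdjust:
    def test_single_p(self):
        q, sig = fdr_adjust([0.05])
        assert q[0] == pytest.approx(0.05)
        assert not sig[0]  # significance requires q < 0.05 strictly

    def test_hand_example(self):
        q, _ = fdr_adjust([0.005, 0.1])
        assert q == pytest.approx([0.01, 0.1])

    def test_matches_bruteforce_on_grid(self):
        grid = [0.004, 0.04, 0.2, 0.9]
        for n in range(1, 5):
            for p in itertools.product(grid, repeat=n):
                q, sig = fdr_adjust(list(p))
                expected = bh_bruteforce(p)
                assert q == pytest.approx(expected)
                assert (sig == (expected < 0.05)).all()

    def test_matches_bruteforce_random_long_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.random(int(rng.integers(5, 9)))
            q, _ = fdr_adjust(p)
            assert q == pytest.approx(bh_bruteforce(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestPrevalenceTest:
    def test_identical_proportions(self):
        assert ase_prevalence_test(5, 10, 5, 10) == pytest.approx(1.0)

    def test_small_table_exact_value(self):
        # [[3,0],[0,3]]: enumerate tables with margins (3,3)x(3,3):
        # P(a)=C(3,a)C(3,3-a)/C(6,3); extremes a=0,3 each 1/20 -> p=0.1
        assert ase_prevalence_test(3, 3, 0, 3) == pytest.approx(0.1)

    def test_zero_margin(self):
        assert ase_prevalence_test(0, 5, 0, 8) == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        # brute-force two-sided Fisher on random 2x2 tables
        rng = np.random.default_rng(1)
        from math import comb
        for _ in range(30):
            n, rn = int(rng.integers(1, 12)), int(rng.integers(1, 12))
            k, rk = int(rng.integers(0, n + 1)), int(rng.integers(0, rn + 1))
            tot, succ = n + rn, k + rk

            def prob(a):
                return comb(n, a) * comb(rn, succ - a) / comb(tot, succ)
            amin, amax = max(0, succ - rn), min(n, succ)
            p_obs = prob(k)
            p_two = sum(prob(a) for a in range(amin, amax + 1)
                        if prob(a) <= p_obs * (1 + 1e-9))
            assert ase_prevalence_test(k, n, rk, rn) == pytest.approx(p_two)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ase_prevalence_test(-1, 5, 1, 5)


def make_panel(te_presence, alleles, ann_rows):
    te = pd.Series(te_presence)
    al = pd.DataFrame(alleles)  # columns = strains, rows = SNPs
    al.index = list(ann_rows)
    ann = pd.DataFrame.from_dict(
        ann_rows, orient="index",
        columns=list(HaplotypePanel.REQUIRED)).astype(bool)
    return HaplotypePanel(te, al, ann)


class TestDiagnosticSnp:
    # annotation tuple order: coding, in_cds_all, syn_all, nonsyn_any, cons_flank
    def test_clean_panel_returns_snp(self):
        panel = make_panel(
            {"s1": True, "s2": False, "s3": True, "s4": False},
            {"s1": [1, 0], "s2": [0, 0], "s3": [0, 0], "s4": [1, 0]},
            {"snp1": (1, 1, 1, 0, 0), "snp2": (1, 1, 1, 0, 0)})
        snp, reason, conf = select_diagnostic_snp(panel, "s1", "s2")
        assert snp == "snp1" and reason == "ok"
        assert conf.empty

    def test_linked_nonsynonymous_confounders_reported(self):
        # two nonsynonymous coding SNPs in perfect association with the TE
        panel = make_panel(
            {"s1": True, "s2": False, "s3": True, "s4": False},
            {"s1": [1, 1, 1], "s2": [0, 0, 0], "s3": [0, 1, 1],
             "s4": [1, 0, 0]},
            {"syn": (1, 1, 1, 0, 0),
             "ns1": (1, 1, 0, 1, 0), "ns2": (1, 1, 0, 1, 0)})
        snp, _, conf = select_diagnostic_snp(panel, "s1", "s2")
        assert snp == "syn"
        assert set(conf["snp"]) == {"ns1", "ns2"}
        assert (conf["kind"] == "nonsynonymous_coding").all()

    def test_no_qualifying_snp(self):
        panel = make_panel(
            {"s1": True, "s2": False},
            {"s1": [1], "s2": [1]},  # same allele in both strains
            {"snp1": (1, 1, 1, 0, 0)})
        snp, reason, _ = select_diagnostic_snp(panel, "s1", "s2")
        assert snp is None
        assert "no synonymous" in reason

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            strains = [f"s{i}" for i in range(6)]
            te = {s: bool(rng.random() < 0.5) for s in strains}
            n_snp = int(rng.integers(1, 8))
            alleles = {s: rng.integers(0, 2, n_snp).tolist() for s in strains}
            ann = {f"snp{j}": tuple(rng.integers(0, 2, 5)) for j in range(n_snp)}
            panel = make_panel(te, alleles, ann)
            got_snp, _, got_conf = select_diagnostic_snp(panel, "s0", "s1")

            # brute force over all SNPs
            al = panel.alleles
            tevec = panel.te_presence

            def perfect(s):
                a = al.loc[s].astype(int)
                t = tevec[al.columns].astype(int)
                return (a == t).all() or (a == 1 - t).all()
            qual = sorted(
                s for s in al.index
                if al.loc[s, "s0"] != al.loc[s, "s1"]
                and panel.annotations.loc[s, "synonymous_all_transcripts"]
                and panel.annotations.loc[s, "in_cds_all_transcripts"])
            unlinked = [s for s in qual if not perfect(s)]
            expect = (unlinked or qual or [None])[0]
            assert got_snp == expect
            expect_conf = {
                s for s in al.index if perfect(s)
                and ((panel.annotations.loc[s, "coding"]
                      and panel.annotations.loc[s, "nonsynonymous_any"])
                     or panel.annotations.loc[s, "conserved_flank"])}
            assert set(got_conf["snp"]) == expect_conf


def _measurements(assays):
    """assays: list of (te, gene, bg, condition, ratios) with gdna 50:50."""
    rows = []
    for te, gene, bg, cond, ratios in assays:
        for i, r in enumerate(ratios, 1):
            rows.append({"te": te, "gene": gene, "background": bg,
                         "condition": cond, "replicate": i,
                         "cdna_te": int(1000 * r), "cdna_ref": 1000,
                         "gdna_te": 500, "gdna_ref": 500})
    return pd.DataFrame(rows)


class TestExperimentAndSummary:
    def test_fit_recovers_ratios_and_flags(self):
        df = _measurements([
            ("te1", "g1", "I", "non-infected", [1.9, 2.0, 2.1]),
            ("te1", "g1", "II", "non-infected", [0.99, 1.0, 1.01]),
        ])
        res = ASEExperiment(df).fit()
        r = res.results.set_index("background")
        assert r.loc["I", "mean_ratio"] == pytest.approx(2.0, rel=1e-6)
        assert bool(r.loc["I", "significant"])
        assert r.loc["I", "direction"] == "TE-higher"
        assert r.loc["II", "direction"] == "none"

    def test_summary_classification(self):
        results = pd.DataFrame({
            "te": ["t1"] * 4 + ["t2"] * 2,
            "gene": ["g1"] * 4 + ["g2"] * 2,
            "background": ["I", "II"] * 3,
            "condition": (["non-infected"] * 2 + ["infected"] * 2
                          + ["non-infected"] * 2),
            "mean_log2": [0.8, -0.2, 0.9, 0.7, -1.0, -1.1],
            "significant": [True, False, True, True, False, False],
        })
        s = ase_summary(results)
        gc = s["gene_condition"].set_index(["gene", "condition"])
        assert gc.loc[("g1", "non-infected"), "concordance"] == "opposite-direction"
        assert gc.loc[("g1", "infected"), "concordance"] == "same-direction"
        assert bool(gc.loc[("g1", "infected"), "significant_both_backgrounds"])
        assert s["counts"]["genes_both_conditions"] == 1
        assert s["counts"]["tes_with_ase_any_condition"] == 1
        assert s["counts"]["genes_with_ase_per_condition"] == {
            "non-infected": 1, "infected": 1}

    def test_summary_counts_permutation_invariant(self):
        df = _measurements([
            ("t1", "g1", "I", "infected", [1.8, 2.0, 2.2]),
            ("t1", "g1", "II", "infected", [1.1, 1.0, 0.9]),
            ("t2", "g2", "I", "infected", [0.5, 0.55, 0.45]),
            ("t2", "g2", "I", "non-infected", [0.9, 1.1, 1.0]),
        ])
        a = ASEExperiment(df).fit().gene_summary()["counts"]
        b = ASEExperiment(
            df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        ).fit().gene_summary()["counts"]
        assert a == b

    def test_fdr_family_choice(self):
        df = _measurements([
            ("t1", "g1", "I", "infected", [2.0, 2.05, 1.95]),
            ("t2", "g2", "I", "non-infected", [1.0, 1.01, 0.99]),
        ])
        per_cond = ASEExperiment(df).fit(fdr_family="condition").results
        joint = ASEExperiment(df).fit(fdr_family="all").results
        # per-condition: the strong test stands alone (q = p); jointly the
        # family has two members
        p1 = per_cond.loc[per_cond["te"] == "t1"].iloc[0]
        j1 = joint.loc[joint["te"] == "t1"].iloc[0]
        assert p1["q"] == pytest.approx(p1["p"])
        assert j1["q"] >= p1["q"]
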