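"""Screening cascade, frequency estimation and gene-proximity assignment."""

import numpy as np
import pandas as pd
import pytest

from teimmune import (GenotypeMatrix, PopulationFrequencyTable, TECatalog,
                      apply_exclusion_cascade, assign_genes,
                      intersect_immune, population_frequency,
                      screen_nonreference, select_candidates)

from conftest import make_catalog, make_gene, make_map


def full_cover_maps(rate=2.0):
    iv = [("2L", 1, 10_000_000, rate)]
    return make_map(iv, "map_A"), make_map(iv, "map_B")


class TestCascade:
    def test_empty_catalog(self):
        cat = make_catalog([])
        retained, report = apply_exclusion_cascade(cat, full_cover_maps())
        assert len(retained) == 0
        assert [s[1] for s in report.steps] == [0, 0, 0]

    def test_sequential_counts_conserve(self):
        rows = ([("2L", 100 * i, 100 * i + 10, True, False) for i in range(1, 4)]
                + [("2L", 10_000 + 100 * i, 10_000 + 100 * i + 10, False, True)
                   for i in range(2)]
                + [("2L", 50_000, 50_100, False, False)])
        cat = make_catalog(rows)
        retained, report = apply_exclusion_cascade(cat, full_cover_maps())
        assert report.to_frame()["excluded"].tolist() == [3, 2, 0]
        assert len(retained) == 1
        report.validate()

    def test_zero_recomb_either_vs_both(self):
        # midpoint 150: rate 0 only in map A
        cat = make_catalog([("2L", 100, 200, False, False)])
        map_a = make_map([("2L", 1, 1000, 0.0)], "map_A")
        map_b = make_map([("2L", 1, 1000, 2.0)], "map_B")
        kept_either, _ = apply_exclusion_cascade(cat, (map_a, map_b), "either")
        kept_both, _ = apply_exclusion_cascade(cat, (map_a, map_b), "both")
        assert len(kept_either) == 0
        assert len(kept_both) == 1

    def test_chromosome_missing_from_both_maps_is_hard_error(self):
        cat = make_catalog([("3R", 100, 200, False, False)])
        with pytest.raises(ValueError, match="3R"):
            apply_exclusion_cascade(cat, full_cover_maps())

    def test_uncovered_position_treated_as_zero_rate(self):
        cat = make_catalog([("2L", 100, 200, False, False)])
        maps = (make_map([("2L", 500, 1000, 2.0)], "map_A"),
                make_map([("2L", 500, 1000, 2.0)], "map_B"))
        retained, report = apply_exclusion_cascade(cat, maps)
        assert len(retained) == 0
        assert report.steps[2][1] == 1

    def test_matches_bruteforce_set_subtraction(self):
        # random 100-TE catalog with random flags vs explicit set algebra
        rng = np.random.default_rng(42)
        rows = []
        for _ in range(100):
            s = int(rng.integers(1, 900_000))
            rows.append(("2L", s, s + 50, bool(rng.random() < 0.3),
                         bool(rng.random() < 0.3)))
        cat = make_catalog(rows)
        # rate-0 stripe in map A only
        map_a = make_map([("2L", 1, 300_000, 0.0),
                          ("2L", 300_000, 1_000_000, 2.0)], "map_A")
        map_b = make_map([("2L", 1, 1_000_000, 1.5)], "map_B")
        retained, report = apply_exclusion_cascade(cat, (map_a, map_b))

        ids = set(cat.df["id"])
        ine1 = set(cat.df.loc[cat.df["is_ine1"], "id"])
        rep = set(cat.df.loc[cat.df["repeat_flanked_or_nested"], "id"])
        mid = (cat.df["start"] + cat.df["end"]) // 2
        zero = set(cat.df.loc[mid < 300_000, "id"])
        expected = ids - ine1 - rep - zero
        assert set(retained.df["id"]) == expected
        assert report.steps[0][1] == len(ine1)
        assert report.steps[1][1] == len(rep - ine1)
        assert report.steps[2][1] == len(zero - ine1 - rep)


class TestPopulationFrequency:
    def _matrix(self, calls, pops):
        df = pd.DataFrame(calls).T
        df.index.name = "te"
        df.columns = list(pops)
        return GenotypeMatrix(df, pops)

    def test_all_present(self):
        strains = {f"s{i}": "popA" for i in range(10)}
        gm = self._matrix({"te0": ["P"] * 10}, strains)
        freqs = population_frequency(gm)
        assert freqs.freq.loc["te0", "popA"] == 1.0

    def test_missing_excluded_from_denominator(self):
        strains = {f"s{i}": "popA" for i in range(10)}
        gm = self._matrix({"te0": ["P"] * 3 + ["A"] * 5 + ["-"] * 2}, strains)
        freqs = population_frequency(gm)
        assert freqs.freq.loc["te0", "popA"] == pytest.approx(0.375)
        assert freqs.n_called.loc["te0", "popA"] == 8

    def test_all_missing_is_undefined_not_zero(self):
        strains = {f"s{i}": "popA" for i in range(3)}
        gm = self._matrix({"te0": ["-"] * 3}, strains)
        freqs = population_frequency(gm)
        assert np.isnan(freqs.freq.loc["te0", "popA"])
        assert bool(freqs.undefined.loc["te0", "popA"])

    def test_estimates_within_binomial_error(self, small_config):
        # simulated matrix vs the truth sidecar at the called sample size
        from teimmune import simulate_genotypes, simulate_te_catalog
        catalog, _ = simulate_te_catalog(small_config)
        gm, truth = simulate_genotypes(catalog, small_config)
        freqs = population_frequency(gm)
        pops = list(small_config.populations)
        err = (freqs.freq[pops] - truth[pops]).abs()
        se = np.sqrt(truth[pops] * (1 - truth[pops])
                     / freqs.n_called[pops].clip(lower=1)).clip(lower=1e-9)
        # 4.5 sigma, Bonferroni-ish over 300 x 4 cells
        frac_bad = ((err > 4.5 * se) & freqs.freq[pops].notna()).to_numpy().mean()
        assert frac_bad < 0.005


class TestSelectCandidates:
    def _table(self, freq_rows):
        freq = pd.DataFrame(freq_rows).T
        freq.columns = ["p1", "p2", "p3", "p4"][:freq.shape[1]]
        n = freq.notna().astype(int) * 10
        return PopulationFrequencyTable(freq, n)

    def test_high_in_one_population_kept(self):
        tab = self._table({"te0": [0.05, 0.12, 0.0, 0.0]})
        assert select_candidates(tab, 0.10)["te"].tolist() == ["te0"]

    def test_fixed_everywhere_excluded(self):
        tab = self._table({"te0": [1.0, 1.0, 1.0, 1.0]})
        assert select_candidates(tab, 0.10).empty

    def test_fixed_only_where_defined_excluded(self):
        tab = self._table({"te0": [1.0, np.nan, 1.0, 1.0]})
        assert select_candidates(tab, 0.10).empty

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        freq = pd.DataFrame(rng.random((50, 4)),
                            index=[f"te{i}" for i in range(50)],
                            columns=list("abcd"))
        tab = PopulationFrequencyTable(freq, (freq * 0 + 10).astype(int))
        c10 = set(select_candidates(tab, 0.10)["te"])
        c15 = set(select_candidates(tab, 0.15)["te"])
        assert c15 <= c10

    def test_threshold_validation(self):
        tab = self._table({"te0": [0.5]})
        with pytest.raises(ValueError):
            select_candidates(tab, 0.0)
        with pytest.raises(ValueError):
            select_candidates(tab, 1.5)


class TestNonReference:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["te", "count", "verified"])

    @pytest.mark.parametrize("count,verified,kept", [
        (15, True, True),   # boundary: exactly the minimum panel count
        (14, True, False),  # one below
        (20, False, False),  # verification gate
    ])
    def test_prefilter_boundaries(self, count, verified, kept):
        out = screen_nonreference(self._df([("t", count, verified)]),
                                  threshold=0.01)
        assert (len(out) == 1) is kept
        if kept:
            assert out["frequency"].iloc[0] == pytest.approx(count / 177)

    def test_count_above_panel_rejected(self):
        with pytest.raises(ValueError):
            screen_nonreference(self._df([("t", 200, True)]))


class TestAssignGenes:
    def test_gene_within_window(self):
        g = make_gene("g1", "2L", 1601, 3000)
        out = assign_genes("2L", 100, 1100, [g], window_bp=1000)
        assert len(out) == 1
        assert out[0]["gap_bp"] == 500
        assert out[0]["relation"] == "5'"

    def test_nearest_gene_fallback(self):
        g = make_gene("kay_like", "2L", 10_000, 12_000, strand="-")
        out = assign_genes("2L", 3000, 5565, [g], window_bp=1000)
        assert len(out) == 1
        assert out[0]["gap_bp"] == 4434
        assert out[0]["relation"] == "3'"  # minus strand, TE beyond gene 3' end

    def test_equidistant_ties_all_kept(self):
        ga = make_gene("ga", "2L", 1, 1000)
        gb = make_gene("gb", "2L", 4001, 5000)
        out = assign_genes("2L", 2501, 2500 + 0, [ga, gb], window_bp=100)
        # TE at 2501..2501: gap to ga = 1500, to gb = 1499 -> not tied
        out = assign_genes("2L", 2500, 2501, [ga, gb], window_bp=100)
        assert {o["gene_id"] for o in out} == {"ga", "gb"}
        assert {o["gap_bp"] for o in out} == {1499}

    def test_overlap_relations(self):
        g = make_gene("g1", "2L", 1000, 9000, cds=[(3000, 7000)])
        assert assign_genes("2L", 3500, 3600, [g])[0]["relation"] == "exon"
        assert assign_genes("2L", 1100, 1200, [g])[0]["relation"] == "UTR"
        g2 = make_gene("g2", "2L", 1000, 9000, cds=[(1500, 2000), (7000, 8000)])
        assert assign_genes("2L", 3500, 3600, [g2])[0]["relation"] == "intron"

    def test_no_genes_on_chromosome(self):
        assert assign_genes("3R", 100, 200, [make_gene("g", "2L", 1, 10)]) == []

    def test_matches_bruteforce_nearest_scan(self):
        rng = np.random.default_rng(3)
        genes = [make_gene(f"g{i}", "2L", s := int(rng.integers(1, 100_000)),
                           s + int(rng.integers(100, 3000)))
                 for i in range(30)]
        for _ in range(50):
            ts = int(rng.integers(1, 100_000))
            te = (ts, ts + int(rng.integers(10, 2000)))
            out = assign_genes("2L", *te, genes, window_bp=1000)

            def gap(g):
                if te[1] < g.start:
                    return g.start - te[1] - 1
                if g.end < te[0]:
                    return te[0] - g.end - 1
                return 0
            gaps = {g.gene_id: gap(g) for g in genes}
            within = {k for k, v in gaps.items() if v < 1000}
            if not within:
                dmin = min(gaps.values())
                within = {k for k, v in gaps.items() if v == dmin}
            assert {o["gene_id"] for o in out} == within


class TestIntersectImmune:
    def test_join_and_gene_listing(self):
        cands = pd.DataFrame({"te": ["te0", "te1"]})
        assoc = pd.DataFrame({
            "te": ["te0", "te0", "te1"],
            "gene_id": ["gA", "gB", "gC"],
            "symbol": ["gA", "gB", "gC"],
            "gap_bp": [1, 340, 10],
            "relation": ["5'", "3'", "5'"],
            "immune_flag": [True, False, False],
            "evidence": ["pathway", "", ""],
        })
        out = intersect_immune(cands, assoc)
        # te0 keeps both genes (TM4SF/ken-style double association);
        # te1 has no immune gene and is dropped
        assert set(out["te"]) == {"te0"}
        assert set(out["gene_id"]) == {"gA", "gB"}

    def test_matches_bruteforce_join(self):
        rng = np.random.default_rng(5)
        tes = [f"te{i}" for i in range(20)]
        assoc = pd.DataFrame({
            "te": rng.choice(tes, 60),
            "gene_id": [f"g{i}" for i in range(60)],
            "symbol": [f"g{i}" for i in range(60)],
            "gap_bp": rng.integers(0, 2000, 60),
            "relation": ["5'"] * 60,
            "immune_flag": rng.random(60) < 0.3,
            "evidence": [""] * 60,
        })
        cands = pd.DataFrame({"te": tes[:12]})
        out = intersect_immune(cands, assoc)
        expected = {
            te for te in tes[:12]
            if assoc.loc[(assoc["te"] == te) & assoc["immune_flag"]].shape[0]
        }
        assert set(out["te"]) == expected


class TestGff3Reader:
    GFF = """\
##gff-version 3
2L\t.\tgene\t1000\t5000\t.\t+\t.\tID=g1;Name=kay;immune=1;evidence=expression,pathway
2L\t.\tmRNA\t1000\t5000\t.\t+\t.\tID=g1.t1;Parent=g1
2L\t.\tCDS\t1500\t4500\t.\t+\t0\tID=c1;Parent=g1.t1
2L\t.\tgene\t9000\t12000\t.\t-\t.\tID=g2;Name=CG0
2L\t.\tmRNA\t9000\t12000\t.\t-\t.\tID=g2.t1;Parent=g2
2L\t.\tCDS\t9500\t11500\t.\t-\t0\tID=c2;Parent=g2.t1
"""

    def test_roundtrip_with_attributes(self, tmp_path):
        from teimmune import read_genes_gff3
        p = tmp_path / "genes.gff3"
        p.write_text(self.GFF)
        genes = {g.gene_id: g for g in read_genes_gff3(p)}
        assert genes["g1"].immune_flag
        assert genes["g1"].evidence == frozenset({"expression", "pathway"})
        assert genes["g1"].transcripts == {"g1.t1": [(1500, 4500)]}
        assert not genes["g2"].immune_flag
        assert genes["g2"].strand == "-"

    def test_sidecar_overrides_attributes(self, tmp_path):
        from teimmune import read_genes_gff3
        p = tmp_path / "genes.gff3"
        p.write_text(self.GFF)
        sc = tmp_path / "immune.tsv"
        sc.write_text("gene_id\timmune_flag\tevidence\n"
                      "g1\tFalse\t\ng2\tTrue\tsurvival\n")
        genes = {g.gene_id: g for g in read_genes_gff3(p, sc)}
        assert not genes["g1"].immune_flag
        assert genes["g2"].immune_flag
        assert genes["g2"].evidence == frozenset({"survival"})

    def test_assign_genes_from_gff(self, tmp_path):
        from teimmune import assign_genes, read_genes_gff3
        p = tmp_path / "genes.gff3"
        p.write_text(self.GFF)
        genes = read_genes_gff3(p)
        out = assign_genes("2L", 5501, 5600, genes, window_bp=1000)
        assert [o["gene_id"] for o in out] == ["g1"]
        assert out[0]["gap_bp"] == 500 and out[0]["relation"] == "3'"
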