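"""EST mapping, expression summaries, correlation clustering and ΔCT."""

import math

import numpy as np
import pandas as pd
import pytest

from ugtfam import simkit
from ugtfam.expressionx import (cluster_expression, delta_ct,
                                expressed_fraction, expression_summary,
                                map_ests, round2)
from ugtfam.formats import ESTRecord, ExpressionTable

from _oracles import average_linkage_bruteforce


class TestMapEsts:
    def test_exact_substring_maps_with_full_identity(self):
        rng = np.random.default_rng(14)
        cds = simkit._random_dna(600, rng)
        est = ESTRecord("e1", cds[100:400], "LIB_FL", "FL")
        res = map_ests([est], {"g1": cds})
        gene, identity, length = res.assignments["e1"]
        assert (gene, identity, length) == ("g1", 1.0, 300)
        assert res.counts.values.loc["g1", "FL"] == 1

    def test_unrelated_read_is_unmapped(self):
        rng = np.random.default_rng(15)
        res = map_ests([ESTRecord("e1", simkit._random_dna(200, rng),
                                  "LIB_FL", "FL")],
                       {"g1": simkit._random_dna(600, rng)})
        assert res.assignments["e1"] is None
        assert res.unmapped == 1

    def test_identical_genes_tie_is_discarded(self):
        rng = np.random.default_rng(16)
        cds = simkit._random_dna(400, rng)
        est = ESTRecord("e1", cds[50:250], "LIB_FL", "FL")
        res = map_ests([est], {"g1": cds, "g2": cds})
        assert res.discarded_ties == 1
        assert int(res.counts.values.to_numpy().sum()) == 0

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="k"):
            map_ests([], {"g": "ACGT" * 30}, k=7)
        with pytest.raises(ValueError, match="empty"):
            map_ests([], {})

    def test_est_conservation_and_planted_recovery(self, family_sim):
        """mapped + unmapped + ties = input; counts within 3 binomial SD of
        the planted sampling; expressed set = genes with ≥ 1 planted EST."""
        est = simkit.simulate_ests(family_sim, n_ests=1500,
                                   error_rate=0.01, seed=21)
        cds = {g: family_sim.cds[g] for g in family_sim.family_genes}
        res = map_ests(est.records, cds)
        mapped = sum(1 for v in res.assignments.values() if v)
        assert mapped + res.unmapped + res.discarded_ties == len(est.records)
        planted = est.planted_counts
        got = res.counts.values
        for g in cds:
            for t in got.columns:
                n = int(planted.loc[g, t])
                sd = math.sqrt(max(n, 1))
                assert abs(int(got.loc[g, t]) - n) <= 3 * sd
        expressed = set(got.index[got.sum(axis=1) > 0])
        assert expressed == set(planted.index[planted.sum(axis=1) > 0])


class TestSummary:
    def _table(self, per_gene, tissue="FL", family=None):
        genes = [f"g{i}" for i in range(len(per_gene))]
        return ExpressionTable(values=pd.DataFrame({tissue: per_gene},
                                                   index=genes))

    def test_family_level_means_and_percentages(self):
        """325 ESTs on 85 of 137 genes: mean 3.82 per expressed gene and
        62.04% of the family expressed."""
        counts = [73] + [3] * 84 + [0] * 52      # 325 ESTs, 85 expressed
        summary = expression_summary(self._table(counts))
        assert summary.total_ests == 325
        assert summary.expressed_genes == 85
        assert summary.family_size == 137
        assert summary.mean_per_expressed == 3.82
        assert summary.pct_expressed == 62.04

    def test_group_means(self):
        """91 ESTs over 13 expressed members → 7.00; 69 over 15 → 4.60."""
        counts = [7] * 13 + [5] * 12 + [3] * 3   # G: 91/13, E: 69/15
        genes = [f"g{i}" for i in range(28)]
        table = ExpressionTable(values=pd.DataFrame({"FL": counts},
                                                    index=genes))
        groups = {g: ("G" if i < 13 else "E") for i, g in enumerate(genes)}
        summary = expression_summary(table, group_map=groups)
        assert summary.per_group.loc["G", "ests"] == 91
        assert summary.per_group.loc["G", "mean_per_expressed"] == 7.00
        assert summary.per_group.loc["E", "ests"] == 69
        assert summary.per_group.loc["E", "mean_per_expressed"] == 4.60

    def test_truncation_mode_percentage(self):
        """60 of 137 genes with microarray evidence is 43.79% truncated
        (43.80 rounded)."""
        vals = pd.DataFrame({"S1": [7.5] * 60 + [5.0] * 77},
                            index=[f"g{i}" for i in range(137)])
        table = ExpressionTable(values=vals, kind="log2_intensity")
        n, pct_trunc = expressed_fraction(table, 6.96, truncate=True)
        assert (n, pct_trunc) == (60, 43.79)
        _, pct_round = expressed_fraction(table, 6.96)
        assert pct_round == 43.80

    def test_empty_counts_all_zero(self):
        table = self._table([0, 0, 0])
        summary = expression_summary(table)
        assert summary.total_ests == 0
        assert summary.pct_expressed == 0.0
        assert summary.mean_per_expressed == 0.0

    def test_percentages_recompute_from_numerators(self, family_sim):
        est = simkit.simulate_ests(family_sim, n_ests=300, seed=22)
        cds = {g: family_sim.cds[g] for g in family_sim.family_genes}
        res = map_ests(est.records, cds)
        s = expression_summary(res.counts)
        assert s.pct_expressed == round2(100 * s.expressed_genes / s.family_size)
        for t, row in s.per_tissue.iterrows():
            assert row["pct_of_ests"] == round2(100 * row["ests"] / s.total_ests)
            assert row["pct_of_genes"] == round2(100 * row["genes"] / s.family_size)


class TestClusterExpression:
    def _table(self, rows, ids=None):
        ids = ids or [f"g{i}" for i in range(len(rows))]
        return ExpressionTable(
            values=pd.DataFrame(rows, index=ids,
                                columns=[f"t{j}" for j in range(len(rows[0]))]),
            kind="log2_intensity")

    def test_identical_rows_merge_first_at_zero(self):
        table = self._table([[1, 2, 3, 4], [2, 4, 6, 8],
                             [1, 2, 3, 4], [4, 3, 2, 1]])
        # rows 0 and 2 are identical; 0,1 perfectly correlated too
        res = cluster_expression(table)
        assert res.linkage[0, 2] == pytest.approx(0.0)

    def test_anticorrelated_distance_is_two(self):
        table = self._table([[1, 2, 3], [3, 2, 1], [1, 3, 2]])
        res = cluster_expression(table)
        from scipy.spatial.distance import squareform
        d = squareform(res.distances)
        assert d[0, 1] == pytest.approx(2.0)

    def test_constant_row_flagged_at_max_distance(self):
        table = self._table([[1, 2, 3], [5, 5, 5], [3, 1, 2]])
        res = cluster_expression(table)
        assert res.constant_rows == ["g1"]
        from scipy.spatial.distance import squareform
        d = squareform(res.distances)
        assert d[1, 0] == 2.0 and d[1, 2] == 2.0

    def test_merge_sequence_matches_bruteforce_average_linkage(self):
        """scipy's agglomeration equals a naive average-linkage oracle on
        6 random rows (heights and cluster compositions)."""
        rng = np.random.default_rng(17)
        rows = rng.normal(size=(6, 8))
        table = self._table(rows.tolist())
        res = cluster_expression(table)
        from scipy.spatial.distance import squareform
        dist = squareform(res.distances)
        expected = average_linkage_bruteforce(dist)
        n = 6
        members = {i: frozenset((i,)) for i in range(n)}
        for step, (a, b, h, _) in enumerate(res.linkage):
            merged = members[int(a)] | members[int(b)]
            members[n + step] = merged
            want_set, want_h = expected[step]
            assert merged == want_set
            assert h == pytest.approx(want_h)

    def test_row_order_covers_all_genes(self, family_sim):
        est = simkit.simulate_ests(family_sim, n_ests=400, seed=23)
        cds = {g: family_sim.cds[g] for g in family_sim.family_genes}
        res = map_ests(est.records, cds)
        clust = cluster_expression(res.counts)
        assert sorted(clust.order) == sorted(res.counts.genes)


class TestDeltaCt:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "tissue", "bio_rep",
                                           "tech_rep", "ct"])

    def test_equal_ct_gives_unit_abundance(self):
        rows = []
        for b in (1, 2, 3):
            for t in (1, 2):
                rows.append(("ref", "FL", b, t, 20.0))
                rows.append(("g1", "FL", b, t, 20.0))
        out = delta_ct(self._table(rows), "ref")
        assert out.abundance_mean[0] == pytest.approx(1.0)
        assert out.abundance_se[0] == pytest.approx(0.0)

    def test_delta_ct_of_one_halves_abundance(self):
        rows = []
        for b in (1, 2):
            rows.append(("ref", "FL", b, 1, 20.0))
            rows.append(("g1", "FL", b, 1, 21.0))
        out = delta_ct(self._table(rows), "ref")
        assert out.abundance_mean[0] == pytest.approx(0.5)

    def test_technical_replicates_averaged_within_bio(self):
        rows = [("ref", "FL", 1, 1, 19.0), ("ref", "FL", 1, 2, 21.0),
                ("g1", "FL", 1, 1, 22.0), ("g1", "FL", 1, 2, 18.0)]
        out = delta_ct(self._table(rows), "ref")
        assert out.abundance_mean[0] == pytest.approx(1.0)

    def test_missing_reference_bio_rep_dropped(self, caplog):
        rows = [("ref", "FL", 1, 1, 20.0),
                ("g1", "FL", 1, 1, 20.0), ("g1", "FL", 2, 1, 25.0)]
        out = delta_ct(self._table(rows), "ref")
        assert out.n_bio[0] == 1

    def test_reference_entirely_missing_is_error(self):
        rows = [("g1", "FL", 1, 1, 20.0)]
        with pytest.raises(ValueError, match="ref"):
            delta_ct(self._table(rows), "ref")

    def test_recovers_planted_abundances(self, family_sim):
        """ΔCT estimates fall within 3 standard errors (known replicate
        noise sd_ct/√n_bio on the ΔCT scale) of the planted abundances."""
        sd_ct, n_bio = 0.1, 3
        ct = simkit.simulate_qpcr(family_sim, sd_ct=sd_ct, n_bio=n_bio,
                                  seed=24)
        out = delta_ct(ct, "ETIF5A")
        truth = family_sim.truth.qpcr_truth
        bound = 3 * sd_ct / math.sqrt(n_bio)
        for row in out.itertuples():
            err = abs(math.log2(row.abundance_mean)
                      - math.log2(truth.loc[row.gene, row.tissue]))
            assert err <= bound
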