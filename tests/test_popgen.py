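"""Diversity, differentiation, and disequilibrium statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foxscape import popgen
from foxscape.genodata import DataError, HaplotypeCounts

from conftest import build_gt


class TestGeneDiversity:
    @pytest.mark.parametrize("counts,expected", [
        ({"O-26": 1, "N-7": 4, "G-38": 100, "F-12": 10}, 0.235),  # Monterey
        ({"K-36": 13}, 0.000),                                    # Santa Barbara
        ({"N-7": 1, "G-38": 18}, 0.100),                          # Morro Bay
        ({"a": 5, "b": 5}, 0.5),
    ])
    def test_values(self, counts, expected):
        assert popgen.gene_diversity(counts) == pytest.approx(expected, abs=5e-4)

    def test_unbiased_variant_and_errors(self):
        assert popgen.gene_diversity([2, 2], unbiased=True) == pytest.approx(
            (4 / 3) * 0.5)
        with pytest.raises(DataError):
            popgen.gene_diversity([0, 0])

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=8)
           .filter(lambda c: sum(c) > 0))
    @settings(max_examples=100, deadline=None)
    def test_bounds(self, counts):
        h = popgen.gene_diversity(counts)
        k = sum(1 for c in counts if c > 0)
        assert 0.0 <= h <= 1.0 - 1.0 / k + 1e-12


class TestDiversityPartition:
    def test_all_identical_frequencies_gives_zero(self):
        hc = HaplotypeCounts(["a", "b"], ["h1", "h2"],
                             np.array([[10, 10], [10, 10]]))
        hc.included_sites = ["a", "b"]
        part = popgen.global_fst_from_diversity(hc)
        assert part.fst == pytest.approx(0.0, abs=1e-12)

    def test_private_haplotypes_give_one(self):
        hc = HaplotypeCounts(["a", "b"], ["h1", "h2"],
                             np.array([[10, 0], [0, 10]]))
        hc.included_sites = ["a", "b"]
        part = popgen.global_fst_from_diversity(hc)
        assert part.h_within_mean == 0.0 and part.fst == 1.0

    @given(st.integers(2, 5), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_wahlund_direction(self, n_sites, seed):
        """Pooling never lowers diversity: partition F_ST >= 0."""
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 30, size=(n_sites, 4))
        counts[:, 0] += 5  # no empty rows
        hc = HaplotypeCounts([f"s{i}" for i in range(n_sites)],
                             list("wxyz"), counts)
        hc.included_sites = hc.sites
        part = popgen.global_fst_from_diversity(hc)
        assert part.fst >= -1e-9


class TestHaploidFst:
    def test_fixed_same_and_different(self):
        same = np.array([[8, 0], [12, 0]])
        assert popgen._haploid_theta(same) == 0.0
        diff = np.array([[8, 0], [0, 8]])
        assert popgen._haploid_theta(diff) == pytest.approx(1.0)

    def test_matches_brute_force_anova_oracle(self):
        # A = {x:3, y:1}, B = {x:1, y:3}; direct MSP/MSG computation
        counts = np.array([[3, 1], [1, 3]])
        n = counts.sum(1)
        N = n.sum()
        r = 2
        p = counts / n[:, None]
        pbar = counts.sum(0) / N
        ssp = sum(n[i] * (p[i, a] - pbar[a]) ** 2
                  for i in range(r) for a in range(2))
        ssg = sum(n[i] * p[i, a] * (1 - p[i, a])
                  for i in range(r) for a in range(2))
        msp = ssp / (r - 1)
        msg = ssg / (N - r)
        nc = (N - (n ** 2).sum() / N) / (r - 1)
        expect = (msp - msg) / (msp + (nc - 1) * msg)
        assert popgen._haploid_theta(counts) == pytest.approx(expect, abs=1e-12)

    def test_pairwise_result_and_linearization_cap(self):
        hc = HaplotypeCounts(["a", "b", "c"], ["h1", "h2"],
                             np.array([[9, 0], [0, 9], [5, 4]]))
        res = popgen.pairwise_haplotype_fst(hc)
        assert res.pairwise.loc("a", "b") == pytest.approx(1.0)
        assert np.isinf(res.linearized.loc("a", "b"))
        assert res.n_capped >= 1
        with pytest.raises(DataError, match="2 sites"):
            popgen.pairwise_haplotype_fst(
                HaplotypeCounts(["a"], ["h1"], np.array([[5]])))


class TestSiteSummaries:
    def test_monomorphic_site(self):
        rows = [(f"i{k}", "A", [("1", "1"), ("2", "2")]) for k in range(6)]
        summ = popgen.site_summary_stats(build_gt(rows, ["L1", "L2"]))["A"]
        assert summ.ho_mean == 0.0 and summ.he_mean == 0.0
        assert summ.ar_mean == pytest.approx(1.0)
        assert summ.f_is is None and summ.flags

    def test_all_heterozygous(self):
        rows = [(f"i{k}", "A", [("1", "2")]) for k in range(10)]
        summ = popgen.site_summary_stats(build_gt(rows, ["L1"]))["A"]
        assert summ.ho_mean == 1.0
        assert summ.he_mean == pytest.approx(0.5)
        assert summ.f_is < 0

    def test_fis_near_zero_under_hwe(self):
        rng = np.random.default_rng(5)
        fvals = []
        for rep in range(20):
            rows = []
            for k in range(200):
                calls = [tuple(str(a) for a in
                               rng.choice(4, size=2, p=[.4, .3, .2, .1]))
                         for _ in range(5)]
                rows.append((f"i{k}", "A", calls))
            gt = build_gt(rows, [f"L{j}" for j in range(5)])
            fvals.append(popgen.site_summary_stats(gt)["A"].f_is)
        assert abs(np.mean(fvals)) < 0.02  # simulation CI at n=200, 20 reps

    def test_rarefaction_autolower_warns(self, synth6):
        gt = synth6[0]
        with pytest.warns(UserWarning, match="rarefaction"):
            popgen.site_summary_stats(gt, rarefaction_g=10 ** 6)


class TestDisequilibrium:
    def test_duplicated_locus_hits_minimum_p(self):
        rng = np.random.default_rng(3)
        rows = []
        for k in range(30):
            g = tuple(str(a) for a in sorted(rng.choice(3, size=2)))
            rows.append((f"i{k}", "A", [g, g]))  # same genotypes at 2 loci
        gt = build_gt(rows, ["L1", "L2"])
        res = popgen.disequilibrium_tests(gt, n_perm=199, seed=0)
        p = res.gametic_p.query("locus_a == 'L1' and locus_b == 'L2'").p.iloc[0]
        assert p == pytest.approx(1 / 200)

    def test_wahlund_pooling_rejects_hwe(self):
        # two strongly diverged sites pooled into one: all loci deviate
        rng = np.random.default_rng(8)
        rows = []
        for s, probs in (("X", [.9, .1, 0, 0]), ("Y", [0, 0, .1, .9])):
            for k in range(40):
                calls = [tuple(str(a) for a in rng.choice(4, size=2, p=probs))
                         for _ in range(4)]
                rows.append((f"{s}{k}", "pooled", calls))
        gt = build_gt(rows, [f"L{j}" for j in range(4)])
        res = popgen.disequilibrium_tests(gt, n_perm=199, seed=1)
        assert (res.hwe_p.loc["pooled"] < 0.05).all()

    def test_permutation_p_bounds_and_nperm_guard(self):
        rows = [(f"i{k}", "A", [(str(k % 3), str((k + 1) % 3))])
                for k in range(20)]
        gt = build_gt(rows, ["L1"])
        res = popgen.disequilibrium_tests(gt, n_perm=99, seed=0)
        p = res.hwe_p.iloc[0, 0]
        assert 1 / 100 <= p <= 1.0
        with pytest.raises(DataError):
            popgen.disequilibrium_tests(gt, n_perm=10)

    def test_sequential_bonferroni(self):
        p = [0.001, 0.011, 0.02, 0.8]
        rej = popgen.sequential_bonferroni(p, alpha=0.05)
        # Holm: 0.001 <= .05/4, 0.011 <= .05/3, 0.02 <= .05/2, stop at 0.8
        assert rej.tolist() == [True, True, True, False]


class TestTheta:
    def _small_table(self):
        rows = [
            ("a1", "A", [("1", "1"), ("1", "2")]),
            ("a2", "A", [("1", "2"), ("2", "2")]),
            ("a3", "A", [("1", "1"), ("1", "1")]),
            ("b1", "B", [("2", "2"), ("1", "2")]),
            ("b2", "B", [("2", "2"), ("2", "2")]),
            ("b3", "B", [("1", "2"), ("2", "2")]),
        ]
        return build_gt(rows, ["L1", "L2"])

    def test_matches_first_principles_oracle(self):
        """Direct Weir-Cockerham variance components, explicit loops."""
        gt = self._small_table()
        a_sum = abc_sum = 0.0
        for locus in gt.loci:
            li = gt.loci.index(locus)
            data = {}
            for s in ("A", "B"):
                idx = gt.index_of(gt.individuals_of(s))
                data[s] = gt.calls[idx, li, :].astype(str)
            alleles = sorted({a for col in data.values() for a in col.ravel()})
            r = 2
            ni = np.array([len(data[s]) for s in ("A", "B")], float)
            nbar = ni.mean()
            nc = (r * nbar - (ni ** 2).sum() / (r * nbar)) / (r - 1)
            for al in alleles:
                p = np.array([(data[s] == al).sum() / (2 * len(data[s]))
                              for s in ("A", "B")])
                h = np.array([np.mean((data[s][:, 0] == al)
                                      ^ (data[s][:, 1] == al))
                              for s in ("A", "B")])
                pbar = (ni * p).sum() / (r * nbar)
                s2 = (ni * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
                hbar = (ni * h).sum() / (r * nbar)
                a = (nbar / nc) * (s2 - (pbar * (1 - pbar)
                                         - (r - 1) / r * s2 - hbar / 4)
                                   / (nbar - 1))
                b = (nbar / (nbar - 1)) * (pbar * (1 - pbar)
                                           - (r - 1) / r * s2
                                           - (2 * nbar - 1) / (4 * nbar) * hbar)
                c = hbar / 2
                a_sum += a
                abc_sum += a + b + c
        res = popgen.weir_cockerham_theta(gt, n_boot=0)
        assert res.global_estimate == pytest.approx(a_sum / abc_sum, abs=1e-12)

    def test_panmictic_split_near_zero(self):
        rng = np.random.default_rng(9)
        rows = []
        for k in range(120):
            calls = [tuple(str(a) for a in rng.choice(6, size=2))
                     for _ in range(10)]
            rows.append((f"i{k}", "A" if k < 60 else "B", calls))
        gt = build_gt(rows, [f"L{j}" for j in range(10)])
        res = popgen.weir_cockerham_theta(gt, n_boot=500, seed=1)
        lo, hi = res.ci95
        assert lo <= 0.0 <= hi or abs(res.global_estimate) < 0.01

    def test_allele_relabel_invariance(self):
        gt = self._small_table()
        relab = {"1": "205", "2": "101"}
        rows2 = []
        for i, ind in enumerate(gt.individuals):
            rows2.append((ind, gt.site_of[ind],
                          [tuple(relab[a] for a in gt.calls[i, j])
                           for j in range(2)]))
        gt2 = build_gt(rows2, gt.loci)
        t1 = popgen.weir_cockerham_theta(gt, n_boot=0).global_estimate
        t2 = popgen.weir_cockerham_theta(gt2, n_boot=0).global_estimate
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_single_locus_has_no_ci(self):
        rows = [("a1", "A", [("1", "2")]), ("a2", "A", [("1", "1")]),
                ("b1", "B", [("2", "2")]), ("b2", "B", [("1", "2")])]
        res = popgen.weir_cockerham_theta(build_gt(rows, ["L1"]), n_boot=100)
        assert res.ci95 is None


class TestNeiDa:
    def test_identical_and_disjoint(self):
        rows = [("a1", "A", [("1", "2")]), ("a2", "A", [("1", "2")]),
                ("b1", "B", [("1", "2")]), ("b2", "B", [("1", "2")])]
        res = popgen.nei_da_distance(build_gt(rows, ["L1"]))
        assert res.pairwise.loc("A", "B") == pytest.approx(0.0)
        rows = [("a1", "A", [("1", "1")]), ("a2", "A", [("1", "1")]),
                ("b1", "B", [("2", "2")]), ("b2", "B", [("2", "2")])]
        res = popgen.nei_da_distance(build_gt(rows, ["L1"]))
        assert res.pairwise.loc("A", "B") == pytest.approx(1.0)

    def test_half_shared_formula(self):
        # x = (1, 0), y = (0.5, 0.5): D_A = 1 - sqrt(0.5)
        rows = [("a1", "A", [("1", "1")]), ("a2", "A", [("1", "1")]),
                ("b1", "B", [("1", "1")]), ("b2", "B", [("2", "2")])]
        res = popgen.nei_da_distance(build_gt(rows, ["L1"]))
        assert res.pairwise.loc("A", "B") == pytest.approx(1 - np.sqrt(0.5))

    def test_locus_order_invariance_and_dropped_count(self):
        rows = [("a1", "A", [("1", "2"), ("3", "3")]),
                ("a2", "A", [("1", "1"), None]),
                ("b1", "B", [("2", "2"), None]),
                ("b2", "B", [("1", "2"), None])]
        gt = build_gt(rows, ["L1", "L2"])
        res = popgen.nei_da_distance(gt)
        rows_swap = [(i, s, cs[::-1]) for i, s, cs in rows]
        res2 = popgen.nei_da_distance(build_gt(rows_swap, ["L2", "L1"]))
        assert res.pairwise.loc("A", "B") == pytest.approx(
            res2.pairwise.loc("A", "B"), abs=1e-12)
        assert res.per_locus["n_dropped"][0, 1] == 1  # L2 untyped in B


class TestSexBias:
    def test_symmetric_island_model_is_one(self):
        assert popgen.sex_biased_gene_flow_ratio(0.2, 0.5).mm_over_mf == \
            pytest.approx(1.0)

    def test_no_male_flow_boundary(self):
        res = popgen.sex_biased_gene_flow_ratio(0.2, 1 / 3)
        assert res.mm_over_mf == pytest.approx(0.0, abs=1e-12)

    def test_negative_male_flow_flagged(self):
        res = popgen.sex_biased_gene_flow_ratio(0.2, 0.3)
        assert res.mm_over_mf == 0.0 and res.flag

    @pytest.mark.parametrize("fnuc,fmt", [(0.0, 0.5), (1.0, 0.5), (0.1, 1.2)])
    def test_domain_errors(self, fnuc, fmt):
        with pytest.raises(DataError):
            popgen.sex_biased_gene_flow_ratio(fnuc, fmt)
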