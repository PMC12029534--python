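"""Exact nonparametric tests, FDR and enrichment against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gcmet import core_data as cd
from gcmet import univariate as uv

# ---------------------------------------------------------------------------
# independent brute-force oracles (kept deliberately naive)
# ---------------------------------------------------------------------------


def brute_wilcoxon_p(diffs):
    d = [x for x in diffs if x != 0]
    ranks = stats.rankdata([abs(x) for x in d])
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    le = ge = total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        le += w <= w_obs + 1e-12
        ge += w >= w_obs - 1e-12
    return min(1.0, 2 * min(le / total, ge / total))


def brute_mannwhitney_p(x, y):
    pooled = list(x) + list(y)
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    le = ge = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2
        total += 1
        le += u <= u_obs + 1e-12
        ge += u >= u_obs - 1e-12
    return min(1.0, 2 * min(le / total, ge / total))


def brute_bh(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        prev = min(prev, p[i] * m / rank_from_end)
        q[i] = prev
    return q


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


class TestPairedWilcoxon:
    def test_all_positive_n6(self):
        # only the all-positive and all-negative sign vectors reach |W|=21
        w, p = uv.paired_wilcoxon([2, 3, 4, 5, 6, 7], [1, 2, 3, 4, 5, 6])
        assert w == 21.0
        assert p == pytest.approx(2 / 64)

    def test_mixed_signs_enumeration(self):
        # differences (1,2,3,4,-5): 10 of 32 sign vectors give W+ <= 10
        adj = np.zeros(5)
        tum = np.array([1.0, 2.0, 3.0, 4.0, -5.0])
        _, p = uv.paired_wilcoxon(tum, adj)
        assert p == pytest.approx(0.625)

    def test_identical_vectors_give_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            _, p = uv.paired_wilcoxon([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            uv.paired_wilcoxon([1, 2], [1, 2, 3])

    @pytest.mark.parametrize("n", range(4, 11))
    def test_exact_equals_enumeration_with_ties(self, n, rng):
        for _ in range(5):
            d = rng.integers(-4, 5, size=n).astype(float)
            if (d != 0).sum() < 1:
                continue
            tum, adj = d, np.zeros(n)
            _, p = uv.paired_wilcoxon(tum, adj)
            assert p == pytest.approx(brute_wilcoxon_p(d))


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_complete_separation(self):
        u, p = uv.mannwhitney_association(
            [1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert u == 0.0
        assert p == pytest.approx(2 / 20)

    def test_identical_groups(self):
        _, p = uv.mannwhitney_association([1, 2, 3, 1, 2, 3],
                                          ["a", "a", "a", "b", "b", "b"])
        assert p == 1.0

    def test_label_swap_symmetry(self, rng):
        vals = rng.normal(size=10)
        labels = np.array(["a"] * 4 + ["b"] * 6)
        u1, p1 = uv.mannwhitney_association(vals, labels)
        u2, p2 = uv.mannwhitney_association(vals, np.where(labels == "a", "b", "a"))
        assert p1 == pytest.approx(p2)
        assert u2 == pytest.approx(4 * 6 - u1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            uv.mannwhitney_association([1, 2, 3], ["a", "a", "a"])

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (2, 8), (5, 5)])
    def test_exact_equals_enumeration_with_ties(self, n1, n2, rng):
        for _ in range(5):
            x = rng.integers(0, 5, size=n1).astype(float)
            y = rng.integers(0, 5, size=n2).astype(float)
            if len(set(np.r_[x, y])) < 2:
                continue
            vals = np.r_[x, y]
            labels = ["a"] * n1 + ["b"] * n2
            _, p = uv.mannwhitney_association(vals, labels)
            assert p == pytest.approx(brute_mannwhitney_p(x, y))


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------


class TestBhFdr:
    def test_stepup_by_hand(self):
        q = uv.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert uv.bh_fdr([0.3]) == pytest.approx([0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            uv.bh_fdr([0.5, 1.2])

    def test_oracle_equivalence_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert uv.bh_fdr(p) == pytest.approx(brute_bh(list(p)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_monotone_in_sorted_p_order(self, ps):
        q = uv.bh_fdr(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------


class TestEnrichment:
    def test_perfect_overlap_closed_form(self):
        universe = {f"m{i}" for i in range(10)}
        pathway = {f"m{i}" for i in range(5)}
        res = uv.hypergeometric_enrichment(pathway, {"pw": pathway}, universe)
        assert res[0].p_value == pytest.approx(1 / 252)

    def test_pathway_equal_universe_is_uninformative(self):
        universe = {f"m{i}" for i in range(8)}
        res = uv.hypergeometric_enrichment(
            {"m0", "m3"}, {"pw": set(universe)}, universe)
        assert res[0].p_value == pytest.approx(1.0)

    def test_singleton_pathway_hit_probability(self):
        # a hit in a 1-metabolite pathway: P(overlap >= 1) = selected/universe
        universe = {f"m{i}" for i in range(10)}
        res = uv.hypergeometric_enrichment(
            {"m0", "m1", "m2"}, {"pw": {"m0"}}, universe)
        assert res[0].overlap_count == 1
        assert res[0].p_value == pytest.approx(3 / 10)
        # a miss is uninformative: P(overlap >= 0) = 1
        res = uv.hypergeometric_enrichment(
            {"m0", "m1", "m2"}, {"pw": {"m5"}}, universe)
        assert res[0].p_value == pytest.approx(1.0)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            uv.hypergeometric_enrichment(set(), {"pw": {"a"}}, {"a", "b"})

    def test_matches_pmf_sum_oracle(self, rng):
        universe = [f"m{i}" for i in range(20)]
        for _ in range(20):
            pw = set(rng.choice(universe, size=rng.integers(1, 15), replace=False))
            sel = set(rng.choice(universe, size=rng.integers(1, 10), replace=False))
            res = uv.hypergeometric_enrichment(sel, {"pw": pw}, set(universe))
            k_obs = len(pw & sel)
            from math import comb
            total = comb(20, len(sel))
            p_brute = sum(
                comb(len(pw), k) * comb(20 - len(pw), len(sel) - k)
                for k in range(k_obs, min(len(pw), len(sel)) + 1)
            ) / total
            assert res[0].p_value == pytest.approx(p_brute)

    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("pw1\tdesc\tm1\tm2\npw2\tdesc\tm3\n")
        assert uv.read_gmt(path) == {"pw1": {"m1", "m2"}, "pw2": {"m3"}}


# ---------------------------------------------------------------------------
# Differential screen and clinical scan
# ---------------------------------------------------------------------------


class TestDifferentialAnalysis:
    def test_planted_effects_recovered(self, small_normalized):
        tissue_pt, tissue, truth = small_normalized
        res = uv.differential_analysis(tissue_pt, tissue)
        by_id = {r.metabolite_id: r for r in res}
        planted = [m for m in truth.differential if m in by_id]
        # strong planted log2FCs (|fc| >= 0.5 at n=20 pairs) are detectable
        detected = [m for m in planted if by_id[m].fdr < 0.05]
        assert len(detected) >= 0.8 * len(planted)
        for m in detected:
            assert (by_id[m].direction == "up") == (truth.differential[m] > 0)

    def test_null_type_one_calibrated(self, rng):
        # no planted effect: p < 0.05 rate near nominal over many metabolites
        n_pairs, n_mets = 20, 300
        tum = rng.lognormal(size=(n_pairs, n_mets))
        adj = rng.lognormal(size=(n_pairs, n_mets))
        hits = sum(
            uv.paired_wilcoxon(tum[:, j], adj[:, j])[1] < 0.05
            for j in range(n_mets)
        )
        assert 0.01 <= hits / n_mets <= 0.10

    def test_constant_metabolite_flat_in_clinical_scan(self, small_normalized):
        tissue_pt, tissue, _ = small_normalized
        pt = cd.PeakTable(tissue_pt.data.copy(), normalized=True)
        pt.data.iloc[:, 0] = 5.0
        mid = pt.metabolite_ids[0]
        res = [r for r in uv.differential_analysis(pt, tissue) if r.metabolite_id == mid]
        table = uv.clinical_association_scan(pt, tissue, res)
        assert (table["p_value"] == 1.0).all()

    def test_empty_differential_gives_empty_scan(self, small_normalized):
        tissue_pt, tissue, _ = small_normalized
        table = uv.clinical_association_scan(tissue_pt, tissue, [])
        assert table.empty

    def test_planted_clinical_shift_detected(self, small_normalized, rng):
        tissue_pt, tissue, _ = small_normalized
        pt = cd.PeakTable(tissue_pt.data.copy(), normalized=True)
        mid = pt.metabolite_ids[1]
        shifted = [s.sample_id for s in tissue
                   if s.tissue_type == "tumor"
                   and s.clinical_indices.get("nerve_invasion") == "yes"]
        sd = pt.data[mid].std()
        pt.data.loc[shifted, mid] += 3 * sd
        res = [r for r in uv.differential_analysis(pt, tissue)
               if r.metabolite_id == mid]
        table = uv.clinical_association_scan(pt, tissue, res)
        row = table[(table.clinical_index == "nerve_invasion")
                    & (table.metabolite_id == mid)]
        assert row["significant"].all()
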