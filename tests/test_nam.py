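"""Stage-wise monotone subnetworks: predicate rules, hubs, triplets, oracle equivalence."""

from _nam_oracle import (
    brute_force_nam,
    _stage_networks_from_values,
    random_instance,
)

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gcmet import core_data as cd
from gcmet import nam

# ---------------------------------------------------------------------------
# predicate
# ---------------------------------------------------------------------------


class TestMonotonePredicate:
    @pytest.mark.parametrize(
        "triple,verdict",
        [
            ((0.8, 0.5, 0.1), "decreasing"),
            ((0.1, 0.5, 0.8), "increasing"),
            ((0.50, 0.49, 0.48), "reject"),   # steps within the 0.02 equality band
            ((0.2, 0.6, 0.3), "reject"),      # not monotone
            ((0.0, 0.6, 0.0), "reject"),      # single-stage spike
            ((0.6, 0.0, 0.0), "decreasing"),  # stage-I-only edge is monotone
            ((0.5, 0.51, 0.2), "decreasing"), # +0.01 step tolerated as equal
            ((-0.1, -0.5, -0.8), "decreasing"),
        ],
    )
    def test_stated_rules(self, triple, verdict):
        assert nam.monotone_edge_predicate(triple) == verdict

    def test_strict_mode_drops_tolerance(self):
        assert nam.monotone_edge_predicate((0.5, 0.51, 0.2)) == "decreasing"
        assert nam.monotone_edge_predicate((0.5, 0.51, 0.2), strict=True) == "reject"

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.tuples(*[st.floats(-1, 1) for _ in range(3)]))
    def test_negation_swaps_direction(self, triple):
        v1 = nam.monotone_edge_predicate(triple)
        v2 = nam.monotone_edge_predicate(tuple(-x for x in triple))
        swap = {"increasing": "decreasing", "decreasing": "increasing",
                "reject": "reject"}
        assert v2 == swap[v1]


# ---------------------------------------------------------------------------
# stage networks
# ---------------------------------------------------------------------------


class TestStageNetworks:
    def test_significant_edge_carries_rho_weight(self, rng):
        x = rng.standard_normal(12)
        stage_values = {
            t: pd.DataFrame({"a": x + 0.01 * rng.standard_normal(12), "b": x,
                             "c": rng.standard_normal(12)})
            for t, x in (("I", x), ("II", x), ("III", x))
        }
        nets = _stage_networks_from_values(stage_values)
        for t in nets.stages:
            assert nets.weights[t].loc["a", "b"] > 0.9
            assert nets.weights[t].loc["a", "c"] == 0.0

    def test_insignificant_pair_has_zero_weight(self, rng):
        # large-ish p: weight must be exactly 0, not the small rho
        stage_values = {t: pd.DataFrame(rng.standard_normal((10, 3)),
                                        columns=list("abc"))
                        for t in ("I", "II", "III")}
        nets = _stage_networks_from_values(stage_values)
        W = np.stack([nets.weights[t].to_numpy() for t in nets.stages])
        assert (W[np.abs(W) < 0.2] == 0).all()

    def test_missing_stage_is_error(self, small_normalized):
        tissue_pt, tissue, _ = small_normalized
        no_iii = [s for s in tissue if s.tnm_stage != "III"]
        pt = tissue_pt.subset_samples([s.sample_id for s in no_iii])
        with pytest.raises(ValueError, match="III"):
            nam.build_stage_networks(pt, no_iii)

    def test_small_stage_excluded_with_warning(self, small_normalized):
        tissue_pt, tissue, _ = small_normalized
        with pytest.warns(UserWarning, match="excluded"):
            nets = nam.build_stage_networks(
                tissue_pt, tissue, stages=("I", "II", "III", "IV"))
        assert "IV" not in nets.stages
        assert nets.stages == ("I", "II", "III")


# ---------------------------------------------------------------------------
# extraction, hubs, triplets
# ---------------------------------------------------------------------------


class TestExtraction:
    def test_membership_requires_presence_in_stage_graph(self):
        # accepted triple (0.8, 0.5, 0): edge in SG_I and SG_II, not SG_III
        mids = ["a", "b"]
        weights = {
            "I": pd.DataFrame([[0, 0.8], [0.8, 0]], index=mids, columns=mids),
            "II": pd.DataFrame([[0, 0.5], [0.5, 0]], index=mids, columns=mids),
            "III": pd.DataFrame([[0, 0.0], [0.0, 0]], index=mids, columns=mids),
        }
        nets = nam.StageNetworkSet(("I", "II", "III"), weights,
                                   {"I": 10, "II": 10, "III": 10}, mids, 0.01)
        subnets = nam.extract_monotone_subnetworks(nets)
        assert len(subnets["I"].edges) == 1
        assert len(subnets["II"].edges) == 1
        assert len(subnets["III"].edges) == 0

    def test_subnetwork_contained_in_stage_graph(self, rng):
        stage_values = random_instance(rng, n_mets=10, n_per_stage=15)
        nets = _stage_networks_from_values(stage_values)
        subnets = nam.extract_monotone_subnetworks(nets)
        for t in nets.stages:
            for _, e in subnets[t].edges.iterrows():
                assert nets.weights[t].loc[e["metabolite_a"],
                                           e["metabolite_b"]] != 0

    def test_exhaustive_oracle_equivalence(self):
        # package output equals the brute-force literal re-implementation
        for seed in range(10):
            rng = np.random.default_rng(seed)
            stage_values = random_instance(rng, n_mets=8, n_per_stage=15)
            nets = _stage_networks_from_values(stage_values)
            subnets = nam.extract_monotone_subnetworks(nets)
            hub_t, hubs = nam.select_hubs(subnets, k=15)
            sg_brute, hubs_brute = brute_force_nam(stage_values)
            for t in nets.stages:
                mine = {tuple(sorted((e["metabolite_a"], e["metabolite_b"])))
                        for _, e in subnets[t].edges.iterrows()}
                brute = {tuple(sorted(p)) for p in sg_brute[t]}
                assert mine == brute, f"seed {seed}, stage {t}"
                assert set(hub_t[t]) == hubs_brute[t], f"seed {seed}, stage {t}"


class TestHubs:
    def _subnet(self, stage, pairs):
        rows = [{"metabolite_a": a, "metabolite_b": b, "w_I": 0.5, "w_II": 0.3,
                 "w_III": 0.1, "trend": "decreasing"} for a, b in pairs]
        cols = ["metabolite_a", "metabolite_b", "w_I", "w_II", "w_III", "trend"]
        return nam.MonotoneSubnetwork(stage, pd.DataFrame(rows, columns=cols))

    def test_ties_at_cutoff_included(self):
        # degrees a:3, b:2, c:2, d:1 with k=2 → {a, b, c}
        sg = self._subnet("I", [("a", "b"), ("a", "c"), ("a", "d"),
                                ("b", "c")])
        hub_t, union = nam.select_hubs({"I": sg}, k=2)
        assert hub_t["I"] == ["a", "b", "c"]

    def test_empty_subnetwork_warns(self):
        sg = self._subnet("I", [])
        with pytest.warns(UserWarning, match="empty"):
            hub_t, union = nam.select_hubs({"I": sg})
        assert hub_t["I"] == [] and union == []

    def test_union_semantics(self):
        sg1 = self._subnet("I", [("a", "b")])
        sg2 = self._subnet("II", [("c", "d")])
        _, union = nam.select_hubs({"I": sg1, "II": sg2}, k=15)
        assert union == ["a", "b", "c", "d"]


class TestTriplets:
    def test_star_sizes_equal_degrees(self):
        pairs_by_stage = {
            "I": [("v", "a")],
            "II": [("v", "a"), ("v", "b")],
            "III": [("v", "a"), ("v", "b"), ("v", "c"), ("a", "b")],
        }
        weights = {}
        mids = ["v", "a", "b", "c"]
        for t, pairs in pairs_by_stage.items():
            W = pd.DataFrame(0.0, index=mids, columns=mids)
            for a, b in pairs:
                W.loc[a, b] = W.loc[b, a] = 0.5
            weights[t] = W
        subnets = {
            t: nam.MonotoneSubnetwork(t, pd.DataFrame(
                [{"metabolite_a": a, "metabolite_b": b, "w_I": 0.1, "w_II": 0.3,
                  "w_III": 0.5, "trend": "increasing"} for a, b in pairs],
                columns=["metabolite_a", "metabolite_b", "w_I", "w_II",
                         "w_III", "trend"]))
            for t, pairs in pairs_by_stage.items()
        }
        nets = nam.StageNetworkSet(("I", "II", "III"), weights,
                                   {t: 10 for t in weights}, mids, 0.01)
        trips = nam.build_triplets(nets, subnets, ["v"])
        assert trips[0].degrees == {"I": 1, "II": 2, "III": 3}
        assert list(trips[0].stars["III"]["neighbor"]) == ["a", "b", "c"]

    def test_isolated_hub_has_empty_star(self):
        mids = ["v", "a"]
        weights = {t: pd.DataFrame(0.0, index=mids, columns=mids)
                   for t in ("I", "II", "III")}
        nets = nam.StageNetworkSet(("I", "II", "III"), weights,
                                   {t: 10 for t in weights}, mids, 0.01)
        cols = ["metabolite_a", "metabolite_b", "w_I", "w_II", "w_III", "trend"]
        subnets = {t: nam.MonotoneSubnetwork(t, pd.DataFrame(columns=cols))
                   for t in ("I", "II", "III")}
        trips = nam.build_triplets(nets, subnets, ["v"])
        assert trips[0].degrees == {"I": 0, "II": 0, "III": 0}

    def test_growing_planted_star_recovered(self):
        # hub gains neighbors with stage: star sizes must be non-decreasing
        from gcmet import synthetic_data as sd
        cat = sd.default_metabolite_catalog(30, sd.DEFAULT_CLASS_PROPORTIONS)
        ids = [m.metabolite_id for m in cat
               if m.internal_standard_id != m.metabolite_id]
        hub, partners = ids[0], ids[1:7]
        # co-regulated block around the hub grows and tightens with stage:
        # 3 → 5 → 7 members, correlation strengthening 0.2 → 0.45 → 0.7
        blocks = {"I": [hub] + partners[:2], "II": [hub] + partners[:4],
                  "III": [hub] + partners}
        strength = {"I": 0.2, "II": 0.45, "III": 0.7}
        edges = []
        for a, b in itertools.combinations([hub] + partners, 2):
            rho = tuple(strength[t] if a in blocks[t] and b in blocks[t] else 0.0
                        for t in ("I", "II", "III"))
            if any(rho):
                edges.append(sd.PlantedEdge((a, b), rho))
        cfg = sd.SyntheticConfig(
            n_patients=120, stage_counts={"I": 40, "II": 40, "III": 40},
            n_metabolites=30, corr_blocks=edges, effect_table=[], seed=6)
        pt, samples, mets, _ = sd.generate_cohort(cfg)
        norm = cd.normalize_intensities(pt, samples, mets)
        tissue = [s for s in samples if not s.is_qc]
        tp = norm.subset_samples([s.sample_id for s in tissue])
        nets, subnets, hub_t, hubs, trips = nam.run_nam(tp, tissue)
        assert hub in hubs
        tri = next(t for t in trips if t.hub == hub)
        sizes = [tri.degrees[t] for t in ("I", "II", "III")]
        assert sizes[0] <= sizes[1] <= sizes[2]
        assert sizes[2] >= 4
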