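"""Stage-wise monotone network topology analysis of tumor progression.

The method traces how metabolite-metabolite association structure rewires
across ordered disease stages (TNM I, II, III).  Per stage t a weighted
network G_t on the common metabolite set is built from tumor-tissue
samples: an edge carries weight w_t = Spearman rho when the stage-t
correlation is significant (p < 0.01), and w_t = 0 otherwise.

From each G_t the monotone subnetwork SG_t keeps the edges of G_t whose
weight triple (w_I, w_II, w_III) changes monotonically across stages —
with adjacent-stage changes of at most 0.02 treated as equality — and
moves by more than 0.05 in at least one adjacent stage pair.  Nodes are
ranked by degree within SG_t; the union of the per-stage top-15 hub sets
gives the important nodes, and for each hub v the informative triplet
Tri(v) = (star of v in SG_I, SG_II, SG_III) displays how v's neighborhood
grows or dissolves with progression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core_data import PeakTable, SampleRecord
from .diffcorr import spearman_matrix

DEFAULT_STAGES = ("I", "II", "III")


@dataclass
class StageNetworkSet:
    stages: tuple[str, ...]
    weights: dict[str, pd.DataFrame]   # stage -> signed weight matrix (0 = absent)
    n_samples: dict[str, int]
    metabolite_ids: list[str]
    alpha: float
    adjacent_reference: pd.DataFrame | None = None  # same convention, adjacent tissue

    def weight_triple(self, a: str, b: str) -> tuple[float, ...]:
        return tuple(float(self.weights[t].loc[a, b]) for t in self.stages)


@dataclass
class MonotoneSubnetwork:
    stage: str
    edges: pd.DataFrame  # metabolite_a, metabolite_b, w_I, w_II, w_III, trend

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for _, e in self.edges.iterrows():
            g.add_edge(e["metabolite_a"], e["metabolite_b"], trend=e["trend"])
        return g

    def degrees(self) -> pd.Series:
        g = self.graph()
        return pd.Series({n: d for n, d in g.degree()}, dtype=int).sort_values(
            ascending=False)


@dataclass
class TripletResult:
    hub: str
    stars: dict[str, pd.DataFrame]  # stage -> incident edges (neighbor, weight, sign)
    degrees: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Stage networks
# ---------------------------------------------------------------------------


def build_stage_networks(
    pt: PeakTable,
    samples: list[SampleRecord],
    alpha: float = 0.01,
    stages: tuple[str, ...] = DEFAULT_STAGES,
    min_samples: int = 5,
    include_adjacent_reference: bool = True,
) -> StageNetworkSet:
    """Per-stage significant-Spearman networks on tumor-tissue samples.

    Stages with fewer than ``min_samples`` tumor samples are excluded with a
    warning (rank correlations are meaningless at such sizes).  The adjacent
    tissue network, built with the same rule over all adjacent samples, is
    attached as a display reference and plays no role in extraction.
    """
    available = sorted({s.tnm_stage for s in samples if s.tissue_type == "tumor"})
    usable = []
    for t in stages:
        sids = [s.sample_id for s in samples
                if s.tissue_type == "tumor" and s.tnm_stage == t]
        if not sids:
            raise ValueError(f"stage {t!r} absent from metadata; available: {available}")
        if len(sids) < min_samples:
            warnings.warn(f"stage {t!r} has {len(sids)} tumor samples (<{min_samples}); excluded")
            continue
        usable.append((t, sids))
    if not usable:
        raise ValueError("no stage has enough tumor samples")

    weights: dict[str, pd.DataFrame] = {}
    n_samples: dict[str, int] = {}
    for t, sids in usable:
        cm = spearman_matrix(pt.data.loc[sids], group=f"TNM_{t}")
        w = cm.rho.where(cm.p < alpha, other=0.0).fillna(0.0)
        np.fill_diagonal(w.to_numpy(), 0.0)
        weights[t] = w
        n_samples[t] = cm.n

    adjacent_ref = None
    if include_adjacent_reference:
        adj_ids = [s.sample_id for s in samples if s.tissue_type == "adjacent"]
        if len(adj_ids) >= min_samples:
            cm = spearman_matrix(pt.data.loc[adj_ids], group="adjacent")
            adjacent_ref = cm.rho.where(cm.p < alpha, other=0.0).fillna(0.0)
            np.fill_diagonal(adjacent_ref.to_numpy(), 0.0)

    return StageNetworkSet(
        stages=tuple(t for t, _ in usable),
        weights=weights,
        n_samples=n_samples,
        metabolite_ids=pt.metabolite_ids,
        alpha=alpha,
        adjacent_reference=adjacent_ref,
    )


# ---------------------------------------------------------------------------
# Monotone edge predicate
# ---------------------------------------------------------------------------


def monotone_edge_predicate(
    w_triple,
    diff_min: float = 0.05,
    equal_tol: float = 0.02,
    strict: bool = False,
) -> str:
    """Classify a stage-weight triple as 'increasing', 'decreasing' or 'reject'.

    A triple is monotone decreasing when each stage-to-stage step goes down,
    allowing steps that go *up* by at most ``equal_tol`` to count as equal
    (mirrored for increasing); ``strict=True`` drops that tolerance.  In
    addition at least one adjacent-stage difference must exceed ``diff_min``
    in absolute value, so near-flat trajectories are rejected.  Evaluated on
    signed weights.  Both orders can only hold simultaneously when every
    step lies within ``equal_tol``, which the ``diff_min`` condition already
    excludes whenever diff_min ≥ equal_tol, so the verdict is unambiguous.
    """
    w = [float(x) for x in w_triple]
    diffs = [w[i + 1] - w[i] for i in range(len(w) - 1)]
    if not any(abs(d) > diff_min for d in diffs):
        return "reject"
    tol = 0.0 if strict else equal_tol
    if all(d >= -tol for d in diffs) and all(d <= tol for d in diffs):
        # every step within tolerance of equality: direction is not defined,
        # but diff_min already excludes this when diff_min >= tol
        return "reject"
    if all(d >= -tol for d in diffs):
        return "increasing"
    if all(d <= tol for d in diffs):
        return "decreasing"
    return "reject"


# ---------------------------------------------------------------------------
# Monotone subnetwork extraction
# ---------------------------------------------------------------------------


def extract_monotone_subnetworks(
    nets: StageNetworkSet,
    diff_min: float = 0.05,
    equal_tol: float = 0.02,
    strict: bool = False,
) -> dict[str, MonotoneSubnetwork]:
    """SG_t per stage: edges of G_t whose weight triple is accepted.

    Membership requires both the accepted monotone triple and presence of
    the edge in G_t (w_t ≠ 0), so the three subnetworks generally differ.
    """
    mids = nets.metabolite_ids
    m = len(mids)
    W = np.stack([nets.weights[t].to_numpy() for t in nets.stages])  # stages × m × m
    rows_per_stage: dict[str, list] = {t: [] for t in nets.stages}
    iu, ju = np.triu_indices(m, k=1)
    for i, j in zip(iu, ju):
        triple = W[:, i, j]
        if not np.any(triple != 0):
            continue
        verdict = monotone_edge_predicate(triple, diff_min, equal_tol, strict)
        if verdict == "reject":
            continue
        for s_idx, t in enumerate(nets.stages):
            if triple[s_idx] != 0:
                rows_per_stage[t].append(
                    {
                        "metabolite_a": mids[i],
                        "metabolite_b": mids[j],
                        **{f"w_{st}": float(triple[k])
                           for k, st in enumerate(nets.stages)},
                        "trend": verdict,
                    }
                )
    cols = ["metabolite_a", "metabolite_b",
            *[f"w_{t}" for t in nets.stages], "trend"]
    return {
        t: MonotoneSubnetwork(stage=t, edges=pd.DataFrame(rows_per_stage[t], columns=cols))
        for t in nets.stages
    }


# ---------------------------------------------------------------------------
# Hubs and triplets
# ---------------------------------------------------------------------------


def select_hubs(
    subnets: dict[str, MonotoneSubnetwork], k: int = 15
) -> tuple[dict[str, list[str]], list[str]]:
    """Top-k degree nodes per stage subnetwork, ties at the cutoff included.

    Returns (per-stage hub lists, union across stages).  Only nodes with
    positive degree are eligible; if fewer than k exist they are all
    returned with a warning.
    """
    hub_t: dict[str, list[str]] = {}
    for t, sg in subnets.items():
        deg = sg.degrees()
        if deg.empty:
            warnings.warn(f"stage {t!r}: monotone subnetwork is empty; no hubs")
            hub_t[t] = []
            continue
        if len(deg) <= k:
            if len(deg) < k:
                warnings.warn(
                    f"stage {t!r}: only {len(deg)} positive-degree nodes (< k={k})")
            hub_t[t] = sorted(deg.index)
            continue
        cutoff = deg.sort_values(ascending=False).iloc[k - 1]
        hub_t[t] = sorted(deg[deg >= cutoff].index)
    union = sorted(set().union(*hub_t.values())) if hub_t else []
    return hub_t, union


def build_triplets(
    nets: StageNetworkSet,
    subnets: dict[str, MonotoneSubnetwork],
    hubs: list[str],
) -> list[TripletResult]:
    """Informative star-subgraph triplet Tri(v) for every hub v.

    Per stage the star holds v's incident edges in SG_t with the Spearman
    weight and its sign (positive/negative correlation).
    """
    results = []
    for v in hubs:
        stars: dict[str, pd.DataFrame] = {}
        degrees: dict[str, int] = {}
        for t in nets.stages:
            e = subnets[t].edges
            inc = e[(e["metabolite_a"] == v) | (e["metabolite_b"] == v)]
            neighbors = np.where(inc["metabolite_a"] == v,
                                 inc["metabolite_b"], inc["metabolite_a"])
            w = inc[f"w_{t}"].to_numpy(dtype=float)
            stars[t] = pd.DataFrame(
                {
                    "neighbor": neighbors,
                    "weight": w,
                    "sign": np.where(w >= 0, "positive", "negative"),
                    "trend": inc["trend"].to_numpy(),
                }
            ).sort_values("neighbor").reset_index(drop=True)
            degrees[t] = len(stars[t])
        results.append(TripletResult(hub=v, stars=stars, degrees=degrees))
    return results


def run_nam(
    pt: PeakTable,
    samples: list[SampleRecord],
    alpha: float = 0.01,
    diff_min: float = 0.05,
    equal_tol: float = 0.02,
    hub_k: int = 15,
    stages: tuple[str, ...] = DEFAULT_STAGES,
    strict: bool = False,
):
    """Full stage-wise pipeline: networks → monotone subnetworks → hubs → triplets."""
    nets = build_stage_networks(pt, samples, alpha=alpha, stages=stages)
    subnets = extract_monotone_subnetworks(nets, diff_min, equal_tol, strict)
    hub_t, hubs = select_hubs(subnets, k=hub_k)
    triplets = build_triplets(nets, subnets, hubs)
    return nets, subnets, hub_t, hubs, triplets
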