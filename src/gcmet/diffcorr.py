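"""Differential Spearman-correlation network between tumor and adjacent tissue.

Each group's metabolite-metabolite association structure is summarized by a
Spearman correlation matrix.  For every metabolite pair the two coefficients
are compared on the Fisher-z scale,

    z = (atanh(rho_A) - atanh(rho_B)) / sqrt(1/(n_A - 3) + 1/(n_B - 3)),

which is approximately standard normal under equal population correlation.
Pairs surviving Benjamini-Hochberg FDR form an undirected differential
network whose connected components are the rewired modules and whose
degree ranking points at hub metabolites.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .univariate import bh_fdr


@dataclass
class CorrelationMatrix:
    group: str
    n: int
    rho: pd.DataFrame
    p: pd.DataFrame

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.rho.columns)


# ---------------------------------------------------------------------------
# Spearman matrix
# ---------------------------------------------------------------------------


def spearman_matrix(X, metabolite_ids=None, group: str = "",
                    exact_n_max: int = 8) -> CorrelationMatrix:
    """All-pairs Spearman correlation of the columns of ``X``.

    rho is the Pearson correlation of average-ranked columns (ties allowed).
    p-values come from the t approximation t = rho·sqrt((n-2)/(1-rho²));
    for n ≤ ``exact_n_max`` the exact permutation null over all n! rank
    orderings is enumerated instead.  Constant columns yield NaN for their
    pairs, with a warning.
    """
    if isinstance(X, pd.DataFrame):
        metabolite_ids = list(X.columns)
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    if metabolite_ids is None:
        metabolite_ids = [f"m{j}" for j in range(m)]

    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    sd = ranks.std(axis=0)
    constant = sd == 0
    if constant.any():
        bad = [metabolite_ids[j] for j in np.flatnonzero(constant)]
        warnings.warn(f"constant columns (rho undefined): {bad}")
    centered = ranks - ranks.mean(axis=0)
    denom = np.sqrt((centered**2).sum(axis=0))
    denom[constant] = np.nan
    rho = (centered.T @ centered) / np.outer(denom, denom)
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)

    if n <= exact_n_max:
        p = _exact_spearman_p_matrix(ranks, rho, constant)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        p[np.abs(rho) >= 1.0] = 0.0
        p[np.isnan(rho)] = np.nan
    np.fill_diagonal(p, np.nan)

    idx = pd.Index(metabolite_ids)
    return CorrelationMatrix(
        group=group, n=n,
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
    )


def _exact_spearman_p_matrix(ranks: np.ndarray, rho: np.ndarray,
                             constant: np.ndarray) -> np.ndarray:
    """Exact two-sided permutation p for every pair (small n only).

    Under the null every ordering of one variable's ranks is equally likely;
    the permutation distribution is enumerated once per pair using the
    observed (tie-averaged) rank vectors.
    """
    n, m = ranks.shape
    perms = np.array(list(itertools.permutations(range(n))))
    p = np.full((m, m), np.nan)
    std = {}
    for j in range(m):
        if constant[j]:
            continue
        c = ranks[:, j] - ranks[:, j].mean()
        std[j] = c / np.linalg.norm(c)
    for i, j in itertools.combinations(range(m), 2):
        if constant[i] or constant[j]:
            continue
        # correlation of x with every permutation of y
        perm_rho = std[i] @ std[j][perms].T
        p[i, j] = p[j, i] = float((np.abs(perm_rho) >= abs(rho[i, j]) - 1e-12).mean())
    return p


# ---------------------------------------------------------------------------
# Fisher-z differential test
# ---------------------------------------------------------------------------


def diffcorr_test(rho_a: float, n_a: int, rho_b: float, n_b: int,
                  fieller: bool = False) -> tuple[float, float]:
    """Fisher-z test of rho_a (group A, n_a samples) vs rho_b (group B).

    ``fieller`` switches the variance from 1/(n-3) to the Fieller correction
    1.06/(n-3) sometimes used for Spearman coefficients.
    """
    if n_a <= 3 or n_b <= 3:
        raise ValueError("need n > 3 in both groups")
    for r in (rho_a, rho_b):
        if not -1 < r < 1:
            raise ValueError(f"|rho| must be < 1, got {r}")
    c = 1.06 if fieller else 1.0
    se = math.sqrt(c / (n_a - 3) + c / (n_b - 3))
    z = (math.atanh(rho_a) - math.atanh(rho_b)) / se
    p = 2 * stats.norm.sf(abs(z))
    return z, p


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------


def build_differential_network(
    X_a, X_b, metabolite_ids=None,
    fdr_threshold: float = 0.05,
    group_labels: tuple[str, str] = ("adjacent", "tumor"),
    fieller: bool = False,
):
    """Differential correlation network between two sample groups.

    Every metabolite pair is tested with the Fisher-z statistic; edges with
    BH-FDR below ``fdr_threshold`` are kept.  Edge ``direction`` records
    whether correlation increased ('gain') or decreased ('loss') from group
    A to group B.  Returns (edge DataFrame of all tested pairs, graph of
    surviving edges, modules as node lists, degree table).
    """
    cm_a = spearman_matrix(X_a, metabolite_ids, group=group_labels[0])
    cm_b = spearman_matrix(X_b, metabolite_ids, group=group_labels[1])
    if cm_a.metabolite_ids != cm_b.metabolite_ids:
        raise ValueError("metabolite sets differ between groups")
    mids = cm_a.metabolite_ids
    rows = []
    for i, j in itertools.combinations(range(len(mids)), 2):
        ra = cm_a.rho.iat[i, j]
        rb = cm_b.rho.iat[i, j]
        if np.isnan(ra) or np.isnan(rb):
            continue
        ra_c = float(np.clip(ra, -0.999999, 0.999999))
        rb_c = float(np.clip(rb, -0.999999, 0.999999))
        z, p = diffcorr_test(ra_c, cm_a.n, rb_c, cm_b.n, fieller=fieller)
        rows.append(
            {
                "metabolite_a": mids[i],
                "metabolite_b": mids[j],
                f"rho_{group_labels[0]}": ra,
                f"rho_{group_labels[1]}": rb,
                "z": z,
                "p_value": p,
                "direction": "gain" if rb > ra else "loss",
            }
        )
    edges = pd.DataFrame(rows)
    if len(edges):
        edges["fdr"] = bh_fdr(edges["p_value"].to_numpy())
    else:
        edges["fdr"] = pd.Series(dtype=float)

    graph = nx.Graph()
    graph.add_nodes_from(mids)
    kept = edges[edges["fdr"] < fdr_threshold] if len(edges) else edges
    for _, e in kept.iterrows():
        graph.add_edge(e["metabolite_a"], e["metabolite_b"],
                       z=e["z"], fdr=e["fdr"], direction=e["direction"])
    modules = [sorted(c) for c in nx.connected_components(graph) if len(c) > 1]
    modules.sort(key=len, reverse=True)
    degree = (
        pd.DataFrame(
            {"metabolite_id": mids, "degree": [graph.degree[m] for m in mids]}
        )
        .sort_values(["degree", "metabolite_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    degree["rank"] = degree["degree"].rank(method="min", ascending=False).astype(int)
    return edges, graph, modules, degree
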