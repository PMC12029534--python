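"""Independent brute-force re-implementation of the stage-wise extraction rules.

Shared by the unit and acceptance suites; deliberately written with plain
loops and scipy's pairwise Spearman so it stays independent of the package's
vectorized implementation path.
"""

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from gcmet import core_data as cd
from gcmet import nam


def brute_force_nam(stage_values, alpha=0.01, diff_min=0.05, equal_tol=0.02, k=15):
    """Literal per-pair re-check of the stage-network extraction rules.

    ``stage_values``: dict stage -> samples × metabolites DataFrame.
    Returns (per-stage edge sets, per-stage hub sets) computed with scipy's
    pairwise Spearman, plain python loops, and explicit condition checks.
    """
    stages = list(stage_values)
    mids = list(stage_values[stages[0]].columns)
    w = {}
    for t in stages:
        X = stage_values[t]
        wt = {}
        for a, b in itertools.combinations(mids, 2):
            res = stats.spearmanr(X[a], X[b])
            wt[(a, b)] = res.statistic if res.pvalue < alpha else 0.0
        w[t] = wt
    sg = {t: set() for t in stages}
    for pair in itertools.combinations(mids, 2):
        triple = [w[t][pair] for t in stages]
        d1, d2 = triple[1] - triple[0], triple[2] - triple[1]
        if not (abs(d1) > diff_min or abs(d2) > diff_min):
            continue
        inc = d1 >= -equal_tol and d2 >= -equal_tol
        dec = d1 <= equal_tol and d2 <= equal_tol
        if not (inc or dec):
            continue
        for t in stages:
            if w[t][pair] != 0.0:
                sg[t].add(pair)
    hubs = {}
    for t in stages:
        deg = {}
        for a, b in sg[t]:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        if not deg:
            hubs[t] = set()
            continue
        ranked = sorted(deg.values(), reverse=True)
        cutoff = ranked[min(k, len(ranked)) - 1]
        hubs[t] = {n for n, d in deg.items() if d >= cutoff}
    return sg, hubs


def _stage_networks_from_values(stage_values, alpha=0.01):
    """Build a StageNetworkSet via the package path from per-stage matrices."""
    frames = []
    samples = []
    for t, X in stage_values.items():
        X = X.copy()
        X.index = [f"{t}_{i}_T" for i in range(len(X))]
        frames.append(X)
        samples += [cd.SampleRecord(sid, f"{t}_{i}", "tumor", 10.0, t)
                    for i, sid in enumerate(X.index)]
    pt = cd.PeakTable(pd.concat(frames), normalized=True)
    return nam.build_stage_networks(pt, samples, alpha=alpha,
                                    include_adjacent_reference=False)


def random_instance(rng, n_mets=8, n_per_stage=15):
    mids = [f"m{j}" for j in range(n_mets)]
    stage_values = {}
    base = rng.standard_normal((n_per_stage, n_mets))
    for t in ("I", "II", "III"):
        X = rng.standard_normal((n_per_stage, n_mets))
        # mix in shared structure so some correlations are significant
        lam = rng.uniform(0, 0.9)
        mixed = lam * base[:, rng.permutation(n_mets)] + (1 - lam) * X
        stage_values[t] = pd.DataFrame(mixed, columns=mids)
    return stage_values


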