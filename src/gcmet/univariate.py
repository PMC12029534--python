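"""Nonparametric differential testing, FDR, clinical associations, enrichment.

Paired tumor-vs-adjacent screening uses the Wilcoxon signed-rank test on
per-patient differences; associations of differential metabolites with
binary clinical contrasts use the Mann-Whitney rank-sum test.  Both tests
switch between exact small-sample enumeration and the tie-corrected normal
approximation; the exact branch enumerates the full permutation null (sign
assignments, or group relabelings) so it remains valid under tied values,
which textbook exact tables do not cover.

Pathway over-representation is the upper-tail hypergeometric test of the
overlap between a selected metabolite set and user-supplied pathway sets,
with Benjamini-Hochberg FDR across pathways.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_data import PeakTable, SampleRecord, paired_patient_samples

EXACT_N_MAX = 12  # switchover from enumeration to the normal approximation


@dataclass
class DifferentialResult:
    metabolite_id: str
    n_pairs: int
    statistic: float
    p_value: float
    log2_fold_change: float
    fdr: float = np.nan

    @property
    def direction(self) -> str:
        return "up" if self.log2_fold_change >= 0 else "down"


@dataclass
class EnrichmentResult:
    pathway_id: str
    pathway_size: int
    overlap_count: int
    universe_size: int
    selected_count: int
    p_value: float
    fdr: float = np.nan
    members: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (paired)
# ---------------------------------------------------------------------------


def paired_wilcoxon(tumor, adjacent, exact_n_max: int = EXACT_N_MAX) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped (Wilcoxon convention).  With at most
    ``exact_n_max`` non-zero differences the p-value is computed by
    enumerating all 2^n sign assignments of the (tie-averaged) ranks;
    beyond that the tie-corrected normal approximation is used.

    Returns (W, p) where W is the positive-rank sum.
    """
    tumor = np.asarray(tumor, dtype=float)
    adjacent = np.asarray(adjacent, dtype=float)
    if tumor.shape != adjacent.shape:
        raise ValueError(f"length mismatch: {tumor.shape} vs {adjacent.shape}")
    d = tumor - adjacent
    d = d[~np.isnan(d)]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_n_max:
        p = _signed_rank_exact_p(ranks, w_pos)
    else:
        # scipy handles the tie-corrected normal approximation
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.wilcoxon(d, zero_method="wilcox", correction=False,
                                 alternative="two-sided", method="approx")
        p = float(res.pvalue)
    return w_pos, p


def _signed_rank_exact_p(ranks: np.ndarray, w_obs: float) -> float:
    """Exact two-sided p by enumerating every sign assignment of the ranks."""
    n = len(ranks)
    # all 2^n subset sums of the rank vector
    signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
    sums = signs @ ranks
    p_le = float((sums <= w_obs + 1e-12).mean())
    p_ge = float((sums >= w_obs - 1e-12).mean())
    return min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# Mann-Whitney rank-sum (unpaired)
# ---------------------------------------------------------------------------


def mannwhitney_association(values, group_labels,
                            exact_n_max: int = EXACT_N_MAX) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of ``values`` between two label groups.

    Exact enumeration over all C(n, n1) group relabelings when the total
    sample size is at most ``exact_n_max``; otherwise the tie-corrected
    normal approximation.  Returns (U, p) with U counted for the first group.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    x = values[labels == levels[0]]
    y = values[labels == levels[1]]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("a group is empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if np.all(pooled == pooled[0]):  # fully tied: no evidence either way
        return u1, 1.0
    if n1 + n2 <= exact_n_max:
        p = _mannwhitney_exact_p(ranks, n1, u1)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic", use_continuity=False)
        p = float(res.pvalue)
    return u1, p


def _mannwhitney_exact_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact two-sided p over all choices of which ranks form group 1."""
    n = len(ranks)
    offset = n1 * (n1 + 1) / 2
    us = np.array([
        sum(ranks[list(idx)]) - offset
        for idx in itertools.combinations(range(n), n1)
    ])
    p_le = float((us <= u_obs + 1e-12).mean())
    p_ge = float((us >= u_obs - 1e-12).mean())
    return min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR
# ---------------------------------------------------------------------------


def bh_fdr(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input.

    ``method`` may be 'fdr_bh' (default) or 'fdr_by' for the
    Benjamini-Yekutieli variant.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


# ---------------------------------------------------------------------------
# Differential screen
# ---------------------------------------------------------------------------


def differential_analysis(
    pt: PeakTable,
    samples: list[SampleRecord],
    fdr_method: str = "fdr_bh",
) -> list[DifferentialResult]:
    """Paired Wilcoxon screen of every metabolite, tumor vs adjacent.

    log2 fold change is log2 of the median per-pair tumor/adjacent ratio.
    """
    pairs = paired_patient_samples(samples)
    if not pairs:
        raise ValueError("no tumor/adjacent pairs in metadata")
    t_ids = [t for _, t, _ in pairs]
    a_ids = [a for _, _, a in pairs]
    tum = pt.data.loc[t_ids].to_numpy()
    adj = pt.data.loc[a_ids].to_numpy()
    results = []
    for j, mid in enumerate(pt.metabolite_ids):
        tv, av = tum[:, j], adj[:, j]
        ok = ~np.isnan(tv) & ~np.isnan(av)
        w, p = paired_wilcoxon(tv[ok], av[ok])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = tv[ok] / av[ok]
        ratio = ratio[np.isfinite(ratio) & (ratio > 0)]
        l2fc = float(np.log2(np.median(ratio))) if len(ratio) else np.nan
        results.append(DifferentialResult(mid, int(ok.sum()), w, p, l2fc))
    qs = bh_fdr([r.p_value for r in results], method=fdr_method)
    for r, q in zip(results, qs):
        r.fdr = float(q)
    return results


def differential_table(results: list[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metabolite_id": [r.metabolite_id for r in results],
            "n_pairs": [r.n_pairs for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "log2_fold_change": [r.log2_fold_change for r in results],
            "direction": [r.direction for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Clinical associations
# ---------------------------------------------------------------------------


def clinical_association_scan(
    pt: PeakTable,
    samples: list[SampleRecord],
    differential: list[DifferentialResult],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mann-Whitney scan of differential metabolites against clinical indices.

    Multi-level indices are expanded into all pairwise binary contrasts on
    tumor-tissue values.  Returns one row per (metabolite, index, contrast)
    with the p-value and a significance flag; the per-index count of flagged
    metabolites supports ranking indices by how many metabolites track them.
    """
    if not differential:
        return pd.DataFrame(
            columns=["metabolite_id", "clinical_index", "contrast", "p_value", "significant"]
        )
    tumor = [s for s in samples if s.tissue_type == "tumor"]
    index_names = sorted({k for s in tumor for k in s.clinical_indices})
    met_ids = [r.metabolite_id for r in differential]
    rows = []
    for index_name in index_names:
        labeled = [(s.sample_id, s.clinical_indices[index_name])
                   for s in tumor if index_name in s.clinical_indices]
        levels = sorted({lv for _, lv in labeled})
        if len(levels) < 2:
            warnings.warn(f"clinical index {index_name!r} has a single level; skipped")
            continue
        for lv_a, lv_b in itertools.combinations(levels, 2):
            sel = [(sid, lv) for sid, lv in labeled if lv in (lv_a, lv_b)]
            sids = [sid for sid, _ in sel]
            labs = np.array([lv for _, lv in sel])
            sub = pt.data.loc[sids, met_ids]
            for mid in met_ids:
                vals = sub[mid].to_numpy()
                ok = ~np.isnan(vals)
                if ok.sum() < 2 or len(set(labs[ok])) < 2:
                    continue
                _, p = mannwhitney_association(vals[ok], labs[ok])
                rows.append(
                    {
                        "metabolite_id": mid,
                        "clinical_index": index_name,
                        "contrast": f"{lv_a} vs {lv_b}",
                        "p_value": p,
                        "significant": p < alpha,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hypergeometric over-representation
# ---------------------------------------------------------------------------


def hypergeometric_enrichment(
    selected,
    pathways: dict[str, set],
    universe,
    min_pathway_size: int = 1,
    fdr_method: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation of ``selected`` in each pathway.

    Pathway sets are intersected with the universe first; p is the probability
    of an overlap at least as large as observed when ``selected_count`` draws
    are made from the universe without replacement.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected:
        raise ValueError("selected metabolite set is empty")
    if not selected <= universe:
        raise ValueError(f"selected ids outside universe: {sorted(selected - universe)}")
    results = []
    for pid, members in pathways.items():
        in_universe = set(members) & universe
        if len(in_universe) < min_pathway_size:
            continue
        overlap = in_universe & selected
        p = float(stats.hypergeom.sf(
            len(overlap) - 1, len(universe), len(in_universe), len(selected)
        ))
        results.append(
            EnrichmentResult(
                pathway_id=pid,
                pathway_size=len(in_universe),
                overlap_count=len(overlap),
                universe_size=len(universe),
                selected_count=len(selected),
                p_value=min(1.0, p),
                members=sorted(overlap),
            )
        )
    qs = bh_fdr([r.p_value for r in results], method=fdr_method)
    for r, q in zip(results, qs):
        r.fdr = float(q)
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results


def read_gmt(path) -> dict[str, set]:
    """Read pathway sets from a GMT file (id, description, members per line)."""
    pathways: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pathways[parts[0]] = set(parts[2:])
    return pathways
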