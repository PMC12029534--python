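"""Biomarker evaluation: patient-level discovery/validation split, ROC, marker combination.

Patients (not samples) are split at a 4:1 ratio so tumor/adjacent pairs
never straddle the sets.  Candidate markers are ranked by their paired-test
p-value computed on the discovery set only; single markers and a
two-marker logistic combination are scored by ROC AUC on both sets, with
the operating threshold chosen as the Youden-optimal point on discovery
and applied unchanged to validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import PeakTable, SampleRecord, paired_patient_samples
from .univariate import DifferentialResult


@dataclass
class SplitSpec:
    seed: int | None
    ratio: float  # discovery fraction, e.g. 0.8 for 4:1
    assignment: dict[str, str]  # patient_id -> 'discovery' | 'validation'

    def patients(self, which: str) -> list[str]:
        return [p for p, w in self.assignment.items() if w == which]


@dataclass
class RocResult:
    markers: list[str]
    auc_discovery: float
    auc_validation: float
    threshold: float
    sensitivity_discovery: float
    specificity_discovery: float
    sensitivity_validation: float
    specificity_validation: float
    coefficients: dict = field(default_factory=dict)
    fallback_ranked: bool = False


# ---------------------------------------------------------------------------
# Split
# ---------------------------------------------------------------------------


def split_patients(samples: list[SampleRecord], ratio: float = 0.8,
                   seed: int | None = 0) -> SplitSpec:
    """Random patient-level split into discovery and validation sets.

    ``ratio`` is the discovery fraction (0.8 = the 4:1 split).  The number
    of validation patients is round((1-ratio)·n); assignment is a uniform
    random choice, deterministic given the seed.
    """
    pairs = paired_patient_samples(samples)
    patients = [pid for pid, _, _ in pairs]
    if len(patients) < 5:
        raise ValueError(f"need at least 5 paired patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    n_val = int(round((1 - ratio) * len(patients)))
    n_val = max(1, min(n_val, len(patients) - 1))
    val = set(rng.choice(patients, size=n_val, replace=False).tolist())
    assignment = {p: ("validation" if p in val else "discovery") for p in patients}
    return SplitSpec(seed=seed, ratio=ratio, assignment=assignment)


def split_table(split: SplitSpec) -> pd.DataFrame:
    return pd.DataFrame(
        {"patient_id": list(split.assignment), "set": list(split.assignment.values())}
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def roc_auc(scores, labels) -> float:
    """Pair-counting AUC: (concordant + 0.5·tied) / (n_pos · n_neg).

    Computed through the Mann-Whitney U identity on rank sums, which handles
    ties exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC coordinates (FPR, TPR, threshold) over unique score cuts."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    n_pos, n_neg = y.sum(), (~y).sum()
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    last = np.r_[np.diff(s) != 0, True]
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    thr = np.r_[np.inf, s[last]]
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


def youden_threshold(scores, labels) -> float:
    """Score cut maximizing Youden's J = sensitivity + specificity − 1."""
    pts = roc_curve_points(scores, labels)
    j = pts["tpr"] - pts["fpr"]
    return float(pts["threshold"].iloc[int(j.to_numpy().argmax())])


def _sens_spec(scores, labels, threshold) -> tuple[float, float]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pred = scores >= threshold
    sens = float((pred & labels).sum() / labels.sum())
    spec = float((~pred & ~labels).sum() / (~labels).sum())
    return sens, spec


# ---------------------------------------------------------------------------
# Marker ranking and combination
# ---------------------------------------------------------------------------


def rank_markers(differential: list[DifferentialResult], top_k: int = 10) -> list[str]:
    """Ascending-p ranking; ties broken by |log2FC| descending, then id."""
    ordered = sorted(
        differential,
        key=lambda r: (r.p_value, -abs(r.log2_fold_change)
                       if np.isfinite(r.log2_fold_change) else 0.0, r.metabolite_id),
    )
    return [r.metabolite_id for r in ordered[:top_k]]


def _marker_matrix(pt: PeakTable, sample_ids, marker_ids) -> np.ndarray:
    return pt.data.loc[list(sample_ids), list(marker_ids)].to_numpy()


def combine_markers(
    pt: PeakTable,
    samples: list[SampleRecord],
    split: SplitSpec,
    marker_ids: list[str],
) -> RocResult:
    """Logistic combination of markers fitted on the discovery set only.

    Markers are auto-scaled with discovery-set centers/scales; the score is
    the logistic linear predictor.  Under perfect separation the maximum
    likelihood estimate diverges, so the score falls back to the sum of
    rank-standardized markers oriented by their discovery AUC, with a
    warning.  Validation samples never influence the fit or the threshold.
    """
    missing = [m for m in marker_ids if m not in pt.data.columns]
    if missing:
        raise ValueError(f"markers not in peak table: {missing}")
    pairs = paired_patient_samples(samples)
    by_set: dict[str, tuple[list[str], list[int]]] = {
        "discovery": ([], []), "validation": ([], [])}
    for pid, t_sid, a_sid in pairs:
        which = split.assignment.get(pid)
        if which is None:
            continue
        by_set[which][0].extend([t_sid, a_sid])
        by_set[which][1].extend([1, 0])
    disc_ids, y_disc = by_set["discovery"]
    val_ids, y_val = by_set["validation"]
    y_disc = np.array(y_disc)
    y_val = np.array(y_val)

    Xd = _marker_matrix(pt, disc_ids, marker_ids)
    Xv = _marker_matrix(pt, val_ids, marker_ids) if val_ids else np.empty((0, len(marker_ids)))
    center = Xd.mean(axis=0)
    scale = Xd.std(axis=0, ddof=1)
    scale[scale == 0] = 1.0
    Zd = (Xd - center) / scale
    Zv = (Xv - center) / scale

    coefs: dict = {}
    fallback = False
    try:
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y_disc, sm.add_constant(Zd)).fit(disp=False, maxiter=200)
        params = np.asarray(fit.params)
        converged = bool(fit.mle_retvals.get("converged", True))
        # a log-likelihood at (numerically) zero means the classes are
        # perfectly separated and the MLE diverges
        separated = fit.llf > -1e-6
        if not converged or separated or not np.all(np.isfinite(params)) \
                or np.max(np.abs(params)) > 50:
            raise np.linalg.LinAlgError("diverging coefficients")
        score_d = sm.add_constant(Zd) @ params
        score_v = sm.add_constant(Zv, has_constant="add") @ params if len(Zv) else np.array([])
        coefs = {"const": float(params[0]),
                 **{m: float(b) for m, b in zip(marker_ids, params[1:])}}
    except Exception:
        warnings.warn("perfect separation in logistic fit; falling back to ranked score")
        fallback = True
        signs = np.array([
            1.0 if roc_auc(Zd[:, j], y_disc) >= 0.5 else -1.0
            for j in range(Zd.shape[1])
        ])
        rank_d = np.column_stack([stats.rankdata(Zd[:, j]) for j in range(Zd.shape[1])])
        score_d = (rank_d * signs).sum(axis=1)
        if len(Zv):
            # validation scored against discovery empirical CDF, per marker
            score_v = np.zeros(len(Zv))
            for j in range(Zv.shape[1]):
                score_v += signs[j] * np.searchsorted(np.sort(Zd[:, j]), Zv[:, j])
        else:
            score_v = np.array([])

    thr = youden_threshold(score_d, y_disc)
    sens_d, spec_d = _sens_spec(score_d, y_disc, thr)
    if len(score_v):
        auc_v = roc_auc(score_v, y_val)
        sens_v, spec_v = _sens_spec(score_v, y_val, thr)
    else:
        auc_v = sens_v = spec_v = float("nan")
    return RocResult(
        markers=list(marker_ids),
        auc_discovery=roc_auc(score_d, y_disc),
        auc_validation=auc_v,
        threshold=thr,
        sensitivity_discovery=sens_d,
        specificity_discovery=spec_d,
        sensitivity_validation=sens_v,
        specificity_validation=spec_v,
        coefficients=coefs,
        fallback_ranked=fallback,
    )


def single_marker_roc(pt: PeakTable, samples: list[SampleRecord],
                      split: SplitSpec, marker_id: str) -> RocResult:
    """ROC of one marker (score = its measured value) on both sets."""
    return combine_markers(pt, samples, split, [marker_id])
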