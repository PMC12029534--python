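"""PLS-DA: NIPALS PLS1 on a ±1 class response, CV component selection, permutation validation.

Partial least squares-discriminant analysis projects the auto-scaled peak
table onto components that maximize covariance with the class response
(tumor = +1, adjacent = -1).  Components are extracted by NIPALS with
X-deflation; class prediction is the sign of the regression score.  The
number of components is chosen by stratified k-fold cross-validated Q2
(predictive R²), and model validity is assessed by a label-permutation test
whose p-value has the analytic floor 1/(B+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_data import PeakTable


@dataclass
class PlsdaModel:
    n_components: int
    weights: np.ndarray       # p × a
    loadings: np.ndarray      # p × a (X-loadings)
    y_loadings: np.ndarray    # a
    scores: np.ndarray        # n × a (training scores)
    coef: np.ndarray          # p, regression vector on scaled X
    x_mean: np.ndarray
    x_scale: np.ndarray
    classes: tuple            # labels encoded (+1, -1)
    keep: np.ndarray | None = None  # column mask when constant columns were dropped

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.keep is not None and X.shape[1] == len(self.keep):
            X = X[:, self.keep]
        return X

    def transform(self, X: np.ndarray) -> np.ndarray:
        Xs = (self._prepare(X) - self.x_mean) / self.x_scale
        T = np.empty((Xs.shape[0], self.n_components))
        E = Xs.copy()
        for a in range(self.n_components):
            t = E @ self.weights[:, a]
            T[:, a] = t
            E -= np.outer(t, self.loadings[:, a])
        return T

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = (self._prepare(X) - self.x_mean) / self.x_scale
        return Xs @ self.coef

    def predict(self, X: np.ndarray) -> np.ndarray:
        score = self.decision_function(X)
        pos, neg = self.classes
        return np.where(score >= 0, pos, neg)


@dataclass
class ComponentReport:
    """Per-component CV accuracy, R2Y and Q2, mirroring the usual PLS-DA diagnostics."""

    accuracy: list[float] = field(default_factory=list)
    r2y: list[float] = field(default_factory=list)
    q2: list[float] = field(default_factory=list)
    chosen: int = 0
    seed: int | None = None


@dataclass
class PermutationReport:
    n_permutations: int
    observed: float
    permuted: np.ndarray
    statistic: str
    seed: int | None = None

    @property
    def p_value(self) -> float:
        b = int(np.sum(self.permuted >= self.observed - 1e-12))
        return (b + 1) / (self.n_permutations + 1)


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------


def autoscale(X, ddof: int = 1) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mean-center and unit-variance scale each column (auto-scaling).

    Constant columns cannot be scaled and are dropped with a warning.
    Returns (scaled, centers, scales, kept_column_mask).
    """
    if isinstance(X, PeakTable):
        X = X.data.to_numpy()
    X = np.asarray(X, dtype=float)
    centers = X.mean(axis=0)
    scales = X.std(axis=0, ddof=ddof)
    keep = scales > 0
    if not keep.any():
        raise ValueError("all columns are constant; nothing to scale")
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant column(s) before scaling")
    Xs = (X[:, keep] - centers[keep]) / scales[keep]
    return Xs, centers[keep], scales[keep], keep


def encode_labels(y) -> tuple[np.ndarray, tuple]:
    """Encode a two-class label vector as ±1.

    Numeric labels map the larger value to +1 (so a vector that is already
    ±1 is preserved and subsetting never flips the encoding); other labels
    map the first class observed to +1.
    """
    y = np.asarray(y)
    classes: list = []
    for v in y.tolist():
        if v not in classes:
            classes.append(v)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if all(isinstance(c, (int, float)) for c in classes):
        classes.sort(reverse=True)
    enc = np.where(y == classes[0], 1.0, -1.0)
    return enc, (classes[0], classes[1])


# ---------------------------------------------------------------------------
# NIPALS PLS1
# ---------------------------------------------------------------------------


def fit_plsda(X, y, n_components: int, scaled: bool = False,
              ddof: int = 1) -> PlsdaModel:
    """Fit PLS1 to a ±1-encoded two-class response by NIPALS with X-deflation.

    For a single response NIPALS reduces to: weight w = X'y / ||X'y||,
    score t = Xw, X-loading p = X't / t't, y-loading q = y't / t't, then
    deflation X ← X − t p'.  The regression vector accumulates so that the
    decision score is a single linear map of scaled X.
    """
    X = np.asarray(X, dtype=float)
    y_enc, classes = encode_labels(y)
    keep_mask = None
    if scaled:
        Xs = X.copy()
        x_mean = np.zeros(X.shape[1])
        x_scale = np.ones(X.shape[1])
    else:
        Xs, x_mean, x_scale, keep = autoscale(X, ddof=ddof)
        if not keep.all():
            keep_mask = keep
    n, p = Xs.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components={n_components} exceeds rank of X")
    if min(n, p) <= 50:
        rank = np.linalg.matrix_rank(Xs)
        if n_components > rank:
            raise ValueError(f"n_components={n_components} exceeds rank {rank} of X")
    for cls in classes:
        if (np.asarray(y) == cls).sum() < n_components + 1:
            raise ValueError(f"class {cls!r} has fewer than n_components+1 samples")

    E = Xs.copy()
    f = y_enc - y_enc.mean()
    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    T = np.empty((n, n_components))
    q = np.empty(n_components)
    x_norm = np.linalg.norm(Xs)
    for a in range(n_components):
        if np.linalg.norm(E) < 1e-10 * max(x_norm, 1.0):
            raise ValueError(f"n_components={n_components} exceeds rank of X")
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError(f"component {a + 1}: residual X carries no covariance with y")
        w /= nw
        t = E @ w
        tt = t @ t
        pl = E.T @ t / tt
        q[a] = f @ t / tt
        E = E - np.outer(t, pl)
        W[:, a] = w
        P[:, a] = pl
        T[:, a] = t
    # B = W (P'W)^{-1} q  maps scaled X to the decision score
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PlsdaModel(
        n_components=n_components,
        weights=W,
        loadings=P,
        y_loadings=q,
        scores=T,
        coef=coef,
        x_mean=x_mean,
        x_scale=x_scale,
        classes=classes,
        keep=keep_mask,
    )


# ---------------------------------------------------------------------------
# Cross-validated component selection
# ---------------------------------------------------------------------------


def _stratified_folds(y_enc: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (1.0, -1.0):
        idx = np.flatnonzero(y_enc == cls)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(j)
    return [np.array(sorted(f)) for f in folds]


def select_components_cv(X, y, max_components: int = 5, k: int = 5,
                         seed: int | None = 0) -> ComponentReport:
    """Choose the component count by k-fold cross-validated Q2.

    Q2 = 1 − PRESS/TSS accumulated over stratified folds; the chosen count is
    the argmax of Q2.  Accuracy (CV misclassification complement) and
    training R2Y per component are reported alongside.
    """
    X = np.asarray(X, dtype=float)
    y_enc, _ = encode_labels(y)
    n_pos = int((y_enc == 1).sum())
    n_neg = int((y_enc == -1).sum())
    if k > min(n_pos, n_neg):
        raise ValueError(f"k={k} folds exceed the smallest class size {min(n_pos, n_neg)}")
    max_components = min(max_components, X.shape[1], X.shape[0] - 2)
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y_enc, k, rng)
    report = ComponentReport(seed=seed)
    tss = float(((y_enc - y_enc.mean()) ** 2).sum())
    for a in range(1, max_components + 1):
        press = 0.0
        correct = 0
        for fold in folds:
            mask = np.ones(len(y_enc), dtype=bool)
            mask[fold] = False
            try:
                model = fit_plsda(X[mask], y_enc[mask], a)
            except ValueError:
                press = np.inf
                break
            pred = model.decision_function(X[fold]) + y_enc[mask].mean()
            press += float(((y_enc[fold] - pred) ** 2).sum())
            correct += int((np.sign(pred) == y_enc[fold]).sum())
        q2 = 1.0 - press / tss if np.isfinite(press) else -np.inf
        full = fit_plsda(X, y_enc, a)
        fitted = full.decision_function(X) + y_enc.mean()
        r2y = 1.0 - float(((y_enc - fitted) ** 2).sum()) / tss
        report.q2.append(q2)
        report.r2y.append(r2y)
        report.accuracy.append(correct / len(y_enc))
    report.chosen = int(np.argmax(report.q2)) + 1
    return report


# ---------------------------------------------------------------------------
# Permutation validation
# ---------------------------------------------------------------------------


def permutation_test(X, y, n_permutations: int = 2000, n_components: int | None = None,
                     k: int = 5, seed: int | None = 0,
                     statistic: str = "q2") -> PermutationReport:
    """Label-permutation validation of the PLS-DA protocol.

    The observed statistic (cross-validated Q2 at the chosen component count,
    or CV accuracy with ``statistic='accuracy'``) is recomputed under
    ``n_permutations`` random relabelings; p = (#{permuted ≥ observed}+1)/(B+1),
    whose minimum attainable value is 1/(B+1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if statistic not in ("q2", "accuracy"):
        raise ValueError(f"unknown statistic {statistic!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)

    def stat_for(labels) -> float:
        rep = select_components_cv(
            X, labels, max_components=n_components or 3, k=k,
            seed=int(rng.integers(2**31 - 1)),
        )
        a = rep.chosen if n_components is None else min(n_components, len(rep.q2))
        return rep.q2[a - 1] if statistic == "q2" else rep.accuracy[a - 1]

    observed = stat_for(y)
    permuted = np.empty(n_permutations)
    for b in range(n_permutations):
        permuted[b] = stat_for(rng.permutation(y))
    return PermutationReport(
        n_permutations=n_permutations,
        observed=observed,
        permuted=permuted,
        statistic=statistic,
        seed=seed,
    )
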