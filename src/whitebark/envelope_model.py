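"""Presence/absence envelope classifier and its diagnostics.

The classifier is a random forest: a bagged ensemble of randomized
decision trees, each fit on a bootstrap resample of the plot samples
with a random covariate subset considered at every split.  Bagging is
implemented here (over scikit-learn decision trees) so the ensemble
exposes exactly the out-of-bag (OOB) machinery the diagnostics need:

* the OOB probability of a sample is the presence-vote fraction among
  the trees whose bootstrap did not contain it;
* permutation importance permutes one covariate within the OOB
  evaluations and reports the mean drop in OOB accuracy;
* the classification threshold is the point where the OOB true-positive
  rate equals the true-negative rate (sensitivity = specificity), found
  by linear interpolation on the score grid, reported alongside the
  Kappa and True Skill Statistic curves and the rank-statistic AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "EnvelopeModel",
    "ConfusionMatrix",
    "ThresholdDiagnostics",
    "fit_envelope",
    "oob_confusion",
    "permutation_importance",
    "roc_auc",
    "select_threshold",
    "cohen_kappa",
]


@dataclass
class EnvelopeModel:
    """A fitted bagged ensemble of randomized decision trees.

    ``oob_prob[i]`` is the fraction of presence votes among trees whose
    bootstrap excluded sample ``i`` (NaN for samples in every bootstrap,
    which is vanishingly rare at the default ensemble size).
    """

    trees: list
    bootstrap_idx: list[np.ndarray]
    covariate_names: list[str]
    hyperparams: dict
    oob_prob: np.ndarray
    labels: np.ndarray
    seed: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def oob_defined(self) -> np.ndarray:
        return ~np.isnan(self.oob_prob)

    def predict_proba(self, X) -> np.ndarray:
        """Ensemble presence-vote fraction for new covariate rows."""
        X = self._as_matrix(X)
        votes = np.zeros(X.shape[0])
        for tree in self.trees:
            votes += _presence_votes(tree, X)
        return votes / self.n_trees

    def oob_votes_with(self, X) -> np.ndarray:
        """OOB presence-vote fractions recomputed on modified training
        rows ``X`` (used by the permutation importance)."""
        X = self._as_matrix(X)
        votes = np.zeros(X.shape[0])
        counts = np.zeros(X.shape[0])
        n = X.shape[0]
        for tree, idx in zip(self.trees, self.bootstrap_idx):
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            if not oob.any():
                continue
            votes[oob] += _presence_votes(tree, X[oob])
            counts[oob] += 1
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0, votes / np.maximum(counts, 1), np.nan)

    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.covariate_names if c not in X.columns]
            if missing:
                raise KeyError(f"missing covariates: {missing}")
            X = X[self.covariate_names].to_numpy()
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.covariate_names):
            raise ValueError("covariate count mismatch")
        return X


def _presence_votes(tree, X) -> np.ndarray:
    """Per-row presence (class 1) vote of a single tree."""
    proba = tree.predict_proba(X)
    classes = list(tree.classes_)
    if 1 not in classes:
        return np.zeros(X.shape[0])
    return (proba[:, classes.index(1)] >= 0.5).astype(float)


def fit_envelope(
    matrix,
    labels,
    n_trees: int = 1000,
    vars_per_split: int | None = None,
    min_node_size: int = 1,
    seed: int = 0,
    class_weight=None,
) -> EnvelopeModel:
    """Fit the bagged-tree envelope model.

    Each of the ``n_trees`` trees is grown on an n-out-of-n bootstrap
    with ``vars_per_split`` covariates considered per split (default
    ``ceil(sqrt(p))``) down to ``min_node_size`` samples per leaf.  The
    fit is a pure function of (data, hyperparameters, seed).
    """
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("matrix and labels are misaligned")
    if np.isnan(X).any():
        raise ValueError("covariate matrix contains missing values")
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class; cannot fit an envelope")

    n, p = X.shape
    mtry = vars_per_split if vars_per_split is not None else int(np.ceil(np.sqrt(p)))
    rng = np.random.default_rng(seed)
    trees, boots = [], []
    votes = np.zeros(n)
    counts = np.zeros(n)
    for t in range(n_trees):
        idx = rng.integers(0, n, size=n)
        tree = DecisionTreeClassifier(
            max_features=mtry,
            min_samples_leaf=min_node_size,
            class_weight=class_weight,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        if oob.any():
            votes[oob] += _presence_votes(tree, X[oob])
            counts[oob] += 1
        trees.append(tree)
        boots.append(idx)
    with np.errstate(invalid="ignore"):
        oob_prob = np.where(counts > 0, votes / np.maximum(counts, 1), np.nan)
    return EnvelopeModel(
        trees=trees,
        bootstrap_idx=boots,
        covariate_names=names,
        hyperparams={
            "n_trees": n_trees,
            "vars_per_split": mtry,
            "min_node_size": min_node_size,
            "class_weight": class_weight,
        },
        oob_prob=oob_prob,
        labels=y,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# confusion matrix


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with predictions on rows and observations on columns.

    ``tp``: predicted presence, observed presence; ``fp``: predicted
    presence, observed absence; ``fn``/``tn`` analogously for the
    predicted-absence row.  Row-normalized percentages describe how
    often each *prediction* is right.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def presence_row_pct_correct(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp)

    @property
    def presence_row_pct_error(self) -> float:
        return 100.0 * self.fp / (self.tp + self.fp)

    @property
    def absence_row_pct_correct(self) -> float:
        return 100.0 * self.tn / (self.fn + self.tn)

    @property
    def absence_row_pct_error(self) -> float:
        return 100.0 * self.fn / (self.fn + self.tn)

    @property
    def error_rate_pct(self) -> float:
        return 100.0 * (self.fp + self.fn) / self.total

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def tnr(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def kappa(self) -> float:
        return cohen_kappa(self.tp, self.fp, self.fn, self.tn)

    @property
    def tss(self) -> float:
        return self.tpr + self.tnr - 1.0


def cohen_kappa(tp: int, fp: int, fn: int, tn: int) -> float:
    """Cohen's chance-corrected agreement for a 2x2 table."""
    n = tp + fp + fn + tn
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    if pe == 1.0:
        return 0.0
    return (po - pe) / (1.0 - pe)


def oob_confusion(model: EnvelopeModel, labels=None, threshold: float = 0.5) -> ConfusionMatrix:
    """Confusion matrix of OOB classifications at a probability threshold
    (OOB probability >= threshold is a predicted presence)."""
    y = np.asarray(labels if labels is not None else model.labels, dtype=int)
    ok = model.oob_defined
    pred = (model.oob_prob[ok] >= threshold).astype(int)
    obs = y[ok]
    return ConfusionMatrix(
        tp=int(((pred == 1) & (obs == 1)).sum()),
        fp=int(((pred == 1) & (obs == 0)).sum()),
        fn=int(((pred == 0) & (obs == 1)).sum()),
        tn=int(((pred == 0) & (obs == 0)).sum()),
    )


# ---------------------------------------------------------------------------
# permutation importance


def permutation_importance(
    model: EnvelopeModel,
    matrix,
    labels=None,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean decrease in OOB accuracy when one covariate is permuted.

    For each covariate and repeat, the column is shuffled across samples,
    OOB vote fractions are recomputed (each tree voting only on its
    out-of-bag rows), and the drop from baseline OOB accuracy at the 0.5
    majority threshold is recorded.  Returns a DataFrame indexed by
    covariate with columns ``importance`` (mean drop) and ``sd``.
    """
    if isinstance(matrix, pd.DataFrame):
        X = matrix[model.covariate_names].to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels if labels is not None else model.labels, dtype=int)
    ok = model.oob_defined
    baseline = float(np.mean((model.oob_prob[ok] >= 0.5).astype(int) == y[ok]))

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    drops = np.empty((len(model.covariate_names), n_repeats))
    for r in range(n_repeats):
        perm = rng.permutation(n)
        for j in range(X.shape[1]):
            if np.all(X[:, j] == X[0, j]):  # constant: permutation is identity
                drops[j, r] = 0.0
                continue
            Xp = X.copy()
            Xp[:, j] = X[perm, j]
            prob = model.oob_votes_with(Xp)
            okp = ~np.isnan(prob)
            acc = float(np.mean((prob[okp] >= 0.5).astype(int) == y[okp]))
            drops[j, r] = baseline - acc
    return pd.DataFrame(
        {
            "importance": drops.mean(axis=1),
            "sd": drops.std(axis=1, ddof=1) if n_repeats > 1 else 0.0,
        },
        index=pd.Index(model.covariate_names, name="covariate"),
    ).sort_values("importance", ascending=False)


# ---------------------------------------------------------------------------
# ROC / AUC and threshold selection


def roc_auc(scores, labels) -> float:
    """AUC as the rank probability that a presence outscores an absence,
    counting ties as one half (Mann–Whitney statistic)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class ThresholdDiagnostics:
    """Threshold curves and the sensitivity = specificity operating point.

    ``grid`` spans the OOB scores; ``tpr``/``tnr``/``kappa``/``tss`` are
    evaluated at each grid threshold (prediction rule: score >= t).
    ``threshold`` interpolates the crossing tpr(t) = tnr(t); the TSS
    identity tss = tpr + tnr - 1 holds pointwise by construction.
    """

    threshold: float
    grid: np.ndarray
    tpr: np.ndarray
    tnr: np.ndarray
    kappa: np.ndarray
    tss: np.ndarray
    auc: float
    tpr_at_threshold: float = field(default=np.nan)
    tnr_at_threshold: float = field(default=np.nan)

    @property
    def max_kappa(self) -> float:
        return float(self.kappa.max())

    @property
    def max_tss(self) -> float:
        return float(self.tss.max())


def select_threshold(scores, labels) -> ThresholdDiagnostics:
    """Select the classification threshold where TPR = TNR.

    The threshold grid is the midpoints of sorted unique scores, padded
    below the minimum and above the maximum so the TPR-TNR difference
    always brackets zero.  The operating point is found by linear
    interpolation between the bracketing grid thresholds; with both
    curves interpolated linearly the equalized rates agree to floating
    point.  Ties (a flat zero stretch) resolve to the smallest t.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    keep = ~np.isnan(s)
    s, y = s[keep], y[keep]
    if np.unique(y).size < 2:
        raise ValueError("threshold selection requires both classes")
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValueError("degenerate constant scores")
    pad = max(1e-6, 0.01 * (uniq[-1] - uniq[0]))
    grid = np.concatenate([[uniq[0] - pad], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + pad]])

    pos, neg = s[y == 1], s[y == 0]
    tpr = np.array([(pos >= t).mean() for t in grid])
    tnr = np.array([(neg < t).mean() for t in grid])
    kappa = np.empty(grid.size)
    for i, t in enumerate(grid):
        kappa[i] = cohen_kappa(
            int((pos >= t).sum()),
            int((neg >= t).sum()),
            int((pos < t).sum()),
            int((neg < t).sum()),
        )
    tss = tpr + tnr - 1.0

    d = tpr - tnr  # starts at +1, ends at -1 on the padded grid
    zero = np.flatnonzero(d == 0.0)
    if zero.size:
        i = int(zero[0])
        t_star, tpr_star, tnr_star = float(grid[i]), float(tpr[i]), float(tnr[i])
    else:
        i = int(np.flatnonzero((d[:-1] > 0) & (d[1:] < 0))[0])
        w = d[i] / (d[i] - d[i + 1])
        t_star = float(grid[i] + w * (grid[i + 1] - grid[i]))
        tpr_star = float(tpr[i] + w * (tpr[i + 1] - tpr[i]))
        tnr_star = float(tnr[i] + w * (tnr[i + 1] - tnr[i]))

    return ThresholdDiagnostics(
        threshold=t_star,
        grid=grid,
        tpr=tpr,
        tnr=tnr,
        kappa=kappa,
        tss=tss,
        auc=roc_auc(s, y),
        tpr_at_threshold=tpr_star,
        tnr_at_threshold=tnr_star,
    )
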