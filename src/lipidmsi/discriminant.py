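"""ROC feature filtering and PLS-DA under Monte-Carlo cross-validation.

The statistical unit is the tissue section: each section contributes one
ROI-averaged, RMS-normalized abundance per feature.  Univariate screening
uses the Mann-Whitney ROC AUC oriented so that AUC > 0.5 means higher
abundance in sham sections; features are kept when their AUC leaves a band
around 0.5 (loose: outside (0.3, 0.7); strict: outside (0.2, 0.8)).

Multivariate models are PLS-DA fits on Pareto-scaled abundances with
t-statistic feature ranking, evaluated by Monte-Carlo cross-validation
(MCCV): repeated stratified 2/3 train / 1/3 test splits, with scaling,
ranking and feature selection done on the training split only.  Test-fold
prediction scores are pooled across repeats into one ROC/AUC; per-repeat
AUCs give a percentile 95% CI; feature importance is the mean |t| over
repeats, with repeats where the feature was not selected counting as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "SampleTable",
    "FeatureAUC",
    "PLSDAModel",
    "MCCVResult",
    "feature_auc",
    "roc_filter",
    "pareto_scale",
    "t_statistic",
    "pls_fit",
    "mccv_plsda",
    "fold_change",
    "model_optimize",
]

SHAM, INJURED = "sham", "injured"


@dataclass
class SampleTable:
    """Sections x features matrix of ROI mean abundances with group labels."""

    X: pd.DataFrame  # rows: section ids, columns: feature labels
    groups: pd.Series  # 'sham' / 'injured' per section

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups, index=self.X.index)
        bad = set(self.groups.unique()) - {SHAM, INJURED}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        if not ((self.groups == SHAM).any() and (self.groups == INJURED).any()):
            raise ValueError("both groups must be represented")

    @property
    def y(self) -> np.ndarray:
        """Class indicator: 1 = sham, 0 = injured."""
        return (self.groups == SHAM).to_numpy(dtype=float)

    def subset_features(self, cols) -> "SampleTable":
        return SampleTable(self.X[cols], self.groups)


@dataclass(frozen=True)
class FeatureAUC:
    feature: str
    auc: float
    mean_sham: float
    mean_injured: float


@dataclass
class PLSDAModel:
    features: list[str]
    n_latent: int
    x_weights: np.ndarray
    x_loadings: np.ndarray
    coef: np.ndarray
    intercept: float
    _pls: PLSRegression = field(repr=False, default=None)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Continuous response score (larger = more sham-like)."""
        return np.asarray(X) @ self.coef.ravel() + self.intercept


@dataclass
class MCCVResult:
    pooled_auc: float
    ci_low: float
    ci_high: float
    repeat_aucs: np.ndarray
    importance: pd.DataFrame  # feature, mean |t|, selection freq, direction
    pooled_scores: np.ndarray
    pooled_truth: np.ndarray
    k: int
    n_latent: int
    seed: int


def _auc_sham_positive(values: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC, ties counted half: P(sham > injured) + P(tie)/2."""
    sham = values[y == 1]
    inj = values[y == 0]
    if sham.size == 0 or inj.size == 0:
        raise ValueError("both groups must be nonempty")
    wins = (sham[:, None] > inj[None, :]).sum()
    ties = (sham[:, None] == inj[None, :]).sum()
    return float((wins + 0.5 * ties) / (sham.size * inj.size))


def feature_auc(values, labels) -> FeatureAUC:
    """ROC AUC of one feature across sections, oriented sham-positive."""
    name = getattr(values, "name", "")
    values = np.asarray(values, dtype=float)
    labels = pd.Series(labels)
    y = (labels == SHAM).to_numpy(dtype=float)
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("both groups must be represented")
    return FeatureAUC(
        feature=str(name),
        auc=_auc_sham_positive(values, y),
        mean_sham=float(values[y == 1].mean()),
        mean_injured=float(values[y == 0].mean()),
    )


ROC_BANDS = {"loose": (0.3, 0.7), "strict": (0.2, 0.8)}


def roc_filter(aucs: list[FeatureAUC], mode: str = "loose") -> list[str]:
    """Features whose AUC lies outside the mode's central band.

    loose keeps AUC > 0.7 (sham-elevated) or < 0.3 (injured-elevated);
    strict tightens to 0.8 / 0.2.  strict-kept is always a subset of
    loose-kept.
    """
    try:
        lo, hi = ROC_BANDS[mode]
    except KeyError:
        raise ValueError(f"mode must be one of {sorted(ROC_BANDS)}") from None
    return [a.feature for a in aucs if a.auc > hi or a.auc < lo]


def pareto_scale(X: np.ndarray) -> np.ndarray:
    """Center columns and divide by the square root of the sample SD.

    Zero-variance columns become all-zero.  Pareto scaling shrinks dominant
    high-abundance features less aggressively than unit-variance scaling:
    a scaled column's variance equals the original column's SD.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to scale")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    out = X - mean
    nz = sd > 0
    out[:, nz] /= np.sqrt(sd[nz])
    out[:, ~nz] = 0.0
    return out


def _pareto_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    scale = np.where(sd > 0, np.sqrt(sd), np.inf)  # zero-var col -> zeros
    return mean, scale


def t_statistic(values, labels) -> float:
    """Pooled-variance two-sample t; sign = sham mean − injured mean.

    Degenerate zero-variance case: t = 0 for equal means, ±inf otherwise
    (so perfectly separating features rank first under |t|).
    """
    values = np.asarray(values, dtype=float)
    labels = pd.Series(labels)
    a = values[(labels == SHAM).to_numpy()]
    b = values[(labels == INJURED).to_numpy()]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 sections per group")
    diff = a.mean() - b.mean()
    dof = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / dof
    if sp2 == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(sp2 * (1 / a.size + 1 / b.size)))


def _t_vector(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized pooled t per column (same conventions as t_statistic)."""
    a, b = X[y == 1], X[y == 0]
    na, nb = len(a), len(b)
    diff = a.mean(axis=0) - b.mean(axis=0)
    va = a.var(axis=0, ddof=1) if na > 1 else np.zeros(X.shape[1])
    vb = b.var(axis=0, ddof=1) if nb > 1 else np.zeros(X.shape[1])
    sp2 = ((na - 1) * va + (nb - 1) * vb) / max(na + nb - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1 / na + 1 / nb))
    t[np.isnan(t)] = 0.0  # zero variance, equal means
    zero_sep = (sp2 == 0) & (diff != 0)
    t[zero_sep] = np.sign(diff[zero_sep]) * np.inf
    return t


def pls_fit(X: np.ndarray, y: np.ndarray, n_latent: int) -> PLSDAModel:
    """PLS-DA: PLS regression (NIPALS) of the class indicator on X.

    X must already be scaled; y is the {0 = injured, 1 = sham} indicator.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(y == y[0]):
        raise ValueError("y is constant; no discrimination defined")
    bound = min(X.shape[1], X.shape[0] - 1)
    if not 1 <= n_latent <= bound:
        raise ValueError(f"n_latent must be in [1, {bound}], got {n_latent}")
    pls = PLSRegression(n_components=n_latent, scale=False)
    pls.fit(X, y)
    return PLSDAModel(
        features=[f"x{i}" for i in range(X.shape[1])],
        n_latent=n_latent,
        x_weights=pls.x_weights_,
        x_loadings=pls.x_loadings_,
        coef=pls.coef_.reshape(-1),
        intercept=float(pls.intercept_[0]) if np.ndim(pls.intercept_) else float(pls.intercept_),
        _pls=pls,
    )


def _stratified_split(y: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_train = max(1, int(round(len(idx) * 2 / 3)))
        if n_train == len(idx):  # keep at least one test section per group
            n_train -= 1
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def mccv_plsda(
    table: SampleTable,
    k: int,
    n_latent: int,
    repeats: int = 100,
    seed: int = 0,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> MCCVResult:
    """Monte-Carlo cross-validated PLS-DA with t-statistic feature ranking.

    Each repeat draws a stratified 2/3 train / 1/3 test split; Pareto
    scaling, |t| ranking and top-k selection happen on the training split
    only, and the trained model scores the held-out sections using the
    training scaling.  Scores pool across repeats into one ROC AUC; the 95%
    CI is the 2.5/97.5 percentile of per-repeat AUCs.

    Explicit (train, test) index ``splits`` may be supplied instead of the
    seeded random draws (``repeats`` then equals their number).
    """
    if splits is not None:
        repeats = len(splits)
    if repeats < 10:
        raise ValueError("need at least 10 MCCV repeats")
    y = table.y
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 sections per group")
    X = table.X.to_numpy(dtype=float)
    feats = list(table.X.columns)
    rng = np.random.default_rng(seed)
    scores_all, truth_all, aucs = [], [], []
    t_sums = np.zeros(len(feats))
    sel_counts = np.zeros(len(feats))
    dir_sums = np.zeros(len(feats))
    for rep in range(repeats):
        if splits is not None:
            tr, te = (np.asarray(s, dtype=int) for s in splits[rep])
            if len(set(y[te])) < 2:
                raise ValueError("each test fold must contain both groups")
        else:
            tr, te = _stratified_split(y, rng)
        mean, scale = _pareto_params(X[tr])
        Xtr = (X[tr] - mean) / scale
        t = _t_vector(Xtr, y[tr])
        rank = np.argsort(-np.abs(t), kind="stable")
        top = rank[: min(k, len(feats))]
        L = min(n_latent, len(top), len(tr) - 1)
        model = pls_fit(Xtr[:, top], y[tr], L)
        Xte = (X[te] - mean) / scale
        s = model.predict(Xte[:, top])
        scores_all.append(s)
        truth_all.append(y[te])
        aucs.append(_auc_sham_positive(s, y[te]))
        t_abs = np.abs(t[top])
        t_abs[~np.isfinite(t_abs)] = np.nanmax(
            np.where(np.isfinite(t_abs), t_abs, np.nan), initial=10.0
        )
        t_sums[top] += t_abs
        sel_counts[top] += 1
        dir_sums[top] += np.sign(t[top])
    scores = np.concatenate(scores_all)
    truth = np.concatenate(truth_all)
    pooled = _auc_sham_positive(scores, truth)
    aucs = np.asarray(aucs)
    # mean |t| over all repeats (zero when not selected): conditioning only
    # on selected repeats would inflate rarely chosen noise features
    mean_t = t_sums / repeats
    importance = pd.DataFrame(
        {
            "feature": feats,
            "importance": mean_t,
            "selection_freq": sel_counts / repeats,
            "direction": np.where(
                dir_sums > 0, "higher_in_sham", np.where(dir_sums < 0, "higher_in_injured", "n/a")
            ),
        }
    ).sort_values("importance", ascending=False, ignore_index=True)
    return MCCVResult(
        pooled_auc=pooled,
        ci_low=float(np.percentile(aucs, 2.5)),
        ci_high=float(np.percentile(aucs, 97.5)),
        repeat_aucs=aucs,
        importance=importance,
        pooled_scores=scores,
        pooled_truth=truth,
        k=k,
        n_latent=n_latent,
        seed=seed,
    )


def fold_change(table: SampleTable, feature: str) -> float:
    """Injured group mean ÷ sham group mean (NaN when sham mean is 0)."""
    v = table.X[feature].to_numpy(dtype=float)
    y = table.y
    sham_mean = v[y == 1].mean()
    if sham_mean == 0:
        return float("nan")
    return float(v[y == 0].mean() / sham_mean)


def model_optimize(
    table: SampleTable,
    k_grid,
    latent_grid,
    repeats: int = 100,
    seed: int = 0,
) -> tuple[int, int, MCCVResult]:
    """Exhaustive (k, latent) grid search maximizing pooled MCCV AUC.

    Every combination is evaluated with the same seed so splits are shared;
    ties break toward smaller k, then smaller latent count.
    """
    k_grid, latent_grid = list(k_grid), list(latent_grid)
    if not k_grid or not latent_grid:
        raise ValueError("grids must be nonempty")
    best = None
    for k in sorted(k_grid):
        for L in sorted(latent_grid):
            res = mccv_plsda(table, k, L, repeats=repeats, seed=seed)
            key = (-res.pooled_auc, k, L)
            if best is None or key < best[0]:
                best = (key, k, L, res)
    return best[1], best[2], best[3]
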