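"""Connectome-based prediction of clinical group and symptom scores.

Classification uses an RBF-kernel SVM under stratified k-fold
cross-validation; symptom estimation uses an L2-regularized L2-loss
linear SVR under leave-one-out cross-validation (LOOCV).  In every
training fold, age and sex are regressed out of the features (and, for
regression, the target) with coefficients estimated on the training rows
only and applied to the held-out rows; feature selection is likewise
fitted inside the fold (two-sample t-test for classification, Pearson
correlation with the target for regression) so no information leaks from
the held-out subject.

The significance of the observed-vs-predicted correlation is assessed by
a permutation test that reshuffles the scores and re-runs the entire
LOOCV pipeline, selection included.  Connection contributions are the
fold-averaged SVR weights (zero in folds where a connection was not
selected); connections above the 90th percentile of absolute mean weight
form the top set, which is then aggregated per ROI and per canonical
network, split into within- and between-network connections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVR

from .qc import ValidationError


# ---------------------------------------------------------------------------
# de-confounding
# ---------------------------------------------------------------------------

def residualize_train_apply(features: np.ndarray, confounds: np.ndarray,
                            train_idx: np.ndarray, test_idx: np.ndarray,
                            scores: np.ndarray | None = None):
    """Regress confounds out of features (and scores) using train rows only.

    Per column, OLS of value ~ intercept + confounds on the training rows;
    residuals are returned for train and test rows using the training
    coefficients.  Constant confound columns in the training rows are
    dropped.
    """
    features = np.asarray(features, dtype=float)
    confounds = np.asarray(confounds, dtype=float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValidationError("train and test indices overlap")
    keep = [c for c in range(confounds.shape[1])
            if np.std(confounds[train_idx, c]) > 0]
    if len(keep) < confounds.shape[1]:
        warnings.warn("constant confound column dropped in training rows")
    X = np.column_stack([np.ones(features.shape[0]), confounds[:, keep]])
    beta, *_ = np.linalg.lstsq(X[train_idx], features[train_idx], rcond=None)
    feat_res = features - X @ beta
    if scores is None:
        return feat_res[train_idx], feat_res[test_idx]
    scores = np.asarray(scores, dtype=float)
    b, *_ = np.linalg.lstsq(X[train_idx], scores[train_idx], rcond=None)
    score_res = scores - X @ b
    return feat_res[train_idx], feat_res[test_idx], score_res[train_idx], score_res[test_idx]


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def select_features_ttest(features: np.ndarray, group_labels: np.ndarray,
                          alpha: float = 0.001, fallback_k: int = 10) -> np.ndarray:
    """Two-sample two-sided t-test feature filter.

    Returns indices of features with p < ``alpha``; if none survive, the
    ``fallback_k`` smallest-p features are returned.  Features with zero
    variance in both groups are never selected.
    """
    features = np.asarray(features, dtype=float)
    group_labels = np.asarray(group_labels)
    uniq = np.unique(group_labels)
    if len(uniq) != 2:
        raise ValidationError("exactly two groups required")
    a = features[group_labels == uniq[0]]
    b = features[group_labels == uniq[1]]
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each group needs n >= 3")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0)
    valid = np.isfinite(p)
    if not valid.any():
        raise ValidationError("no feature with variance in either group")
    sel = np.flatnonzero(valid & (p < alpha))
    if sel.size == 0:
        order = np.argsort(np.where(valid, p, np.inf))
        sel = order[:min(fallback_k, int(valid.sum()))]
        warnings.warn("t-test selection empty; falling back to smallest-p features")
    return np.sort(sel)


def _pearson_p(features: np.ndarray, y: np.ndarray):
    """Vectorized Pearson r and two-sided p of each column against y."""
    n = len(y)
    yc = y - y.mean()
    fc = features - features.mean(axis=0)
    sy = np.sqrt((yc ** 2).sum())
    sf = np.sqrt((fc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (fc.T @ yc) / (sf * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[~np.isfinite(r)] = np.nan
    p[np.abs(r) == 1.0] = 0.0
    return r, p


def select_features_correlation(features: np.ndarray, y: np.ndarray,
                                alpha: float = 0.001,
                                correction: str = "bonferroni",
                                fallback_k: int = 10) -> np.ndarray:
    """Pearson-correlation feature filter for regression targets.

    ``correction='bonferroni'`` tests p < alpha / n_features; ``'none'``
    tests p < alpha.  Empty selections fall back to the ``fallback_k``
    smallest-p features.
    """
    r, p = _pearson_p(np.asarray(features, dtype=float), np.asarray(y, dtype=float))
    valid = np.isfinite(p)
    if not valid.any():
        raise ValidationError("no valid features (all constant?)")
    if correction == "bonferroni":
        thr = alpha / features.shape[1]
    elif correction == "none":
        thr = alpha
    else:
        raise ValidationError(f"unknown correction: {correction!r}")
    sel = np.flatnonzero(valid & (p < thr))
    if sel.size == 0:
        order = np.argsort(np.where(valid, p, np.inf))
        sel = order[:min(fallback_k, int(valid.sum()))]
    return np.sort(sel)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    auc: float
    acc: float
    sen: float
    spe: float
    fold_of_subject: np.ndarray
    n_selected_per_fold: list


def classify_cv(features: np.ndarray, labels: np.ndarray,
                confounds: np.ndarray, k: int = 5, seed: int = 0,
                alpha: float = 0.001, C: float = 1.0) -> ClassificationReport:
    """Stratified k-fold RBF-SVM classification with in-fold selection.

    Within each training fold: residualize confounds -> t-test feature
    selection -> standardize -> RBF SVM (C=1, kernel width 1/n_features
    after standardization).  Metrics are pooled over test folds; AUC from
    decision values.  The second label in sorted order is the positive
    class for sensitivity/specificity.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValidationError("binary classification only")
    y = (labels == uniq[1]).astype(int)
    if y.sum() < k or (1 - y).sum() < k:
        raise ValidationError("need >= k subjects per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    dec = np.zeros(len(y))
    pred = np.zeros(len(y), dtype=int)
    fold_of = np.zeros(len(y), dtype=int)
    n_sel = []
    for f, (tr, te) in enumerate(skf.split(features, y)):
        ftr, fte = residualize_train_apply(features, confounds, tr, te)
        sel = select_features_ttest(ftr, y[tr], alpha=alpha)
        n_sel.append(len(sel))
        scaler = StandardScaler().fit(ftr[:, sel])
        clf = SVC(C=C, kernel="rbf", gamma=1.0 / len(sel))
        clf.fit(scaler.transform(ftr[:, sel]), y[tr])
        Xte = scaler.transform(fte[:, sel])
        dec[te] = clf.decision_function(Xte)
        pred[te] = clf.predict(Xte)
        fold_of[te] = f
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return ClassificationReport(
        auc=float(roc_auc_score(y, dec)),
        acc=(tp + tn) / len(y),
        sen=tp / max(1, tp + fn),
        spe=tn / max(1, tn + fp),
        fold_of_subject=fold_of,
        n_selected_per_fold=n_sel,
    )


# ---------------------------------------------------------------------------
# symptom regression (LOOCV SVR)
# ---------------------------------------------------------------------------

@dataclass
class PredictionReport:
    predicted: np.ndarray
    observed: np.ndarray
    r: float
    fold_weights: np.ndarray          # (n_subjects, n_features), zeros unselected
    n_selected_per_fold: np.ndarray
    permutation_p: float | None = None
    permutation_rs: np.ndarray | None = None

    @property
    def mean_weights(self) -> np.ndarray:
        return self.fold_weights.mean(axis=0)


def evaluate_prediction(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Pearson r between predicted and observed scores (nan if constant)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size < 3:
        raise ValidationError("need equal-length vectors of >= 3")
    if np.std(predicted) == 0 or np.std(observed) == 0:
        return float("nan")
    return float(np.corrcoef(predicted, observed)[0, 1])


def predict_svr_loocv(features: np.ndarray, scores: np.ndarray,
                      confounds: np.ndarray, alpha: float = 0.001,
                      correction: str = "bonferroni", C: float = 1.0,
                      epsilon: float = 0.1, fallback_k: int = 10) -> PredictionReport:
    """Leave-one-out linear SVR with nested de-confounding and selection.

    Per left-out subject: residualize features and scores on the training
    rows, select features by Pearson-correlation p with the training
    scores (under ``correction``), fit an L2-regularized L2-loss linear
    SVR, and predict the held-out subject.  Each fold's weight vector is
    stored expanded to the full feature space with zeros at unselected
    features.
    """
    features = np.asarray(features, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n, n_feat = features.shape
    if n < 10:
        raise ValidationError("need n >= 10 subjects for LOOCV")
    if np.std(scores) == 0:
        raise ValidationError("scores are constant")
    predicted = np.zeros(n)
    fold_weights = np.zeros((n, n_feat))
    n_sel = np.zeros(n, dtype=int)
    all_idx = np.arange(n)
    for i in range(n):
        tr = np.delete(all_idx, i)
        te = np.array([i])
        ftr, fte, str_, _ = residualize_train_apply(features, confounds, tr, te,
                                                    scores=scores)
        sel = select_features_correlation(ftr, str_, alpha=alpha,
                                          correction=correction,
                                          fallback_k=fallback_k)
        model = LinearSVR(C=C, epsilon=epsilon,
                          loss="squared_epsilon_insensitive", dual=False,
                          max_iter=10000)
        model.fit(ftr[:, sel], str_)
        predicted[i] = model.predict(fte[:, sel])[0]
        fold_weights[i, sel] = model.coef_
        n_sel[i] = len(sel)
    r = evaluate_prediction(predicted, scores)
    return PredictionReport(predicted=predicted, observed=scores.copy(), r=r,
                            fold_weights=fold_weights, n_selected_per_fold=n_sel)


def permutation_test(features: np.ndarray, scores: np.ndarray,
                     confounds: np.ndarray, r_observed: float | None = None,
                     n_perm: int = 1000, seed: int = 0,
                     estimator: str = "add_one", **loocv_kwargs):
    """Permutation p for the observed-vs-predicted correlation.

    Each permutation reshuffles the scores across subjects and re-runs
    the entire LOOCV pipeline (residualization and selection inside the
    folds).  ``estimator='add_one'`` returns (1 + #{r_perm >= r_obs}) /
    (1 + n_perm); ``'raw'`` returns the plain exceedance fraction.

    Returns ``(p, permuted_rs)``.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if r_observed is None:
        r_observed = predict_svr_loocv(features, scores, confounds,
                                       **loocv_kwargs).r
    rng = np.random.default_rng(seed)
    rs = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(scores)
        rs[b] = predict_svr_loocv(features, perm, confounds, **loocv_kwargs).r
    exceed = int(np.sum(rs >= r_observed))
    if estimator == "add_one":
        p = (1 + exceed) / (1 + n_perm)
    elif estimator == "raw":
        p = exceed / n_perm
    else:
        raise ValidationError(f"unknown estimator: {estimator!r}")
    return float(p), rs


# ---------------------------------------------------------------------------
# contribution analysis
# ---------------------------------------------------------------------------

@dataclass
class ContributionTables:
    mean_weights: np.ndarray         # per connection, zeros where never selected
    top_connections: np.ndarray      # feature indices above the 90th percentile
    roi_contribution: np.ndarray     # per ROI, sum of |mean weight| incident
    network_within: dict             # canonical network -> summed |mean weight|
    network_between: dict
    n_top_within: int                # top-set split on the fine network map
    n_top_between: int


def contribution_analysis(fold_weights: np.ndarray, feature_table: np.ndarray,
                          network_of_roi: np.ndarray,
                          canonical_of_network: np.ndarray,
                          percentile: float = 90.0,
                          over_selected_only: bool = True) -> ContributionTables:
    """Fold-averaged connection weights -> top set -> ROI/network tables.

    The top set holds the connections above the given percentile of
    |mean weight| over connections selected in >= 1 fold (over all
    connections when ``over_selected_only`` is False): the
    ceil((1 - percentile/100) * pool size) largest, so the set is never
    empty while anything was selected.  ROI contribution sums
    |mean weight| of the ROI's incident connections; the network table
    sums |mean weight| of top connections per canonical network, split
    into within- and between-network connections.
    """
    fold_weights = np.asarray(fold_weights, dtype=float)
    mean_w = fold_weights.mean(axis=0)
    selected_any = np.any(fold_weights != 0, axis=0)
    if not selected_any.any():
        warnings.warn("all-zero weights: empty contribution report")
        empty = np.array([], dtype=int)
        n_rois = len(network_of_roi)
        return ContributionTables(mean_w, empty, np.zeros(n_rois), {}, {}, 0, 0)
    pool = np.flatnonzero(selected_any) if over_selected_only \
        else np.arange(mean_w.size)
    k = int(np.ceil((1.0 - percentile / 100.0) * pool.size))
    order = pool[np.argsort(-np.abs(mean_w[pool]), kind="stable")]
    top = np.sort(order[:k])

    network_of_roi = np.asarray(network_of_roi, dtype=np.int64)
    canonical_of_network = np.asarray(canonical_of_network, dtype=np.int64)
    n_rois = len(network_of_roi)
    roi_contribution = np.zeros(n_rois)
    for f in np.flatnonzero(mean_w != 0):
        i, j = feature_table[f]
        roi_contribution[i - 1] += abs(mean_w[f])
        roi_contribution[j - 1] += abs(mean_w[f])

    network_within: dict = {}
    network_between: dict = {}
    n_top_within = n_top_between = 0
    for f in top:
        i, j = feature_table[f]
        fine_i, fine_j = network_of_roi[i - 1], network_of_roi[j - 1]
        can_i = int(canonical_of_network[fine_i - 1])
        can_j = int(canonical_of_network[fine_j - 1])
        w = abs(mean_w[f])
        if fine_i == fine_j:
            n_top_within += 1
        else:
            n_top_between += 1
        if can_i == can_j:
            network_within[can_i] = network_within.get(can_i, 0.0) + w
        else:
            network_between[can_i] = network_between.get(can_i, 0.0) + w
            network_between[can_j] = network_between.get(can_j, 0.0) + w
    return ContributionTables(mean_weights=mean_w, top_connections=top,
                              roi_contribution=roi_contribution,
                              network_within=network_within,
                              network_between=network_between,
                              n_top_within=n_top_within,
                              n_top_between=n_top_between)
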