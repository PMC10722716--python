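"""MCI discrimination: rebalancing, composite network score, and
Monte-Carlo cross-validated classifiers.

The class imbalance (many HC, few MCI) is addressed by bootstrap
resampling: plain random oversampling of the minority class, or the
smoothed-bootstrap scheme that draws each output row's class with
probability one half, picks a donor row of that class, and perturbs it
with a Gaussian kernel (diagonal bandwidth = shrink x per-feature
Silverman rule); the combined over/under mode keeps the total sample size
fixed, so one draw can turn 402:47 into roughly balanced counts.

The composite network score z-scores each significant network's loading,
groups networks by complete-linkage clustering of the 1 - |Spearman|
distance (cut at 0.5) so correlated networks share weight
(weight = 1 / (cluster size x number of clusters), weights sum to one),
aligns signs so higher = healthy direction, and sums.

Feature sets are the nested Models 1-6 (cognition; composite; both; plus
confounders age/sex/education; plus MRI volumes; all).  Classifiers are a
radial-kernel SVM (C = 1) and unpenalized logistic regression, evaluated
by Monte-Carlo 5-fold cross-validation (default 100 random partitions),
with metrics pooled over folds within an iteration and averaged over
iterations.  ``protocol_faithful`` mode resamples once before CV (duplicated
subjects can straddle folds — the published protocol); ``leak_safe``
resamples inside each training split only and is the recommended mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

COGNITIVE_FEATURES = ["word_list_memory", "tmt_a", "tmt_b", "sdst"]
CONFOUNDERS = ["age", "sex_code", "education"]
MRI_FEATURES = ["right_hippocampus", "left_hippocampus",
                "cerebral_white_matter", "subcortical_gray_matter",
                "total_gray_matter", "etiv"]


def model_features(model_id: int) -> list[str]:
    """Feature list of Models 1-6 (composite score column: 'composite')."""
    sets = {
        1: COGNITIVE_FEATURES,
        2: ["composite"],
        3: COGNITIVE_FEATURES + ["composite"],
        4: COGNITIVE_FEATURES + ["composite"] + CONFOUNDERS,
        5: COGNITIVE_FEATURES + CONFOUNDERS + MRI_FEATURES,
        6: COGNITIVE_FEATURES + ["composite"] + CONFOUNDERS + MRI_FEATURES,
    }
    if model_id not in sets:
        raise ValueError("model id must be 1..6")
    return list(sets[model_id])


# ---------------------------------------------------------------------------
# resampling


@dataclass(frozen=True)
class ResampleSpec:
    method: str = "combined_over_under"  # or random_oversample, rose_smoothed
    target_prob: float = 0.5
    shrink: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_prob < 1:
            raise ValueError("target class probability must be in (0, 1)")
        if self.method not in ("random_oversample", "rose_smoothed",
                               "combined_over_under"):
            raise ValueError(f"unknown resampling method {self.method!r}")


def _silverman_bandwidth(X: np.ndarray) -> np.ndarray:
    """Per-feature Silverman rule for a diagonal Gaussian kernel."""
    n, d = X.shape
    sd = X.std(axis=0, ddof=1)
    return (4.0 / ((d + 2.0) * n)) ** (1.0 / (d + 4.0)) * sd


def rebalance(features: np.ndarray, labels: np.ndarray,
              spec: ResampleSpec | None = None,
              rng: np.random.Generator | None = None,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap class rebalancing; returns (features, labels)."""
    spec = spec or ResampleSpec()
    X = np.asarray(features, float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("rebalancing requires exactly two classes")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if spec.method == "random_oversample":
        minority = classes[np.argmin(counts)]
        deficit = int(counts.max() - counts.min())
        if deficit == 0:
            return X.copy(), y.copy()
        pool = np.where(y == minority)[0]
        extra = rng.choice(pool, size=deficit, replace=True)
        idx = np.concatenate([np.arange(len(y)), extra])
        return X[idx], y[idx]
    # smoothed bootstrap: per output row draw class, donor, kernel noise
    n_out = len(y) if spec.method == "combined_over_under" else 2 * counts.max()
    probs = {classes[0]: 1.0 - spec.target_prob, classes[1]: spec.target_prob}
    out_X, out_y = [], []
    bw = {c: spec.shrink * _silverman_bandwidth(X[y == c]) for c in classes}
    pools = {c: np.where(y == c)[0] for c in classes}
    draw = rng.choice(classes, size=n_out,
                      p=[probs[classes[0]], probs[classes[1]]])
    for c in draw:
        donor = X[rng.choice(pools[c])]
        out_X.append(donor + bw[c] * rng.standard_normal(X.shape[1]))
        out_y.append(c)
    return np.asarray(out_X), np.asarray(out_y)


# ---------------------------------------------------------------------------
# composite network score


@dataclass
class CompositeScore:
    scores: np.ndarray               # per subject
    weights: np.ndarray              # per network, sum to 1
    signs: np.ndarray                # +-1 per network (HC direction)
    clusters: np.ndarray             # cluster id per network
    train_mean: np.ndarray
    train_sd: np.ndarray

    def apply(self, loadings: np.ndarray) -> np.ndarray:
        """Score new subjects with the frozen weights/statistics."""
        z = (np.asarray(loadings, float) - self.train_mean) / self.train_sd
        return z @ (self.weights * self.signs)


def composite_score(loadings: np.ndarray, groups,
                    train_idx: np.ndarray | None = None,
                    cut: float = 0.5) -> CompositeScore:
    """Weighted z-score composite of significant-network loadings.

    z-scoring statistics, the clustering and the sign alignment are
    computed on ``train_idx`` only (all subjects by default), so the score
    can be embedded in cross-validation without leakage.
    """
    L = np.atleast_2d(np.asarray(loadings, float))
    groups = np.asarray(groups)
    if train_idx is None:
        train_idx = np.arange(L.shape[0])
    Lt, gt = L[train_idx], groups[train_idx]
    mean, sd = Lt.mean(axis=0), Lt.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance network loading")
    k = L.shape[1]
    if k == 1:
        clusters = np.array([1])
    else:
        rs = spearmanr(Lt).statistic
        if np.ndim(rs) == 0:  # scipy returns a scalar for two features
            rs = np.array([[1.0, rs], [rs, 1.0]])
        dist = 1.0 - np.abs(rs)
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="complete")
        clusters = fcluster(Z, t=cut, criterion="distance")
    n_clusters = len(np.unique(clusters))
    sizes = pd.Series(clusters).map(pd.Series(clusters).value_counts())
    weights = 1.0 / (sizes.to_numpy(float) * n_clusters)
    # sign: positive when HC mean exceeds MCI mean (higher = healthier)
    hc, mci = gt == "HC", gt == "MCI"
    if hc.any() and mci.any():
        signs = np.sign(Lt[hc].mean(axis=0) - Lt[mci].mean(axis=0))
        signs[signs == 0] = 1.0
    else:
        signs = np.ones(k)
    z = (L - mean) / sd
    return CompositeScore(scores=z @ (weights * signs), weights=weights,
                          signs=signs, clusters=clusters,
                          train_mean=mean, train_sd=sd)


# ---------------------------------------------------------------------------
# metrics


def classification_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                           scores: np.ndarray | None = None,
                           positive=1) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity, precision, F1 and rank-based AUC.

    Ratios with zero denominators are reported as None, never as 0.  AUC
    is the Mann-Whitney statistic on the scores (ties credit 0.5).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    tp = int(np.sum(pos & (y_pred == positive)))
    tn = int(np.sum(~pos & (y_pred != positive)))
    fp = int(np.sum(~pos & (y_pred == positive)))
    fn = int(np.sum(pos & (y_pred != positive)))
    n = tp + tn + fp + fn
    if n == 0:
        raise ValueError("no observations")

    def ratio(num, den):
        return num / den if den > 0 else None

    out = {
        "accuracy": (tp + tn) / n,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "precision": ratio(tp, tp + fp),
    }
    prec, sens = out["precision"], out["sensitivity"]
    out["f1"] = (2 * prec * sens / (prec + sens)
                 if prec is not None and sens is not None and prec + sens > 0
                 else None)
    out["auc"] = rank_auc(scores, pos) if scores is not None else None
    return out


def rank_auc(scores: np.ndarray, positive_mask: np.ndarray) -> float | None:
    """AUC as the normalized Mann-Whitney U (tied scores get 0.5 credit)."""
    scores = np.asarray(scores, float)
    pos = np.asarray(positive_mask, bool)
    n1, n0 = pos.sum(), (~pos).sum()
    if n1 == 0 or n0 == 0:
        return None
    order = pd.Series(scores).rank(method="average").to_numpy()
    u = order[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation


@dataclass
class CVResult:
    classifier: str
    model_id: int
    mode: str
    n_iterations: int
    k_folds: int
    seed: int
    per_iteration: pd.DataFrame = field(repr=False, default=None)

    @property
    def aggregate(self) -> dict[str, float]:
        return {c: float(self.per_iteration[c].mean())
                for c in self.per_iteration.columns}


def _make_classifier(name: str, seed: int):
    if name == "svm":
        return SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    if name == "logistic":
        # unpenalized logistic regression
        return LogisticRegression(C=np.inf, max_iter=2000)
    raise ValueError(f"unknown classifier {name!r}")


def prepare_feature_table(subjects: pd.DataFrame,
                          composite: np.ndarray | None = None) -> pd.DataFrame:
    """Numeric feature table: encodes sex, attaches the composite column."""
    t = subjects.copy()
    if "sex" in t.columns and "sex_code" not in t.columns:
        t["sex_code"] = (t["sex"] == "F").astype(float)
    if composite is not None:
        t["composite"] = composite
    return t


def run_cv(subjects: pd.DataFrame, model_id: int, classifier: str = "svm",
           n_iterations: int = 100, k_folds: int = 5,
           resample: ResampleSpec | None = None, mode: str = "leak_safe",
           seed: int = 0, loadings: np.ndarray | None = None) -> CVResult:
    """Monte-Carlo k-fold cross-validation of one model/classifier pair.

    ``subjects`` must contain a ``group`` column and the model's feature
    columns; Models 2/3/4/6 need either a precomputed ``composite`` column
    or raw ``loadings`` (n_subjects x n_networks) from which the composite
    is built on each training split (leak_safe) or once globally
    (protocol_faithful).
    """
    if mode not in ("leak_safe", "protocol_faithful"):
        raise ValueError("mode must be leak_safe or protocol_faithful")
    resample = resample or ResampleSpec()
    feats = model_features(model_id)
    needs_comp = "composite" in feats
    table = prepare_feature_table(subjects)
    groups = table["group"].to_numpy()
    y_all = (groups == "MCI").astype(int)
    if len(np.unique(y_all)) < 2:
        raise ValueError("cohort contains a single class")
    if needs_comp and "composite" not in table.columns:
        if loadings is None:
            raise ValueError("model needs a composite score: supply "
                             "`loadings` or a precomputed column")
        if mode == "protocol_faithful":
            table["composite"] = composite_score(loadings, groups).scores
    missing = [f for f in feats if f not in table.columns and f != "composite"]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    rng = np.random.default_rng(seed)
    n = len(table)

    def feature_matrix(tab):
        return tab[feats].to_numpy(float)

    if mode == "protocol_faithful":
        X0 = feature_matrix(table)
        X0, y0 = rebalance(X0, y_all, resample, rng=rng)
    rows = []
    for _ in range(n_iterations):
        if mode == "protocol_faithful":
            X, y = X0, y0
            folds = np.array_split(rng.permutation(len(y)), k_folds)
            y_true_it, y_pred_it, score_it = [], [], []
            for fold in folds:
                tr = np.setdiff1d(np.arange(len(y)), fold)
                yt, yp, sc = _fit_predict(X[tr], y[tr], X[fold], y[fold],
                                          classifier, rng)
                y_true_it.append(yt)
                y_pred_it.append(yp)
                score_it.append(sc)
        else:
            folds = np.array_split(rng.permutation(n), k_folds)
            y_true_it, y_pred_it, score_it = [], [], []
            for fold in folds:
                tr = np.setdiff1d(np.arange(n), fold)
                tab = table.copy()
                if needs_comp and "composite" not in subjects.columns:
                    comp = composite_score(loadings, groups, train_idx=tr)
                    tab["composite"] = comp.apply(loadings)
                Xtr, ytr = feature_matrix(tab.iloc[tr]), y_all[tr]
                Xte, yte = feature_matrix(tab.iloc[fold]), y_all[fold]
                Xtr, ytr = rebalance(Xtr, ytr, resample, rng=rng)
                yt, yp, sc = _fit_predict(Xtr, ytr, Xte, yte, classifier, rng)
                y_true_it.append(yt)
                y_pred_it.append(yp)
                score_it.append(sc)
        yt = np.concatenate(y_true_it)
        yp = np.concatenate(y_pred_it)
        sc = np.concatenate(score_it)
        rows.append(classification_metrics(yt, yp, scores=sc))
    per_it = pd.DataFrame(rows).astype(float)
    return CVResult(classifier=classifier, model_id=model_id, mode=mode,
                    n_iterations=n_iterations, k_folds=k_folds, seed=seed,
                    per_iteration=per_it)


def _fit_predict(Xtr, ytr, Xte, yte, classifier: str, rng):
    """Scale on the training split, fit, return (y_true, y_pred, scores)."""
    if len(np.unique(ytr)) < 2:
        # degenerate resample draw: predict the only class seen
        only = ytr[0]
        return yte, np.full(len(yte), only), np.full(len(yte), float(only))
    scaler = StandardScaler().fit(Xtr)
    clf = _make_classifier(classifier, int(rng.integers(2**31 - 1)))
    clf.fit(scaler.transform(Xtr), ytr)
    Xte_s = scaler.transform(Xte)
    pred = clf.predict(Xte_s)
    score = clf.decision_function(Xte_s)
    return yte, pred, score
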