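"""Benign/malignant classification of ROI feature records.

Three routes, mirroring a clinical decision-support workflow:

1. A 2-step threshold rule on a single feature, evaluated by leave-one-out
   cross-validation: step 1 assigns a case to a tumour group when its value
   lies within one standard deviation of that group's training mean and of
   that group's only; step 2 (the ambiguous cases — inside both intervals
   or neither) assigns by nearest group mean.
2. SMOTE-balanced KNN / RBF-SVM on the full feature set under stratified
   k-fold cross-validation, with an ambiguity band on the predicted
   probability (confident above 0.8, ambiguous between 0.5 and 0.8).
3. Net reclassification improvement (NRI) of one prediction set over
   another, e.g. a classifier against a radiologist's initial read.

Feature selection uses the two-sided Mann-Whitney U test per feature
(exact by enumeration for small tie-free groups), optionally Bonferroni
corrected, with optional Spearman-correlation pruning of redundant
centiles.  Malignant is the positive class throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from miror.repository import FeatureRecord

log = logging.getLogger(__name__)

POSITIVE = "malignant"
NEGATIVE = "benign"

#: The feature subset used for single-feature threshold classification after
#: manual centile pruning (highly correlated ADC centiles collapse to the
#: 15th and 75th).
PRESET_FEATURES = ("mean", "median", "kurtosis", "skewness", "entropy", "c15", "c75")

EXACT_MAX_N = 8


@dataclass
class TestResult:
    """Mann-Whitney comparison of one feature between the two groups."""

    feature: str
    U: float
    p_raw: float
    p_adjusted: float = float("nan")
    significant: bool = False


@dataclass
class ClassificationOutcome:
    """Predicted label for one case, with provenance of the decision."""

    case_id: str
    predicted: str
    truth: str | None = None
    step: str = "model"  # 'interval' | 'nearest-mean' | 'model'
    ambiguous: bool = False
    probability: float | None = None


@dataclass
class CVMetrics:
    """Aggregate cross-validation metrics (malignant = positive class)."""

    sensitivity: float
    specificity: float
    accuracy: float
    balanced_accuracy: float
    auc: float | None
    per_case: list[ClassificationOutcome]
    scheme: str
    n_ambiguous: int = 0


@dataclass
class NRIResult:
    """Net reclassification improvement of a new method over an old one."""

    nri: float
    event_net: float
    nonevent_net: float


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    U counts pairs where an ``a`` value exceeds a ``b`` value (ties count
    one half).  The P value is exact — enumeration of all C(n1+n2, n1)
    group labelings — when both groups have at most 8 observations and the
    pooled sample is tie-free; otherwise the normal approximation with tie
    and continuity corrections is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N and no_ties:
        p = _exact_p(pooled, n1, u)
    else:
        p = _normal_p(pooled, n1, n2, u)
    return TestResult(feature="", U=u, p_raw=p)


def _exact_p(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact two-sided P by enumerating every assignment of group labels.

    For each way of choosing which n1 pooled ranks form group a, U is the
    sum of (rank position - within-group order); the two-sided P is the
    fraction of labelings at least as far from the null mean n1*n2/2.
    """
    n = pooled.size
    n2 = n - n1
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    count = 0
    for positions in combinations(range(n), n1):
        u = sum(p - k for k, p in enumerate(positions))
        if abs(u - mu) >= dev - 1e-12:
            count += 1
    return count / comb(n, n1)


def _normal_p(pooled: np.ndarray, n1: int, n2: int, u: float) -> float:
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    diff = u - mu
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = (diff - cc) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

def _feature_matrix(records: list[FeatureRecord], feature_names=None):
    if feature_names is None:
        keys = set(records[0].features)
        for r in records[1:]:
            keys &= set(r.features)
        keys -= {"n_voxels", "volume_ml", "degenerate"}
        feature_names = sorted(keys)
    X = np.array([[float(r.features[f]) for f in feature_names] for r in records])
    y = np.array([1 if r.group == POSITIVE else 0 for r in records])
    return X, y, list(feature_names)


def select_features(records: list[FeatureRecord], alpha: float = 0.05,
                    use_correction: bool = False,
                    correlation_prune: float | None = None,
                    preset: bool = False) -> tuple[list[str], list[TestResult]]:
    """Mann-Whitney feature screening between the two tumour groups.

    Features with P < ``alpha`` (Bonferroni-adjusted when ``use_correction``)
    are retained.  ``correlation_prune`` keeps, within each cluster of
    selected features whose pairwise |Spearman rho| exceeds the threshold,
    only the one with the smallest raw P.  ``preset`` bypasses the screen
    and returns the manually pruned single-feature set
    (mean, median, kurtosis, skewness, entropy, c15, c75).
    """
    X, y, names = _feature_matrix(records)
    if preset:
        missing = [f for f in PRESET_FEATURES if f not in names]
        if missing:
            raise ValueError(f"preset features absent from records: {missing}")
        return list(PRESET_FEATURES), []
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need >=2 records per group for feature selection")
    if not use_correction:
        log.warning("feature selection on raw P values (no multiplicity correction)")
    m = len(names)
    results: list[TestResult] = []
    for j, name in enumerate(names):
        r = mann_whitney_u(X[y == 1, j], X[y == 0, j])
        p_adj = min(1.0, r.p_raw * m)
        p_eff = p_adj if use_correction else r.p_raw
        results.append(TestResult(feature=name, U=r.U, p_raw=r.p_raw,
                                  p_adjusted=p_adj, significant=p_eff < alpha))
    selected = [r.feature for r in results if r.significant]
    if not selected:
        log.warning("no feature passed the significance screen at alpha=%g", alpha)
    if correlation_prune is not None and len(selected) > 1:
        selected = _prune_correlated(X, names, results, selected, correlation_prune)
    return selected, results


def _prune_correlated(X, names, results, selected, threshold):
    """Cluster selected features by |Spearman rho| > threshold (transitive
    closure) and keep the smallest-raw-P member of each cluster."""
    idx = [names.index(f) for f in selected]
    rho = stats.spearmanr(X[:, idx]).statistic
    rho = np.atleast_2d(rho)
    k = len(selected)
    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(k):
        for j in range(i + 1, k):
            if abs(rho[i, j]) > threshold:
                parent[find(i)] = find(j)
    p_of = {r.feature: r.p_raw for r in results}
    clusters: dict[int, list[str]] = {}
    for i, f in enumerate(selected):
        clusters.setdefault(find(i), []).append(f)
    kept = [min(members, key=lambda f: p_of[f]) for members in clusters.values()]
    return [f for f in selected if f in kept]


# ---------------------------------------------------------------------------
# 2-step threshold classifier
# ---------------------------------------------------------------------------

def threshold_classify(value: float, malignant_stats, benign_stats,
                       case_id: str = "") -> ClassificationOutcome:
    """Assign one feature value to a tumour group by the 2-step rule.

    Step 1: membership in the mean ± 1 SD interval of exactly one group
    assigns that group.  Step 2 (inside both intervals, or neither): assign
    by smallest absolute distance to the group means, flagged ambiguous;
    ties go to malignant.
    """
    m_mean, m_sd = float(malignant_stats[0]), float(malignant_stats[1])
    b_mean, b_sd = float(benign_stats[0]), float(benign_stats[1])
    if m_sd <= 0 or b_sd <= 0:
        raise ValueError("group SD must be positive for interval classification")
    value = float(value)
    in_m = abs(value - m_mean) <= m_sd
    in_b = abs(value - b_mean) <= b_sd
    if in_m != in_b:
        return ClassificationOutcome(case_id=case_id,
                                     predicted=POSITIVE if in_m else NEGATIVE,
                                     step="interval", ambiguous=False)
    predicted = POSITIVE if abs(value - m_mean) <= abs(value - b_mean) else NEGATIVE
    return ClassificationOutcome(case_id=case_id, predicted=predicted,
                                 step="nearest-mean", ambiguous=True)


def _metrics_from_outcomes(outcomes: list[ClassificationOutcome], scheme: str,
                           auc: float | None = None) -> CVMetrics:
    tp = sum(1 for o in outcomes if o.truth == POSITIVE and o.predicted == POSITIVE)
    fn = sum(1 for o in outcomes if o.truth == POSITIVE and o.predicted == NEGATIVE)
    tn = sum(1 for o in outcomes if o.truth == NEGATIVE and o.predicted == NEGATIVE)
    fp = sum(1 for o in outcomes if o.truth == NEGATIVE and o.predicted == POSITIVE)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(outcomes)
    return CVMetrics(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        balanced_accuracy=(sens + spec) / 2.0,
        auc=auc,
        per_case=outcomes,
        scheme=scheme,
        n_ambiguous=sum(1 for o in outcomes if o.ambiguous),
    )


def loocv_threshold(records: list[FeatureRecord], feature: str,
                    sample_sd: bool = False) -> CVMetrics:
    """Leave-one-out cross-validation of the 2-step threshold classifier.

    Each case in turn is held out; both groups' mean and SD of ``feature``
    are recomputed from the remaining cases and the held-out value is
    classified by :func:`threshold_classify`.
    """
    values = np.array([float(r.features[feature]) for r in records])
    groups = np.array([r.group for r in records])
    if (groups == POSITIVE).sum() < 2 or (groups == NEGATIVE).sum() < 2:
        raise ValueError("need >=2 records per group for LOOCV")
    ddof = 1 if sample_sd else 0
    outcomes = []
    for i, rec in enumerate(records):
        keep = np.ones(len(records), dtype=bool)
        keep[i] = False
        mv = values[keep & (groups == POSITIVE)]
        bv = values[keep & (groups == NEGATIVE)]
        if mv.size < 2 or bv.size < 2:
            raise ValueError("a LOOCV fold left fewer than 2 cases in a group")
        m_stats = (mv.mean(), mv.std(ddof=ddof))
        b_stats = (bv.mean(), bv.std(ddof=ddof))
        out = threshold_classify(values[i], m_stats, b_stats, case_id=rec.case_id)
        out.truth = rec.group
        outcomes.append(out)
    return _metrics_from_outcomes(outcomes, scheme="LOOCV")


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote(minority: np.ndarray, k: int, n_new: int, rng) -> np.ndarray:
    """Synthetic minority oversampling by nearest-neighbour interpolation.

    Each synthetic sample is x_i + u * (x_nn - x_i) with u ~ Uniform(0, 1)
    and x_nn a uniformly chosen one of the k nearest minority neighbours of
    a uniformly chosen minority point x_i.  All synthetic points therefore
    lie on segments between minority points (inside their convex hull).
    """
    minority = np.atleast_2d(np.asarray(minority, dtype=float))
    n = minority.shape[0]
    if n < 2:
        raise ValueError("SMOTE needs a minority class of >= 2 samples")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the minority size {n}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority)
    _, neighbors = nn.kneighbors(minority)  # column 0 is the point itself
    base = rng.integers(0, n, size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    xi = minority[base]
    xnn = minority[neighbors[base, pick]]
    return xi + u[:, None] * (xnn - xi)


# ---------------------------------------------------------------------------
# KNN / SVM with stratified k-fold CV
# ---------------------------------------------------------------------------

def _make_model(model: str, seed: int):
    if model.lower() == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if model.lower() == "svm":
        return SVC(kernel="rbf", C=1.0, probability=True, random_state=seed)
    raise ValueError(f"unknown model {model!r}; expected 'knn' or 'svm'")


def model_cv(records: list[FeatureRecord], model: str = "knn", folds: int = 10,
             seed: int = 0, feature_names=None, use_smote: bool = True,
             smote_k: int = 5,
             ambiguity_band: tuple[float, float] = (0.5, 0.8)) -> CVMetrics:
    """Stratified k-fold cross-validation of a KNN or RBF-SVM classifier.

    Features are z-scored on each training fold; SMOTE (applied to the
    training portion only, never the held-out fold) oversamples the
    minority class to parity.  Per held-out case the malignancy probability
    is recorded; the label is the more probable class, and a case is
    ambiguous when the winning-class probability does not exceed the upper
    edge of ``ambiguity_band``.
    """
    X, y, _ = _feature_matrix(records, feature_names)
    n_pos, n_neg = int(y.sum()), int((y == 0).sum())
    if min(n_pos, n_neg) < folds:
        raise ValueError(
            f"need >= {folds} cases per class for {folds}-fold stratified CV "
            f"(have {n_pos} malignant / {n_neg} benign)"
        )
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    prob = np.full(len(y), np.nan)
    for train_idx, test_idx in skf.split(X, y):
        scaler = StandardScaler().fit(X[train_idx])
        X_tr, y_tr = scaler.transform(X[train_idx]), y[train_idx]
        if use_smote:
            X_tr, y_tr = _balance_with_smote(X_tr, y_tr, smote_k, rng)
        clf = _make_model(model, seed)
        clf.fit(X_tr, y_tr)
        p = clf.predict_proba(scaler.transform(X[test_idx]))
        prob[test_idx] = p[:, list(clf.classes_).index(1)]
    lo, hi = ambiguity_band
    outcomes = []
    for i, r in enumerate(records):
        p_mal = float(prob[i])
        confidence = max(p_mal, 1.0 - p_mal)
        outcomes.append(ClassificationOutcome(
            case_id=r.case_id,
            predicted=POSITIVE if p_mal >= 0.5 else NEGATIVE,
            truth=r.group,
            step="model",
            ambiguous=confidence <= hi,
            probability=p_mal,
        ))
    _, _, auc = roc_auc(prob, y)
    return _metrics_from_outcomes(outcomes, scheme=f"{folds}-fold", auc=auc)


def _balance_with_smote(X, y, k, rng):
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == n_neg:
        return X, y
    minority_label = 1 if n_pos < n_neg else 0
    minority = X[y == minority_label]
    n_new = abs(n_pos - n_neg)
    k_eff = min(k, minority.shape[0] - 1)
    synth = smote(minority, k_eff, n_new, rng)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority_label)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# ROC / AUC and NRI
# ---------------------------------------------------------------------------

def roc_auc(scores, truth) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve by threshold sweep and AUC by the trapezoidal rule.

    ``truth`` may be 0/1 integers or group labels.  The AUC equals the
    Mann-Whitney statistic U/(n1*n2) of the scores (ties counted half).
    Returns (fpr, tpr, auc).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if truth.dtype.kind in "US":
        truth = (truth == POSITIVE).astype(int)
    truth = truth.astype(int)
    if len(np.unique(truth)) < 2:
        raise ValueError("truth must contain both classes")
    fpr, tpr, _ = roc_curve(truth, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def nri(new_pred, old_pred, truth) -> NRIResult:
    """Net reclassification improvement of ``new_pred`` over ``old_pred``.

    Among events (malignant cases) the net fraction moved from wrong to
    right, plus the same among non-events (benign cases).  For binary
    labels this equals ΔSensitivity + ΔSpecificity.
    """
    new_pred = np.asarray(new_pred)
    old_pred = np.asarray(old_pred)
    truth = np.asarray(truth)
    if not (len(new_pred) == len(old_pred) == len(truth)):
        raise ValueError("prediction and truth lists must have equal length")
    if POSITIVE not in truth or NEGATIVE not in truth:
        raise ValueError("truth must contain both malignant and benign cases")

    def net(label):
        sel = truth == label
        old_right = old_pred[sel] == label
        new_right = new_pred[sel] == label
        up = int((~old_right & new_right).sum())
        down = int((old_right & ~new_right).sum())
        return (up - down) / sel.sum()

    event_net = net(POSITIVE)
    nonevent_net = net(NEGATIVE)
    return NRIResult(nri=event_net + nonevent_net,
                     event_net=event_net, nonevent_net=nonevent_net)
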