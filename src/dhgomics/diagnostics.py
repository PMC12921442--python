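"""Dual-importance biomarker screening and diagnostic-model evaluation.

Two complementary importance screens run over the candidate features (the
differential features of the crucial pathways): a random-forest mean
decrease in accuracy (out-of-bag permutation importance over an explicit
bootstrap of 500 decision trees, reported in percentage points) and a
linear-SVM averaged importance (normalised absolute weight over balanced
subsamples).  The union of threshold passers, restricted to crucial-pathway
members, forms the biomarker panel.  Panels are evaluated per marker
(empirical AUC with a DeLong confidence interval) and jointly by pooling
held-out scores from Monte-Carlo cross-validation with balanced subsampling
under logistic-regression, random-forest and SVM classifiers, with a frozen
discovery-cohort model applied unchanged to the validation cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .matrix import IntensityMatrix


class DiagnosticsError(ValueError):
    pass


@dataclass
class ImportanceResult:
    feature_ids: list[str]
    rf_mda: dict[str, float] = field(default_factory=dict)
    svm_importance: dict[str, float] = field(default_factory=dict)

    def rank(self, criterion: str) -> dict[str, int]:
        """1 = most important under the given criterion (ties by id)."""
        table = getattr(self, criterion)
        order = sorted(self.feature_ids, key=lambda f: (-table[f], f))
        return {f: i + 1 for i, f in enumerate(order)}


@dataclass
class BiomarkerPanel:
    marker_ids: list[str]
    provenance: dict[str, list[str]]  # marker -> criteria passed
    empty_warning: bool = False


@dataclass
class DiagnosticResult:
    model_kind: str
    auc: float
    ci_low: float
    ci_high: float
    cohort: str = "discovery"
    per_sample_probability: dict[str, float] = field(default_factory=dict)
    per_marker_auc: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def _xy(m: IntensityMatrix) -> tuple[np.ndarray, np.ndarray]:
    m.require_two_groups()
    X = m.values.to_numpy(dtype=float).T  # samples x features
    y = (m.groups.to_numpy() == "case").astype(int)
    return X, y


# ---------------------------------------------------------------------------
# importance screens
# ---------------------------------------------------------------------------

def rf_importance(
    m: IntensityMatrix,
    n_trees: int = 500,
    n_repeats: int = 1,
    seed: int = 0,
) -> ImportanceResult:
    """Random-forest out-of-bag mean decrease in accuracy, in % points.

    Each tree is grown on a bootstrap sample; its out-of-bag accuracy is
    compared with the accuracy after permuting one feature's out-of-bag
    values.  The drop is averaged over trees (and ``n_repeats`` permutations
    per tree) and scaled to percentage points.
    """
    X, y = _xy(m)
    if X.shape[1] < 2:
        raise DiagnosticsError("need at least 2 candidate features")
    n = len(y)
    rng = np.random.default_rng(seed)
    drops = np.zeros(X.shape[1])
    counts = np.zeros(X.shape[1])
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(oob) == 0 or len(np.unique(y[boot])) < 2:
            continue
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(X[boot], y[boot])
        base = (tree.predict(X[oob]) == y[oob]).mean()
        for j in range(X.shape[1]):
            for _ in range(n_repeats):
                Xp = X[oob].copy()
                Xp[:, j] = Xp[rng.permutation(len(oob)), j]
                perm_acc = (tree.predict(Xp) == y[oob]).mean()
                drops[j] += base - perm_acc
                counts[j] += 1
    mda = np.where(counts > 0, drops / np.maximum(counts, 1), 0.0) * 100.0
    return ImportanceResult(
        feature_ids=m.feature_ids,
        rf_mda=dict(zip(m.feature_ids, mda.tolist())),
    )


def svm_importance(
    m: IntensityMatrix,
    n_subsamples: int = 50,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> ImportanceResult:
    """Linear-SVM averaged feature importance (normalised |weight|).

    Per balanced subsample (equal numbers of cases and controls drawn
    without replacement), a linear-kernel SVM is fit on standardised
    features; importance is the absolute weight normalised to sum 1,
    averaged over subsamples.
    """
    X, y = _xy(m)
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    if min(len(case_idx), len(ctrl_idx)) < 2:
        raise DiagnosticsError("each class needs at least 2 samples")
    per_class = max(2, int(round(subsample_fraction * min(len(case_idx), len(ctrl_idx)))))
    per_class = min(per_class, len(case_idx), len(ctrl_idx))
    acc = np.zeros(X.shape[1])
    for _ in range(n_subsamples):
        idx = np.concatenate([
            rng.choice(case_idx, per_class, replace=False),
            rng.choice(ctrl_idx, per_class, replace=False),
        ])
        model = Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="linear", C=1.0)),
        ])
        model.fit(X[idx], y[idx])
        w = np.abs(model.named_steps["svm"].coef_.ravel())
        total = w.sum()
        if total > 0:
            acc += w / total
    imp = acc / n_subsamples
    if imp.sum() > 0:
        imp = imp / imp.sum()
    return ImportanceResult(
        feature_ids=m.feature_ids,
        svm_importance=dict(zip(m.feature_ids, imp.tolist())),
    )


def assemble_panel(
    rf: ImportanceResult,
    svm: ImportanceResult,
    crucial_members: set[str],
    rf_threshold: float = 14.0,
    svm_threshold: float = 0.01,
) -> BiomarkerPanel:
    """Union of the two importance screens, within crucial-pathway members.

    A feature enters the panel when its RF mean decrease accuracy exceeds
    ``rf_threshold`` (percentage points) or its averaged SVM importance
    exceeds ``svm_threshold``, provided it belongs to a crucial pathway.
    """
    if set(rf.feature_ids) != set(svm.feature_ids):
        raise DiagnosticsError("RF and SVM screens cover different feature sets")
    provenance: dict[str, list[str]] = {}
    for fid in sorted(rf.feature_ids):
        if fid not in crucial_members:
            continue
        passed = []
        if rf.rf_mda.get(fid, 0.0) > rf_threshold:
            passed.append("rf_mda")
        if svm.svm_importance.get(fid, 0.0) > svm_threshold:
            passed.append("svm_importance")
        if passed:
            provenance[fid] = passed
    markers = sorted(provenance)
    empty = len(markers) == 0
    if empty:
        warnings.warn("biomarker panel is empty under the given thresholds",
                      stacklevel=2)
    return BiomarkerPanel(marker_ids=markers, provenance=provenance,
                          empty_warning=empty)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def _auc_mannwhitney(case_scores: np.ndarray, ctrl_scores: np.ndarray) -> float:
    """AUC as the concordance probability P(case > control) + 0.5 P(tie)."""
    gt = (case_scores[:, None] > ctrl_scores[None, :]).sum()
    eq = (case_scores[:, None] == ctrl_scores[None, :]).sum()
    return (gt + 0.5 * eq) / (len(case_scores) * len(ctrl_scores))


def _delong_ci(case_scores: np.ndarray, ctrl_scores: np.ndarray,
               auc: float, level: float = 0.95) -> tuple[float, float]:
    m, n = len(case_scores), len(ctrl_scores)
    psi = (case_scores[:, None] > ctrl_scores[None, :]).astype(float)
    psi += 0.5 * (case_scores[:, None] == ctrl_scores[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = norm.ppf(0.5 + level / 2)
    return float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se))


def roc_single(
    scores: np.ndarray, groups: np.ndarray, orient: bool = True
) -> tuple[float, tuple[float, float], str]:
    """Empirical AUC with a DeLong CI for one score vector.

    ``groups`` holds ``case`` / ``control`` labels.  When ``orient`` is set,
    the direction giving AUC >= 0.5 is reported (``>`` means cases score
    higher).  Constant scores yield AUC 0.5 with a zero-width CI warning.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    case = scores[groups == "case"]
    ctrl = scores[groups == "control"]
    if len(case) == 0 or len(ctrl) == 0:
        raise DiagnosticsError("both classes must be present")
    if np.all(scores == scores[0]):
        warnings.warn("constant scores: AUC 0.5 with zero-width CI", stacklevel=2)
        return 0.5, (0.5, 0.5), ">"
    auc = _auc_mannwhitney(case, ctrl)
    direction = ">"
    if orient and auc < 0.5:
        auc = 1.0 - auc
        case, ctrl = -case, -ctrl
        direction = "<"
    ci = _delong_ci(case, ctrl, auc)
    return float(auc), ci, direction


# ---------------------------------------------------------------------------
# combined diagnostic models
# ---------------------------------------------------------------------------

def _make_classifier(model_kind: str, seed: int):
    if model_kind == "LR":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(max_iter=5000)),
        ])
    if model_kind == "RF":
        return RandomForestClassifier(n_estimators=500, random_state=seed)
    if model_kind == "SVM":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", SVC(kernel="linear", C=1.0)),
        ])
    raise DiagnosticsError(f"unknown model kind {model_kind!r} (use LR, RF or SVM)")


def _score_samples(model, model_kind: str, X: np.ndarray) -> np.ndarray:
    """Predicted case probability; SVM decision values pass a logistic link."""
    if model_kind == "SVM":
        d = model.decision_function(X)
        return 1.0 / (1.0 + np.exp(-d))
    return model.predict_proba(X)[:, 1]


def mccv_combined_roc(
    m: IntensityMatrix,
    model_kind: str = "LR",
    n_iter: int = 50,
    train_fraction: float = 2 / 3,
    seed: int = 0,
) -> DiagnosticResult:
    """Pooled ROC of a marker panel under Monte-Carlo cross-validation.

    Per iteration a class-balanced training set (equal numbers per class,
    ``train_fraction`` of the minority class size) is drawn, the classifier
    fit, and all held-out samples scored; held-out scores pool into a single
    AUC with a DeLong CI.  Per-sample probabilities average over the
    iterations in which the sample was held out.
    """
    if m.n_features == 0:
        raise DiagnosticsError("empty marker panel")
    X, y = _xy(m)
    sample_ids = m.sample_ids
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    n_min = min(len(case_idx), len(ctrl_idx))
    n_train = int(round(train_fraction * n_min))
    if n_min - n_train < 2 or len(y) - 2 * n_train < 4:
        raise DiagnosticsError("train_fraction leaves too few test samples per class")
    rng = np.random.default_rng(seed)
    pooled_scores, pooled_groups = [], []
    prob_sum = np.zeros(len(y))
    prob_cnt = np.zeros(len(y))
    for i in range(n_iter):
        train = np.concatenate([
            rng.choice(case_idx, n_train, replace=False),
            rng.choice(ctrl_idx, n_train, replace=False),
        ])
        test = np.setdiff1d(np.arange(len(y)), train)
        clf = _make_classifier(model_kind, seed=int(rng.integers(2**31 - 1)))
        clf.fit(X[train], y[train])
        s = _score_samples(clf, model_kind, X[test])
        pooled_scores.append(s)
        pooled_groups.append(np.where(y[test] == 1, "case", "control"))
        prob_sum[test] += s
        prob_cnt[test] += 1
    scores = np.concatenate(pooled_scores)
    groups = np.concatenate(pooled_groups)
    auc, ci, _ = roc_single(scores, groups, orient=False)
    probs = {
        sample_ids[i]: float(prob_sum[i] / prob_cnt[i])
        for i in range(len(y)) if prob_cnt[i] > 0
    }
    return DiagnosticResult(model_kind=model_kind, auc=float(auc),
                            ci_low=ci[0], ci_high=ci[1],
                            per_sample_probability=probs)


@dataclass
class FittedPanelModel:
    model_kind: str
    feature_ids: list[str]
    model: object


def fit_panel_model(
    m: IntensityMatrix, model_kind: str = "LR", seed: int = 0
) -> FittedPanelModel:
    """Fit one classifier on the full discovery cohort (for validation use)."""
    X, y = _xy(m)
    clf = _make_classifier(model_kind, seed)
    clf.fit(X, y)
    return FittedPanelModel(model_kind=model_kind, feature_ids=m.feature_ids,
                            model=clf)


def evaluate_validation(
    fitted: FittedPanelModel, m_val: IntensityMatrix
) -> DiagnosticResult:
    """Apply a frozen discovery model to an independent validation cohort."""
    if m_val.n_samples == 0:
        raise DiagnosticsError("empty validation cohort")
    if list(m_val.feature_ids) != list(fitted.feature_ids):
        raise DiagnosticsError(
            "validation features do not match the fitted panel: "
            f"{fitted.feature_ids} vs {m_val.feature_ids}"
        )
    X, y = _xy(m_val)
    s = _score_samples(fitted.model, fitted.model_kind, X)
    groups = np.where(y == 1, "case", "control")
    auc, ci, _ = roc_single(s, groups, orient=False)
    probs = dict(zip(m_val.sample_ids, s.tolist()))
    return DiagnosticResult(model_kind=fitted.model_kind, auc=float(auc),
                            ci_low=ci[0], ci_high=ci[1], cohort="validation",
                            per_sample_probability=probs)


def per_marker_auc(m: IntensityMatrix) -> dict[str, tuple[float, float, float]]:
    """Single-marker empirical AUC (orientation-free, >= 0.5) with DeLong CI."""
    groups = m.groups.to_numpy()
    out = {}
    for fid in m.feature_ids:
        auc, ci, _ = roc_single(m.values.loc[fid].to_numpy(dtype=float), groups)
        out[fid] = (auc, ci[0], ci[1])
    return out
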