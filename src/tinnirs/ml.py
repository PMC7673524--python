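"""Feature ranking, classifiers and cross-validated performance reports.

Continuous features are ranked by information gain — the reduction in
label entropy after equal-frequency discretisation — normalised so the
best feature has weight 1; features above a weight threshold (0.45 or
0.56 in the reference workflow) are kept.  Four classifiers are
supported: Gaussian Naive Bayes, K-nearest neighbours (k = 1), a
RIPPER-style separate-and-conquer rule learner, and a single-hidden-
layer neural network.  Performance is pooled sensitivity / specificity /
accuracy over seeded stratified 10-fold cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

CLASSIFIER_KINDS = ("naive_bayes", "knn", "rule_induction", "neural_net")

#: Tinnitus Handicap Inventory severity bands (score 0-100).
THI_BANDS = (
    (0, 16, "slight"),
    (18, 36, "mild"),
    (38, 56, "moderate"),
    (58, 76, "severe"),
    (78, 100, "catastrophic"),
)


def severity_class(thi: float) -> str:
    """Named THI severity band for a score (band gaps map to the band below)."""
    if not 0 <= thi <= 100:
        raise ValueError("THI must be in 0..100")
    for _, hi, name in THI_BANDS:
        if thi <= hi + 1:  # scores are even; odd gap values fall to the lower band's edge
            return name
    return "catastrophic"


def severity_binary(thi: float, threshold: float = 36.0) -> int:
    """1 for moderate/severe (+), 0 for slight/mild."""
    return int(thi > threshold)


# ------------------------------------------------------ information gain


def _entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def information_gain(values: np.ndarray, labels: np.ndarray, n_bins: int = 5) -> float:
    """IG of one continuous feature after equal-frequency discretisation."""
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    if len(values) == 0 or len(np.unique(labels)) < 2:
        return 0.0
    if np.unique(values).size == 1:
        return 0.0
    try:
        binned = pd.qcut(values, q=min(n_bins, np.unique(values).size), duplicates="drop")
    except ValueError:
        # degenerate spread (e.g. subnormal range): carries no usable signal
        return 0.0
    h_label = _entropy(np.bincount(pd.factorize(labels)[0]))
    cond = 0.0
    y = pd.factorize(labels)[0]
    for _, idx in pd.Series(range(len(values))).groupby(binned.codes):
        sub = y[idx.to_numpy()]
        cond += len(sub) / len(y) * _entropy(np.bincount(sub))
    return max(h_label - cond, 0.0)


def information_gain_rank(
    features: pd.DataFrame, labels: np.ndarray, n_bins: int = 5
) -> pd.Series:
    """Per-feature IG weights normalised to [0, 1] by the maximum gain."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        return pd.Series(0.0, index=features.columns)
    raw = {
        col: information_gain(features[col].to_numpy(dtype=float), labels, n_bins)
        for col in features.columns
    }
    weights = pd.Series(raw)
    top = weights.max()
    return weights / top if top > 0 else weights


def select_features(weights: pd.Series, threshold: float) -> list[str]:
    """Features with weight strictly above the threshold, best first."""
    chosen = weights[weights > threshold].sort_values(ascending=False)
    if chosen.empty:
        raise ValueError(f"no features weighted above {threshold}")
    return list(chosen.index)


# ---------------------------------------------------------- classifiers


class RuleInductionClassifier(BaseEstimator, ClassifierMixin):
    """RIPPER-style separate-and-conquer rule learner for binary labels.

    Rules for the minority (positive) class are grown literal-by-literal
    on threshold conditions chosen by FOIL information gain, then
    simplified by reduced-error pruning on a held-out third of the
    training data; covered examples are removed and the process repeats.
    An example is predicted positive when any rule fires, and the default
    prediction is the majority class.
    """

    def __init__(self, random_state: int = 0, prune_fraction: float = 1 / 3,
                 max_rules: int = 8, max_literals: int = 4):
        self.random_state = random_state
        self.prune_fraction = prune_fraction
        self.max_rules = max_rules
        self.max_literals = max_literals

    @staticmethod
    def _covers(rule, X):
        mask = np.ones(len(X), dtype=bool)
        for j, op, thr in rule:
            mask &= X[:, j] <= thr if op == "<=" else X[:, j] > thr
        return mask

    @staticmethod
    def _foil_gain(p0, n0, p1, n1):
        if p1 == 0:
            return -np.inf
        return p1 * (np.log2(p1 / (p1 + n1)) - np.log2(max(p0, 1e-9) / (p0 + n0)))

    def _grow(self, X, y):
        rule = []
        mask = np.ones(len(X), dtype=bool)
        while len(rule) < self.max_literals:
            p0, n0 = (y[mask] == 1).sum(), (y[mask] == 0).sum()
            if n0 == 0 or p0 == 0:
                break
            best, best_gain = None, 0.0
            for j in range(X.shape[1]):
                vals = np.unique(X[mask, j])
                if len(vals) < 2:
                    continue
                cuts = (vals[:-1] + vals[1:]) / 2
                if len(cuts) > 16:
                    cuts = cuts[np.linspace(0, len(cuts) - 1, 16).astype(int)]
                for thr in cuts:
                    for op in ("<=", ">"):
                        m = mask & (X[:, j] <= thr if op == "<=" else X[:, j] > thr)
                        gain = self._foil_gain(p0, n0, (y[m] == 1).sum(), (y[m] == 0).sum())
                        if gain > best_gain:
                            best, best_gain = (j, op, thr), gain
            if best is None:
                break
            rule.append(best)
            j, op, thr = best
            mask &= X[:, j] <= thr if op == "<=" else X[:, j] > thr
        return rule

    def _prune(self, rule, X, y):
        def value(r):
            if not r:
                return -np.inf
            m = self._covers(r, X)
            p, n = (y[m] == 1).sum(), (y[m] == 0).sum()
            return (p - n) / (p + n) if p + n else -np.inf
        while len(rule) > 1 and value(rule[:-1]) >= value(rule):
            rule = rule[:-1]
        return rule

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        if len(self.classes_) != 2:
            raise ValueError("rule induction supports binary labels only")
        self.positive_ = self.classes_[np.argmin(counts)]
        yb = (y == self.positive_).astype(int)
        rng = np.random.default_rng(self.random_state)
        order = rng.permutation(len(y))
        n_prune = max(int(len(y) * self.prune_fraction), 2)
        prune_idx, grow_idx = order[:n_prune], order[n_prune:]
        Xg, yg = X[grow_idx], yb[grow_idx]
        Xp, yp = X[prune_idx], yb[prune_idx]

        self.rules_ = []
        active = np.ones(len(yg), dtype=bool)
        while (yg[active] == 1).any() and len(self.rules_) < self.max_rules:
            rule = self._grow(Xg[active], yg[active])
            if not rule:
                break
            rule = self._prune(rule, Xp, yp)
            m = self._covers(rule, Xg[active])
            p, n = (yg[active][m] == 1).sum(), (yg[active][m] == 0).sum()
            if p == 0 or p < n:  # rule worse than chance on grow data
                break
            self.rules_.append(rule)
            covered = np.zeros(len(yg), dtype=bool)
            covered[np.flatnonzero(active)[m]] = True
            active &= ~covered
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        fired = np.zeros(len(X), dtype=bool)
        for rule in getattr(self, "rules_", []):
            fired |= self._covers(rule, X)
        negative = self.classes_[self.classes_ != self.positive_][0]
        return np.where(fired, self.positive_, negative)


def make_classifier(kind: str, seed: int = 0, knn_k: int = 1, ann_hidden: int = 10):
    """Instantiate one of the four supported classifiers."""
    if kind == "naive_bayes":
        return GaussianNB()
    if kind == "knn":
        return Pipeline([
            ("scale", StandardScaler()),
            ("knn", KNeighborsClassifier(n_neighbors=knn_k)),
        ])
    if kind == "rule_induction":
        return RuleInductionClassifier(random_state=seed)
    if kind == "neural_net":
        return Pipeline([
            ("scale", StandardScaler()),
            ("ann", MLPClassifier(
                hidden_layer_sizes=(ann_hidden,), activation="logistic",
                solver="adam", learning_rate_init=0.01, max_iter=800,
                random_state=seed, tol=1e-5,
            )),
        ])
    raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")


def train_classifier(kind: str, features, labels, seed: int = 0, **hyper):
    """Fit a classifier of the given kind on a feature matrix."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if kind == "knn" and hyper.get("knn_k", 1) > len(y):
        raise ValueError("k exceeds the number of training samples")
    model = make_classifier(kind, seed=seed, **hyper)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter on tiny folds
        model.fit(X, y)
    return model


# ------------------------------------------------------ cross-validation


@dataclass
class ClassificationReport:
    classifier: str
    feature_set: str
    selected_features: list = field(default_factory=list)
    feature_weights: dict = field(default_factory=dict)
    fold_confusions: list = field(default_factory=list)
    fold_assignments: list = field(default_factory=list)
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    task: str = "group"
    threshold: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else np.nan

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else np.nan

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n if self.n else np.nan

    def summary_row(self) -> dict:
        return {
            "task": self.task, "classifier": self.classifier, "feature_set": self.feature_set,
            "threshold": self.threshold, "n_features": len(self.selected_features),
            "sensitivity_pct": round(self.sensitivity, 2),
            "specificity_pct": round(self.specificity, 2),
            "accuracy_pct": round(self.accuracy, 2), "n": self.n,
        }


def stratified_folds(labels: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded stratified partition; fold sizes differ by at most one.

    Members of each class are shuffled and dealt cyclically into folds,
    continuing the deal across classes so overall fold sizes stay
    balanced even when a class has fewer members than folds.
    """
    n = len(labels)
    if n < n_folds:
        raise ValueError("fewer samples than folds")
    assignment = np.empty(n, dtype=int)
    offset = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for k, i in enumerate(idx):
            assignment[i] = (offset + k) % n_folds
        offset += len(idx)
    return assignment


def _impute_train_means(X_train: np.ndarray, X_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = np.nanmean(
        np.where(np.isfinite(X_train), X_train, np.nan), axis=0, keepdims=True
    )
    means = np.where(np.isfinite(means), means, 0.0)
    fill = lambda A: np.where(np.isfinite(A), A, means)
    return fill(X_train), fill(X_test)


def crossvalidate(
    kind: str,
    features,
    labels,
    folds: int = 10,
    seed: int = 0,
    feature_set: str = "custom",
    task: str = "group",
    **hyper,
) -> ClassificationReport:
    """Pooled confusion counts over seeded stratified k-fold CV.

    Positive class is label 1.  Missing feature values are mean-imputed
    from the training fold.  A degenerate fold whose training data holds
    a single class triggers a reseeded redraw of the partition.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    for attempt in range(10):
        assignment = stratified_folds(y, folds, rng)
        if all(len(np.unique(y[assignment != k])) == 2 for k in range(folds)):
            break
        warnings.warn("single-class training fold; redrawing partition")
    report = ClassificationReport(
        classifier=kind, feature_set=feature_set, task=task,
        fold_assignments=assignment.tolist(),
    )
    for k in range(folds):
        test = assignment == k
        X_tr, X_te = _impute_train_means(X[~test], X[test])
        model = train_classifier(kind, X_tr, y[~test], seed=seed + k, **hyper)
        pred = model.predict(X_te)
        truth = y[test]
        conf = {
            "fold": k,
            "tp": int(((pred == 1) & (truth == 1)).sum()),
            "tn": int(((pred == 0) & (truth == 0)).sum()),
            "fp": int(((pred == 1) & (truth == 0)).sum()),
            "fn": int(((pred == 0) & (truth == 1)).sum()),
        }
        report.fold_confusions.append(conf)
        report.tp += conf["tp"]; report.tn += conf["tn"]
        report.fp += conf["fp"]; report.fn += conf["fn"]
    return report


def run_classification_workflow(table: pd.DataFrame, config=None, seed: int = 0) -> list[ClassificationReport]:
    """The full classification grid on a cohort feature table.

    Two tasks — tinnitus vs control, and (within the tinnitus group)
    moderate/severe vs slight/mild by THI — each over the four feature
    sets {auditory, visual, connectivity, combined} and four classifier
    kinds, with information-gain selection at the per-set weight
    threshold.  If no feature clears the threshold the ten best-weighted
    features are used instead (logged in the report).
    """
    from .config import RunConfig
    from .pipeline import feature_columns

    config = config or RunConfig()
    reports = []

    tasks = [("group", table, (table["group"] == "tinnitus").to_numpy().astype(int))]
    tin = table[table["group"] == "tinnitus"]
    if len(tin) >= config.cv_folds and "thi" in tin.columns:
        sev = np.array([severity_binary(t, config.severity_binary_threshold) for t in tin["thi"]])
        if len(np.unique(sev)) == 2:
            tasks.append(("severity", tin, sev))
        else:
            warnings.warn("severity labels degenerate; severity task skipped")
    else:
        warnings.warn("too few tinnitus subjects; severity task skipped")

    for task, sub, y in tasks:
        for feature_set in ("auditory", "visual", "connectivity", "combined"):
            cols = [c for c in feature_columns(sub, feature_set) if sub[c].notna().any()]
            if not cols:
                continue
            X = sub[cols].apply(lambda c: c.fillna(c.mean()))
            weights = information_gain_rank(X, y, config.ig_bins)
            threshold = config.ig_thresholds.get(feature_set, 0.45)
            try:
                chosen = select_features(weights, threshold)
            except ValueError:
                warnings.warn(f"{task}/{feature_set}: nothing above {threshold}; using top 10")
                chosen = list(weights.sort_values(ascending=False).index[:10])
            for kind in CLASSIFIER_KINDS:
                rep = crossvalidate(
                    kind, sub[chosen].apply(lambda c: c.fillna(np.nan)), y,
                    folds=config.cv_folds, seed=seed, feature_set=feature_set,
                    task=task, knn_k=config.knn_k, ann_hidden=config.ann_hidden,
                )
                rep.selected_features = chosen
                rep.feature_weights = weights[chosen].to_dict()
                rep.threshold = threshold
                reports.append(rep)
    return reports


def reports_to_frame(reports: list[ClassificationReport]) -> pd.DataFrame:
    return pd.DataFrame([r.summary_row() for r in reports])
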