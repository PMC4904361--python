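"""Classifiers over truncated topological profiles.

The Bayes classifier uses, for each reference class, the empirical
discrete density of truncated topological profiles (TTPs) estimated from
seeded rotation/truncation simulation; profiles act as hash keys with
limited support, so the density estimate is an unbiased Bernoulli-rate
estimator converging at the parametric rate.  The posterior is

    p(class | T)  propto  p(T | class) p(class)

with a uniform prior over the merged classes by default.  When a test
profile was never seen in any class's training set, the Bayes rule
abstains (a "no match"); abstentions count as misclassification.

SVM and LDA classifiers operate on the same 231-dimensional profile
vectors (standardized per column) and, unlike the exact-match Bayes rule,
remain usable when test profiles are mis-specified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import SUBSETS, TP_DIM


def _keys(profiles: np.ndarray) -> list[bytes]:
    arr = np.ascontiguousarray(np.atleast_2d(profiles), dtype=np.int64)
    return [row.tobytes() for row in arr]


@dataclass
class TTPDensity:
    """Empirical discrete TTP density for one class."""

    class_label: int
    counts: dict[bytes, int]
    n: int

    @classmethod
    def estimate(cls, profiles: np.ndarray, class_label: int) -> "TTPDensity":
        keys = _keys(profiles)
        if not keys:
            raise ValueError("empty training set")
        counts: dict[bytes, int] = {}
        for k in keys:
            counts[k] = counts.get(k, 0) + 1
        return cls(class_label=class_label, counts=counts, n=len(keys))

    def prob(self, profile) -> float:
        key = profile if isinstance(profile, bytes) else _keys(profile)[0]
        return self.counts.get(key, 0) / self.n

    @property
    def support_size(self) -> int:
        return len(self.counts)


def estimate_density(profiles: np.ndarray, class_label: int) -> TTPDensity:
    """Normalized hash-count table p(T | class) = count(T)/n."""
    return TTPDensity.estimate(profiles, class_label)


class BayesClassifier:
    """Empirical-density Bayes rule over the merged class space."""

    def __init__(self, densities: dict[int, TTPDensity],
                 prior: dict[int, float] | None = None):
        self.labels = sorted(densities)
        self.densities = densities
        if prior is None:
            p = 1.0 / len(self.labels)
            self.prior = {c: p for c in self.labels}
        else:
            tot = sum(prior.get(c, 0.0) for c in self.labels)
            if abs(tot - 1.0) > 1e-9:
                raise ValueError("prior must sum to 1 over the classes")
            self.prior = {c: float(prior[c]) for c in self.labels}
        self._prior_vec = np.array([self.prior[c] for c in self.labels])
        self._cache: dict[bytes, tuple[int, np.ndarray]] = {}

    def posterior(self, profile) -> tuple[int | None, np.ndarray]:
        """(argmax class or None, normalized posterior vector).

        Ties are broken by the lowest class label; when every class
        likelihood is zero the rule abstains and the posterior is all
        zeros.
        """
        key = profile if isinstance(profile, bytes) else _keys(profile)[0]
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        lik = np.array([self.densities[c].counts.get(key, 0) /
                        self.densities[c].n for c in self.labels])
        unnorm = lik * self._prior_vec
        tot = unnorm.sum()
        if tot <= 0.0:
            res: tuple[int | None, np.ndarray] = (None, np.zeros(len(self.labels)))
        else:
            post = unnorm / tot
            res = (self.labels[int(np.argmax(post))], post)
        self._cache[key] = res
        return res

    def classify(self, profiles: np.ndarray) -> np.ndarray:
        """Predicted labels for a batch; abstention encoded as -1."""
        out = np.empty(len(np.atleast_2d(profiles)), dtype=np.int64)
        for i, key in enumerate(_keys(profiles)):
            lab, _ = self.posterior(key)
            out[i] = -1 if lab is None else lab
        return out


def bayes_classify(profile, densities: dict[int, TTPDensity],
                   prior: dict[int, float] | None = None):
    """One-shot Bayes classification; see `BayesClassifier.posterior`."""
    return BayesClassifier(densities, prior).posterior(profile)


# --------------------------------------------------------------------------
# discriminative classifiers

class DiscriminativeClassifier:
    """SVM or LDA on (optionally feature-masked) profile vectors.

    Features are standardized per column with training statistics.
    Identical training rows are merged with multiplicity weights for the
    SVM (the TTP distributions have small support, which makes kernel
    training dramatically cheaper at unchanged solutions).
    """

    def __init__(self, method: str = "svm", feature_subset: str = "all",
                 svm_c: float = 1.0, svm_gamma="scale"):
        if method not in ("svm", "lda"):
            raise ValueError("method must be 'svm' or 'lda'")
        if feature_subset not in SUBSETS:
            raise ValueError(f"unknown feature subset {feature_subset!r}")
        self.method = method
        self.feature_subset = feature_subset
        self.svm_c = svm_c
        self.svm_gamma = svm_gamma
        self._mask = SUBSETS[feature_subset]
        self._model = None

    def _design(self, X):
        X = np.atleast_2d(np.asarray(X))
        if X.shape[1] != TP_DIM:
            raise ValueError(f"feature dimension must be {TP_DIM}")
        return X[:, self._mask].astype(float)

    def fit(self, X, y):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        Xd = self._design(X)
        y = np.asarray(y, dtype=np.int64)
        if self.method == "lda":
            labels, cnt = np.unique(y, return_counts=True)
            if np.any(cnt < 2):
                raise ValueError("LDA needs >= 2 training points per class")
            self._model = Pipeline([
                ("scale", StandardScaler()),
                ("clf", LinearDiscriminantAnalysis()),
            ])
            try:
                self._model.fit(Xd, y)
            except (IndexError, np.linalg.LinAlgError):
                # degenerate within-class scatter (classes made of
                # duplicated rows): LDA with vanishing isotropic
                # within-class covariance reduces to nearest centroid
                from sklearn.neighbors import NearestCentroid

                self._model = Pipeline([
                    ("scale", StandardScaler()),
                    ("clf", NearestCentroid()),
                ])
                self._model.fit(Xd, y)
        else:
            # merge duplicate rows into sample weights
            full = np.column_stack([Xd, y[:, None]])
            uniq, counts = np.unique(full, axis=0, return_counts=True)
            Xu, yu = uniq[:, :-1], uniq[:, -1].astype(np.int64)
            self._model = Pipeline([
                ("scale", StandardScaler()),
                ("clf", SVC(kernel="rbf", C=self.svm_c, gamma=self.svm_gamma,
                            decision_function_shape="ovo")),
            ])
            self._model.fit(Xu, yu, clf__sample_weight=counts.astype(float))
        return self

    def predict(self, X) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("classifier is not fitted")
        return self._model.predict(self._design(X)).astype(np.int64)


def train_discriminative(X, y, method="svm",
                         feature_subset="all") -> DiscriminativeClassifier:
    return DiscriminativeClassifier(method=method,
                                    feature_subset=feature_subset).fit(X, y)


# --------------------------------------------------------------------------
# evaluation

@dataclass
class EvaluationResult:
    """Confusion matrix and summary statistics of one evaluation run.

    confusion[i, j] counts test profiles of true class labels[j]
    predicted as labels[i]; an extra final row collects abstentions.
    """

    labels: list[int]
    confusion: np.ndarray
    per_class_error: dict[int, float] = field(default_factory=dict)
    overall_error: float = float("nan")

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels=None) -> "EvaluationResult":
        y_true = np.asarray(y_true, dtype=np.int64)
        y_pred = np.asarray(y_pred, dtype=np.int64)
        if y_true.shape != y_pred.shape:
            raise ValueError("prediction/truth length mismatch")
        if labels is None:
            labels = sorted(set(y_true.tolist()))
        labels = list(labels)
        extra = set(y_pred.tolist()) - set(labels) - {-1}
        if extra:
            raise ValueError(f"predicted labels outside class space: {extra}")
        pos = {c: i for i, c in enumerate(labels)}
        M = np.zeros((len(labels) + 1, len(labels)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            row = pos[p] if p != -1 else len(labels)
            M[row, pos[t]] += 1
        per_class = {}
        for c in labels:
            j = pos[c]
            tot = M[:, j].sum()
            per_class[c] = 1.0 - (M[pos[c], j] / tot if tot else 0.0)
        overall = float(np.mean(list(per_class.values())))
        return cls(labels=labels, confusion=M, per_class_error=per_class,
                   overall_error=overall)

    # -- statistics --------------------------------------------------------

    def ppv(self) -> dict[int, float]:
        """Positive predictive value per predicted class.

        PPV(c) = (test profiles truly of class c predicted as c) /
        (all test profiles predicted as c); classes never predicted are
        omitted.
        """
        out = {}
        for i, c in enumerate(self.labels):
            row = self.confusion[i, :]
            tot = row.sum()
            if tot > 0:
                out[c] = float(row[i] / tot)
        return out

    def mean_ppv(self) -> float:
        vals = list(self.ppv().values())
        return float(np.mean(vals)) if vals else float("nan")

    def regret(self, baseline: "EvaluationResult") -> dict[int, float]:
        """Per-class misclassification excess over a baseline classifier."""
        return {c: self.per_class_error[c] - baseline.per_class_error[c]
                for c in self.labels}

    def mean_regret(self, baseline: "EvaluationResult") -> float:
        return float(np.mean(list(self.regret(baseline).values())))

    def family_confusion_mass(self, true_ids, pred_ids) -> float:
        """Fraction of test profiles with true class in `true_ids`
        predicted into `pred_ids` (label sets)."""
        pos = {c: i for i, c in enumerate(self.labels)}
        cols = [pos[c] for c in true_ids if c in pos]
        rows = [pos[c] for c in pred_ids if c in pos]
        if not cols:
            return float("nan")
        sub = self.confusion[np.ix_(rows, cols)]
        denom = self.confusion[:, cols].sum()
        return float(sub.sum() / denom) if denom else float("nan")


def match_probability(pred_by_level: dict) -> dict[tuple, float]:
    """Pairwise agreement of predictions across truncation levels.

    For each pair of levels (t, s) returns the fraction of objects
    assigned the same class at both levels.
    """
    levels = sorted(pred_by_level)
    out = {}
    for i, t in enumerate(levels):
        for s in levels[i + 1:]:
            a = np.asarray(pred_by_level[t])
            b = np.asarray(pred_by_level[s])
            if a.shape != b.shape:
                raise ValueError("prediction vectors differ in length")
            out[(t, s)] = float(np.mean(a == b))
    return out
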