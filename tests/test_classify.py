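import numpy as np
import pytest

from polyclass.classify import (BayesClassifier, DiscriminativeClassifier,
                                EvaluationResult, TTPDensity, bayes_classify,
                                estimate_density, match_probability)
from polyclass.features import TP_DIM


def _profiles(rows):
    """Embed small integer rows as 231-dim profile vectors."""
    out = np.zeros((len(rows), TP_DIM), dtype=np.int64)
    for i, row in enumerate(rows):
        out[i, :len(row)] = row
    return out


def test_density_single_atom():
    profs = _profiles([[1, 2]] * 7)
    d = estimate_density(profs, class_label=3)
    assert d.n == 7 and d.support_size == 1
    assert d.prob(profs[:1]) == 1.0


def test_density_counts_and_unseen():
    profs = _profiles([[1], [1], [1], [2]])
    d = estimate_density(profs, 1)
    assert d.prob(profs[:1]) == 0.75
    assert d.prob(profs[3:4]) == 0.25
    assert d.prob(_profiles([[9]])[:1]) == 0.0
    with pytest.raises(ValueError):
        estimate_density(np.zeros((0, TP_DIM)), 1)


def test_density_estimate_is_unbiased():
    # resample a known two-atom distribution; mean within 3 SE of truth
    rng = np.random.default_rng(0)
    p_true, n, reps = 0.3, 50, 100
    atoms = _profiles([[1], [2]])
    est = []
    for _ in range(reps):
        draws = atoms[(rng.random(n) > p_true).astype(int)]
        est.append(estimate_density(draws, 1).prob(atoms[:1]))
    se = np.sqrt(p_true * (1 - p_true) / n / reps)
    assert abs(np.mean(est) - p_true) < 3 * se


def test_bayes_posterior_arithmetic():
    t1, t2, t3 = _profiles([[1], [2], [3]])
    densities = {
        1: TTPDensity(1, {t1.tobytes(): 2, t2.tobytes(): 8}, 10),
        2: TTPDensity(2, {t2.tobytes(): 1, t3.tobytes(): 9}, 10),
    }
    clf = BayesClassifier(densities)
    label, post = clf.posterior(t1[None, :])
    assert label == 1 and np.allclose(post, [1.0, 0.0])
    # likelihoods 0.8 vs 0.1 with uniform prior -> posteriors 8/9, 1/9
    label, post = clf.posterior(t2[None, :])
    assert label == 1
    assert np.allclose(post, [8 / 9, 1 / 9])
    # never-seen profile: abstention
    label, post = clf.posterior(_profiles([[7]])[0][None, :])
    assert label is None and not post.any()


def test_bayes_prior_and_ties():
    t1 = _profiles([[1]])[0]
    densities = {1: TTPDensity(1, {t1.tobytes(): 1}, 1),
                 2: TTPDensity(2, {t1.tobytes(): 1}, 1)}
    label, post = bayes_classify(t1[None, :], densities)
    assert label == 1  # tie broken to the lowest class label
    assert post.sum() == pytest.approx(1.0)
    label, _ = bayes_classify(t1[None, :], densities,
                              prior={1: 0.1, 2: 0.9})
    assert label == 2
    with pytest.raises(ValueError, match="sum to 1"):
        BayesClassifier(densities, prior={1: 0.5, 2: 0.6})


def test_discriminative_perfect_separation():
    X = np.vstack([_profiles([[5, 0, 1]] * 10), _profiles([[0, 7, 2]] * 10)])
    y = np.array([1] * 10 + [2] * 10)
    for method in ("svm", "lda"):
        clf = DiscriminativeClassifier(method=method).fit(X, y)
        assert (clf.predict(X) == y).all()


def test_discriminative_input_validation():
    X = _profiles([[1], [1], [2], [2]])
    y = np.array([1, 1, 2, 2])
    with pytest.raises(ValueError):
        DiscriminativeClassifier(method="forest")
    with pytest.raises(ValueError):
        DiscriminativeClassifier(feature_subset="nope")
    clf = DiscriminativeClassifier(method="lda")
    with pytest.raises(ValueError, match=">= 2"):
        clf.fit(X, np.array([1, 1, 2, 3]))
    clf.fit(X, y)
    with pytest.raises(ValueError, match="dimension"):
        clf.predict(np.zeros((2, 10)))


def test_feature_subset_masks_change_the_design():
    rng = np.random.default_rng(1)
    X = rng.integers(0, 5, size=(30, TP_DIM))
    y = rng.integers(1, 4, size=30)
    g = DiscriminativeClassifier(method="lda", feature_subset="global")
    assert g._design(X).shape == (30, 3)
    c = DiscriminativeClassifier(method="lda", feature_subset="complete")
    assert c._design(X).shape == (30, 12)


# -- evaluation -------------------------------------------------------------

def test_evaluation_perfect_and_constant():
    y = np.repeat([1, 2, 3], 5)
    perfect = EvaluationResult.from_predictions(y, y)
    assert perfect.overall_error == 0.0
    assert np.trace(perfect.confusion[:3]) == 15
    const = EvaluationResult.from_predictions(y, np.ones_like(y))
    assert const.per_class_error[1] == 0.0
    assert const.per_class_error[2] == 1.0
    assert const.overall_error == pytest.approx(2 / 3)
    # column sums equal the per-class test counts
    assert (const.confusion.sum(axis=0) == 5).all()


def test_evaluation_abstention_counts_as_error():
    y = np.array([1, 1, 2, 2])
    pred = np.array([1, -1, 2, -1])
    res = EvaluationResult.from_predictions(y, pred)
    assert res.per_class_error[1] == pytest.approx(0.5)
    assert res.confusion[-1].sum() == 2  # abstention row


def test_ppv_and_regret():
    y = np.repeat([1, 2], 10)
    pred = np.array([1] * 8 + [2] * 2 + [1] * 4 + [2] * 6)
    res = EvaluationResult.from_predictions(y, pred)
    ppv = res.ppv()
    assert ppv[1] == pytest.approx(8 / 12)
    assert ppv[2] == pytest.approx(6 / 8)
    base = EvaluationResult.from_predictions(y, y)
    regret = res.regret(base)
    assert regret[1] == pytest.approx(0.2)
    assert res.mean_regret(base) == pytest.approx(0.3)
    assert base.mean_regret(base) == 0.0


def test_family_confusion_mass():
    y = np.repeat([1, 2], 4)
    pred = np.array([1, 1, 2, 2, 2, 2, 2, 2])
    res = EvaluationResult.from_predictions(y, pred)
    # mass of true-class-1 objects predicted into {2}
    assert res.family_confusion_mass([1], [2]) == pytest.approx(0.5)


def test_match_probability():
    preds = {10: np.array([1, 2, 3]), 20: np.array([1, 2, 4]),
             30: np.array([1, 5, 4])}
    mp = match_probability(preds)
    assert mp[(10, 20)] == pytest.approx(2 / 3)
    assert mp[(10, 30)] == pytest.approx(1 / 3)
    assert mp[(20, 30)] == pytest.approx(2 / 3)
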