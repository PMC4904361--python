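"""Reproducible simulate -> train -> evaluate experiment pipelines.

A single experiment seed expands into independent per-(class, percent,
stage) substreams, so training sets, test sets and perturbation draws are
reproducible individually and under partial re-runs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from .classify import (BayesClassifier, DiscriminativeClassifier,
                       EvaluationResult, TTPDensity)
from .features import SUBSETS, compute_profile
from .library import ClassMap, build_library, find_duplicate_profiles
from .truncation import (TruncationSampler, generate_ttps,
                         perturb_delete_vertex, truncate)

_STAGE_TRAIN, _STAGE_TEST, _STAGE_PERTURB = 0, 1, 2


def _substream_seed(root: int, label: int, percent: float, stage: int):
    return [int(root), int(label), int(round(percent * 100)), int(stage)]


@dataclass
class ExperimentConfig:
    """Configuration of a full classification experiment."""

    percents: tuple[float, ...] = (10.0, 15.0, 20.0, 25.0, 30.0)
    n_train: int = 4500
    n_test: int = 500
    seed: int = 0
    method: str = "bayes"  # bayes | svm | lda
    feature_subset: str = "all"
    vertex_cap: int | None = None
    perturb: bool = False

    def __post_init__(self):
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("n_train and n_test must be positive")
        for p in self.percents:
            if not 0.0 <= p < 100.0:
                raise ValueError("truncation percents must be in [0, 100)")
        if self.method not in ("bayes", "svm", "lda"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.feature_subset not in SUBSETS:
            raise ValueError(f"unknown feature subset {self.feature_subset!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        obj = json.loads(text)
        obj["percents"] = tuple(obj["percents"])
        return cls(**obj)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class ClassSpace:
    """Merged class space with per-class representative solids."""

    class_map: ClassMap
    samplers: dict[int, TruncationSampler] = field(repr=False)
    solids: dict[int, object] = field(repr=False)

    @classmethod
    def build(cls, vertex_cap: int | None = None) -> "ClassSpace":
        library = build_library()
        cmap = find_duplicate_profiles(library)
        by_id = {p.id: p for p in library}
        samplers, solids = {}, {}
        for label in cmap.classes():
            rep = by_id[cmap.representative(label)]
            if vertex_cap is not None and rep.n_vertices > vertex_cap:
                continue
            solids[label] = rep
            samplers[label] = TruncationSampler(rep)
        return cls(class_map=cmap, samplers=samplers, solids=solids)

    @property
    def labels(self) -> list[int]:
        return sorted(self.samplers)

    def family_of(self, label: int) -> str:
        return self.solids[label].family


def training_profiles(space: ClassSpace, label: int, percent: float,
                      n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(
        _substream_seed(seed, label, percent, _STAGE_TRAIN))
    phis = rng.uniform(0.0, 2.0 * np.pi, size=(n, 2))
    return space.samplers[label].profiles(phis, percent)


def heldout_profiles(space: ClassSpace, label: int, percent: float,
                  nt: int, seed: int, perturb: bool = False) -> np.ndarray:
    rng = np.random.default_rng(
        _substream_seed(seed, label, percent, _STAGE_TEST))
    phis = rng.uniform(0.0, 2.0 * np.pi, size=(nt, 2))
    if not perturb:
        return space.samplers[label].profiles(phis, percent)
    # mis-specified graphs: delete one random vertex before profiling
    prng = np.random.default_rng(
        _substream_seed(seed, label, percent, _STAGE_PERTURB))
    solid = space.solids[label]
    d = space.samplers[label].plane_distance(percent)
    out = np.empty((nt, 231), dtype=np.int64)
    for i, phi in enumerate(phis):
        pg = truncate(solid, tuple(phi), d)
        pg = perturb_delete_vertex(pg, prng)
        out[i] = compute_profile(pg).vector
    return out


def train_bayes(space: ClassSpace, percent: float, n: int,
                seed: int) -> BayesClassifier:
    densities = {
        label: TTPDensity.estimate(
            training_profiles(space, label, percent, n, seed), label)
        for label in space.labels}
    return BayesClassifier(densities)


def stacked_test_set(space: ClassSpace, percent: float, nt: int, seed: int,
                     perturb: bool = False):
    Xs, ys = [], []
    for label in space.labels:
        Xs.append(heldout_profiles(space, label, percent, nt, seed, perturb))
        ys.append(np.full(nt, label, dtype=np.int64))
    return np.vstack(Xs), np.concatenate(ys)


def stacked_training_set(space: ClassSpace, percent: float, n: int, seed: int):
    Xs, ys = [], []
    for label in space.labels:
        Xs.append(training_profiles(space, label, percent, n, seed))
        ys.append(np.full(n, label, dtype=np.int64))
    return np.vstack(Xs), np.concatenate(ys)


def bayes_study(space: ClassSpace, percents, n_train: int, n_test: int,
                seed: int) -> dict[float, EvaluationResult]:
    """Bayes misclassification per truncation percent (matched train/test)."""
    out = {}
    for percent in percents:
        clf = train_bayes(space, percent, n_train, seed)
        X, y = stacked_test_set(space, percent, n_test, seed)
        pred = clf.classify(X)
        out[percent] = EvaluationResult.from_predictions(
            y, pred, labels=space.labels)
    return out


def discriminative_study(space: ClassSpace, percent: float, n_train: int,
                         n_test: int, seed: int, methods=("svm", "lda"),
                         perturb: bool = False, feature_subset: str = "all"):
    """SVM/LDA vs Bayes on one truncation level, shared train/test sets.

    Returns {"bayes": EvaluationResult, method: EvaluationResult, ...}.
    """
    Xtr, ytr = stacked_training_set(space, percent, n_train, seed)
    Xte, yte = stacked_test_set(space, percent, n_test, seed, perturb=perturb)

    results: dict[str, EvaluationResult] = {}
    bayes = train_bayes(space, percent, n_train, seed)
    results["bayes"] = EvaluationResult.from_predictions(
        yte, bayes.classify(Xte), labels=space.labels)
    for method in methods:
        clf = DiscriminativeClassifier(
            method=method, feature_subset=feature_subset).fit(Xtr, ytr)
        results[method] = EvaluationResult.from_predictions(
            yte, clf.predict(Xte), labels=space.labels)
    return results


def feature_subset_regret(space: ClassSpace, percent: float, n_train: int,
                          n_test: int, seed: int, method: str = "svm",
                          subsets=("all", "global", "local", "complete",
                                   "incomplete"),
                          perturb: bool = False) -> dict[str, float]:
    """Mean regret of feature-subset classifiers vs the all-features one."""
    Xtr, ytr = stacked_training_set(space, percent, n_train, seed)
    Xte, yte = stacked_test_set(space, percent, n_test, seed, perturb=perturb)
    evals = {}
    for sub in subsets:
        clf = DiscriminativeClassifier(method=method, feature_subset=sub)
        clf.fit(Xtr, ytr)
        evals[sub] = EvaluationResult.from_predictions(
            yte, clf.predict(Xte), labels=space.labels)
    base = evals["all"]
    return {sub: evals[sub].mean_regret(base) for sub in subsets}


def run_experiment(config: ExperimentConfig, outdir) -> dict:
    """Execute a configured experiment and write artifacts to `outdir`.

    Writes confusion_<percent>.csv, summary.json and a run log; returns
    the summary dictionary.
    """
    import pathlib

    import pandas as pd

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    space = ClassSpace.build(vertex_cap=config.vertex_cap)
    summary = {"config": asdict(config), "config_hash": config.config_hash,
               "n_classes": len(space.labels), "percents": {}}
    log = [f"config_hash {config.config_hash}", f"seed {config.seed}",
           f"classes {len(space.labels)}"]
    for percent in config.percents:
        if config.method == "bayes":
            res = bayes_study(space, [percent], config.n_train,
                              config.n_test, config.seed)[percent]
        else:
            res = discriminative_study(
                space, percent, config.n_train, config.n_test, config.seed,
                methods=(config.method,), perturb=config.perturb,
                feature_subset=config.feature_subset)[config.method]
        fname = outdir / f"confusion_{config.config_hash}_{percent:g}.csv"
        pd.DataFrame(res.confusion,
                     index=[*res.labels, "abstain"],
                     columns=res.labels).to_csv(fname)
        summary["percents"][str(percent)] = {
            "overall_error": res.overall_error,
            "mean_ppv": res.mean_ppv(),
        }
        log.append(f"percent {percent} error {res.overall_error:.4f} "
                   f"elapsed {time.time() - t0:.1f}s")
    with open(outdir / f"summary_{config.config_hash}.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    with open(outdir / f"log_{config.config_hash}.txt", "w") as fh:
        fh.write("\n".join(log) + "\n")
    return summary
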