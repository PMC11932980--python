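"""Pair classification and cross-validated evaluation.

A protein pair is encoded by concatenating the two per-protein feature
vectors.  Concatenation is order-sensitive while interaction is not, so
training augments every pair in both orders and prediction averages the two
orientations.  The flagship classifier is gradient-boosted decision trees
(``gbdt``); naive Bayes, LDA, an RBF SVM, a decision tree and k-NN are kept
as comparison arms.  The ordered target statistic — the prefix target mean
with an additive prior that ordered boosting uses to encode categorical
features without target leakage — is exposed as a standalone encoder.

Evaluation follows stratified k-fold cross-validation with *per-fold*
feature learning: the autoencoder only ever sees training-fold proteins, so
no information leaks from held-out pairs into the representation.  Metrics
are accuracy (ACC), precision (PE), sensitivity (SN), the Matthews
correlation coefficient (MCC), and the area under the ROC curve (AUC).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .baselines import HOGConfig, hog_features
from .dae import DAEConfig, FeatureVector, extract_features, train_dae
from .pssm_io import PSSM
from .transforms import (
    EQUAL_SIZE,
    ZERO_PAD,
    FixedMatrix,
    equal_size_transform,
    scale_matrix,
    zero_pad_transform,
)

CLASSIFIER_KINDS = ("gbdt", "nb", "lda", "svm", "dt", "knn")
EXTRACTOR_KINDS = ("dae", "hog", "none")
METRIC_NAMES = ("ACC", "PE", "SN", "MCC", "AUC")


@dataclass
class PairExample:
    """One labelled protein pair with its concatenated feature vector."""

    id_a: str
    id_b: str
    features: np.ndarray
    label: int

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float).ravel()
        if self.features.size % 2 != 0:
            raise ValueError("pair feature length must be even (two concatenated halves)")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class TargetStatConfig:
    """Prior and ordering for the ordered target statistic.

    ``prior_p`` is the prior success probability, ``prior_weight`` its
    weight (pseudo-count).  The processing order is either an explicit
    ``permutation`` or one drawn reproducibly from ``seed``.
    """

    prior_p: float = 0.5
    prior_weight: float = 1.0
    permutation: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.prior_p <= 1.0):
            raise ValueError("prior_p must be in [0, 1]")
        if self.prior_weight <= 0:
            raise ValueError("prior_weight must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline choices: transform -> extractor -> classifier."""

    transform: str = EQUAL_SIZE
    extractor: str = "dae"
    classifier: str = "gbdt"
    dae: DAEConfig = field(default_factory=DAEConfig)
    hog: HOGConfig = field(default_factory=HOGConfig)
    classifier_params: Mapping | None = None

    def __post_init__(self) -> None:
        if self.transform not in (EQUAL_SIZE, ZERO_PAD):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.extractor not in EXTRACTOR_KINDS:
            raise ValueError(f"unknown extractor {self.extractor!r}; choose from {EXTRACTOR_KINDS}")
        if self.classifier not in CLASSIFIER_KINDS:
            raise ValueError(
                f"unknown classifier {self.classifier!r}; choose from {CLASSIFIER_KINDS}"
            )


@dataclass
class EvalReport:
    """Per-fold and aggregate cross-validation metrics plus ROC points."""

    per_fold: list[dict]
    mean: dict
    std: dict
    roc_points: list[list[tuple[float, float]]]
    config: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_fold": self.per_fold,
                "mean": self.mean,
                "std": self.std,
                "roc_points": self.roc_points,
                "config": self.config,
            },
            default=float,
        )

    def format_table(self) -> str:
        """Aligned text table: one row per fold, then the mean +/- std row."""
        header = f"{'Testing set':<12}" + "".join(f"{m:>18}" for m in METRIC_NAMES)
        lines = [header]
        for i, fold in enumerate(self.per_fold, start=1):
            lines.append(
                f"{i:<12}" + "".join(f"{fold[m]:>18.4f}" for m in METRIC_NAMES)
            )
        lines.append(
            f"{'Average':<12}"
            + "".join(
                f"{self.mean[m]:>9.4f} ± {self.std[m]:.4f}" for m in METRIC_NAMES
            )
        )
        return "\n".join(lines)


def pair_features(fa: FeatureVector | np.ndarray, fb: FeatureVector | np.ndarray) -> np.ndarray:
    """Concatenate two per-protein feature vectors into one pair vector."""
    va = fa.values if isinstance(fa, FeatureVector) else np.asarray(fa, dtype=float)
    vb = fb.values if isinstance(fb, FeatureVector) else np.asarray(fb, dtype=float)
    if va.shape != vb.shape:
        raise ValueError(f"feature length mismatch: {va.shape} vs {vb.shape}")
    return np.concatenate([va, vb])


def ordered_target_statistic(
    categories: Sequence, labels: Sequence[int], config: TargetStatConfig | None = None
) -> np.ndarray:
    """Leakage-free numeric encoding of a categorical feature.

    Items are visited in a (random or given) order sigma; the item at
    position p of sigma receives

        (sum of labels of *earlier* items with the same category
         + prior_weight * prior_p) / (their count + prior_weight)

    so no item's own label, nor any later item's, influences its encoding.
    Values are returned in the original index order.
    """
    if config is None:
        config = TargetStatConfig()
    labels = np.asarray(labels)
    n = len(categories)
    if len(labels) != n:
        raise ValueError(f"length mismatch: {n} categories vs {len(labels)} labels")
    if config.permutation is not None:
        sigma = list(config.permutation)
        if sorted(sigma) != list(range(n)):
            raise ValueError("permutation is not a bijection on 0..n-1")
    else:
        sigma = list(np.random.default_rng(config.seed).permutation(n))
    out = np.empty(n, dtype=float)
    label_sum: dict = {}
    count: dict = {}
    for i in sigma:
        c = categories[i]
        s = label_sum.get(c, 0.0)
        k = count.get(c, 0)
        out[i] = (s + config.prior_weight * config.prior_p) / (k + config.prior_weight)
        label_sum[c] = s + float(labels[i])
        count[c] = k + 1
    return out


def _make_classifier(kind: str, params: Mapping | None, seed: int):
    params = dict(params or {})
    if kind == "gbdt":
        defaults = dict(
            n_estimators=500, max_depth=6, num_leaves=63, learning_rate=0.05,
            random_state=seed, deterministic=True, force_row_wise=True,
            n_jobs=1, verbose=-1,
        )
        defaults.update(params)
        return LGBMClassifier(**defaults)
    if kind == "nb":
        return GaussianNB(**params)
    if kind == "lda":
        return LinearDiscriminantAnalysis(**params)
    if kind == "svm":
        defaults = dict(kernel="rbf", random_state=seed)
        defaults.update(params)
        # probability calibration wrapper: SVC alone only emits margins
        return CalibratedClassifierCV(SVC(**defaults), ensemble=False)
    if kind == "dt":
        defaults = dict(random_state=seed)
        defaults.update(params)
        return DecisionTreeClassifier(**defaults)
    if kind == "knn":
        defaults = dict(n_neighbors=5)
        defaults.update(params)
        return KNeighborsClassifier(**defaults)
    raise ValueError(f"unknown classifier {kind!r}; choose from {CLASSIFIER_KINDS}")


def train_classifier(
    X: np.ndarray, y: Sequence[int], kind: str = "gbdt",
    params: Mapping | None = None, seed: int = 0,
):
    """Fit a binary classifier exposing ``predict_proba``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} rows but {y.shape[0]} labels")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if not np.all(np.isfinite(X)):
        raise ValueError("training features contain NaN or infinite values")
    model = _make_classifier(kind, params, seed)
    model.fit(X, y)
    model._evoppi_n_features = X.shape[1]
    return model


def predict_proba(model, X: np.ndarray) -> np.ndarray:
    """Positive-class probability per row, in [0, 1]."""
    X = np.asarray(X, dtype=float)
    expected = getattr(model, "_evoppi_n_features", None)
    if expected is not None and X.shape[1] != expected:
        raise ValueError(f"feature width {X.shape[1]} != training width {expected}")
    pos_col = int(np.where(np.asarray(model.classes_) == 1)[0][0])
    with warnings.catch_warnings():
        # plain ndarrays carry no feature names; the mismatch warning is noise
        warnings.filterwarnings("ignore", message=".*valid feature names.*")
        return model.predict_proba(X)[:, pos_col]


def confusion(labels: Sequence[int], predicted: Sequence[int]) -> ConfusionCounts:
    """Confusion counts of hard binary predictions against true labels."""
    labels = np.asarray(labels)
    predicted = np.asarray(predicted)
    if labels.shape != predicted.shape:
        raise ValueError(f"length mismatch: {labels.shape} vs {predicted.shape}")
    tp = int(np.sum((labels == 1) & (predicted == 1)))
    tn = int(np.sum((labels == 0) & (predicted == 0)))
    fp = int(np.sum((labels == 0) & (predicted == 1)))
    fn = int(np.sum((labels == 1) & (predicted == 0)))
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def metrics(c: ConfusionCounts) -> dict:
    """ACC, PE, SN and MCC from confusion counts.

    Undefined ratios (zero denominators) come back as ``nan`` rather than
    raising, so fold aggregation can skip them explicitly.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = float(c.TP), float(c.TN), float(c.FP), float(c.FN)
    acc = (tn + tp) / (tn + tp + fn + fp)
    pe = tp / (fp + tp) if (fp + tp) > 0 else math.nan
    sn = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    denom = (tp + fp) * (tn + fn) * (tn + fp) * (tp + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else math.nan
    return {"ACC": acc, "PE": pe, "SN": sn, "MCC": mcc}


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> dict:
    """ROC curve and AUC by trapezoidal integration over all thresholds.

    Equals the probability a random positive outscores a random negative,
    with ties counted one half.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores differ in length")
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return {"auc": auc, "points": list(zip(fpr.tolist(), tpr.tolist()))}


def _transform_and_scale(pssms: Mapping[str, PSSM], transform: str) -> dict[str, FixedMatrix]:
    fn = equal_size_transform if transform == EQUAL_SIZE else zero_pad_transform
    return {pid: scale_matrix(fn(p)) for pid, p in pssms.items()}


def _fold_features(
    matrices: Mapping[str, FixedMatrix],
    train_ids: set[str],
    extractor: str,
    dae_config: DAEConfig,
    hog_config: HOGConfig,
) -> dict[str, np.ndarray]:
    """Learn/apply the extractor using only training-fold proteins for fitting."""
    if extractor == "dae":
        train_mats = [matrices[pid] for pid in sorted(train_ids)]
        model = train_dae(train_mats, dae_config)
        feats = extract_features(model, list(matrices.values()))
        return {f.protein_id: f.values for f in feats}
    if extractor == "hog":
        return {pid: hog_features(m, hog_config).values for pid, m in matrices.items()}
    if extractor == "none":
        return {pid: m.flat() for pid, m in matrices.items()}
    raise ValueError(f"unknown extractor {extractor!r}")


def _pair_matrix(pairs, feats, augment: bool):
    """Stack pair feature rows; with augment, both orientations of each pair."""
    rows, y = [], []
    for id_a, id_b, label in pairs:
        rows.append(pair_features(feats[id_a], feats[id_b]))
        y.append(label)
        if augment:
            rows.append(pair_features(feats[id_b], feats[id_a]))
            y.append(label)
    return np.asarray(rows), np.asarray(y)


def _score_pairs(model, pairs, feats) -> np.ndarray:
    """Orientation-averaged positive-class scores for unordered pairs."""
    X_ab, _ = _pair_matrix(pairs, feats, augment=False)
    X_ba, _ = _pair_matrix([(b, a, l) for a, b, l in pairs], feats, augment=False)
    return 0.5 * (predict_proba(model, X_ab) + predict_proba(model, X_ba))


def _cv_core(
    pairs: Sequence[tuple[str, str, int]],
    pssms: Mapping[str, PSSM],
    config: PipelineConfig,
    classifier_kinds: Sequence[str],
    k: int,
    seed: int,
) -> dict[str, EvalReport]:
    """Shared CV loop; features are extracted once per fold, then every
    requested classifier is fitted on them (the ablation grid exploits this)."""
    if k < 2:
        raise ValueError("k must be at least 2")
    labels = np.asarray([p[2] for p in pairs])
    for cls in (0, 1):
        if np.sum(labels == cls) < k:
            raise ValueError(f"need at least {k} examples of class {cls} for {k}-fold CV")
    matrices = _transform_and_scale(pssms, config.transform)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    results: dict[str, dict] = {kind: {"folds": [], "roc": []} for kind in classifier_kinds}
    dae_cfg = replace(config.dae, seed=seed)

    for fold_idx, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(pairs)), labels)):
        train_pairs = [pairs[i] for i in train_idx]
        test_pairs = [pairs[i] for i in test_idx]
        train_ids = {pid for a, b, _ in train_pairs for pid in (a, b)}
        feats = _fold_features(matrices, train_ids, config.extractor, dae_cfg, config.hog)

        X_train, y_train = _pair_matrix(train_pairs, feats, augment=True)
        y_test = np.asarray([p[2] for p in test_pairs])
        for kind in classifier_kinds:
            model = train_classifier(X_train, y_train, kind=kind,
                                     params=config.classifier_params, seed=seed)
            scores = _score_pairs(model, test_pairs, feats)
            preds = (scores >= 0.5).astype(int)
            fold_metrics = metrics(confusion(y_test, preds))
            roc = roc_auc(y_test, scores)
            fold_metrics["AUC"] = roc["auc"]
            results[kind]["folds"].append(fold_metrics)
            results[kind]["roc"].append(roc["points"])

    reports = {}
    for kind in classifier_kinds:
        folds = results[kind]["folds"]
        mean = {m: float(np.nanmean([f[m] for f in folds])) for m in METRIC_NAMES}
        std = {m: float(np.nanstd([f[m] for f in folds])) for m in METRIC_NAMES}
        snapshot = {
            "transform": config.transform, "extractor": config.extractor,
            "classifier": kind, "k": k, "seed": seed,
            "dae": asdict(config.dae), "hog": asdict(config.hog),
        }
        reports[kind] = EvalReport(per_fold=folds, mean=mean, std=std,
                                   roc_points=results[kind]["roc"], config=snapshot)
    return reports


def cross_validate(
    pairs: Sequence[tuple[str, str, int]],
    pssms: Mapping[str, PSSM],
    config: PipelineConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold evaluation of the full pipeline.

    Per fold, the feature extractor (when learned) and the classifier are
    fitted on training-fold proteins/pairs only; held-out pairs are scored
    with orientation averaging and summarised as mean +/- std of
    ACC/PE/SN/MCC/AUC across folds.
    """
    if config is None:
        config = PipelineConfig()
    return _cv_core(pairs, pssms, config, [config.classifier], k, seed)[config.classifier]


def run_grid(
    pairs: Sequence[tuple[str, str, int]],
    pssms: Mapping[str, PSSM],
    transforms: Sequence[str] = (EQUAL_SIZE, ZERO_PAD),
    extractors: Sequence[str] = ("dae", "hog"),
    classifiers: Sequence[str] = CLASSIFIER_KINDS,
    k: int = 5,
    seed: int = 0,
    dae_config: DAEConfig | None = None,
    hog_config: HOGConfig | None = None,
) -> dict[tuple[str, str, str], EvalReport]:
    """Run the full ablation grid (transform x extractor x classifier).

    Feature extraction is shared across classifiers within each
    transform/extractor cell, so the grid costs one extractor fit per fold
    per cell rather than one per classifier.
    """
    out: dict[tuple[str, str, str], EvalReport] = {}
    for tr in transforms:
        for ex in extractors:
            cfg = PipelineConfig(
                transform=tr, extractor=ex, classifier=classifiers[0],
                dae=dae_config or DAEConfig(), hog=hog_config or HOGConfig(),
            )
            reports = _cv_core(pairs, pssms, cfg, list(classifiers), k, seed)
            for kind, rep in reports.items():
                out[(tr, ex, kind)] = rep
    return out


def format_grid_table(grid: Mapping[tuple[str, str, str], EvalReport]) -> str:
    """Mean +/- std summary of a grid run, one row per configuration."""
    header = (
        f"{'Transform':<12}{'Extractor':<11}{'Classifier':<12}"
        + "".join(f"{m + ' (%)':>20}" for m in METRIC_NAMES)
    )
    lines = [header]
    for (tr, ex, kind), rep in sorted(grid.items()):
        cells = "".join(
            f"{100 * rep.mean[m]:>11.2f} ± {100 * rep.std[m]:>5.2f}"
            for m in METRIC_NAMES
        )
        lines.append(f"{tr:<12}{ex:<11}{kind:<12}" + cells)
    return "\n".join(lines)


def rank_predictions(
    model, candidates: Sequence[PairExample], top_n: int | None = None
) -> list[tuple[str, str, float]]:
    """Score candidate pairs and rank them, best first.

    Scores average both pair orientations; ties break lexicographically on
    (id_a, id_b) so output is deterministic.
    """
    if not candidates:
        raise ValueError("no candidate pairs to rank")
    X_ab = np.asarray([c.features for c in candidates])
    half = X_ab.shape[1] // 2
    X_ba = np.concatenate([X_ab[:, half:], X_ab[:, :half]], axis=1)
    scores = 0.5 * (predict_proba(model, X_ab) + predict_proba(model, X_ba))
    ranked = sorted(
        zip((c.id_a for c in candidates), (c.id_b for c in candidates), scores),
        key=lambda t: (-t[2], t[0], t[1]),
    )
    ranked = [(a, b, float(s)) for a, b, s in ranked]
    return ranked[:top_n] if top_n is not None else ranked
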