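"""RBF-SVM training, prediction and the repeated cross-validation protocol.

A trained model bundles everything prediction needs: the four
class-conditional frequency models estimated from the training windows,
the feature manifest, the feature scaler fitted on training features, and
the fitted support vector machine.  The default configuration follows the
splice-site setup this package implements: RBF kernel with gamma 0.2,
cost 1.0, the reduced 49-feature manifest, z-scored features and
probability outputs thresholded at 0.5.

``cross_validate`` runs the 10-set x fivefold protocol over
:class:`~donorpred.sequence_io.DatasetSplit` records: frequency models and
the scaler are re-fitted from each training partition (leakage-safe; a
``whole_dataset_models`` escape hatch reproduces the alternative of fitting
them once on everything), the held-out partition is scored, and both areas
are averaged over all folds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .encoding import MANIFESTS, TABLE1_49, FeatureSetManifest, FrequencyModelBundle, encode
from .frequency_models import estimate_dependency, estimate_positional
from .metrics import auc_pr, auc_roc
from .sequence_io import (
    DEFAULT_GEOMETRY,
    LABEL_TRUE,
    DatasetSplit,
    SpliceWindow,
    WindowGeometry,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    """Classifier and encoding configuration."""

    kernel: str = "rbf"
    gamma: float = 0.2
    cost: float = 1.0
    probability_output: bool = True
    scaling: str = "zscore"  # "zscore" | "none"
    feature_set_id: str = "table1_49"
    pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.cost <= 0:
            raise ValueError(f"cost must be positive, got {self.cost}")
        if self.scaling not in ("zscore", "none"):
            raise ValueError(f"scaling must be 'zscore' or 'none', got {self.scaling}")

    def manifest(self) -> FeatureSetManifest:
        try:
            return MANIFESTS[self.feature_set_id]
        except KeyError:
            raise ValueError(
                f"unknown feature_set_id '{self.feature_set_id}'; "
                f"expected one of {sorted(MANIFESTS)}"
            ) from None


@dataclass
class _Scaler:
    """Per-feature z-scoring fitted on training data.

    Constant features are passed through unscaled (unit divisor) with a
    warning rather than producing NaNs.
    """

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Scaler":
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        constant = sd < 1e-12
        if constant.any():
            logger.warning(
                "%d constant feature(s) under z-scoring passed through unscaled",
                int(constant.sum()),
            )
        scale = np.where(constant, 1.0, sd)
        return cls(mean=np.where(constant, 0.0, mean), scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale

    @classmethod
    def identity(cls, n_features: int) -> "_Scaler":
        return cls(mean=np.zeros(n_features), scale=np.ones(n_features))


@dataclass
class TrainedModel:
    """A fitted donor-site classifier and everything needed to apply it."""

    classifier: SVC
    manifest: FeatureSetManifest
    scaler: _Scaler
    models: FrequencyModelBundle
    config: ModelConfig
    geometry: WindowGeometry
    n_true_train: int
    n_false_train: int

    @property
    def L(self) -> int:
        return self.models.L

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return model


def _infer_geometry(windows: Sequence[SpliceWindow]) -> WindowGeometry:
    """Recover the window geometry from the conserved GT shared by all windows."""
    if not windows:
        return DEFAULT_GEOMETRY
    L = len(windows[0].sequence)
    if L == DEFAULT_GEOMETRY.window_length:
        candidates = [DEFAULT_GEOMETRY.gt_offset] + [
            g for g in range(2, L) if g != DEFAULT_GEOMETRY.gt_offset
        ]
    else:
        candidates = list(range(2, L))
    for g in candidates:
        if all(w.sequence[g - 1 : g + 1] == "GT" for w in windows):
            return WindowGeometry(L, g)
    raise ValueError("cannot infer geometry: no position carries GT in every window")


def _split_by_label(windows: Sequence[SpliceWindow]) -> tuple[list, list]:
    true_w = [w for w in windows if w.label == LABEL_TRUE]
    false_w = [w for w in windows if w.label not in (None, LABEL_TRUE)]
    unlabelled = len(windows) - len(true_w) - len(false_w)
    if unlabelled:
        raise ValueError(f"{unlabelled} window(s) carry no class label")
    if not true_w or not false_w:
        raise ValueError(
            f"both classes are required for training; got {len(true_w)} true "
            f"and {len(false_w)} false windows"
        )
    return true_w, false_w


def fit_frequency_models(
    windows: Sequence[SpliceWindow], pseudocount: float = 1.0
) -> FrequencyModelBundle:
    """Estimate the four class-conditional frequency models."""
    true_w, false_w = _split_by_label(windows)
    return FrequencyModelBundle(
        true_positional=estimate_positional(true_w, pseudocount, class_tag="true"),
        false_positional=estimate_positional(false_w, pseudocount, class_tag="false"),
        true_dependency=estimate_dependency(true_w, pseudocount, class_tag="true"),
        false_dependency=estimate_dependency(false_w, pseudocount, class_tag="false"),
    )


def train(
    train_windows: Sequence[SpliceWindow],
    config: ModelConfig = ModelConfig(),
    models: Optional[FrequencyModelBundle] = None,
    geometry: Optional[WindowGeometry] = None,
) -> TrainedModel:
    """Fit frequency models, encoder scaling and the SVM on labelled windows.

    ``models`` overrides the frequency-model fitting (used by the
    whole-dataset mode of cross-validation); by default they are estimated
    from ``train_windows`` only.  ``geometry`` is stored with the model so
    downstream scanning knows where the conserved GT sits; if omitted it
    is inferred from the training windows (the shared GT position).
    """
    if geometry is None:
        geometry = _infer_geometry(train_windows)
    if train_windows and geometry.window_length != len(train_windows[0].sequence):
        raise ValueError(
            f"geometry window_length {geometry.window_length} mismatches "
            f"training windows of length {len(train_windows[0].sequence)}"
        )
    true_w, false_w = _split_by_label(train_windows)
    if models is None:
        models = fit_frequency_models(train_windows, config.pseudocount)
    manifest = config.manifest()
    X = encode(list(train_windows), models, manifest).to_numpy()
    y = np.array([w.label == LABEL_TRUE for w in train_windows], dtype=int)
    scaler = _Scaler.fit(X) if config.scaling == "zscore" else _Scaler.identity(X.shape[1])
    Xs = scaler.transform(X)
    clf = SVC(
        kernel=config.kernel,
        gamma=config.gamma,
        C=config.cost,
        probability=config.probability_output,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        # seeded internal sigmoid calibration is exactly what we want;
        # newer sklearn steers users to CalibratedClassifierCV instead
        warnings.filterwarnings("ignore", message=".*probability.*", category=FutureWarning)
        clf.fit(Xs, y)
    return TrainedModel(
        classifier=clf,
        manifest=manifest,
        scaler=scaler,
        models=models,
        config=config,
        geometry=geometry,
        n_true_train=len(true_w),
        n_false_train=len(false_w),
    )


def predict(model: TrainedModel, windows: Sequence[SpliceWindow]) -> pd.DataFrame:
    """Score windows with a trained model.

    Returns a DataFrame aligned with the input order with columns
    ``probability`` (of being a true donor site) and ``call`` (probability
    > 0.5).  Raises if any window's length mismatches the model geometry.
    """
    if len(windows) == 0:
        return pd.DataFrame(columns=["probability", "call"])
    for w in windows:
        if len(w.sequence) != model.L:
            raise ValueError(
                f"window '{w.source_id}' has length {len(w.sequence)}; "
                f"model was trained at L={model.L}"
            )
    X = encode(list(windows), model.models, model.manifest).to_numpy()
    Xs = model.scaler.transform(X)
    if model.config.probability_output:
        prob = model.classifier.predict_proba(Xs)[:, 1]
    else:
        # decision values squashed to (0, 1); monotone in the SVM margin
        prob = 1.0 / (1.0 + np.exp(-model.classifier.decision_function(Xs)))
    return pd.DataFrame(
        {
            "probability": prob,
            "call": prob > 0.5,
        },
        index=pd.Index([w.source_id or str(i) for i, w in enumerate(windows)], name="window"),
    )


def decision_scores(model: TrainedModel, windows: Sequence[SpliceWindow]) -> np.ndarray:
    """Raw SVM decision values (monotone with the class probability)."""
    X = encode(list(windows), model.models, model.manifest).to_numpy()
    return model.classifier.decision_function(model.scaler.transform(X))


@dataclass
class EvalResult:
    """Per-fold and aggregated areas for a repeated cross-validation run."""

    per_fold: pd.DataFrame  # columns: set, fold, auc_roc, auc_pr
    config: ModelConfig
    seed: int

    @property
    def mean_auc_roc(self) -> float:
        return float(self.per_fold["auc_roc"].mean())

    @property
    def mean_auc_pr(self) -> float:
        return float(self.per_fold["auc_pr"].mean())

    def summary(self) -> pd.DataFrame:
        out = self.per_fold.copy()
        out.loc["mean"] = ["-", "-", self.mean_auc_roc, self.mean_auc_pr]
        return out

    def to_table(self, path: str | Path) -> None:
        self.summary().to_csv(path, sep="\t", index=False)


def cross_validate(
    splits: Sequence[DatasetSplit],
    config: ModelConfig = ModelConfig(),
    whole_dataset_models: bool = False,
) -> EvalResult:
    """Run the repeated k-fold protocol over pre-built dataset splits.

    For each (set, fold): train on the training partition, score the
    held-out partition with the SVM decision value (both areas are
    invariant under the monotone probability mapping, so the costlier
    probability calibration is skipped here), and record AUC-ROC and
    AUC-PR.  Folds whose test partition contains a single class are
    flagged, excluded from the mean, and reported with NaN areas.

    ``whole_dataset_models=True`` estimates the frequency models once from
    the union of all windows (training and test) instead of per training
    partition -- the leak-prone variant, available only for comparison.
    """
    if not splits:
        raise ValueError("no dataset splits provided")
    shared_models = None
    if whole_dataset_models:
        seen: dict[int, SpliceWindow] = {}
        for sp in splits:
            for w in sp.train + sp.test:
                seen[id(w)] = w
        shared_models = fit_frequency_models(list(seen.values()), config.pseudocount)

    cv_config = replace(config, probability_output=False)
    rows = []
    for sp in splits:
        test_labels = [w.label == LABEL_TRUE for w in sp.test]
        if all(test_labels) or not any(test_labels):
            logger.warning(
                "set %d fold %d: single-class test partition, excluded from the mean",
                sp.set_index, sp.fold_index,
            )
            rows.append((sp.set_index, sp.fold_index, np.nan, np.nan))
            continue
        model = train(sp.train, cv_config, models=shared_models)
        scores = decision_scores(model, sp.test)
        rows.append(
            (
                sp.set_index,
                sp.fold_index,
                auc_roc(scores, test_labels),
                auc_pr(scores, test_labels),
            )
        )
    per_fold = pd.DataFrame(rows, columns=["set", "fold", "auc_roc", "auc_pr"])
    return EvalResult(per_fold=per_fold, config=config, seed=splits[0].seed)
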