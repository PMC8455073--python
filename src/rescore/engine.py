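"""Semi-supervised SVM training for PSM rescoring.

The dynamic training loop mirrors the classic semi-supervised rescoring
algorithm: starting from the single best-separating feature, targets
accepted below a training FDR threshold become the positive class, all
decoys the negative class, and an L2-regularized linear SVM is refit on
that labelled subset; rescoring with the new model expands (or shrinks)
the positive set, and the process repeats for a fixed number of
iterations.  The whole procedure runs inside a cross-validation scheme so
that every PSM's final score comes from a model that never saw it during
training; the per-fold scores are put on a common scale before merging.

The SVM is liblinear's primal L2-loss (squared hinge) formulation with
asymmetric class costs.  The primal Newton solver involves no random
state, so model optimization is fully deterministic: the only randomness
in the pipeline is the seeded assignment of spectra to cross-validation
folds.
"""

from __future__ import annotations

import datetime
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import LinearSVC

from . import confidence as conf
from .exceptions import RescoreError, SmallExperimentWarning
from .pin_io import PsmTable

__all__ = [
    "TrainConfig",
    "LinearModel",
    "BrewResult",
    "normalize_features",
    "choose_initial_direction",
    "fit_semisupervised",
    "normalize_fold_scores",
    "brew",
]


@dataclass
class TrainConfig:
    """Hyperparameters of the semi-supervised training procedure.

    ``train_fdr`` is the FDR threshold used to select positive training
    examples (distinct from the reporting threshold). ``svm_cost_positive``
    and ``svm_cost_negative`` are the asymmetric misclassification costs.
    ``small_dataset_warning_threshold`` is the minimum recommended number
    of total PSMs; below it a :class:`SmallExperimentWarning` is emitted.
    """

    train_fdr: float = 0.01
    max_iter: int = 10
    folds: int = 3
    seed: int = 0
    svm_cost_positive: float = 1.0
    svm_cost_negative: float = 1.0
    min_positives: int = 10
    small_dataset_warning_threshold: int = 5000

    def __post_init__(self) -> None:
        if not 0 < self.train_fdr < 1:
            raise ValueError("train_fdr must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class LinearModel:
    """A linear scoring model in the original (unnormalized) feature space.

    ``score = features @ weights + intercept``. The normalization
    statistics used during training are retained for provenance; they are
    not needed to apply the model.
    """

    feature_names: list[str]
    weights: np.ndarray
    intercept: float
    norm_mean: np.ndarray
    norm_scale: np.ndarray
    provenance: dict = field(default_factory=dict)
    degraded: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.norm_mean = np.asarray(self.norm_mean, dtype=float)
        self.norm_scale = np.asarray(self.norm_scale, dtype=float)
        if len(self.weights) != len(self.feature_names):
            raise ValueError("weights and feature_names must have equal length")
        if (self.norm_scale <= 0).any():
            raise ValueError("normalization scales must be positive")

    def decision_function(self, features) -> np.ndarray:
        """Score a feature frame (columns selected by name) or matrix."""
        if hasattr(features, "columns"):
            missing = [f for f in self.feature_names if f not in features.columns]
            if missing:
                raise RescoreError(f"features missing from input: {missing}")
            mat = features[self.feature_names].to_numpy(dtype=float)
        else:
            mat = np.asarray(features, dtype=float)
        return mat @ self.weights + self.intercept

    def score_table(self, table: PsmTable) -> np.ndarray:
        return self.decision_function(table.features)


@dataclass
class BrewResult:
    """Output of the cross-validated dynamic pipeline.

    ``merged_scores`` are aligned with the input PSMs; each PSM's score
    was produced (and then fold-normalized) by the model of the fold that
    held it out, which ``fold_assignment`` records.
    """

    merged_scores: np.ndarray
    fold_models: list[LinearModel]
    fold_assignment: np.ndarray
    confidence: conf.ConfidenceResult


def normalize_features(table: PsmTable):
    """Z-score each feature column (population SD); constant columns get
    scale 1 so they become all-zero. Returns (matrix, mean, scale)."""
    if len(table) < 2:
        raise RescoreError("need at least 2 PSMs to normalize features")
    mat = table.feature_matrix
    mean = mat.mean(axis=0)
    scale = mat.std(axis=0)
    scale[scale == 0] = 1.0
    return (mat - mean) / scale, mean, scale


def choose_initial_direction(table: PsmTable, train_fdr: float):
    """Pick the (feature index, sign) whose signed values accept the most
    targets at ``train_fdr`` when used directly as the score.

    Ties break toward the lower feature index, then the positive sign. If
    no (feature, sign) accepts any target, falls back to the feature with
    the largest standardized target-decoy mean difference and flags the
    result. Returns ``(index, sign, fallback_used)``.
    """
    if table.features.shape[1] < 1:
        raise RescoreError("table has no features")
    if table.n_targets == 0 or table.n_decoys == 0:
        raise RescoreError("need both targets and decoys to choose a direction")
    mat = table.feature_matrix
    labels = table.is_target
    best = (-1, 0, 1)  # (count, -sign preference handled by scan order)
    best_pair = (0, 1)
    for j in range(mat.shape[1]):
        for sign in (1, -1):
            qv = conf.tdc_qvalues(sign * mat[:, j], labels)
            count = int((qv <= train_fdr).sum())
            if count > best[0]:
                best = (count, j, sign)
                best_pair = (j, sign)
    if best[0] > 0:
        return best_pair[0], best_pair[1], False
    # Degenerate path: nothing is accepted anywhere; use the standardized
    # mean difference as a deterministic criterion.
    zed, _, _ = normalize_features(table)
    diff = zed[labels].mean(axis=0) - zed[~labels].mean(axis=0)
    j = int(np.argmax(np.abs(diff)))
    sign = 1 if diff[j] >= 0 else -1
    return j, sign, True


def _single_feature_model(table: PsmTable, mean, scale, j: int, sign: int, config, extra) -> LinearModel:
    weights = np.zeros(table.features.shape[1])
    weights[j] = sign / scale[j]
    intercept = -sign * mean[j] / scale[j]
    prov = _provenance(table, config)
    prov.update(extra)
    return LinearModel(
        feature_names=table.feature_names,
        weights=weights,
        intercept=float(intercept),
        norm_mean=mean,
        norm_scale=scale,
        provenance=prov,
        degraded=True,
    )


def _provenance(table: PsmTable, config: TrainConfig) -> dict:
    return {
        "n_psms": len(table),
        "n_targets": table.n_targets,
        "n_decoys": table.n_decoys,
        "train_fdr": config.train_fdr,
        "max_iter": config.max_iter,
        "svm_cost_positive": config.svm_cost_positive,
        "svm_cost_negative": config.svm_cost_negative,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds"),
    }


def fit_semisupervised(
    train_table: PsmTable,
    config: TrainConfig,
    initial_direction: np.ndarray | None = None,
) -> LinearModel:
    """Run the iterative positive-set-expansion SVM loop on one table.

    Iteration 0 scores the PSMs with ``initial_direction`` (a weight
    vector in original feature space) if given, otherwise with the best
    single feature. Each iteration selects targets with q <= ``train_fdr``
    as positives and all decoys as negatives, fits the SVM, and rescores.
    If fewer than ``config.min_positives`` positives exist at iteration 0
    the model degrades to the single best feature; if a later iteration
    selects zero positives the loop stops and keeps the previous model.
    """
    if train_table.n_targets == 0 or train_table.n_decoys == 0:
        raise RescoreError("training table must contain both targets and decoys")
    zed, mean, scale = normalize_features(train_table)
    labels = train_table.is_target
    decoy_idx = np.flatnonzero(~labels)

    if initial_direction is not None:
        scores = train_table.feature_matrix @ np.asarray(initial_direction, dtype=float)
        init = None
    else:
        j, sign, fb = choose_initial_direction(train_table, config.train_fdr)
        scores = sign * zed[:, j]
        init = (j, sign, fb)

    svc = LinearSVC(
        loss="squared_hinge",
        dual=False,
        C=1.0,
        class_weight={1: config.svm_cost_positive, -1: config.svm_cost_negative},
        tol=1e-5,
        max_iter=10000,
    )
    iteration_positives: list[int] = []
    w_n = None
    b_n = 0.0
    for it in range(config.max_iter):
        qv = conf.tdc_qvalues(scores, labels)
        pos_idx = np.flatnonzero(labels)[qv <= config.train_fdr]
        n_pos = len(pos_idx)
        if it == 0 and n_pos < config.min_positives:
            if init is None:
                j, sign, fb = choose_initial_direction(train_table, config.train_fdr)
            else:
                j, sign, fb = init
            return _single_feature_model(
                train_table, mean, scale, j, sign, config,
                {"mode": "single-feature-fallback", "iteration_positives": [n_pos],
                 "direction_fallback": fb},
            )
        if n_pos == 0:
            break
        iteration_positives.append(n_pos)
        rows = np.concatenate([pos_idx, decoy_idx])
        y = np.concatenate([np.ones(n_pos, dtype=int), -np.ones(len(decoy_idx), dtype=int)])
        fitted = svc.fit(zed[rows], y)
        w_n = fitted.coef_.ravel().copy()
        b_n = float(fitted.intercept_[0])
        scores = zed @ w_n + b_n

    if w_n is None:  # max_iter reached without ever fitting (cannot happen after guard)
        raise RescoreError("semi-supervised training selected no positives")

    weights = w_n / scale
    intercept = b_n - float((w_n * mean / scale).sum())
    prov = _provenance(train_table, config)
    prov.update({"mode": "svm", "iteration_positives": iteration_positives})
    return LinearModel(
        feature_names=train_table.feature_names,
        weights=weights,
        intercept=intercept,
        norm_mean=mean,
        norm_scale=scale,
        provenance=prov,
    )


def _fold_anchors(scores: np.ndarray, is_target: np.ndarray, train_fdr: float):
    """Anchors of the per-fold affine score normalization.

    The score at the ``train_fdr`` acceptance threshold maps to 0 and the
    median decoy score maps to -1; with no accepted target, the maximum
    score maps to 0.
    """
    if not (~is_target).any():
        raise RescoreError("fold-score normalization requires decoy PSMs")
    qv = conf.tdc_qvalues(scores, is_target)
    accepted = scores[is_target][qv <= train_fdr]
    t_star = float(accepted.min()) if len(accepted) else float(scores.max())
    med_decoy = float(np.median(scores[~is_target]))
    denom = t_star - med_decoy
    if denom <= 0:
        denom = 1.0
    return t_star, denom


def normalize_fold_scores(held_out_scores, held_out_labels, train_fdr: float) -> np.ndarray:
    """Affine-normalize one fold's held-out scores onto the common scale
    (acceptance threshold -> 0, median decoy -> -1)."""
    scores = np.asarray(held_out_scores, dtype=float)
    labels = np.asarray(held_out_labels, dtype=bool)
    t_star, denom = _fold_anchors(scores, labels, train_fdr)
    return (scores - t_star) / denom


def brew(table: PsmTable, config: TrainConfig, eval_fdr: float = 0.01) -> BrewResult:
    """The full dynamic pipeline: seeded fold split, per-fold
    semi-supervised training, held-out scoring, fold-score merging and
    confidence assignment.

    PSMs sharing a scan number always land in one fold, so candidate
    ranks of one spectrum never straddle the train/test boundary. Emits a
    :class:`SmallExperimentWarning` for datasets below the recommended
    minimum size (by default 5,000 total PSMs, under the rule of thumb
    that roughly one third of PSMs should be confidently assignable).
    """
    if table.n_targets == 0 or table.n_decoys == 0:
        raise RescoreError("brew requires both target and decoy PSMs")
    if len(table) < config.small_dataset_warning_threshold:
        warnings.warn(
            f"dataset has only {len(table)} PSMs "
            f"(< {config.small_dataset_warning_threshold}); semi-supervised "
            "training is unreliable at this scale — consider applying a "
            "static model trained on a larger dataset instead",
            SmallExperimentWarning,
            stacklevel=2,
        )

    rng = np.random.default_rng(config.seed)
    scans = np.unique(table.scan_nr)
    shuffled = scans[rng.permutation(len(scans))]
    fold_of_scan = np.empty(len(scans), dtype=np.int64)
    for f, chunk in enumerate(np.array_split(shuffled, config.folds)):
        # map scan value -> fold via searchsorted on the sorted scan array
        fold_of_scan[np.searchsorted(scans, chunk)] = f
    assignment = fold_of_scan[np.searchsorted(scans, table.scan_nr)]

    merged = np.empty(len(table), dtype=float)
    fold_models: list[LinearModel] = []
    for f in range(config.folds):
        held = assignment == f
        train_table = table.take(~held)
        if train_table.n_decoys == 0 or not (~table.is_target[held]).any():
            raise RescoreError(
                f"fold {f} has no decoys on one side of the split; "
                "use fewer folds or a larger dataset"
            )
        if train_table.n_targets == 0 or not table.is_target[held].any():
            raise RescoreError(
                f"fold {f} has no targets on one side of the split; "
                "use fewer folds or a larger dataset"
            )
        model = fit_semisupervised(train_table, config)
        raw = model.decision_function(table.features[held])
        t_star, denom = _fold_anchors(raw, table.is_target[held], config.train_fdr)
        merged[held] = (raw - t_star) / denom
        # Rescale the model itself onto the merged-score scale so that the
        # per-fold models are directly comparable (and can be averaged).
        fold_models.append(
            LinearModel(
                feature_names=model.feature_names,
                weights=model.weights / denom,
                intercept=(model.intercept - t_star) / denom,
                norm_mean=model.norm_mean,
                norm_scale=model.norm_scale,
                provenance={**model.provenance, "fold": f, "score_shift": t_star,
                            "score_scale": denom},
                degraded=model.degraded,
            )
        )

    result = conf.assign_confidence(table, merged, eval_fdr)
    return BrewResult(
        merged_scores=merged,
        fold_models=fold_models,
        fold_assignment=assignment,
        confidence=result,
    )
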