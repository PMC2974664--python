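"""SVM training, decision scores and the 0-9 per-residue confidence scale.

The classifier follows the SVM-light parameterization the method was tuned
with: an RBF kernel (t 2) with gamma g, or a polynomial kernel (t 1) of
degree d; C is the margin trade-off and the cost factor j multiplies the
penalty on positive-class training errors (implemented as an asymmetric
class weight).  Decision scores are thresholded at Thr (default -0.3, the
operating point at which sensitivity and specificity balance) and mapped to
a 0-9 scale by empirical deciles of the training-score distribution: 0 means
rarest chance of the residue being epitopic, 9 the most probable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
import joblib
import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

#: Default decision-value cutoff for calling a residue epitopic.
DEFAULT_THRESHOLD = -0.3


@dataclass
class SVMConfig:
    """Kernel and cost settings in SVM-light vocabulary.

    ``j`` is the cost factor: training errors on positives cost j times as
    much as errors on negatives (j=1 for balanced sets; j>1 compensates the
    class imbalance of realistic sets).
    """

    kernel: str = "rbf"
    gamma: float | None = 0.01
    degree: int | None = None
    C: float = 1.0
    j: float = 1.0
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.kernel == "rbf":
            if self.gamma is None or self.gamma <= 0:
                raise ValueError("RBF kernel requires gamma > 0")
        elif self.kernel == "poly":
            if self.degree is None or self.degree < 1:
                raise ValueError("polynomial kernel requires degree >= 1")
        else:
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.C <= 0 or self.j <= 0:
            raise ValueError("C and j must be positive")

    def to_estimator(self) -> SVC:
        kwargs = dict(
            C=self.C,
            class_weight={0: 1.0, 1: self.j},
            tol=1e-3,
            cache_size=200,
        )
        if self.kernel == "rbf":
            return SVC(kernel="rbf", gamma=self.gamma, **kwargs)
        return SVC(
            kernel="poly",
            degree=self.degree,
            gamma=self.gamma if self.gamma else "scale",
            coef0=1.0,
            **kwargs,
        )


@dataclass
class TrainedModel:
    """A fitted decision function plus everything needed to apply it safely."""

    estimator: SVC
    config: SVMConfig
    encoding: str
    W: int
    n_features: int
    calibration: np.ndarray  # 9 interior decile cut points of training scores
    fingerprint: dict = field(default_factory=dict)

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"model expects {self.encoding.upper()}/W={self.W} features of "
                f"dimension {self.n_features}, got {X.shape[1]}"
            )
        return X


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: SVMConfig,
    seed: int = 0,
    encoding: str = "cpp",
    W: int = 19,
) -> TrainedModel:
    """Fit an SVM on encoded patterns; deterministic given (data, config).

    Requires at least one example of each class.  The 0-9 calibration is the
    empirical deciles of the training decision scores, stored with the model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one label per row")
    classes = set(np.unique(y).tolist())
    if classes != {0, 1}:
        raise ValueError(f"need both classes 0 and 1 in training labels, got {classes}")

    est = config.to_estimator()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    if getattr(est, "fit_status_", 0) != 0:
        warnings.warn("SVM optimizer did not fully converge", RuntimeWarning)

    scores = est.decision_function(X)
    calibration = np.quantile(scores, np.arange(1, 10) / 10.0)
    return TrainedModel(
        estimator=est,
        config=config,
        encoding=encoding,
        W=W,
        n_features=X.shape[1],
        calibration=calibration,
        fingerprint={
            "n_positive": int((y == 1).sum()),
            "n_negative": int((y == 0).sum()),
            "seed": seed,
        },
    )


def predict_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Decision values, one per pattern, order-preserving with the input."""
    X = model._check_input(X)
    return model.estimator.decision_function(X)


def scores_to_scale(
    scores: np.ndarray, calibration: np.ndarray
) -> np.ndarray:
    """Map decision scores to integers 0..9 via stored decile cut points.

    Monotone non-decreasing; scores below/above the calibrated range clamp
    to 0/9.
    """
    calibration = np.asarray(calibration, dtype=float)
    if calibration.shape != (9,) or np.any(np.diff(calibration) < 0):
        raise ValueError("calibration must be 9 non-decreasing cut points")
    return np.searchsorted(calibration, np.asarray(scores, dtype=float), side="right")


def predict_antigen(
    model: TrainedModel,
    antigen,
    threshold: float | None = None,
    scales=None,
) -> pd.DataFrame:
    """Score every residue of a plain (unlabeled) antigen sequence.

    Returns one row per residue with the decision score, the 0-9 scale value
    and the binary call at the threshold (score >= Thr is positive,
    inclusive).  Threshold defaults to the model's configured Thr.
    """
    from .encoders import encode_patterns
    from .patterns import generate_patterns

    if len(antigen.sequence) < 1:
        raise ValueError("cannot predict on an empty sequence")
    thr = model.config.threshold if threshold is None else threshold
    pats = generate_patterns(antigen, model.W, labeled=False)
    X, _ = encode_patterns(pats, model.encoding, scales=scales)
    scores = predict_scores(model, X)
    return pd.DataFrame(
        {
            "antigen_id": antigen.id,
            "position": np.arange(1, len(antigen.sequence) + 1),
            "residue": list(antigen.sequence),
            "decision_score": scores,
            "scale0to9": scores_to_scale(scores, model.calibration),
            "call_at_threshold": (scores >= thr).astype(int),
        }
    )


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model as a single-file bundle."""
    joblib.dump(
        {
            "estimator": model.estimator,
            "config": model.config,
            "encoding": model.encoding,
            "W": model.W,
            "n_features": model.n_features,
            "calibration": model.calibration,
            "fingerprint": model.fingerprint,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    bundle = joblib.load(path)
    return TrainedModel(**bundle)
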