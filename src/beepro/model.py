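"""Class-weighted RBF support-vector classification of epitope residues.

The classifier is a soft-margin SVM with the radial basis function kernel
``K(x_i, x_j) = exp(-gamma ||x_i - x_j||^2)`` and asymmetric class penalties:
the effective regularization for class y is ``C * weight_y``, mirroring the
``-w`` flags of the LIBSVM tool family.  The positive class (+1, epitope) is
up-weighted to counter the heavy class imbalance of epitope data.

Hard labels use the classifier's native decision boundary (threshold 0);
evaluation primarily ranks residues by the continuous decision value, which
is threshold-free.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.svm import SVC

from .features import FeatureMatrix, FeatureScaler
from .scales import PropensityScale


class SingleClassError(ValueError):
    """Training data containing only one class."""


class DimensionError(ValueError):
    """Feature width mismatch between training and prediction."""


@dataclass(frozen=True)
class SVMConfig:
    """Hyperparameters of the class-weighted RBF SVM.

    Defaults are the optimized hybrid-model setting: C=1, gamma=10,
    positive-class weight 15, negative-class weight 1.
    """

    c: float = 1.0
    gamma: float = 10.0
    weight_pos: float = 15.0
    weight_neg: float = 1.0

    def __post_init__(self) -> None:
        for name in ("c", "gamma", "weight_pos", "weight_neg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @staticmethod
    def single_scale_protocol(n_features: int) -> "SVMConfig":
        """The single-scale protocol: w+1=20, w-1=1, tool defaults C=1 and
        gamma = 1 / n_features."""
        return SVMConfig(c=1.0, gamma=1.0 / n_features, weight_pos=20.0, weight_neg=1.0)


@dataclass
class TrainedModel:
    """A fitted classifier bundled with its fold-specific preprocessing.

    Carries the feature scaler and the AAR propensity scale that were fitted
    on the same training material, so applying the model to new sequences
    cannot leak information from evaluation data.
    """

    clf: SVC
    config: SVMConfig
    scaler: FeatureScaler | None = None
    aar_scale: PropensityScale | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def row_width(self) -> int:
        return int(self.clf.n_features_in_)


def train_svm(
    train: FeatureMatrix,
    config: SVMConfig = SVMConfig(),
    scaler: FeatureScaler | None = None,
    aar_scale: PropensityScale | None = None,
    provenance: dict | None = None,
) -> TrainedModel:
    """Fit the class-weighted RBF SVM on (already scaled) training rows.

    Deterministic for identical inputs: the dual solver is initialized from
    the data only and tie-breaking probability estimates are disabled.
    """
    classes = np.unique(train.labels)
    if classes.size < 2:
        raise SingleClassError(
            f"training data contains only class {classes.tolist()}"
        )
    clf = SVC(
        C=config.c,
        kernel="rbf",
        gamma=config.gamma,
        class_weight={1: config.weight_pos, -1: config.weight_neg},
        random_state=0,
    )
    clf.fit(train.X, train.labels)
    return TrainedModel(
        clf=clf,
        config=config,
        scaler=scaler,
        aar_scale=aar_scale,
        provenance={**train.provenance, **(provenance or {})},
    )


def predict_decision(model: TrainedModel, m: FeatureMatrix) -> np.ndarray:
    """Signed decision value per row; positive means epitope class."""
    if m.row_width != model.row_width:
        raise DimensionError(
            f"matrix width {m.row_width} != model width {model.row_width}"
        )
    dec = model.clf.decision_function(m.X)
    # sklearn orients the decision function toward classes_[1]; with +/-1
    # labels that is +1, the epitope class.
    assert model.clf.classes_[1] == 1
    return dec


def predict_labels(
    model: TrainedModel, m: FeatureMatrix, threshold: float = 0.0
) -> np.ndarray:
    """+1 where the decision value exceeds the threshold, else -1 (ties -> -1)."""
    return np.where(predict_decision(model, m) > threshold, 1, -1)


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Persist a trained model (classifier, scaler, AAR scale, config, provenance)."""
    path = Path(path)
    payload = {
        "format_version": 1,
        "clf": model.clf,
        "config": asdict(model.config),
        "scaler": model.scaler,
        "aar_scale": (
            None
            if model.aar_scale is None
            else {
                "name": model.aar_scale.name,
                "values": dict(model.aar_scale.values),
                "normalized": model.aar_scale.normalized,
            }
        ),
        "provenance": model.provenance,
    }
    joblib.dump(payload, path)
    manifest = {k: payload[k] for k in ("format_version", "config", "provenance")}
    Path(str(path) + ".json").write_text(json.dumps(manifest, indent=2, default=str))
    return path


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    aar = payload["aar_scale"]
    return TrainedModel(
        clf=payload["clf"],
        config=SVMConfig(**payload["config"]),
        scaler=payload["scaler"],
        aar_scale=None if aar is None else PropensityScale(**aar),
        provenance=payload["provenance"],
    )
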