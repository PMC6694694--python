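"""Linear classifier fixtures persisted as JSON.

The two supervised components of the pipeline (vessel-pixel color
refinement and red-lesion candidate scoring) are linear models trained
once, with a fixed seed, on generator-labeled synthetic scenes and shipped
as versioned JSON coefficient records under ``fundusdr/models/``.  JSON
keeps the fixtures human-inspectable and diff-able, and scoring reduces to
one matrix product, independent of the training library's runtime.

``scripts/train_models.py`` regenerates the fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from ._exceptions import ConfigurationError, ContractError


@dataclass
class LinearModel:
    """Standardized linear decision function: score = (x - mu) / sigma @ w + b."""

    feature_names: list[str]
    mean: np.ndarray
    scale: np.ndarray
    coef: np.ndarray
    intercept: float
    classes: list[str]          # [negative, positive] by decision sign
    version: str = "1"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.scale = np.asarray(self.scale, dtype=np.float64)
        self.coef = np.asarray(self.coef, dtype=np.float64)
        if not (self.mean.shape == self.scale.shape == self.coef.shape):
            raise ContractError("inconsistent model vector shapes")
        if len(self.classes) != 2:
            raise ContractError("LinearModel is binary")

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        z = (X - self.mean) / self.scale
        return z @ self.coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores > 0, self.classes[1], self.classes[0])

    def to_json(self, path: str | Path) -> None:
        d = {
            "feature_names": self.feature_names,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "coef": self.coef.tolist(),
            "intercept": float(self.intercept),
            "classes": self.classes,
            "version": self.version,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(d, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            feature_names=d["feature_names"],
            mean=np.array(d["mean"]),
            scale=np.array(d["scale"]),
            coef=np.array(d["coef"]),
            intercept=d["intercept"],
            classes=d["classes"],
            version=d.get("version", "1"),
            metadata=d.get("metadata", {}),
        )


def fit_linear_model(
    X: np.ndarray,
    y: list[str] | np.ndarray,
    feature_names: list[str],
    seed: int,
    metadata: dict | None = None,
    class_weight: str | None = None,
) -> LinearModel:
    """Fit a standardized logistic-regression margin classifier.

    Deterministic given (data, seed): features are standardized, the lbfgs
    solver is seeded and class order is sorted lexically.
    ``class_weight='balanced'`` counters label imbalance.
    """
    from sklearn.linear_model import LogisticRegression

    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = sorted(set(map(str, y)))
    if len(classes) < 2:
        raise ContractError("training data must contain at least 2 classes")
    if len(classes) > 2:
        raise ContractError("LinearModel is binary; collapse labels first")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    sigma[sigma < 1e-9] = 1.0
    z = (X - mu) / sigma
    clf = LogisticRegression(max_iter=2000, random_state=seed, class_weight=class_weight)
    clf.fit(z, (y == classes[1]).astype(int))
    return LinearModel(
        feature_names=list(feature_names),
        mean=mu,
        scale=sigma,
        coef=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
        classes=classes,
        metadata={"seed": seed, "n_train": int(len(y)), **(metadata or {})},
    )


@dataclass
class RbfSvmModel:
    """RBF-kernel support-vector classifier, self-contained in JSON.

    Scoring needs only the standardized support vectors, their dual
    coefficients, gamma and the intercept:
    score(x) = sum_i alpha_i exp(-gamma ||sv_i - z||^2) + b with
    z = (x - mu) / sigma.  Positive score predicts ``classes[1]``.
    """

    feature_names: list[str]
    mean: np.ndarray
    scale: np.ndarray
    support_vectors: np.ndarray   # (n_sv, n_features), standardized
    dual_coef: np.ndarray         # (n_sv,)
    gamma: float
    intercept: float
    classes: list[str]
    version: str = "1"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.scale = np.asarray(self.scale, dtype=np.float64)
        self.support_vectors = np.asarray(self.support_vectors, dtype=np.float64)
        self.dual_coef = np.asarray(self.dual_coef, dtype=np.float64)
        if len(self.classes) != 2:
            raise ContractError("RbfSvmModel is binary")

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        z = (X - self.mean) / self.scale
        d2 = ((z[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma * d2) @ self.dual_coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, self.classes[1], self.classes[0])

    def to_json(self, path: str | Path) -> None:
        d = {
            "kind": "rbf_svm",
            "feature_names": self.feature_names,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "gamma": float(self.gamma),
            "intercept": float(self.intercept),
            "classes": self.classes,
            "version": self.version,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(d, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "RbfSvmModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            feature_names=d["feature_names"],
            mean=np.array(d["mean"]),
            scale=np.array(d["scale"]),
            support_vectors=np.array(d["support_vectors"]),
            dual_coef=np.array(d["dual_coef"]),
            gamma=d["gamma"],
            intercept=d["intercept"],
            classes=d["classes"],
            version=d.get("version", "1"),
            metadata=d.get("metadata", {}),
        )


def fit_rbf_svm(
    X: np.ndarray,
    y: list[str] | np.ndarray,
    feature_names: list[str],
    seed: int,
    C: float = 10.0,
    metadata: dict | None = None,
) -> RbfSvmModel:
    """Fit a standardized RBF support-vector classifier (deterministic
    given data and seed)."""
    from sklearn.svm import SVC

    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = sorted(set(map(str, y)))
    if len(classes) != 2:
        raise ContractError("need exactly 2 classes")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    sigma[sigma < 1e-9] = 1.0
    z = (X - mu) / sigma
    clf = SVC(C=C, kernel="rbf", gamma="scale", random_state=seed)
    clf.fit(z, (y == classes[1]).astype(int))
    return RbfSvmModel(
        feature_names=list(feature_names),
        mean=mu,
        scale=sigma,
        support_vectors=clf.support_vectors_,
        dual_coef=clf.dual_coef_.ravel(),
        gamma=float(clf._gamma),
        intercept=float(clf.intercept_[0]),
        classes=classes,
        metadata={"seed": seed, "n_train": int(len(y)), "C": C, **(metadata or {})},
    )


def load_bundled(name: str) -> "LinearModel | RbfSvmModel":
    """Load a shipped model fixture (``vessel_pixel`` or ``red_candidate``)."""
    ref = resources.files("fundusdr") / "models" / f"{name}.json"
    if not ref.is_file():
        raise ConfigurationError(
            f"model fixture {name!r} not found; run scripts/train_models.py"
        )
    with resources.as_file(ref) as p:
        kind = json.loads(Path(p).read_text(encoding="utf-8")).get("kind", "linear")
        if kind == "rbf_svm":
            return RbfSvmModel.from_json(p)
        return LinearModel.from_json(p)
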