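"""Classifiers for interface-residue prediction: Naive Bayes and soft-margin SVM.

The Naive Bayes classifier assigns label 1 when the posterior ratio
P(C=1|x)/P(C=0|x) >= 1. Probabilities come from the training data with the
Laplace (add-one) estimator for binary features and per-class Gaussians
(variance floored) for continuous features; scoring is done in log space, and
the returned ranking score is the log posterior ratio.

The SVM solves the usual soft-margin problem

    min_(w,b,xi)  1/2 w'w + C sum_i xi_i   s.t.  y_i (w'Phi(x_i) + b) >= 1 - xi_i

with either a polynomial kernel K(x,z) = (x.z + 1)^p or an RBF kernel
K(x,z) = exp(-gamma ||x-z||^2). Defaults are p=1, gamma=0.01, C=1.0, used
without tuning. The quadratic program is delegated to scikit-learn's SVC;
the fitted model is kept as its dual expansion (support vectors, alpha_i y_i,
bias) so decision values and serialization are self-contained. Ranking scores
are raw signed decision values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import EncodedInstance, instances_to_arrays, undersample
from .structio import PREDICTION_COLUMNS

__all__ = [
    "KernelSpec",
    "TrainConfig",
    "NBModel",
    "SVMModel",
    "train_nb",
    "nb_score",
    "kernel_eval",
    "train_svm",
    "svm_score",
    "predict",
    "save_model",
    "load_model",
]

_VAR_FLOOR = 1e-9


@dataclass(frozen=True)
class KernelSpec:
    family: str = "rbf"  # "polynomial" | "rbf"
    p: int = 1
    gamma: float = 0.01

    def __post_init__(self) -> None:
        if self.family not in ("polynomial", "rbf"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.p < 1 or int(self.p) != self.p:
            raise ValueError("polynomial degree p must be a positive integer")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class TrainConfig:
    algorithm: str = "svm"  # "nb" | "svm"
    kernel: KernelSpec = field(default_factory=KernelSpec)
    C: float = 1.0
    balance: bool = True  # undersample the majority class before SVM training
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("nb", "svm"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


# ---------------------------------------------------------------------------
# Naive Bayes
# ---------------------------------------------------------------------------

@dataclass
class NBModel:
    log_priors: np.ndarray  # (2,) for classes (0, 1)
    is_binary: np.ndarray  # (d,) bool per feature
    p_one: np.ndarray  # (2, d) Laplace P(x_j=1 | c); meaningful where is_binary
    means: np.ndarray  # (2, d) Gaussian means; meaningful where continuous
    variances: np.ndarray  # (2, d) floored Gaussian variances

    @property
    def n_features(self) -> int:
        return self.is_binary.shape[0]


def train_nb(instances: list[EncodedInstance]) -> NBModel:
    """Fit the mixed Bernoulli/Gaussian Naive Bayes model.

    A feature column whose training values are all in {0, 1} is treated as
    binary with add-one Laplace estimates (k+1)/(n+2); any other column gets
    per-class Gaussian parameters with a variance floor.
    """
    X, y, _ = instances_to_arrays(instances)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    is_binary = np.all((X == 0) | (X == 1), axis=0)

    n = len(y)
    log_priors = np.array([np.log(np.sum(y == c) / n) for c in (0, 1)])
    p_one = np.zeros((2, X.shape[1]))
    means = np.zeros((2, X.shape[1]))
    variances = np.full((2, X.shape[1]), _VAR_FLOOR)
    for c in (0, 1):
        Xc = X[y == c]
        nc = len(Xc)
        p_one[c] = (Xc.sum(axis=0) + 1.0) / (nc + 2.0)
        means[c] = Xc.mean(axis=0)
        variances[c] = np.maximum(Xc.var(axis=0), _VAR_FLOOR)
    return NBModel(
        log_priors=log_priors,
        is_binary=is_binary,
        p_one=p_one,
        means=means,
        variances=variances,
    )


def _nb_class_loglik(model: NBModel, X: np.ndarray, c: int) -> np.ndarray:
    b = model.is_binary
    out = np.zeros(len(X))
    if b.any():
        p = model.p_one[c, b]
        xb = X[:, b]
        out += xb @ np.log(p) + (1.0 - xb) @ np.log1p(-p)
    g = ~b
    if g.any():
        mu = model.means[c, g]
        var = model.variances[c, g]
        xg = X[:, g]
        out += np.sum(
            -0.5 * np.log(2.0 * np.pi * var) - (xg - mu) ** 2 / (2.0 * var), axis=1
        )
    return out


def nb_score(model: NBModel, x: np.ndarray) -> np.ndarray | float:
    """Log posterior ratio log P(C=1|x) - log P(C=0|x); label 1 iff score >= 0."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {X.shape[1]}")
    scores = (
        model.log_priors[1]
        + _nb_class_loglik(model, X, 1)
        - model.log_priors[0]
        - _nb_class_loglik(model, X, 0)
    )
    return float(scores[0]) if np.asarray(x).ndim == 1 else scores


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

def _kernel_matrix(spec: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    from sklearn.metrics.pairwise import polynomial_kernel, rbf_kernel

    if spec.family == "polynomial":
        return polynomial_kernel(A, B, degree=spec.p, gamma=1.0, coef0=1.0)
    return rbf_kernel(A, B, gamma=spec.gamma)


def kernel_eval(spec: KernelSpec, xi: np.ndarray, xj: np.ndarray) -> float:
    """Evaluate K(xi, xj): (xi.xj + 1)^p or exp(-gamma ||xi-xj||^2)."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise ValueError(f"dimension mismatch {xi.shape} vs {xj.shape}")
    if spec.family == "polynomial":
        return float((xi @ xj + 1.0) ** spec.p)
    return float(np.exp(-spec.gamma * np.sum((xi - xj) ** 2)))


@dataclass
class SVMModel:
    support_vectors: np.ndarray  # (n_sv, d)
    dual_coefs: np.ndarray  # (n_sv,) alpha_i * y_i
    bias: float
    kernel: KernelSpec
    C: float
    seed: int = 0

    @property
    def n_features(self) -> int:
        return self.support_vectors.shape[1]


def train_svm(instances: list[EncodedInstance], config: TrainConfig) -> SVMModel:
    """Train the soft-margin SVM (undersampling the majority class first when
    ``config.balance``); the QP is solved by scikit-learn's SVC."""
    from sklearn.svm import SVC

    if config.balance:
        instances = undersample(instances, seed=config.seed)
    X, y, _ = instances_to_arrays(instances)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    spec = config.kernel
    # solver tolerance well inside the 1e-3 KKT contract on the fitted model
    if spec.family == "polynomial":
        svc = SVC(kernel="poly", degree=spec.p, gamma=1.0, coef0=1.0, C=config.C, tol=1e-6)
    else:
        svc = SVC(kernel="rbf", gamma=spec.gamma, C=config.C, tol=1e-6)
    svc.fit(X, y)
    # classes_ is (0, 1); decision_function > 0 predicts class 1
    return SVMModel(
        support_vectors=np.array(svc.support_vectors_),
        dual_coefs=np.array(svc.dual_coef_[0]),
        bias=float(svc.intercept_[0]),
        kernel=spec,
        C=config.C,
        seed=config.seed,
    )


def svm_score(model: SVMModel, x: np.ndarray) -> np.ndarray | float:
    """Signed decision value f(x) = sum_i alpha_i y_i K(x_i, x) + b."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {X.shape[1]}")
    K = _kernel_matrix(model.kernel, X, model.support_vectors)
    scores = K @ model.dual_coefs + model.bias
    return float(scores[0]) if np.asarray(x).ndim == 1 else scores


def score(model, x):
    """Dispatch to nb_score or svm_score by model type."""
    if isinstance(model, NBModel):
        return nb_score(model, x)
    if isinstance(model, SVMModel):
        return svm_score(model, x)
    raise TypeError(f"unknown model type {type(model).__name__}")


def predict(
    model,
    instances: list[EncodedInstance],
    threshold: float = 0.0,
    residues: dict[tuple[tuple[str, str], int], str] | None = None,
) -> pd.DataFrame:
    """Score instances and threshold into a prediction table.

    Labels come along from the instances so that the table can be evaluated
    directly; residue letters are filled from ``residues`` when provided.
    """
    X, y, meta = instances_to_arrays(instances)
    scores = np.asarray(score(model, X), dtype=float)
    preds = (scores >= threshold).astype(int)
    return pd.DataFrame(
        {
            "chain_id": [key[1] for key, _ in meta],
            "position": [pos for _, pos in meta],
            "residue": [
                (residues or {}).get((key, pos), "X") for key, pos in meta
            ],
            "score": scores,
            "pred": preds,
            "label": y,
        },
        columns=PREDICTION_COLUMNS,
    )


# ---------------------------------------------------------------------------
# Serialization (versioned JSON envelope)
# ---------------------------------------------------------------------------

def save_model(model, path: str | Path) -> None:
    if isinstance(model, NBModel):
        payload = {
            "format": "rnaiface-model",
            "version": 1,
            "type": "nb",
            "log_priors": model.log_priors.tolist(),
            "is_binary": model.is_binary.astype(int).tolist(),
            "p_one": model.p_one.tolist(),
            "means": model.means.tolist(),
            "variances": model.variances.tolist(),
        }
    elif isinstance(model, SVMModel):
        payload = {
            "format": "rnaiface-model",
            "version": 1,
            "type": "svm",
            "support_vectors": model.support_vectors.tolist(),
            "dual_coefs": model.dual_coefs.tolist(),
            "bias": model.bias,
            "kernel": {"family": model.kernel.family, "p": model.kernel.p, "gamma": model.kernel.gamma},
            "C": model.C,
            "seed": model.seed,
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path):
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "rnaiface-model":
        raise ValueError(f"{path}: not a model file")
    if payload["type"] == "nb":
        return NBModel(
            log_priors=np.array(payload["log_priors"]),
            is_binary=np.array(payload["is_binary"], dtype=bool),
            p_one=np.array(payload["p_one"]),
            means=np.array(payload["means"]),
            variances=np.array(payload["variances"]),
        )
    if payload["type"] == "svm":
        k = payload["kernel"]
        return SVMModel(
            support_vectors=np.array(payload["support_vectors"]),
            dual_coefs=np.array(payload["dual_coefs"]),
            bias=float(payload["bias"]),
            kernel=KernelSpec(family=k["family"], p=k["p"], gamma=k["gamma"]),
            C=float(payload["C"]),
            seed=int(payload.get("seed", 0)),
        )
    raise ValueError(f"{path}: unknown model type {payload['type']!r}")
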