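"""Three-category training set and the linear least-squares scoring model.

A candidate complex is scored by f(x) = w·x over its 10-dimensional feature
vector, with no intercept.  The weight vector is fitted by full-batch
gradient descent on the squared error L = sum_i (y_i - w·x_i)^2, where the
labels encode three sample categories: known complexes (y=2), "uncertainty"
complexes predicted by another detector but unmatched to the benchmark
(y=1), and random node sets (y=0).  The extra intermediate category makes
the scorer more discriminative than a binary one.

Weights start at zero and the learning rate is halved whenever a step would
increase the loss, so the recorded loss trace is non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .complex_features import FEATURE_NAMES, feature_vector
from .pin_io import ComplexCatalog

logger = logging.getLogger("pincomplex")

__all__ = [
    "TrainingSample",
    "RegressionModel",
    "ConvergenceError",
    "build_training_set",
    "sample_negative_complexes",
    "fit",
    "score",
    "equal_weight_model",
    "save_model",
    "load_model",
]

#: Category labels.
LABEL_NEGATIVE, LABEL_INTERMEDIATE, LABEL_POSITIVE = 0, 1, 2

_MAX_RESAMPLE_TRIES = 1000
_MAX_ETA_HALVINGS = 200


class ConvergenceError(RuntimeError):
    """Raised when gradient descent cannot make a finite, non-increasing step."""


@dataclass
class TrainingSample:
    members: frozenset[str]
    x: np.ndarray
    y: int


@dataclass
class RegressionModel:
    """Fitted (or constructed) linear scorer: weights in canonical feature order."""

    omega: np.ndarray
    iterations: int = 0
    learning_rate: float = 0.0
    loss_trace: list[float] = field(default_factory=list)
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)


def score(model: RegressionModel, x: Sequence[float]) -> float:
    """f(x) = w·x (no intercept)."""
    x = np.asarray(x, dtype=float)
    if x.shape != model.omega.shape:
        raise ValueError(f"feature dimension {x.shape} != model dimension {model.omega.shape}")
    return float(model.omega @ x)


def equal_weight_model(dim: int = 10) -> RegressionModel:
    """Baseline scorer giving every feature the same weight (all ones)."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    names = FEATURE_NAMES if dim == len(FEATURE_NAMES) else tuple(f"f{i}" for i in range(dim))
    return RegressionModel(omega=np.ones(dim), feature_names=names)


def sample_negative_complexes(
    gu: nx.Graph,
    size_distribution: Sequence[int],
    n: int,
    seed: int,
    exclusions: Iterable[frozenset[str]] = (),
) -> list[frozenset[str]]:
    """Random node sets for the negative category.

    Each set's size is drawn from *size_distribution* (typically the positive
    catalog's sizes, power-law shaped) and its members uniformly without
    replacement from the graph's nodes.  Sets identical to an exclusion
    (positives/intermediates) are rejected and resampled; persistent failure
    is an error.
    """
    if n == 0:
        return []
    sizes = list(size_distribution)
    if not sizes:
        raise ValueError("empty size distribution")
    nodes = sorted(gu.nodes)
    if max(sizes) > len(nodes):
        raise ValueError(f"requested size {max(sizes)} exceeds graph order {len(nodes)}")
    excl = {frozenset(e) for e in exclusions}
    rng = np.random.default_rng(seed)
    out: list[frozenset[str]] = []
    for _ in range(n):
        for _try in range(_MAX_RESAMPLE_TRIES):
            size = int(sizes[rng.integers(len(sizes))])
            members = frozenset(rng.choice(nodes, size=size, replace=False))
            if members not in excl:
                out.append(members)
                break
        else:
            raise RuntimeError(
                f"could not sample a non-excluded node set after {_MAX_RESAMPLE_TRIES} tries"
            )
    return out


def build_training_set(
    positives: ComplexCatalog,
    intermediates: ComplexCatalog,
    gu: nx.Graph,
    gw: nx.Graph,
    n_negatives: int,
    seed: int,
) -> list[TrainingSample]:
    """Assemble the three-category training set with feature vectors.

    Members absent from the network are dropped per complex; complexes
    reduced below 2 members are discarded with a warning.  Negative sizes are
    drawn from the (restricted) positive size distribution.
    """
    if len(positives) == 0 or len(intermediates) == 0:
        raise ValueError("positive and intermediate catalogs must be non-empty")
    pos = positives.restricted_to(gu.nodes)
    inter = intermediates.restricted_to(gu.nodes)
    if len(pos) == 0:
        raise ValueError("no positive complex survives restriction to the network")
    samples = [
        TrainingSample(c, feature_vector(c, gu, gw), LABEL_POSITIVE) for c in pos
    ]
    samples += [
        TrainingSample(c, feature_vector(c, gu, gw), LABEL_INTERMEDIATE) for c in inter
    ]
    negatives = sample_negative_complexes(
        gu,
        pos.sizes(),
        n_negatives,
        seed,
        exclusions=list(pos) + list(inter),
    )
    samples += [
        TrainingSample(c, feature_vector(c, gu, gw), LABEL_NEGATIVE) for c in negatives
    ]
    return samples


def fit(
    samples: Sequence[TrainingSample],
    iterations: int = 500,
    eta: float = 1e-4,
    seed: int = 0,
) -> RegressionModel:
    """Full-batch gradient descent on the squared error, from zero weights.

    The step direction is the descending one, w <- w + 2*eta*X^T(y - Xw).
    Whenever a step would raise the loss the learning rate is halved and the
    step retried, so the loss trace is non-increasing.  *seed* is accepted
    for interface symmetry; the fit itself is deterministic.
    """
    if not samples:
        raise ValueError("need at least one training sample")
    if eta <= 0:
        raise ValueError("eta must be positive")
    X = np.vstack([s.x for s in samples]).astype(float)
    y = np.asarray([s.y for s in samples], dtype=float)
    dim = X.shape[1]
    w = np.zeros(dim)
    residual = y - X @ w
    loss = float(residual @ residual)
    trace = [loss]
    for _ in range(iterations):
        grad = 2.0 * (X.T @ residual)  # descent direction for L
        halvings = 0
        while True:
            w_new = w + eta * grad
            r_new = y - X @ w_new
            loss_new = float(r_new @ r_new)
            if np.isfinite(loss_new) and loss_new <= loss:
                break
            halvings += 1
            if halvings > _MAX_ETA_HALVINGS:
                raise ConvergenceError("loss not reducible after exhausting step-size halvings")
            eta /= 2.0
        w, residual, loss = w_new, r_new, loss_new
        trace.append(loss)
    return RegressionModel(
        omega=w,
        iterations=iterations,
        learning_rate=eta,
        loss_trace=trace,
        feature_names=FEATURE_NAMES if dim == len(FEATURE_NAMES) else tuple(f"f{i}" for i in range(dim)),
    )


def save_model(model: RegressionModel, path: str | PathLike) -> None:
    """Serialize a model as plain-text key/value lines."""
    with open(path, "w") as fh:
        fh.write(f"iterations\t{model.iterations}\n")
        fh.write(f"learning_rate\t{model.learning_rate:.10g}\n")
        for name, w in zip(model.feature_names, model.omega):
            fh.write(f"w:{name}\t{w:.17g}\n")


def load_model(path: str | PathLike) -> RegressionModel:
    iterations, eta = 0, 0.0
    names: list[str] = []
    weights: list[float] = []
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("#"):
                continue
            key, val = raw.rstrip("\n").split("\t")
            if key == "iterations":
                iterations = int(val)
            elif key == "learning_rate":
                eta = float(val)
            elif key.startswith("w:"):
                names.append(key[2:])
                weights.append(float(val))
    return RegressionModel(
        omega=np.asarray(weights),
        iterations=iterations,
        learning_rate=eta,
        feature_names=tuple(names),
    )
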