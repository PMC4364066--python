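"""Kronecker regularized least squares (KronRLS) for pairwise inputs.

The learner solves ridge regression over drug-target pairs whose kernel is
the product of a drug kernel and a target kernel: objective

    J(f) = sum_i (y_i - f(x_i))^2 + lambda * ||f||_k^2,

with k((d,t),(d',t')) = Kd(d,d') * Kt(t,t').  For a *complete* label matrix
Y the dual coefficients solve (Kron(Kt, Kd) + lambda I) vec(A) = vec(Y)
(column-major vec, so vec(Kd A Kt^T) = Kron(Kt, Kd) vec(A)), and the
eigendecompositions Kd = Vd diag(s_d) Vd^T, Kt = Vt diag(s_t) Vt^T give the
closed form

    A = Vd [ (Vd^T Y Vt) / (outer(s_d, s_t) + lambda) ] Vt^T

so the n_d*n_t x n_d*n_t Kronecker system is never materialized.  Tables
with unmeasured entries are mean-imputed from training entries before the
solve; evaluation downstream uses only genuinely measured pairs.

A primal ridge variant over explicit tensor-product feature columns backs
the greedy forward feature-selection experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConditioningError, EmptyDataError, ShapeError
from .io import InteractionTable, mean_impute
from .kernels import KernelSpectrum, SimilarityMatrix, decompose

__all__ = [
    "KronRLSModel",
    "PrimalRLSModel",
    "DEFAULT_LAMBDA",
    "fit_complete",
    "fit",
    "predict",
    "fit_primal_selected",
    "save_model",
    "load_model",
]

#: default regularization weight; the common default in pairwise RLS studies
DEFAULT_LAMBDA = 1.0

#: denominators s_d * s_t + lambda below this magnitude abort the solve
CONDITION_FLOOR = 1e-12


@dataclass
class KronRLSModel:
    """Fitted KronRLS model.

    ``dual_coefficients`` is the (n_drugs, n_targets) matrix A above;
    predictions for arbitrary pairs are ``Kd_cross @ A @ Kt_cross^T`` where
    the cross blocks hold test-versus-training kernel evaluations.
    """

    lambda_reg: float
    dual_coefficients: np.ndarray
    train_drug_ids: list[str]
    train_target_ids: list[str]
    kernel_refs: tuple[KernelSpectrum, KernelSpectrum] | None = field(
        default=None, repr=False
    )
    training_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.lambda_reg <= 0:
            raise ValueError("lambda_reg must be > 0")
        self.dual_coefficients = np.asarray(self.dual_coefficients, dtype=float)
        shape = (len(self.train_drug_ids), len(self.train_target_ids))
        if self.dual_coefficients.shape != shape:
            raise ShapeError(
                f"dual coefficients {self.dual_coefficients.shape} != ids {shape}"
            )


@dataclass
class PrimalRLSModel:
    """Ridge model over an explicit subset of tensor-product features."""

    lambda_reg: float
    selected_features: list[int]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if len(self.selected_features) != self.weights.size:
            raise ShapeError("weights length != number of selected features")

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float)[:, self.selected_features] @ self.weights


def fit_complete(
    Y: np.ndarray,
    Kd: KernelSpectrum,
    Kt: KernelSpectrum,
    lambda_reg: float = DEFAULT_LAMBDA,
) -> KronRLSModel:
    """Solve KronRLS in closed form for a complete label matrix.

    Cost is O(n_d^2 n_t + n_d n_t^2) given the spectra, versus
    O((n_d n_t)^3) for the naive Kronecker system.
    """
    if lambda_reg <= 0:
        raise ValueError("lambda_reg must be > 0")
    Y = np.asarray(Y, dtype=float)
    if Y.shape != (Kd.n, Kt.n):
        raise ShapeError(f"label matrix {Y.shape} does not match kernels ({Kd.n}, {Kt.n})")
    if not np.all(np.isfinite(Y)):
        raise ShapeError("label matrix must be complete; mean_impute() first")
    denom = Kd.eigenvalues[:, None] * Kt.eigenvalues[None, :] + lambda_reg
    if np.min(np.abs(denom)) < CONDITION_FLOOR:
        raise ConditioningError(
            "an eigenvalue product s_d*s_t + lambda is below 1e-12; "
            "use psd_policy='clip' or a larger lambda"
        )
    core = (Kd.eigenvectors.T @ Y @ Kt.eigenvectors) / denom
    A = Kd.eigenvectors @ core @ Kt.eigenvectors.T
    return KronRLSModel(
        lambda_reg=lambda_reg,
        dual_coefficients=A,
        train_drug_ids=list(Kd.ids),
        train_target_ids=list(Kt.ids),
        kernel_refs=(Kd, Kt),
    )


def fit(
    table: InteractionTable,
    Kd: SimilarityMatrix,
    Kt: SimilarityMatrix,
    lambda_reg: float = DEFAULT_LAMBDA,
    psd_policy: str = "keep",
) -> KronRLSModel:
    """Fit KronRLS on a (possibly incomplete) interaction table.

    Unmeasured entries are mean-imputed from the measured training entries;
    the original mask is recorded on the model so downstream evaluation can
    ignore imputed cells.  Kernel matrices are reindexed to the table's
    drug/target order (table ids must be a subset of kernel ids).
    """
    if table.n_measured == 0:
        raise EmptyDataError("cannot fit with zero measured entries")
    Kd_sub = Kd.subset(table.drug_ids)
    Kt_sub = Kt.subset(table.target_ids)
    full = mean_impute(table)
    model = fit_complete(
        full.labels, decompose(Kd_sub, psd_policy), decompose(Kt_sub, psd_policy),
        lambda_reg,
    )
    model.training_mask = table.measured_mask.copy()
    return model


def predict(
    model: KronRLSModel, Kd_cross: np.ndarray, Kt_cross: np.ndarray
) -> np.ndarray:
    """Predict a (n_test_drugs, n_test_targets) block of affinities.

    ``Kd_cross`` holds kernel values between test drugs (rows) and the
    model's training drugs (columns, in training order); likewise
    ``Kt_cross`` for targets.  Passing the training Gram matrices themselves
    reproduces the in-sample predictions.
    """
    Kd_cross = np.atleast_2d(np.asarray(Kd_cross, dtype=float))
    Kt_cross = np.atleast_2d(np.asarray(Kt_cross, dtype=float))
    n_d, n_t = model.dual_coefficients.shape
    if Kd_cross.shape[1] != n_d:
        raise ShapeError(
            f"drug cross-kernel has {Kd_cross.shape[1]} columns, expected {n_d}"
        )
    if Kt_cross.shape[1] != n_t:
        raise ShapeError(
            f"target cross-kernel has {Kt_cross.shape[1]} columns, expected {n_t}"
        )
    return Kd_cross @ model.dual_coefficients @ Kt_cross.T


def fit_primal_selected(
    X: np.ndarray,
    y: np.ndarray,
    lambda_reg: float,
    selected: list[int],
) -> PrimalRLSModel:
    """Ridge regression restricted to the selected feature columns.

    Minimizes ``||X[:, selected] w - y||^2 + lambda ||w||^2`` through the
    normal equations; with a handful of selected columns this is a tiny
    symmetric solve regardless of the total feature count.
    """
    if len(selected) == 0:
        raise ValueError("at least one feature must be selected")
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be >= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ShapeError(f"{X.shape[0]} rows of X but {y.size} labels")
    Xs = X[:, list(selected)]
    G = Xs.T @ Xs + lambda_reg * np.eye(Xs.shape[1])
    w = np.linalg.solve(G, Xs.T @ y)
    return PrimalRLSModel(
        lambda_reg=lambda_reg, selected_features=list(selected), weights=w
    )


# ---------------------------------------------------------------------------
# plain-text model serialization


def save_model(model: KronRLSModel, path) -> None:
    """Serialize lambda, id lists and the dual coefficient grid as text."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"#kronrls\tlambda={model.lambda_reg!r}\n")
        fh.write("\t".join([""] + model.train_target_ids) + "\n")
        for rid, row in zip(model.train_drug_ids, model.dual_coefficients):
            fh.write("\t".join([rid] + ["%.17g" % v for v in row]) + "\n")


def load_model(path) -> KronRLSModel:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or not header[0].startswith("#kronrls"):
            raise ShapeError(f"{path}: not a kronrls model file")
        lam = float(header[1].split("=", 1)[1])
        target_ids = fh.readline().rstrip("\n").split("\t")[1:]
        drug_ids, rows = [], []
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(target_ids) + 1:
                raise ShapeError(f"{path}: ragged coefficient row")
            drug_ids.append(cells[0])
            rows.append([float(c) for c in cells[1:]])
    return KronRLSModel(
        lambda_reg=lam,
        dual_coefficients=np.array(rows, dtype=float),
        train_drug_ids=drug_ids,
        train_target_ids=target_ids,
    )
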