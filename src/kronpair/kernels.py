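"""Drug and target kernels built from similarity matrices.

A drug-drug or target-target similarity matrix (Tanimoto coefficients,
Smith-Waterman alignment scores, ...) is used directly as the Gram matrix
of a kernel.  The kernel on drug-target *pairs* is the product of the drug
kernel and the target kernel, i.e. the Kronecker product at the Gram-matrix
level.  This module provides the standard preprocessing steps (cosine
normalization to a unit diagonal, symmetrization of asymmetric alignment
scores, the identity "delta" kernel) and the eigendecomposition consumed by
the closed-form solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import IdentifierError, NormalizationError, ShapeError

__all__ = [
    "SimilarityMatrix",
    "KernelSpectrum",
    "normalize_similarity",
    "symmetrize",
    "delta_kernel",
    "pair_kernel_value",
    "decompose",
]

#: relative tolerance used for symmetry checks and spectral reconstruction
EIG_TOL = 1e-8


def _check_unique_ids(ids: list[str]) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = {i for i in ids if i in seen or seen.add(i)}
        raise IdentifierError(f"duplicate identifiers: {sorted(dups)}")


@dataclass
class SimilarityMatrix:
    """Square, identifier-indexed similarity (kernel Gram) matrix.

    Parameters
    ----------
    ids
        Ordered unique entity identifiers (drugs or targets).
    values
        ``(n, n)`` real matrix; ``values[i, j]`` is the similarity between
        entity ``ids[i]`` and ``ids[j]``.  Symmetry is *checked*, never
        silently assumed or enforced.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        _check_unique_ids(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ShapeError(f"similarity matrix must be square, got {self.values.shape}")
        if self.values.shape[0] != len(self.ids):
            raise ShapeError(
                f"{len(self.ids)} ids but {self.values.shape[0]} rows"
            )
        if not np.all(np.isfinite(self.values)):
            raise ShapeError("similarity matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_symmetric(self, tol: float = EIG_TOL) -> bool:
        scale = max(1.0, float(np.abs(self.values).max(initial=0.0)))
        return bool(np.abs(self.values - self.values.T).max(initial=0.0) <= tol * scale)

    def index_of(self, entity_id: str) -> int:
        try:
            return self.ids.index(entity_id)
        except ValueError:
            raise IdentifierError(f"unknown identifier {entity_id!r}") from None

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def subset(self, ids: list[str]) -> "SimilarityMatrix":
        """Reindex to the given id subset, preserving the requested order."""
        idx = np.array([self.index_of(i) for i in ids], dtype=int)
        return SimilarityMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def cross_block(self, row_ids: list[str], col_ids: list[str]) -> np.ndarray:
        """Rectangular block ``values[row_ids, col_ids]`` (e.g. test x train)."""
        ri = np.array([self.index_of(i) for i in row_ids], dtype=int)
        ci = np.array([self.index_of(i) for i in col_ids], dtype=int)
        return self.values[np.ix_(ri, ci)]


@dataclass
class KernelSpectrum:
    """Eigendecomposition of a symmetric similarity matrix.

    Eigenvalues are sorted descending; eigenvectors are the matching
    orthonormal columns.  With ``psd_policy="clip"`` negative eigenvalues
    have been set to zero, which projects an indefinite similarity matrix
    onto the PSD cone.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    ids: list[str]
    psd_policy: str = "keep"
    origin: SimilarityMatrix | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.ids)

    def reconstruct(self) -> np.ndarray:
        """``V diag(lambda) V^T`` — equals the source matrix under ``keep``."""
        return (self.eigenvectors * self.eigenvalues) @ self.eigenvectors.T


def normalize_similarity(S: SimilarityMatrix) -> SimilarityMatrix:
    """Cosine-normalize so the diagonal becomes exactly 1.

    ``out[i, j] = S[i, j] / sqrt(S[i, i] * S[j, j])``.  This is the standard
    normalization applied to raw Smith-Waterman scores (dividing by the
    geometric mean of the self-alignment scores).
    """
    d = np.diag(S.values).copy()
    if np.any(d <= 0):
        bad = [S.ids[i] for i in np.nonzero(d <= 0)[0]]
        raise NormalizationError(f"nonpositive self-similarity for {bad}")
    inv = 1.0 / np.sqrt(d)
    out = S.values * np.outer(inv, inv)
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(list(S.ids), out)


def symmetrize(S: SimilarityMatrix) -> SimilarityMatrix:
    """Replace S by ``(S + S^T) / 2``."""
    return SimilarityMatrix(list(S.ids), 0.5 * (S.values + S.values.T))


def delta_kernel(ids: list[str]) -> SimilarityMatrix:
    """Identity (delta) kernel: each entity is similar only to itself.

    Using the delta kernel on one side removes all generalization
    information for that side — the device used to show that predicting for
    unseen drugs requires a real drug-drug similarity.
    """
    ids = list(ids)
    if not ids:
        raise IdentifierError("delta kernel requires a nonempty id list")
    _check_unique_ids(ids)
    return SimilarityMatrix(ids, np.eye(len(ids)))


def pair_kernel_value(
    Kd: SimilarityMatrix,
    Kt: SimilarityMatrix,
    a: tuple[str, str],
    b: tuple[str, str],
) -> float:
    """Product pair kernel between drug-target pairs ``a`` and ``b``.

    ``k((d, t), (d', t')) = Kd(d, d') * Kt(t, t')``.
    """
    return Kd.loc(a[0], b[0]) * Kt.loc(a[1], b[1])


def decompose(S: SimilarityMatrix, psd_policy: str = "keep") -> KernelSpectrum:
    """Eigendecompose a symmetric similarity matrix.

    Parameters
    ----------
    S
        Symmetric similarity matrix (symmetrize first if needed; asymmetry
        beyond tolerance is an error, not a silent fix).
    psd_policy
        ``"keep"`` retains negative eigenvalues of an indefinite matrix;
        ``"clip"`` zeroes them.
    """
    if psd_policy not in ("keep", "clip"):
        raise ValueError(f"psd_policy must be 'keep' or 'clip', got {psd_policy!r}")
    if not S.is_symmetric():
        raise ShapeError("matrix is asymmetric beyond tolerance; symmetrize() first")
    # eigh on the explicitly symmetrized values for numerical hygiene
    w, V = np.linalg.eigh(0.5 * (S.values + S.values.T))
    order = np.argsort(-w, kind="stable")
    w, V = w[order], V[:, order]
    if psd_policy == "clip":
        w = np.maximum(w, 0.0)
    return KernelSpectrum(w, V, list(S.ids), psd_policy, origin=S)


def warn_if_asymmetric(S: SimilarityMatrix, context: str = "") -> None:
    if not S.is_symmetric():
        warnings.warn(
            f"similarity matrix {context or 'input'} is asymmetric; "
            "consider symmetrize() before use as a kernel",
            stacklevel=2,
        )
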