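"""Reading, writing and transforming drug-target interaction tables.

The on-disk dialect is the plain TSV grid used by the public drug-target
benchmark matrices: the first row holds target identifiers (preceded by an
empty cell), the first column holds drug identifiers, and every other cell
is a decimal number or a missing-value token ("NA" by default; "nan" in any
case is also accepted).  Similarity matrices use the same grid with matching
row and column identifiers.

Label conventions: Kd and Ki bioactivities are in nM, where *smaller* means
tighter binding.  An :class:`InteractionTable` therefore carries a
``larger_is_stronger`` flag; :func:`transform_labels` with ``negate`` or
``neglog10`` flips raw bioactivities into the "larger = stronger" orientation
expected by ranking metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import (
    DomainError,
    EmptyDataError,
    FormatError,
    IdentifierError,
    ShapeError,
    StateError,
)
from .kernels import SimilarityMatrix, _check_unique_ids, warn_if_asymmetric

__all__ = [
    "InteractionTable",
    "DatasetStats",
    "read_interaction_matrix",
    "write_interaction_matrix",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "transform_labels",
    "binarize",
    "mean_impute",
    "dataset_stats",
]

#: default serialization for missing (unmeasured) entries
DEFAULT_MISSING_TOKEN = "NA"

#: float format that round-trips IEEE doubles exactly
_FLOAT_FMT = "%.17g"


@dataclass
class InteractionTable:
    """Drug x target label matrix with a measured-entry mask.

    Parameters
    ----------
    drug_ids, target_ids
        Ordered unique identifiers for rows and columns.
    labels
        ``(n_drugs, n_targets)`` real matrix.  Entries where
        ``measured_mask`` is False carry no information (NaN by convention).
    measured_mask
        Boolean matrix marking which entries were experimentally measured.
    label_kind
        ``"quantitative"`` (affinities, transformed affinities) or
        ``"binary"`` (all measured labels in {0, 1}).
    larger_is_stronger
        Orientation flag: True if a larger label means stronger interaction
        (binary labels, -log10 affinities), False for raw Kd/Ki in nM.
    original_mask
        Set by :func:`mean_impute`: the pre-imputation mask, so evaluation
        can be restricted to genuinely measured pairs.
    """

    drug_ids: list[str]
    target_ids: list[str]
    labels: np.ndarray
    measured_mask: np.ndarray
    label_kind: str = "quantitative"
    larger_is_stronger: bool = True
    original_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.drug_ids = [str(d) for d in self.drug_ids]
        self.target_ids = [str(t) for t in self.target_ids]
        _check_unique_ids(self.drug_ids)
        _check_unique_ids(self.target_ids)
        self.labels = np.asarray(self.labels, dtype=float)
        self.measured_mask = np.asarray(self.measured_mask, dtype=bool)
        shape = (len(self.drug_ids), len(self.target_ids))
        if self.labels.shape != shape:
            raise ShapeError(f"labels shape {self.labels.shape} != id shape {shape}")
        if self.measured_mask.shape != shape:
            raise ShapeError(
                f"mask shape {self.measured_mask.shape} != id shape {shape}"
            )
        if self.label_kind not in ("quantitative", "binary"):
            raise ValueError(f"unknown label_kind {self.label_kind!r}")
        measured = self.labels[self.measured_mask]
        if measured.size and not np.all(np.isfinite(measured)):
            raise ShapeError("non-finite label at a measured entry")
        if self.label_kind == "binary" and measured.size:
            if not np.all(np.isin(measured, (0.0, 1.0))):
                raise StateError("binary table has measured labels outside {0, 1}")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_measured(self) -> int:
        return int(self.measured_mask.sum())

    def measured_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (drug, target) of measured entries, row-major order."""
        di, ti = np.nonzero(self.measured_mask)
        return list(zip(di.tolist(), ti.tolist()))

    def equals(self, other: "InteractionTable") -> bool:
        return (
            self.drug_ids == other.drug_ids
            and self.target_ids == other.target_ids
            and np.array_equal(self.measured_mask, other.measured_mask)
            and np.array_equal(
                self.labels[self.measured_mask], other.labels[other.measured_mask]
            )
            and self.label_kind == other.label_kind
        )


@dataclass
class DatasetStats:
    """Size, shape-ratio and promiscuity summary of a binary table.

    ``ratio`` is drugs per target; ``promiscuity`` is the number of
    interactions divided by the number of *measured* drug-target pairs, a
    proxy for the degree of polypharmacology in the data set.
    """

    n_drugs: int
    n_targets: int
    ratio: float
    n_interactions: int
    n_measured: int
    promiscuity: float


# ---------------------------------------------------------------------------
# TSV grid parsing


def _parse_grid(
    path, missing_token: str
) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Parse the labelled TSV grid into (row_ids, col_ids, values, mask)."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        lines = fh.read().split("\n")
    while lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header and header[0] == "":
        col_ids = header[1:]
    else:
        # tolerate a header without the leading empty cell
        col_ids = header
    _check_unique_ids(col_ids)
    n_cols = len(col_ids)
    row_ids: list[str] = []
    values = np.empty((len(lines) - 1, n_cols), dtype=float)
    mask = np.ones_like(values, dtype=bool)
    missing_lower = missing_token.lower()
    for r, line in enumerate(lines[1:]):
        cells = line.split("\t")
        if len(cells) != n_cols + 1:
            raise FormatError(
                f"{path}: row {r + 2} has {len(cells)} cells, expected {n_cols + 1}"
            )
        row_ids.append(cells[0])
        for c, cell in enumerate(cells[1:]):
            s = cell.strip()
            if s.lower() in (missing_lower, "nan"):
                values[r, c] = np.nan
                mask[r, c] = False
                continue
            try:
                values[r, c] = float(s)
            except ValueError:
                raise FormatError(
                    f"{path}: unparseable cell {cell!r} at row {r + 2}, column {c + 2}"
                ) from None
            if not math.isfinite(values[r, c]):
                values[r, c] = np.nan
                mask[r, c] = False
    _check_unique_ids(row_ids)
    return row_ids, col_ids, values, mask


def _write_grid(
    path,
    row_ids: list[str],
    col_ids: list[str],
    values: np.ndarray,
    mask: np.ndarray,
    missing_token: str,
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join([""] + list(col_ids)) + "\n")
        for r, rid in enumerate(row_ids):
            cells = [rid]
            for c in range(len(col_ids)):
                cells.append(
                    _FLOAT_FMT % values[r, c] if mask[r, c] else missing_token
                )
            fh.write("\t".join(cells) + "\n")


def read_interaction_matrix(
    path, missing_token: str = DEFAULT_MISSING_TOKEN, larger_is_stronger: bool = True
) -> InteractionTable:
    """Read a drug x target interaction matrix from a labelled TSV grid.

    Rows are drugs, columns are targets; identifiers are preserved in file
    order.  Cells equal to ``missing_token`` (or "nan", case-insensitively)
    become unmeasured entries.
    """
    drug_ids, target_ids, values, mask = _parse_grid(path, missing_token)
    measured = values[mask]
    kind = (
        "binary"
        if measured.size and np.all(np.isin(measured, (0.0, 1.0)))
        else "quantitative"
    )
    return InteractionTable(
        drug_ids, target_ids, values, mask,
        label_kind=kind, larger_is_stronger=larger_is_stronger,
    )


def write_interaction_matrix(
    table: InteractionTable, path, missing_token: str = DEFAULT_MISSING_TOKEN
) -> None:
    """Write a table to the TSV grid dialect; round-trip safe."""
    _write_grid(
        path, table.drug_ids, table.target_ids, table.labels,
        table.measured_mask, missing_token,
    )


def read_similarity_matrix(
    path, missing_token: str = DEFAULT_MISSING_TOKEN
) -> SimilarityMatrix:
    """Read a square similarity matrix; row ids must equal column ids.

    Asymmetry (as in raw Smith-Waterman scores) is preserved and flagged
    with a warning — it is never silently symmetrized.
    """
    row_ids, col_ids, values, mask = _parse_grid(path, missing_token)
    if len(row_ids) != len(col_ids):
        raise ShapeError(
            f"{path}: similarity matrix is {len(row_ids)}x{len(col_ids)}, not square"
        )
    if row_ids != col_ids:
        raise IdentifierError(f"{path}: row ids differ from column ids")
    if not mask.all():
        raise FormatError(f"{path}: similarity matrix has missing entries")
    S = SimilarityMatrix(row_ids, values)
    warn_if_asymmetric(S, context=str(path))
    return S


def write_similarity_matrix(S: SimilarityMatrix, path) -> None:
    _write_grid(
        path, S.ids, S.ids, S.values, np.ones_like(S.values, dtype=bool),
        DEFAULT_MISSING_TOKEN,
    )


# ---------------------------------------------------------------------------
# Label transforms


def transform_labels(table: InteractionTable, mode: str) -> InteractionTable:
    """Elementwise monotone transform of measured labels.

    ``identity`` is a no-op; ``negate`` maps y to -y; ``neglog10`` maps y to
    -log10(y) (the usual transform for nM affinities, e.g. 100 nM -> -2).
    ``negate`` and ``neglog10`` flip the orientation flag, since both reverse
    the label order.
    """
    if table.label_kind != "quantitative":
        raise StateError("transform_labels requires quantitative labels")
    if mode == "identity":
        return replace(table, labels=table.labels.copy())
    if mode not in ("negate", "neglog10"):
        raise ValueError(f"unknown transform mode {mode!r}")
    labels = table.labels.copy()
    m = table.measured_mask
    if mode == "negate":
        labels[m] = -labels[m]
    else:
        if np.any(labels[m] <= 0):
            raise DomainError("neglog10 requires strictly positive labels")
        labels[m] = -np.log10(labels[m])
    return replace(
        table, labels=labels, larger_is_stronger=not table.larger_is_stronger
    )


def binarize(
    table: InteractionTable, cutoff: float, below_is_interaction: bool = True
) -> InteractionTable:
    """Threshold quantitative labels into binary interaction calls.

    With the default direction an entry is an interaction (1) iff its label
    is *strictly below* the cutoff — matching the convention for Kd/Ki in nM
    where e.g. Kd < 30.00 nM defines an interaction, and the boundary value
    itself maps to 0.  With ``below_is_interaction=False`` the rule is
    strictly above.
    """
    if table.label_kind == "binary":
        raise StateError("table is already binary")
    labels = np.full_like(table.labels, np.nan)
    m = table.measured_mask
    if below_is_interaction:
        labels[m] = (table.labels[m] < cutoff).astype(float)
    else:
        labels[m] = (table.labels[m] > cutoff).astype(float)
    return replace(
        table, labels=labels, label_kind="binary", larger_is_stronger=True
    )


def mean_impute(table: InteractionTable) -> InteractionTable:
    """Fill unmeasured entries with the mean of all measured entries.

    The returned table is fully measured (so the complete-matrix solver
    applies) but keeps the pre-imputation mask in ``original_mask`` so that
    prediction performance can be evaluated on measured pairs only.
    """
    if table.n_measured == 0:
        raise EmptyDataError("cannot impute a table with zero measured entries")
    if table.measured_mask.all():
        return replace(
            table,
            labels=table.labels.copy(),
            original_mask=table.measured_mask.copy(),
        )
    mean = float(table.labels[table.measured_mask].mean())
    labels = table.labels.copy()
    labels[~table.measured_mask] = mean
    return replace(
        table,
        labels=labels,
        measured_mask=np.ones_like(table.measured_mask),
        original_mask=table.measured_mask.copy(),
    )


def dataset_stats(table: InteractionTable) -> DatasetStats:
    """Characterize a binary interaction table.

    ``ratio = n_drugs / n_targets``; ``promiscuity = n_interactions /
    n_measured``.  Quantitative tables must be binarized at a stated cutoff
    first.
    """
    if table.n_targets == 0:
        raise ShapeError("table has zero targets")
    if table.label_kind != "binary":
        raise StateError("dataset_stats requires a binary table; binarize() first")
    n_measured = table.n_measured
    n_interactions = int(np.nansum(table.labels[table.measured_mask]))
    return DatasetStats(
        n_drugs=table.n_drugs,
        n_targets=table.n_targets,
        ratio=table.n_drugs / table.n_targets,
        n_interactions=n_interactions,
        n_measured=n_measured,
        promiscuity=(n_interactions / n_measured) if n_measured else 0.0,
    )
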