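"""Setting-aware cross-validation for pairwise drug-target data.

Pairwise inputs break the assumptions behind ordinary cross-validation:
whether a test pair's drug and/or target were seen during training changes
the difficulty of the task entirely.  Four experimental settings are
distinguished:

* S1 — both the drug and the target of a test pair occur in training
  (random hold-out of matrix *entries*);
* S2 — the target is known but the drug is new (hold out whole *rows*);
* S3 — the drug is known but the target is new (hold out whole *columns*);
* S4 — both are new (hold out a row-block x column-block submatrix; entries
  sharing exactly one of the held-out row or column groups can be used
  neither for training nor testing and are *discarded* for that round).

This module builds fold plans for all four settings plus their minimal-fold
variants (leave-one-pair-out, leave-drug-out, leave-target-out), runs
cross-validation with averaging or pooling aggregation, selects the ridge
weight lambda on an inner grid, performs nested cross-validation (outer
folds estimate performance, inner folds — built from outer training pairs
only — pick hyperparameters), and implements greedy forward selection over
explicit pair features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import EvaluationError, FoldError, IdentifierError, ShapeError
from .io import InteractionTable, mean_impute
from .kernels import SimilarityMatrix, decompose
from .kronrls import DEFAULT_LAMBDA, fit_complete, fit_primal_selected, predict
from .metrics import METRICS, UNDEFINED, UndefinedMetric, is_defined

__all__ = [
    "Split",
    "SplitPlan",
    "EvaluationResult",
    "make_folds_s1",
    "make_folds_s2",
    "make_folds_s3",
    "make_folds_s4",
    "make_loo_variants",
    "run_cv",
    "select_lambda",
    "nested_cv",
    "greedy_forward_selection",
    "DEFAULT_LAMBDA_GRID",
]

Pair = tuple[int, int]

#: powers of 2 from 2^-15 to 2^30: covers both the customary default
#: lambda = 1 and the large optima seen on quantitative affinity data
DEFAULT_LAMBDA_GRID = [2.0**p for p in range(-15, 31)]


@dataclass(frozen=True)
class Split:
    """One train/test(/discarded) partition of the measured pairs."""

    train_pairs: frozenset[Pair]
    test_pairs: frozenset[Pair]
    discarded_pairs: frozenset[Pair] = frozenset()

    def __post_init__(self) -> None:
        if self.train_pairs & self.test_pairs:
            raise FoldError("train and test pairs overlap")
        if self.discarded_pairs & (self.train_pairs | self.test_pairs):
            raise FoldError("discarded pairs overlap train or test")

    @property
    def is_degenerate(self) -> bool:
        return len(self.train_pairs) == 0


@dataclass
class SplitPlan:
    """Ordered splits tagged with their experimental setting."""

    setting: str
    splits: list[Split]
    seed: int | None = None
    fold_spec: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.setting not in ("S1", "S2", "S3", "S4"):
            raise ValueError(f"unknown setting {self.setting!r}")

    def __len__(self) -> int:
        return len(self.splits)

    def __iter__(self):
        return iter(self.splits)


@dataclass
class EvaluationResult:
    """Per-fold metric values plus the aggregate.

    ``per_fold`` holds one entry per split; folds where the metric was
    undefined carry the UNDEFINED marker and are excluded from averaging
    (their count is in ``n_undefined``).  Under the pooled strategy the
    aggregate is computed once on all test predictions concatenated.
    """

    metric_name: str
    per_fold: list[float | UndefinedMetric]
    aggregate: float
    strategy: str
    setting: str
    n_undefined: int = 0
    selected_hyperparams: list[dict] | None = None


# ---------------------------------------------------------------------------
# fold construction


def _partition(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition of range(n) into k folds with sizes differing <= 1."""
    return np.array_split(rng.permutation(n), k)


def make_folds_s1(table: InteractionTable, k: int, seed: int) -> SplitPlan:
    """Random k-fold partition of the measured *entries* (setting S1)."""
    pairs = table.measured_pairs()
    if k < 2 or k > len(pairs):
        raise FoldError(f"cannot make {k} folds from {len(pairs)} measured pairs")
    rng = np.random.default_rng(seed)
    folds = _partition(len(pairs), k, rng)
    pair_arr = np.array(pairs, dtype=int)
    splits = []
    for fold in folds:
        test = frozenset(map(tuple, pair_arr[fold]))
        splits.append(Split(frozenset(pairs) - test, test))
    return SplitPlan("S1", splits, seed, (k,))


def _entity_folds_plan(
    table: InteractionTable, k: int, seed: int, axis: int
) -> SplitPlan:
    """Shared row/column fold logic behind S2 (axis 0) and S3 (axis 1)."""
    n_entities = table.n_drugs if axis == 0 else table.n_targets
    if k < 2 or k > n_entities:
        raise FoldError(f"cannot make {k} folds from {n_entities} entities")
    rng = np.random.default_rng(seed)
    folds = _partition(n_entities, k, rng)
    pairs = table.measured_pairs()
    splits = []
    for fold in folds:
        held = set(fold.tolist())
        test = frozenset(p for p in pairs if p[axis] in held)
        train = frozenset(p for p in pairs if p[axis] not in held)
        splits.append(Split(train, test))
    return SplitPlan("S2" if axis == 0 else "S3", splits, seed, (k,))


def make_folds_s2(table: InteractionTable, k: int, seed: int) -> SplitPlan:
    """k-fold partition of the *drugs*; each split tests whole rows (S2)."""
    return _entity_folds_plan(table, k, seed, axis=0)


def make_folds_s3(table: InteractionTable, k: int, seed: int) -> SplitPlan:
    """k-fold partition of the *targets*; each split tests whole columns (S3)."""
    return _entity_folds_plan(table, k, seed, axis=1)


def make_folds_s4(
    table: InteractionTable, kd: int, kt: int, seed: int
) -> SplitPlan:
    """Joint kd x kt block partition for the both-new setting S4.

    Drugs and targets are partitioned independently; split (i, j) tests the
    measured pairs in drug-fold i x target-fold j, trains on pairs whose
    drug and target both lie outside those folds, and discards pairs
    sharing exactly one coordinate's fold with the test block.
    """
    if kd < 2 or kd > table.n_drugs:
        raise FoldError(f"cannot make {kd} drug folds from {table.n_drugs} drugs")
    if kt < 2 or kt > table.n_targets:
        raise FoldError(f"cannot make {kt} target folds from {table.n_targets} targets")
    rng = np.random.default_rng(seed)
    drug_folds = _partition(table.n_drugs, kd, rng)
    target_folds = _partition(table.n_targets, kt, rng)
    pairs = table.measured_pairs()
    splits = []
    for dfold in drug_folds:
        dheld = set(dfold.tolist())
        for tfold in target_folds:
            theld = set(tfold.tolist())
            test, train, discarded = set(), set(), set()
            for d, t in pairs:
                in_d, in_t = d in dheld, t in theld
                if in_d and in_t:
                    test.add((d, t))
                elif in_d or in_t:
                    discarded.add((d, t))
                else:
                    train.add((d, t))
            splits.append(
                Split(frozenset(train), frozenset(test), frozenset(discarded))
            )
    return SplitPlan("S4", splits, seed, (kd, kt))


def make_loo_variants(table: InteractionTable, variant: str) -> SplitPlan:
    """Minimal-fold plans: LOO (per pair), LDO (per drug), LTO (per target).

    These keep fold sizes as small as the setting's constraints allow; the
    price is that multivariate metrics are often undefined per fold, which
    is why the pooled aggregation strategy exists.
    """
    pairs = table.measured_pairs()
    if not pairs:
        raise FoldError("table has no measured pairs")
    if variant == "LOO":
        splits = [
            Split(frozenset(pairs) - {p}, frozenset({p})) for p in pairs
        ]
        return SplitPlan("S1", splits, None, (len(pairs),))
    if variant == "LDO":
        drugs = sorted({d for d, _ in pairs})
        splits = [
            Split(
                frozenset(p for p in pairs if p[0] != d),
                frozenset(p for p in pairs if p[0] == d),
            )
            for d in drugs
        ]
        return SplitPlan("S2", splits, None, (len(drugs),))
    if variant == "LTO":
        targets = sorted({t for _, t in pairs})
        splits = [
            Split(
                frozenset(p for p in pairs if p[1] != t),
                frozenset(p for p in pairs if p[1] == t),
            )
            for t in targets
        ]
        return SplitPlan("S3", splits, None, (len(targets),))
    raise ValueError(f"unknown variant {variant!r}; expected LOO, LDO or LTO")


# ---------------------------------------------------------------------------
# running cross-validation


def _check_kernel_alignment(
    table: InteractionTable, Kd: SimilarityMatrix, Kt: SimilarityMatrix
) -> None:
    if list(Kd.ids) != list(table.drug_ids):
        raise IdentifierError("drug kernel ids do not match table drug ids")
    if list(Kt.ids) != list(table.target_ids):
        raise IdentifierError("target kernel ids do not match table target ids")


def _subtable_for_pairs(
    table: InteractionTable, pairs: frozenset[Pair]
) -> tuple[InteractionTable, list[int], list[int]]:
    """Restrict the table to the drugs/targets spanned by ``pairs``.

    Entries of the submatrix not in ``pairs`` are marked unmeasured, so the
    training mean and the fit see training information only.
    """
    drugs = sorted({d for d, _ in pairs})
    targets = sorted({t for _, t in pairs})
    dpos = {d: i for i, d in enumerate(drugs)}
    tpos = {t: j for j, t in enumerate(targets)}
    labels = table.labels[np.ix_(drugs, targets)].copy()
    mask = np.zeros((len(drugs), len(targets)), dtype=bool)
    for d, t in pairs:
        mask[dpos[d], tpos[t]] = True
    labels[~mask] = np.nan
    sub = InteractionTable(
        [table.drug_ids[d] for d in drugs],
        [table.target_ids[t] for t in targets],
        labels,
        mask,
        label_kind=table.label_kind,
        larger_is_stronger=table.larger_is_stronger,
    )
    return sub, drugs, targets


def _fit_split_predict(
    table: InteractionTable,
    Kd: SimilarityMatrix,
    Kt: SimilarityMatrix,
    split: Split,
    lambda_reg: float,
    psd_policy: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit on a split's training pairs, return (y_test, f_test) vectors."""
    sub, train_drugs, train_targets = _subtable_for_pairs(table, split.train_pairs)
    full = mean_impute(sub)
    Kd_train = SimilarityMatrix(
        sub.drug_ids, Kd.values[np.ix_(train_drugs, train_drugs)]
    )
    Kt_train = SimilarityMatrix(
        sub.target_ids, Kt.values[np.ix_(train_targets, train_targets)]
    )
    model = fit_complete(
        full.labels, decompose(Kd_train, psd_policy), decompose(Kt_train, psd_policy),
        lambda_reg,
    )
    test = sorted(split.test_pairs)
    test_drugs = sorted({d for d, _ in test})
    test_targets = sorted({t for _, t in test})
    Kd_cross = Kd.values[np.ix_(test_drugs, train_drugs)]
    Kt_cross = Kt.values[np.ix_(test_targets, train_targets)]
    block = predict(model, Kd_cross, Kt_cross)
    drow = {d: i for i, d in enumerate(test_drugs)}
    tcol = {t: j for j, t in enumerate(test_targets)}
    y = np.array([table.labels[d, t] for d, t in test])
    f = np.array([block[drow[d], tcol[t]] for d, t in test])
    return y, f


def run_cv(
    table: InteractionTable,
    Kd: SimilarityMatrix,
    Kt: SimilarityMatrix,
    plan: SplitPlan,
    lambda_reg: float = DEFAULT_LAMBDA,
    metric: str = "ci",
    strategy: str = "averaged",
    psd_policy: str = "keep",
) -> EvaluationResult:
    """Cross-validate KronRLS over a fold plan.

    Each split is fitted on its training pairs only (the training submatrix
    is mean-imputed from training entries — never from test or discarded
    cells) and scored on its test pairs.  ``strategy="averaged"`` averages
    the defined per-fold metric values; ``"pooled"`` concatenates all test
    predictions and computes the metric once, the fallback the minimal-fold
    variants need.
    """
    _check_kernel_alignment(table, Kd, Kt)
    if strategy not in ("averaged", "pooled"):
        raise ValueError(f"unknown strategy {strategy!r}")
    stat = METRICS[metric]
    per_fold: list[float | UndefinedMetric] = []
    pooled_y, pooled_f = [], []
    for split in plan:
        if split.is_degenerate or not split.test_pairs:
            per_fold.append(UNDEFINED)
            continue
        y, f = _fit_split_predict(table, Kd, Kt, split, lambda_reg, psd_policy)
        pooled_y.append(y)
        pooled_f.append(f)
        per_fold.append(stat(y, f))
    defined = [v for v in per_fold if is_defined(v)]
    n_undefined = len(per_fold) - len(defined)
    if strategy == "averaged":
        if not defined:
            raise EvaluationError("metric undefined on every fold; try pooling")
        aggregate = float(np.mean(defined))
    else:
        if not pooled_y:
            raise EvaluationError("no test predictions produced")
        pooled = stat(np.concatenate(pooled_y), np.concatenate(pooled_f))
        if not is_defined(pooled):
            raise EvaluationError("metric undefined even on pooled predictions")
        aggregate = float(pooled)
    return EvaluationResult(
        metric_name=metric,
        per_fold=per_fold,
        aggregate=aggregate,
        strategy=strategy,
        setting=plan.setting,
        n_undefined=n_undefined,
    )


def select_lambda(
    table: InteractionTable,
    Kd: SimilarityMatrix,
    Kt: SimilarityMatrix,
    plan: SplitPlan,
    grid: list[float],
    metric: str = "ci",
    strategy: str = "averaged",
    psd_policy: str = "keep",
) -> tuple[float, list[tuple[float, float]]]:
    """Grid-search lambda by inner cross-validation.

    Returns the grid value maximizing the aggregate metric and the full
    (lambda, score) curve.  Ties break toward the smaller lambda, which is
    the stronger regularizer relative to nothing and keeps selection
    deterministic.
    """
    if not grid:
        raise ValueError("lambda grid must be nonempty")
    curve = []
    for lam in sorted(grid):
        try:
            res = run_cv(table, Kd, Kt, plan, lam, metric, strategy, psd_policy)
            score = res.aggregate
        except EvaluationError:
            score = -np.inf
        curve.append((lam, score))
    best_lam, _ = max(curve, key=lambda ls: (ls[1], -ls[0]))
    return best_lam, curve


def _inner_plan(
    sub: InteractionTable, setting: str, inner_spec: tuple[int, ...], seed: int
) -> SplitPlan:
    if setting == "S1":
        return make_folds_s1(sub, inner_spec[0], seed)
    if setting == "S2":
        return make_folds_s2(sub, min(inner_spec[0], sub.n_drugs), seed)
    if setting == "S3":
        return make_folds_s3(sub, min(inner_spec[0], sub.n_targets), seed)
    kd, kt = inner_spec
    return make_folds_s4(
        sub, min(kd, sub.n_drugs), min(kt, sub.n_targets), seed
    )


def nested_cv(
    table: InteractionTable,
    Kd: SimilarityMatrix,
    Kt: SimilarityMatrix,
    outer: SplitPlan,
    inner_spec: tuple[int, ...],
    grid: list[float],
    metric: str = "ci",
    strategy: str = "averaged",
    psd_policy: str = "keep",
    seed: int = 0,
) -> EvaluationResult:
    """Two-level cross-validation: outer folds estimate, inner folds select.

    For each outer split the inner fold plan is built from the outer
    *training* pairs only, under the same experimental setting, so the
    selected lambda never saw the outer test data.  The model is then refit
    on the full outer training set with the selected lambda and scored on
    the outer test pairs.  This removes the optimism that plagues reporting
    simple-CV accuracy at the selected hyperparameter.
    """
    _check_kernel_alignment(table, Kd, Kt)
    stat = METRICS[metric]
    per_fold: list[float | UndefinedMetric] = []
    pooled_y, pooled_f = [], []
    chosen: list[dict] = []
    for i, split in enumerate(outer):
        if split.is_degenerate or not split.test_pairs:
            per_fold.append(UNDEFINED)
            chosen.append({})
            continue
        sub, train_drugs, train_targets = _subtable_for_pairs(
            table, split.train_pairs
        )
        Kd_sub = SimilarityMatrix(
            sub.drug_ids, Kd.values[np.ix_(train_drugs, train_drugs)]
        )
        Kt_sub = SimilarityMatrix(
            sub.target_ids, Kt.values[np.ix_(train_targets, train_targets)]
        )
        try:
            inner = _inner_plan(sub, outer.setting, inner_spec, seed + i)
        except FoldError as exc:
            raise FoldError(
                f"outer fold {i}: training set too small for inner folds"
            ) from exc
        lam, _ = select_lambda(
            sub, Kd_sub, Kt_sub, inner, grid, metric, strategy, psd_policy
        )
        chosen.append({"lambda": lam})
        y, f = _fit_split_predict(table, Kd, Kt, split, lam, psd_policy)
        pooled_y.append(y)
        pooled_f.append(f)
        per_fold.append(stat(y, f))
    defined = [v for v in per_fold if is_defined(v)]
    n_undefined = len(per_fold) - len(defined)
    if strategy == "averaged":
        if not defined:
            raise EvaluationError("metric undefined on every outer fold")
        aggregate = float(np.mean(defined))
    else:
        pooled = stat(np.concatenate(pooled_y), np.concatenate(pooled_f))
        if not is_defined(pooled):
            raise EvaluationError("metric undefined on pooled predictions")
        aggregate = float(pooled)
    return EvaluationResult(
        metric_name=metric,
        per_fold=per_fold,
        aggregate=aggregate,
        strategy=strategy,
        setting=outer.setting,
        n_undefined=n_undefined,
        selected_hyperparams=chosen,
    )


# ---------------------------------------------------------------------------
# greedy forward feature selection over explicit pair features


def _kfold_indices(n: int, k: int, rng: np.random.Generator):
    for fold in _partition(n, k, rng):
        test = np.sort(fold)
        train = np.setdiff1d(np.arange(n), test)
        yield train, test


def greedy_forward_selection(
    X: np.ndarray,
    y: np.ndarray,
    lambda_reg: float = DEFAULT_LAMBDA,
    n_folds: int = 5,
    max_features: int = 10,
    metric: str = "ci",
    seed: int = 0,
) -> tuple[list[int], list[float]]:
    """Greedy forward selection of tensor-product feature columns.

    At each step the candidate feature whose addition maximizes the simple
    inner-CV metric of the primal ridge fit is added (ties break toward the
    lowest column index).  Returns the selection order and the inner-CV
    score curve after each addition.  The curve is exactly the optimistic
    "simple CV" estimate: the same folds that chose the features also score
    them, so its maximum overstates independent-test performance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ShapeError("X must be (n_pairs, n_features) aligned with y")
    if max_features < 1:
        raise ValueError("max_features must be >= 1")
    if max_features > X.shape[1]:
        raise ValueError("max_features exceeds the number of features")
    stat = METRICS[metric]
    rng = np.random.default_rng(seed)
    folds = list(_kfold_indices(X.shape[0], n_folds, rng))
    selected: list[int] = []
    curve: list[float] = []
    remaining = list(range(X.shape[1]))
    for _ in range(max_features):
        best_j, best_score = None, -np.inf
        for j in remaining:
            cols = selected + [j]
            vals = []
            for train, test in folds:
                model = fit_primal_selected(X[train], y[train], lambda_reg, cols)
                v = stat(y[test], model.predict(X[test]))
                if is_defined(v):
                    vals.append(v)
            score = float(np.mean(vals)) if vals else -np.inf
            if score > best_score:
                best_j, best_score = j, score
        selected.append(best_j)
        remaining.remove(best_j)
        curve.append(best_score)
    return selected, curve
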