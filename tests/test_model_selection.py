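import numpy as np
import pytest

from kronpair import (
    InteractionTable,
    SyntheticSpec,
    delta_kernel,
    generate,
    greedy_forward_selection,
    is_defined,
    make_folds_s1,
    make_folds_s2,
    make_folds_s3,
    make_folds_s4,
    make_loo_variants,
    nested_cv,
    run_cv,
    select_lambda,
)
from kronpair.exceptions import FoldError


def complete_table(nd, nt, seed=0):
    rng = np.random.default_rng(seed)
    return InteractionTable(
        [f"d{i}" for i in range(nd)],
        [f"t{j}" for j in range(nt)],
        rng.standard_normal((nd, nt)),
        np.ones((nd, nt), dtype=bool),
    )


def check_split_constraints(plan, table):
    """Independent checker re-deriving drug/target memberships from the raw
    index sets, asserting the setting's constraints and pair trichotomy."""
    measured = set(table.measured_pairs())
    tested = []
    for split in plan:
        train, test, disc = (
            set(split.train_pairs),
            set(split.test_pairs),
            set(split.discarded_pairs),
        )
        assert not (train & test) and not (train & disc) and not (test & disc)
        assert train | test | disc <= measured
        train_drugs = {d for d, _ in train}
        train_targets = {t for _, t in train}
        test_drugs = {d for d, _ in test}
        test_targets = {t for _, t in test}
        if plan.setting in ("S2", "S4"):
            assert not (train_drugs & test_drugs)
        if plan.setting in ("S3", "S4"):
            assert not (train_targets & test_targets)
        if plan.setting == "S4":
            # pairs sharing exactly one observable coordinate with the test
            # block must be discarded ...
            must_discard = {
                (d, t)
                for d, t in measured
                if ((d in test_drugs) != (t in test_targets))
            }
            assert must_discard <= disc
            # ... and no discarded pair may lie fully inside the test block
            # or fully inside the training block
            for d, t in disc:
                assert not (d in test_drugs and t in test_targets)
                assert not (d in train_drugs and t in train_targets)
            assert train | test | disc == measured
        else:
            assert disc == set()
            assert train | test == measured
        tested.extend(test)
    # coverage: every measured pair tested exactly once across the plan
    assert len(tested) == len(measured)
    assert set(tested) == measured


class TestS1Folds:
    def test_equal_fold_sizes(self):
        table = complete_table(2, 5)
        plan = make_folds_s1(table, 5, seed=1)
        assert [len(s.test_pairs) for s in plan] == [2, 2, 2, 2, 2]

    def test_partition_property(self):
        table = complete_table(4, 6, seed=3)
        check_split_constraints(make_folds_s1(table, 5, seed=2), table)

    def test_seed_determinism(self):
        table = complete_table(5, 5)
        a = make_folds_s1(table, 4, seed=7)
        b = make_folds_s1(table, 4, seed=7)
        assert [s.test_pairs for s in a] == [s.test_pairs for s in b]
        c = make_folds_s1(table, 4, seed=8)
        assert [s.test_pairs for s in a] != [s.test_pairs for s in c]

    def test_too_many_folds_rejected(self):
        with pytest.raises(FoldError):
            make_folds_s1(complete_table(2, 2), 5, seed=0)


class TestS2S3Folds:
    def test_s2_no_shared_drugs(self):
        table = complete_table(4, 3)
        plan = make_folds_s2(table, 2, seed=0)
        assert len(plan) == 2
        check_split_constraints(plan, table)

    def test_s2_with_missing_entries(self):
        rng = np.random.default_rng(11)
        labels = rng.standard_normal((6, 5))
        mask = rng.random((6, 5)) > 0.3
        labels[~mask] = np.nan
        table = InteractionTable(
            [f"d{i}" for i in range(6)], [f"t{j}" for j in range(5)], labels, mask
        )
        check_split_constraints(make_folds_s2(table, 3, seed=5), table)
        check_split_constraints(make_folds_s3(table, 2, seed=5), table)

    def test_k_equals_n_drugs_is_ldo(self):
        table = complete_table(4, 3)
        plan = make_folds_s2(table, 4, seed=0)
        ldo = make_loo_variants(table, "LDO")
        assert {s.test_pairs for s in plan} == {s.test_pairs for s in ldo}

    def test_s3_mirrors_s2_on_transpose(self):
        table = complete_table(5, 4, seed=9)
        transposed = InteractionTable(
            table.target_ids, table.drug_ids, table.labels.T,
            table.measured_mask.T,
        )
        s3 = make_folds_s3(table, 2, seed=4)
        s2 = make_folds_s2(transposed, 2, seed=4)
        flipped = [
            frozenset((t, d) for d, t in s.test_pairs) for s in s2
        ]
        assert [s.test_pairs for s in s3] == flipped


class TestS4Folds:
    def test_three_by_three_gives_nine_splits(self):
        table = complete_table(9, 9)
        plan = make_folds_s4(table, 3, 3, seed=0)
        assert len(plan) == 9
        check_split_constraints(plan, table)

    def test_singleton_folds_on_3x3_grid(self):
        table = complete_table(3, 3)
        plan = make_folds_s4(table, 3, 3, seed=0)
        for split in plan:
            assert len(split.test_pairs) == 1
            assert len(split.train_pairs) == 4
            assert len(split.discarded_pairs) == 4

    def test_trichotomy(self):
        table = complete_table(7, 5, seed=13)
        check_split_constraints(make_folds_s4(table, 3, 2, seed=3), table)

    def test_fold_count_limits(self):
        with pytest.raises(FoldError):
            make_folds_s4(complete_table(3, 3), 4, 2, seed=0)


class TestLooVariants:
    def test_counts_on_3x2_table(self):
        table = complete_table(3, 2)
        assert len(make_loo_variants(table, "LOO")) == 6
        assert len(make_loo_variants(table, "LDO")) == 3
        assert len(make_loo_variants(table, "LTO")) == 2

    def test_ldo_excludes_all_pairs_of_held_drug(self):
        table = complete_table(3, 4)
        for split in make_loo_variants(table, "LDO"):
            held = {d for d, _ in split.test_pairs}
            assert len(held) == 1
            assert all(d not in held for d, _ in split.train_pairs)

    def test_single_pair_loo_is_degenerate(self):
        table = InteractionTable(
            ["d"], ["t"], np.array([[1.0]]), np.ones((1, 1), dtype=bool)
        )
        plan = make_loo_variants(table, "LOO")
        assert len(plan) == 1 and plan.splits[0].is_degenerate

    def test_coverage(self):
        table = complete_table(4, 3, seed=21)
        for variant in ("LOO", "LDO", "LTO"):
            check_split_constraints(make_loo_variants(table, variant), table)


class TestRunCv:
    def test_perfect_signal_ranks_near_perfectly(self):
        """Noiseless low-rank labels with the matching Gram kernels are
        exactly representable; S1 CV ranking is near-perfect.  It is not
        exactly 1.0 because the complete-matrix protocol mean-imputes the
        held-out cells into the training matrix, which slightly biases the
        rank-limited fit."""
        Kd, Kt, table, _ = generate(SyntheticSpec(12, 10, latent_rank=2, seed=3))
        plan = make_folds_s1(table, 5, seed=1)
        res = run_cv(table, Kd, Kt, plan, lambda_reg=1e-8)
        assert res.aggregate >= 0.9

    def test_averaged_aggregate_is_mean(self):
        Kd, Kt, table, _ = generate(
            SyntheticSpec(8, 8, latent_rank=2, noise_sd=1.0, seed=4)
        )
        plan = make_folds_s1(table, 4, seed=2)
        res = run_cv(table, Kd, Kt, plan)
        defined = [v for v in res.per_fold if is_defined(v)]
        assert res.aggregate == pytest.approx(float(np.mean(defined)))

    def test_constant_fold_labels_undefined_averaged_but_pooled_defined(self):
        # binary table arranged so each drug has constant labels: S2 folds
        # with one drug per fold give undefined per-fold CI
        labels = np.array([[1.0, 1.0], [0.0, 0.0], [1.0, 1.0], [0.0, 0.0]])
        table = InteractionTable(
            [f"d{i}" for i in range(4)], ["t0", "t1"], labels,
            np.ones((4, 2), dtype=bool), label_kind="binary",
        )
        Kd = delta_kernel(table.drug_ids)
        Kt = delta_kernel(table.target_ids)
        plan = make_loo_variants(table, "LDO")
        res = run_cv(table, Kd, Kt, plan, metric="ci", strategy="pooled")
        assert res.n_undefined == len(plan)
        assert 0.0 <= res.aggregate <= 1.0

    def test_training_mean_never_uses_test_entries(self):
        """Imputation leak check: with exactly one training entry per fold
        the predictions must derive from that value alone."""
        labels = np.array([[5.0, np.nan], [np.nan, -3.0]])
        mask = ~np.isnan(labels)
        table = InteractionTable(["d0", "d1"], ["t0", "t1"], labels, mask)
        Kd = delta_kernel(table.drug_ids)
        Kt = delta_kernel(table.target_ids)
        plan = make_loo_variants(table, "LOO")
        for split in plan:
            (train_pair,) = split.train_pairs
            from kronpair.model_selection import _fit_split_predict

            y, f = _fit_split_predict(table, Kd, Kt, split, 1.0, "keep")
            # delta kernels + unseen drug/target: prediction must be 0,
            # never contaminated by the held-out label
            assert f[0] == pytest.approx(0.0)


class TestSelectLambda:
    def test_singleton_grid(self):
        Kd, Kt, table, _ = generate(
            SyntheticSpec(8, 6, latent_rank=2, noise_sd=0.5, seed=6)
        )
        plan = make_folds_s1(table, 4, seed=1)
        lam, curve = select_lambda(table, Kd, Kt, plan, [2.0])
        assert lam == 2.0 and len(curve) == 1

    def test_tie_breaks_toward_smaller_lambda(self, monkeypatch):
        Kd, Kt, table, _ = generate(SyntheticSpec(6, 6, latent_rank=2, seed=7))
        plan = make_folds_s1(table, 3, seed=1)
        import kronpair.model_selection as ms

        monkeypatch.setitem(ms.METRICS, "const", lambda y, f: 0.5)
        lam, curve = select_lambda(table, Kd, Kt, plan, [4.0, 1.0], metric="const")
        assert lam == 1.0
        assert len(curve) == 2

    def test_empty_grid_rejected(self):
        Kd, Kt, table, _ = generate(SyntheticSpec(5, 5, latent_rank=2, seed=8))
        plan = make_folds_s1(table, 3, seed=1)
        with pytest.raises(ValueError):
            select_lambda(table, Kd, Kt, plan, [])


class TestNestedCv:
    def test_singleton_grid_equals_run_cv(self):
        Kd, Kt, table, _ = generate(
            SyntheticSpec(10, 8, latent_rank=2, noise_sd=0.5, seed=9)
        )
        outer = make_folds_s1(table, 4, seed=2)
        nested = nested_cv(table, Kd, Kt, outer, (3,), [1.0], seed=0)
        simple = run_cv(table, Kd, Kt, outer, 1.0)
        assert nested.aggregate == pytest.approx(simple.aggregate)
        assert all(h == {"lambda": 1.0} for h in nested.selected_hyperparams)

    def test_records_lambda_per_outer_fold(self):
        Kd, Kt, table, _ = generate(
            SyntheticSpec(10, 8, latent_rank=2, noise_sd=1.0, seed=10)
        )
        outer = make_folds_s2(table, 3, seed=2)
        res = nested_cv(table, Kd, Kt, outer, (3,), [0.1, 10.0], seed=1)
        assert len(res.selected_hyperparams) == len(outer)
        assert all(h["lambda"] in (0.1, 10.0) for h in res.selected_hyperparams)

    def test_null_labels_near_chance(self):
        """On pure-noise labels the nested-CV CI stays at chance level."""
        vals = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            Kd, Kt, table, _ = generate(
                SyntheticSpec(10, 8, latent_rank=2, seed=seed)
            )
            table = InteractionTable(
                table.drug_ids, table.target_ids,
                rng.standard_normal(table.labels.shape),
                np.ones_like(table.measured_mask),
            )
            outer = make_folds_s1(table, 4, seed=seed)
            res = nested_cv(table, Kd, Kt, outer, (3,), [0.1, 1.0, 10.0], seed=seed)
            vals.append(res.aggregate)
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.5) < max(3 * se, 0.05)


class TestGreedyForwardSelection:
    def test_exact_feature_selected_first(self):
        rng = np.random.default_rng(15)
        y = rng.standard_normal(60)
        X = rng.standard_normal((60, 8))
        X[:, 5] = y  # one feature equals the labels exactly
        selected, curve = greedy_forward_selection(
            X, y, lambda_reg=1e-6, n_folds=3, max_features=3, seed=0
        )
        assert selected[0] == 5
        assert len(curve) == 3

    def test_exhaustive_selection_is_permutation(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        selected, curve = greedy_forward_selection(
            X, y, n_folds=3, max_features=4, seed=1
        )
        assert sorted(selected) == [0, 1, 2, 3]
        assert len(curve) == 4

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(17)
        X = rng.standard_normal((40, 6))
        y = rng.standard_normal(40)
        a = greedy_forward_selection(X, y, n_folds=4, max_features=3, seed=5)
        b = greedy_forward_selection(X, y, n_folds=4, max_features=3, seed=5)
        assert a == b

    def test_max_features_bounds(self):
        X = np.ones((10, 2))
        y = np.arange(10.0)
        with pytest.raises(ValueError):
            greedy_forward_selection(X, y, max_features=0)
        with pytest.raises(ValueError):
            greedy_forward_selection(X, y, max_features=3)
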