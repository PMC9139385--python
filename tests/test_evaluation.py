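from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from biplanar3d import evaluation, gan, phantom


class TestKFold:
    @pytest.mark.parametrize("n, k", [(10, 10), (40, 10), (12, 3), (9, 4)])
    def test_partition_coverage_and_disjointness(self, n, k):
        ids = list(range(n))
        splits = evaluation.kfold_splits(ids, k, seed=0)
        assert len(splits) == k
        tested = []
        for s in splits:
            groups = set(s.train_ids) | set(s.val_ids) | set(s.test_ids)
            assert groups == set(ids)
            assert not set(s.train_ids) & set(s.test_ids)
            assert not set(s.val_ids) & set(s.test_ids)
            tested += list(s.test_ids)
        assert sorted(tested) == sorted(ids)    # each id tested exactly once
        sizes = [len(s.test_ids) for s in splits]
        assert max(sizes) - min(sizes) <= 1

    def test_ten_ids_ten_folds_gives_8_1_1(self):
        splits = evaluation.kfold_splits(list(range(10)), 10, seed=1)
        for s in splits:
            assert (len(s.train_ids), len(s.val_ids), len(s.test_ids)) \
                == (8, 1, 1)

    def test_forty_ids_ten_folds_test_four_each(self):
        splits = evaluation.kfold_splits(list(range(40)), 10, seed=2)
        assert all(len(s.test_ids) == 4 for s in splits)

    def test_two_fold_keeps_training_data(self):
        splits = evaluation.kfold_splits(list(range(40)), 2, seed=3)
        for s in splits:
            assert len(s.test_ids) == 20
            assert len(s.val_ids) >= 1
            assert len(s.train_ids) >= 1
            assert set(s.train_ids) | set(s.val_ids) | set(s.test_ids) == \
                set(range(40))

    def test_too_few_ids_rejected(self):
        with pytest.raises(ValueError):
            evaluation.kfold_splits([1, 2], 3, seed=0)
        with pytest.raises(ValueError):
            evaluation.kfold_splits(list(range(5)), 1, seed=0)


def _exact_mwu_p(a, b):
    """Enumerate all rank assignments of the pooled sample."""
    pooled = np.concatenate([a, b])
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    obs = ranks[:len(a)].sum()
    u_obs = obs - len(a) * (len(a) + 1) / 2
    u_obs = min(u_obs, len(a) * len(b) - u_obs)
    count = 0
    total = 0
    for idx in combinations(range(n), len(a)):
        r = ranks[list(idx)].sum()
        u = r - len(a) * (len(a) + 1) / 2
        u = min(u, len(a) * len(b) - u)
        total += 1
        if u <= u_obs:
            count += 1
    return count / total


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        u, p = evaluation.mann_whitney_u((1, 2, 3), (10, 11, 12))
        assert min(u, 9 - u) == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_give_p_one(self):
        _, p = evaluation.mann_whitney_u((1.0, 2.0, 5.0), (1.0, 2.0, 5.0))
        assert p >= 0.999

    def test_symmetry_in_arguments(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=5)
        _, p1 = evaluation.mann_whitney_u(a, b)
        _, p2 = evaluation.mann_whitney_u(b, a)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_exact_p_matches_enumeration(self, rng):
        for na, nb in [(3, 3), (4, 3), (5, 5), (4, 6)]:
            a = rng.normal(size=na)
            b = rng.normal(size=nb)
            _, p = evaluation.mann_whitney_u(a, b)
            assert p == pytest.approx(_exact_mwu_p(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            evaluation.mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = evaluation.kruskal_wallis([(2.0, 2.0), (2.0, 2.0),
                                          (2.0, 2.0)])
        assert h == 0.0
        assert p == 1.0

    def test_matches_hand_computed_rank_formula(self):
        groups = [(1.0, 2.0), (3.0, 4.0), (5.0, 6.0)]
        h, p = evaluation.kruskal_wallis(groups)
        # ranks 1..6; group mean ranks 1.5, 3.5, 5.5; grand mean 3.5
        expected = 12.0 / (6 * 7) * (2 * 4 + 0 + 2 * 4)
        assert h == pytest.approx(expected, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(expected, 2), abs=1e-12)

    def test_shift_invariance(self, rng):
        groups = [rng.normal(size=5) for _ in range(3)]
        h1, _ = evaluation.kruskal_wallis(groups)
        h2, _ = evaluation.kruskal_wallis([g + 100.0 for g in groups])
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            evaluation.kruskal_wallis([(1.0,), ()])


def _fake_results(offset=0.0, rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for condition, delta in (("original", 0.0), ("enhanced", offset)):
        for size in (8, 16):
            for fold in range(5):
                base = 0.5 + delta + 0.01 * rng.normal()
                rows.append({"condition": condition, "size": size,
                             "fold": fold,
                             **{m: base for m in ("dsc", "jsc", "ov",
                                                  "ssim_ap", "ssim_lat")}})
    return pd.DataFrame(rows)


class TestSignificanceTable:
    def test_equal_conditions_not_flagged(self):
        table = evaluation.significance_table(_fake_results(offset=0.0))
        assert not table.sig_condition.any()

    def test_clear_separation_is_flagged(self):
        table = evaluation.significance_table(_fake_results(offset=0.3))
        assert table.sig_condition.all()

    def test_one_row_per_metric_and_condition(self):
        table = evaluation.significance_table(_fake_results())
        assert len(table) == 5 * 2
        assert set(table.metric) == {"dsc", "jsc", "ov", "ssim_ap",
                                     "ssim_lat"}

    def test_insufficient_groups_rejected(self):
        df = _fake_results()
        single = df[(df.condition == "original") & (df["size"] == 8)]
        with pytest.raises(ValueError):
            evaluation.significance_table(single)


@pytest.fixture(scope="module")
def tiny_run(desk_spec):
    phantoms = phantom.generate_dataset(8, desk_spec, seed=5)
    grid = evaluation.ExperimentGrid(signal_conditions=("enhanced",),
                                     dataset_sizes=(8,), k=2, seed=5)
    gcfg = gan.GeneratorConfig(scale=0.25)
    tcfg = gan.TrainConfig(epochs=2, batch_size=4, seed=0)

    def run():
        return evaluation.run_grid(grid, phantoms, gcfg,
                                   gan.DiscriminatorConfig(),
                                   gan.LossWeights(), tcfg)
    return run(), run()


class TestRunGrid:
    def test_smoke_contract(self, tiny_run):
        res, _ = tiny_run
        assert len(res) == 2                      # one row per fold
        for m in ("dsc", "jsc", "ov", "ssim_ap", "ssim_lat",
                  "baseline_dsc"):
            assert res[m].between(0.0, 1.0).all()
            assert np.isfinite(res[m]).all()

    def test_bit_reproducible(self, tiny_run):
        res1, res2 = tiny_run
        pd.testing.assert_frame_equal(res1, res2)

    def test_size_exceeding_phantoms_rejected(self, desk_spec):
        phantoms = phantom.generate_dataset(2, desk_spec, seed=1)
        grid = evaluation.ExperimentGrid(dataset_sizes=(10,), k=2, seed=0)
        with pytest.raises(ValueError):
            grid.validate(len(phantoms))
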