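import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from perspect.algorithms import Algorithm, BaselineAlgorithm, OracleAlgorithm
from perspect.evaluation_protocol import (
    ProtocolConfig,
    grid_search,
    kendall_tau_b,
    ndcg,
    paired_bonferroni,
    rmse,
    run_protocol,
    split_user_ratings,
    split_users,
)
from perspect.synthetic_data import GeneratorConfig, generate_ratings


class TestSplitUsers:
    def test_even_split(self):
        folds = split_users([f"u{i}" for i in range(100)], 5, seed=0)
        assert [len(f) for f in folds] == [20] * 5

    def test_pilot_sized_split(self):
        folds = split_users([f"u{i}" for i in range(846)], 5, seed=1)
        assert sorted(len(f) for f in folds) == [169, 169, 169, 169, 170]

    def test_partition_laws(self):
        users = [f"u{i}" for i in range(37)]
        folds = split_users(users, 5, seed=2)
        flat = [u for f in folds for u in f]
        assert sorted(flat) == sorted(users)
        assert len(set(flat)) == len(flat)

    def test_too_few_users(self):
        with pytest.raises(ValueError):
            split_users(["a", "b"], 5)


class TestSplitUserRatings:
    @pytest.fixture
    def cfg(self):
        return ProtocolConfig()

    def test_default_geometry(self, cfg):
        split = split_user_ratings(list(range(20)), cfg, seed=0)
        assert len(split.folds) == 5
        for fold in split.folds:
            assert len(fold["test"]) == 4
            for size in (5, 10, 16):
                assert len(fold["observed"][size]) == size
                assert not set(fold["observed"][size]) & set(fold["test"])

    def test_size_16_is_exact_complement(self, cfg):
        split = split_user_ratings(list(range(20)), cfg, seed=3)
        for fold in split.folds:
            assert sorted(fold["observed"][16] + fold["test"]) == list(range(20))

    def test_test_folds_partition_the_ratings(self, cfg):
        split = split_user_ratings(list(range(20)), cfg, seed=4)
        test_all = sorted(i for f in split.folds for i in f["test"])
        assert test_all == list(range(20))

    def test_insufficient_ratings_names_user(self, cfg):
        with pytest.raises(ValueError, match="u77"):
            split_user_ratings(list(range(19)), cfg, seed=0, user="u77")


class TestRmse:
    def test_identical_vectors(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_arithmetic(self):
        assert rmse([4, 3], [5, 3]) == pytest.approx(0.7071, abs=1e-4)

    def test_matches_loop_oracle(self, rng):
        p = rng.uniform(1, 5, 50)
        a = rng.uniform(1, 5, 50)
        loop = math.sqrt(sum((x - y) ** 2 for x, y in zip(p, a)) / 50)
        assert rmse(p, a) == pytest.approx(loop, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1, 2, 3])


def tau_oracle(x, y):
    """Direct pair enumeration of the tau-b formula."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0:
            tx += 1
        if dy == 0:
            ty += 1
        if dx != 0 and dy != 0:
            if dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) // 2
    den = math.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / den if den else float("nan")


class TestKendallTauB:
    def test_perfect_agreement(self):
        assert kendall_tau_b([1, 2, 3, 4], [10, 20, 30, 40]) == 1.0

    def test_single_swap(self):
        assert kendall_tau_b([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(2 / 3)

    def test_reversal_is_minus_one(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        assert kendall_tau_b(x, [-v for v in x]) == -1.0

    def test_all_tied_undefined(self):
        assert math.isnan(kendall_tau_b([2, 2, 2], [1, 2, 3]))

    def test_all_permutations_of_five_match_enumeration_and_scipy(self):
        base = [1, 2, 3, 4, 5]
        for perm in itertools.permutations(base):
            got = kendall_tau_b(base, perm)
            assert got == pytest.approx(tau_oracle(base, list(perm)))
            assert got == pytest.approx(stats.kendalltau(base, perm).statistic)

    def test_tied_vectors_match_scipy(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 6))
            x = rng.integers(1, 4, n).astype(float)
            y = rng.integers(1, 4, n).astype(float)
            got = kendall_tau_b(x, y)
            ref = stats.kendalltau(x, y).statistic
            if math.isnan(got) or math.isnan(ref):
                assert math.isnan(got) and math.isnan(ref)
            else:
                assert got == pytest.approx(ref)


def ndcg_oracle(pred, rel, depth=None):
    """Worst-case-over-ties DCG divided by best-over-all-permutations DCG."""
    n = len(rel)
    depth = depth or n

    def dcg(order):
        return sum((2 ** rel[i] - 1) / math.log2(k + 2) for k, i in enumerate(order[:depth]))

    idcg = max(dcg(p) for p in itertools.permutations(range(n)))
    if idcg == 0:
        return float("nan")
    # orderings consistent with sorting by predicted score descending
    consistent = [
        p
        for p in itertools.permutations(range(n))
        if all(pred[p[k]] >= pred[p[k + 1]] for k in range(n - 1))
    ]
    return min(dcg(p) for p in consistent) / idcg


class TestNdcg:
    def test_ideal_order_is_one(self):
        assert ndcg([3, 2, 1], [5, 4, 1]) == pytest.approx(1.0)

    def test_hand_example_worst_order(self):
        # relevances (1,2,3) presented in ascending-gain order
        assert ndcg([3, 2, 1], [1, 2, 3]) == pytest.approx(0.6806, abs=1e-4)
        assert ndcg([3, 2, 1], [1, 2, 3]) == pytest.approx(6.392789 / 9.392789, abs=1e-6)

    def test_all_zero_relevance_undefined(self):
        assert math.isnan(ndcg([1, 2, 3], [0, 0, 0]))

    def test_monotone_transform_invariance(self, rng):
        p = rng.uniform(0, 1, 6)
        r = rng.integers(1, 6, 6).astype(float)
        base = ndcg(p, r)
        assert ndcg(2 * p + 1, r) == pytest.approx(base)
        assert ndcg(np.exp(p), r) == pytest.approx(base)

    def test_matches_brute_force_on_short_vectors(self, rng):
        for _ in range(150):
            n = int(rng.integers(1, 6))
            pred = rng.integers(0, 3, n).astype(float)  # coarse scores force ties
            rel = rng.integers(0, 4, n).astype(float)
            got = ndcg(pred, rel) if rel.sum() else float("nan")
            ref = ndcg_oracle(pred.tolist(), rel.tolist())
            if math.isnan(ref):
                assert math.isnan(ndcg(pred, rel))
            else:
                assert got == pytest.approx(ref), (pred, rel)

    def test_depth_truncation(self):
        full = ndcg([4, 3, 2, 1], [5, 1, 1, 1], depth=1)
        assert full == pytest.approx(1.0)


class _FakeAlgorithm(Algorithm):
    """Validation RMSE is a known function of its single hyperparameter."""

    name = "fake"

    def __init__(self, width):
        self.width = width

    def fit(self, train, seed=0):
        pass

    def predict_for_user(self, observed, targets):
        # constant prediction whose error grows with |width - 7|
        return np.full(len(targets), 3.0 + abs(self.width - 7) * 0.1)


def _validation_cases():
    return [({}, {"m1": 3.0, "m2": 3.0})]


class TestGridSearch:
    def make_train(self):
        data, _ = generate_ratings(GeneratorConfig(n_users=5, n_messages=5, ratings_per_user=3, seed=0))
        return data

    def test_single_point_grid(self):
        res = grid_search(_FakeAlgorithm, {"width": [4]}, self.make_train(), _validation_cases())
        assert res.params == {"width": 4}
        assert res.extensions == {"width": 0}

    def test_interior_optimum_no_extension(self):
        res = grid_search(_FakeAlgorithm, {"width": [5, 7, 9]}, self.make_train(), _validation_cases())
        assert res.params == {"width": 7}
        assert not res.boundary_warning
        assert res.extensions["width"] == 0

    def test_boundary_extension_finds_exterior_optimum(self):
        res = grid_search(_FakeAlgorithm, {"width": [1, 3, 5]}, self.make_train(), _validation_cases())
        assert res.params == {"width": 7}
        assert res.extensions["width"] >= 1
        assert not res.boundary_warning
        # full-enumeration oracle over the extended range agrees
        widths = sorted(set(res.trace["width"]))
        best = min(widths, key=lambda w: abs(w - 7))
        assert res.params["width"] == best

    def test_extension_cap_flags_warning(self):
        res = grid_search(
            _FakeAlgorithm, {"width": [30, 31]}, self.make_train(), _validation_cases(),
            max_extensions=2,
        )
        assert res.boundary_warning


@pytest.fixture(scope="module")
def dataset():
    data, _ = generate_ratings(
        GeneratorConfig(n_users=20, n_messages=25, ratings_per_user=20, seed=5)
    )
    return data


class TestRunProtocol:

    def test_perfect_oracle_has_zero_rmse_everywhere(self, dataset):
        lookup = {
            (row.user, row.message): float(row.rating)
            for row in dataset.triplets.itertuples()
        }
        cfg = ProtocolConfig(n_user_folds=2, n_train_val_repeats=1, seed=0)
        report = run_protocol({"oracle": OracleAlgorithm(lookup)}, dataset, cfg)
        assert (report.cells["rmse"] == 0.0).all()

    def test_cell_count_at_defaults(self, dataset):
        algos = {"global_mean": BaselineAlgorithm("GLOBAL_MEAN"), "user_mean": BaselineAlgorithm("USER_MEAN")}
        report = run_protocol(algos, dataset, ProtocolConfig(seed=1))
        assert len(report.cells) == 2 * 5 * 3 * 3
        key = report.cells[["algorithm", "user_fold", "repeat", "observed_size"]]
        assert not key.duplicated().any()

    def test_insufficient_ratings_rejected(self):
        data, _ = generate_ratings(GeneratorConfig(n_users=10, n_messages=25, ratings_per_user=10, seed=6))
        with pytest.raises(ValueError, match="fewer"):
            run_protocol({"g": BaselineAlgorithm("GLOBAL_MEAN")}, data, ProtocolConfig())


class TestPairedBonferroni:
    def _report(self, a_vals, b_vals):
        rows = []
        for i, (a, b) in enumerate(zip(a_vals, b_vals)):
            rows.append({"algorithm": "ref", "user_fold": i, "repeat": 0, "observed_size": 5, "rmse": a})
            rows.append({"algorithm": "other", "user_fold": i, "repeat": 0, "observed_size": 5, "rmse": b})
        return pd.DataFrame(rows)

    def test_identical_vectors(self):
        out = paired_bonferroni(self._report([1, 2, 3], [1, 2, 3]), "rmse", "ref")
        row = out.iloc[0]
        assert row.t == 0.0 and row.p_raw == 1.0 and not row.degenerate

    def test_constant_nonzero_difference_degenerate(self):
        out = paired_bonferroni(self._report([1.1, 1.2, 1.3, 1.4], [1.0, 1.1, 1.2, 1.3]), "rmse", "ref")
        row = out.iloc[0]
        assert row.degenerate and math.isnan(row.t)

    def test_matches_scipy_on_hand_example(self, rng):
        a = rng.uniform(0.5, 1.0, 5)
        b = a + rng.normal(0.1, 0.05, 5)
        out = paired_bonferroni(self._report(a, b), "rmse", "ref")
        ref = stats.ttest_rel(a, b)
        assert out.iloc[0].t == pytest.approx(ref.statistic)
        assert out.iloc[0].p_raw == pytest.approx(ref.pvalue)

    def test_bonferroni_multiplies_by_family_size(self):
        rows = []
        rng = np.random.default_rng(0)
        for i in range(6):
            for alg in ("ref", "b", "c", "d"):
                rows.append(
                    {"algorithm": alg, "user_fold": i, "repeat": 0, "observed_size": 5,
                     "rmse": float(rng.uniform(0.5, 1.5))}
                )
        out = paired_bonferroni(pd.DataFrame(rows), "rmse", "ref")
        assert len(out) == 3
        for _, row in out.iterrows():
            assert row.p_adjusted == pytest.approx(min(1.0, row.p_raw * 3))
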