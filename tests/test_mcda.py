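"""Entropy-weighted TOPSIS: stage-by-stage hand values, invariants, and
equivalence with an independent brute-force loop implementation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from croprank import (
    IndicatorMatrix,
    closeness,
    entropy_weights,
    evaluate,
    normalize_vector,
    orient_matrix,
    topsis_rank,
)


def matrix(values, orientation=None, names=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    names = names or [f"i{j}" for j in range(m)]
    orientation = orientation or {name: "benefit" for name in names}
    return IndicatorMatrix(
        alternative_ids=tuple(f"a{i}" for i in range(n)),
        indicator_names=tuple(names),
        values=values,
        orientation=orientation,
    )


# ---------------------------------------------------------------------------
# independent oracle: explicit loops over the formulas, no numpy vectorization


def brute_force_evaluate(values, orientations, cost_transform="reciprocal"):
    """Naive loop implementation of the whole procedure, kept deliberately
    separate from the library's vectorized code path."""
    rows = [list(map(float, r)) for r in values]
    n, m = len(rows), len(rows[0])

    # orient
    for j in range(m):
        if orientations[j] == "cost":
            col = [rows[i][j] for i in range(n)]
            for i in range(n):
                if cost_transform == "max-minus":
                    rows[i][j] = max(col) - rows[i][j]
                else:
                    rows[i][j] = 1.0 / rows[i][j]

    # entropy weights on the oriented raw matrix
    divergence = []
    for j in range(m):
        col = [rows[i][j] for i in range(n)]
        cmin = min(col)
        if cmin < 0:
            col = [x - cmin for x in col]
        total = sum(col)
        if total == 0 or max(col) == min(col):
            divergence.append(0.0)
            continue
        e = 0.0
        for x in col:
            p = x / total
            if p > 0:
                e -= p * math.log(p)
        e /= math.log(n)
        divergence.append(1.0 - e)
    wsum = sum(divergence)
    weights = [d / wsum for d in divergence]

    # vector normalization
    for j in range(m):
        norm = math.sqrt(sum(rows[i][j] ** 2 for i in range(n)))
        for i in range(n):
            rows[i][j] /= norm

    # weighting, ideals, distances, closeness
    v = [[weights[j] * rows[i][j] for j in range(m)] for i in range(n)]
    z_plus = [max(v[i][j] for i in range(n)) for j in range(m)]
    z_minus = [min(v[i][j] for i in range(n)) for j in range(m)]
    close = []
    for i in range(n):
        dp = math.sqrt(sum((z_plus[j] - v[i][j]) ** 2 for j in range(m)))
        dm = math.sqrt(sum((v[i][j] - z_minus[j]) ** 2 for j in range(m)))
        close.append(dm / (dp + dm))
    return weights, close


# ---------------------------------------------------------------------------


class TestOrient:
    def test_benefit_only_is_identity(self):
        m = matrix([[1.0, 2.0], [3.0, 4.0]])
        assert np.array_equal(orient_matrix(m).values, m.values)

    def test_cost_column_max_minus(self):
        m = matrix([[10.0], [30.0]], orientation={"i0": "cost"})
        assert orient_matrix(m, "max-minus").values[:, 0].tolist() == [20.0, 0.0]

    def test_cost_column_reciprocal(self):
        m = matrix([[2.0], [4.0]], orientation={"i0": "cost"})
        assert orient_matrix(m, "reciprocal").values[:, 0].tolist() == [0.5, 0.25]

    def test_double_application_is_not_identity(self):
        """Regression guard: reapplying max-minus to the already oriented
        (now benefit-declared) matrix flips the ordering back."""
        m = matrix([[10.0], [30.0]], orientation={"i0": "cost"})
        once = orient_matrix(m, "max-minus")
        twice = orient_matrix(
            IndicatorMatrix(once.alternative_ids, once.indicator_names,
                            once.values, {"i0": "cost"}),
            "max-minus")
        assert not np.array_equal(once.values, twice.values)
        assert np.argmax(twice.values[:, 0]) != np.argmax(once.values[:, 0])

    def test_unknown_orientation_rejected(self):
        with pytest.raises(ValueError, match="orientation"):
            matrix([[1.0], [2.0]], orientation={"i0": "sideways"})


class TestEntropyWeights:
    def test_constant_column_gets_zero_weight(self):
        m = matrix([[1.0, 1.0], [1.0, 0.0]])
        w = entropy_weights(m)
        assert w.entropy[0] == pytest.approx(1.0)
        assert w.weights.tolist() == [0.0, 1.0]

    def test_hand_computed_three_row_column(self):
        """Column [1,2,3]: p=(1/6,2/6,3/6), e=0.9206, d=0.0794, w=1."""
        m = matrix([[1.0], [2.0], [3.0]])
        w = entropy_weights(m)
        assert w.entropy[0] == pytest.approx(0.9206, abs=5e-5)
        assert w.divergence[0] == pytest.approx(0.0794, abs=5e-5)
        assert w.weights[0] == 1.0

    def test_all_constant_matrix_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            entropy_weights(matrix([[1.0, 2.0], [1.0, 2.0]]))

    def test_negative_column_shift_recorded(self):
        m = matrix([[-1.0, 1.0], [3.0, 2.0]])
        w = entropy_weights(m)
        assert w.shifts == {"i0": pytest.approx(1.0)}
        assert w.weights.sum() == pytest.approx(1.0)

    @given(st.integers(2, 6), st.integers(1, 4), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_weights_sum_to_one_and_entropy_in_unit_interval(self, n, m, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0.1, 10.0, size=(n, m))
        X[:, 0] = np.linspace(1, 2, n)  # ensure at least one informative column
        w = entropy_weights(matrix(X))
        assert w.weights.sum() == pytest.approx(1.0)
        assert np.all((w.entropy >= 0) & (w.entropy <= 1 + 1e-12))
        assert np.all(w.weights >= 0)


class TestNormalize:
    def test_three_four_five(self):
        m = matrix([[3.0], [4.0]])
        assert normalize_vector(m).values[:, 0].tolist() == [0.6, 0.8]

    def test_norm_three_column(self):
        m = matrix([[1.0], [2.0], [2.0]])
        assert normalize_vector(m).values[:, 0] == pytest.approx([1/3, 2/3, 2/3])

    def test_unit_column_norms(self):
        rng = np.random.default_rng(0)
        m = matrix(rng.uniform(0.1, 5, size=(5, 3)))
        norms = np.linalg.norm(normalize_vector(m).values, axis=0)
        assert norms == pytest.approx([1.0, 1.0, 1.0])

    def test_all_zero_column_names_indicator(self):
        with pytest.raises(ValueError, match="i1"):
            normalize_vector(matrix([[1.0, 0.0], [2.0, 0.0]]))


class TestCloseness:
    @pytest.mark.parametrize(
        "dp, dm, expected",
        [
            (0.129, 0.072, 0.358),  # worst-ranked control, year 1
            (0.061, 0.123, 0.668),  # best strategy, year 2
            (0.056, 0.132, 0.702),  # best strategy, year 1
        ],
    )
    def test_published_distance_pairs(self, dp, dm, expected):
        assert round(closeness(dp, dm), 3) == expected

    def test_boundaries(self):
        assert closeness(0.0, 0.5) == 1.0
        assert closeness(0.5, 0.0) == 0.0
        with pytest.raises(ValueError):
            closeness(0.0, 0.0)


class TestTopsis:
    def test_ideal_and_worst_alternatives(self):
        m = normalize_vector(matrix([[5.0, 5.0], [1.0, 1.0], [3.0, 2.0]]))
        res = topsis_rank(m, entropy_weights(m))
        assert res.d_plus[0] == pytest.approx(0.0)
        assert res.closeness[0] == pytest.approx(1.0)
        assert res.closeness[1] == pytest.approx(0.0)
        assert res.rank.tolist()[0] == 1

    def test_two_alternatives_one_indicator(self):
        m = normalize_vector(matrix([[4.0], [2.0]]))
        res = topsis_rank(m, entropy_weights(m))
        assert res.closeness == pytest.approx([1.0, 0.0])

    def test_identical_alternatives_error(self):
        from croprank import EntropyWeights

        m = normalize_vector(matrix([[1.0, 2.0], [1.0, 2.0]]))
        w = EntropyWeights(m.indicator_names, np.array([0.5, 0.5]),
                           np.array([0.5, 0.5]), np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="identical"):
            topsis_rank(m, w)


class TestEvaluate:
    def test_dominant_alternative_ranks_first(self):
        m = matrix([[10.0, 1.0], [8.0, 2.0], [6.0, 3.0]],
                   orientation={"i0": "benefit", "i1": "cost"})
        res, _ = evaluate(m)
        assert res.rank[0] == 1

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(1, 9, size=(5, 3))
        res, _ = evaluate(matrix(X))
        perm = [3, 0, 4, 1, 2]
        res_p, _ = evaluate(matrix(X[perm]))
        assert res_p.closeness == pytest.approx(res.closeness[perm])
        assert res_p.rank.tolist() == [res.rank[i] for i in perm]

    def test_scale_invariance_of_benefit_columns(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(1, 9, size=(6, 4))
        res, w = evaluate(matrix(X))
        Y = X.copy()
        Y[:, 2] *= 1234.5
        res_s, w_s = evaluate(matrix(Y))
        assert w_s.weights == pytest.approx(w.weights)
        assert res_s.closeness == pytest.approx(res.closeness)
        assert res_s.rank.tolist() == res.rank.tolist()

    def test_dominance_consistency(self):
        """If A >= B in every oriented indicator (one strictly), c_A >= c_B."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            n, m = 5, 4
            X = rng.uniform(1, 9, size=(n, m))
            X[0] = X[1] + rng.uniform(0.0, 1.0, size=m)  # row 0 dominates row 1
            X[0, 0] += 0.5
            res, _ = evaluate(matrix(X))
            assert res.closeness[0] >= res.closeness[1] - 1e-12

    def test_worked_3x2_example_matches_oracle(self):
        values = [[4.0, 2.0], [2.0, 6.0], [3.0, 5.0]]
        orientations = ["benefit", "cost"]
        w_ref, c_ref = brute_force_evaluate(values, orientations)
        res, w = evaluate(matrix(values, orientation={"i0": "benefit",
                                                      "i1": "cost"}))
        assert w.weights == pytest.approx(w_ref, abs=1e-12)
        assert res.closeness == pytest.approx(c_ref, abs=1e-12)

    @pytest.mark.parametrize("cost_transform", ["reciprocal", "max-minus"])
    @pytest.mark.parametrize("trial", range(60))
    def test_oracle_equivalence_random_matrices(self, trial, cost_transform):
        """Vectorized pipeline vs naive loop oracle on random small matrices."""
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(2, 7))
        m = int(rng.integers(1, 6))
        X = rng.uniform(0.5, 10.0, size=(n, m))
        X[:, 0] = np.linspace(1, 2, n)  # at least one informative column
        orientations = ["cost" if rng.random() < 0.4 else "benefit"
                        for _ in range(m)]
        mat = matrix(X, orientation=dict(zip([f"i{j}" for j in range(m)],
                                             orientations)))
        try:
            res, w = evaluate(mat, cost_transform=cost_transform)
        except ValueError:
            # degenerate (e.g. all-zero column after max-minus); oracle would
            # also divide by zero — skip this draw
            return
        w_ref, c_ref = brute_force_evaluate(X, orientations, cost_transform)
        assert float(np.abs(w.weights - np.array(w_ref)).max()) < 1e-12
        assert float(np.abs(res.closeness - np.array(c_ref)).max()) < 1e-12
        assert np.all((res.closeness >= 0) & (res.closeness <= 1))
        assert sorted(res.rank.tolist()) == sorted(
            np.arange(1, n + 1).tolist()) or len(set(res.rank)) < n
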