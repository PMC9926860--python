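"""Spearman block correlations and the RV2 matrix coefficient."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats

from glycotraits.correlation import (
    align_by_rows,
    correlate_blocks,
    cross_class_trait_correlations,
    rv2,
    rv2_permutation_test,
    spearman,
    stars,
)


def test_perfect_monotone_pairs():
    assert spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
    assert spearman([1, 2, 3, 4], [4, 3, 2, 1])[0] == pytest.approx(-1.0)


def test_ties_match_midrank_pearson_oracle():
    rng = np.random.default_rng(5)
    for _ in range(20):
        x = rng.integers(0, 4, size=8).astype(float)  # heavy ties
        y = rng.integers(0, 4, size=8).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        rho, _ = spearman(x, y)
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)


def test_monotone_transform_invariance():
    rng = np.random.default_rng(6)
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    base, _ = spearman(x, y)
    warped, _ = spearman(np.exp(x), y**3)  # both transforms strictly monotone
    assert warped == pytest.approx(base, abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    xs=st.lists(st.integers(0, 5), min_size=6, max_size=12),
    ys_seed=st.integers(0, 2**31 - 1),
)
def test_spearman_equals_rank_pearson_for_any_tied_data(xs, ys_seed):
    """Midrank Spearman == Pearson on rankdata, whatever the tie structure."""
    rng = np.random.default_rng(ys_seed)
    ys = rng.integers(0, 5, size=len(xs)).astype(float)
    xs = np.asarray(xs, dtype=float)
    assume(np.ptp(xs) > 0 and np.ptp(ys) > 0)
    rho, _ = spearman(xs, ys)
    oracle = np.corrcoef(stats.rankdata(xs), stats.rankdata(ys))[0, 1]
    assert rho == pytest.approx(oracle, abs=1e-12)


def test_constant_vector_yields_nan_with_warning():
    with pytest.warns(UserWarning, match="constant"):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
    assert np.isnan(rho) and np.isnan(p)


def test_too_few_samples_refused():
    with pytest.raises(ValueError, match="at least 4"):
        spearman([1, 2, 3], [3, 2, 1])


def test_permutation_p_close_to_t_approximation():
    rng = np.random.default_rng(7)
    x = rng.normal(size=15)
    y = 0.8 * x + rng.normal(size=15) * 0.5
    _, p_t = spearman(x, y)
    _, p_perm = spearman(x, y, method="permutation", n_perm=2000, seed=1)
    assert p_perm == pytest.approx(p_t, abs=0.02)


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------


def test_duplicated_feature_gives_rho_one():
    rng = np.random.default_rng(8)
    samples = [f"S{i}" for i in range(10)]
    traits = pd.DataFrame({"t": rng.normal(size=10)}, index=samples)
    genes = pd.DataFrame({"pseudo": traits["t"]}, index=samples)
    res = correlate_blocks(traits, genes)
    assert res.rho.at["t", "pseudo"] == pytest.approx(1.0)
    assert res.star_table.at["t", "pseudo"] == "***"


def test_refuses_fewer_than_four_shared_samples():
    a = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=["A", "B", "C"])
    b = pd.DataFrame({"y": [1.0, 2.0, 3.0]}, index=["A", "B", "Z"])
    with pytest.raises(ValueError, match="shared samples"):
        correlate_blocks(a, b)


def test_null_star_rate_close_to_nominal():
    """Independent columns, n=19: ~5% of pairs starred at p <= 0.05."""
    rng = np.random.default_rng(9)
    samples = [f"S{i}" for i in range(19)]
    rows = pd.DataFrame(rng.normal(size=(19, 10)), index=samples)
    cols = pd.DataFrame(rng.normal(size=(19, 10)), index=samples)
    res = correlate_blocks(rows, cols)
    frac = (res.p.to_numpy() <= 0.05).mean()
    assert 0.005 <= frac <= 0.12  # 100 pairs, loose band


def test_planted_coupling_detected(cohort):
    from glycotraits.trait_engine import compute_trait_matrix, default_rules, integrate_traits

    rules = default_rules()
    integ = integrate_traits(
        [compute_trait_matrix(p, rules) for p in cohort.panels.values()]
    )
    gst = cohort.expression.values.loc[["FUT7"]].T
    res = correlate_blocks(integ, gst)
    assert res.rho.at["(s)Lex/a", "FUT7"] > 0.5
    assert res.p.at["(s)Lex/a", "FUT7"] < 0.01


def test_benjamini_hochberg_column_is_monotone():
    rng = np.random.default_rng(10)
    samples = [f"S{i}" for i in range(12)]
    rows = pd.DataFrame(rng.normal(size=(12, 4)), index=samples)
    cols = pd.DataFrame(rng.normal(size=(12, 5)), index=samples)
    res = correlate_blocks(rows, cols)
    assert (res.p_adjusted.to_numpy() >= res.p.to_numpy() - 1e-12).all()


def test_cross_class_trait_correlations_shape(cohort):
    from glycotraits.trait_engine import compute_trait_matrix, default_rules

    rules = default_rules()
    mats = {c: compute_trait_matrix(p, rules) for c, p in cohort.panels.items()}
    out = cross_class_trait_correlations(
        mats,
        [("H antigen", "O", "GSL"), ("(s)Lex/a", "O", "GSL"), ("a2,3-sialylation", "N", "GSL")],
    )
    assert list(out.columns) == ["trait", "class_a", "class_b", "rho", "p", "n"]
    assert (out["rho"].abs() <= 1).all()
    assert (out["n"] == 19).all()


# ---------------------------------------------------------------------------
# RV2
# ---------------------------------------------------------------------------


@pytest.fixture()
def random_matrix():
    rng = np.random.default_rng(12)
    return rng.normal(size=(6, 4))


def test_rv2_self_is_one(random_matrix):
    assert rv2(random_matrix, random_matrix).coefficient == pytest.approx(1.0, abs=1e-12)


def test_rv2_orthogonal_rotation_invariance(random_matrix):
    rng = np.random.default_rng(13)
    Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
    assert rv2(random_matrix, random_matrix @ Q).coefficient == pytest.approx(1.0, abs=1e-10)


def test_rv2_bounds_and_symmetry():
    rng = np.random.default_rng(14)
    for _ in range(20):
        A = rng.normal(size=(7, 3))
        B = rng.normal(size=(7, 5))
        c = rv2(A, B).coefficient
        assert -1.0 - 1e-12 <= c <= 1.0 + 1e-12
        assert rv2(B, A).coefficient == pytest.approx(c, abs=1e-12)


def test_rv2_double_loop_oracle():
    """Small integer matrices vs an explicit sum over off-diagonal entries."""
    A = np.array([[1.0, 2.0], [3.0, 1.0], [0.0, 4.0], [2.0, 2.0]])
    B = np.array([[2.0, 0.0, 1.0], [1.0, 1.0, 3.0], [4.0, 2.0, 0.0], [0.0, 3.0, 2.0]])

    def oracle(A, B):
        Ac = A - A.mean(axis=0)
        Bc = B - B.mean(axis=0)
        Sa, Sb = Ac @ Ac.T, Bc @ Bc.T
        num = den_a = den_b = 0.0
        n = A.shape[0]
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                num += Sa[i, j] * Sb[i, j]
                den_a += Sa[i, j] ** 2
                den_b += Sb[i, j] ** 2
        return num / np.sqrt(den_a * den_b)

    assert rv2(A, B).coefficient == pytest.approx(oracle(A, B), abs=1e-12)


def test_rv2_row_permutation_and_column_scaling_invariance(random_matrix):
    rng = np.random.default_rng(15)
    B = rng.normal(size=(6, 5))
    base = rv2(random_matrix, B).coefficient
    perm = rng.permutation(6)
    assert rv2(random_matrix[perm], B[perm]).coefficient == pytest.approx(base, abs=1e-12)
    assert rv2(random_matrix * 3.7, B).coefficient == pytest.approx(base, abs=1e-12)


def test_rv2_refuses_degenerate_inputs():
    with pytest.raises(ValueError, match="at least 3 rows"):
        rv2(np.ones((2, 3)), np.ones((2, 3)))
    with pytest.raises(ValueError, match="row mismatch"):
        rv2(np.ones((4, 2)), np.ones((5, 2)))


def test_rv2_permutation_p_minimal_for_self():
    rng = np.random.default_rng(16)
    A = rng.normal(size=(8, 4))
    res = rv2_permutation_test(A, A, n_perm=99, seed=0)
    assert res.coefficient == pytest.approx(1.0, abs=1e-12)
    assert res.p_value <= 5 / 100  # observed is maximal up to permutation ties


def test_rv2_permutation_deterministic_given_seed():
    rng = np.random.default_rng(17)
    A = rng.normal(size=(9, 3))
    B = rng.normal(size=(9, 4))
    r1 = rv2_permutation_test(A, B, n_perm=199, seed=5)
    r2 = rv2_permutation_test(A, B, n_perm=199, seed=5)
    assert r1.p_value == r2.p_value


def test_rv2_permutation_p_roughly_uniform_under_null():
    rng = np.random.default_rng(18)
    ps = []
    for _ in range(30):
        A = rng.normal(size=(10, 3))
        B = rng.normal(size=(10, 3))
        ps.append(rv2_permutation_test(A, B, n_perm=99, seed=1).p_value)
    ps = np.asarray(ps)
    assert 0.2 <= ps.mean() <= 0.8  # coarse uniformity check


def test_align_by_rows_sorts_shared_genes():
    A = pd.DataFrame(np.arange(6).reshape(3, 2), index=["FUT7", "ST3GAL4", "SPI1"])
    B = pd.DataFrame(np.arange(4).reshape(2, 2), index=["SPI1", "FUT7"])
    a, b = align_by_rows(A, B)
    assert list(a.index) == list(b.index) == ["FUT7", "SPI1"]


def test_stars_thresholds():
    assert stars(0.04) == "*"
    assert stars(0.009) == "**"
    assert stars(0.0009) == "***"
    assert stars(0.2) == ""
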