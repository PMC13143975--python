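"""Conditional-independence backends: correctness, calibration hooks,
test-wise deletion, and the insufficiency path."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from helpers import random_tiered_model
from pcdsp import (
    Dataset,
    FisherZTester,
    G2Tester,
    OracleCITester,
    ValidationError,
    Variable,
    VariableTable,
    d_separated,
    make_tester,
)


def _dataset(columns: dict, vtypes=None, epoques=None):
    names = list(columns)
    vtypes = vtypes or {n: "cardinal" for n in names}
    epoques = epoques or {n: 1 for n in names}
    table = VariableTable([(n, vtypes[n], epoques[n]) for n in names])
    return Dataset(np.column_stack([columns[n] for n in names]), table)


# ---------------------------------------------------------------------------
# Fisher-z


def test_duplicate_column_is_overwhelmingly_dependent():
    rng = np.random.default_rng(1)
    x = rng.normal(size=200)
    d = _dataset({"x": x, "y": x.copy()})
    res = FisherZTester(d).test("x", "y")
    assert res.p_value < 1e-15
    assert not res.independent


def test_symmetry_in_arguments():
    rng = np.random.default_rng(2)
    d = _dataset({n: rng.normal(size=150) for n in "wxyz"})
    t = FisherZTester(d)
    a = t.test("x", "y", ("w", "z"))
    b = t.test("y", "x", ("z", "w"))
    assert a is b  # canonicalised and cached
    assert a.p_value == b.p_value


def test_testwise_deletion_ignores_unrelated_columns():
    rng = np.random.default_rng(3)
    cols = {n: rng.normal(size=300) for n in ["x", "y", "s", "junk"]}
    clean = _dataset(cols)
    res_clean = FisherZTester(clean).test("x", "y", ("s",))

    noisy_vals = {k: v.copy() for k, v in cols.items()}
    noisy_vals["junk"][::3] = np.nan
    noisy = _dataset(noisy_vals)
    res_noisy = FisherZTester(noisy).test("x", "y", ("s",))
    assert res_clean.statistic == res_noisy.statistic
    assert res_clean.n_effective == res_noisy.n_effective == 300


def test_monotone_transform_invariance():
    rng = np.random.default_rng(4)
    s = rng.normal(size=250)
    x = 0.7 * s + rng.normal(size=250)
    y = 0.7 * s + rng.normal(size=250)
    base = _dataset({"x": x, "y": y, "s": s})
    warped = _dataset({"x": np.exp(x), "y": y**3, "s": s})
    r1 = FisherZTester(base).test("x", "y", ("s",))
    r2 = FisherZTester(warped).test("x", "y", ("s",))
    assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)


def test_insufficient_rows_reported_independent_and_logged():
    rng = np.random.default_rng(5)
    cols = {n: rng.normal(size=40) for n in ["x", "y", "a", "b", "c"]}
    # leave only 5 complete rows; |S|=3 needs at least 7
    for n in cols:
        cols[n][5:] = np.nan if n == "x" else cols[n][5:]
    cols["x"][5:] = np.nan
    d = _dataset(cols)
    t = FisherZTester(d)
    res = t.test("x", "y", ("a", "b", "c"))
    assert res.insufficient and res.independent and res.p_value == 1.0
    assert t.insufficient_log  # the event is auditable


def test_zero_variance_column_takes_insufficiency_path():
    d = _dataset({"x": np.ones(50), "y": np.arange(50.0)})
    res = FisherZTester(d).test("x", "y")
    assert res.insufficient and res.independent


def test_variable_determined_by_conditioning_set_is_independent():
    # y's residual variance given S={x} is zero when y duplicates x's partner
    rng = np.random.default_rng(6)
    x = rng.normal(size=100)
    d = _dataset({"t": rng.normal(size=100), "y": x, "x": x.copy()})
    res = FisherZTester(d).test("t", "y", ("x",))
    assert res.insufficient and res.independent


def test_fisher_z_matches_permutation_oracle():
    """p-value within Monte-Carlo + normal-approximation error of a
    20,000-draw permutation oracle on a fixed 30-row dataset, |S| = 2."""
    rng = np.random.default_rng(2024)
    n = 30
    s1, s2 = rng.normal(size=n), rng.normal(size=n)
    x = 0.5 * s1 - 0.3 * s2 + rng.normal(size=n)
    y = 0.4 * s1 + 0.5 * s2 + 0.45 * x + rng.normal(size=n)
    d = _dataset({"x": x, "y": y, "s1": s1, "s2": s2})
    res = FisherZTester(d).test("x", "y", ("s1", "s2"))

    # oracle: permute x's rank residuals against y's, recompute |r| each draw
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    design = np.column_stack([np.ones(n), stats.rankdata(s1), stats.rankdata(s2)])
    ex = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    ey = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    r_obs = abs(np.corrcoef(ex, ey)[0, 1])
    prng = np.random.default_rng(7)
    perms = np.array([prng.permutation(ex) for _ in range(20_000)])
    eyc = (ey - ey.mean()) / ey.std()
    pc = (perms - perms.mean(axis=1, keepdims=True)) / perms.std(axis=1, keepdims=True)
    r_perm = np.abs(pc @ eyc / n)
    p_perm = float((r_perm >= r_obs).mean())
    assert abs(res.p_value - p_perm) < 0.03


# ---------------------------------------------------------------------------
# G-squared


def _discrete_dataset_from_2x2(counts):
    rows = []
    for i in (0, 1):
        for j in (0, 1):
            rows += [[i, j]] * counts[i][j]
    arr = np.array(rows, dtype=float)
    table = VariableTable([("x", "binary", 1), ("y", "binary", 1)])
    return Dataset(arr, table)


def test_g2_exact_independence_is_zero():
    d = _discrete_dataset_from_2x2([[25, 25], [25, 25]])
    res = G2Tester(d).test("x", "y")
    assert res.statistic == 0.0
    assert res.p_value == 1.0
    assert res.df == 1.0


def test_g2_matches_scipy_log_likelihood_oracle():
    counts = [[30, 10], [10, 30]]
    d = _discrete_dataset_from_2x2(counts)
    res = G2Tester(d).test("x", "y")
    g2_oracle, p_oracle, dof, _ = stats.chi2_contingency(
        np.array(counts), correction=False, lambda_="log-likelihood"
    )
    assert res.statistic == pytest.approx(g2_oracle, abs=1e-10)
    assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
    assert res.df == dof


def test_g2_df_accounts_for_conditioning_strata():
    # binary x, y given one 3-level variable: df = (2-1)(2-1)*3 = 3
    rng = np.random.default_rng(8)
    n = 600
    s = rng.integers(0, 3, n)
    x = rng.integers(0, 2, n)
    y = rng.integers(0, 2, n)
    table = VariableTable(
        [("x", "binary", 1), ("y", "binary", 1), ("s", "ordinal", 1)]
    )
    d = Dataset(np.column_stack([x, y, s]).astype(float), table)
    res = G2Tester(d).test("x", "y", ("s",))
    assert res.df == 3.0


def test_g2_rejects_cardinal_variables():
    rng = np.random.default_rng(9)
    table = VariableTable([("x", "cardinal", 1), ("y", "binary", 1)])
    d = Dataset(np.column_stack([rng.normal(size=50), rng.integers(0, 2, 50)]), table)
    with pytest.raises(ValidationError, match="cardinal"):
        G2Tester(d)


def test_g2_degenerate_levels_take_insufficiency_path():
    table = VariableTable([("x", "binary", 1), ("y", "binary", 1)])
    d = Dataset(np.column_stack([np.zeros(30), np.r_[np.zeros(15), np.ones(15)]]), table)
    res = G2Tester(d).test("x", "y")
    assert res.insufficient and res.independent


# ---------------------------------------------------------------------------
# oracle backend


def test_oracle_tester_mirrors_d_separation():
    rng = np.random.default_rng(10)
    model = random_tiered_model(rng, n_lo=8, n_hi=8)
    t = OracleCITester(model)
    nodes = model.variables
    for x, y in itertools.combinations(nodes[:6], 2):
        for S in itertools.combinations([n for n in nodes if n not in (x, y)], 2):
            res = t.test(x, y, S)
            assert res.independent == d_separated(model, x, y, S)
            assert res.p_value in (0.0, 1.0)
            assert math.isinf(res.n_effective)


def test_oracle_adjacent_pairs_never_separate():
    rng = np.random.default_rng(11)
    model = random_tiered_model(rng, n_lo=6, n_hi=10, density=(0.3, 0.5))
    t = OracleCITester(model)
    for u, v in model.dag.edges:
        rest = [n for n in model.variables if n not in (u, v)]
        for S in itertools.combinations(rest, min(2, len(rest))):
            assert not t.test(u, v, S).independent


# ---------------------------------------------------------------------------
# backend selection


def test_make_tester_auto_selects_g2_only_for_small_discrete():
    rng = np.random.default_rng(12)
    disc = _dataset(
        {
            "a": rng.integers(0, 2, 100).astype(float),
            "b": rng.integers(0, 3, 100).astype(float),
        },
        vtypes={"a": "binary", "b": "ordinal"},
    )
    assert isinstance(make_tester(disc, method="auto"), G2Tester)
    cont = _dataset({"a": rng.normal(size=100), "b": rng.normal(size=100)})
    assert isinstance(make_tester(cont, method="auto"), FisherZTester)
    with pytest.raises(ValueError):
        make_tester(cont, method="bogus")
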