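"""Unit and property tests for the five base p-value combiners."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ldpool as lp
from ldpool.combine import combine_rows

# -- worked examples ---------------------------------------------------------


@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.01, 0.5, 0.9], 0.03),
        ([0.6, 0.7], 1.0),  # capped at 1
        ([0.3], 0.3),
    ],
)
def test_bonferroni_examples(p, expected):
    assert lp.bonferroni(lp.PValueSet("g", p)).p == pytest.approx(expected, abs=1e-12)


def test_bonferroni_permutation_invariant_replicated_min():
    rng = np.random.default_rng(0)
    m = 0.002956
    p = np.concatenate([[m], rng.uniform(0.01, 1.0, 22)])
    base = lp.bonferroni(lp.PValueSet("g", p)).p
    assert base == pytest.approx(23 * m, rel=1e-12)
    for _ in range(5):
        assert lp.bonferroni(lp.PValueSet("g", rng.permutation(p))).p == base


@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.01, 0.5, 0.9], 1 - 0.99**3),  # 0.029701
        ([0.3], 0.3),  # single-test identity
    ],
)
def test_tippett_examples(p, expected):
    assert lp.tippett(lp.PValueSet("g", p)).p == pytest.approx(expected, rel=1e-12)


def test_binomial_excess_significance():
    # 10 of 100 independent p-values significant at 0.05
    p = [0.04] * 10 + [0.5] * 90
    res = lp.binomial_test(lp.PValueSet("g", p))
    assert res.statistic == 10
    assert res.p == pytest.approx(0.0281882941634, rel=1e-10)
    assert round(res.p, 3) == 0.028


def test_binomial_corners():
    assert lp.binomial_test(lp.PValueSet("g", [0.5] * 7)).p == 1.0  # r = 0
    res = lp.binomial_test(lp.PValueSet("g", [0.01] * 5))
    assert res.p == pytest.approx(0.05**5, rel=1e-12)  # all significant


def test_binomial_ties_counted_inclusive():
    res = lp.binomial_test(lp.PValueSet("g", [0.05, 0.5]))
    assert res.statistic == 1


def test_fisher_closed_form():
    # X2 = -4 ln 0.5 = 2.7726; chi2 survival with 4 df is e^{-x/2}(1 + x/2)
    res = lp.fisher(lp.PValueSet("g", [0.5, 0.5]))
    x2 = -4 * np.log(0.5)
    assert res.statistic == pytest.approx(x2, rel=1e-12)
    assert res.p == pytest.approx(np.exp(-x2 / 2) * (1 + x2 / 2), rel=1e-12)
    # one p-value: identity
    assert lp.fisher(lp.PValueSet("g", [0.2])).p == pytest.approx(0.2, rel=1e-12)


def test_stouffer_examples():
    assert lp.stouffer(lp.PValueSet("g", [0.5, 0.5])).p == pytest.approx(0.5, abs=1e-12)
    assert lp.stouffer(lp.PValueSet("g", [0.2])).p == pytest.approx(0.2, rel=1e-9)
    res = lp.stouffer(lp.PValueSet("g", [0.05, 0.05]))
    from scipy.stats import norm

    z = 2 * norm.isf(0.05) / np.sqrt(2)
    assert res.statistic == pytest.approx(z, rel=1e-9)
    assert res.p == pytest.approx(norm.sf(z), rel=1e-9)


# -- ingest invariants -------------------------------------------------------


@pytest.mark.parametrize("bad", [[], [0.0, 0.5], [-0.1], [1.5], [np.nan]])
def test_invalid_pvalues_rejected(bad):
    with pytest.raises(lp.InputError):
        lp.PValueSet("g", bad)


def test_p_equal_one_accepted():
    for method in ("bonferroni", "tippett", "binomial", "fisher", "stouffer"):
        res = lp.combine(lp.PValueSet("g", [1.0, 0.5]), method)
        assert 0.0 <= res.p <= 1.0


# -- properties --------------------------------------------------------------


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=1e-12, max_value=1.0, exclude_min=False), min_size=1, max_size=30),
    st.sampled_from(["bonferroni", "tippett", "binomial", "fisher", "stouffer"]),
)
def test_combiners_in_unit_interval_and_permutation_invariant(p, method):
    pset = lp.PValueSet("g", p)
    res = lp.combine(pset, method)
    assert 0.0 <= res.p <= 1.0
    perm = lp.PValueSet("g", list(reversed(p)))
    # summation order may shift the last ulp for fisher/stouffer
    assert lp.combine(perm, method).p == pytest.approx(res.p, rel=1e-12, abs=1e-15)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=1, max_size=20))
def test_tippett_never_exceeds_bonferroni(p):
    pset = lp.PValueSet("g", p)
    assert lp.tippett(pset).p <= lp.bonferroni(pset).p + 1e-12


def test_row_combiners_match_scalar():
    rng = np.random.default_rng(3)
    P = rng.uniform(1e-6, 1.0, size=(50, 8))
    for method in ("bonferroni", "tippett", "binomial", "fisher", "stouffer"):
        rows = combine_rows(P, method)
        scalars = [lp.combine(lp.PValueSet("g", row), method).p for row in P]
        np.testing.assert_allclose(rows, scalars, rtol=1e-12)


def test_calibration_under_independence_quick():
    """Tippett/Fisher/Stouffer reject ~alpha of independent-uniform nulls;
    binomial and Bonferroni stay at or below alpha."""
    rng = np.random.default_rng(11)
    reps, k, alpha = 20_000, 10, 0.05
    P = rng.uniform(size=(reps, k))
    se3 = 3 * np.sqrt(alpha * (1 - alpha) / reps)
    for method in ("tippett", "fisher", "stouffer"):
        rate = np.mean(combine_rows(P, method) <= alpha)
        assert abs(rate - alpha) < se3, (method, rate)
    assert np.mean(combine_rows(P, "bonferroni") <= alpha) <= alpha + se3
    assert np.mean(combine_rows(P, "binomial") <= alpha) <= alpha + se3
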