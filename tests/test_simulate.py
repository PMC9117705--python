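"""Tests for genotype simulation, LD estimation, trend tests and the
Monte Carlo harness."""

import numpy as np
import pytest
from scipy import stats

import ldpool as lp
from ldpool.simulate import _select_causal


# -- Cochran-Armitage trend test ---------------------------------------------


def test_trend_test_matches_independent_implementation():
    """Fixed 2x3 table (cases 10/20/30, controls 30/20/10); expected value
    frozen from R's stats::prop.trend.test with scores (0,1,2)."""
    g = np.repeat([0, 1, 2], [40, 40, 40])
    y = np.concatenate(
        [np.ones(10), np.zeros(30), np.ones(20), np.zeros(20), np.ones(30), np.zeros(10)]
    )
    assert lp.trend_test(g, y) == pytest.approx(7.74421643104407e-06, rel=1e-10)


def test_trend_test_degenerate_tables_return_one():
    # identical genotype distributions in cases and controls -> z = 0
    g = np.repeat([0, 1, 2], [10, 10, 10])
    y = np.tile([0, 1], 15)
    assert lp.trend_test(g, y) == 1.0
    # all one genotype
    assert lp.trend_test(np.ones(20), np.tile([0, 1], 10)) == 1.0
    # all one phenotype class
    assert lp.trend_test(np.repeat([0, 1, 2], 5), np.ones(15)) == 1.0


def test_trend_test_detects_perfect_separation():
    g = np.repeat([0, 2], [50, 50])
    y = np.repeat([0, 1], [50, 50])
    assert lp.trend_test(g, y) < 1e-15


def test_trend_test_null_pvalues_uniform():
    G = lp.simulate_genotypes(1000, 1, {"kind": "independent"}, 0.3, seed=6)
    rng = np.random.default_rng(7)
    Y = rng.binomial(1, 0.5, size=(2000, 1000))
    p = lp.trend_test_matrix(G.G.astype(float), Y).ravel()
    assert stats.kstest(p, "uniform").pvalue > 0.01


# -- genotype simulation -----------------------------------------------------


def test_hardy_weinberg_at_independence():
    G = lp.simulate_genotypes(20_000, 3, {"kind": "independent"}, 0.5, seed=1)
    freqs = np.array([np.mean(G.G == c) for c in (0, 1, 2)])
    np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=0.02)
    R = lp.estimate_ld(G)
    off = R.R[np.triu_indices(3, 1)]
    assert np.max(np.abs(off)) < 0.03


def test_perfect_latent_ld_gives_identical_columns():
    G = lp.simulate_genotypes(200, 4, {"kind": "block", "rho": 1.0}, 0.3, seed=2)
    for j in range(1, 4):
        np.testing.assert_array_equal(G.G[:, 0], G.G[:, j])


def test_ar1_ld_decays_with_lag():
    G = lp.simulate_genotypes(5000, 10, {"kind": "ar1", "rho": 0.8}, 0.3, seed=3)
    R = lp.estimate_ld(G).R
    lag1 = np.diag(R, 1).mean()
    lag3 = np.diag(R, 3).mean()
    lag6 = np.diag(R, 6).mean()
    assert lag1 > lag3 > lag6 > 0
    # realized LD is attenuated relative to the latent rho
    assert 0.4 < lag1 < 0.8


def test_realized_maf_near_target():
    G = lp.simulate_genotypes(5000, 5, {"kind": "independent"}, 0.2, seed=4)
    np.testing.assert_allclose(G.maf, 0.2, atol=0.03)
    assert np.all((G.maf > 0) & (G.maf <= 0.5))


def test_infeasible_ld_profile_rejected():
    with pytest.raises(lp.InputError, match="attainable"):
        lp.simulate_genotypes(100, 5, {"kind": "exchangeable", "rho": -0.9}, 0.3, seed=0)
    with pytest.raises(lp.InputError):
        lp.simulate_genotypes(100, 5, {"kind": "ar1", "rho": 1.5}, 0.3, seed=0)


# -- LD estimation -----------------------------------------------------------


def test_duplicated_column_has_unit_correlation():
    G0 = lp.simulate_genotypes(300, 1, {"kind": "independent"}, 0.3, seed=5)
    G = lp.GenotypeMatrix(np.column_stack([G0.G[:, 0], G0.G[:, 0]]))
    for est in ("composite", "em_hwe"):
        R = lp.estimate_ld(G, est)
        assert R.R[0, 1] == pytest.approx(1.0, abs=1e-9)


def test_em_hwe_recovers_known_haplotype_correlation():
    """Individuals built from homozygous haplotype pairs carry no phase
    ambiguity, so the EM estimate equals the direct haplotype correlation."""
    # haplotype pool: 15 AB/AB, 15 ab/ab, 10 Ab/Ab, 10 aB/aB individuals
    blocks = [(2, 2, 15), (0, 0, 15), (2, 0, 10), (0, 2, 10)]
    x = np.concatenate([np.full(n, gx) for gx, gy, n in blocks])
    y = np.concatenate([np.full(n, gy) for gx, gy, n in blocks])
    G = lp.GenotypeMatrix(np.column_stack([x, y]).astype(np.int8))
    # haplotype frequencies: pAB=0.3, pAb=0.2, paB=0.2, pab=0.3
    # D = 0.3 - 0.5*0.5 = 0.05; r = 0.05 / 0.25 = 0.2
    R = lp.estimate_ld(G, "em_hwe")
    assert R.R[0, 1] == pytest.approx(0.2, abs=1e-8)


def test_em_hwe_consistent_with_composite_under_hwe():
    G = lp.simulate_genotypes(4000, 4, {"kind": "exchangeable", "rho": 0.6}, 0.3, seed=8)
    R1 = lp.estimate_ld(G, "composite").R
    R2 = lp.estimate_ld(G, "em_hwe").R
    np.testing.assert_allclose(R1, R2, atol=0.05)


def test_monomorphic_column_rejected_at_ingest():
    with pytest.raises(lp.InputError, match="monomorphic"):
        lp.GenotypeMatrix(np.column_stack([np.zeros(10), np.ones(10)]).astype(int))


# -- phenotype model ---------------------------------------------------------


def test_null_phenotype_is_fair_coin():
    G = lp.simulate_genotypes(200, 5, {"kind": "independent"}, 0.3, seed=9)
    rng = np.random.default_rng(10)
    ys = [lp.assign_phenotype(G, lp.ScenarioSpec(), seed=rng) for _ in range(200)]
    assert np.mean([y.mean() for y in ys]) == pytest.approx(0.5, abs=0.01)


def test_alternative_phenotype_centred_near_half():
    """The intercept of the logistic model centres the case fraction."""
    G = lp.simulate_genotypes(1000, 50, {"kind": "ar1", "rho": 0.5}, 0.3, seed=11)
    rng = np.random.default_rng(12)
    spec = lp.ScenarioSpec(causal="pct20", effect_size=0.5, distributed=False)
    fracs = [lp.assign_phenotype(G, spec, seed=rng).mean() for _ in range(100)]
    assert np.mean(fracs) == pytest.approx(0.5, abs=0.02)


def test_causal_selection_layouts():
    rng = np.random.default_rng(13)
    # pct20 of k=50 selects 10 SNPs
    spec_c = lp.ScenarioSpec(causal="pct20", effect_size=0.2, compact=True)
    idx = _select_causal(50, spec_c, rng)
    assert idx.size == 10 and np.all(np.diff(idx) == 1)  # consecutive block
    spec_d = lp.ScenarioSpec(causal="pct20", effect_size=0.2, compact=False)
    idx = _select_causal(50, spec_d, rng)
    assert idx.size == 10 and np.all(np.diff(idx) >= 2)  # dispersed
    assert _select_causal(50, lp.ScenarioSpec(causal="single", effect_size=0.2), rng).size == 1


def test_distributed_effect_divides_beta():
    """With a distributed pct20 effect on k = 50, each causal beta is
    effect/10; verified through the induced linear predictor."""
    G = lp.simulate_genotypes(500, 50, {"kind": "independent"}, 0.3, seed=14)
    spec = lp.ScenarioSpec(causal="pct20", effect_size=0.2, distributed=True)
    idx = np.arange(10)
    # per-SNP coefficient 0.02 -> max |eta - mean| is small; the case
    # probability stays close to 0.5 for every individual
    from scipy.special import expit

    beta = np.zeros(50)
    beta[idx] = 0.2 / 10
    eta = G.G @ beta
    pi = expit(eta - eta.mean())
    assert np.max(np.abs(pi - 0.5)) < 0.1


def test_tiny_gene_floors_causal_count_with_warning():
    rng = np.random.default_rng(15)
    with pytest.warns(UserWarning, match="using 1"):
        idx = _select_causal(4, lp.ScenarioSpec(causal="pct5", effect_size=0.2), rng)
    assert idx.size == 1


# -- gene characteristics ----------------------------------------------------


def test_gene_characteristics_identities():
    assert lp.gene_characteristics(lp.LDMatrix.identity(5)).srmsc == 0.0
    ones = lp.LDMatrix(np.ones((4, 4)))
    assert lp.gene_characteristics(ones).srmsc == pytest.approx(1.0)


def test_gene_characteristics_hand_value():
    R = np.eye(3)
    R[0, 1] = R[1, 0] = 0.6
    R[0, 2] = R[2, 0] = 0.0
    R[1, 2] = R[2, 1] = -0.8
    gc = lp.gene_characteristics(lp.LDMatrix(R))
    assert gc.srmsc == pytest.approx(np.sqrt((0.36 + 0.0 + 0.64) / 3), rel=1e-12)
    assert gc.mean_r == pytest.approx((0.6 + 0.0 - 0.8) / 3, rel=1e-12)


# -- scenario harness --------------------------------------------------------


def test_run_scenario_deterministic_given_seed():
    G = lp.simulate_genotypes(102, 8, {"kind": "ar1", "rho": 0.6}, 0.3, seed=16)
    spec = lp.ScenarioSpec(reps=100)
    methods = [("bonferroni", "none"), ("fisher", "dependent")]
    a = lp.run_scenario(G, spec, methods, seed=5, s_empirical=2000)
    b = lp.run_scenario(G, spec, methods, seed=5, s_empirical=2000)
    assert a.equals(b)


def test_run_scenario_null_bonferroni_controlled():
    G = lp.simulate_genotypes(102, 10, {"kind": "ar1", "rho": 0.8}, 0.3, seed=17)
    spec = lp.ScenarioSpec(reps=500)
    df = lp.run_scenario(G, spec, [("bonferroni", "none")], seed=6)
    rate = df["rate"].iloc[0]
    assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 500)


def test_run_scenario_rejects_bad_method_pairs():
    G = lp.simulate_genotypes(102, 5, {"kind": "independent"}, 0.3, seed=18)
    with pytest.raises(lp.InputError):
        lp.run_scenario(G, lp.ScenarioSpec(reps=10), [("bonferroni", "dependent")], seed=0)
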