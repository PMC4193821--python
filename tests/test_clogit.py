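import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from triogxe import (InestimableError, NoInformationError, SimConfig,
                     TrioConditionalLogit, design_row, lrt,
                     matched_set_genotypes, simulate_arrays)


def fit_sets(G, E=None, names=()):
    return TrioConditionalLogit(G, E, names).fit()


def grid_loglik(G, beta):
    """Conditional log-likelihood written independently of the model class."""
    eta = np.asarray(G, float) * beta
    return float((eta[:, 0] - np.log(np.exp(eta).sum(axis=1))).sum())


# ---------------------------------------------------------------- design

def test_design_row_layout():
    assert list(design_row(2, {}, ())) == [2.0]
    assert list(design_row(1, {"ETS": 1, "VIT": 0}, ("ETS", "VIT"))) == [1, 1, 0]
    assert list(design_row(0, {"ETS": 1}, ("ETS",))) == [0.0, 0.0]


# ---------------------------------------------------------------- fitting

def test_het_case_symmetry_gives_zero():
    """All cases heterozygous from Aa x Aa matings: the score vanishes at 0."""
    G = np.array([[1, 2, 1, 0]] * 20)
    res = fit_sets(G)
    assert res.params[0] == pytest.approx(0.0, abs=1e-10)
    assert res.llf == pytest.approx(res.llnull)


def test_closed_form_and_grid_search_oracle(aa_x_aa_trios):
    """Aa x aa matings, 9 transmissions vs 3: MLE is log(T/U) = log 3, and it
    agrees with an independent 1-D optimisation of the conditional
    likelihood to 1e-6."""
    from triogxe import build_matched_sets, sets_to_arrays
    sets, _ = build_matched_sets(aa_x_aa_trios, 0, "rs1")
    G, _ = sets_to_arrays(sets)
    res = fit_sets(G)
    assert res.params[0] == pytest.approx(np.log(3), abs=1e-8)
    opt = minimize_scalar(lambda b: -grid_loglik(G, b), bounds=(-5, 5),
                          method="bounded", options={"xatol": 1e-10})
    assert res.params[0] == pytest.approx(opt.x, abs=1e-6)
    assert np.exp(res.params[0]) == pytest.approx(3.0, abs=1e-6)


def test_agreement_with_statsmodels_reference():
    """Same fixture, independent implementation: coefficients, SEs and Wald
    p-values agree with statsmodels' ConditionalLogit to 1e-6."""
    sm = pytest.importorskip("statsmodels.api")
    from statsmodels.discrete.conditional_models import ConditionalLogit
    rng = np.random.default_rng(5)
    cfg = SimConfig(n_trios=300, maf=0.25, exposure_names=("ETS",),
                    exposure_rates={"ETS": 0.4}, beta_g=-0.4,
                    beta_gxe=(0.5,), seed=0)
    F, M, C, E = simulate_arrays(cfg, rng)
    G = matched_set_genotypes(F, M, C)
    res = TrioConditionalLogit(G, E, ("ETS",)).fit()

    n = G.shape[0]
    y = np.tile([1, 0, 0, 0], n)
    x1 = G.reshape(-1).astype(float)
    x2 = x1 * np.repeat(E[:, 0], 4)
    groups = np.repeat(np.arange(n), 4)
    ref = ConditionalLogit(y, np.column_stack([x1, x2]), groups=groups).fit(
        method="newton", tol=1e-12, maxiter=200, disp=0)
    np.testing.assert_allclose(res.params, ref.params, atol=1e-6)
    np.testing.assert_allclose(res.bse, ref.bse, atol=1e-6)
    for j in range(2):
        assert res.wald_test(j)[2] == pytest.approx(ref.pvalues[j], abs=1e-6)
    # statsmodels keeps uninformative groups, each contributing log(1/4)
    n_uninf = n - res.n_sets_informative
    assert res.llf + n_uninf * np.log(0.25) == pytest.approx(ref.llf, abs=1e-6)


def test_exposure_main_effect_is_inestimable():
    """A column constant within each set (an exposure main effect) cannot be
    identified against the matching and is reported, not absorbed."""
    rng = np.random.default_rng(8)
    G = matched_set_genotypes(*simulate_arrays(
        SimConfig(n_trios=100, maf=0.3, seed=0), rng)[:3])
    E = rng.integers(0, 2, G.shape[0]).astype(float)
    X = np.empty((G.shape[0], 4, 2))
    X[:, :, 0] = G
    X[:, :, 1] = E[:, None]  # set-constant main effect
    with pytest.raises(InestimableError, match="E"):
        TrioConditionalLogit(G, design=X, names=["G", "E"]).fit()


def test_all_zero_interaction_is_inestimable():
    rng = np.random.default_rng(9)
    G = matched_set_genotypes(*simulate_arrays(
        SimConfig(n_trios=100, maf=0.3, seed=0), rng)[:3])
    E = np.zeros((G.shape[0], 1), dtype=np.int8)
    with pytest.raises(InestimableError, match="G:ETS"):
        TrioConditionalLogit(G, E, ("ETS",)).fit()


def test_no_informative_sets_is_an_error():
    with pytest.raises(NoInformationError, match="no information"):
        TrioConditionalLogit(np.array([[1, 1, 1, 1]] * 5)).fit()


def test_estimates_invariant_to_pseudocontrol_order():
    rng = np.random.default_rng(11)
    G = matched_set_genotypes(*simulate_arrays(
        SimConfig(n_trios=200, maf=0.3, beta_g=0.3, seed=0), rng)[:3])
    res1 = fit_sets(G)
    G2 = G.copy()
    G2[:, 1:] = G2[:, [3, 1, 2]]  # permute pseudo-controls
    res2 = fit_sets(G2)
    assert res1.params[0] == pytest.approx(res2.params[0], abs=1e-10)
    assert res1.llf == pytest.approx(res2.llf, abs=1e-10)


def test_separation_flagged_for_one_sided_transmissions():
    """Every case carries the maximal genotype: the likelihood is monotone
    and the fit must flag separation with infinite SEs."""
    G = np.array([[2, 1, 1, 0]] * 30)
    res = fit_sets(G)
    assert res.separation and not res.converged
    assert np.isinf(res.bse).all()


# ---------------------------------------------------------------- inference

@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.lists(st.floats(-3, 3), min_size=1, max_size=1))
def test_set_probabilities_sum_to_one(beta):
    G = np.array([[1, 2, 1, 0], [2, 1, 1, 0], [1, 1, 0, 0]])
    model = TrioConditionalLogit(G)
    P = model.set_probabilities(np.array(beta))
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


def test_wald_edge_cases():
    G = np.array([[1, 2, 1, 0]] * 20)
    res = fit_sets(G)  # beta-hat = 0
    z, _, p = res.wald_test(0)
    assert p == pytest.approx(1.0, abs=1e-9)


def test_wald_z_196_gives_p_005():
    """Engineer c'beta / se = 1.96 via a synthetic results object."""
    from triogxe import TrioConditionalLogitResults
    G = np.array([[1, 2, 1, 0]] * 5)
    model = TrioConditionalLogit(G)
    res = TrioConditionalLogitResults(model, np.array([1.96]),
                                      np.array([[1.0]]), -5.0, True, False)
    assert res.wald_test(0)[2] == pytest.approx(0.05, abs=2e-4)


def test_lrt_df_and_nesting():
    rng = np.random.default_rng(13)
    cfg = SimConfig(n_trios=400, maf=0.3, exposure_names=("ETS", "VIT"),
                    exposure_rates={"ETS": 0.5, "VIT": 0.3}, seed=0)
    F, M, C, E = simulate_arrays(cfg, rng)
    G = matched_set_genotypes(F, M, C)
    full = TrioConditionalLogit(G, E, ("ETS", "VIT")).fit()
    stat, df, p = lrt(full)
    assert df == 3 and stat >= 0
    assert lrt(full, full)[0] == pytest.approx(0.0, abs=1e-12)
    assert lrt(full, full)[2] == pytest.approx(1.0)
    reduced = TrioConditionalLogit(G, E[:, :1], ("ETS",)).fit()
    stat2, df2, _ = lrt(full, reduced)
    assert df2 == 1 and stat2 >= 0
    # different sets -> refuse
    half = TrioConditionalLogit(G[: len(G) // 2]).fit()
    with pytest.raises(ValueError, match="set mismatch"):
        lrt(full, half)


def test_loglik_never_below_null(null_panel):
    from triogxe import build_matched_sets, sets_to_arrays
    _, trios = null_panel
    sets, _ = build_matched_sets(trios, 0, "snp1", ("ETS",))
    G, E = sets_to_arrays(sets, ("ETS",))
    res = TrioConditionalLogit(G, E, ("ETS",)).fit()
    assert res.llf >= res.llnull - 1e-10
    assert res.llnull == pytest.approx(res.n_sets_informative * np.log(0.25))
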