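import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triogxe import (SimConfig, allelic_tdt, bonferroni, build_matched_sets,
                     gtdt, joint_test, sets_to_arrays, simulate_trios,
                     stratum_or, stratum_table)
from conftest import make_trio


# ---------------------------------------------------------------- gTDT

def test_gtdt_closed_form_or(aa_x_aa_trios):
    res, rows = gtdt(aa_x_aa_trios, 0, "rs1")
    (row,) = rows
    assert row.or_value == pytest.approx(3.0, abs=1e-6)
    assert row.ci_lo < 3.0 < row.ci_hi
    assert row.n_sets == 12


def test_gtdt_balanced_transmissions_is_null():
    trios = [make_trio(f"A{i}", [1], [0], [1]) for i in range(8)]
    trios += [make_trio(f"B{i}", [1], [0], [0]) for i in range(8)]
    _, (row,) = gtdt(trios, 0, "rs1")
    assert row.or_value == pytest.approx(1.0, abs=1e-8)
    assert row.wald_p == pytest.approx(1.0, abs=1e-6)


def test_gtdt_wald_approaches_allelic_tdt(aa_x_aa_trios):
    """On single-heterozygous-parent matings the two tests are asymptotically
    the same; with T=90, U=30 the p-values agree to ~15%."""
    trios = [make_trio(f"T{i}", [1], [0], [1]) for i in range(90)]
    trios += [make_trio(f"U{i}", [1], [0], [0]) for i in range(30)]
    _, (row,) = gtdt(trios, 0, "rs1")
    b, c, stat, p = allelic_tdt(trios, 0)
    assert (b, c) == (90, 30)
    assert np.log(row.wald_p) == pytest.approx(np.log(p), rel=0.15)


# ---------------------------------------------------------------- joint

def test_joint_with_no_exposures_equals_gtdt(null_panel):
    _, trios = null_panel
    res_g, _ = gtdt(trios, 0, "snp1")
    res_j, _ = joint_test(trios, 0, "snp1", ())
    assert res_j.params[0] == pytest.approx(res_g.params[0], abs=1e-12)
    assert res_j.llf == pytest.approx(res_g.llf, abs=1e-12)


def test_joint_lrt_degrees_of_freedom(null_panel):
    _, trios = null_panel
    _, rows = joint_test(trios, 0, "snp1", ("ETS", "VIT"))
    lrt_row = [r for r in rows if r.term == "LRT"][0]
    assert lrt_row.lrt_df == 3
    _, rows1 = joint_test(trios, 0, "snp1", ("ETS",))
    assert [r for r in rows1 if r.term == "LRT"][0].lrt_df == 2


def test_joint_complete_case_shrinks_denominator(null_panel):
    """A trio missing one exposure leaves the ETS model but not both."""
    _, trios = null_panel
    from triogxe import MISSING
    trios[0].exposures["VIT"] = MISSING
    res_e, _ = joint_test(trios, 0, "snp1", ("ETS",))
    res_ev, _ = joint_test(trios, 0, "snp1", ("ETS", "VIT"))
    assert res_ev.model.n_sets_total == res_e.model.n_sets_total - 1


def test_joint_constant_zero_exposure_inestimable():
    trios = [make_trio(f"F{i}", [1], [1], [1], ETS=0) for i in range(30)]
    res, rows = joint_test(trios, 0, "rs1", ("ETS",))
    assert res is None  # inestimable interaction column reported as NaN row
    assert np.isnan(rows[0].lrt_p)


# ---------------------------------------------------------------- strata

def test_stratum_or_contrasts(null_panel):
    _, trios = null_panel
    res, _ = joint_test(trios, 0, "snp1", ("ETS", "VIT"))
    base = stratum_or(res, {"ETS": 0, "VIT": 0}, 1, ("ETS", "VIT"))
    assert base.or_value == pytest.approx(np.exp(res.params[0]))
    two = stratum_or(res, {}, 2, ("ETS", "VIT"))
    assert two.or_value == pytest.approx(base.or_value ** 2)
    both = stratum_or(res, {"ETS": 1, "VIT": 1}, 1, ("ETS", "VIT"))
    assert both.or_value == pytest.approx(np.exp(res.params.sum()))
    assert base.ci_lo <= base.or_value <= base.ci_hi


def test_stratum_or_variance_against_bootstrap():
    """Delta-method SE of the exposed-stratum log-OR vs a set-resampling
    bootstrap on a fixed simulated panel (agreement within ~10%)."""
    cfg = SimConfig(n_trios=800, maf=0.25, exposure_names=("ETS",),
                    exposure_rates={"ETS": 0.4}, beta_g=-0.4, beta_gxe=(0.5,),
                    seed=21)
    _, trios = simulate_trios(cfg)
    sets, _ = build_matched_sets(trios, 0, "snp1", ("ETS",))
    G, E = sets_to_arrays(sets, ("ETS",))
    from triogxe import TrioConditionalLogit
    res = TrioConditionalLogit(G, E, ("ETS",)).fit()
    c = np.array([1.0, 1.0])
    se_delta = float(np.sqrt(c @ res.cov_params @ c))
    rng = np.random.default_rng(22)
    boots = []
    for _ in range(400):
        idx = rng.integers(0, len(G), len(G))
        bres = TrioConditionalLogit(G[idx], E[idx], ("ETS",)).fit()
        boots.append(float(c @ bres.params))
    assert np.std(boots, ddof=1) == pytest.approx(se_delta, rel=0.10)


def test_stratum_table_counts_and_recovery():
    """Simulated per-stratum one-copy ORs are recovered within 3 SE and the
    stratum counts add up to the analyzed trios."""
    true = {(0, 0): 0.58, (1, 0): 0.95, (0, 1): 0.7, (1, 1): 1.1}
    cfg = SimConfig.from_stratum_ors(
        true, ("ETS", "VIT"), n_trios=5000, maf=0.2,
        exposure_rates={"ETS": 0.382, "VIT": 0.15}, seed=33)
    _, trios = simulate_trios(cfg)
    res, strata, rows = stratum_table(trios, 0, "snp1", ("ETS", "VIT"))
    assert len(strata) <= 4
    assert sum(s.n_trios for s in strata) == res.model.n_sets_total
    for s in strata:
        key = (s.exposure_combo["ETS"], s.exposure_combo["VIT"])
        se = (np.log(s.ci_hi) - np.log(s.ci_lo)) / (2 * 1.959963984540054)
        assert abs(np.log(s.or_value) - np.log(true[key])) < 3 * se
        assert 0 < s.stratum_maf < 0.5


# ---------------------------------------------------------------- allelic TDT

def test_allelic_tdt_counts_and_statistic():
    trios = [make_trio(f"B{i}", [1], [2], [2]) for i in range(15)]
    trios += [make_trio(f"C{i}", [1], [2], [1]) for i in range(5)]
    b, c, stat, p = allelic_tdt(trios, 0)
    assert (b, c) == (15, 5)
    assert stat == pytest.approx(5.0)


def test_allelic_tdt_balanced_and_empty():
    trios = [make_trio(f"B{i}", [1], [1], [1]) for i in range(10)]
    b, c, stat, p = allelic_tdt(trios, 0)
    assert b == c and stat == 0 and p == pytest.approx(1.0)
    hom = [make_trio("H", [0], [2], [1])]
    assert np.isnan(allelic_tdt(hom, 0)[2])


def test_allelic_tdt_skips_inconsistent_trios():
    trios = [make_trio("A", [1], [0], [1]), make_trio("X", [0], [0], [2])]
    b, c, _, _ = allelic_tdt(trios, 0)
    assert (b, c) == (1, 0)


# ---------------------------------------------------------------- Bonferroni

def test_bonferroni_cap_and_values():
    assert bonferroni(0.5, 3) == 1.0
    assert bonferroni(4.39e-5, 117) == pytest.approx(117 * 4.39e-5)


@settings(derandomize=True, max_examples=80, deadline=None)
@given(st.floats(0, 1), st.floats(0, 1), st.integers(1, 500), st.integers(1, 500))
def test_bonferroni_monotone(p1, p2, m1, m2):
    if p1 <= p2:
        assert bonferroni(p1, m1) <= bonferroni(p2, m1)
    if m1 <= m2:
        assert bonferroni(p1, m1) <= bonferroni(p1, m2)
    assert 0 <= bonferroni(p1, m1) <= 1
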