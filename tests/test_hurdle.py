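"""Two-part hurdle fits, summed-χ² LRT, prefilter and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

import isletime as it
from isletime.hurdle import (HurdleDesign, _batch_logistic, _batch_wls,
                             bh_adjust, fit_hurdle, lrt_hurdle,
                             prefilter_genes, run_design)

from conftest import single_type_config


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------

def hand_bh(p):
    """Independent step-up oracle."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


def test_bh_worked_example():
    q = bh_adjust(np.array([0.01, 0.02, 0.03]))
    assert np.allclose(q, [0.03, 0.03, 0.03])


def test_bh_all_ones_and_singleton():
    assert np.allclose(bh_adjust(np.ones(5)), 1.0)
    assert np.allclose(bh_adjust(np.array([0.2])), [0.2])


def test_bh_empty_rejected():
    with pytest.raises(ValueError):
        bh_adjust(np.array([]))


@settings(max_examples=40, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
def test_bh_matches_hand_step_up(p):
    assert np.allclose(bh_adjust(np.array(p)), hand_bh(p), atol=1e-12)


# ---------------------------------------------------------------------------
# prefilter
# ---------------------------------------------------------------------------

def test_prefilter_boundary_and_zero_median():
    totals = np.full(5, 10_000.0)
    counts = np.zeros((5, 3))
    counts[:, 0] = 2.0          # CP10K 2 everywhere: retained
    counts[:2, 1] = 10.0        # >50% zeros: median 0, removed
    counts[:, 2] = [0, 0, 1, 3, 9]  # median CP10K exactly 1: retained (>=)
    keep = prefilter_genes(counts, totals=totals)
    assert keep.tolist() == [True, False, True]


def test_prefilter_empty_survivors_is_error():
    counts = np.zeros((4, 2))
    counts[0, :] = 1
    with pytest.raises(ValueError):
        prefilter_genes(counts, totals=np.full(4, 1e6))


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def _two_group_X(n):
    g = np.repeat([0.0, 1.0], n // 2)
    return np.column_stack([np.ones(n), g]), g


def test_no_signal_gives_null_coefficients():
    rng = np.random.default_rng(0)
    X, _ = _two_group_X(400)
    y = np.abs(rng.normal(1.0, 0.3, 400)) * (rng.random(400) < 0.7)
    full = fit_hurdle(y, X)
    reduced = fit_hurdle(y, X[:, :1])
    chi2, df, p = lrt_hurdle(full, reduced)
    assert abs(full.coefs_cont[1]) < 0.2
    assert chi2[0] < 8.0 and p[0] > 0.01


def test_fully_detected_gene_reduces_to_ols():
    rng = np.random.default_rng(1)
    X, g = _two_group_X(300)
    y = 1.0 + 0.5 * g + rng.normal(0, 0.4, 300) + 5.0  # strictly positive
    fit = fit_hurdle(y, X)
    assert fit.disc_degenerate[0]
    ols = sm.OLS(y, X).fit()
    assert np.allclose(fit.coefs_cont, ols.params, atol=1e-8)
    # LRT df counts only the live (continuous) part
    reduced = fit_hurdle(y, X[:, :1])
    _, df, _ = lrt_hurdle(fit, reduced)
    assert df[0] == 1


def test_planted_shift_recovered_and_matches_reference_glms():
    rng = np.random.default_rng(2)
    n = 400
    X, g = _two_group_X(n)
    detected = rng.random(n) < 0.8
    y = np.where(detected, 1.5 + 1.0 * g + rng.normal(0, 0.5, n), 0.0)
    y = np.abs(y) * detected
    fit = fit_hurdle(y, X)
    assert abs(fit.coefs_cont[1] - 1.0) < 0.15
    # independent reference fits
    z = (y > 0).astype(float)
    logit_ref = sm.Logit(z, X).fit(disp=0)
    ols_ref = sm.OLS(y[y > 0], X[y > 0]).fit()
    assert np.allclose(fit.coefs_disc, logit_ref.params, atol=1e-3)
    assert np.allclose(fit.coefs_cont, ols_ref.params, atol=1e-8)
    assert np.isclose(fit.ll_disc[0], logit_ref.llf, atol=1e-6)


def test_all_zero_gene_contributes_no_df():
    X, _ = _two_group_X(100)
    y = np.zeros(100)
    fit = fit_hurdle(y, X)
    assert fit.disc_degenerate[0] and fit.cont_degenerate[0]
    reduced = fit_hurdle(y, X[:, :1])
    chi2, df, p = lrt_hurdle(fit, reduced)
    assert df[0] == 0 and p[0] == 1.0


def test_lrt_identity_and_nesting_guard():
    rng = np.random.default_rng(3)
    X, _ = _two_group_X(200)
    y = np.abs(rng.normal(1, 0.3, 200)) * (rng.random(200) < 0.6)
    fit = fit_hurdle(y, X)
    with pytest.raises(ValueError):
        lrt_hurdle(fit, fit)


def test_batched_fits_agree_with_single_gene_path():
    rng = np.random.default_rng(4)
    n, G = 250, 20
    X = np.column_stack([np.ones(n), rng.normal(size=n),
                         np.repeat([0.0, 1.0], n // 2)])
    Y = np.abs(rng.normal(1.0, 0.5, (n, G))) * (rng.random((n, G)) < 0.7)
    Z = (Y > 0).astype(float)
    bd, lld, dd, _ = _batch_logistic(Z, X)
    bc, s2, llc, dc = _batch_wls(Y, Z, X)
    for j in rng.choice(G, 5, replace=False):
        single = fit_hurdle(Y[:, j], X)
        assert np.allclose(single.coefs_disc, bd[j], atol=1e-10)
        assert np.allclose(single.coefs_cont, bc[j], atol=1e-10)
        assert np.isclose(single.ll_disc[0], lld[j])
        assert np.isclose(single.ll_cont[0], llc[j])


def test_null_pvalues_uniform_fast():
    """Pure-numpy null: Gaussian levels, Bernoulli detection, binary group."""
    rng = np.random.default_rng(5)
    n, G = 300, 400
    X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n // 2)])
    Z = (rng.random((n, G)) < 0.7).astype(float)
    Y = np.abs(rng.normal(1.5, 0.5, (n, G))) * Z
    bd_f, lld_f, dd_f, cap = _batch_logistic(Z, X)
    bc_f, s2, llc_f, dc_f = _batch_wls(Y, Z, X)
    bd_r, lld_r, dd_r, _ = _batch_logistic(Z, X[:, :1])
    bc_r, _, llc_r, dc_r = _batch_wls(Y, Z, X[:, :1])
    full = it.HurdleFit(bd_f, bc_f, s2, lld_f, llc_f, dd_f, dc_f, cap, 2)
    red = it.HurdleFit(bd_r, bc_r, None, lld_r, llc_r, dd_r, dc_r, None, 1)
    chi2, df, p = lrt_hurdle(full, red)
    assert kstest(p, "uniform").pvalue > 1e-3


def test_continuous_coefficient_unbiased_in_lognormal_mode():
    """With the generator's log-normal count mode (Gaussian level part), the
    recovered glucose coefficient is close to the planted shift."""
    coefs = []
    for seed in (1, 2, 3):
        cfg = single_type_config(
            n_genes=800, n_cells_per_well=100, count_mode="lognormal",
            effect_spec=it.EffectSpec(0, 0.0, 10, 1.0, 0, 0.0,
                                      detection_coupling=0.0),
            module_spec=it.ModuleSpec(sizes=(), shapes=()),
            hurdle_spec=it.HurdleSpec(mean_detection=0.9, logit_sd=0.3))
        adata, truth = it.simulate_dataset(cfg, seed=seed)
        filtered, _ = it.apply_qc_filters(adata)
        expr = it.normalize_log_cp10k(filtered)
        labels = truth.cells.loc[expr.obs_names, "cell_type"]
        res = run_design(expr, HurdleDesign("LvH", 24.0), "beta",
                         labels).set_index("gene")
        planted = truth.genes.index[truth.genes["glucose_effect"]]
        shifts = truth.genes.loc[planted, "glucose_shift"]
        tested = planted.intersection(res.index)
        rec = res.loc[tested, "coef_cont"] * np.sign(shifts.loc[tested])
        coefs.append(rec.mean())
    assert abs(np.mean(coefs) - 1.0) < 0.15, coefs


def test_run_design_deterministic(small_expr, true_labels):
    expr, _, _ = small_expr
    r1 = run_design(expr, HurdleDesign("time"), "beta", true_labels)
    r2 = run_design(expr, HurdleDesign("time"), "beta", true_labels)
    pd.testing.assert_frame_equal(r1, r2)


def test_discrete_design_requires_both_groups(small_expr, true_labels):
    expr, _, _ = small_expr
    with pytest.raises(ValueError):
        run_design(expr, HurdleDesign("LvH", 3.0), "beta", true_labels)


def test_design_metadata_and_q_monotonicity(small_expr, true_labels):
    expr, _, _ = small_expr
    res = run_design(expr, HurdleDesign("glucose"), "beta", true_labels)
    assert ((res["p"] >= 0) & (res["p"] <= 1)).all()
    assert (res["q"] >= res["p"] - 1e-12).all()
    assert set(res["df"].unique()) <= {0, 1, 2}
    assert "complexity" in res.attrs["design_columns"]
    assert any(c.startswith("donor[") for c in res.attrs["design_columns"])
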