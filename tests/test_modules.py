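"""Profile smoothing, the DPGP sampler, consensus, and module extraction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import isletime as it
from isletime.modules import (GRID, _zscore_rows, consensus_from_runs,
                              default_config_grid, dpgp_cluster,
                              extract_modules, select_module_genes,
                              smooth_profiles)


# ---------------------------------------------------------------------------
# gene selection
# ---------------------------------------------------------------------------

def _dge_frame(design, genes, qs):
    return pd.DataFrame({"gene": genes, "design": design, "q": qs,
                         "cell_type": "beta", "time_point": np.nan,
                         "p": qs})


def test_bvh_only_genes_excluded():
    res = [_dge_frame("BvH", ["g1"], [0.001]),
           _dge_frame("LvH", ["g2"], [0.049]),
           _dge_frame("time", ["g3"], [0.2])]
    assert select_module_genes(res) == ["g2"]


def test_threshold_rule_is_strict():
    res = [_dge_frame("LvH", ["a", "b"], [0.0499, 0.05])]
    assert select_module_genes(res) == ["a"]


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def test_smoother_preserves_constants_and_lines():
    rng = np.random.default_rng(0)
    n = 300
    t = rng.random(n)
    arms = np.repeat(["low", "high"], n // 2)
    y = np.column_stack([np.full(n, 2.5), 2.0 * t])
    prof = smooth_profiles(y, t, arms, ["const", "linear"])
    assert np.allclose(prof.values[0], 2.5, atol=1e-9)
    for ai in range(2):
        assert np.allclose(prof.values[1, :, ai], 2.0 * GRID, atol=1e-6)


def test_smoother_tracks_noisy_sinusoid():
    rng = np.random.default_rng(1)
    n = 2000
    t = rng.random(n)
    arms = np.repeat(["low", "high"], n // 2)
    y = (np.sin(2 * np.pi * t) + rng.normal(0, 0.3, n))[:, None]
    prof = smooth_profiles(y, t, arms, ["sine"], frac=0.2)
    truth = np.sin(2 * np.pi * GRID)
    assert np.abs(prof.values[0, :, 0] - truth).max() < 0.15


def test_small_arm_falls_back_to_linear():
    rng = np.random.default_rng(2)
    t = np.concatenate([rng.random(50), [0.2, 0.8]])
    arms = np.array(["low"] * 50 + ["high"] * 2)
    y = (3.0 * t)[:, None]
    prof = smooth_profiles(y, t, arms, ["g"])
    assert prof.linear_fallback["high"] and not prof.linear_fallback["low"]
    assert np.allclose(prof.values[0, :, 1], 3.0 * GRID, atol=1e-9)


def test_missing_arm_is_an_error():
    with pytest.raises(ValueError, match="arm"):
        smooth_profiles(np.ones((5, 1)), np.linspace(0, 1, 5),
                        np.array(["low"] * 5), ["g"])


# ---------------------------------------------------------------------------
# DPGP
# ---------------------------------------------------------------------------

def test_two_distinct_shapes_fully_separated():
    rng = np.random.default_rng(0)
    Y = np.vstack([np.tile(np.sin(2 * np.pi * GRID), (10, 1)),
                   np.tile(-np.sin(2 * np.pi * GRID), (10, 1))])
    Y += rng.normal(0, 0.05, Y.shape)
    res = dpgp_cluster(_zscore_rows(Y), alpha=1.0, n_aux=4, seed=1, n_iter=40)
    truth = np.repeat([0, 1], 10)
    assert adjusted_rand_score(truth, res.assignments) == 1.0
    assert res.similarity[:10, :10].min() > 0.9
    assert res.similarity[:10, 10:].max() < 0.1


def test_homogeneous_profiles_form_one_cluster():
    rng = np.random.default_rng(1)
    base = np.cumsum(rng.normal(0, 0.3, len(GRID)))
    Y = np.tile(base, (30, 1)) + rng.normal(0, 0.05, (30, len(GRID)))
    res = dpgp_cluster(_zscore_rows(Y), alpha=1.0, n_aux=4, seed=1, n_iter=40)
    sizes = np.bincount(res.assignments)
    assert sizes.max() / 30 >= 0.9


def test_three_planted_shapes_recovered():
    rng = np.random.default_rng(2)
    shapes = [np.sin(np.pi * GRID), GRID ** 2, 1 - GRID]
    Y = np.vstack([np.tile(s, (20, 1)) + rng.normal(0, 0.25, (20, len(GRID)))
                   for s in shapes])
    truth = np.repeat([0, 1, 2], 20)
    res = dpgp_cluster(_zscore_rows(Y), alpha=1.0, n_aux=8, seed=3, n_iter=60)
    assert adjusted_rand_score(truth, res.assignments) >= 0.9


def test_split_chains_agree_on_separable_data():
    rng = np.random.default_rng(3)
    Y = np.vstack([np.tile(np.sin(2 * np.pi * GRID), (10, 1)),
                   np.tile(GRID, (10, 1))]) + rng.normal(0, 0.1, (20, len(GRID)))
    Z = _zscore_rows(Y)
    r1 = dpgp_cluster(Z, alpha=1.0, n_aux=8, seed=11, n_iter=60)
    r2 = dpgp_cluster(Z, alpha=1.0, n_aux=8, seed=12, n_iter=60)
    assert np.abs(r1.similarity - r2.similarity).mean() < 0.1


def test_dpgp_needs_two_genes():
    with pytest.raises(ValueError):
        dpgp_cluster(np.ones((1, 21)))


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def test_config_grid_has_45_pairs_within_quoted_ranges():
    grid = default_config_grid()
    assert len(grid) == 45
    alphas = {a for a, _ in grid}
    n_aux = {m for _, m in grid}
    assert min(alphas) == pytest.approx(0.001) and max(alphas) == pytest.approx(10.0)
    assert min(n_aux) == 2 and max(n_aux) == 16


def test_consensus_agreement_limit_gives_binary_entries():
    rng = np.random.default_rng(4)
    low = np.vstack([np.tile(GRID, (8, 1)), np.tile(1 - GRID, (8, 1))])
    high = low.copy()
    low += rng.normal(0, 0.02, low.shape)
    high += rng.normal(0, 0.02, high.shape)
    prof = it.SmoothedProfiles(
        values=np.stack([low, high], axis=2),
        genes=[f"g{i}" for i in range(16)], arms=("low", "high"),
        grid=GRID.copy(), frac=0.3)
    cons = consensus_from_runs(prof, configs=[(1.0, 4), (0.5, 8), (2.0, 2)],
                               seed=0, n_iter=30)
    M = cons.matrix.to_numpy()
    assert cons.n_configs_used == 3
    assert np.allclose(M, M.T) and np.allclose(np.diag(M), 1.0)
    assert np.isin(M, [0.0, 1.0]).all()
    assert (M[:8, :8] == 1.0).all() and (M[:8, 8:] == 0.0).all()


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def _consensus_df(M, genes):
    return pd.DataFrame(M, index=genes, columns=genes)


def test_exact_blocks_extracted():
    genes = [f"g{i:02d}" for i in range(20)]
    M = np.zeros((20, 20))
    M[:10, :10] = 1.0
    M[10:, 10:] = 1.0
    ms = extract_modules(_consensus_df(M, genes))
    assert sorted(map(len, ms.modules.values())) == [10, 10]
    assert not ms.unassigned


def test_small_perfect_block_discarded_by_min_size():
    genes = [f"g{i:02d}" for i in range(14)]
    M = np.zeros((14, 14))
    M[:10, :10] = 1.0
    M[10:, 10:] = 1.0
    ms = extract_modules(_consensus_df(M, genes))
    assert sorted(map(len, ms.modules.values())) == [10]
    assert sorted(ms.unassigned) == genes[10:]


@pytest.mark.parametrize("seed", range(5))
def test_noisy_planted_blocks_recovered_exactly(seed):
    rng = np.random.default_rng(seed)
    sizes = [12, 9, 7]
    n = sum(sizes)
    genes = [f"g{i:02d}" for i in range(n)]
    M = np.full((n, n), 0.1) + rng.uniform(-0.05, 0.05, (n, n))
    start = 0
    truth = np.empty(n, dtype=int)
    for b, s in enumerate(sizes):
        M[start:start + s, start:start + s] = \
            0.92 + rng.uniform(-0.05, 0.05, (s, s))
        truth[start:start + s] = b
        start += s
    M = (M + M.T) / 2
    np.fill_diagonal(M, 1.0)
    ms = extract_modules(_consensus_df(M, genes))
    labels = ms.labels().reindex(genes).to_numpy()
    assert adjusted_rand_score(truth, labels) == 1.0


def test_extraction_invariant_to_gene_order():
    rng = np.random.default_rng(9)
    genes = [f"g{i:02d}" for i in range(18)]
    M = np.full((18, 18), 0.05)
    M[:9, :9] = 0.9
    M[9:, 9:] = 0.9
    np.fill_diagonal(M, 1.0)
    df = _consensus_df(M, genes)
    ms1 = extract_modules(df)
    perm = rng.permutation(18)
    ms2 = extract_modules(df.iloc[perm, perm])
    sets1 = {frozenset(v) for v in ms1.modules.values()}
    sets2 = {frozenset(v) for v in ms2.modules.values()}
    assert sets1 == sets2


def test_emitted_modules_respect_frequency_rule():
    rng = np.random.default_rng(10)
    n = 30
    genes = [f"g{i:02d}" for i in range(n)]
    M = rng.uniform(0, 1, (n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 1.0)
    ms = extract_modules(_consensus_df(M, genes), freq_min=0.75, min_size=5)
    for gs in ms.modules.values():
        idx = [genes.index(g) for g in gs]
        sub = M[np.ix_(idx, idx)]
        off = sub[~np.eye(len(idx), dtype=bool)]
        assert len(gs) >= 5 and off.min() >= 0.75
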