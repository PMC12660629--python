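import itertools

import numpy as np
import pytest
from scipy import stats as sst

import nirsconn as nc
from nirsconn.connectivity import ConnectivityMatrix
from nirsconn.stats import (
    bh_fdr,
    dunn_bonferroni,
    exact_spearman_p,
    kruskal_wallis,
    normality_gate,
    paired_edge_tests,
    scale_change_tests,
    spearman_delta,
    wilcoxon_signed_rank,
)


def _matrix(r, subject_id="S"):
    r = np.asarray(r, float)
    z = np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7))
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        r=r, z=z, valid_mask=np.ones(r.shape[0], bool), subject_id=subject_id
    )


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------


def test_gate_operating_characteristics(rng):
    normal_hits = sum(
        normality_gate(rng.standard_normal(34)) == "parametric"
        for _ in range(60)
    )
    heavy_hits = sum(
        normality_gate(rng.standard_t(1, 34)) == "nonparametric"
        for _ in range(60)
    )
    assert normal_hits >= 0.85 * 60
    assert heavy_hits >= 0.80 * 60


def test_gate_overrides_and_small_n():
    assert normality_gate([1, 2, 3], mode="wilcoxon") == "nonparametric"
    assert normality_gate([1, 2, 3], mode="t") == "parametric"
    with pytest.warns(UserWarning, match="fewer than 3"):
        assert normality_gate([1.0, 2.0]) == "nonparametric"


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def _bh_oracle(p):
    """Brute-force step-up: q_i = min over j with p_j >= p_i of m p_(j)/rank."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    sorted_q = [min(1.0, m * p[order[j]] / (j + 1)) for j in range(m)]
    for i in range(m):
        q[order[i]] = min(sorted_q[i:])
    return q


def test_bh_hand_example():
    q, sig = bh_fdr(np.array([0.01, 0.02, 0.03]))
    assert np.allclose(q, [0.03, 0.03, 0.03])
    assert sig.all()


def test_bh_no_discoveries_at_p_one():
    q, sig = bh_fdr(np.ones(10))
    assert not sig.any()
    assert np.allclose(q, 1.0)


def test_bh_matches_bruteforce_and_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(25):
        p = rng.uniform(size=rng.integers(2, 11))
        q, sig = bh_fdr(p)
        assert np.allclose(q, _bh_oracle(p), atol=1e-12)
        reject_sm, q_sm, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.allclose(q, q_sm, atol=1e-12)


def test_bh_monotone_in_threshold(rng):
    p = rng.uniform(size=50) ** 3
    _, sig_strict = bh_fdr(p, q=0.01)
    _, sig_loose = bh_fdr(p, q=0.05)
    assert np.all(sig_loose[sig_strict])


def test_bh_handles_nan_and_rejects_invalid():
    q, sig = bh_fdr(np.array([0.01, np.nan, 0.5]))
    assert np.isnan(q[1]) and not sig[1]
    with pytest.raises(ValueError):
        bh_fdr(np.array([0.1, 1.5]))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def _wilcoxon_exact_oracle(d):
    """Two-sided p by exhaustive 2^n sign-flip enumeration of W+."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sst.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    mu = n * (n + 1) / 4
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / 2**n


def test_wilcoxon_all_positive_three():
    w, z, p = wilcoxon_signed_rank([0, 0, 0], [1, 2, 3])
    assert p == pytest.approx(0.25)  # 2/8 sign patterns as extreme
    assert w == 0.0


def test_wilcoxon_symmetric_differences_are_null():
    _, z, p = wilcoxon_signed_rank([0, 0, 0, 0], [-2, -1, 1, 2])
    assert z == 0.0
    assert p == pytest.approx(1.0)


def test_wilcoxon_matches_signflip_enumeration(rng):
    for n in (5, 8, 11):
        for _ in range(5):
            d = rng.standard_normal(n)
            _, _, p = wilcoxon_signed_rank(np.zeros(n), d)
            assert p == pytest.approx(_wilcoxon_exact_oracle(d), abs=1e-12)


def test_wilcoxon_normal_approximation_large_n(rng):
    pre = rng.standard_normal(30)
    post = pre + rng.standard_normal(30)
    _, z, p = wilcoxon_signed_rank(pre, post)
    ref = sst.wilcoxon(post - pre, zero_method="wilcox", method="approx",
                       correction=True)
    assert p == pytest.approx(float(ref.pvalue), abs=1e-3)


def test_wilcoxon_degenerate_all_zero():
    w, z, p = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
    assert np.isnan(w) and z == 0.0 and p == 1.0


# ---------------------------------------------------------------------------
# edgewise paired tests
# ---------------------------------------------------------------------------


def _edge_matrices(values, edge=(0, 1), n_nodes=4):
    """Build per-subject matrices carrying `values` at one edge."""
    out = []
    for k, v in enumerate(values):
        r = np.eye(n_nodes)
        r[edge] = r[edge[::-1]] = v
        out.append(_matrix(r, subject_id=f"S{k}"))
    return out


def test_paired_edges_null_when_post_equals_pre(rng):
    vals = rng.uniform(0.1, 0.8, 6)
    pre = _edge_matrices(vals)
    post = _edge_matrices(vals)
    table = paired_edge_tests(pre, post, [(0, 1)], mode="t")
    assert table.statistic.iloc[0] == 0.0
    assert table.p_raw.iloc[0] == 1.0


def test_paired_t_matches_hand_computation():
    pre_r = np.array([0.50, 0.62, 0.41, 0.55, 0.47, 0.60])
    post_r = np.array([0.40, 0.50, 0.35, 0.52, 0.30, 0.45])
    table = paired_edge_tests(
        _edge_matrices(pre_r), _edge_matrices(post_r), [(0, 1)], mode="t"
    )
    d = np.arctanh(post_r) - np.arctanh(pre_r)
    t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(6))
    assert table.statistic.iloc[0] == pytest.approx(t_expected, abs=1e-10)
    assert table.df.iloc[0] == 5
    assert table.mean_pre.iloc[0] == pytest.approx(pre_r.mean())


def test_planted_edge_has_smallest_p(rng):
    n_sub, n_nodes = 34, 8
    edges = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    pre, post = [], []
    for k in range(n_sub):
        r1 = np.eye(n_nodes)
        r2 = np.eye(n_nodes)
        for i, j in edges:
            base = 0.4 + 0.15 * rng.standard_normal()
            r1[i, j] = r1[j, i] = base
            delta = -0.3 if (i, j) == (2, 5) else 0.0
            r2[i, j] = r2[j, i] = base + delta + 0.05 * rng.standard_normal()
        pre.append(_matrix(r1, f"S{k}"))
        post.append(_matrix(r2, f"S{k}"))
    table = paired_edge_tests(pre, post, edges, mode="t")
    best = table.loc[table.p_raw.idxmin()]
    assert (best.chan_i, best.chan_j) == (3, 6)  # 1-based (2,5)
    assert table.significant.sum() >= 1


def test_untestable_edge_flagged():
    pre = _edge_matrices([0.5, 0.6])
    post = _edge_matrices([0.4, 0.5])
    table = paired_edge_tests(pre, post, [(0, 1)], mode="t")
    assert table.untestable.iloc[0]
    assert np.isnan(table.p_raw.iloc[0])


def test_edgewise_invariant_to_subject_order(rng):
    vals_pre = rng.uniform(0.2, 0.7, 8)
    vals_post = vals_pre - rng.uniform(0, 0.2, 8)
    pre = _edge_matrices(vals_pre)
    post = _edge_matrices(vals_post)
    t1 = paired_edge_tests(pre, post, [(0, 1)], mode="t")
    perm = np.random.default_rng(0).permutation(8)
    t2 = paired_edge_tests([pre[i] for i in perm], [post[i] for i in perm],
                           [(0, 1)], mode="t")
    assert t1.statistic.iloc[0] == pytest.approx(t2.statistic.iloc[0], abs=1e-12)


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn-Bonferroni
# ---------------------------------------------------------------------------


def test_kruskal_hand_computed_example():
    h, p = kruskal_wallis([np.array([1, 2, 3]), np.array([4, 5, 6]),
                           np.array([7, 8, 9])])
    assert h == pytest.approx(7.2, abs=1e-10)


def test_kruskal_identical_groups():
    h, p = kruskal_wallis([np.ones(5), np.ones(4)])
    assert h == 0.0 and p == 1.0


def test_kruskal_type_one_error_calibrated(rng):
    hits = 0
    reps = 2000
    for _ in range(reps):
        pooled = rng.standard_normal(24)
        groups = [pooled[:8], pooled[8:16], pooled[16:]]
        _, p = kruskal_wallis(groups)
        hits += p < 0.05
    assert 0.03 <= hits / reps <= 0.07


def test_dunn_separated_groups_all_significant():
    table = dunn_bonferroni([np.arange(10), np.arange(20, 30),
                             np.arange(40, 50)], ["a", "b", "c"])
    assert len(table) == 3
    assert table.significant.all()


def test_dunn_identical_pair_has_zero_z(rng):
    x = rng.standard_normal(12)
    table = dunn_bonferroni([x, x.copy(), x + 10], ["a", "b", "c"])
    row = table[(table.group_a == "a") & (table.group_b == "b")].iloc[0]
    assert abs(row.z_dunn) < 1e-9


def test_dunn_bonferroni_multiplier_and_monotonicity(rng):
    table = dunn_bonferroni(
        [rng.standard_normal(10) for _ in range(3)], ["a", "b", "c"]
    )
    assert np.allclose(
        table.p_bonferroni, np.minimum(1.0, table.p_raw * 3), atol=1e-12
    )
    assert (table.p_bonferroni >= table.p_raw - 1e-15).all()


# ---------------------------------------------------------------------------
# scale tests
# ---------------------------------------------------------------------------


class _Subj:
    def __init__(self, group, g1, g2, p1, p2):
        self.group, self.gad7_t1, self.gad7_t2 = group, g1, g2
        self.phq9_t1, self.phq9_t2 = p1, p2


def test_scale_tests_null_change(rng):
    subs = [_Subj("MT", g, g, p, p)
            for g, p in zip(rng.integers(5, 15, 10), rng.integers(0, 20, 10))]
    out = scale_change_tests(subs)
    row = out["within"].iloc[0]
    assert row.t == 0.0 and row.p == 1.0 and row.df == 9


def test_scale_tests_detect_planted_improvement(rng):
    subs = []
    for _ in range(34):
        g1 = int(rng.integers(6, 15))
        subs.append(_Subj("MT", g1, g1 - 2 + int(rng.integers(-2, 3)),
                          10, 8))
    out = scale_change_tests(subs)
    gad = out["within"][out["within"].scale == "GAD7"].iloc[0]
    assert gad.df == 33
    assert gad.p < 0.001 and gad.delta_mean < 0


def test_scale_baseline_tables(fast_cohort):
    out = scale_change_tests(fast_cohort.subjects)
    baseline = out["baseline"]
    assert set(baseline.test) == {"t_mt_vs_wl", "kruskal_wallis_3group"}
    assert (baseline.p >= 0).all() and (baseline.p <= 1).all()


# ---------------------------------------------------------------------------
# Spearman delta correlations
# ---------------------------------------------------------------------------


def _spearman_perm_oracle(x, y):
    """Full-permutation two-sided p using scipy's rho for each permutation."""
    rho_obs = abs(sst.spearmanr(x, y).statistic)
    count = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(sst.spearmanr(x, perm).statistic) >= rho_obs - 1e-12:
            count += 1
    return count / total


def test_spearman_monotone_extremes():
    out = spearman_delta(
        np.array([4, 3, 2, 1]), np.array([[10], [20], [30], [40]]), ["1-2"]
    )
    assert out.spearman_rho.iloc[0] == pytest.approx(-1.0)
    out2 = spearman_delta(
        np.array([1, 2, 3, 4]), np.array([[10], [20], [30], [40]]), ["1-2"]
    )
    assert out2.spearman_rho.iloc[0] == pytest.approx(1.0)


def test_spearman_exact_p_matches_enumeration(rng):
    for n in (5, 6, 7):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        assert exact_spearman_p(x, y) == pytest.approx(
            _spearman_perm_oracle(x, y), abs=1e-12
        )


def test_spearman_exact_with_ties(rng):
    x = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 5.0])
    y = rng.standard_normal(6)
    assert exact_spearman_p(x, y) == pytest.approx(
        _spearman_perm_oracle(x, y), abs=1e-12
    )


def test_spearman_zero_variance_flagged():
    out = spearman_delta(
        np.array([1, 1, 1, 1, 1]), np.arange(5).reshape(-1, 1), ["1-2"]
    )
    assert np.isnan(out.spearman_rho.iloc[0])
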