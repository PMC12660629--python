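"""Hypothesis tests for the connectivity pipeline.

Covers: the normality gate choosing between paired t and Wilcoxon signed-rank
branches; edgewise longitudinal paired tests across the retained network
edges with Benjamini-Hochberg (BH) false-discovery-rate control at q < 0.05;
Kruskal-Wallis baseline group comparison with Dunn-Bonferroni post hocs;
within/between-group symptom-scale tests; and Spearman correlation between
per-subject symptom change and per-edge connectivity change.

Edgewise tests run on Fisher-z values (variance-stabilised), while all
reported edge summaries (means, SDs) stay in r units.  Tests are two-sided
throughout.  FDR is controlled separately within each analysis family.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .connectivity import ConnectivityMatrix

Q_DEFAULT = 0.05


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------


def normality_gate(differences: np.ndarray, alpha: float = 0.05,
                   mode: str = "auto") -> str:
    """Choose the test branch for paired differences.

    Shapiro-Wilk on the differences: p >= alpha keeps the parametric branch
    (paired t), otherwise the nonparametric branch (Wilcoxon signed-rank).
    ``mode`` "t" or "wilcoxon" bypasses the gate; n < 3 defaults to
    nonparametric with a warning.
    """
    if mode == "t":
        return "parametric"
    if mode == "wilcoxon":
        return "nonparametric"
    if mode != "auto":
        raise ValueError(f"unknown mode {mode!r}")
    d = np.asarray(differences, dtype=float)
    if len(d) < 3:
        warnings.warn("fewer than 3 differences; defaulting to nonparametric",
                      stacklevel=2)
        return "nonparametric"
    if np.ptp(d) == 0:
        return "nonparametric"  # Shapiro undefined on constant data
    _, p = sst.shapiro(d)
    return "parametric" if p >= alpha else "nonparametric"


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR
# ---------------------------------------------------------------------------


def bh_fdr(p_values: np.ndarray, q: float = Q_DEFAULT
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted q-values and significance flags.

    q_i = min over j >= i (in the ascending p ordering) of m * p_j / j,
    capped at 1; a discovery is q < ``q``.  NaN p-values (untestable rows)
    propagate as NaN and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    qv = np.full_like(p, np.nan)
    idx = np.flatnonzero(finite)
    m = len(idx)
    if m:
        order = idx[np.argsort(p[idx], kind="stable")]
        ranked = p[order] * m / np.arange(1, m + 1)
        qv[order] = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    flags = np.zeros_like(p, dtype=bool)
    flags[finite] = qv[finite] < q
    return qv, flags


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank(
    x_pre: np.ndarray, x_post: np.ndarray
) -> tuple[float, float, float]:
    """Wilcoxon signed-rank test on paired samples (post minus pre).

    Zero differences are dropped; tied |differences| get midranks.  The null
    distribution is exact (sign-flip enumeration) for n <= 25 without ties,
    and a normal approximation with continuity and tie correction otherwise.
    Returns (W = smaller signed-rank sum, |z| approximation, two-sided p);
    all-zero differences give (nan, 0, 1).
    """
    d = np.asarray(x_post, dtype=float) - np.asarray(x_pre, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return float("nan"), 0.0, 1.0
    ranks = sst.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    # normal approximation with continuity correction and tie correction
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    z = abs(w_plus - mu)
    z = max(z - 0.5, 0.0) / math.sqrt(var) if var > 0 else 0.0
    has_ties = len(tie_counts) < n
    if n <= 25 and not has_ties:
        res = sst.wilcoxon(d, zero_method="wilcox", method="exact")
        p = float(res.pvalue)
    else:
        p = float(2.0 * sst.norm.sf(z))
    return w, float(z), min(p, 1.0)


# ---------------------------------------------------------------------------
# Edgewise longitudinal tests
# ---------------------------------------------------------------------------


def _paired_matrices(
    pre: list[ConnectivityMatrix], post: list[ConnectivityMatrix]
) -> list[tuple[ConnectivityMatrix, ConnectivityMatrix]]:
    if len(pre) != len(post):
        raise ValueError("pre/post subject lists differ in length")
    by_id = {m.subject_id: m for m in post}
    if len(by_id) == len(post) and all(m.subject_id in by_id for m in pre):
        return [(m, by_id[m.subject_id]) for m in pre]
    return list(zip(pre, post))


def paired_edge_tests(
    pre: list[ConnectivityMatrix],
    post: list[ConnectivityMatrix],
    edges: list[tuple[int, int]],
    mode: str = "t",
    q: float = Q_DEFAULT,
) -> pd.DataFrame:
    """Per-edge paired test of pre vs post FC across subjects, with BH FDR.

    Tests run on Fisher-z values; summaries are reported in r units.  Edges
    with fewer than 3 complete (valid in both sessions) pairs are flagged
    untestable (NaN statistics, excluded from the FDR family).  ``mode`` "t"
    is the paired t-test, "wilcoxon" the signed-rank branch.
    """
    if mode not in ("t", "wilcoxon"):
        raise ValueError(f"unknown mode {mode!r}")
    paired = _paired_matrices(pre, post)
    rows = []
    e_idx = np.array(edges, dtype=int)
    pre_z = np.stack([m.z for m, _ in paired])
    post_z = np.stack([m.z for _, m in paired])
    pre_r = np.stack([m.r for m, _ in paired])
    post_r = np.stack([m.r for _, m in paired])
    for i, j in e_idx:
        zp, zq = pre_z[:, i, j], post_z[:, i, j]
        complete = np.isfinite(zp) & np.isfinite(zq)
        n = int(complete.sum())
        label = f"{i + 1}-{j + 1}"
        rp, rq = pre_r[complete, i, j], post_r[complete, i, j]
        base = {
            "edge": label, "chan_i": i + 1, "chan_j": j + 1, "n": n,
            "mean_pre": float(np.mean(rp)) if n else np.nan,
            "mean_post": float(np.mean(rq)) if n else np.nan,
            "sd_pre": float(np.std(rp, ddof=1)) if n > 1 else np.nan,
            "sd_post": float(np.std(rq, ddof=1)) if n > 1 else np.nan,
        }
        if n < 3:
            rows.append({**base, "test": mode, "statistic": np.nan,
                         "df": np.nan, "p_raw": np.nan, "untestable": True})
            continue
        d = zq[complete] - zp[complete]
        if mode == "t":
            sd = float(np.std(d, ddof=1))
            if sd == 0.0:
                stat, p = 0.0, 1.0
            else:
                stat = float(np.mean(d) / (sd / math.sqrt(n)))
                p = float(2.0 * sst.t.sf(abs(stat), n - 1))
            rows.append({**base, "test": "paired_t", "statistic": stat,
                         "df": n - 1, "p_raw": p, "untestable": False})
        else:
            w, _, p = wilcoxon_signed_rank(zp[complete], zq[complete])
            rows.append({**base, "test": "wilcoxon", "statistic": w,
                         "df": np.nan, "p_raw": p, "untestable": False})
    table = pd.DataFrame(rows)
    qv, flags = bh_fdr(table["p_raw"].to_numpy(), q)
    table["q_bh"] = qv
    table["significant"] = flags
    return table


# ---------------------------------------------------------------------------
# Group comparison: Kruskal-Wallis + Dunn-Bonferroni
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """Omnibus H test plus pairwise Dunn-Bonferroni post hocs."""

    h: float
    p: float
    posthoc: pd.DataFrame  # group_a, group_b, z_dunn, p_raw, p_bonferroni, significant


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square p (k - 1 df)."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    if len(pooled) < 3:
        raise ValueError("need at least 3 observations in total")
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sst.kruskal(*groups)
    return float(h), float(p)


def dunn_bonferroni(
    groups: list[np.ndarray], labels: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled ranks with Bonferroni adjustment.

    z_ab = (Rbar_a - Rbar_b) / sqrt((N(N+1)/12 - T) (1/n_a + 1/n_b)) with the
    tie correction T = sum(t^3 - t) / (12 (N - 1)); adjusted
    p = min(1, raw * k(k-1)/2).  Adjusted p never falls below raw p.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    labels = labels or [f"group{i + 1}" for i in range(k)]
    arrays = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sst.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_corr = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))
    tie_corr /= 12.0 * (n_total - 1)
    var_base = n_total * (n_total + 1) / 12.0 - tie_corr
    mean_ranks, sizes = [], []
    pos = 0
    for g in arrays:
        mean_ranks.append(float(ranks[pos: pos + len(g)].mean()))
        sizes.append(len(g))
        pos += len(g)
    n_pairs = k * (k - 1) // 2
    rows = []
    for a, b in itertools.combinations(range(k), 2):
        se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = float(2.0 * sst.norm.sf(abs(z)))
        p_adj = min(1.0, p_raw * n_pairs)
        rows.append({
            "group_a": labels[a], "group_b": labels[b], "z_dunn": float(z),
            "p_raw": p_raw, "p_bonferroni": p_adj,
            "significant": p_adj < alpha,
        })
    return pd.DataFrame(rows)


def compare_groups(
    groups: list[np.ndarray], labels: list[str] | None = None
) -> GroupComparison:
    """Kruskal-Wallis omnibus followed by Dunn-Bonferroni post hocs."""
    h, p = kruskal_wallis(groups)
    return GroupComparison(h=h, p=p, posthoc=dunn_bonferroni(groups, labels))


# ---------------------------------------------------------------------------
# Symptom-scale tests
# ---------------------------------------------------------------------------


def scale_change_tests(subjects: list) -> dict[str, pd.DataFrame]:
    """Within-group paired t on scale changes and between-group baseline tests.

    ``subjects`` are SubjectSpec-like records with gad7_t1/gad7_t2/
    phq9_t1/phq9_t2 and group fields.  Returns {"within": ..., "baseline": ...}
    tables.  Within-group rows report the T2-T1 change (mean, SD), t with
    df = n - 1 and two-sided p.  Baseline rows compare the anxiety groups by
    independent t and all three groups by Kruskal-Wallis.
    """
    frame = pd.DataFrame(
        {
            "group": [s.group for s in subjects],
            "gad7_t1": [s.gad7_t1 for s in subjects],
            "gad7_t2": [s.gad7_t2 for s in subjects],
            "phq9_t1": [s.phq9_t1 for s in subjects],
            "phq9_t2": [s.phq9_t2 for s in subjects],
        }
    )
    within_rows = []
    for group, sub in frame.groupby("group", sort=False):
        for scale in ("gad7", "phq9"):
            t1 = sub[f"{scale}_t1"].to_numpy(float)
            t2 = sub[f"{scale}_t2"].to_numpy(float)
            if len(t1) < 2:
                continue
            delta = t2 - t1
            sd = float(delta.std(ddof=1))
            n = len(delta)
            if sd == 0.0:
                stat, p = 0.0, 1.0
            else:
                stat = float(delta.mean() / (sd / math.sqrt(n)))
                p = float(2.0 * sst.t.sf(abs(stat), n - 1))
            within_rows.append({
                "group": group, "scale": scale.upper(), "n": n,
                "delta_mean": float(delta.mean()), "delta_sd": sd,
                "t": stat, "df": n - 1, "p": p,
            })
    baseline_rows = []
    for scale in ("gad7", "phq9"):
        mt = frame.loc[frame.group == "MT", f"{scale}_t1"].to_numpy(float)
        wl = frame.loc[frame.group == "WL", f"{scale}_t1"].to_numpy(float)
        if len(mt) > 1 and len(wl) > 1:
            t_stat, t_p = sst.ttest_ind(mt, wl)
            baseline_rows.append({
                "scale": scale.upper(), "test": "t_mt_vs_wl",
                "statistic": float(t_stat), "p": float(t_p),
                "df": len(mt) + len(wl) - 2,
            })
        by_group = [
            frame.loc[frame.group == g, f"{scale}_t1"].to_numpy(float)
            for g in ("MT", "WL", "HC")
            if (frame.group == g).any()
        ]
        if len(by_group) >= 2:
            h, p = kruskal_wallis(by_group)
            baseline_rows.append({
                "scale": scale.upper(), "test": "kruskal_wallis_3group",
                "statistic": h, "p": p, "df": len(by_group) - 1,
            })
    return {"within": pd.DataFrame(within_rows),
            "baseline": pd.DataFrame(baseline_rows)}


# ---------------------------------------------------------------------------
# Delta-delta Spearman correlation
# ---------------------------------------------------------------------------


def exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman rho (n <= 9).

    Enumerates all n! permutations of the y ranks; ties are handled via
    midranks in both the observed statistic and the permutation null.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n > 9:
        raise ValueError("exact enumeration limited to n <= 9")
    rx = sst.rankdata(x)
    ry = sst.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    if denom == 0:
        return float("nan")
    observed = float(rx_c @ ry_c) / denom
    perms = np.array(list(itertools.permutations(ry_c)))
    stats = perms @ rx_c / denom
    return float(np.mean(np.abs(stats) >= abs(observed) - 1e-12))


def spearman_delta(
    delta_scale: np.ndarray,
    delta_fc: np.ndarray,
    edges: list[tuple[int, int]] | list[str],
) -> pd.DataFrame:
    """Spearman correlation of symptom change against per-edge FC change.

    ``delta_fc`` has shape (n_subjects, n_edges); rows with a missing value
    in either vector are dropped per edge.  The p-value is exact (full
    permutation enumeration) for n <= 9 and the t approximation otherwise.
    Zero variance in either vector flags the edge undefined (NaN rho).
    """
    ds = np.asarray(delta_scale, float)
    dfc = np.atleast_2d(np.asarray(delta_fc, float))
    if dfc.shape[0] != len(ds):
        raise ValueError("delta_scale and delta_fc disagree on subject count")
    if dfc.shape[1] != len(edges):
        raise ValueError("edge labels do not match delta_fc columns")
    rows = []
    for k, edge in enumerate(edges):
        label = edge if isinstance(edge, str) else f"{edge[0]}-{edge[1]}"
        col = dfc[:, k]
        ok = np.isfinite(ds) & np.isfinite(col)
        n = int(ok.sum())
        if n < 4 or np.ptp(ds[ok]) == 0 or np.ptp(col[ok]) == 0:
            rows.append({"edge": label, "spearman_rho": np.nan,
                         "p": np.nan, "n": n})
            continue
        rho, p_approx = sst.spearmanr(ds[ok], col[ok])
        p = exact_spearman_p(ds[ok], col[ok]) if n <= 9 else float(p_approx)
        rows.append({"edge": label, "spearman_rho": float(rho), "p": p, "n": n})
    return pd.DataFrame(rows)
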