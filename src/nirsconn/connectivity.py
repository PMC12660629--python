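"""Channelwise functional connectivity: correlation matrices, global summaries
and sparsity-thresholded binary networks.

Functional connectivity (FC) is the Pearson correlation between two channels'
HbO series.  Each participant/session yields a full, weighted 48 x 48 matrix;
a Fisher z twin (atanh) stabilises sampling variance for parametric tests.
Invalid channels keep their matrix slots with NaN entries and a False bit in
``valid_mask`` — they are flagged missing, never imputed as zero.

A sparsity threshold retains the top fraction of strongest edges by signed r
(largest positive first; reported negative post-treatment edge values imply
weak, not strong, connections) to form a binary network whose topology is
comparable across participants regardless of overall connectivity strength.
At the default 30% threshold a fully valid 48-channel matrix retains
floor(0.3 * 1128) = 338 edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import HemoglobinSeries

FISHER_CLAMP = 1.0 - 1e-7


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher r-to-z transform, z = atanh(r).

    Values with |r| >= 1 (numerically degenerate correlations) are clamped to
    +/-(1 - 1e-7) with a warning rather than returning infinities.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr[np.isfinite(arr)]) >= 1.0):
        warnings.warn("clamping |r| >= 1 before Fisher transform", stacklevel=2)
        arr = np.clip(arr, -FISHER_CLAMP, FISHER_CLAMP)
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) else out


@dataclass
class ConnectivityMatrix:
    """Symmetric channelwise Pearson matrix with its Fisher-z twin and mask."""

    r: np.ndarray  # (n, n), NaN on invalid rows/columns
    z: np.ndarray
    valid_mask: np.ndarray  # (n,) bool
    subject_id: str = ""
    session: str = ""

    @property
    def n_channels(self) -> int:
        return self.r.shape[0]

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


@dataclass
class BinaryNetwork:
    """Sparsity-thresholded graph: top-k strongest edges of a matrix."""

    adjacency: np.ndarray  # (n, n) bool, symmetric
    sparsity: float
    retained_edge_count: int
    mean_retained_weight: float
    pairs: list[tuple[int, int]]  # retained edges, 0-based, strongest first

    @property
    def edge_labels(self) -> list[str]:
        return [f"{i + 1}-{j + 1}" for i, j in self.pairs]


def compute_fc(hb: HemoglobinSeries) -> ConnectivityMatrix:
    """Pearson correlation of the preprocessed HbO series between all channels.

    HbR is deliberately ignored.  Constant (zero-variance) channels are
    masked and their pairs flagged undefined (NaN).  Requires at least two
    valid channels and ten samples.
    """
    x = hb.hbo
    if x.shape[0] < 10:
        raise ValueError("need at least 10 samples to estimate connectivity")
    valid = hb.valid_mask.copy()
    sd = x.std(axis=0)
    # relative tolerance: a nominally constant channel retains rounding-level
    # variance, which would otherwise produce garbage correlations
    valid &= sd > 1e-10 * np.maximum(np.abs(x).max(axis=0), 1e-30)
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid channels")
    n = x.shape[1]
    r = np.full((n, n), np.nan)
    idx = np.flatnonzero(valid)
    sub = np.corrcoef(x[:, idx].T)
    r[np.ix_(idx, idx)] = sub
    np.fill_diagonal(r, np.where(valid, 1.0, np.nan))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z = np.arctanh(np.clip(r, -FISHER_CLAMP, FISHER_CLAMP))
    np.fill_diagonal(z, 0.0)
    z[np.isnan(r)] = np.nan
    return ConnectivityMatrix(
        r=r, z=z, valid_mask=valid,
        subject_id=hb.subject_id, session=hb.session,
    )


def valid_pairs(m: ConnectivityMatrix) -> list[tuple[int, int]]:
    """Unique off-diagonal valid channel pairs (i < j, 0-based)."""
    idx = np.flatnonzero(m.valid_mask)
    return [(int(i), int(j)) for a, i in enumerate(idx) for j in idx[a + 1:]]


def global_mean_fc(m: ConnectivityMatrix) -> float:
    """Mean of r over the unique valid off-diagonal pairs (each counted once)."""
    pairs = valid_pairs(m)
    if not pairs:
        raise ValueError("no valid channel pairs")
    return float(np.mean([m.r[i, j] for i, j in pairs]))


def apply_sparsity(
    m: ConnectivityMatrix, sparsity: float = 0.3, rank_by: str = "signed"
) -> BinaryNetwork:
    """Retain the top ``floor(sparsity * E_valid)`` strongest edges.

    "Strongest" means largest signed r by default (``rank_by="abs"`` ranks by
    magnitude instead).  Ties break deterministically by (i, j) lexicographic
    order.  E_valid = n_valid * (n_valid - 1) / 2.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    if rank_by not in ("signed", "abs"):
        raise ValueError(f"unknown ranking {rank_by!r}")
    pairs = valid_pairs(m)
    k = int(np.floor(sparsity * len(pairs)))
    key = (lambda p: (-abs(m.r[p]), p)) if rank_by == "abs" else (
        lambda p: (-m.r[p], p)
    )
    ranked = sorted(pairs, key=key)
    retained = ranked[:k]
    n = m.n_channels
    adj = np.zeros((n, n), dtype=bool)
    for i, j in retained:
        adj[i, j] = adj[j, i] = True
    mean_w = float(np.mean([m.r[p] for p in retained])) if retained else float("nan")
    return BinaryNetwork(
        adjacency=adj,
        sparsity=sparsity,
        retained_edge_count=k,
        mean_retained_weight=mean_w,
        pairs=retained,
    )


def group_mean_matrix(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Elementwise mean over subjects, pairwise-complete over validity masks."""
    if not matrices:
        raise ValueError("need at least one matrix")
    n = matrices[0].n_channels
    if any(m.n_channels != n for m in matrices):
        raise ValueError("matrices disagree on channel count (montage mismatch)")
    stack = np.stack([m.r for m in matrices])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_r = np.nanmean(stack, axis=0)
    valid = np.stack([m.valid_mask for m in matrices]).any(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z = np.arctanh(np.clip(mean_r, -FISHER_CLAMP, FISHER_CLAMP))
    np.fill_diagonal(z, 0.0)
    z[np.isnan(mean_r)] = np.nan
    return ConnectivityMatrix(
        r=mean_r, z=z, valid_mask=valid, subject_id="group_mean",
        session=matrices[0].session,
    )
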