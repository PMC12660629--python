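"""Synthetic cohort generator with known ground truth.

Emulates a three-group longitudinal resting/listening-state fNIRS study:
a treated group (MT), a waiting-list group (WL) and a healthy control group
(HC), each measured at two time points (T1, T2), together with GAD-7 / PHQ-9
symptom scores.  Every downstream stage of the pipeline is testable against
the planted truth this module records:

* group-level channelwise correlation structure, built as lobe-blocked
  matrices calibrated so the global mean connectivity and the mean weight of
  the top 30% of edges hit configurable group targets;
* per-subject heterogeneity (a multiplicative connectivity scale and
  entrywise jitter) shared across the two sessions, so pre/post designs see
  genuinely paired data;
* planted pre-to-post connectivity reductions on named effect edges in the
  treated group only, with per-subject effect sizes;
* a rank-based (Gaussian copula) negative coupling between each treated
  subject's realized connectivity change and their GAD-7 change;
* physiological noise (cardiac, respiratory, Mayer waves, drift, white
  noise) and motion artifacts (spikes, baseline shifts) with a ground-truth
  event log;
* a forward modified Beer-Lambert map from concentration changes to
  dual-wavelength raw intensities, the exact inverse of the preprocessing
  conversion.

All randomness descends from a single master seed through
``numpy.random.SeedSequence`` spawning, so identical specs give bit-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import signal as sps
from scipy.stats import norm, rankdata

from .montage import MontageSpec, build_montage, channel_lobe
from .preprocess import (
    DEFAULT_DPF,
    HemoglobinSeries,
    RawIntensityRecording,
    mbll_system_matrix,
)

GROUPS = ("MT", "WL", "HC")

# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseSpec:
    """Physiological noise and motion-artifact parameters.

    Sinusoidal components are (frequency Hz, amplitude) in the same relative
    micromolar units as the hemodynamic signal; each channel gets a random
    phase.  ``drift_scale`` is the per-sample SD of a random-walk baseline.
    ``artifact_rate`` is the expected number of motion events (spikes and
    baseline shifts) per minute of recording; ``artifact_amplitude`` is the
    typical spike size in concentration units (50 micromolar maps to roughly
    1 OD unit through the forward optics, comfortably above the 0.5 OD motion
    threshold).
    """

    cardiac: tuple[float, float] = (1.2, 0.8)
    respiratory: tuple[float, float] = (0.3, 0.3)
    mayer: tuple[float, float] = (0.1, 0.06)
    drift_scale: float = 0.008
    white_sd: float = 0.4
    artifact_rate: float = 0.5
    artifact_amplitude: float = 50.0

    def __post_init__(self) -> None:
        for freq, amp in (self.cardiac, self.respiratory, self.mayer):
            if freq < 0 or amp < 0:
                raise ValueError("noise frequencies and amplitudes must be >= 0")
        if min(self.drift_scale, self.white_sd, self.artifact_rate,
               self.artifact_amplitude) < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def is_null(self) -> bool:
        return (
            self.cardiac[1] == 0 and self.respiratory[1] == 0
            and self.mayer[1] == 0 and self.drift_scale == 0
            and self.white_sd == 0 and self.artifact_rate == 0
        )

    def scaled(self, factor: float, artifact_rate: float | None = None) -> "NoiseSpec":
        """Amplitude-scaled copy (used for the smaller HbR noise)."""
        return NoiseSpec(
            cardiac=(self.cardiac[0], self.cardiac[1] * factor),
            respiratory=(self.respiratory[0], self.respiratory[1] * factor),
            mayer=(self.mayer[0], self.mayer[1] * factor),
            drift_scale=self.drift_scale * factor,
            white_sd=self.white_sd * factor,
            artifact_rate=self.artifact_rate if artifact_rate is None else artifact_rate,
            artifact_amplitude=self.artifact_amplitude * factor,
        )


NULL_NOISE = NoiseSpec(
    cardiac=(1.2, 0.0), respiratory=(0.3, 0.0), mayer=(0.1, 0.0),
    drift_scale=0.0, white_sd=0.0, artifact_rate=0.0, artifact_amplitude=0.0,
)


@dataclass(frozen=True)
class GroundTruthNetwork:
    """A correlation (unit-diagonal covariance) matrix plus planted effects."""

    corr: np.ndarray
    planted_edges: tuple[tuple[tuple[int, int], float], ...] = ()
    repaired: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.corr, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.abs(c).max() > 1 + 1e-9:
            raise ValueError("correlation entries must lie in [-1, 1]")


@dataclass(frozen=True)
class SubjectSpec:
    """One participant: group, symptom scores at both time points, seed."""

    subject_id: str
    group: str
    gad7_t1: int
    gad7_t2: int
    phq9_t1: int
    phq9_t2: int
    seed: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        for v in (self.gad7_t1, self.gad7_t2):
            if not 0 <= v <= 21:
                raise ValueError("GAD-7 outside [0, 21]")
        for v in (self.phq9_t1, self.phq9_t2):
            if not 0 <= v <= 27:
                raise ValueError("PHQ-9 outside [0, 27]")
        if self.group == "HC" and self.gad7_t1 >= 5:
            raise ValueError("HC screening requires GAD-7 < 5 at baseline")
        if self.group in ("MT", "WL") and self.gad7_t1 < 5:
            raise ValueError("anxiety-group screening requires GAD-7 >= 5 at baseline")


@dataclass(frozen=True)
class EffectSpec:
    """Planted intervention effects and their coupling to symptom change.

    ``edges`` are 1-based channel pairs; ``baseline_r`` their group-level T1
    connectivity; ``delta_r`` the mean pre-to-post change planted in the
    treated group.  Per-subject effect sizes scatter around ``delta_r`` with
    SD ``delta_sd``; per-subject baselines scatter with SD ``edge_sd``.
    ``coupling_rho`` is the target Spearman correlation between the treated
    subjects' realized connectivity change on ``coupling_edge`` and their
    GAD-7 change (negative by default).
    """

    edges: tuple[tuple[int, int], ...] = ((10, 34), (7, 48), (4, 47))
    delta_r: tuple[float, ...] = (-0.302, -0.328, -0.347)
    baseline_r: tuple[float, ...] = (0.601, 0.357, 0.267)
    delta_sd: float = 0.15
    edge_sd: float = 0.20
    coupling_edge: tuple[int, int] = (10, 34)
    coupling_rho: float = -0.45

    def __post_init__(self) -> None:
        if not (len(self.edges) == len(self.delta_r) == len(self.baseline_r)):
            raise ValueError("edges, delta_r and baseline_r must align")
        if abs(self.coupling_rho) >= 1:
            raise ValueError("|coupling_rho| must be < 1")


NULL_EFFECT = EffectSpec(edges=(), delta_r=(), baseline_r=())


def _default_group_mean_fc() -> dict[str, float]:
    return {"MT": 0.437, "WL": 0.448, "HC": 0.501}


def _default_group_within_fc() -> dict[str, float]:
    return {"MT": 0.754, "WL": 0.752, "HC": 0.814}


@dataclass(frozen=True)
class CohortSpec:
    """Study design: group sizes, recording length, targets, noise, effects.

    Defaults reproduce the emulated study's conditions: 34/32/17 subjects,
    group global-mean connectivity targets 0.437/0.448/0.501 with
    top-30%-edge means 0.754/0.752/0.814, three planted effect edges in the
    treated group, and a -0.45 Spearman coupling to GAD-7 change.
    ``optics`` False skips noise and the intensity forward model and returns
    clean concentration series directly (statistically equivalent because the
    optics round trip is exact; used for large Monte-Carlo replicate runs).
    """

    n_mt: int = 34
    n_wl: int = 32
    n_hc: int = 17
    duration_s: float = 300.0
    group_mean_fc: dict[str, float] = field(default_factory=_default_group_mean_fc)
    group_within_fc: dict[str, float] = field(default_factory=_default_group_within_fc)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    effect: EffectSpec = field(default_factory=EffectSpec)
    subject_scale_sd: float = 0.25
    subject_jitter_sd: float = 0.04
    session_jitter_sd: float = 0.02
    hemo_lowpass_hz: float = 0.15
    hemo_amplitude: float = 0.5
    optics: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mt, self.n_wl, self.n_hc) < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.duration_s < 60:
            raise ValueError(
                "duration must be >= 60 s so onset/offset truncation never "
                "empties a recording"
            )
        for g in GROUPS:
            if g not in self.group_mean_fc or g not in self.group_within_fc:
                raise ValueError(f"missing connectivity target for group {g}")


class ArtifactEvent(NamedTuple):
    """Ground-truth motion event: kind, 1-based channel, sample range, size."""

    kind: str  # "spike" | "shift"
    channel: int
    start: int
    stop: int
    amplitude: float


@dataclass
class CohortBundle:
    """Everything `simulate_cohort` produces, plus the planted truth."""

    spec: CohortSpec
    montage: MontageSpec
    subjects: list[SubjectSpec]
    recordings: dict[tuple[str, str], RawIntensityRecording | HemoglobinSeries]
    group_truth: dict[str, GroundTruthNetwork]
    subject_truth: dict[str, dict]
    artifact_log: dict[tuple[str, str], list[ArtifactEvent]]
    pd_repairs: int = 0

    def subjects_in(self, group: str) -> list[SubjectSpec]:
        return [s for s in self.subjects if s.group == group]


# ---------------------------------------------------------------------------
# Correlation-structure construction
# ---------------------------------------------------------------------------


def nearest_pd_correlation(
    r: np.ndarray, min_eig: float = 1e-4
) -> tuple[np.ndarray, bool]:
    """Eigenvalue-clipping repair to the nearest unit-diagonal PD matrix.

    Returns the (possibly repaired) matrix and whether repair fired.
    """
    r = np.asarray(r, dtype=float)
    w, v = np.linalg.eigh((r + r.T) / 2.0)
    if w.min() >= min_eig:
        return r, False
    w = np.clip(w, min_eig, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0, True


_LOADING_CAP = 0.985  # per-channel a^2 + b^2 ceiling keeping matrices PD


def _same_lobe_mask(montage: MontageSpec) -> np.ndarray:
    lobes = np.array([channel_lobe(i + 1) for i in range(montage.n_channels)])
    return lobes[:, None] == lobes[None, :]


def _corr_from_loadings(a: np.ndarray, b: np.ndarray, same: np.ndarray) -> np.ndarray:
    """Unit-diagonal correlation matrix from global (a) and lobe (b) loadings.

    r_ij = a_i a_j + b_i b_j [same lobe]; positive definite by construction
    because every channel keeps idiosyncratic variance 1 - a^2 - b^2 > 0.
    """
    r = np.outer(a, a) + np.outer(b, b) * same
    np.fill_diagonal(r, 1.0)
    return r


def _draw_subject_loadings(
    a: np.ndarray,
    b: np.ndarray,
    rng: np.random.Generator,
    scale_sd: float,
    jitter_sd: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Subject-level loadings: one connectivity scale plus per-channel jitter.

    The multiplicative scale g (clipped symmetrically, so its mean stays 1)
    multiplies every correlation; the cap on a^2 + b^2 saturates extreme
    subjects the way correlations saturate near 1.
    """
    lo, hi = 1.0 - 2.0 * scale_sd, 1.0 + 2.0 * scale_sd
    g = float(np.clip(rng.normal(1.0, scale_sd), max(lo, 0.05), hi))
    root = np.sqrt(g)
    aj = (a + rng.normal(0.0, jitter_sd, a.size)) * root
    bj = (b + rng.normal(0.0, jitter_sd, b.size)) * root
    norm2 = aj**2 + bj**2
    shrink = np.where(norm2 > _LOADING_CAP, np.sqrt(_LOADING_CAP / norm2), 1.0)
    return aj * shrink, bj * shrink


@dataclass(frozen=True)
class GroupStructure:
    """Calibrated group loadings and the implied base correlation matrix.

    The raw loadings may exceed the per-channel variance cap: the capped
    subject-level draws then average out to the calibration targets.  The
    exposed base matrix always applies the cap, so it is a valid PD
    correlation matrix.
    """

    a: np.ndarray
    b: np.ndarray
    same_lobe: np.ndarray

    @property
    def corr(self) -> np.ndarray:
        norm2 = self.a**2 + self.b**2
        shrink = np.where(
            norm2 > _LOADING_CAP, np.sqrt(_LOADING_CAP / norm2), 1.0
        )
        return _corr_from_loadings(self.a * shrink, self.b * shrink, self.same_lobe)


def _apply_reserve(
    a: np.ndarray, b: np.ndarray, reserve_idx: np.ndarray, norm2_max: float
) -> tuple[np.ndarray, np.ndarray]:
    """Shrink loadings of selected channels so a^2 + b^2 <= norm2_max there.

    Channels carrying planted effect edges need idiosyncratic-variance
    headroom for the PD-safe entry edits; reserving it at the group level
    lets the calibration loop compensate elsewhere.
    """
    a = a.copy()
    b = b.copy()
    if reserve_idx.size:
        n2 = a[reserve_idx] ** 2 + b[reserve_idx] ** 2
        shrink = np.where(n2 > norm2_max, np.sqrt(norm2_max / np.maximum(n2, 1e-12)), 1.0)
        a[reserve_idx] *= shrink
        b[reserve_idx] *= shrink
    return a, b


def _group_loadings(
    montage: MontageSpec,
    mean_fc: float,
    within_fc: float,
    rng: np.random.Generator,
    scale_sd: float,
    jitter_sd: float,
    a_spread: float = 0.22,
    b_spread: float = 0.12,
    n_probe: int = 256,
    n_iter: int = 6,
    reserve_channels: tuple[int, ...] = (),
    reserve_norm2: float = 0.35,
) -> GroupStructure:
    """Group loadings calibrated so subject-expected connectivity hits targets.

    Within-lobe correlations centre on ``within_fc`` (the expected weight of
    the strongest edges) and between-lobe correlations on the level that
    makes the global off-diagonal mean equal ``mean_fc``.  Because the
    subject-level scale draw saturates high-connectivity channels at the
    loading cap, the calibration iterates against a probe sample of subject
    draws rather than trusting the closed-form means.
    """
    n = montage.n_channels
    same = _same_lobe_mask(montage)
    iu = np.triu_indices(n, 1)
    within_pairs = same[iu]
    n_total = len(iu[0])
    n_within = int(within_pairs.sum())
    n_between = n_total - n_within
    mu_between = (mean_fc * n_total - n_within * within_fc) / n_between
    if not 0 < mu_between < within_fc:
        raise ValueError(
            "connectivity targets are inconsistent: implied between-lobe "
            f"level {mu_between:.3f} outside (0, within target)"
        )
    a = np.abs(np.sqrt(mu_between) * (1.0 + a_spread * rng.standard_normal(n)))
    b = np.abs(
        np.sqrt(max(within_fc - mu_between, 1e-3))
        * (1.0 + b_spread * rng.standard_normal(n))
    )
    reserve_idx = np.array([c - 1 for c in reserve_channels], dtype=int)
    a, b = _apply_reserve(a, b, reserve_idx, reserve_norm2)
    probe_rng = np.random.default_rng(int(rng.integers(2**31)))
    lo, hi = max(1.0 - 2.0 * scale_sd, 0.05), 1.0 + 2.0 * scale_sd
    probe_g = np.clip(probe_rng.normal(1.0, scale_sd, n_probe), lo, hi)
    probe_jit = probe_rng.normal(0.0, jitter_sd, (n_probe, 2 * n))
    lobes = np.array([channel_lobe(i + 1) for i in range(n)])
    onehot = (lobes[:, None] == np.unique(lobes)[None, :]).astype(float)

    def probe_means(av: np.ndarray, bv: np.ndarray) -> tuple[float, float]:
        # vectorised over probe subjects; pair sums of products come from
        # lobe-wise loading sums: sum_{i<j} x_i x_j = (S^2 - sum x^2) / 2
        root = np.sqrt(probe_g)[:, None]
        ak = (av[None, :] + probe_jit[:, :n]) * root
        bk = (bv[None, :] + probe_jit[:, n:]) * root
        norm2 = ak**2 + bk**2
        shrink = np.where(norm2 > _LOADING_CAP, np.sqrt(_LOADING_CAP / norm2), 1.0)
        ak *= shrink
        bk *= shrink
        all_a = ((ak.sum(axis=1) ** 2 - (ak**2).sum(axis=1)) / 2.0).mean()
        sa_l = ak @ onehot
        qa_l = (ak**2) @ onehot
        within_a = ((sa_l**2 - qa_l) / 2.0).sum(axis=1).mean()
        sb_l = bk @ onehot
        qb_l = (bk**2) @ onehot
        within_b = ((sb_l**2 - qb_l) / 2.0).sum(axis=1).mean()
        between_mean = (all_a - within_a) / n_between
        within_mean = (within_a + within_b) / n_within
        return float(between_mean), float(within_mean)

    for _ in range(n_iter):
        between_hat, within_hat = probe_means(a, b)
        # the global factor's within-pair contribution is close to its
        # between-pair mean, so the probe split attributes the remainder to b
        bb_hat = max(within_hat - between_hat, 1e-6)
        bb_needed = within_fc - mu_between
        a = a * np.sqrt(np.clip(mu_between / max(between_hat, 1e-6), 0.25, 4.0))
        if bb_needed > 1e-4:
            b = b * np.sqrt(np.clip(bb_needed / bb_hat, 0.25, 4.0))
        a, b = _apply_reserve(a, b, reserve_idx, reserve_norm2)
    # Base loadings may exceed the per-channel cap: they are calibrated so the
    # capped subject-level draws average out to the targets.  The cap is
    # applied in _draw_subject_loadings and when exposing the base matrix.
    return GroupStructure(a=a, b=b, same_lobe=same)


def group_base_correlation(
    montage: MontageSpec,
    mean_fc: float,
    within_fc: float,
    rng: np.random.Generator,
    scale_sd: float = 0.25,
    jitter_sd: float = 0.04,
) -> tuple[np.ndarray, bool]:
    """Group base correlation matrix (positive definite by construction)."""
    structure = _group_loadings(
        montage, mean_fc, within_fc, rng, scale_sd, jitter_sd
    )
    return structure.corr, False


def _edge_index(edge: tuple[int, int]) -> tuple[int, int]:
    i, j = edge
    return i - 1, j - 1


# ---------------------------------------------------------------------------
# Signal generation
# ---------------------------------------------------------------------------


def simulate_hemodynamics(
    cov: GroundTruthNetwork | np.ndarray,
    n_samples: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
    lowpass_hz: float | None = None,
    sampling_rate: float = 11.0,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Zero-mean Gaussian series with population covariance ``amplitude^2 * cov``.

    With ``lowpass_hz`` set, a zero-phase low-pass shapes each channel into
    the hemodynamic band; the same filter acts on every channel, so the
    cross-channel correlation structure is preserved, and channels are
    rescaled so their sample SD equals ``amplitude`` times the target SD.
    Deterministic given the seed.
    """
    c = cov.corr if isinstance(cov, GroundTruthNetwork) else np.asarray(cov, float)
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    try:
        chol = np.linalg.cholesky(c)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance matrix is not positive definite") from err
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if lowpass_hz is not None:
        # simulate with padding and keep the interior: the zero-phase
        # low-pass would otherwise leave boundary transients (nearly
        # unfiltered noise) at the record edges
        pad = int(round(20.0 * sampling_rate))
        x = rng.standard_normal((n_samples + 2 * pad, c.shape[0])) @ chol.T
        sos = sps.butter(4, lowpass_hz / (sampling_rate / 2.0), "lowpass", output="sos")
        x = sps.sosfiltfilt(sos, x, axis=0)[pad: pad + n_samples]
        sd = x.std(axis=0, ddof=0)
        target = np.sqrt(np.diag(c))
        x = x / np.where(sd > 0, sd, 1.0) * target
    else:
        x = rng.standard_normal((n_samples, c.shape[0])) @ chol.T
    return x * amplitude


def add_noise_and_artifacts(
    signals: np.ndarray,
    noise: NoiseSpec,
    seed: int | np.random.SeedSequence | np.random.Generator,
    sampling_rate: float = 11.0,
) -> tuple[np.ndarray, list[ArtifactEvent]]:
    """Contaminate concentration series with physiological noise and motion.

    Adds per-channel random-phase sinusoids (cardiac, respiratory, Mayer),
    a random-walk drift, white noise, and randomly placed spike (1-3 sample)
    and baseline-shift artifacts; returns the contaminated copy and the
    ground-truth event log.  An all-zero NoiseSpec is the identity.
    """
    x = np.asarray(signals, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input signals must be finite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise.is_null:
        return x.copy(), []
    n_t, n_ch = x.shape
    out = x.copy()
    t = np.arange(n_t) / sampling_rate
    for freq, amp in (noise.cardiac, noise.respiratory, noise.mayer):
        if amp > 0:
            phase = rng.uniform(0, 2 * np.pi, n_ch)
            out += amp * np.sin(2 * np.pi * freq * t[:, None] + phase[None, :])
    if noise.drift_scale > 0:
        out += np.cumsum(rng.normal(0.0, noise.drift_scale, (n_t, n_ch)), axis=0)
    if noise.white_sd > 0:
        out += rng.normal(0.0, noise.white_sd, (n_t, n_ch))
    events: list[ArtifactEvent] = []
    if noise.artifact_rate > 0 and noise.artifact_amplitude > 0:
        n_events = rng.poisson(noise.artifact_rate * n_t / sampling_rate / 60.0)
        for _ in range(n_events):
            ch = int(rng.integers(0, n_ch))
            sign = float(rng.choice([-1.0, 1.0]))
            size = float(noise.artifact_amplitude * rng.uniform(0.5, 1.5))
            if rng.random() < 0.6:
                start = int(rng.integers(0, n_t - 3))
                width = int(rng.integers(1, 4))
                stop = start + width
                out[start:stop, ch] += sign * size
                events.append(ArtifactEvent("spike", ch + 1, start, stop, sign * size))
            else:
                start = int(rng.integers(1, n_t - 1))
                shift = 0.6 * sign * size
                out[start:, ch] += shift
                events.append(ArtifactEvent("shift", ch + 1, start, n_t, shift))
    return out, events


def hemoglobin_to_intensity(
    hbo: HemoglobinSeries | np.ndarray,
    hbr: np.ndarray | None = None,
    montage: MontageSpec | None = None,
    dpf: tuple[float, float] = DEFAULT_DPF,
    baseline_intensity: tuple[float, float] = (1.0, 1.0),
    sampling_rate: float = 11.0,
    subject_id: str = "",
    session: str = "",
) -> RawIntensityRecording:
    """Forward modified Beer-Lambert map: concentrations to raw intensities.

    For each wavelength, dOD = (eps_HbO * dC_HbO + eps_HbR * dC_HbR) * L * DPF
    and I = I0 * 10^(-dOD).  Exact inverse of ``preprocess.mbll_convert`` up
    to floating-point tolerance.
    """
    if isinstance(hbo, HemoglobinSeries):
        series = hbo
        hbo_arr, hbr_arr = series.hbo, series.hbr
        montage = montage or series.montage
        sampling_rate = series.sampling_rate
        subject_id = subject_id or series.subject_id
        session = session or series.session
    else:
        hbo_arr = np.asarray(hbo, dtype=float)
        if hbr is None:
            raise ValueError("hbr required when hbo is a bare array")
        hbr_arr = np.asarray(hbr, dtype=float)
    if montage is None:
        montage = build_montage()
    i0 = np.asarray(baseline_intensity, dtype=float)
    if np.any(i0 <= 0):
        raise ValueError("baseline intensity must be positive")
    m = mbll_system_matrix(montage, dpf)  # validates extinction matrix and DPF
    conc = np.stack([hbo_arr, hbr_arr], axis=-1)  # (t, ch, 2)
    od = conc @ m.T  # (t, ch, wavelength)
    intensity = i0[None, None, :] * 10.0 ** (-od)
    return RawIntensityRecording(
        subject_id=subject_id,
        session=session,
        data=intensity,
        sampling_rate=sampling_rate,
        montage=montage,
    )


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


def _sample_t1_scores(group: str, rng: np.random.Generator) -> tuple[int, int]:
    """Baseline (GAD-7, PHQ-9) honouring the screening rules by construction.

    Anxiety groups draw GAD-7 as 5 + lognormal excess (right-skewed, since
    the group mean sits close to the screening floor), controls as a normal
    clipped below 5.
    """
    if group == "MT":
        gad = 5 + rng.lognormal(-0.067, 1.31)
        phq = rng.normal(10.03, 3.84)
    elif group == "WL":
        gad = 5 + rng.lognormal(-0.116, 1.27)
        phq = rng.normal(11.15, 4.30)
    else:
        gad = np.clip(rng.normal(2.50, 1.47), 0, 4.49)
        phq = rng.normal(3.20, 1.98)
    gad_i = int(np.clip(round(float(gad)), 5 if group != "HC" else 0,
                        21 if group != "HC" else 4))
    phq_i = int(np.clip(round(float(phq)), 0, 27))
    return gad_i, phq_i


_DELTA_PARAMS = {  # (mean, sd) of (GAD-7, PHQ-9) change per group
    "MT": ((-1.97, 2.15), (-4.19, 3.62)),
    "WL": ((0.72, 4.60), (-1.28, 2.87)),
    "HC": ((0.0, 1.0), (0.0, 1.0)),
}


def _subject_session_correlations(
    structure: GroupStructure,
    group: str,
    effect: EffectSpec,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Per-subject T1/T2 correlation matrices with planted paired structure.

    The subject keeps one connectivity scale, one loading-jitter draw and one
    set of effect-edge baselines across both sessions; only a small
    session-specific loading wobble and (for treated subjects) the planted
    effect differ between T1 and T2.  The effect edges are set by direct
    entry surgery, so a mild eigenvalue repair may fire there; repairs are
    counted and returned.
    """
    a_s, b_s = _draw_subject_loadings(
        structure.a, structure.b, rng, spec.subject_scale_sd, spec.subject_jitter_sd
    )
    edge_base = np.array(
        [bl + rng.normal(0.0, effect.edge_sd) for bl in effect.baseline_r]
    )
    deltas = np.array(
        [
            d + rng.normal(0.0, effect.delta_sd) if group == "MT" else 0.0
            for d in effect.delta_r
        ]
    )
    repairs = 0
    mats = []
    for session_idx in range(2):
        a_t, b_t = a_s, b_s
        if spec.session_jitter_sd > 0:
            a_t = a_s + rng.normal(0.0, spec.session_jitter_sd, a_s.size)
            b_t = b_s + rng.normal(0.0, spec.session_jitter_sd, b_s.size)
            norm2 = a_t**2 + b_t**2
            shrink = np.where(
                norm2 > _LOADING_CAP, np.sqrt(_LOADING_CAP / norm2), 1.0
            )
            a_t, b_t = a_t * shrink, b_t * shrink
        r = _corr_from_loadings(a_t, b_t, structure.same_lobe)
        # Effect edges are planted as rank-1 "edge factors": moving entry
        # (i, j) by delta stays positive definite as long as both channels
        # keep |delta| of idiosyncratic variance in reserve, so the edit
        # never needs a global eigenvalue repair.  When headroom runs out
        # the delta is clipped and counted as a repair event.
        room = _LOADING_CAP - (a_t**2 + b_t**2)
        for k, edge in enumerate(effect.edges):
            i, j = _edge_index(edge)
            value = float(np.clip(
                edge_base[k] + (deltas[k] if session_idx == 1 else 0.0),
                -0.95, 0.95,
            ))
            want = value - r[i, j]
            allowed = max(min(room[i], room[j]), 0.0)
            move = float(np.clip(want, -allowed, allowed))
            if abs(want) > allowed + 1e-12:
                repairs += 1
            r[i, j] = r[j, i] = r[i, j] + move
            room[i] -= abs(move)
            room[j] -= abs(move)
        mats.append(r)
    return mats[0], mats[1], deltas, repairs


def _coupled_gad_deltas(
    realized_dfc: np.ndarray,
    rho_target: float,
    mean: float,
    sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """GAD-7 changes rank-coupled (Gaussian copula) to connectivity changes.

    The copula Pearson parameter 2*sin(pi*rho_s/6) yields the target Spearman
    rho between the latent variables; rounding to integer scores attenuates
    it only marginally.
    """
    n = len(realized_dfc)
    ranks = rankdata(realized_dfc)
    z_d = norm.ppf((ranks - 0.5) / n)
    rho_p = 2.0 * np.sin(np.pi * rho_target / 6.0)
    z_g = rho_p * z_d + np.sqrt(1.0 - rho_p**2) * rng.standard_normal(n)
    return mean + sd * z_g


def simulate_cohort(spec: CohortSpec) -> CohortBundle:
    """Generate the full cohort: recordings at T1/T2, subjects, ground truth.

    Treated subjects' T2 correlation matrices carry the planted effect-edge
    reductions; WL and HC carry none.  GAD-7 change in the treated group is
    drawn with a negative monotone coupling to each subject's realized clean
    connectivity change on the coupling edge.  Reproducible bit-for-bit from
    ``spec.master_seed``.
    """
    montage = build_montage()
    root = np.random.SeedSequence(spec.master_seed)
    group_ss, subject_master_ss, score_ss = root.spawn(3)

    group_truth: dict[str, GroundTruthNetwork] = {}
    structures: dict[str, GroupStructure] = {}
    pd_repairs = 0
    effect_channels = tuple(sorted({c for e in spec.effect.edges for c in e}))
    for g, ss in zip(GROUPS, group_ss.spawn(len(GROUPS))):
        structures[g] = _group_loadings(
            montage,
            spec.group_mean_fc[g],
            spec.group_within_fc[g],
            np.random.default_rng(ss),
            scale_sd=spec.subject_scale_sd,
            jitter_sd=spec.subject_jitter_sd,
            reserve_channels=effect_channels,
        )
        planted = tuple(
            (edge, d) for edge, d in zip(spec.effect.edges, spec.effect.delta_r)
        ) if g == "MT" else ()
        base_corr = structures[g].corr
        for edge, baseline in zip(spec.effect.edges, spec.effect.baseline_r):
            i, j = _edge_index(edge)
            base_corr[i, j] = base_corr[j, i] = baseline
        group_truth[g] = GroundTruthNetwork(base_corr, planted, False)

    roster = (
        [("MT", i) for i in range(spec.n_mt)]
        + [("WL", i) for i in range(spec.n_wl)]
        + [("HC", i) for i in range(spec.n_hc)]
    )
    subject_ss = subject_master_ss.spawn(len(roster))
    n_samples = int(round(spec.duration_s * montage.sampling_rate))

    recordings: dict[tuple[str, str], RawIntensityRecording | HemoglobinSeries] = {}
    artifact_log: dict[tuple[str, str], list[ArtifactEvent]] = {}
    subject_truth: dict[str, dict] = {}
    baseline_scores: dict[str, tuple[int, int]] = {}
    order: list[tuple[str, str, int]] = []  # (sid, group, seed)

    coupling_idx = (
        spec.effect.edges.index(spec.effect.coupling_edge)
        if spec.effect.edges and spec.effect.coupling_edge in spec.effect.edges
        else None
    )

    for (group, idx), ss in zip(roster, subject_ss):
        sid = f"{group}{idx + 1:02d}"
        rng = np.random.default_rng(ss)
        seed_int = int(ss.generate_state(1)[0] % (2**31))
        r1, r2, deltas, repairs = _subject_session_correlations(
            structures[group], group, spec.effect, spec, rng
        )
        pd_repairs += repairs
        clean_fc: dict[str, np.ndarray] = {}
        for session, r in (("T1", r1), ("T2", r2)):
            hbo = simulate_hemodynamics(
                r, n_samples, rng,
                lowpass_hz=spec.hemo_lowpass_hz,
                sampling_rate=montage.sampling_rate,
                amplitude=spec.hemo_amplitude,
            )
            sample_corr = np.corrcoef(hbo.T)
            clean_fc[session] = np.array(
                [sample_corr[_edge_index(e)] for e in spec.effect.edges]
            )
            if spec.optics:
                hbr = -0.33 * hbo + simulate_hemodynamics(
                    np.eye(montage.n_channels), n_samples, rng,
                    lowpass_hz=spec.hemo_lowpass_hz,
                    sampling_rate=montage.sampling_rate,
                    amplitude=0.25 * spec.hemo_amplitude,
                )
                hbo_noisy, events = add_noise_and_artifacts(
                    hbo, spec.noise, rng, montage.sampling_rate
                )
                hbr_noisy, _ = add_noise_and_artifacts(
                    hbr, spec.noise.scaled(0.35, artifact_rate=0.0),
                    rng, montage.sampling_rate,
                )
                recordings[(sid, session)] = hemoglobin_to_intensity(
                    hbo_noisy, hbr_noisy, montage,
                    sampling_rate=montage.sampling_rate,
                    subject_id=sid, session=session,
                )
                artifact_log[(sid, session)] = events
            else:
                # HbR carries no information downstream (connectivity uses
                # HbO only); the fast path uses the typical anticorrelated
                # proxy instead of simulating a second series
                hbr = -0.33 * hbo
                recordings[(sid, session)] = HemoglobinSeries(
                    hbo=hbo, hbr=hbr,
                    valid_mask=np.ones(montage.n_channels, dtype=bool),
                    sampling_rate=montage.sampling_rate,
                    montage=montage, subject_id=sid, session=session,
                )
                artifact_log[(sid, session)] = []
        subject_truth[sid] = {
            "group": group,
            "r_t1": r1,
            "r_t2": r2,
            "edge_deltas": deltas,
            "clean_edge_fc": clean_fc,
            "realized_dfc": (
                clean_fc["T2"] - clean_fc["T1"] if len(spec.effect.edges) else np.array([])
            ),
        }
        baseline_scores[sid] = _sample_t1_scores(group, rng)
        order.append((sid, group, seed_int))

    # Symptom changes: copula-coupled for treated subjects, independent draws
    # elsewhere; a dedicated seed stream keeps this stage deterministic.
    score_rng = np.random.default_rng(score_ss)
    mt_ids = [sid for sid, g, _ in order if g == "MT"]
    if coupling_idx is not None and mt_ids:
        dfc = np.array(
            [subject_truth[sid]["realized_dfc"][coupling_idx] for sid in mt_ids]
        )
        (gmean, gsd), _ = _DELTA_PARAMS["MT"]
        gad_deltas = _coupled_gad_deltas(
            dfc, spec.effect.coupling_rho, gmean, gsd, score_rng
        )
        mt_gad_delta = dict(zip(mt_ids, gad_deltas))
    else:
        (gmean, gsd), _ = _DELTA_PARAMS["MT"]
        mt_gad_delta = {
            sid: score_rng.normal(gmean, gsd) for sid in mt_ids
        }

    subjects: list[SubjectSpec] = []
    for sid, group, seed_int in order:
        gad1, phq1 = baseline_scores[sid]
        (gmean, gsd), (pmean, psd) = _DELTA_PARAMS[group]
        d_gad = mt_gad_delta[sid] if group == "MT" else score_rng.normal(gmean, gsd)
        d_phq = score_rng.normal(pmean, psd)
        gad2 = int(np.clip(round(gad1 + float(d_gad)), 0, 21))
        phq2 = int(np.clip(round(phq1 + float(d_phq)), 0, 27))
        subjects.append(
            SubjectSpec(sid, group, gad1, gad2, phq1, phq2, seed_int)
        )

    return CohortBundle(
        spec=spec,
        montage=montage,
        subjects=subjects,
        recordings=recordings,
        group_truth=group_truth,
        subject_truth=subject_truth,
        artifact_log=artifact_log,
        pd_repairs=pd_repairs,
    )
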