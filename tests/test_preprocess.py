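import numpy as np
import pytest
from dataclasses import replace

import nirsconn as nc
from nirsconn.preprocess import (
    OpticalDensitySeries,
    PreprocessConfig,
    RawIntensityRecording,
    bandpass,
    channel_cv,
    classify_channels,
    correct_motion,
    detect_flatline,
    intensity_to_od,
    mbll_convert,
    run_preprocessing,
    truncate_edges,
)

FS = 11.0


def _recording(montage, data):
    return RawIntensityRecording(
        subject_id="S", session="T1", data=data, sampling_rate=FS, montage=montage
    )


def _od(montage, data, fs=FS):
    n_ch = data.shape[1]
    return OpticalDensitySeries(
        data=data, baseline=np.ones((n_ch, 2)), sampling_rate=fs,
        montage=montage, valid_mask=np.ones(n_ch, dtype=bool),
    )


# ---------------------------------------------------------------------------
# optical density
# ---------------------------------------------------------------------------


def test_od_constant_channel_is_zero(montage):
    data = np.full((100, 48, 2), 5.0)
    od = intensity_to_od(_recording(montage, data))
    assert np.allclose(od.data, 0.0)


def test_od_decade_definition(montage):
    data = np.full((100, 48, 2), 1.0)
    data[50, 0, 0] = 0.1  # one decade below baseline
    od = intensity_to_od(_recording(montage, data), baseline_method="median")
    assert od.data[50, 0, 0] == pytest.approx(1.0, abs=1e-12)


def test_od_matches_log_ratio_oracle(montage, rng):
    data = rng.uniform(0.5, 2.0, (200, 48, 2))
    od = intensity_to_od(_recording(montage, data))
    i0 = data.mean(axis=0)
    expected = -np.log10(data / i0)
    assert np.abs(od.data - expected).max() < 1e-12


def test_od_masks_nonpositive_channel_instead_of_crashing(montage, rng):
    data = rng.uniform(0.5, 2.0, (100, 48, 2))
    data[10, 3, 1] = -0.1
    od = intensity_to_od(_recording(montage, data))
    assert not od.valid_mask[3]
    assert np.all(od.data[:, 3, :] == 0)
    assert od.valid_mask.sum() == 47


# ---------------------------------------------------------------------------
# CV quality control
# ---------------------------------------------------------------------------


def test_cv_two_point_hand_computation(montage):
    data = np.full((2, 48, 2), 10.0)
    data[:, 0, 0] = [9.0, 11.0]  # mean 10, sample SD sqrt(2)
    cv = channel_cv(_recording(montage, data))
    assert cv[0, 0] == pytest.approx(100 * np.sqrt(2) / 10, abs=1e-9)
    assert cv[1, 0] == 0.0


def test_cv_scale_invariance(montage, rng):
    data = rng.uniform(1.0, 2.0, (50, 48, 2))
    cv1 = channel_cv(_recording(montage, data))
    cv2 = channel_cv(_recording(montage, 7.5 * data))
    assert np.allclose(cv1, cv2)


@pytest.mark.parametrize(
    "cv, expected",
    [(5.0, "optimal"), (5.01, "borderline"), (20.0, "borderline"),
     (20.01, "excluded"), (0.0, "optimal")],
)
def test_cv_class_boundaries(cv, expected):
    cvw = np.zeros((48, 2))
    cvw[0, :] = cv
    report = classify_channels(cvw)
    assert report.classes[0] == expected


def test_participant_exclusion_at_10_of_48_channels():
    cvw = np.zeros((48, 2))
    cvw[:10, 0] = 25.0  # 10 channels excluded -> 38/48 = 0.792 < 0.8
    report = classify_channels(cvw)
    assert report.valid_fraction == pytest.approx(38 / 48)
    assert not report.participant_valid


def test_all_clean_channels_keep_participant():
    report = classify_channels(np.zeros((48, 2)))
    assert report.participant_valid
    assert all(c == "optimal" for c in report.classes)


def test_artifact_flag_forces_exclusion():
    report = classify_channels(np.zeros((48, 2)), artifact_flags={5: ["flatline"]})
    assert report.classes[4] == "excluded"
    assert 5 in report.excluded_channels


# ---------------------------------------------------------------------------
# motion correction
# ---------------------------------------------------------------------------


def _sinusoid_od(montage, amp=0.02, freq=0.05, n=2200):
    t = np.arange(n) / FS
    x = amp * np.sin(2 * np.pi * freq * t)
    data = np.tile(x[:, None, None], (1, 48, 2))
    return _od(montage, data)


def test_motion_noop_on_clean_sinusoid(montage):
    od = _sinusoid_od(montage)
    corrected, segments = correct_motion(od)
    assert segments == {}
    assert np.array_equal(corrected.data, od.data)


def test_motion_removes_planted_spike(montage):
    od = _sinusoid_od(montage)
    od.data[1100:1102, 7, :] += 1.0  # 1 OD spike
    corrected, segments = correct_motion(od)
    assert 8 in segments
    residual = corrected.data[:, 7, 0] - _sinusoid_od(montage).data[:, 7, 0]
    assert np.abs(residual).max() < 0.1


def test_motion_amplitude_rule_thresholds(montage):
    # 0.6 OD step exceeds the 0.5 OD amplitude rule
    od = _sinusoid_od(montage)
    od.data[1100:, 3, :] += 0.6
    _, segments = correct_motion(od, std_thresh=np.inf)
    assert 4 in segments
    # 0.1 OD step does not trip the amplitude rule
    od2 = _sinusoid_od(montage)
    od2.data[1100:, 3, :] += 0.1
    _, segments2 = correct_motion(od2, std_thresh=np.inf)
    assert 4 not in segments2


def test_motion_realigns_baseline_shift(montage):
    od = _sinusoid_od(montage)
    od.data[1100:, 5, :] += 0.8
    corrected, segments = correct_motion(od)
    assert 6 in segments  # 1-based channel keys
    residual = corrected.data[:, 5, 0] - _sinusoid_od(montage).data[:, 5, 0]
    # the step level is removed, not merely bridged
    assert np.abs(residual[1300:]).max() < 0.1


def test_motion_never_inflates_variance_on_clean_noise(montage, rng):
    data = 0.01 * rng.standard_normal((2200, 48, 2))
    data = bandpass(data, FS, 0.01, 0.2)
    od = _od(montage, data)
    corrected, _ = correct_motion(od)
    assert np.all(
        corrected.data.var(axis=0) <= od.data.var(axis=0) + 1e-15
    )


def test_motion_masks_channel_overwhelmed_by_artifact(montage, rng):
    data = 0.005 * rng.standard_normal((2200, 48, 2))
    # alternating large steps over >50% of the record
    data[::7, 9, :] += 2.0
    od = _od(montage, data)
    corrected, segments = correct_motion(od)
    assert not corrected.valid_mask[9]


# ---------------------------------------------------------------------------
# band-pass filter
# ---------------------------------------------------------------------------


def _probe(freq, n=3300):
    t = np.arange(n) / FS
    return np.sin(2 * np.pi * freq * t)


def test_bandpass_attenuates_cardiac_band():
    x = _probe(1.0)
    y = bandpass(x[:, None], FS)[:, 0]
    assert np.sqrt((y**2).mean()) <= 0.1 * np.sqrt((x**2).mean())


def test_bandpass_preserves_passband():
    x = _probe(0.05)
    y = bandpass(x[:, None], FS)[:, 0]
    assert abs(np.sqrt((y**2).mean()) / np.sqrt((x**2).mean()) - 1) < 0.12


def test_bandpass_removes_dc():
    y = bandpass(np.ones((3300, 1)), FS)[:, 0]
    assert np.abs(y).max() < 1e-6


def test_bandpass_is_zero_phase():
    x = _probe(0.05)
    y = bandpass(x[:, None], FS)[:, 0]
    lags = np.arange(-10, 11)
    cc = [np.corrcoef(x[20:-20], y[20 + l: len(x) - 20 + l])[0, 1] for l in lags]
    assert lags[int(np.argmax(cc))] == 0


def test_bandpass_rejects_cutoffs_beyond_nyquist():
    with pytest.raises(ValueError, match="Nyquist"):
        bandpass(np.zeros((100, 1)), FS, low=0.01, high=6.0)


# ---------------------------------------------------------------------------
# truncation
# ---------------------------------------------------------------------------


def test_truncation_arithmetic():
    x = np.zeros((3300, 48))
    assert truncate_edges(x, FS, 10, 10).shape[0] == 3080


def test_truncation_identity_and_guard():
    x = np.zeros((100, 2))
    assert truncate_edges(x, FS, 0, 0).shape[0] == 100
    with pytest.raises(ValueError, match="shorter than truncation"):
        truncate_edges(np.zeros((165, 2)), FS, 10, 10)  # 15 s recording


# ---------------------------------------------------------------------------
# MBLL
# ---------------------------------------------------------------------------


def test_mbll_zero_od_gives_zero_concentration(montage):
    od = _od(montage, np.zeros((50, 48, 2)))
    hb = mbll_convert(od, montage)
    assert np.allclose(hb.hbo, 0) and np.allclose(hb.hbr, 0)


def test_mbll_linearity(montage, rng):
    od1 = rng.normal(size=(50, 48, 2))
    od2 = rng.normal(size=(50, 48, 2))
    a, b = 1.7, -0.4
    h1 = mbll_convert(_od(montage, od1), montage)
    h2 = mbll_convert(_od(montage, od2), montage)
    h12 = mbll_convert(_od(montage, a * od1 + b * od2), montage)
    assert np.abs(h12.hbo - (a * h1.hbo + b * h2.hbo)).max() < 1e-10


def test_mbll_wavelength_permutation_symmetry(montage, rng):
    od = rng.normal(size=(50, 48, 2))
    swapped_montage = replace(
        montage, wavelengths=(montage.wavelengths[1], montage.wavelengths[0])
    )
    h = mbll_convert(_od(montage, od), montage)
    h_swapped = mbll_convert(_od(montage, od[:, :, ::-1]), swapped_montage)
    assert np.allclose(h.hbo, h_swapped.hbo, atol=1e-12)
    assert np.allclose(h.hbr, h_swapped.hbr, atol=1e-12)


def test_unknown_wavelength_rejected(montage):
    bad = replace(montage, wavelengths=(500.0, 850.0))
    with pytest.raises(ValueError, match="extinction"):
        mbll_convert(_od(montage, np.zeros((10, 48, 2))), bad)


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------


def test_chain_happy_path(clean_recording):
    _, rec = clean_recording
    hb, report = run_preprocessing(rec)
    assert report.participant_valid
    assert hb.valid_mask.sum() == 48
    assert np.all(np.isfinite(hb.hbo))
    assert hb.hbo.shape[0] == rec.n_samples - 220  # 2 x 10 s trimmed


def test_chain_masks_planted_noisy_channel(clean_recording, rng):
    _, rec = clean_recording
    data = rec.data.copy()
    data[:, 17, :] *= rng.uniform(0.5, 1.5, (rec.n_samples, 1))  # CV >> 20%
    noisy = RawIntensityRecording(
        subject_id="S", session="T1", data=data,
        sampling_rate=rec.sampling_rate, montage=rec.montage,
    )
    hb, report = run_preprocessing(noisy)
    assert report.classes[17] == "excluded"
    assert not hb.valid_mask[17]
    m = nc.compute_fc(hb)
    assert np.all(np.isnan(m.r[17, :18]))  # masked channels propagate


def test_chain_excludes_flatlined_participant(montage):
    data = np.full((1400, 48, 2), 3.0)  # every channel dead flat
    rec = RawIntensityRecording(
        subject_id="S", session="T1", data=data,
        sampling_rate=FS, montage=montage,
    )
    hb, report = run_preprocessing(rec)
    assert all(c == "excluded" for c in report.classes)
    assert not report.participant_valid


def test_flatline_detector_on_partial_flat(montage, rng):
    data = 1.0 + 0.01 * rng.standard_normal((1400, 48, 2))
    data[:, 5, :] = 1.0  # one dead channel
    rec = RawIntensityRecording(
        subject_id="S", session="T1", data=data, sampling_rate=FS,
        montage=montage,
    )
    flat = detect_flatline(rec)
    assert flat[5] and flat.sum() == 1


def test_preprocess_config_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(cv_optimal=25.0)
    with pytest.raises(ValueError):
        PreprocessConfig(band=(0.2, 0.1))
    with pytest.raises(ValueError):
        PreprocessConfig(baseline_method="mode")
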