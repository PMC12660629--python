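"""File formats, configuration and the run manifest.

Recordings travel either as an SNIRF-style HDF5 subset (``/nirs/data1``
intensity block plus ``/nirs/probe`` geometry, SNIRF v1.0 naming) or as
long-format CSV with columns ``subject, session, channel, wavelength, t,
intensity``.  Matrices and result tables are written as TSV/CSV with 1-based
channel headers and "i-j" pair labels so they can be compared directly with
published channel-pair tables.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .cohort import CohortSpec, EffectSpec, NoiseSpec
from .connectivity import BinaryNetwork, ConnectivityMatrix
from .montage import MontageSpec, build_montage
from .preprocess import HemoglobinSeries, PreprocessConfig, RawIntensityRecording

FORMAT_VERSION = "1.0"


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Validated parameters for a full pipeline run.

    ``seed`` overrides the cohort's master seed so a single integer controls
    every source of randomness.  The resolved configuration is serialised
    next to the outputs for reproducibility.
    """

    cohort: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    sparsity: float = 0.3
    q_threshold: float = 0.05
    edge_test_mode: str = "t"  # "t" | "wilcoxon"
    montage_name: str = "whole_head_48"
    seed: int | None = None
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not 0 < self.sparsity <= 1:
            raise ValueError("sparsity must lie in (0, 1]")
        if not 0 < self.q_threshold < 1:
            raise ValueError("q threshold must lie in (0, 1)")
        if self.edge_test_mode not in ("t", "wilcoxon"):
            raise ValueError(f"unknown edge test mode {self.edge_test_mode!r}")
        if self.seed is not None:
            self.cohort = dataclasses.replace(self.cohort, master_seed=int(self.seed))

    def to_dict(self) -> dict:
        def undata(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: undata(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: undata(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [undata(v) for v in obj]
            return obj

        return undata(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload or {})
        cohort_d = dict(payload.pop("cohort", {}) or {})
        if "noise" in cohort_d and isinstance(cohort_d["noise"], dict):
            cohort_d["noise"] = NoiseSpec(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in cohort_d["noise"].items()
            })
        if "effect" in cohort_d and isinstance(cohort_d["effect"], dict):
            eff = {
                k: tuple(tuple(e) if isinstance(e, list) else e for e in v)
                if isinstance(v, list) else v
                for k, v in cohort_d["effect"].items()
            }
            cohort_d["effect"] = EffectSpec(**eff)
        pre_d = dict(payload.pop("preprocess", {}) or {})
        for key in ("band", "dpf"):
            if key in pre_d and isinstance(pre_d[key], list):
                pre_d[key] = tuple(pre_d[key])
        return cls(
            cohort=CohortSpec(**cohort_d),
            preprocess=PreprocessConfig(**pre_d),
            **payload,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def save_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Machine-readable record of a run: stages, exclusions, provenance."""

    seed: int | None = None
    software_version: str = "nirsconn 0.1.0"
    stages: list[dict] = field(default_factory=list)
    exclusions: list[dict] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def start_stage(self, name: str) -> float:
        return time.perf_counter()

    def end_stage(self, name: str, t0: float, **info) -> None:
        self.stages.append(
            {"stage": name, "seconds": round(time.perf_counter() - t0, 3), **info}
        )

    def exclude(self, subject_id: str, reason_code: str, **detail) -> None:
        self.exclusions.append(
            {"subject_id": subject_id, "reason_code": reason_code, **detail}
        )

    def warn(self, code: str, **detail) -> None:
        self.events.append({"code": code, **detail})

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


# ---------------------------------------------------------------------------
# Recording IO
# ---------------------------------------------------------------------------


def write_recording_csv(rec: RawIntensityRecording, path: str | Path) -> None:
    """Long-format CSV: subject, session, channel, wavelength, t, intensity."""
    n_t, n_ch, n_wl = rec.data.shape
    t = np.arange(n_t) / rec.sampling_rate
    frames = []
    for ch in range(n_ch):
        for k in range(n_wl):
            frames.append(pd.DataFrame({
                "subject": rec.subject_id, "session": rec.session,
                "channel": ch + 1, "wavelength": rec.montage.wavelengths[k],
                "t": t, "intensity": rec.data[:, ch, k],
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_recording_csv(
    path: str | Path, montage: MontageSpec | None = None
) -> RawIntensityRecording:
    frame = pd.read_csv(path)
    for col in ("subject", "session", "channel", "wavelength", "t", "intensity"):
        if col not in frame.columns:
            raise ValueError(f"recording CSV is missing the {col!r} column")
    montage = montage or build_montage()
    wavelengths = np.sort(frame["wavelength"].unique())
    if len(wavelengths) != 2:
        raise ValueError("exactly two wavelengths required")
    times = np.sort(frame["t"].unique())
    n_t = len(times)
    dt = np.median(np.diff(times)) if n_t > 1 else 1.0
    fs = 1.0 / dt
    data = np.empty((n_t, montage.n_channels, 2))
    pivot = frame.pivot_table(
        index="t", columns=["channel", "wavelength"], values="intensity"
    ).sort_index()
    for ch in range(montage.n_channels):
        for k, wl in enumerate(wavelengths):
            data[:, ch, k] = pivot[(ch + 1, wl)].to_numpy()
    return RawIntensityRecording(
        subject_id=str(frame["subject"].iloc[0]),
        session=str(frame["session"].iloc[0]),
        data=data,
        sampling_rate=float(fs),
        montage=montage,
    )


def write_snirf(rec: RawIntensityRecording, path: str | Path) -> None:
    """Minimal SNIRF v1.0-style container: intensity block + probe geometry."""
    n_t, n_ch, n_wl = rec.data.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=FORMAT_VERSION)
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject_id)
        meta.create_dataset("SessionID", data=rec.session)
        meta.create_dataset("LengthUnit", data="cm")
        data1 = nirs.create_group("data1")
        flat = rec.data.reshape(n_t, n_ch * n_wl)  # channel-major, wl minor
        data1.create_dataset("dataTimeSeries", data=flat)
        data1.create_dataset("time", data=np.arange(n_t) / rec.sampling_rate)
        for col in range(n_ch * n_wl):
            ch, k = divmod(col, n_wl)
            ml = data1.create_group(f"measurementList{col + 1}")
            ml.create_dataset("sourceIndex", data=rec.montage.channels[ch].source)
            ml.create_dataset("detectorIndex", data=rec.montage.channels[ch].detector)
            ml.create_dataset("wavelengthIndex", data=k + 1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.montage.wavelengths))
        if rec.montage.source_pos:
            probe.create_dataset("sourcePos2D", data=np.asarray(rec.montage.source_pos))
        if rec.montage.detector_pos:
            probe.create_dataset(
                "detectorPos2D", data=np.asarray(rec.montage.detector_pos)
            )


def read_snirf(
    path: str | Path, montage: MontageSpec | None = None
) -> RawIntensityRecording:
    montage = montage or build_montage()
    with h5py.File(path, "r") as f:
        wavelengths = np.asarray(f["nirs/probe/wavelengths"])
        if len(wavelengths) != 2:
            raise ValueError("exactly two wavelengths required")
        flat = np.asarray(f["nirs/data1/dataTimeSeries"])
        t = np.asarray(f["nirs/data1/time"])
        if flat.shape[1] != montage.n_channels * 2:
            raise ValueError(
                f"expected {montage.n_channels * 2} measurement columns, "
                f"got {flat.shape[1]}"
            )
        # verify the measurement list matches the montage's channel ordering
        for col in range(flat.shape[1]):
            ch, k = divmod(col, 2)
            ml = f[f"nirs/data1/measurementList{col + 1}"]
            src = int(np.asarray(ml["sourceIndex"]))
            det = int(np.asarray(ml["detectorIndex"]))
            expect = montage.channels[ch]
            if (src, det) != (expect.source, expect.detector):
                raise ValueError(
                    f"measurement column {col + 1} maps to optode pair "
                    f"{src}-{det}, montage expects {expect.source}-{expect.detector}"
                )
        meta = f["nirs/metaDataTags"]
        subject = meta["SubjectID"][()]
        session = meta["SessionID"][()]
    subject = subject.decode() if isinstance(subject, bytes) else str(subject)
    session = session.decode() if isinstance(session, bytes) else str(session)
    fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    data = flat.reshape(len(t), montage.n_channels, 2)
    return RawIntensityRecording(
        subject_id=subject, session=session, data=data,
        sampling_rate=fs, montage=montage,
    )


def read_recording(
    path: str | Path, montage: MontageSpec | None = None
) -> RawIntensityRecording:
    """Dispatch on extension: .snirf/.h5 HDF5 subset, otherwise CSV."""
    p = Path(path)
    if p.suffix.lower() in (".snirf", ".h5", ".hdf5"):
        return read_snirf(p, montage)
    return read_recording_csv(p, montage)


# ---------------------------------------------------------------------------
# Hemoglobin / matrix / table IO
# ---------------------------------------------------------------------------


def write_hemoglobin_csv(hb: HemoglobinSeries, path: str | Path) -> None:
    """Long-format CSV: t, channel, hbo, hbr, valid."""
    n_t, n_ch = hb.hbo.shape
    t = np.arange(n_t) / hb.sampling_rate
    frames = [
        pd.DataFrame({
            "t": t, "channel": ch + 1,
            "hbo": hb.hbo[:, ch], "hbr": hb.hbr[:, ch],
            "valid": bool(hb.valid_mask[ch]),
        })
        for ch in range(n_ch)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_hemoglobin_csv(
    path: str | Path, montage: MontageSpec | None = None,
    subject_id: str = "", session: str = "",
) -> HemoglobinSeries:
    frame = pd.read_csv(path)
    montage = montage or build_montage()
    times = np.sort(frame["t"].unique())
    n_t = len(times)
    hbo = np.empty((n_t, montage.n_channels))
    hbr = np.empty((n_t, montage.n_channels))
    valid = np.ones(montage.n_channels, dtype=bool)
    for ch, sub in frame.groupby("channel"):
        sub = sub.sort_values("t")
        hbo[:, int(ch) - 1] = sub["hbo"].to_numpy()
        hbr[:, int(ch) - 1] = sub["hbr"].to_numpy()
        valid[int(ch) - 1] = bool(sub["valid"].iloc[0])
    fs = 1.0 / float(np.median(np.diff(times))) if n_t > 1 else 1.0
    return HemoglobinSeries(
        hbo=hbo, hbr=hbr, valid_mask=valid, sampling_rate=fs,
        montage=montage, subject_id=subject_id, session=session,
    )


def write_matrix_tsv(m: ConnectivityMatrix, path: str | Path) -> None:
    """48 x 48 TSV with 1-based channel headers (r values, NaN for masked)."""
    labels = [str(i + 1) for i in range(m.n_channels)]
    pd.DataFrame(m.r, index=labels, columns=labels).to_csv(path, sep="\t")


def read_matrix_tsv(
    path: str | Path, subject_id: str = "", session: str = ""
) -> ConnectivityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    r = frame.to_numpy(dtype=float)
    valid = ~np.all(np.isnan(r - np.diag(np.diag(r))) | np.eye(len(r), dtype=bool),
                    axis=1)
    z = np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7))
    np.fill_diagonal(z, 0.0)
    z[np.isnan(r)] = np.nan
    return ConnectivityMatrix(r=r, z=z, valid_mask=valid,
                              subject_id=subject_id, session=session)


def matrix_long_frame(
    m: ConnectivityMatrix, network: BinaryNetwork | None = None
) -> pd.DataFrame:
    """Long-format edge table: chan_i, chan_j, r, z, retained."""
    rows = []
    retained = set(network.pairs) if network is not None else set()
    n = m.n_channels
    for i in range(n):
        for j in range(i + 1, n):
            rows.append({
                "chan_i": i + 1, "chan_j": j + 1, "edge": f"{i + 1}-{j + 1}",
                "r": m.r[i, j], "z": m.z[i, j],
                "retained": (i, j) in retained,
            })
    return pd.DataFrame(rows)
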