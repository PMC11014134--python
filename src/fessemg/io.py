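"""Readers and writers for recordings, windows, images, features and metrics.

Formats:

* recordings - CSV (columns ``time_s, ch1..chN``) or HDF5 (one dataset per
  recording with labels, sampling rate, stimulation parameters and seed as
  attributes), plus a labels manifest CSV;
* windows - one HDF5 dataset per window with label attributes;
* time-frequency images - 8-bit RGB PNG plus a JSON sidecar carrying labels,
  method and axes;
* feature tables, predictions, training history - CSV via pandas;
* metrics - JSON and CSV.

HDF5 round-trips are bit-exact; CSV stores 9 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from PIL import Image

from .evaluation import ConfusionMatrix, MetricsReport
from .imaging import TFImage
from .preprocess import SignalWindow
from .simulate import RawRecording


# -- recordings -------------------------------------------------------------

def save_recording_csv(rec: RawRecording, path) -> None:
    n = rec.samples.shape[1]
    data = {"time_s": np.arange(n) / rec.sampling_rate_hz}
    for c in range(rec.n_channels):
        data[f"ch{c + 1}"] = rec.samples[c]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def load_recording_csv(path, sampling_rate_hz: float | None = None,
                       motion_label: str = "", fatigue_label: str = "",
                       stim_params=(0.0, 0.0, 0.0), seed: int = 0) -> RawRecording:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("ch")]
    if "time_s" not in df.columns or not cols:
        raise ValueError(
            f"{path}: expected columns 'time_s, ch1..chN', got {list(df.columns)}"
        )
    if sampling_rate_hz is None:
        dt = np.diff(df["time_s"].to_numpy()[:2])[0]
        sampling_rate_hz = 1.0 / dt
    return RawRecording(
        samples=df[cols].to_numpy().T.copy(),
        sampling_rate_hz=float(sampling_rate_hz),
        motion_label=motion_label, fatigue_label=fatigue_label,
        stim_params=tuple(stim_params), seed=seed,
        recording_id=Path(path).stem,
    )


def save_recordings_hdf5(recordings: list[RawRecording], path) -> None:
    with h5py.File(path, "w") as f:
        for i, rec in enumerate(recordings):
            rid = rec.recording_id or f"recording_{i:05d}"
            ds = f.create_dataset(rid, data=rec.samples)
            ds.attrs["sampling_rate_hz"] = rec.sampling_rate_hz
            ds.attrs["motion_label"] = rec.motion_label
            ds.attrs["fatigue_label"] = rec.fatigue_label
            ds.attrs["stim_params"] = list(rec.stim_params)
            ds.attrs["seed"] = rec.seed
            if rec.clean is not None:
                cds = f.create_dataset(rid + "__clean", data=rec.clean)
                cds.attrs["role"] = "ground_truth_clean"


def load_recordings_hdf5(path) -> list[RawRecording]:
    out = []
    with h5py.File(path, "r") as f:
        names = [k for k in f.keys() if not k.endswith("__clean")]
        for rid in sorted(names):
            ds = f[rid]
            required = ["sampling_rate_hz", "motion_label", "fatigue_label"]
            missing = [a for a in required if a not in ds.attrs]
            if missing:
                raise ValueError(f"{path}:{rid}: missing attributes {missing}")
            clean = f[rid + "__clean"][...] if rid + "__clean" in f else None
            out.append(RawRecording(
                samples=ds[...],
                sampling_rate_hz=float(ds.attrs["sampling_rate_hz"]),
                motion_label=str(ds.attrs["motion_label"]),
                fatigue_label=str(ds.attrs["fatigue_label"]),
                stim_params=tuple(ds.attrs.get("stim_params", (0.0, 0.0, 0.0))),
                seed=int(ds.attrs.get("seed", 0)),
                clean=clean,
                recording_id=rid,
            ))
    return out


def save_manifest(recordings: list[RawRecording], path) -> None:
    pd.DataFrame([{
        "recording_id": r.recording_id, "motion": r.motion_label,
        "fatigue": r.fatigue_label, "seed": r.seed,
    } for r in recordings]).to_csv(path, index=False)


def load_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"recording_id", "motion", "fatigue", "seed"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


# -- windows ----------------------------------------------------------------

def save_windows_hdf5(windows: list[SignalWindow], path) -> None:
    with h5py.File(path, "w") as f:
        for i, w in enumerate(windows):
            ds = f.create_dataset(f"window_{i:06d}", data=w.samples)
            ds.attrs.update({
                "channel_id": w.channel_id,
                "sampling_rate_hz": w.sampling_rate_hz,
                "start_time_s": w.start_time_s,
                "motion_label": w.motion_label,
                "fatigue_label": w.fatigue_label,
                "recording_id": w.recording_id,
            })


def load_windows_hdf5(path) -> list[SignalWindow]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            ds = f[name]
            out.append(SignalWindow(
                samples=ds[...],
                channel_id=int(ds.attrs["channel_id"]),
                sampling_rate_hz=float(ds.attrs["sampling_rate_hz"]),
                start_time_s=float(ds.attrs["start_time_s"]),
                motion_label=str(ds.attrs["motion_label"]),
                fatigue_label=str(ds.attrs["fatigue_label"]),
                recording_id=str(ds.attrs.get("recording_id", "")),
            ))
    return out


# -- images -----------------------------------------------------------------

def save_image_png(img: TFImage, path) -> None:
    path = Path(path)
    rgb = np.clip(np.round(img.pixels * 255), 0, 255).astype(np.uint8)
    Image.fromarray(rgb, mode="RGB").save(path)
    sidecar = {
        "method": img.method,
        "channel_id": img.channel_id,
        "motion_label": img.motion_label,
        "fatigue_label": img.fatigue_label,
        "recording_id": img.recording_id,
        "freq_axis_hz": [float(img.freq_axis[0]), float(img.freq_axis[-1])],
        "time_axis_s": [float(img.time_axis[0]), float(img.time_axis[-1])],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_image_png(path) -> TFImage:
    path = Path(path)
    rgb = np.asarray(Image.open(path).convert("RGB"), dtype=np.float64) / 255.0
    meta = json.loads(path.with_suffix(".json").read_text())
    lo_f, hi_f = meta["freq_axis_hz"]
    lo_t, hi_t = meta["time_axis_s"]
    return TFImage(
        pixels=rgb, method=meta["method"], channel_id=meta["channel_id"],
        motion_label=meta["motion_label"], fatigue_label=meta["fatigue_label"],
        freq_axis=np.linspace(lo_f, hi_f, rgb.shape[0]),
        time_axis=np.linspace(lo_t, hi_t, rgb.shape[1]),
        recording_id=meta.get("recording_id", ""),
    )


# -- features / predictions / metrics ---------------------------------------

def save_feature_table(rows: list[dict], path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def save_predictions(records: list[dict], path) -> None:
    pd.DataFrame(records).to_csv(path, index=False)


def load_labeled_column(path, column: str) -> np.ndarray:
    df = pd.read_csv(path)
    if column not in df.columns:
        raise ValueError(f"{path}: missing required column {column!r}")
    return df[column].to_numpy()


def save_metrics(report: MetricsReport, path_json, path_csv=None) -> None:
    Path(path_json).write_text(json.dumps(report.as_dict(), indent=1))
    if path_csv is not None:
        pd.DataFrame({
            "class": report.class_labels,
            "precision": report.precision,
            "recall": report.recall,
            "f1": report.f1,
        }).to_csv(path_csv, index=False, float_format="%.4f")


def save_confusion_csv(cm: ConfusionMatrix, path) -> None:
    pd.DataFrame(cm.matrix, index=cm.class_labels,
                 columns=cm.class_labels).to_csv(path, float_format="%.6g")


def load_confusion_csv(path, normalized: bool = False) -> ConfusionMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConfusionMatrix(matrix=df.to_numpy(dtype=float),
                           class_labels=list(df.columns), normalized=normalized)


def save_history_csv(history: list[dict], path) -> None:
    pd.DataFrame(history).to_csv(path, index=False)
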