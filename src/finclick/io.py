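"""File I/O: WAV audio, CSV tables, model persistence, YAML configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .detect import ClassifierModel, DetectorConfig
from .simulate import ScenarioConfig
from .types import AudioClip, ClickEvent, ClickTrain, SyntheticClick

__all__ = [
    "read_wav", "write_wav",
    "write_events_csv", "read_events_csv",
    "write_trains_csv", "write_density_csv", "read_density_csv",
    "write_truth_csv", "read_truth_csv",
    "save_model", "load_model",
    "save_config", "load_detector_config", "load_scenario_config",
]


# ---------------------------------------------------------------------------
# WAV
# ---------------------------------------------------------------------------

def read_wav(path) -> AudioClip:
    """Read a PCM (int16/int32/float) WAV into a float AudioClip in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        samples = data.astype(float) / scale
    else:
        samples = data.astype(float)
    return AudioClip(samples=samples, sample_rate=float(rate))


def write_wav(path, clip: AudioClip) -> None:
    """Write an AudioClip as 16-bit PCM WAV."""
    x = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(path, int(clip.sample_rate),
                  (x * 32767.0).astype(np.int16))


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def write_events_csv(path, events: list[ClickEvent]) -> None:
    pd.DataFrame([
        {"time_s": e.time, "duration_s": e.duration,
         "peak_frequency_hz": e.peak_frequency, "score": e.score}
        for e in events
    ], columns=["time_s", "duration_s", "peak_frequency_hz", "score"]
    ).to_csv(path, index=False)


def read_events_csv(path) -> list[ClickEvent]:
    df = pd.read_csv(path)
    return [ClickEvent(time=r.time_s, duration=r.duration_s,
                       peak_frequency=r.peak_frequency_hz, score=r.score)
            for r in df.itertuples()]


def write_trains_csv(path, trains: list[ClickTrain]) -> None:
    rows = []
    for i, t in enumerate(trains):
        rows.append({
            "train_id": i,
            "n_clicks": len(t.clicks),
            "start_s": t.start,
            "end_s": t.end,
            "median_ici_ms": 1000.0 * float(np.median(t.icis)),
        })
    pd.DataFrame(rows, columns=["train_id", "n_clicks", "start_s", "end_s",
                                "median_ici_ms"]).to_csv(path, index=False)


def write_density_csv(path, density: pd.DataFrame) -> None:
    density.to_csv(path, index=False)


def read_density_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth_csv(path, clicks: list[SyntheticClick]) -> None:
    pd.DataFrame([
        {"center_time_s": c.center_time, "peak_frequency_hz": c.peak_frequency,
         "snr_db": c.snr_db}
        for c in clicks
    ], columns=["center_time_s", "peak_frequency_hz", "snr_db"]
    ).to_csv(path, index=False)


def read_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# classifier persistence: joblib binary + JSON metadata sidecar
# ---------------------------------------------------------------------------

def save_model(path, model: ClassifierModel) -> None:
    path = Path(path)
    joblib.dump(model.svm, path)
    meta = {
        "format_version": model.format_version,
        "n_bins": model.n_bins,
        "normalization": model.normalization,
        "n_samples": model.n_samples,
        "seed": model.seed,
        "cv_accuracy": model.cv_accuracy,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2))


def load_model(path) -> ClassifierModel:
    path = Path(path)
    svm = joblib.load(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if meta.get("format_version") != 1:
        raise ValueError(f"unsupported model format: {meta.get('format_version')}")
    return ClassifierModel(svm=svm, n_bins=meta["n_bins"],
                           normalization=meta["normalization"],
                           n_samples=meta["n_samples"], seed=meta["seed"],
                           cv_accuracy=meta.get("cv_accuracy"))


# ---------------------------------------------------------------------------
# YAML configs
# ---------------------------------------------------------------------------

def save_config(path, config) -> None:
    """Serialize a DetectorConfig or ScenarioConfig dataclass to YAML."""
    d = dataclasses.asdict(config)
    d["__type__"] = type(config).__name__
    Path(path).write_text(yaml.safe_dump(_plain(d), sort_keys=False))


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _load_yaml(path) -> dict:
    d = yaml.safe_load(Path(path).read_text())
    d.pop("__type__", None)
    return d


def load_detector_config(path) -> DetectorConfig:
    d = _load_yaml(path)
    if "click_band" in d:
        d["click_band"] = tuple(d["click_band"])
    return DetectorConfig(**d)


def load_scenario_config(path) -> ScenarioConfig:
    d = _load_yaml(path)
    for key in ("individuals_probs", "enrichment_probs", "event_probs",
                "visitor_probs"):
        if key in d:
            d[key] = tuple(d[key])
    return ScenarioConfig(**d)
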