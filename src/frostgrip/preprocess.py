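"""Raw grasp trials -> fixed-length model inputs.

Pipeline per trial: detect the grasp segment from the summed pressure
signal, denoise the pressure frames with a short moving average,
linearly resample both modalities to 50 uniformly spaced time steps over
the segment, flatten each 6x6 frame row-major to 36 channels, min-max
normalize the pressure trial jointly over all channels, high-pass the
vibration stream (causal second-order Butterworth, 30 Hz cutoff at the
nominal 200 Hz rate) and z-score it per trial, and attach the one-hot
label (index 0 = normal, index 1 = frost_damaged).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import FROST, GraspTrial, LABELS, NORMAL

__all__ = [
    "PreprocessConfig",
    "ModelInput",
    "detect_grasp_segment",
    "denoise_pressure",
    "resample_to_length",
    "normalize_pressure",
    "highpass_vibration",
    "build_model_input",
    "build_model_inputs",
    "save_model_inputs",
    "load_model_inputs",
]


@dataclass
class PreprocessConfig:
    target_length: int = 50
    hp_order: int = 2
    hp_cutoff_hz: float = 30.0
    nominal_vib_rate_hz: float = 200.0
    denoise_window: int = 3
    onset_threshold_k: float = 5.0
    norm_epsilon: float = 1e-8

    def __post_init__(self):
        if self.target_length < 2:
            raise ValueError("target_length must be >= 2")
        if self.hp_cutoff_hz >= self.nominal_vib_rate_hz / 2.0:
            raise ValueError("high-pass cutoff must be below Nyquist")
        if self.denoise_window < 1 or self.denoise_window % 2 == 0:
            raise ValueError("denoise_window must be a positive odd integer")


@dataclass
class ModelInput:
    """One standardized sample: 50x36 pressure, 50x1 vibration, one-hot."""

    trial_id: str
    pressure_seq: np.ndarray    # (50, 36), values in [0, 1]
    vibration_seq: np.ndarray   # (50, 1), z-scored
    label_onehot: np.ndarray    # (2,), [1,0]=normal, [0,1]=frost

    @property
    def label(self) -> str:
        return NORMAL if self.label_onehot[0] == 1 else FROST


def detect_grasp_segment(trial: GraspTrial,
                         cfg: PreprocessConfig) -> tuple[float, float]:
    """Locate the grasp window from the summed pressure frames.

    The leading 10% of frames estimate the pre-contact baseline;
    t_start is the first timestamp whose frame sum exceeds the baseline
    level by k baseline scales. The trailing 10% of frames play the
    symmetric role for t_end (last timestamp still above the trailing
    threshold). Baseline level and scale are the median and the
    normal-consistent MAD (1.4826 * MAD), so a baseline window that
    slightly overlaps the ramp does not inflate the threshold.
    """
    if len(trial.pressure_timestamps) == 0 or len(trial.vibration_timestamps) == 0:
        raise ValueError("trial streams must be non-empty")
    sums = trial.pressure_counts.reshape(len(trial.pressure_timestamps), -1) \
        .sum(axis=1).astype(float)
    nb = max(3, int(np.ceil(0.1 * len(sums))))

    def threshold(window: np.ndarray) -> float:
        level = np.median(window)
        scale = 1.4826 * np.median(np.abs(window - level))
        return level + cfg.onset_threshold_k * scale

    thr_start = threshold(sums[:nb])
    thr_end = threshold(sums[-nb:])
    above_start = np.nonzero(sums > thr_start)[0]
    above_end = np.nonzero(sums > thr_end)[0]
    if len(above_start) == 0 or len(above_end) == 0:
        raise ValueError("no contact detected")
    t_start = float(trial.pressure_timestamps[above_start[0]])
    t_end = float(trial.pressure_timestamps[above_end[-1]])
    if not t_start < t_end:
        raise ValueError("no contact detected")
    return t_start, t_end


def denoise_pressure(frames: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Centered moving average per channel; edges use shrunken windows."""
    if cfg.denoise_window % 2 == 0 or cfg.denoise_window < 1:
        raise ValueError("denoise_window must be a positive odd integer")
    n = frames.shape[0]
    if n < cfg.denoise_window:
        raise ValueError("fewer frames than the denoising window")
    if cfg.denoise_window == 1:
        return frames.astype(float).copy()
    half = cfg.denoise_window // 2
    x = frames.astype(float).reshape(n, -1)
    csum = np.cumsum(np.vstack([np.zeros((1, x.shape[1])), x]), axis=0)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    out = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
    return out.reshape(frames.shape)


def resample_to_length(timestamps: np.ndarray, values: np.ndarray,
                       target_length: int) -> np.ndarray:
    """Linear interpolation of each channel onto a uniform grid.

    ``values`` is (n, channels); output is (target_length, channels) with
    endpoints preserved exactly.
    """
    if len(timestamps) < 2:
        raise ValueError("need at least 2 time points to resample")
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] != len(timestamps):
        values = values.T
    grid = np.linspace(timestamps[0], timestamps[-1], target_length)
    out = np.empty((target_length, values.shape[1]))
    for c in range(values.shape[1]):
        out[:, c] = np.interp(grid, timestamps, values[:, c])
    out[0] = values[0]
    out[-1] = values[-1]
    return out


def normalize_pressure(seq: np.ndarray, epsilon: float = 1e-8) -> np.ndarray:
    """Joint per-trial min-max over all entries -> [0, 1].

    The single shared scale preserves the relative spatial load pattern
    across the 36 channels; a constant trial maps to all zeros via the
    epsilon guard.
    """
    if not np.all(np.isfinite(seq)):
        raise ValueError("pressure sequence must be finite")
    lo, hi = seq.min(), seq.max()
    return (seq - lo) / (hi - lo + epsilon)


def highpass_vibration(samples: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Causal single-pass second-order Butterworth high-pass at 30 Hz.

    Designed by bilinear transform with prewarped cutoff at the nominal
    vibration rate; the series mean is removed first. Gain at the cutoff
    is 1/sqrt(2) and DC is fully rejected.
    """
    if cfg.hp_cutoff_hz >= cfg.nominal_vib_rate_hz / 2.0:
        raise ValueError("high-pass cutoff must be below Nyquist")
    samples = np.asarray(samples, dtype=float)
    if len(samples) <= 3 * cfg.hp_order:
        raise ValueError("series too short for the filter order")
    sos = signal.butter(cfg.hp_order, cfg.hp_cutoff_hz, btype="highpass",
                        fs=cfg.nominal_vib_rate_hz, output="sos")
    return signal.sosfilt(sos, samples - samples.mean())


def _crop(timestamps: np.ndarray, values: np.ndarray,
          t_start: float, t_end: float):
    mask = (timestamps >= t_start) & (timestamps <= t_end)
    return timestamps[mask], values[mask]


def build_model_input(trial: GraspTrial, cfg: PreprocessConfig) -> ModelInput:
    """Run the full per-trial pipeline; see the module docstring."""
    t_start, t_end = detect_grasp_segment(trial, cfg)

    tp, frames = _crop(trial.pressure_timestamps, trial.pressure_counts,
                       t_start, t_end)
    frames = denoise_pressure(frames, cfg)
    flat = frames.reshape(len(tp), 36)  # row-major p00..p55
    pressure = resample_to_length(tp, flat, cfg.target_length)
    pressure = normalize_pressure(pressure, cfg.norm_epsilon)

    tv, vib = _crop(trial.vibration_timestamps,
                    trial.vibration_counts.astype(float), t_start, t_end)
    vib = highpass_vibration(vib, cfg)
    vib = resample_to_length(tv, vib[:, None], cfg.target_length)
    vib = (vib - vib.mean()) / (vib.std() + cfg.norm_epsilon)

    onehot = np.array([1.0, 0.0]) if trial.label == NORMAL else np.array([0.0, 1.0])
    return ModelInput(trial_id=trial.trial_id, pressure_seq=pressure,
                      vibration_seq=vib, label_onehot=onehot)


def build_model_inputs(trials: list[GraspTrial],
                       cfg: PreprocessConfig) -> list[ModelInput]:
    return [build_model_input(t, cfg) for t in trials]


INPUT_COLUMNS = [f"f{c:02d}" for c in range(36)] + ["v"]


def save_model_inputs(inputs: list[ModelInput], cfg: PreprocessConfig,
                      out_dir) -> Path:
    """Write ``<trial_id>_input.csv`` per sample plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for mi in inputs:
        df = pd.DataFrame(np.hstack([mi.pressure_seq, mi.vibration_seq]),
                          columns=INPUT_COLUMNS)
        fname = f"{mi.trial_id}_input.csv"
        df.to_csv(out / fname, index=False, float_format="%.9g")
        entries.append({"trial_id": mi.trial_id, "label": mi.label,
                        "file": fname})
    manifest = {"config": asdict(cfg), "inputs": entries}
    with open(out / "inputs_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def load_model_inputs(in_dir) -> list[ModelInput]:
    src = Path(in_dir)
    with open(src / "inputs_manifest.json") as fh:
        manifest = json.load(fh)
    inputs = []
    for entry in manifest["inputs"]:
        df = pd.read_csv(src / entry["file"])
        arr = df[INPUT_COLUMNS].to_numpy()
        onehot = (np.array([1.0, 0.0]) if entry["label"] == NORMAL
                  else np.array([0.0, 1.0]))
        inputs.append(ModelInput(trial_id=entry["trial_id"],
                                 pressure_seq=arr[:, :36],
                                 vibration_seq=arr[:, 36:],
                                 label_onehot=onehot))
    return inputs
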