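"""Synthetic multimodal tactile grasp simulator.

Generates labeled pressure-matrix and vibration recordings of robotic
citrus grasps with the statistical structure the downstream analysis
assumes: a parallel-finger gripper closes on a fruit, loads to a force
plateau, holds, and releases, while a 6x6 pressure matrix (~20 Hz) and a
piezoelectric vibration film (~200 Hz) record 10-bit ADC counts.

The generative model encodes the mechanics of freeze-thaw injury
qualitatively: frost-damaged tissue is softer and more dissipative, so
the damaged class has a slower force ramp (longer time constant), a
slightly wider contact footprint, a lower-frequency and more strongly
damped contact transient, and more micro-slip events during loading.
Class differences are concentrated at contact onset and early loading;
the hold phase differs only through the slow tail of the force creep.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "FruitProfile",
    "GraspTrial",
    "sample_fruit_profile",
    "simulate_trial",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
    "NORMAL",
    "FROST",
]

NORMAL = "normal"
FROST = "frost_damaged"
LABELS = (NORMAL, FROST)

# Diameter statistics of the fruit lot (mm).
DIAMETER_MEAN_MM = 73.54
DIAMETER_SD_MM = 3.41
DIAMETER_RANGE_MM = (66.31, 81.34)

# Normal-class mechanical baselines. Frost-damaged fruit shift each of
# these by effect_size * delta (see sample_fruit_profile).
TAU_BASE_S = 0.15          # force-ramp time constant
SPREAD_BASE = 1.0          # Gaussian footprint SD, grid units
VIB_FREQ_BASE_HZ = 80.0    # contact-transient resonant frequency
DAMPING_BASE = 0.04        # transient damping ratio
EVENT_RATE_BASE_HZ = 1.0   # micro-slip events per second during loading
BIO_JITTER_SD = 0.10       # lognormal multiplicative biological scatter

# Documented ADC operating points and signal amplitudes (counts).
PRESSURE_BASELINE_COUNTS = 8.0
VIB_MIDPOINT_COUNTS = 512.0
VIB_TRANSIENT_AMP = 180.0
VIB_DRIFT_AMP = 15.0
MICRO_EVENT_AMP = 70.0
MICRO_EVENT_FREQ_HZ = 90.0
MICRO_EVENT_DECAY_PER_S = 6.0

RAMP_TAU_MULTIPLES = 4.0   # loading phase lasts this many time constants
RELEASE_S = 0.2            # linear force ramp-down
TAIL_S = 0.4               # post-release baseline tail
TIMESTAMP_JITTER_FRAC = 0.02  # uniform jitter, fraction of sample interval


@dataclass
class SimulationConfig:
    """Conditions of one simulated acquisition campaign."""

    n_per_class: int = 120
    effect_size: float = 1.0
    pressure_rate_hz: float = 20.0
    vibration_rate_hz: float = 200.0
    close_speed_mm_s: float = 50.0
    force_max_N: float = 20.0
    hold_s: float = 5.0
    pre_contact_s: float = 0.5
    adc_max: int = 1023
    pressure_sd_counts: float = 2.0
    vibration_sd_counts: float = 8.0
    delta_tau: float = 0.08
    delta_sigma: float = 0.15
    delta_freq: float = 20.0
    delta_damping: float = 0.05
    delta_event_rate: float = 8.0
    gain_counts_per_N: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [0, 1]")
        if self.pressure_rate_hz <= 0 or self.vibration_rate_hz <= 0:
            raise ValueError("sampling rates must be positive")
        if self.force_max_N <= 0:
            raise ValueError("force_max_N must be positive")
        for name in ("delta_tau", "delta_sigma", "delta_freq",
                     "delta_damping", "delta_event_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class FruitProfile:
    """Ground-truth mechanical parameters of one fruit."""

    fruit_id: str
    label: str
    diameter_mm: float
    stiffness_tau_s: float
    footprint_center: tuple[float, float]
    footprint_spread: float
    vib_freq_hz: float
    damping_ratio: float
    micro_event_rate_hz: float

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")
        lo, hi = DIAMETER_RANGE_MM
        if not lo <= self.diameter_mm <= hi:
            raise ValueError("diameter out of the lot's observed range")
        if min(self.stiffness_tau_s, self.footprint_spread, self.vib_freq_hz) <= 0:
            raise ValueError("mechanical parameters must be positive")
        if not 0.0 < self.damping_ratio < 1.0:
            raise ValueError("damping_ratio must lie in (0, 1)")
        if self.micro_event_rate_hz < 0:
            raise ValueError("micro_event_rate_hz must be >= 0")


@dataclass
class GraspTrial:
    """One grasping event: raw streams plus ground truth."""

    trial_id: str
    fruit: FruitProfile
    pressure_timestamps: np.ndarray   # (n_frames,)
    pressure_counts: np.ndarray       # (n_frames, 6, 6) int
    vibration_timestamps: np.ndarray  # (n_samples,)
    vibration_counts: np.ndarray      # (n_samples,) int
    contact_onset_s: float
    metadata: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        return self.fruit.label


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated normal rejection failed")  # pragma: no cover


def sample_fruit_profile(config: SimulationConfig, label: str,
                         rng: np.random.Generator,
                         fruit_id: str = "fruit") -> FruitProfile:
    """Draw ground-truth mechanical parameters for one fruit.

    Normal fruit receive the class baselines; frost-damaged fruit shift
    every mechanical parameter by ``effect_size * delta`` in the
    direction softer/wider/slower/more-damped/more-eventful. Both
    classes then receive independent lognormal biological jitter
    (multiplicative, sd 10%), so at effect_size=0 the two classes are
    distributionally identical by construction.
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
    diameter = _truncated_normal(rng, DIAMETER_MEAN_MM, DIAMETER_SD_MM,
                                 *DIAMETER_RANGE_MM)
    e = config.effect_size if label == FROST else 0.0
    tau = TAU_BASE_S + e * config.delta_tau
    spread = SPREAD_BASE + e * config.delta_sigma
    freq = VIB_FREQ_BASE_HZ - e * config.delta_freq
    damping = DAMPING_BASE + e * config.delta_damping
    rate = EVENT_RATE_BASE_HZ + e * config.delta_event_rate

    sigma = np.sqrt(np.log(1.0 + BIO_JITTER_SD**2))
    jitter = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=5)
    center = tuple(rng.uniform(2.0, 3.0, size=2))
    return FruitProfile(
        fruit_id=fruit_id,
        label=label,
        diameter_mm=diameter,
        stiffness_tau_s=tau * jitter[0],
        footprint_center=(float(center[0]), float(center[1])),
        footprint_spread=spread * jitter[1],
        vib_freq_hz=min(freq * jitter[2], 0.49 * config.vibration_rate_hz),
        damping_ratio=float(np.clip(damping * jitter[3], 1e-3, 0.99)),
        micro_event_rate_hz=rate * jitter[4],
    )


def _force_trajectory(t: np.ndarray, t0: float, tau: float, f_max: float,
                      t_release: float) -> np.ndarray:
    """Exponential loading to a clamped plateau, linear release."""
    f = np.zeros_like(t)
    loading = (t >= t0) & (t < t_release)
    f[loading] = np.minimum(
        f_max * (1.0 - np.exp(-(t[loading] - t0) / tau)), f_max
    )
    f_at_release = f_max * (1.0 - np.exp(-(t_release - t0) / tau))
    releasing = (t >= t_release) & (t < t_release + RELEASE_S)
    f[releasing] = f_at_release * (1.0 - (t[releasing] - t_release) / RELEASE_S)
    return f


def _jittered_grid(rng: np.random.Generator, duration: float,
                   rate: float) -> np.ndarray:
    n = int(np.floor(duration * rate)) + 1
    base = np.arange(n) / rate
    jit = rng.uniform(-TIMESTAMP_JITTER_FRAC, TIMESTAMP_JITTER_FRAC, size=n) / rate
    jit[0] = abs(jit[0])  # keep t >= 0
    return base + jit


def _footprint_weights(center: tuple[float, float], spread: float) -> np.ndarray:
    rows, cols = np.mgrid[0:6, 0:6]
    w = np.exp(-((rows - center[0]) ** 2 + (cols - center[1]) ** 2)
               / (2.0 * spread**2))
    return w / w.sum()


def simulate_trial(profile: FruitProfile, config: SimulationConfig,
                   rng: np.random.Generator,
                   trial_id: str = "trial") -> GraspTrial:
    """Synthesize the two raw sensor streams for one grasp.

    Pressure frame at time t:  ``clip(round(baseline + gain * w_ij * F(t)
    + noise), 0, adc_max)`` with Gaussian spatial weights w normalized to
    sum 1. Vibration sample: ADC midpoint + slow sinusoidal drift
    (< 5 Hz) + damped contact transient for t >= onset + Poisson-timed
    micro-slip transients during loading + white noise.
    """
    for name in ("stiffness_tau_s", "footprint_spread", "vib_freq_hz",
                 "damping_ratio", "micro_event_rate_hz"):
        if not np.isfinite(getattr(profile, name)):
            raise ValueError(f"non-finite fruit parameter: {name}")

    t0 = config.pre_contact_s
    ramp_s = RAMP_TAU_MULTIPLES * profile.stiffness_tau_s
    t_release = t0 + ramp_s + config.hold_s
    duration = t_release + RELEASE_S + TAIL_S

    # --- pressure stream -------------------------------------------------
    tp = _jittered_grid(rng, duration, config.pressure_rate_hz)
    force = _force_trajectory(tp, t0, profile.stiffness_tau_s,
                              config.force_max_N, t_release)
    w = _footprint_weights(profile.footprint_center, profile.footprint_spread)
    raw = (PRESSURE_BASELINE_COUNTS
           + config.gain_counts_per_N * w[None, :, :] * force[:, None, None])
    if config.pressure_sd_counts > 0:
        raw = raw + rng.normal(0.0, config.pressure_sd_counts, size=raw.shape)
    pressure = np.clip(np.rint(raw), 0, config.adc_max).astype(np.int64)

    # --- vibration stream ------------------------------------------------
    tv = _jittered_grid(rng, duration, config.vibration_rate_hz)
    drift_freq = rng.uniform(0.2, 2.0)
    drift_phase = rng.uniform(0.0, 2.0 * np.pi)
    v = VIB_MIDPOINT_COUNTS + VIB_DRIFT_AMP * np.sin(
        2.0 * np.pi * drift_freq * tv + drift_phase)

    omega = 2.0 * np.pi * profile.vib_freq_hz
    zeta = profile.damping_ratio
    omega_d = omega * np.sqrt(1.0 - zeta**2)
    after = tv >= t0
    dt = tv[after] - t0
    v[after] += VIB_TRANSIENT_AMP * np.exp(-zeta * omega * dt) * np.sin(omega_d * dt)

    # Poisson micro-slip events while the ramp loads the tissue.
    n_events = rng.poisson(profile.micro_event_rate_hz * ramp_s)
    event_times = t0 + rng.uniform(0.0, ramp_s, size=n_events)
    for te in event_times:
        m = tv >= te
        dte = tv[m] - te
        v[m] += MICRO_EVENT_AMP * np.exp(-MICRO_EVENT_DECAY_PER_S * dte) * np.sin(
            2.0 * np.pi * MICRO_EVENT_FREQ_HZ * dte)

    if config.vibration_sd_counts > 0:
        v = v + rng.normal(0.0, config.vibration_sd_counts, size=v.shape)
    vibration = np.clip(np.rint(v), 0, config.adc_max).astype(np.int64)

    return GraspTrial(
        trial_id=trial_id,
        fruit=profile,
        pressure_timestamps=tp,
        pressure_counts=pressure,
        vibration_timestamps=tv,
        vibration_counts=vibration,
        contact_onset_s=t0,
        metadata={"t_release_s": t_release, "duration_s": duration,
                  "n_micro_events": int(n_events)},
    )


def generate_dataset(config: SimulationConfig):
    """Generate ``n_per_class`` trials per class, deterministically.

    Returns ``(trials, manifest)``; the manifest records every trial's
    label and ground-truth fruit parameters plus a config echo, so the
    dataset is reconstructable and auditable.
    """
    rng = np.random.default_rng(config.seed)
    trials: list[GraspTrial] = []
    entries = []
    for label in LABELS:
        for i in range(config.n_per_class):
            short = "normal" if label == NORMAL else "frost"
            tid = f"{short}_{i:04d}"
            profile = sample_fruit_profile(config, label, rng,
                                           fruit_id=f"fruit_{tid}")
            trial = simulate_trial(profile, config, rng, trial_id=tid)
            trials.append(trial)
            entries.append({
                "trial_id": tid,
                "label": label,
                "contact_onset_s": trial.contact_onset_s,
                "fruit": asdict(profile),
                "files": {
                    "pressure": f"{tid}_pressure.csv",
                    "vibration": f"{tid}_vibration.csv",
                },
            })
    manifest = {
        "config": asdict(config),
        "n_trials": len(trials),
        "trials": entries,
    }
    return trials, manifest


PRESSURE_COLUMNS = ["timestamp_s"] + [f"p{r}{c}" for r in range(6) for c in range(6)]


def save_dataset(trials: list[GraspTrial], manifest: dict, out_dir) -> Path:
    """Write per-trial CSVs and ``manifest.json`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for trial in trials:
        flat = trial.pressure_counts.reshape(len(trial.pressure_timestamps), 36)
        dfp = pd.DataFrame(flat, columns=PRESSURE_COLUMNS[1:])
        dfp.insert(0, "timestamp_s", trial.pressure_timestamps)
        dfp.to_csv(out / f"{trial.trial_id}_pressure.csv", index=False,
                   float_format="%.6f")
        dfv = pd.DataFrame({"timestamp_s": trial.vibration_timestamps,
                            "v": trial.vibration_counts})
        dfv.to_csv(out / f"{trial.trial_id}_vibration.csv", index=False,
                   float_format="%.6f")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def load_dataset(in_dir) -> tuple[list[GraspTrial], dict]:
    """Read a dataset written by :func:`save_dataset` (or real recordings
    laid out the same way)."""
    src = Path(in_dir)
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    trials = []
    for entry in manifest["trials"]:
        dfp = pd.read_csv(src / entry["files"]["pressure"])
        dfv = pd.read_csv(src / entry["files"]["vibration"])
        fruit_kwargs = dict(entry["fruit"])
        fruit_kwargs["footprint_center"] = tuple(fruit_kwargs["footprint_center"])
        fruit = FruitProfile(**fruit_kwargs)
        trials.append(GraspTrial(
            trial_id=entry["trial_id"],
            fruit=fruit,
            pressure_timestamps=dfp["timestamp_s"].to_numpy(),
            pressure_counts=dfp[PRESSURE_COLUMNS[1:]].to_numpy()
                .reshape(-1, 6, 6).astype(np.int64),
            vibration_timestamps=dfv["timestamp_s"].to_numpy(),
            vibration_counts=dfv["v"].to_numpy().astype(np.int64),
            contact_onset_s=entry["contact_onset_s"],
        ))
    return trials, manifest
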