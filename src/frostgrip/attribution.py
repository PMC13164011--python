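"""Residual-aware attention rollout and temporal attribution.

From the post-softmax per-head attention maps of each Transformer
branch, the analysis (i) averages heads, (ii) adjusts for the residual
path by row-normalizing A_bar + I (which equals (A_bar + I)/2 for a
row-stochastic A_bar), (iii) rolls attention out through the L stacked
blocks by matrix product (the single-block case returns the adjusted
map unchanged), (iv) scores each time step by its mean incoming
attention over all query positions, (v) min-max normalizes the profile
per sample, (vi) fuses the two modality profiles by equal-weight
averaging, and (vii) summarizes where the fused profile peaks across
samples as a fixed-width interval histogram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .models import GraspClassifier, extract_attention_maps
from .preprocess import ModelInput

__all__ = [
    "AttributionConfig",
    "RolloutIntermediates",
    "AttributionProfile",
    "PeakHistogram",
    "average_heads",
    "residual_adjust",
    "rollout",
    "temporal_score",
    "minmax_normalize",
    "fuse_profiles",
    "peak_time",
    "peak_interval_histogram",
    "attribute_sample",
    "attribute_dataset",
    "save_attributions",
]


@dataclass
class AttributionConfig:
    epsilon: float = 1e-8
    interval_width: int = 5
    # argmax ties break to the earliest index (np.argmax convention)

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.interval_width < 1:
            raise ValueError("interval_width must be >= 1")


@dataclass
class RolloutIntermediates:
    A_bar: np.ndarray    # head-averaged map
    A_tilde: np.ndarray  # residual-adjusted map
    R: np.ndarray        # rollout matrix


@dataclass
class AttributionProfile:
    sample_id: str
    s_p: np.ndarray | None
    s_v: np.ndarray | None
    s_hat_p: np.ndarray | None
    s_hat_v: np.ndarray | None
    s_hat_fused: np.ndarray
    t_star: int
    label: str | None = None


@dataclass
class PeakHistogram:
    edges: np.ndarray        # interval edges in time steps, len n_bins + 1
    counts: np.ndarray       # per-interval totals
    per_class: dict | None = None


def average_heads(maps: list[np.ndarray]) -> np.ndarray:
    """Elementwise mean over heads; preserves row-stochasticity."""
    if len(maps) == 0:
        raise ValueError("need at least one attention map")
    return np.mean(np.stack(maps), axis=0)


def residual_adjust(A_bar: np.ndarray) -> np.ndarray:
    """RowNorm(A_bar + I); equals (A_bar + I)/2 for row-stochastic input."""
    adj = A_bar + np.eye(A_bar.shape[0])
    return adj / adj.sum(axis=1, keepdims=True)


def rollout(A_tilde_layers: list[np.ndarray]) -> np.ndarray:
    """Ordered product over stacked blocks; identity passthrough at L=1."""
    if len(A_tilde_layers) == 0:
        raise ValueError("need at least one layer map")
    if len(A_tilde_layers) == 1:
        return A_tilde_layers[0]
    R = A_tilde_layers[0]
    for A in A_tilde_layers[1:]:
        if A.shape != R.shape:
            raise ValueError("layer maps must share a common shape")
        R = R @ A
    return R


def temporal_score(R: np.ndarray) -> np.ndarray:
    """s(t) = mean incoming attention over query positions (column means);
    sums to 1 for a row-stochastic R."""
    return R.mean(axis=0)


def minmax_normalize(s: np.ndarray, epsilon: float = 1e-8) -> np.ndarray:
    return (s - s.min()) / (s.max() - s.min() + epsilon)


def fuse_profiles(s_hat_p: np.ndarray, s_hat_v: np.ndarray) -> np.ndarray:
    if len(s_hat_p) != len(s_hat_v):
        raise ValueError("profiles must have equal length")
    return 0.5 * (s_hat_p + s_hat_v)


def peak_time(s_hat_fused: np.ndarray) -> int:
    """Argmax time step, earliest index on ties."""
    if len(s_hat_fused) == 0:
        raise ValueError("empty profile")
    return int(np.argmax(s_hat_fused))


def peak_interval_histogram(t_stars, cfg: AttributionConfig, T: int,
                            labels=None) -> PeakHistogram:
    """Fixed-width interval counts [0,w), [w,2w), ...; a final partial
    interval covers the remainder of the sequence."""
    t_stars = np.asarray(t_stars, dtype=int)
    if len(t_stars) == 0:
        raise ValueError("no peak times supplied")
    if (t_stars < 0).any() or (t_stars >= T).any():
        raise ValueError("peak times must lie in [0, T-1]")
    w = cfg.interval_width
    n_bins = int(np.ceil(T / w))
    edges = np.minimum(np.arange(n_bins + 1) * w, T)
    bins = t_stars // w
    counts = np.bincount(bins, minlength=n_bins)
    per_class = None
    if labels is not None:
        per_class = {}
        labels = np.asarray(labels)
        for cls in np.unique(labels):
            per_class[str(cls)] = np.bincount(
                bins[labels == cls], minlength=n_bins).tolist()
    return PeakHistogram(edges=edges, counts=counts, per_class=per_class)


def _branch_pipeline(maps: list[np.ndarray]):
    A_bar = average_heads(maps)
    A_tilde = residual_adjust(A_bar)
    R = rollout([A_tilde])
    s = temporal_score(R)
    return RolloutIntermediates(A_bar, A_tilde, R), s


def attribute_sample(model: GraspClassifier, sample: ModelInput,
                     cfg: AttributionConfig | None = None,
                     return_intermediates: bool = False):
    """Run the full rollout attribution for one sample.

    For single-modality models the fused profile is the normalized
    profile of the lone branch.
    """
    cfg = cfg or AttributionConfig()
    kwargs = {}
    if "P" in model.required:
        kwargs["pressure_seq"] = sample.pressure_seq
    if "V" in model.required:
        kwargs["vibration_seq"] = sample.vibration_seq
    maps = extract_attention_maps(model, **kwargs)
    if maps.pressure is None and maps.vibration is None:
        raise ValueError("model exposes no attention maps")

    s_p = s_v = s_hat_p = s_hat_v = None
    inter = {}
    if maps.pressure is not None:
        inter["pressure"], s_p = _branch_pipeline(maps.pressure)
        s_hat_p = minmax_normalize(s_p, cfg.epsilon)
    if maps.vibration is not None:
        inter["vibration"], s_v = _branch_pipeline(maps.vibration)
        s_hat_v = minmax_normalize(s_v, cfg.epsilon)
    if s_hat_p is not None and s_hat_v is not None:
        fused = fuse_profiles(s_hat_p, s_hat_v)
    else:
        fused = s_hat_p if s_hat_p is not None else s_hat_v
    profile = AttributionProfile(
        sample_id=sample.trial_id, s_p=s_p, s_v=s_v,
        s_hat_p=s_hat_p, s_hat_v=s_hat_v, s_hat_fused=fused,
        t_star=peak_time(fused), label=sample.label)
    return (profile, inter) if return_intermediates else profile


def attribute_dataset(model: GraspClassifier, inputs: list[ModelInput],
                      cfg: AttributionConfig | None = None):
    """Attribution profiles for every sample plus the peak histogram."""
    cfg = cfg or AttributionConfig()
    profiles = [attribute_sample(model, s, cfg) for s in inputs]
    T = len(profiles[0].s_hat_fused)
    hist = peak_interval_histogram([p.t_star for p in profiles], cfg, T,
                                   labels=[p.label for p in profiles])
    return profiles, hist


def save_attributions(profiles: list[AttributionProfile],
                      hist: PeakHistogram, out_dir) -> Path:
    """Write ``profiles.csv`` (fused profiles per sample) and
    ``histogram.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    T = len(profiles[0].s_hat_fused)
    rows = []
    for p in profiles:
        row = {"sample_id": p.sample_id, "label": p.label, "t_star": p.t_star}
        row.update({f"s{t:02d}": p.s_hat_fused[t] for t in range(T)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "profiles.csv", index=False,
                              float_format="%.6g")
    with open(out / "histogram.json", "w") as fh:
        json.dump({"edges": hist.edges.tolist(),
                   "counts": hist.counts.tolist(),
                   "per_class": hist.per_class}, fh, indent=2)
    return out
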