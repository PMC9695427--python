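"""Synthetic discoloration videos, conductivity traces, and factorial
datasets with closed-form ground truth.

The video model is an exponential approach per pixel,

    R(x, y, t) = R_inf - (R_inf - R0) * exp(-k(x, y) * t),

with a rate field decaying with distance from a rotor center,
``k = k0 * exp(-d / lambda)``. For a threshold placed at fraction X of
the R0 -> R_inf range, the crossing time is exactly
``t* = ln(1 / (1 - X)) / k``, which makes every pipeline stage testable
against an analytic oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .colorimetry import FrameStack
from .conductometry import ConductivityTrace, RunMetadata
from .crossing import ceil_to_grid

__all__ = [
    "VideoSynthSpec",
    "VideoGroundTruth",
    "TraceSynthSpec",
    "synth_video",
    "synth_trace",
    "synth_design",
    "render_rgb",
    "crossing_time_order_statistic",
]


@dataclass
class VideoSynthSpec:
    """Parameters of a synthetic discoloration video."""

    height: int = 64
    width: int = 64
    duration: float = 10.0
    fps: float = 60.0
    R0: float = 40.0
    R_inf: float = 240.0
    k0: float = 2.0              # base discoloration rate, 1/s
    decay_length: float = 1e9    # spatial decay length of the rate field, px
    rotor_center: tuple[float, float] | None = None  # (row, col); default frame center
    noise_sd: float = 0.0        # gray levels
    seed: int = 0
    quantize: bool = False       # round frames to uint8 (loses exactness)
    rgb: bool = False            # render blue->colorless RGB frames

    def __post_init__(self) -> None:
        if not (0 <= self.R0 < self.R_inf <= 255):
            raise ValueError("need 0 <= R0 < R_inf <= 255")
        if self.k0 <= 0 or self.decay_length <= 0:
            raise ValueError("k0 and decay_length must be positive")
        if self.fps <= 0 or self.duration <= 0:
            raise ValueError("fps and duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.height < 1 or self.width < 1:
            raise ValueError("frame dimensions must be >= 1")


@dataclass
class VideoGroundTruth:
    """Analytic truth accompanying a synthetic video (computed before
    noise/quantization)."""

    k_map: np.ndarray           # 1/s per pixel
    crossing_map: np.ndarray    # threshold-crossing time per pixel, s
    mixing_coefficient: float
    true_t90: float             # order statistic of crossing times (see below)
    true_t90_on_grid: float     # true_t90 rounded up to the frame grid
    spec: VideoSynthSpec = field(repr=False, default=None)


def crossing_time_order_statistic(crossing_times: np.ndarray,
                                  level: float = 90.0) -> float:
    """The crossing time at which the mixed fraction first reaches
    ``level`` percent.

    With n pixels, M >= level requires at least ``ceil(level/100 * n)``
    pixels mixed, so the defining time is that order statistic of the
    per-pixel crossing times — the exact continuous-time counterpart of
    the pipeline's first-frame-with-M>=level rule.
    """
    flat = np.sort(np.asarray(crossing_times, dtype=float).ravel())
    n = flat.size
    m = math.ceil(level / 100.0 * n)
    return float(flat[m - 1])


def synth_video(spec: VideoSynthSpec,
                mixing_coefficient: float = 0.5,
                mixed_level: float = 90.0) -> tuple[FrameStack, VideoGroundTruth]:
    """Generate a discoloration video and its analytic ground truth.

    Deterministic under ``spec.seed``. The ground truth carries the rate
    map, the per-pixel crossing time for the given mixing coefficient,
    and the true discoloration time at ``mixed_level``.
    """
    rng = np.random.default_rng(spec.seed)
    T = int(round(spec.duration * spec.fps))
    if T < 2:
        raise ValueError("duration * fps must give at least 2 frames")
    rows = np.arange(spec.height)[:, None]
    cols = np.arange(spec.width)[None, :]
    cr, cc = spec.rotor_center or ((spec.height - 1) / 2.0, (spec.width - 1) / 2.0)
    dist = np.hypot(rows - cr, cols - cc)
    k_map = spec.k0 * np.exp(-dist / spec.decay_length)

    t = (np.arange(T) / spec.fps)[:, None, None]
    frames = spec.R_inf - (spec.R_inf - spec.R0) * np.exp(-k_map[None] * t)
    if spec.noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.noise_sd, size=frames.shape)
    frames = np.clip(frames, 0.0, 255.0)
    if spec.quantize:
        frames = np.floor(frames + 0.5).astype(np.uint8)

    crossing = np.log(1.0 / (1.0 - mixing_coefficient)) / k_map \
        if mixing_coefficient < 1 else np.full_like(k_map, np.inf)
    true_t90 = crossing_time_order_statistic(crossing, mixed_level)
    truth = VideoGroundTruth(
        k_map=k_map, crossing_map=crossing,
        mixing_coefficient=mixing_coefficient,
        true_t90=true_t90,
        true_t90_on_grid=ceil_to_grid(true_t90, spec.fps),
        spec=spec)

    stack = FrameStack(frames=frames, fps=spec.fps)
    if spec.rgb:
        stack = FrameStack(frames=render_rgb(frames), fps=spec.fps)
    return stack, truth


@dataclass
class TraceSynthSpec:
    """Parameters of a synthetic first-order conductivity rise."""

    tau: float = 1.0             # time constant, s
    baseline: float = 100.0      # instrument units before powder addition
    amplitude: float = 900.0     # plateau rise above baseline
    sample_rate: float = 100.0   # Hz
    duration: float | None = None  # default: lag + 10 * tau
    noise_sd: float = 0.0        # fraction of amplitude
    lag: float = 0.0             # s before powder addition
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.sample_rate <= 0:
            raise ValueError("tau and sample_rate must be positive")
        if self.duration is None:
            self.duration = self.lag + 10.0 * self.tau
        if self.duration <= self.tau:
            raise ValueError("duration must exceed tau")
        if self.noise_sd < 0 or self.lag < 0 or self.amplitude <= 0:
            raise ValueError("invalid noise_sd, lag, or amplitude")


def synth_trace(spec: TraceSynthSpec,
                metadata: RunMetadata | None = None
                ) -> tuple[ConductivityTrace, float]:
    """Generate a conductivity trace; returns ``(trace, true_t90)``.

    ``true_t90 = lag + tau * ln(10)``, the 90%-of-range crossing of the
    noiseless model. Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sample_rate)) + 1
    times = np.arange(n) / spec.sample_rate
    rise = np.where(times >= spec.lag,
                    1.0 - np.exp(-np.maximum(times - spec.lag, 0.0) / spec.tau),
                    0.0)
    values = spec.baseline + spec.amplitude * rise
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd * spec.amplitude, size=n)
    trace = ConductivityTrace(times=times, values=values,
                              metadata=metadata or RunMetadata())
    return trace, spec.lag + spec.tau * math.log(10.0)


def synth_design(factors: dict[str, list],
                 effects: dict[str, dict] | None = None,
                 interaction_effects: dict[tuple[str, str], dict] | None = None,
                 grand_mean: float = 10.0,
                 residual_sd: float = 1.0,
                 replicates: int = 3,
                 seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Full-factorial design table with a planted linear model.

    ``factors`` maps factor name -> list of levels (>= 2 each).
    ``effects[name][level]`` is an additive shift for that level;
    ``interaction_effects[(a, b)][(la, lb)]`` an extra shift for the
    level pair. Response = grand mean + shifts + N(0, residual_sd).
    Returns the design table and the true model for verification.
    """
    effects = effects or {}
    interaction_effects = interaction_effects or {}
    for name, levels in factors.items():
        if len(levels) < 2:
            raise ValueError(f"factor {name!r} needs >= 2 levels")
    for name in effects:
        if name not in factors:
            raise ValueError(f"effect on unknown factor {name!r}")
    for pair in interaction_effects:
        if pair[0] not in factors or pair[1] not in factors:
            raise ValueError(f"interaction on unknown factors {pair!r}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    rng = np.random.default_rng(seed)
    names = list(factors)
    grids = np.meshgrid(*[np.arange(len(factors[n])) for n in names], indexing="ij")
    combos = np.stack([g.ravel() for g in grids], axis=1)
    rows = []
    for combo in combos:
        levels = {n: factors[n][i] for n, i in zip(names, combo)}
        mu = grand_mean
        for n, lv in levels.items():
            mu += effects.get(n, {}).get(lv, 0.0)
        for (a, b), table in interaction_effects.items():
            mu += table.get((levels[a], levels[b]), 0.0)
        for _ in range(replicates):
            resp = mu + (rng.normal(0.0, residual_sd) if residual_sd > 0 else 0.0)
            rows.append({**levels, "response_s": resp, "censored": False})
    design = pd.DataFrame(rows)
    truth = {"grand_mean": grand_mean, "effects": effects,
             "interaction_effects": interaction_effects,
             "residual_sd": residual_sd, "replicates": replicates, "seed": seed}
    return design, truth


def render_rgb(gray: np.ndarray) -> np.ndarray:
    """Map gray levels to a blue -> colorless (white) colormap.

    gray 0 -> saturated blue (0, 0, 255); gray 255 -> white. The red and
    green channels ramp linearly, blue stays saturated, so any positive
    weighting gives a luma monotone in the input gray level.
    """
    g = np.asarray(gray, dtype=float)
    if g.min() < 0 or g.max() > 255:
        raise ValueError("gray values must lie in [0, 255]")
    g8 = np.floor(g + 0.5)
    rgb = np.stack([g8, g8, np.full_like(g8, 255.0)], axis=-1)
    return rgb.astype(np.uint8)
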