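"""Colorimetric mixing analysis of discoloration videos.

A video of a dye-decolorization experiment is reduced to a per-pixel
gray threshold (anchored between the first and last frames), a binary
mixed/unmixed classification per frame, the percent-mixed curve M(t),
the discoloration time t90, and a map of first-mixed times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .crossing import first_crossing_index

__all__ = [
    "FrameStack",
    "RoiSpec",
    "ColorimetryConfig",
    "ThresholdMap",
    "MixingCurve",
    "DiscolorationResult",
    "FirstMixedMap",
    "NoDynamicsError",
    "load_frames",
    "to_grayscale",
    "crop_roi",
    "threshold_map",
    "threshold_map_from_stack",
    "classify_mixed",
    "mixing_curve",
    "discoloration_time",
    "first_mixed_map",
    "analyze_stack",
]

#: Sentinel written into first-mixed maps for never-mixed / invalid pixels.
NEVER_MIXED = np.nan

ITU_R_601_WEIGHTS = (0.299, 0.587, 0.114)


class NoDynamicsError(ValueError):
    """Raised when every pixel is static (no discoloration signal)."""


@dataclass
class FrameStack:
    """Time-ordered stack of frames with a frame rate.

    ``frames`` is ``(T, H, W)`` grayscale or ``(T, H, W, 3)`` RGB, values
    in [0, 255]. Integer dtype is the norm for loaded video; float frames
    (still bounded by [0, 255]) are accepted so that noiseless synthetic
    stacks can carry sub-gray-level resolution. Frame ``k`` (0-based) is
    acquired at ``t0_offset + k / fps``.
    """

    frames: np.ndarray
    fps: float
    t0_offset: float = 0.0
    mask: np.ndarray | None = None  # optional H x W ROI validity mask

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (T, H, W) or (T, H, W, 3)")
        if self.frames.ndim == 4 and self.frames.shape[-1] != 3:
            raise ValueError("RGB frames must have 3 channels")
        if self.frames.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        fmin, fmax = self.frames.min(), self.frames.max()
        if fmin < 0 or fmax > 255:
            raise ValueError(f"gray values outside [0, 255]: [{fmin}, {fmax}]")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.frames.shape[1:3]:
                raise ValueError("mask shape must match frame shape")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    @property
    def is_rgb(self) -> bool:
        return self.frames.ndim == 4

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset + np.arange(self.n_frames) / self.fps


@dataclass
class RoiSpec:
    """Region of interest: an axis-aligned rectangle or a boolean mask.

    Rectangles are 0-based half-open ``(row0, col0, height, width)``.
    """

    rect: tuple[int, int, int, int] | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.rect is None) == (self.mask is None):
            raise ValueError("specify exactly one of rect or mask")
        if self.rect is not None:
            r0, c0, h, w = self.rect
            if h <= 0 or w <= 0 or r0 < 0 or c0 < 0:
                raise ValueError("rectangle must be non-empty and non-negative")
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.ndim != 2:
                raise ValueError("mask must be 2-D")

    @classmethod
    def rectangle(cls, row0: int, col0: int, height: int, width: int) -> "RoiSpec":
        return cls(rect=(row0, col0, height, width))

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "RoiSpec":
        return cls(mask=mask)


@dataclass
class ColorimetryConfig:
    """Tunable parameters of the discoloration analysis.

    ``mixing_coefficient`` places the per-pixel threshold between the
    initial and final gray levels (0.5 = halfway). ``mixed_level`` is the
    percent-mixed level defining the discoloration time. Pixels whose
    total gray change is below ``static_epsilon`` are excluded as static.
    """

    mixing_coefficient: float = 0.5
    mixed_level: float = 90.0
    static_epsilon: float = 10.0
    reference_last_n: int = 1
    grayscale_weights: tuple[float, float, float] = ITU_R_601_WEIGHTS
    strict: bool = True  # mixed iff R > beta; False uses >=
    interpolate: bool = False  # sub-frame linear interpolation of t90

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixing_coefficient <= 1.0:
            raise ValueError("mixing_coefficient must be in [0, 1]")
        if not 0.0 < self.mixed_level <= 100.0:
            raise ValueError("mixed_level must be in (0, 100]")
        if self.static_epsilon < 0:
            raise ValueError("static_epsilon must be >= 0")
        if self.reference_last_n < 1:
            raise ValueError("reference_last_n must be >= 1")
        if abs(sum(self.grayscale_weights) - 1.0) > 1e-9:
            raise ValueError("grayscale_weights must sum to 1")


@dataclass
class ThresholdMap:
    """Per-pixel gray thresholds ``beta`` and validity mask.

    ``valid`` is False where the pixel showed no usable dynamics.
    """

    beta: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.beta.shape != self.valid.shape or self.beta.ndim != 2:
            raise ValueError("beta and valid must be matching 2-D arrays")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class MixingCurve:
    """Percent-of-ROI-pixels-mixed versus time."""

    times: np.ndarray
    M: np.ndarray
    n_valid: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if self.times.shape != self.M.shape:
            raise ValueError("times and M must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.M.min() < 0 or self.M.max() > 100:
            raise ValueError("M must lie in [0, 100]")


@dataclass
class DiscolorationResult:
    """Discoloration time with censoring status and provenance."""

    t90: float
    censored: bool
    curve: MixingCurve
    config: ColorimetryConfig
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "t90_s": round(float(self.t90), 6),
            "censored": bool(self.censored),
            "n_valid": int(self.curve.n_valid),
            "mixed_level": self.config.mixed_level,
            "mixing_coefficient": self.config.mixing_coefficient,
            "static_epsilon": self.config.static_epsilon,
            "metadata": dict(self.metadata),
        }


@dataclass
class FirstMixedMap:
    """Per-pixel first-mixed times; NaN marks never-mixed/invalid pixels."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 2:
            raise ValueError("times must be 2-D")


# ---------------------------------------------------------------------------
# operations


def load_frames(source, fps: float | None = None) -> FrameStack:
    """Load a FrameStack from an image-sequence directory or a video file.

    Directories are read as lexicographically sorted PNG/TIFF/JPEG/BMP
    frames and require an explicit ``fps``. Video containers are decoded
    with imageio and may carry their own frame rate, which ``fps``
    overrides. 16-bit frames are rescaled to 0-255 with a warning.
    """
    import imageio.v3 as iio

    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(f"input source not found: {source}")

    if source.is_dir():
        paths = sorted(
            p for p in source.iterdir()
            if p.suffix.lower() in {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}
        )
        if len(paths) < 2:
            raise ValueError(f"need at least 2 frames, found {len(paths)} in {source}")
        frames = []
        for p in paths:
            try:
                frames.append(iio.imread(p))
            except Exception as exc:  # pragma: no cover - backend specific
                raise ValueError(f"unreadable frame {p}: {exc}") from exc
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent frame shapes in {source}: {sorted(shapes)}")
        stack = np.stack(frames)
        meta_fps = None
    else:
        try:
            stack = np.asarray(iio.imread(source, plugin="pyav" if source.suffix in {".mp4", ".avi", ".mov"} else None))
        except Exception:
            stack = np.asarray(iio.imread(source))
        if stack.ndim == 3 and stack.shape[-1] == 3:
            raise ValueError(f"{source} decoded as a single RGB frame; need >= 2 frames")
        meta_fps = None
        try:
            meta = iio.immeta(source)
            meta_fps = meta.get("fps")
        except Exception:
            pass

    if stack.ndim == 4 and stack.shape[-1] == 4:  # drop alpha
        stack = stack[..., :3]

    if stack.dtype == np.uint16 or (np.issubdtype(stack.dtype, np.integer) and stack.max() > 255):
        warnings.warn("rescaling >8-bit frames to the 0-255 range")
        stack = np.round(stack.astype(float) * (255.0 / stack.max())).astype(np.uint8)

    eff_fps = fps if fps is not None else meta_fps
    if eff_fps is None:
        raise ValueError("frame rate unresolvable: pass fps explicitly")
    return FrameStack(frames=stack, fps=float(eff_fps))


def to_grayscale(stack: FrameStack, weights: tuple[float, float, float] = ITU_R_601_WEIGHTS) -> FrameStack:
    """Convert RGB frames to 0-255 grayscale by a weighted channel sum.

    The weighted sum is rounded half-up to an integer gray level. An
    already-grayscale stack is returned unchanged.
    """
    if not stack.is_rgb:
        return stack
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,):
        raise ValueError("weights must be a length-3 sequence")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("grayscale weights must sum to 1")
    gray = np.floor(stack.frames.astype(float) @ w + 0.5)
    gray = np.clip(gray, 0, 255).astype(np.uint8)
    return FrameStack(frames=gray, fps=stack.fps, t0_offset=stack.t0_offset, mask=stack.mask)


def crop_roi(stack: FrameStack, roi: RoiSpec) -> FrameStack:
    """Restrict a stack to a region of interest.

    Rectangles slice the frames. Mask ROIs crop to the mask's bounding
    box and attach the mask, which downstream thresholding folds into
    the validity mask (so masked-out pixels never enter M's denominator).
    """
    H, W = stack.shape
    if roi.rect is not None:
        r0, c0, h, w = roi.rect
        if r0 + h > H or c0 + w > W:
            raise ValueError(f"ROI rectangle {roi.rect} exceeds frame shape {(H, W)}")
        frames = stack.frames[:, r0:r0 + h, c0:c0 + w]
        mask = stack.mask[r0:r0 + h, c0:c0 + w] if stack.mask is not None else None
        return FrameStack(frames=frames, fps=stack.fps, t0_offset=stack.t0_offset, mask=mask)

    m = roi.mask
    if m.shape != (H, W):
        raise ValueError(f"ROI mask shape {m.shape} does not match frame shape {(H, W)}")
    if not m.any():
        raise ValueError("ROI mask selects no pixels")
    rows = np.nonzero(m.any(axis=1))[0]
    cols = np.nonzero(m.any(axis=0))[0]
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    sub = m[r0:r1, c0:c1]
    if stack.mask is not None:
        sub = sub & stack.mask[r0:r1, c0:c1]
    return FrameStack(frames=stack.frames[:, r0:r1, c0:c1], fps=stack.fps,
                      t0_offset=stack.t0_offset, mask=sub)


def threshold_map(first: np.ndarray, last: np.ndarray,
                  config: ColorimetryConfig | None = None) -> ThresholdMap:
    """Per-pixel threshold between the initial and final gray levels.

    ``beta = R0 + X * (Rinf - R0)`` with X = ``config.mixing_coefficient``.
    Pixels with ``|Rinf - R0| < static_epsilon`` carry no signal and are
    marked invalid. Raises :class:`NoDynamicsError` if nothing is valid.
    """
    config = config or ColorimetryConfig()
    r0 = np.asarray(first, dtype=float)
    rinf = np.asarray(last, dtype=float)
    if r0.shape != rinf.shape or r0.ndim != 2:
        raise ValueError("first and last frames must be matching 2-D arrays")
    beta = r0 + config.mixing_coefficient * (rinf - r0)
    valid = np.abs(rinf - r0) >= config.static_epsilon
    if not valid.any():
        raise NoDynamicsError(
            f"all pixels static: max |Rinf - R0| = {np.abs(rinf - r0).max():.3g} "
            f"< epsilon = {config.static_epsilon}")
    return ThresholdMap(beta=beta, valid=valid)


def threshold_map_from_stack(stack: FrameStack,
                             config: ColorimetryConfig | None = None) -> ThresholdMap:
    """Threshold map using frame 0 as R0 and the mean of the final
    ``reference_last_n`` frames as the Rinf reference."""
    config = config or ColorimetryConfig()
    if stack.is_rgb:
        raise ValueError("convert to grayscale before thresholding")
    n = min(config.reference_last_n, stack.n_frames)
    r0 = stack.frames[0].astype(float)
    rinf = stack.frames[-n:].astype(float).mean(axis=0)
    tmap = threshold_map(r0, rinf, config)
    if stack.mask is not None:
        valid = tmap.valid & stack.mask
        if not valid.any():
            raise NoDynamicsError("no valid pixels inside the ROI mask")
        tmap = ThresholdMap(beta=tmap.beta, valid=valid)
    return tmap


def classify_mixed(stack: FrameStack, tmap: ThresholdMap,
                   strict: bool = True) -> np.ndarray:
    """Binary mixed/unmixed classification, one frame at a time.

    A pixel is mixed when its gray value exceeds its threshold (strict
    ``>`` by default). Classification is per frame with no latching;
    invalid pixels are always 0.
    """
    if stack.is_rgb:
        raise ValueError("convert to grayscale before classification")
    if stack.shape != tmap.beta.shape:
        raise ValueError(f"stack shape {stack.shape} != threshold shape {tmap.beta.shape}")
    frames = stack.frames.astype(float)
    binary = frames > tmap.beta if strict else frames >= tmap.beta
    binary &= tmap.valid
    return binary


def mixing_curve(binary: np.ndarray, tmap: ThresholdMap, fps: float,
                 t0_offset: float = 0.0) -> MixingCurve:
    """Percent of valid pixels classified mixed in each frame."""
    n_valid = tmap.n_valid
    if n_valid == 0:
        raise NoDynamicsError("zero valid pixels in denominator")
    counts = binary[:, tmap.valid].sum(axis=1)
    M = 100.0 * counts / n_valid
    times = t0_offset + np.arange(binary.shape[0]) / fps
    return MixingCurve(times=times, M=M, n_valid=n_valid)


def discoloration_time(curve: MixingCurve,
                       config: ColorimetryConfig | None = None,
                       metadata: dict | None = None) -> DiscolorationResult:
    """Time of the first frame with M >= mixed_level.

    No sub-frame interpolation by default (resolution 1/fps). A curve
    that never reaches the level yields a result censored at the final
    frame time, flagged explicitly.
    """
    config = config or ColorimetryConfig()
    idx = first_crossing_index(curve.M, config.mixed_level)
    if idx is None:
        return DiscolorationResult(t90=float(curve.times[-1]), censored=True,
                                   curve=curve, config=config,
                                   metadata=metadata or {})
    t = float(curve.times[idx])
    if config.interpolate and idx > 0 and curve.M[idx] > curve.M[idx - 1]:
        frac = (config.mixed_level - curve.M[idx - 1]) / (curve.M[idx] - curve.M[idx - 1])
        t = float(curve.times[idx - 1] + frac * (curve.times[idx] - curve.times[idx - 1]))
    return DiscolorationResult(t90=t, censored=False, curve=curve,
                               config=config, metadata=metadata or {})


def first_mixed_map(binary: np.ndarray, fps: float,
                    t0_offset: float = 0.0) -> FirstMixedMap:
    """Time each pixel was first classified mixed; NaN if never."""
    T = binary.shape[0]
    ever = binary.any(axis=0)
    first_idx = binary.argmax(axis=0)  # 0 for all-False rows, masked below
    times = t0_offset + first_idx / fps
    out = np.where(ever, times, NEVER_MIXED)
    return FirstMixedMap(times=out)


def analyze_stack(stack: FrameStack,
                  config: ColorimetryConfig | None = None,
                  roi: RoiSpec | None = None,
                  metadata: dict | None = None):
    """Full pipeline: (optional ROI crop, grayscale) -> threshold ->
    classify -> mixing curve -> discoloration time + first-mixed map.

    Returns ``(DiscolorationResult, FirstMixedMap)``.
    """
    config = config or ColorimetryConfig()
    if roi is not None:
        stack = crop_roi(stack, roi)
    if stack.is_rgb:
        stack = to_grayscale(stack, config.grayscale_weights)
    tmap = threshold_map_from_stack(stack, config)
    binary = classify_mixed(stack, tmap, strict=config.strict)
    curve = mixing_curve(binary, tmap, stack.fps, stack.t0_offset)
    result = discoloration_time(curve, config, metadata=metadata)
    fmap = first_mixed_map(binary, stack.fps, stack.t0_offset)
    return result, fmap
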