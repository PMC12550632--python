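"""Synthetic dual-channel fluorescence frames and classical cell counting.

The instrument alternates LED colors frame by frame, so a recorded stack
interleaves two channels: the target cells being detached and a reference
monolayer used for coverage QC.  This module renders synthetic stacks with
that structure (Gaussian-blob cells on a noisy background, cells leaving
over time according to a departure schedule) and counts cells per frame
with a deterministic classical detector: difference-of-Gaussians band-pass,
robust noise-scaled threshold, connected components with an area gate.

The detector is intentionally simple — the downstream analysis consumes
only per-frame counts, and on well-separated blobs at moderate SNR the
classical pipeline counts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import difference_of_gaussians
from skimage.measure import label, regionprops

from .detachment import CountTrace

__all__ = [
    "CHANNELS",
    "SyntheticScene",
    "FrameStack",
    "DetectorParams",
    "CountResult",
    "render_frames",
    "demux_channels",
    "count_cells",
    "stack_to_count_trace",
]

CHANNELS = ("target", "monolayer")

#: Default physical pixel size (nm) of the 20x configuration.
DEFAULT_PIXEL_SIZE_NM = 170.0


@dataclass(frozen=True)
class SyntheticScene:
    """Ground-truth layout for rendering one trial's frames."""

    target_centers: np.ndarray  # (n, 2) row/col pixel coordinates
    monolayer_centers: np.ndarray
    shape: tuple[int, int] = (512, 512)
    cell_radius_px: float = 5.0
    psf_sigma_px: float = 1.5
    background: float = 100.0
    amplitude: float = 50.0
    noise_sd: float = 10.0

    def __post_init__(self) -> None:
        for name in ("target_centers", "monolayer_centers"):
            c = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if c.size == 0:
                c = np.empty((0, 2))
            if c.shape[1] != 2:
                raise ValueError(f"{name} must be an (n, 2) array")
            if len(c) and (
                c.min() < 0
                or c[:, 0].max() >= self.shape[0]
                or c[:, 1].max() >= self.shape[1]
            ):
                raise ValueError(f"{name} must lie within the frame bounds")
            object.__setattr__(self, name, c)
        if not self.cell_radius_px > 0:
            raise ValueError("cell_radius_px must be > 0")

    @property
    def snr(self) -> float:
        return self.amplitude / self.noise_sd


@dataclass(frozen=True)
class FrameStack:
    """Interleaved two-channel image stack (even frames target, odd monolayer)."""

    frames: np.ndarray  # (n_frames, h, w)
    timestamps_s: np.ndarray
    channel_labels: tuple[str, ...]
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        t = np.asarray(self.timestamps_s, dtype=float)
        if f.ndim != 3 or len(t) != len(f) or len(self.channel_labels) != len(f):
            raise ValueError("frames, timestamps and labels must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "frames", f)
        object.__setattr__(self, "timestamps_s", t)

    def is_alternating(self) -> bool:
        return all(
            lab == CHANNELS[i % 2] for i, lab in enumerate(self.channel_labels)
        )


@dataclass(frozen=True)
class DetectorParams:
    """Classical spot-detector settings (pixel units)."""

    low_sigma_px: float = 1.5
    high_sigma_px: float = 8.0
    threshold_nsigma: float = 5.0
    min_area_px: int = 10
    max_area_px: int | None = None
    saturation_level: float | None = None


@dataclass(frozen=True)
class CountResult:
    count: int
    centroids: np.ndarray  # (n, 2) row/col
    flags: tuple[str, ...] = ()


def _render_channel(
    centers: np.ndarray, scene: SyntheticScene, rng: np.random.Generator
) -> np.ndarray:
    img = np.zeros(scene.shape)
    if len(centers):
        rr, cc = np.indices(scene.shape, sparse=True)
        canvas = np.zeros(scene.shape)
        for r, c in centers:
            # disk of the cell's footprint; PSF blur applied once below
            mask = (rr - r) ** 2 + (cc - c) ** 2 <= scene.cell_radius_px**2
            canvas[mask] = 1.0
        img = scene.amplitude * ndimage.gaussian_filter(canvas, scene.psf_sigma_px)
    img += scene.background
    img += rng.normal(0.0, scene.noise_sd, size=scene.shape)
    return img


def render_frames(
    scene: SyntheticScene,
    n_frames: int,
    departure_schedule: np.ndarray | None = None,
    seed: int = 0,
    frame_interval_s: float = 0.25,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
) -> FrameStack:
    """Render an interleaved two-channel stack of ``n_frames`` total frames.

    ``departure_schedule`` gives the number of target cells still present at
    each *target* frame (cells leave in reverse order of their index); when
    omitted all cells stay.  The monolayer channel is static.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    n_target = (n_frames + 1) // 2
    if departure_schedule is None:
        departure_schedule = np.full(n_target, len(scene.target_centers))
    departure_schedule = np.asarray(departure_schedule, dtype=int)
    if len(departure_schedule) != n_target:
        raise ValueError(
            f"departure_schedule must have one entry per target frame ({n_target})"
        )
    if departure_schedule.max(initial=0) > len(scene.target_centers):
        raise ValueError("departure_schedule exceeds the number of target cells")

    rng = np.random.default_rng(seed)
    frames = []
    labels = []
    t_idx = 0
    for i in range(n_frames):
        ch = CHANNELS[i % 2]
        if ch == "target":
            present = scene.target_centers[: departure_schedule[t_idx]]
            frames.append(_render_channel(present, scene, rng))
            t_idx += 1
        else:
            frames.append(_render_channel(scene.monolayer_centers, scene, rng))
        labels.append(ch)
    times = frame_interval_s * np.arange(n_frames)
    return FrameStack(
        frames=np.stack(frames),
        timestamps_s=times,
        channel_labels=tuple(labels),
        pixel_size_nm=pixel_size_nm,
    )


def demux_channels(stack: FrameStack) -> tuple[FrameStack, FrameStack]:
    """Split an alternating stack into (target, monolayer) sub-stacks."""
    if not stack.is_alternating():
        raise ValueError("stack labels do not alternate target/monolayer")
    out = []
    for parity, name in enumerate(CHANNELS):
        sel = slice(parity, None, 2)
        out.append(
            FrameStack(
                frames=stack.frames[sel],
                timestamps_s=stack.timestamps_s[sel],
                channel_labels=tuple([name] * len(stack.frames[sel])),
                pixel_size_nm=stack.pixel_size_nm,
            )
        )
    return out[0], out[1]


def count_cells(frame: np.ndarray, params: DetectorParams = DetectorParams()) -> CountResult:
    """Count blob-like cells in a single-channel frame.

    Difference-of-Gaussians band-pass removes the background pedestal and
    high-frequency noise; pixels above ``threshold_nsigma`` robust noise SDs
    are grouped into connected components, and components passing the area
    gate are counted.  Blank or saturated frames return zero with a QC flag.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("count_cells expects a single 2-D frame")
    flags: list[str] = []

    if params.saturation_level is not None:
        sat = np.mean(img >= params.saturation_level)
        if sat > 0.5:
            return CountResult(0, np.empty((0, 2)), ("saturated",))

    dog = difference_of_gaussians(img, params.low_sigma_px, params.high_sigma_px)
    med = np.median(dog)
    mad = np.median(np.abs(dog - med))
    sigma = 1.4826 * mad
    if sigma == 0:
        return CountResult(0, np.empty((0, 2)), ("blank",))
    mask = dog > med + params.threshold_nsigma * sigma

    lab = label(mask)
    centroids = []
    for region in regionprops(lab):
        if region.area < params.min_area_px:
            continue
        if params.max_area_px is not None and region.area > params.max_area_px:
            continue
        centroids.append(region.centroid)
    centroids_arr = np.array(centroids) if centroids else np.empty((0, 2))
    if len(centroids_arr) == 0:
        flags.append("blank")
    return CountResult(len(centroids_arr), centroids_arr, tuple(flags))


def stack_to_count_trace(
    stack: FrameStack,
    params: DetectorParams = DetectorParams(),
    include_monolayer: bool = True,
) -> CountTrace:
    """Count every frame of an interleaved stack into a :class:`CountTrace`.

    Target-channel counts carry their own timestamps; when the monolayer
    channel is present its counts are attached via nearest-frame lookup for
    coverage QC.
    """
    target, mono = demux_channels(stack)
    t_counts = np.array([count_cells(f, params).count for f in target.frames], dtype=float)
    mono_aligned = None
    if include_monolayer and len(mono.frames):
        m_counts = np.array([count_cells(f, params).count for f in mono.frames], dtype=float)
        nearest = np.searchsorted(mono.timestamps_s, target.timestamps_s)
        nearest = np.clip(nearest, 0, len(m_counts) - 1)
        mono_aligned = m_counts[nearest]
    return CountTrace(
        times_s=target.timestamps_s,
        target_counts=t_counts,
        monolayer_counts=mono_aligned,
    )
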