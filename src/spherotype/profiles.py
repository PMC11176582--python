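"""Plot-profile extraction from multi-channel spheroid z-stacks.

A profile is the per-channel intensity along the long axis of a rectangular
region spanning the spheroid center: at each long-axis position the
intensity is averaged across the short axis, per-slice profiles are summed
over the stack, a centered rolling average suppresses noise, and the area
under the curve is taken above a lower-quartile baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "CHANNELS",
    "SpheroidStack",
    "ProfileROI",
    "PlotProfile",
    "extract_stack_profile",
    "auto_roi",
    "smooth_profile",
    "baseline_and_auc",
    "read_stack",
    "write_stack",
    "write_profile_csv",
    "read_profile_csv",
]

CHANNELS = ("CAM", "PI", "TL")


@dataclass
class SpheroidStack:
    """3-channel (CAM, PI, TL) z-stack with physical pixel size."""

    voxels: np.ndarray  # (3, Z, H, W)
    pixel_size_um: float
    channel_names: tuple[str, str, str] = CHANNELS

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4 or self.voxels.shape[0] != 3:
            raise ValueError("voxels must have shape (3, Z, H, W)")
        if self.voxels.shape[1] < 1:
            raise ValueError("need at least one z-slice")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if len(self.channel_names) != 3:
            raise ValueError("exactly 3 channel names required")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.voxels.shape

    def channel(self, name: str) -> np.ndarray:
        return self.voxels[self.channel_names.index(name)]


@dataclass(frozen=True)
class ProfileROI:
    """Rectangle spanning the spheroid center: ``center`` in (x, y) pixel
    coordinates, ``angle`` the long-axis orientation in degrees."""

    center: tuple[float, float]
    angle: float = 0.0
    length_px: int = 0
    width_px: int = 10

    def __post_init__(self) -> None:
        if self.length_px < 1:
            raise ValueError("length_px must be >= 1")
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")

    def sample_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) sampling grids of shape (width_px, length_px)."""
        t = np.arange(self.length_px) - (self.length_px - 1) / 2.0
        w = np.arange(self.width_px) - (self.width_px - 1) / 2.0
        a = np.deg2rad(self.angle)
        dx, dy = np.cos(a), np.sin(a)
        cx, cy = self.center
        cols = cx + t[None, :] * dx + w[:, None] * (-dy)
        rows = cy + t[None, :] * dy + w[:, None] * dx
        return rows, cols


@dataclass
class PlotProfile:
    """Per-channel intensity vs position (μm) along the ROI long axis."""

    positions_um: np.ndarray
    intensities: dict[str, np.ndarray]
    pixel_size_um: float
    smoothed: bool = False
    baselines: dict[str, float] = field(default_factory=dict)
    aucs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        n = self.positions_um.size
        if n < 1:
            raise ValueError("empty profile")
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValueError("positions must be strictly increasing")
        for name, y in self.intensities.items():
            y = np.asarray(y, dtype=float)
            if y.size != n:
                raise ValueError(f"channel {name} length mismatch")
            self.intensities[name] = y

    def __len__(self) -> int:
        return self.positions_um.size


def extract_stack_profile(stack: SpheroidStack, roi: ProfileROI) -> PlotProfile:
    """Average across the ROI short axis, per slice and channel, then sum
    the per-slice profiles over Z.  Positions are returned in μm."""
    rows, cols = roi.sample_coordinates()
    _, _, h, w = stack.shape
    if rows.min() < 0 or cols.min() < 0 or rows.max() > h - 1 or cols.max() > w - 1:
        raise ValueError("ROI extends outside image bounds")

    coords = np.stack([rows.ravel(), cols.ravel()])
    out: dict[str, np.ndarray] = {}
    for ci, name in enumerate(stack.channel_names):
        total = np.zeros(roi.length_px)
        for z in range(stack.shape[1]):
            sampled = ndimage.map_coordinates(
                stack.voxels[ci, z], coords, order=1, mode="nearest"
            ).reshape(roi.width_px, roi.length_px)
            total += sampled.mean(axis=0)
        out[name] = total
    positions = np.arange(roi.length_px) * stack.pixel_size_um
    return PlotProfile(positions_um=positions, intensities=out,
                       pixel_size_um=stack.pixel_size_um)


def _coherent_mask(img: np.ndarray) -> np.ndarray | None:
    """Otsu mask if it forms one dominant blob (a spheroid), else None.
    Noise-only images threshold to speckle whose largest component is a
    negligible fraction of the mask."""
    if img.max() <= img.min():
        return None
    mask = img > threshold_otsu(img)
    n_fg = mask.sum()
    if n_fg == 0 or n_fg > 0.7 * mask.size:
        return None
    labels, n = ndimage.label(mask)
    if n == 0:
        return None
    sizes = np.bincount(labels.ravel())[1:]
    if sizes.max() < 0.5 * n_fg:
        return None
    return mask


def _spheroid_mask(stack: SpheroidStack) -> np.ndarray:
    """Binary mask of the spheroid from the central-slice TL attenuation
    (dark object on bright background); falls back to the CAM channel."""
    zc = stack.shape[1] // 2
    tl = stack.channel("TL")[zc]
    mask = _coherent_mask(tl.max() - tl)
    if mask is None:
        mask = _coherent_mask(stack.channel("CAM")[zc])
    if mask is None:
        raise ValueError("blank stack: no spheroid signal in TL or CAM")
    return mask


def auto_roi(stack: SpheroidStack, width_px: int = 10,
             length_factor: float = 1.5) -> ProfileROI:
    """Horizontal ROI centered on the spheroid: center at the mask
    centroid, length ``length_factor`` × the mask-equivalent diameter
    (clipped to the field of view)."""
    mask = _spheroid_mask(stack)
    mask = ndimage.binary_fill_holes(mask)
    cy, cx = ndimage.center_of_mass(mask)
    diameter_px = 2.0 * np.sqrt(mask.sum() / np.pi)
    _, _, h, w = stack.shape
    length = int(round(length_factor * diameter_px))
    max_len = int(2 * min(cx, w - 1 - cx)) + 1
    length = max(3, min(length, max_len, w))
    return ProfileROI(center=(float(cx), float(cy)), angle=0.0,
                      length_px=length, width_px=width_px)


def smooth_profile(profile: PlotProfile, window: int = 3) -> PlotProfile:
    """Centered rolling average per channel; endpoints use shrunken windows
    so length is preserved."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    n = len(profile)
    if window > n:
        raise ValueError("window larger than profile")
    half = window // 2
    smoothed = {}
    for name, y in profile.intensities.items():
        csum = np.concatenate([[0.0], np.cumsum(y)])
        idx = np.arange(n)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half, n - 1)
        smoothed[name] = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return PlotProfile(positions_um=profile.positions_um.copy(),
                       intensities=smoothed,
                       pixel_size_um=profile.pixel_size_um,
                       smoothed=True)


def baseline_and_auc(profile: PlotProfile) -> dict[str, tuple[float, float]]:
    """Lower-quartile baseline and baseline-corrected trapezoidal AUC per
    channel.  Negative excursions are clipped to zero before integration.
    Results are stored on the profile and returned as
    ``{channel: (baseline, auc)}``."""
    if not profile.smoothed:
        raise ValueError("profile must be smoothed before baselining")
    if len(profile) < 4:
        raise ValueError("profile too short (need >= 4 samples)")
    out = {}
    for name, y in profile.intensities.items():
        baseline = float(np.percentile(y, 25))
        corrected = np.clip(y - baseline, 0.0, None)
        auc = float(np.trapezoid(corrected, profile.positions_um))
        profile.baselines[name] = baseline
        profile.aucs[name] = auc
        out[name] = (baseline, auc)
    return out


# ---------------------------------------------------------------- file I/O

def write_stack(stack: SpheroidStack, path: str | Path) -> None:
    """Write a (3, Z, H, W) stack as a multi-page TIFF with channel order
    and pixel size recorded in the image description."""
    meta = {
        "channel_names": list(stack.channel_names),
        "pixel_size_um": stack.pixel_size_um,
        "axes": "CZYX",
    }
    tifffile.imwrite(
        Path(path),
        stack.voxels.astype(np.float32),
        description=json.dumps(meta, sort_keys=True),
        photometric="minisblack",
    )


def read_stack(path: str | Path,
               channel_order: tuple[str, str, str] | None = None,
               pixel_size_um: float | None = None) -> SpheroidStack:
    """Read a multi-page TIFF written by :func:`write_stack`.  Explicit
    ``channel_order`` / ``pixel_size_um`` override the embedded metadata."""
    with tifffile.TiffFile(Path(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    names = tuple(channel_order or meta.get("channel_names", CHANNELS))
    px = pixel_size_um or meta.get("pixel_size_um")
    if px is None:
        raise ValueError("pixel size missing from metadata; pass pixel_size_um")
    data = np.asarray(data, dtype=float)
    if data.ndim == 3:  # single slice stored as (3, H, W)
        data = data[:, None, :, :]
    return SpheroidStack(voxels=data, pixel_size_um=float(px),
                         channel_names=names)  # type: ignore[arg-type]


def write_profile_csv(profile: PlotProfile, path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame({"position_um": profile.positions_um})
    for name in profile.intensities:
        df[name.lower()] = profile.intensities[name]
    with open(path, "w") as fh:
        fh.write(f"# smoothed={profile.smoothed} "
                 f"pixel_size_um={profile.pixel_size_um}\n")
        df.to_csv(fh, index=False)


def read_profile_csv(path: str | Path) -> PlotProfile:
    import pandas as pd

    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    smoothed = "smoothed=True" in header
    px = float(header.split("pixel_size_um=")[1].split()[0])
    intensities = {
        name: df[name.lower()].to_numpy()
        for name in CHANNELS if name.lower() in df
    }
    return PlotProfile(positions_um=df["position_um"].to_numpy(),
                       intensities=intensities, pixel_size_um=px,
                       smoothed=smoothed)
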