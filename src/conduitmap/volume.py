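"""Volume I/O and pixel-level preprocessing.

Covers the image-side half of the extraction pipeline: z-intensity
equalization of block-face stacks, local-threshold segmentation, mask
arithmetic (used to subtract blood vessels from the conduit channel) and
largest-connected-object selection.

Conventions: arrays are indexed ``(z, y, x)``; voxel indices are 0-based;
the world position of voxel ``(i, j, k)`` is ``origin + (index + 0.5) *
voxel_size`` in micrometres, with isotropic voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "VolumeImage",
    "EqualizationProfile",
    "equalize_z",
    "segment",
    "mask_combine",
    "largest_component",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class VolumeImage:
    """A 3D scalar grid with isotropic voxel size in micrometres.

    ``role`` is ``"grayscale"`` (8-bit intensities) or ``"mask"`` (values
    in {0, 1}).
    """

    data: np.ndarray
    voxel_size: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    role: str = "grayscale"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume must be a 3D grid with all extents >= 1")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.role not in ("grayscale", "mask"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "mask":
            vals = np.unique(self.data)
            if not np.isin(vals, [0, 1]).all():
                raise ValueError("mask volume must contain only {0, 1}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)

    def index_to_world(self, idx) -> np.ndarray:
        """World (x, y, z) position of voxel center(s) at index ``(z, y, x)``.

        ``origin`` is stored in world (x, y, z) order; array axes run
        (z, y, x), so the index is reversed before mapping.
        """
        idx = np.asarray(idx, dtype=float)
        return self.origin + (idx[..., ::-1] + 0.5) * self.voxel_size

    def world_to_index(self, pos) -> np.ndarray:
        """Fractional (z, y, x) index of a world (x, y, z) position."""
        pos = np.asarray(pos, dtype=float)
        return ((pos - self.origin) / self.voxel_size - 0.5)[..., ::-1]

    def like(self, data: np.ndarray, role: str | None = None) -> "VolumeImage":
        return VolumeImage(data, self.voxel_size, self.origin.copy(),
                           role or self.role)

    # -- TIFF I/O (8-bit grayscale; masks stored as 0/255) ----------------
    def save_tiff(self, path) -> None:
        if self.role == "mask":
            out = (self.as_bool() * np.uint8(255))
        else:
            out = np.clip(self.data, 0, 255).astype(np.uint8)
        tifffile.imwrite(str(path), out)

    @classmethod
    def load_tiff(cls, path, voxel_size: float = 1.0, origin=(0.0, 0.0, 0.0),
                  role: str = "grayscale") -> "VolumeImage":
        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]
        if role == "mask":
            data = (data > 0).astype(np.uint8)
        return cls(data, voxel_size, np.asarray(origin, dtype=float), role)


@dataclass
class EqualizationProfile:
    """Per-plane intensity record of the z-equalization step.

    ``correction`` is ``f(z) = a * SA(z) / A(z) + (1 - a)`` for planes with
    ``A(z) > 0`` and 1 elsewhere, where ``A`` is the plane average above a
    noise threshold and ``SA`` its smoothed counterpart.
    """

    average: np.ndarray          # A(z)
    smoothed_average: np.ndarray  # SA(z)
    correction: np.ndarray       # f(z)
    a: float


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, edge-truncated (window shrinks at the ends)."""
    n = len(values)
    half = window // 2
    out = np.empty(n, dtype=float)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def equalize_z(img: VolumeImage, a: float = 0.9, noise_threshold: float = 0.0,
               smooth_window: int = 21) -> tuple[VolumeImage, EqualizationProfile]:
    """Equalize average intensity along z.

    For each plane the average intensity ``A(z)`` of pixels above
    ``noise_threshold`` is computed, smoothed along z into ``SA(z)``, and
    each plane is multiplied by ``f(z) = a*SA(z)/A(z) + (1-a)`` then clamped
    to [0, 255].  The weight ``a`` (default 0.9) limits over-correction;
    ``a = 0`` leaves the image unchanged.  Planes with no above-threshold
    signal get ``f(z) = 1``.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("a must lie in [0, 1]")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    if img.data.size == 0:
        raise ValueError("empty image")
    data = img.data.astype(float)
    nz = data.shape[0]
    avg = np.zeros(nz)
    for z in range(nz):
        plane = data[z]
        sel = plane > noise_threshold
        if sel.any():
            avg[z] = plane[sel].mean()
    smoothed = _moving_average(avg, smooth_window)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(avg > 0, a * smoothed / np.where(avg > 0, avg, 1.0) + (1 - a), 1.0)
    corrected = np.clip(data * f[:, None, None], 0, 255)
    profile = EqualizationProfile(avg, smoothed, f, a)
    return img.like(corrected, role="grayscale"), profile


def segment(img: VolumeImage, window: float = 25.0, offset: float = 30.0) -> VolumeImage:
    """Local-threshold segmentation.

    A voxel is foreground iff its intensity exceeds the mean over a cubic
    window of side ``window`` um centered on it, plus ``offset`` intensity
    units.  The windowed mean uses reflective boundaries.  Local (rather
    than global) thresholding is what lets fine dim tubes survive next to
    bright thick ones.
    """
    size = int(round(window / img.voxel_size))
    if size < 1:
        raise ValueError("threshold window is smaller than one voxel")
    data = img.data.astype(float)
    local_mean = ndimage.uniform_filter(data, size=size, mode="reflect")
    mask = (data > local_mean + offset).astype(np.uint8)
    return img.like(mask, role="mask")


def mask_combine(a: VolumeImage, b: VolumeImage, mode: str = "union",
                 grow: float = 0.0) -> VolumeImage:
    """Combine two masks: ``union`` (a OR b) or ``subtract`` (a AND NOT b').

    For subtraction ``b`` is first dilated by a Euclidean distance of
    ``grow`` um, which is how perivascular conduit sleeves are removed
    together with the vessel core they wrap.
    """
    if a.data.shape != b.data.shape:
        raise ValueError("mask grids do not match")
    if a.role != "mask" or b.role != "mask":
        raise ValueError("mask_combine requires mask-role volumes")
    bb = b.as_bool()
    if mode == "union":
        out = a.as_bool() | bb
    elif mode == "subtract":
        if grow > 0 and bb.any():
            dist = ndimage.distance_transform_edt(~bb, sampling=b.voxel_size)
            bb = dist <= grow
        out = a.as_bool() & ~bb
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return a.like(out.astype(np.uint8), role="mask")


def largest_component(mask: VolumeImage, connectivity: int = 26) -> VolumeImage:
    """Keep only the largest connected foreground component.

    Ties are broken toward the component first encountered in scan order
    (lowest label index).
    """
    if mask.role != "mask":
        raise ValueError("largest_component requires a mask volume")
    fg = mask.as_bool()
    if not fg.any():
        raise ValueError("empty mask")
    labels, n = ndimage.label(fg, structure=_STRUCTURES[connectivity])
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = int(np.argmax(counts))  # argmax returns the lowest index on ties
    return mask.like((labels == keep).astype(np.uint8), role="mask")
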