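"""Reading and binarizing scanned root-system images.

Root systems are scanned as grayscale images of washed roots spread on a
black background, so the network is bright on dark and a single global
threshold separates it.  Binarization is followed by small-component
removal to drop scanner dust and water droplets without deleting fine
lateral roots.

Physical scale is carried explicitly: every mask knows its pixels per
centimetre, and all downstream traits are reported in cm-based units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "PX_PER_CM_300DPI",
    "ScanImage",
    "BinaryMask",
    "load_scan",
    "binarize",
    "load_mask",
]

#: pixels per centimetre of a 300 dpi scan
PX_PER_CM_300DPI = 300.0 / 2.54

# 8-connectivity structuring element, used for components and perimeter
# throughout so skeleton / perimeter conventions cannot diverge.
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class ScanImage:
    """A grayscale scan with physical scale.

    Attributes
    ----------
    pixels : ndarray
        2-D grayscale intensity grid (row index increases downward,
        i.e. toward rooting depth).
    px_per_cm : float
        Pixels per centimetre.
    """

    pixels: np.ndarray
    px_per_cm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"scan must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(np.asarray(self.pixels, dtype=float))):
            raise ValueError("scan contains non-finite intensities")
        if not (np.isfinite(self.px_per_cm) and self.px_per_cm > 0):
            raise ValueError(f"px_per_cm must be positive, got {self.px_per_cm}")


@dataclass
class BinaryMask:
    """Boolean pixel grid of a root network with physical scale.

    Origin is the top-left corner; the row index increases downward,
    toward rooting depth.
    """

    grid: np.ndarray
    px_per_cm: float
    n_removed_components: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.grid.shape}")
        if not (np.isfinite(self.px_per_cm) and self.px_per_cm > 0):
            raise ValueError(f"px_per_cm must be positive, got {self.px_per_cm}")

    @property
    def cm_per_px(self) -> float:
        return 1.0 / self.px_per_cm

    def count_foreground(self) -> int:
        return int(self.grid.sum())

    def save(self, path: str | Path) -> None:
        """Write the mask as a 1-bit PNG (white roots on black)."""
        img = Image.fromarray(self.grid.astype(np.uint8) * 255).convert("1")
        dpi = self.px_per_cm * 2.54
        img.save(Path(path), dpi=(dpi, dpi))


def _luminance(arr: np.ndarray) -> np.ndarray:
    """ITU-R 601 luminance of an RGB(A) array."""
    rgb = arr[..., :3].astype(np.float64)
    return rgb @ np.array([0.299, 0.587, 0.114])


def load_scan(path: str | Path, px_per_cm: float | None = None) -> ScanImage:
    """Load a PNG or TIFF scan as a single-channel :class:`ScanImage`.

    Multi-channel images are converted by luminance.  The physical scale
    is taken from the file's dpi metadata when present; an explicit
    ``px_per_cm`` argument overrides metadata.  If neither is available
    an error is raised (pass the scanner resolution explicitly).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scan not found: {path}")
    try:
        with Image.open(path) as img:
            img.load()
            dpi = img.info.get("dpi")
            arr = np.asarray(img)
    except FileNotFoundError:
        raise
    except Exception as exc:  # PIL raises various per-format errors
        raise ValueError(f"cannot read image {path}: {exc}") from exc

    if arr.ndim == 3:
        arr = _luminance(arr)
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality in {path}: {arr.shape}")

    if px_per_cm is None:
        if dpi is not None and float(dpi[0]) > 0:
            px_per_cm = float(dpi[0]) / 2.54
        else:
            raise ValueError(
                f"{path} carries no resolution metadata; pass px_per_cm explicitly"
            )
    return ScanImage(pixels=arr, px_per_cm=float(px_per_cm))


def default_min_component_px(px_per_cm: float, base: int = 50) -> int:
    """Speckle-size floor, ``base`` px at 300 dpi scaled by area."""
    return max(1, round(base * (px_per_cm / PX_PER_CM_300DPI) ** 2))


def binarize(
    scan: ScanImage,
    method: str = "otsu",
    threshold: float | None = None,
    min_component_px: int | None = None,
) -> BinaryMask:
    """Threshold a scan into a root mask and remove speckle.

    Foreground is every pixel strictly brighter than the threshold
    (roots are brighter than the black background).  Connected
    components (8-connectivity) smaller than ``min_component_px`` are
    removed; the number removed is recorded on the returned mask.

    Parameters
    ----------
    method : {"otsu", "fixed"}
        "otsu" picks the threshold from the grayscale histogram;
        "fixed" uses the ``threshold`` argument.
    """
    pixels = np.asarray(scan.pixels, dtype=float)
    if method == "otsu":
        if pixels.max() == pixels.min():
            raise ValueError("no root network detected (constant image)")
        thr = float(threshold_otsu(pixels))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown threshold method {method!r}")

    fg = pixels > thr
    if min_component_px is None:
        min_component_px = default_min_component_px(scan.px_per_cm)

    n_removed = 0
    if min_component_px > 1 and fg.any():
        labels, n_comp = ndimage.label(fg, structure=_STRUCT8)
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_component_px
        keep[0] = False
        n_removed = int(n_comp - keep[1:].sum())
        fg = keep[labels]

    if not fg.any():
        raise ValueError("no root network detected")
    return BinaryMask(
        grid=fg,
        px_per_cm=scan.px_per_cm,
        n_removed_components=n_removed,
        meta={"threshold": thr, "method": method, "min_component_px": min_component_px},
    )


def load_mask(path: str | Path, px_per_cm: float | None = None) -> BinaryMask:
    """Load an already-binary (or near-binary) mask image.

    Any pixel above half the intensity range counts as foreground; no
    speckle removal is applied.
    """
    scan = load_scan(path, px_per_cm=px_per_cm)
    pixels = np.asarray(scan.pixels, dtype=float)
    thr = 0.5 * (pixels.max() + pixels.min())
    grid = pixels > thr
    if not grid.any():
        warnings.warn(f"mask {path} has no foreground pixels")
    return BinaryMask(grid=grid, px_per_cm=scan.px_per_cm)
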