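"""Image conditioning: Gaussian blur, CLAHE, thresholding, batch processing.

The chain runs in a fixed order — blur, local contrast enhancement, then
threshold/binarize — and is fully deterministic: identical input bytes and
configuration give identical output bytes.  8-bit grayscale is the working
convention; color inputs are converted by luminance on load.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import exposure, filters

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "gaussian_blur",
    "clahe",
    "binarize",
    "preprocess_image",
    "preprocess_batch",
    "load_grayscale",
    "save_grayscale",
]

#: file extensions accepted by the batch processor
IMAGE_EXTENSIONS = (".png", ".tif", ".jpg")


@dataclass(frozen=True)
class PreprocessConfig:
    """Pipeline settings.

    sigma : float
        Standard deviation (pixels) of the Gaussian blur; default 2.
    clahe_block : int
        CLAHE tile side in pixels (odd, >= 3); default 127.
    clahe_bins : int
        Histogram bins per tile; default 256.
    clahe_clip : float
        Contrast cap expressed as a max slope of the tile mapping
        (histogram clipped at clip/bins of the tile pixel count); default 3.
    threshold_method : str
        'otsu' (default) or 'fixed'.
    fixed_threshold : int, optional
        Intensity cut for the fixed method (foreground strictly above).
    """

    sigma: float = 2.0
    clahe_block: int = 127
    clahe_bins: int = 256
    clahe_clip: float = 3.0
    threshold_method: str = "otsu"
    fixed_threshold: int | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.clahe_block < 3 or self.clahe_block % 2 == 0:
            raise ValueError(f"clahe_block must be odd and >= 3, got {self.clahe_block}")
        if self.clahe_bins < 2:
            raise ValueError(f"clahe_bins must be >= 2, got {self.clahe_bins}")
        if self.clahe_clip < 1:
            raise ValueError(f"clahe_clip must be >= 1, got {self.clahe_clip}")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if self.threshold_method == "fixed":
            if self.fixed_threshold is None or not 0 <= self.fixed_threshold <= 255:
                raise ValueError("fixed threshold must be set and within [0, 255]")


def _check_gray(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2D grayscale image, got shape {arr.shape}")
    return arr


def gaussian_blur(img: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Convolve with the discrete, renormalized 2D Gaussian kernel.

    The kernel samples the Gaussian density on the integer grid, truncated
    at a 4-sigma radius and renormalized to unit sum, with reflect padding
    at the borders; a constant image is therefore reproduced exactly and
    the mean intensity is conserved away from the boundary.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    arr = _check_gray(img)
    out = ndimage.gaussian_filter(arr, sigma=sigma, mode="reflect", truncate=4.0)
    return np.clip(out, 0.0, 255.0)


def clahe(
    img: np.ndarray, block: int = 127, bins: int = 256, clip: float = 3.0
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Tile-wise equalization with the cumulative-mapping slope capped at
    ``clip`` (the tile histogram is clipped at ``clip/bins`` of the tile
    pixel count, the max-slope convention of the common ImageJ plugin).
    Output is rescaled back to the 8-bit range [0, 255].
    """
    cfg = PreprocessConfig(clahe_block=block, clahe_bins=bins, clahe_clip=clip)
    arr = _check_gray(img)
    if np.ptp(arr) == 0:
        return arr.copy()  # flat histogram: nothing to equalize
    out = exposure.equalize_adapthist(
        arr.astype(np.uint8),
        kernel_size=cfg.clahe_block,
        clip_limit=cfg.clahe_clip / cfg.clahe_bins,
        nbins=cfg.clahe_bins,
    )
    return out * 255.0


def binarize(
    img: np.ndarray,
    method: str = "otsu",
    fixed_threshold: int | None = None,
) -> np.ndarray:
    """Threshold a grayscale image; foreground = pixels strictly above the cut.

    Otsu's criterion (maximum between-class variance) picks the threshold
    by default.  A constant image cannot be split and yields an all-
    background mask with a warning rather than an error.
    """
    arr = _check_gray(img)
    if method == "fixed":
        if fixed_threshold is None or not 0 <= fixed_threshold <= 255:
            raise ValueError("fixed threshold must be set and within [0, 255]")
        thr = float(fixed_threshold)
    elif method == "otsu":
        if np.ptp(arr) == 0:
            warnings.warn(
                "constant image: Otsu threshold undefined, returning all-background mask",
                RuntimeWarning,
                stacklevel=2,
            )
            return np.zeros(arr.shape, dtype=bool)
        thr = float(filters.threshold_otsu(arr.astype(np.uint8)))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    logger.debug("binarize: method=%s threshold=%.2f", method, thr)
    return arr > thr


def preprocess_image(img: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Full chain: blur -> CLAHE -> threshold; returns the boolean foreground mask."""
    cfg = config or PreprocessConfig()
    out = gaussian_blur(img, cfg.sigma)
    out = clahe(out, cfg.clahe_block, cfg.clahe_bins, cfg.clahe_clip)
    return binarize(out, cfg.threshold_method, cfg.fixed_threshold)


def enhance_image(img: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Blur + CLAHE only (the grayscale result saved by the batch processor)."""
    cfg = config or PreprocessConfig()
    out = gaussian_blur(img, cfg.sigma)
    return clahe(out, cfg.clahe_block, cfg.clahe_bins, cfg.clahe_clip)


# --- file I/O -------------------------------------------------------------

#: ITU-R 601 luminance weights used for color -> gray conversion
_LUMA = (0.299, 0.587, 0.114)


def load_grayscale(path: str | Path) -> np.ndarray:
    """Read an image file as 8-bit grayscale (color converted by luminance)."""
    from PIL import Image

    with Image.open(path) as im:
        if im.mode not in ("L", "I;16", "I"):
            im = im.convert("L")  # Pillow applies the ITU-R 601 weights
        arr = np.asarray(im)
    if arr.dtype != np.uint8:
        arr = np.clip(arr.astype(float) / max(1, arr.max()) * 255.0, 0, 255).astype(np.uint8)
    return arr


def save_grayscale(path: str | Path, img: np.ndarray) -> None:
    """Write an array as an 8-bit grayscale PNG (rounded and clipped)."""
    from PIL import Image

    arr = np.asarray(img)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    else:
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def preprocess_batch(
    in_dir: str | Path,
    out_dir: str | Path,
    config: PreprocessConfig | None = None,
) -> dict[str, int]:
    """Process every image file of a directory, in sorted order.

    Files with extensions .png/.tif/.jpg (any case) are blurred and
    CLAHE-enhanced and saved as ``<stem>_processed.png``; everything else
    is skipped and counted.  Unreadable image files are logged and skipped
    rather than aborting the batch.
    """
    cfg = config or PreprocessConfig()
    in_dir = Path(in_dir)
    out_dir = Path(out_dir)
    if not in_dir.is_dir():
        raise FileNotFoundError(f"input directory not found: {in_dir}")
    out_dir.mkdir(parents=True, exist_ok=True)
    processed = skipped = failed = 0
    for path in sorted(in_dir.iterdir()):
        if not path.is_file() or path.suffix.lower() not in IMAGE_EXTENSIONS:
            if path.is_file():
                skipped += 1
            continue
        try:
            img = load_grayscale(path)
            out = enhance_image(img, cfg)
        except Exception as exc:  # unreadable/corrupt file: skip, don't abort
            logger.warning("skipping unreadable file %s: %s", path.name, exc)
            failed += 1
            continue
        save_grayscale(out_dir / f"{path.stem}_processed.png", out)
        processed += 1
    logger.info(
        "preprocess_batch: %d processed, %d skipped, %d failed (%s -> %s)",
        processed, skipped, failed, in_dir, out_dir,
    )
    return {"processed": processed, "skipped": skipped, "failed": failed}
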