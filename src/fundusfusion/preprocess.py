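"""Smart preprocessing of raw fundus photographs.

Five stages turn a raw RGB fundus photograph into the pair of 78x116
tensors the CNN branch consumes:

1. ingest the raw image (which carries burned-in patient/date text);
2. blacken the text band (all text pixels set to exactly 0);
3. single-scale Retinex to remove the flash illumination field:
   per channel, ``log(I + eps) - log(G_sigma * I + eps)``, rescaled to
   [0, 255];
4. restrict to an elliptical region of interest covering optic cup,
   disc and macula — pixels outside the ellipse are zeroed, and in
   "delete" mode the frame is additionally cropped to the ellipse's
   bounding box;
5. augment each image into two (the original plus one random rotation
   from {30, 60, 90, 120, 180} degrees counterclockwise) and resize to
   78 rows x 116 columns with exact area interpolation (mean
   preserving).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

ROTATION_ANGLES = (30, 60, 90, 120, 180)
TARGET_SHAPE = (78, 116)


@dataclass(frozen=True)
class RetinexParams:
    """Single-scale Retinex with a Gaussian surround."""

    surround_sigma: float = 30.0
    epsilon: float = 1.0
    output_rescale: str = "minmax"  # or "clip"

    def __post_init__(self) -> None:
        if self.surround_sigma <= 0:
            raise ValueError(f"surround_sigma must be > 0, got {self.surround_sigma}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.output_rescale not in ("minmax", "clip"):
            raise ValueError(f"unknown output_rescale {self.output_rescale!r}")


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned ellipse selecting cup, disc and macula."""

    center_row: float
    center_col: float
    semi_axis_row: float
    semi_axis_col: float
    outside_treatment: str = "delete"  # or "black_fill"

    def __post_init__(self) -> None:
        if self.semi_axis_row <= 0 or self.semi_axis_col <= 0:
            raise ValueError("ROI semi-axes must be > 0")
        if self.outside_treatment not in ("delete", "black_fill"):
            raise ValueError(f"unknown outside_treatment {self.outside_treatment!r}")


@dataclass(frozen=True)
class ProcessedImage:
    """A 78x116x3 tensor plus its provenance."""

    pixels: np.ndarray = field(compare=False)
    source_id: str = ""
    rotation_deg: int = 0

    def __post_init__(self) -> None:
        if self.pixels.shape[:2] != TARGET_SHAPE or self.pixels.shape[2] != 3:
            raise ValueError(f"processed image must be {TARGET_SHAPE}+(3,), got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("processed image contains non-finite values")


@dataclass(frozen=True)
class PreprocessConfig:
    """Configuration of the full preprocessing pipeline."""

    band: tuple[int, int, int, int] | None
    retinex: RetinexParams
    roi: ROISpec
    target_shape: tuple[int, int] = TARGET_SHAPE


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected a rows x cols x 3 image, got shape {image.shape}")
    if image.shape[0] == 0 or image.shape[1] == 0:
        raise ValueError("image has zero extent")
    return image.astype(float)


def mask_text(image: np.ndarray, band: tuple[int, int, int, int]) -> np.ndarray:
    """Blacken the burned-in text band.

    ``band`` is (row0, row1, col0, col1) with exclusive ends.  Pixels in
    the band become exactly 0 in every channel; all others are copied
    unchanged.
    """
    image = _check_image(image)
    r0, r1, c0, c1 = band
    h, w = image.shape[:2]
    if not (0 <= r0 <= r1 <= h and 0 <= c0 <= c1 <= w):
        raise ValueError(f"band {band} outside image bounds {(h, w)}")
    out = image.copy()
    out[r0:r1, c0:c1, :] = 0.0
    return out


def retinex(image: np.ndarray, params: RetinexParams = RetinexParams()) -> np.ndarray:
    """Single-scale Retinex illumination correction, per channel.

    Computes ``log(I + eps) - log(G_sigma * I + eps)`` and rescales to
    [0, 255].  A multiplicative illumination field varying slower than
    the surround sigma cancels in the log-ratio, so the output depends
    (approximately) only on reflectance.
    """
    image = _check_image(image)
    out = np.empty_like(image)
    for ch in range(3):
        chan = image[..., ch]
        surround = ndimage.gaussian_filter(chan, sigma=params.surround_sigma, mode="reflect")
        r = np.log(chan + params.epsilon) - np.log(surround + params.epsilon)
        if params.output_rescale == "minmax":
            lo, hi = r.min(), r.max()
            out[..., ch] = 0.0 if hi - lo < 1e-12 else (r - lo) / (hi - lo) * 255.0
        else:  # clip
            out[..., ch] = np.clip(127.5 + 80.0 * (r - r.mean()), 0.0, 255.0)
    return out


def roi_mask(shape: tuple[int, int], roi: ROISpec) -> np.ndarray:
    """Boolean membership mask of the ROI ellipse on an image grid."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    return ((rr - roi.center_row) / roi.semi_axis_row) ** 2 + (
        (cc - roi.center_col) / roi.semi_axis_col
    ) ** 2 <= 1.0


def apply_roi(image: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Zero everything outside the ROI ellipse.

    In ``black_fill`` mode the full frame is kept; in ``delete`` mode
    the output is cropped to the ellipse's bounding box (intersected
    with the image), with outside-ellipse pixels still 0.
    """
    image = _check_image(image)
    h, w = image.shape[:2]
    mask = roi_mask((h, w), roi)
    if not mask.any():
        raise ValueError("ROI ellipse does not intersect the image")
    out = np.where(mask[..., None], image, 0.0)
    if roi.outside_treatment == "black_fill":
        return out
    r0 = max(0, int(np.floor(roi.center_row - roi.semi_axis_row)))
    r1 = min(h, int(np.ceil(roi.center_row + roi.semi_axis_row)) + 1)
    c0 = max(0, int(np.floor(roi.center_col - roi.semi_axis_col)))
    c1 = min(w, int(np.ceil(roi.center_col + roi.semi_axis_col)) + 1)
    return out[r0:r1, c0:c1, :]


def rotate_ccw(image: np.ndarray, angle: int) -> np.ndarray:
    """Rotate counterclockwise about the image center.

    Multiples of 90 degrees are exact (nearest-neighbor grid moves, the
    canvas transposes with the content); other angles use bilinear
    interpolation on a fixed canvas with out-of-canvas regions 0.
    """
    image = _check_image(image)
    if angle % 360 == 0:
        return image.copy()
    if angle % 90 == 0:
        return np.ascontiguousarray(np.rot90(image, k=(angle // 90) % 4, axes=(0, 1)))
    from skimage.transform import rotate as sk_rotate

    return sk_rotate(image, angle, resize=False, order=1, preserve_range=True, cval=0.0)


def augment_rotate(
    image: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, int]:
    """Augment one image into two: the original plus one random rotation.

    The angle is drawn uniformly from {30, 60, 90, 120, 180} degrees
    counterclockwise.  Returns (original, rotated, angle).
    """
    image = _check_image(image)
    angle = int(rng.choice(ROTATION_ANGLES))
    return image.copy(), rotate_ccw(image, angle), angle


def resize_image(image: np.ndarray, target_shape: tuple[int, int] = TARGET_SHAPE) -> np.ndarray:
    """Exact area-interpolated resize.

    Each output pixel is the mean of the input over its (fractional)
    source box, computed from the integral image — so a constant image
    stays constant and the global mean is preserved to float precision.
    """
    image = _check_image(image)
    h, w = image.shape[:2]
    th, tw = target_shape
    if th <= 0 or tw <= 0:
        raise ValueError(f"target shape must be positive, got {target_shape}")
    row_edges = np.linspace(0.0, h, th + 1)
    col_edges = np.linspace(0.0, w, tw + 1)
    out = np.empty((th, tw, 3), dtype=float)
    area = (h / th) * (w / tw)
    for ch in range(3):
        integral = np.zeros((h + 1, w + 1))
        integral[1:, 1:] = np.cumsum(np.cumsum(image[..., ch], axis=0), axis=1)
        # the integral image is bilinear within each cell, so order-1
        # interpolation recovers the exact integral at fractional edges
        grid_r, grid_c = np.meshgrid(row_edges, col_edges, indexing="ij")
        s = ndimage.map_coordinates(integral, [grid_r, grid_c], order=1, mode="nearest")
        box = s[1:, 1:] - s[:-1, 1:] - s[1:, :-1] + s[:-1, :-1]
        out[..., ch] = box / area
    return out


def preprocess_pipeline(
    image: np.ndarray,
    config: PreprocessConfig,
    rng: np.random.Generator | int,
    source_id: str = "",
) -> list[ProcessedImage]:
    """Run stages 2-5 on one raw image; returns two ProcessedImages.

    Composition: mask_text -> retinex -> apply_roi -> augment_rotate ->
    resize.  Deterministic for a fixed rng seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = _check_image(image)
    if config.band is not None:
        x = mask_text(x, config.band)
    x = retinex(x, config.retinex)
    x = apply_roi(x, config.roi)
    original, rotated, angle = augment_rotate(x, rng)
    return [
        ProcessedImage(
            pixels=resize_image(original, config.target_shape).astype(np.float32),
            source_id=source_id,
            rotation_deg=0,
        ),
        ProcessedImage(
            pixels=resize_image(rotated, config.target_shape).astype(np.float32),
            source_id=source_id,
            rotation_deg=angle,
        ),
    ]


def default_config_for(image_rows: int, image_cols: int, band=None) -> PreprocessConfig:
    """A pipeline config whose ROI spans the phantom's disc and macula."""
    return PreprocessConfig(
        band=band,
        retinex=RetinexParams(surround_sigma=30.0 * image_rows / 500.0),
        roi=ROISpec(
            center_row=0.5 * image_rows,
            center_col=0.53 * image_cols,
            semi_axis_row=0.42 * image_rows,
            semi_axis_col=0.40 * image_cols,
            outside_treatment="delete",
        ),
    )
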