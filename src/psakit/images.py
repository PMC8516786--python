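"""Pupil-minus-CR gaze estimation from grayscale eye images.

The estimation chain of a simple video eye tracker: threshold the frame into
very dark (pupil) and very bright (corneal-reflection) regions, screen the
binary blobs with size/shape criteria, take binary centers of mass, average
the three lowest CR spots, and map the pupil-minus-CR vector to gaze with a
second-order (quadratic) polynomial fitted on calibration targets.

Conventions: origin at the top-left pixel center, x rightward, y downward,
pixel centers at integer coordinates; "lower" CRs are those with larger y.
Images are processed at 8-bit depth; 10-bit input is right-shifted first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.measure import label, regionprops

__all__ = [
    "EyeImage",
    "Blob",
    "BlobCriteria",
    "PupilCrFeatures",
    "PolyCalibration",
    "load_image",
    "extract_blobs",
    "filter_blobs",
    "blob_center",
    "select_lower_crs",
    "detect_features",
    "fit_calibration",
    "apply_calibration",
    "DEFAULT_PUPIL_CRITERIA",
    "DEFAULT_CR_CRITERIA",
]


@dataclass(frozen=True)
class EyeImage:
    """8-bit grayscale eye frame."""

    pixels: np.ndarray  # (height, width) uint8

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 2:
            raise ValueError("expected a 2-D grayscale image")
        if px.dtype != np.uint8:
            raise ValueError("expected 8-bit pixels; see from_array")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def from_array(cls, arr: np.ndarray, bit_depth: int = 8) -> "EyeImage":
        """Wrap an intensity array; 10-bit input is right-shifted to 8-bit."""
        arr = np.asarray(arr)
        if bit_depth == 8:
            return cls(arr.astype(np.uint8))
        if bit_depth == 10:
            return cls((arr.astype(np.uint16) >> 2).astype(np.uint8))
        raise ValueError("bit_depth must be 8 or 10")


def load_image(path) -> EyeImage:
    """Read a grayscale PNG (8- or 16-bit container with 10-bit data)."""
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.dtype == np.uint8:
        return EyeImage(arr)
    return EyeImage.from_array(arr, bit_depth=10)


@dataclass(frozen=True)
class Blob:
    """One connected component of a thresholded binary mask."""

    coords: np.ndarray  # (n, 2) row, col pixel coordinates
    area: int
    centroid: tuple[float, float]  # (x, y)
    axis_major: float
    axis_minor: float

    @property
    def axis_ratio(self) -> float:
        """Fitted-ellipse major/minor axis ratio (inf for degenerate blobs)."""
        if self.axis_minor <= 0:
            return float("inf")
        return self.axis_major / self.axis_minor

    @property
    def fill_fraction(self) -> float:
        """Pixel area over fitted-ellipse area (~1 for a solid disk)."""
        if self.axis_major <= 0 or self.axis_minor <= 0:
            return 0.0
        ellipse_area = np.pi * (self.axis_major / 2) * (self.axis_minor / 2)
        return self.area / ellipse_area


@dataclass(frozen=True)
class BlobCriteria:
    """Size and shape screen applied to candidate blobs."""

    min_area: float  # px^2
    max_area: float  # px^2
    max_ellipse_axis_ratio: float = 2.0
    min_fill_fraction: float = 0.6

    def __post_init__(self) -> None:
        if not 0 <= self.min_area < self.max_area:
            raise ValueError("need 0 <= min_area < max_area")
        if self.max_ellipse_axis_ratio < 1:
            raise ValueError("max_ellipse_axis_ratio must be >= 1")
        if not 0 < self.min_fill_fraction <= 1:
            raise ValueError("min_fill_fraction must be in (0, 1]")


DEFAULT_PUPIL_CRITERIA = BlobCriteria(min_area=50, max_area=20000)
DEFAULT_CR_CRITERIA = BlobCriteria(min_area=4, max_area=400)


@dataclass(frozen=True)
class PupilCrFeatures:
    """Per-frame features: pupil center, CR centers and the p-CR vector."""

    pupil_center: tuple[float, float]  # px (x, y)
    cr_centers: tuple[tuple[float, float], ...]
    cr_mean: tuple[float, float] | None  # mean of the k lowest CRs
    valid: bool = True

    @property
    def pcr_vector(self) -> tuple[float, float]:
        """Pupil center minus mean-CR position (px)."""
        if self.cr_mean is None:
            raise ValueError("cr_mean undefined (fewer CRs than required)")
        return (self.pupil_center[0] - self.cr_mean[0],
                self.pupil_center[1] - self.cr_mean[1])


# ---------------------------------------------------------------------------
# blob operations
# ---------------------------------------------------------------------------


def _label_blobs(mask: np.ndarray) -> list[Blob]:
    blobs = []
    for rp in regionprops(label(mask, connectivity=2)):
        cy, cx = rp.centroid
        blobs.append(Blob(coords=rp.coords, area=int(rp.area),
                          centroid=(float(cx), float(cy)),
                          axis_major=float(rp.axis_major_length),
                          axis_minor=float(rp.axis_minor_length)))
    return blobs


def extract_blobs(image: EyeImage, dark_threshold: int,
                  bright_threshold: int) -> tuple[list[Blob], list[Blob]]:
    """Threshold into dark (pupil candidates) and bright (CR candidates)
    binary masks and label their 8-connected components.

    A pixel is dark when its intensity is strictly below ``dark_threshold``
    and bright when strictly above ``bright_threshold``.
    """
    for th in (dark_threshold, bright_threshold):
        if not 0 <= th <= 255:
            raise ValueError("thresholds must lie within the 8-bit range")
    dark = _label_blobs(image.pixels < dark_threshold)
    bright = _label_blobs(image.pixels > bright_threshold)
    return dark, bright


def filter_blobs(blobs: Sequence[Blob], criteria: BlobCriteria) -> list[Blob]:
    """Keep blobs passing the area, axis-ratio and fill-fraction screen."""
    out = []
    for b in blobs:
        if not criteria.min_area <= b.area <= criteria.max_area:
            continue
        if b.area > 1 and b.axis_ratio > criteria.max_ellipse_axis_ratio:
            continue
        if b.area > 1 and b.fill_fraction < criteria.min_fill_fraction:
            continue
        out.append(b)
    return out


def blob_center(blob: Blob) -> tuple[float, float]:
    """Binary (unweighted) center of mass of the blob, in (x, y) pixels."""
    return blob.centroid


def select_lower_crs(cr_centers: Sequence[tuple[float, float]],
                     k: int = 3) -> tuple[float, float]:
    """Mean position of the ``k`` lowest CRs (largest y).

    Ties in y are broken by ascending x so the selection is deterministic.

    Raises
    ------
    ValueError
        If fewer than ``k`` candidates are available.
    """
    if len(cr_centers) < k:
        raise ValueError(f"need at least {k} CR candidates, "
                         f"got {len(cr_centers)}")
    order = sorted(cr_centers, key=lambda c: (-c[1], c[0]))
    chosen = order[:k]
    return (float(np.mean([c[0] for c in chosen])),
            float(np.mean([c[1] for c in chosen])))


def detect_features(image: EyeImage, dark_threshold: int,
                    bright_threshold: int,
                    pupil_criteria: BlobCriteria = DEFAULT_PUPIL_CRITERIA,
                    cr_criteria: BlobCriteria = DEFAULT_CR_CRITERIA,
                    n_crs: int = 3) -> PupilCrFeatures:
    """Full per-frame feature extraction.

    Thresholds, screens, and picks the largest surviving dark blob as the
    pupil; all surviving bright blobs are CR candidates, of which the
    ``n_crs`` lowest are averaged.  A frame lacking a pupil or enough CRs
    comes back with ``valid=False``.
    """
    dark, bright = extract_blobs(image, dark_threshold, bright_threshold)
    pupils = filter_blobs(dark, pupil_criteria)
    crs = filter_blobs(bright, cr_criteria)
    cr_centers = tuple(blob_center(b) for b in crs)
    if not pupils:
        return PupilCrFeatures(pupil_center=(float("nan"), float("nan")),
                               cr_centers=cr_centers, cr_mean=None,
                               valid=False)
    pupil = max(pupils, key=lambda b: b.area)
    try:
        cr_mean = select_lower_crs(cr_centers, k=n_crs)
    except ValueError:
        return PupilCrFeatures(pupil_center=blob_center(pupil),
                               cr_centers=cr_centers, cr_mean=None,
                               valid=False)
    return PupilCrFeatures(pupil_center=blob_center(pupil),
                           cr_centers=cr_centers, cr_mean=cr_mean)


# ---------------------------------------------------------------------------
# polynomial calibration
# ---------------------------------------------------------------------------


def _design(xy: np.ndarray) -> np.ndarray:
    x, y = xy[:, 0], xy[:, 1]
    return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])


@dataclass(frozen=True)
class PolyCalibration:
    """Second-order map from p-CR vectors to gaze positions.

    ``coefficients`` is 2 x 6 — per gaze axis the weights of the terms
    (1, x, y, x^2, x*y, y^2) over the p-CR vector components.
    """

    coefficients: np.ndarray  # (2, 6)
    fit_residuals: np.ndarray  # (2,) RMS residual per axis

    def __post_init__(self) -> None:
        if self.coefficients.shape != (2, 6):
            raise ValueError("coefficients must be 2 x 6")


def fit_calibration(features: Sequence[PupilCrFeatures],
                    targets: Sequence[tuple[float, float]],
                    ) -> PolyCalibration:
    """Least-squares fit of the quadratic gaze map from calibration points.

    ``targets`` are the known gaze positions (degrees or screen units) shown
    while the corresponding features were captured; a ten-point grid is
    typical, six non-degenerate points are the minimum.

    Raises
    ------
    ValueError
        On fewer than six points or a rank-deficient design (e.g. collinear
        calibration targets).
    """
    pcr = np.array([f.pcr_vector for f in features], dtype=float)
    tgt = np.array(targets, dtype=float)
    if pcr.shape[0] != tgt.shape[0]:
        raise ValueError("features and targets differ in length")
    if pcr.shape[0] < 6:
        raise ValueError("need at least 6 calibration points for a "
                         "second-order fit")
    X = _design(pcr)
    rank = np.linalg.matrix_rank(X)
    if rank < 6:
        raise ValueError(f"rank-deficient calibration design (rank {rank} "
                         "< 6); targets/vectors are degenerate")
    coef, *_ = np.linalg.lstsq(X, tgt, rcond=None)
    resid = X @ coef - tgt
    rms = np.sqrt(np.mean(resid**2, axis=0))
    return PolyCalibration(coefficients=coef.T, fit_residuals=rms)


def apply_calibration(cal: PolyCalibration,
                      features: PupilCrFeatures | Sequence[PupilCrFeatures],
                      ) -> np.ndarray:
    """Evaluate the calibrated gaze map on one frame's features (or many).

    Returns an ``(2,)`` array for a single frame, ``(n, 2)`` for a sequence.
    """
    single = isinstance(features, PupilCrFeatures)
    feats = [features] if single else list(features)
    pcr = np.array([f.pcr_vector for f in feats], dtype=float)
    out = _design(pcr) @ cal.coefficients.T
    return out[0] if single else out
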