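"""Macro 1: PLA-area / nucleus-area quantification of a two-channel z-stack.

The per-image score is computed channel by channel, each channel treated
independently:

1. 3D Gaussian pre-blur (``sigma = 3`` for the nucleus channel, ``1`` for the
   PLA channel);
2. best-focus plane = z-slice with maximal mean intensity;
3. automatic threshold on that plane only — Li minimum cross-entropy for the
   DAPI nucleus, Triangle for the sparse PLA dots;
4. the resulting band is applied to every plane of the blurred 3D stack;
5. connected components smaller than a size minimum are discarded;
6. ratio = PLA foreground voxels / nucleus foreground voxels.

"Area" in a 3D stack is the total foreground voxel count summed over z; the
units cancel in the ratio, so neither pixel size nor z-spacing enters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .exceptions import (
    DegenerateImageError,
    ParameterError,
    UndefinedRatioError,
    ValidationError,
)
from .io import StackPair, VolumeChannel

TRIANGLE_BINS = 256  # histogram bins over the observed min-max range


@dataclass(frozen=True)
class ThresholdBand:
    """Lower/upper intensity bounds defining foreground.

    The foreground predicate is inclusive on both ends:
    ``lower <= v <= upper``. Automatic methods yield a single cut; for
    bright-on-dark signal the upper bound is the top of the representable
    range and is non-binding.
    """

    lower: float
    upper: float
    method: str  # "li" or "triangle"
    source_plane: int = 0

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ParameterError(
                f"threshold band requires lower <= upper, got "
                f"({self.lower}, {self.upper})"
            )


@dataclass(frozen=True)
class PlaParams:
    """Tunable parameters of the macro-1 pipeline (defaults as published)."""

    sigma_nucleus: float = 3.0
    sigma_pla: float = 1.0
    min_size_pla: int = 4
    min_size_nucleus: int = 500
    connectivity: int = 26           # 6 or 26, for the 3D size filter
    nucleus_area_mode: str = "3d"    # "3d" sum or "best_plane" only

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 26):
            raise ParameterError("connectivity must be 6 or 26")
        if self.nucleus_area_mode not in ("3d", "best_plane"):
            raise ParameterError("nucleus_area_mode must be '3d' or 'best_plane'")


@dataclass
class PlaImageResult:
    """Per-image macro-1 quantification with full provenance."""

    image_id: str
    group_label: str
    pla_area: int
    nucleus_area: int
    ratio: float
    best_focus_nucleus: int
    best_focus_pla: int
    band_nucleus: ThresholdBand
    band_pla: ThresholdBand
    sigma_nucleus: float = 3.0
    sigma_pla: float = 1.0

    def to_record(self) -> dict:
        return {
            "image_id": self.image_id,
            "group_label": self.group_label,
            "pla_area": self.pla_area,
            "nucleus_area": self.nucleus_area,
            "ratio": self.ratio,
            "best_focus_nucleus": self.best_focus_nucleus,
            "best_focus_pla": self.best_focus_pla,
            "threshold_nucleus_lower": self.band_nucleus.lower,
            "threshold_nucleus_upper": self.band_nucleus.upper,
            "threshold_pla_lower": self.band_pla.lower,
            "threshold_pla_upper": self.band_pla.upper,
            "sigma_nucleus": self.sigma_nucleus,
            "sigma_pla": self.sigma_pla,
        }


def _as_voxels(channel) -> np.ndarray:
    if isinstance(channel, VolumeChannel):
        return channel.voxels
    return np.asarray(channel)


def gaussian_blur_3d(channel, sigma: float) -> np.ndarray:
    """Isotropic separable 3D Gaussian blur with reflective boundaries.

    Returns a real-valued (float64) working copy: re-quantizing before
    thresholding would discard the sub-integer structure the auto-threshold
    methods rely on. ``sigma`` is in voxel units on every axis.
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    voxels = _as_voxels(channel)
    if voxels.ndim != 3 or voxels.shape[0] < 1:
        raise ValidationError("expected a (z,y,x) stack with >= 1 plane")
    return ndi.gaussian_filter(voxels.astype(np.float64), sigma=sigma, mode="reflect")


def best_focus_index(stack) -> int:
    """Z-index of best focus: argmax over planes of the mean intensity.

    Ties break toward the smallest z.
    """
    voxels = _as_voxels(stack)
    if voxels.ndim != 3 or voxels.shape[0] < 1:
        raise ValidationError("expected a (z,y,x) stack with >= 1 plane")
    return int(np.argmax(voxels.reshape(voxels.shape[0], -1).mean(axis=1)))


def _li_cross_entropy(sums_below: np.ndarray, counts_below: np.ndarray,
                      total_sum: float, total_count: int) -> np.ndarray:
    """Li-Lee objective -(S_b log mu_b + S_f log mu_f) for every candidate cut."""
    s_b = sums_below
    n_b = counts_below
    s_f = total_sum - s_b
    n_f = total_count - n_b
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_b = np.where(n_b > 0, s_b / np.maximum(n_b, 1), 0.0)
        mu_f = np.where(n_f > 0, s_f / np.maximum(n_f, 1), 0.0)
        term_b = np.where(s_b > 0, s_b * np.log(np.where(mu_b > 0, mu_b, 1.0)), 0.0)
        term_f = np.where(s_f > 0, s_f * np.log(np.where(mu_f > 0, mu_f, 1.0)), 0.0)
    return -(term_b + term_f)


def li_threshold(plane, upper: float | None = None,
                 source_plane: int = 0) -> ThresholdBand:
    """Li minimum cross-entropy threshold of a 2D (or any) intensity array.

    Minimizes the cross-entropy between the image and its two-class mean
    reconstruction by an exhaustive scan over every distinct intensity cut
    (background ``v <= cut``, foreground ``v > cut``). The objective is
    evaluated on the raw intensities (cross-entropy is scale- but not
    shift-invariant, and the histogram-based reference implementations work
    on raw gray levels); zero-intensity mass uses the 0*log(0) = 0
    convention, and negative intensities are rejected. The returned ``lower``
    is the smallest intensity classified as foreground. Ties go to the
    lowest cut.
    """
    values = np.asarray(plane, dtype=np.float64).ravel()
    distinct, counts = np.unique(values, return_counts=True)
    if distinct.size < 2:
        raise DegenerateImageError("constant plane: no Li threshold exists")
    if distinct[0] < 0:
        raise ParameterError("Li threshold requires non-negative intensities")
    sums = np.cumsum(distinct * counts)[:-1]      # S_b for cut at distinct[i]
    ns = np.cumsum(counts)[:-1]
    objective = _li_cross_entropy(sums, ns, float((distinct * counts).sum()),
                                  int(counts.sum()))
    best = int(np.argmin(objective))              # ties -> lowest cut
    lower = float(distinct[best + 1])
    if upper is None:
        upper = float(distinct[-1])
    return ThresholdBand(lower=lower, upper=float(upper), method="li",
                         source_plane=source_plane)


def triangle_threshold(plane, upper: float | None = None,
                       source_plane: int = 0,
                       bins: int = TRIANGLE_BINS) -> ThresholdBand:
    """Triangle threshold of a 2D (or any) intensity array.

    The histogram (``bins`` bins spanning the observed min-max range) is
    normalized to unit peak height; a chord joins the peak bin to the farthest
    non-empty bin on the longer-tail side, and the threshold is the upper edge
    of the bin with maximal perpendicular distance below that chord. Side
    selection is symmetric: a mirrored image yields the mirrored cut.
    """
    values = np.asarray(plane, dtype=np.float64).ravel()
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise DegenerateImageError("constant plane: no Triangle threshold exists")
    hist, edges = np.histogram(values, bins=bins, range=(vmin, vmax))
    peak = int(np.argmax(hist))
    nonzero = np.nonzero(hist)[0]
    first_nz, last_nz = int(nonzero[0]), int(nonzero[-1])

    flipped = (peak - first_nz) > (last_nz - peak)  # longer tail on the left
    if flipped:
        hist = hist[::-1]
        peak = bins - 1 - peak
        last_nz = bins - 1 - first_nz

    cut_bin = _triangle_argmax(hist, peak, last_nz)

    if flipped:
        # cut just below the mirrored bin: lower edge in original orientation
        lower = float(edges[bins - 1 - cut_bin])
    else:
        lower = float(edges[cut_bin + 1])
    if upper is None:
        upper = vmax
    return ThresholdBand(lower=lower, upper=float(upper), method="triangle",
                         source_plane=source_plane)


def _triangle_argmax(hist: np.ndarray, peak: int, end: int) -> int:
    """Bin of maximal perpendicular distance to the peak->end chord."""
    if end - peak < 2:
        return peak
    y = hist / hist[peak]
    xs = np.arange(peak + 1, end, dtype=np.float64)
    # chord from (peak, 1) to (end, y[end]); distance of (x, y[x]) to it
    dx, dy = float(end - peak), float(y[end] - 1.0)
    norm = np.hypot(dx, dy)
    dist = ((xs - peak) * dy - (y[peak + 1:end] - 1.0) * dx) / norm
    return peak + 1 + int(np.argmax(dist))  # signed distance > 0 below the chord


def apply_band_3d(stack, band: ThresholdBand) -> np.ndarray:
    """Apply one threshold band to every plane of a stack (inclusive bounds)."""
    voxels = np.asarray(_as_voxels(stack), dtype=np.float64)
    return (voxels >= band.lower) & (voxels <= band.upper)


def size_filter(binary: np.ndarray, min_voxels: int,
                connectivity: int = 26) -> np.ndarray:
    """Remove 3D connected components smaller than ``min_voxels``.

    ``connectivity`` is 6 (faces) or 26 (faces+edges+corners, the default).
    """
    if min_voxels < 1:
        raise ParameterError("min_voxels must be >= 1")
    if connectivity not in (6, 26):
        raise ParameterError("connectivity must be 6 or 26")
    binary = np.asarray(binary, dtype=bool)
    if min_voxels == 1:
        return binary.copy()
    structure = ndi.generate_binary_structure(3, 3 if connectivity == 26 else 1)
    labels, n = ndi.label(binary, structure=structure)
    if n == 0:
        return binary.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return keep[labels]


def quantify_pla_image(pair: StackPair, params: PlaParams | None = None) -> PlaImageResult:
    """Run the full macro-1 pipeline on one {nucleus, PLA} stack pair.

    Raises
    ------
    UndefinedRatioError
        If the nucleus foreground is empty after size filtering (the image
        should be excluded downstream, with the reason logged).
    DegenerateImageError
        If a best-focus plane is constant so no threshold exists.
    """
    params = params or PlaParams()
    if pair.primary_channel.channel_name != "nucleus":
        raise ValidationError("macro 1 expects a nucleus primary channel")

    nuc = pair.primary_channel
    pla = pair.pla_channel

    nuc_blur = gaussian_blur_3d(nuc, params.sigma_nucleus)
    pla_blur = gaussian_blur_3d(pla, params.sigma_pla)

    z_nuc = best_focus_index(nuc_blur)
    z_pla = best_focus_index(pla_blur)

    band_nuc = li_threshold(nuc_blur[z_nuc], upper=float(nuc.intensity_max),
                            source_plane=z_nuc)
    band_pla = triangle_threshold(pla_blur[z_pla], upper=float(pla.intensity_max),
                                  source_plane=z_pla)

    nuc_mask = size_filter(apply_band_3d(nuc_blur, band_nuc),
                           params.min_size_nucleus, params.connectivity)
    pla_mask = size_filter(apply_band_3d(pla_blur, band_pla),
                           params.min_size_pla, params.connectivity)

    if params.nucleus_area_mode == "best_plane":
        nucleus_area = int(nuc_mask[z_nuc].sum())
    else:
        nucleus_area = int(nuc_mask.sum())
    pla_area = int(pla_mask.sum())

    if nucleus_area == 0:
        raise UndefinedRatioError(
            f"image {pair.image_id!r}: empty nucleus foreground, ratio undefined"
        )
    return PlaImageResult(
        image_id=pair.image_id,
        group_label=pair.group_label,
        pla_area=pla_area,
        nucleus_area=nucleus_area,
        ratio=pla_area / nucleus_area,
        best_focus_nucleus=z_nuc,
        best_focus_pla=z_pla,
        band_nucleus=band_nuc,
        band_pla=band_pla,
        sigma_nucleus=params.sigma_nucleus,
        sigma_pla=params.sigma_pla,
    )
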