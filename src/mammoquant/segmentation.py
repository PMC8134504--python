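"""Whole-mount epithelial-tree segmentation.

Carmine-stained mammary whole mounts are scanned as RGB images in which the
epithelial tree is darker than the surrounding stromal fat pad. The fixed
processing chain converts such a scan into a binary tree mask:

    gamma adjustment -> PCA grayscale -> CLAHE -> wide-Gaussian background
    subtraction -> Otsu binarisation (dark class = epithelium) ->
    morphological closing -> small-object removal -> keep the connected
    component nearest the nipple.

The lymph node, typically the darkest feature in a whole mount, is found
separately by sweeping multilevel Otsu thresholds and scoring candidate
dark blobs by compactness and expected size.

The nipple (tree origin) is a required input: it is determined visually on
the scan, as is standard for whole-mount morphometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, measure, morphology
from skimage.filters import threshold_multiotsu

from .errors import DegenerateImageError, NoForegroundError, ParameterError
from .images import RasterImage

log = logging.getLogger(__name__)

# Rec. 709 luminance weights, used only to orient the principal component.
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class SegmentationConfig:
    """Tunable knobs of the segmentation chain.

    ``gamma`` (0.45) and ``background_sigma_px`` (20) follow the published
    whole-mount protocol; CLAHE and cleanup parameters are package defaults
    chosen for ~10 µm/px scans.
    """

    gamma: float = 0.45
    apply_gamma: bool = True
    clahe_clip: float = 0.01
    clahe_tile_px: int = 64
    background_sigma_px: float = 20.0
    min_object_px: int = 64
    closing_radius_px: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ParameterError("gamma must be in (0, 1]")
        for name in ("clahe_clip", "clahe_tile_px", "background_sigma_px",
                     "min_object_px"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.closing_radius_px < 0:
            raise ParameterError("closing_radius_px must be >= 0 (0 skips)")


@dataclass
class LymphNodeConfig:
    """Scoring rule for lymph-node candidates.

    A candidate dark component scores ``solidity * exp(-(area-expected)^2 /
    (2 tol^2))``; the sweep stops at the first candidate whose score exceeds
    ``accept_score``, otherwise the global best is returned.
    """

    expected_area_px: float = 2000.0
    area_tol_px: float = 1500.0
    accept_score: float = 0.8
    min_area_px: int = 50


@dataclass
class TreeSegmentation:
    """Binary tree mask plus annotations produced by :func:`segment_tree`."""

    tree_mask: np.ndarray
    nipple_px: tuple[int, int]
    ln_mask: np.ndarray | None = None
    ln_centroid_px: tuple[float, float] | None = None
    config: SegmentationConfig = field(default_factory=SegmentationConfig)


def _normalize01(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateImageError("image is constant; cannot rescale")
    return (x - lo) / (hi - lo)


def pca_grayscale(img: RasterImage) -> RasterImage:
    """Project an RGB image onto the first principal component of its pixels.

    The component is sign-oriented so that the output correlates positively
    with luminance (dark epithelium stays dark), then min-max rescaled to
    [0, 1].
    """
    if not img.is_rgb:
        raise ParameterError("pca_grayscale expects an RGB image")
    flat = img.pixels.reshape(-1, 3).astype(float)
    centered = flat - flat.mean(axis=0)
    cov = centered.T @ centered / max(flat.shape[0] - 1, 1)
    if not np.any(cov):
        raise DegenerateImageError("constant image: zero RGB covariance")
    evals, evecs = np.linalg.eigh(cov)
    pc1 = evecs[:, np.argmax(evals)]
    # orient towards luminance so epithelium (dark) maps to low values
    if float(pc1 @ _LUMA) < 0:
        pc1 = -pc1
    scores = centered @ pc1
    gray = _normalize01(scores).reshape(img.shape)
    return RasterImage(pixels=gray, pixel_size_um=img.pixel_size_um)


def subtract_background(img: RasterImage, sigma_px: float) -> RasterImage:
    """Remove smooth background: image minus a wide Gaussian blur of itself.

    Reflective boundary handling avoids edge darkening. The operation is not
    idempotent (the residual still has some low-frequency content).
    """
    if not sigma_px > 0:
        raise ParameterError("sigma_px must be > 0")
    if img.is_rgb:
        raise ParameterError("subtract_background expects a scalar image")
    pix = np.asarray(img.pixels, dtype=float)
    blur = ndi.gaussian_filter(pix, sigma=sigma_px, mode="reflect")
    return RasterImage(pixels=pix - blur, pixel_size_um=img.pixel_size_um)


def otsu_threshold(counts: np.ndarray, bin_values: np.ndarray | None = None
                   ) -> float:
    """Otsu threshold of a histogram: maximise between-class variance.

    Parameters
    ----------
    counts : per-bin pixel counts.
    bin_values : intensity value of each bin (defaults to 0..len-1).

    Returns the value of the highest bin assigned to the lower class; ties
    are broken towards the lowest qualifying threshold.
    """
    counts = np.asarray(counts, dtype=float)
    if bin_values is None:
        bin_values = np.arange(counts.size, dtype=float)
    bin_values = np.asarray(bin_values, dtype=float)
    if counts.ndim != 1 or counts.size != bin_values.size:
        raise ParameterError("counts and bin_values must be 1-D, same size")
    nonempty = np.nonzero(counts)[0]
    if nonempty.size < 2:
        raise DegenerateImageError("need at least two nonempty bins")

    w = counts / counts.sum()
    mu = w * bin_values
    omega0 = np.cumsum(w)
    mu0_cum = np.cumsum(mu)
    mu_total = mu0_cum[-1]
    omega1 = 1.0 - omega0
    # between-class variance for a cut after each bin (last cut invalid)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega0 - mu0_cum) ** 2 / (omega0 * omega1)
    sigma_b = sigma_b[:-1]
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    best = int(np.argmax(sigma_b))  # argmax returns the first (lowest) tie
    return float(bin_values[best])


def _binarize_dark(gray: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Threshold a float image with Otsu; return the darker class as True."""
    counts, edges = np.histogram(gray, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    t = otsu_threshold(counts, centers)
    return gray <= t


def _gamma_adjust(pixels: np.ndarray, gamma: float) -> np.ndarray:
    """Gamma on the globally min-max normalised image.

    Normalising first makes the whole chain invariant to positive affine
    transforms of the raw intensities.
    """
    return _normalize01(pixels) ** gamma


def segment_tree(img: RasterImage, nipple_px: tuple[int, int],
                 cfg: SegmentationConfig | None = None) -> TreeSegmentation:
    """Run the full whole-mount chain and return the epithelial tree mask.

    The connected component nearest the nipple is kept and the nipple is
    snapped to the nearest mask pixel.
    """
    cfg = cfg or SegmentationConfig()
    r, c = nipple_px
    if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]):
        raise ParameterError("nipple must lie inside the image")

    pixels = img.pixels
    if cfg.apply_gamma:
        pixels = _gamma_adjust(pixels, cfg.gamma)
    work = RasterImage(pixels=pixels, pixel_size_um=img.pixel_size_um)
    gray = pca_grayscale(work) if work.is_rgb else RasterImage(
        _normalize01(work.pixels), work.pixel_size_um)
    enhanced = exposure.equalize_adapthist(
        gray.pixels, kernel_size=cfg.clahe_tile_px, clip_limit=cfg.clahe_clip)
    flat = subtract_background(
        RasterImage(enhanced, img.pixel_size_um), cfg.background_sigma_px)

    fg = _binarize_dark(flat.pixels)
    if cfg.closing_radius_px > 0:  # "if necessary": 0 skips the closing
        footprint = morphology.disk(cfg.closing_radius_px)
        fg = ndi.binary_erosion(ndi.binary_dilation(fg, footprint), footprint)
    labels, n = ndi.label(fg)
    if n:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        fg = np.isin(labels, np.nonzero(sizes >= cfg.min_object_px)[0])
    if not fg.any():
        raise NoForegroundError("no foreground left after cleanup")

    labels, n = ndi.label(fg)
    if n > 1:
        coords = np.column_stack(np.nonzero(fg))
        d2 = (coords[:, 0] - r) ** 2 + (coords[:, 1] - c) ** 2
        keep = labels[tuple(coords[np.argmin(d2)])]
        fg = labels == keep
    snapped = _snap_to_mask(fg, (r, c))
    return TreeSegmentation(tree_mask=fg, nipple_px=snapped, config=cfg)


def _snap_to_mask(mask: np.ndarray, point: tuple[int, int]) -> tuple[int, int]:
    coords = np.column_stack(np.nonzero(mask))
    d2 = (coords[:, 0] - point[0]) ** 2 + (coords[:, 1] - point[1]) ** 2
    best = coords[np.argmin(d2)]
    return int(best[0]), int(best[1])


def segment_lymph_node(
    img: RasterImage,
    tree_mask: np.ndarray,
    cfg: LymphNodeConfig | None = None,
) -> tuple[np.ndarray, tuple[float, float]] | None:
    """Locate the lymph node in a PCA-grayscale whole-mount image.

    Sweeps multilevel Otsu with 2..6 classes; at each level the connected
    components of the darkest class lying outside the tree mask are scored
    by ``solidity * exp(-(area - expected)^2 / (2 tol^2))``. The first
    component exceeding the acceptance score wins; failing that the global
    best; failing that the node is reported absent (a valid outcome — not
    every image contains one).
    """
    cfg = cfg or LymphNodeConfig()
    if img.is_rgb:
        raise ParameterError("segment_lymph_node expects the grayscale image")
    gray = np.asarray(img.pixels, dtype=float)
    if gray.min() == gray.max():
        return None

    best: tuple[float, np.ndarray, tuple[float, float]] | None = None
    for k in range(2, 7):
        try:
            ts = threshold_multiotsu(gray, classes=k, nbins=256)
        except ValueError:  # fewer distinct levels than classes
            continue
        dark = (gray <= ts[0]) & ~tree_mask
        if not dark.any():
            continue
        labels = measure.label(dark)
        for prop in measure.regionprops(labels):
            if prop.area < cfg.min_area_px:
                continue
            score = prop.solidity * float(np.exp(
                -((prop.area - cfg.expected_area_px) ** 2)
                / (2 * cfg.area_tol_px ** 2)))
            if best is None or score > best[0]:
                best = (score, labels == prop.label, prop.centroid)
            if score > cfg.accept_score:
                return labels == prop.label, prop.centroid
    if best is None:
        return None
    return best[1], best[2]
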