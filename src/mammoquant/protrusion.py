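"""Compartmentalised intensity and protrusion dynamics in 3-D cyst assays.

A :class:`CystScene` holds one imaging field: named fluorescence channels,
a cyst *body* mask and zero or more *protrusion* masks (subcellular
extensions reaching into the matrix), all on the same pixel grid. Masks
are inputs — drawn by the analyst or produced by a generator — mirroring
the outlined-region approach used for these assays.

Quantities:

* **localized translation ratio** (SUnSET): mean puromycin intensity in a
  protrusion over a size-matched region of the cyst-body rim. The rim is a
  band of configurable physical width (default 10 µm) around the body,
  because the body's central region carries little puromycin signal; the
  size-matched region is the connected run of band pixels nearest the
  protrusion root, grown until it has as many pixels as the protrusion.
* **normalized region intensity**: a region's mean over the whole-cyst
  (body plus protrusions) mean — the F-actin / paxillin readout.
* **protrusion tracks**: greedy frame-to-frame IoU linking in a time
  lapse, reporting per-track lifetime (inclusive of birth and death
  frames) and maximum geodesic length from the body boundary.

All ratios are invariant to global multiplicative rescaling of the raw
channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.graph import MCP_Geometric
from skimage.morphology import disk

from .errors import ParameterError
from .images import RasterImage
from .segmentation import subtract_background

log = logging.getLogger(__name__)


@dataclass
class CystScene:
    """One field of view: channels plus body and protrusion masks."""

    channels: dict[str, np.ndarray]
    body_mask: np.ndarray
    protrusion_masks: list[np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        shape = self.body_mask.shape
        for name, ch in self.channels.items():
            if ch.shape != shape:
                raise ParameterError(f"channel {name!r} shape mismatch")
        for i, m in enumerate(self.protrusion_masks):
            if m.shape != shape:
                raise ParameterError(f"protrusion mask {i} shape mismatch")
            if (m & self.body_mask).any():
                raise ParameterError(f"protrusion mask {i} overlaps the body")

    @property
    def cyst_mask(self) -> np.ndarray:
        out = self.body_mask.copy()
        for m in self.protrusion_masks:
            out |= m
        return out


@dataclass
class IntensityReport:
    region_means: dict[str, float]
    normalized: dict[str, float]
    localized_ratios: dict[int, float]


@dataclass
class ProtrusionTrack:
    track_id: int
    frames: list[int]
    lifetime_h: float
    max_length_um: float


def correct_background(img: RasterImage, sigma_px: float = 50.0) -> RasterImage:
    """Flatten non-uniform illumination: subtract a wide blur, clip at zero.

    Fluorescence is non-negative, so the residual is clipped at 0.
    """
    out = subtract_background(img, sigma_px)
    return RasterImage(np.clip(out.pixels, 0, None), out.pixel_size_um)


def body_band(
    body_mask: np.ndarray,
    width_um: float,
    pixel_size_um: float,
    protrusion_masks: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Rim band of ``width_um`` around the body, excluding protrusions."""
    if not width_um > 0:
        raise ParameterError("width_um must be > 0")
    width_px = int(round(width_um / pixel_size_um))
    if width_px < 1:
        raise ParameterError("band width is below one pixel at this scale")
    body = np.asarray(body_mask, dtype=bool)
    band = ndi.binary_dilation(body, structure=disk(width_px)) & ~body
    for m in protrusion_masks or []:
        band &= ~np.asarray(m, dtype=bool)
    return band


def _mean_in(img: np.ndarray, mask: np.ndarray) -> float:
    if not mask.any():
        raise ParameterError("region is empty")
    return float(img[mask].mean())


def _corrected(scene: CystScene, channel: str,
               sigma_px: float | None) -> np.ndarray:
    """Channel as float, optionally flattened with `correct_background`.

    Intensity ratios are computed on the channel as given by default:
    high-pass background subtraction on an already evenly illuminated
    scene would brighten structures jutting into dark matrix relative to
    structures inside the cyst and bias compartment ratios. Pass a sigma
    (or pre-apply :func:`correct_background`) when the raw image carries
    shading.
    """
    img = scene.channels[channel].astype(float)
    if sigma_px is None:
        return img
    return correct_background(
        RasterImage(img, scene.pixel_size_um), sigma_px).pixels


def _size_matched_band_region(
    band: np.ndarray, protrusion: np.ndarray
) -> np.ndarray:
    """Connected band run nearest the protrusion root, equal in pixel count.

    The root is the band pixel closest to the protrusion; the region grows
    along the band (8-connected geodesic order) until it matches the
    protrusion's area. If the whole band is smaller than the protrusion the
    full band is used and a warning logged.
    """
    n_target = int(protrusion.sum())
    band_px = np.column_stack(np.nonzero(band))
    if len(band_px) == 0:
        raise ParameterError("band is empty")
    if len(band_px) <= n_target:
        log.warning("band (%d px) smaller than protrusion (%d px); "
                    "using whole band", len(band_px), n_target)
        return band
    dist_to_prot = ndi.distance_transform_edt(~protrusion)
    root = tuple(band_px[np.argmin(dist_to_prot[tuple(band_px.T)])])
    costs = np.where(band, 1.0, np.inf)
    mcp = MCP_Geometric(costs)
    cum, _ = mcp.find_costs([root])
    geo = cum[band]
    order = np.argsort(geo, kind="stable")
    chosen = band_px[order[:n_target]]
    region = np.zeros_like(band)
    region[tuple(chosen.T)] = True
    return region


def localized_translation_ratio(
    scene: CystScene,
    channel: str,
    protrusion_id: int = 0,
    width_um: float = 10.0,
    background_sigma_px: float | None = None,
) -> float:
    """Protrusion mean over a size-matched body-rim mean (SUnSET readout)."""
    prot = np.asarray(scene.protrusion_masks[protrusion_id], dtype=bool)
    if not prot.any():
        raise ParameterError("protrusion mask is empty")
    band = body_band(scene.body_mask, width_um, scene.pixel_size_um,
                     scene.protrusion_masks)
    if not band.any():
        raise ParameterError("body band is empty")
    img = _corrected(scene, channel, background_sigma_px)
    region = _size_matched_band_region(band, prot)
    return _mean_in(img, prot) / _mean_in(img, region)


def normalized_region_intensity(
    scene: CystScene,
    channel: str,
    region: np.ndarray,
    background_sigma_px: float | None = None,
) -> float:
    """Region mean over the whole-cyst mean, after background correction."""
    region = np.asarray(region, dtype=bool)
    img = _corrected(scene, channel, background_sigma_px)
    return _mean_in(img, region) / _mean_in(img, scene.cyst_mask)


def protrusion_length_um(scene: CystScene, protrusion_id: int) -> float:
    """Maximum geodesic distance from the body boundary along a protrusion.

    Measured within body + protrusion so curved protrusions are measured
    along their extent, not as the crow flies.
    """
    prot = np.asarray(scene.protrusion_masks[protrusion_id], dtype=bool)
    if not prot.any():
        return 0.0
    body = np.asarray(scene.body_mask, dtype=bool)
    region = body | prot
    costs = np.where(region, 1.0, np.inf)
    starts = [tuple(p) for p in np.column_stack(np.nonzero(body))]
    if not starts:
        raise ParameterError("body mask is empty")
    cum, _ = MCP_Geometric(costs).find_costs(starts)
    vals = cum[prot]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:  # protrusion not connected to the body
        return 0.0
    return float(vals.max()) * scene.pixel_size_um


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.count_nonzero(a & b)
    if inter == 0:
        return 0.0
    return inter / np.count_nonzero(a | b)


def track_protrusions(
    frames: list[CystScene],
    frame_interval_h: float,
    min_iou: float = 0.3,
) -> list[ProtrusionTrack]:
    """Link protrusion masks across frames by greedy IoU matching.

    Tracks are temporally contiguous: a track that finds no match in a
    frame is closed (no gap bridging — a vanished protrusion that reappears
    is a new one). Lifetime counts both birth and death frames.
    """
    if len(frames) == 0:
        raise ParameterError("need at least one frame")
    active: list[dict] = []
    closed: list[dict] = []
    next_id = 0
    for t, scene in enumerate(frames):
        masks = [np.asarray(m, dtype=bool) for m in scene.protrusion_masks]
        lengths = [protrusion_length_um(scene, i) for i in range(len(masks))]
        pairs = [(_iou(tr["mask"], m), ti, mi)
                 for ti, tr in enumerate(active)
                 for mi, m in enumerate(masks)]
        pairs = sorted((p for p in pairs if p[0] >= min_iou), reverse=True)
        used_t: set[int] = set()
        used_m: set[int] = set()
        for iou, ti, mi in pairs:
            if ti in used_t or mi in used_m:
                continue
            used_t.add(ti); used_m.add(mi)
            tr = active[ti]
            tr["frames"].append(t)
            tr["mask"] = masks[mi]
            tr["max_len"] = max(tr["max_len"], lengths[mi])
        still = []
        for ti, tr in enumerate(active):
            (still if ti in used_t else closed).append(tr)
        active = still
        for mi, m in enumerate(masks):
            if mi not in used_m:
                active.append({"id": next_id, "frames": [t], "mask": m,
                               "max_len": lengths[mi]})
                next_id += 1
    closed.extend(active)
    closed.sort(key=lambda tr: tr["id"])
    return [
        ProtrusionTrack(track_id=tr["id"], frames=tr["frames"],
                        lifetime_h=len(tr["frames"]) * frame_interval_h,
                        max_length_um=tr["max_len"])
        for tr in closed
    ]


def intensity_report(
    scene: CystScene,
    channel: str,
    width_um: float = 10.0,
    background_sigma_px: float | None = None,
) -> IntensityReport:
    """Per-region means, normalized intensities and localized ratios."""
    img = _corrected(scene, channel, background_sigma_px)
    cyst_mean = _mean_in(img, scene.cyst_mask)
    regions = {"body": np.asarray(scene.body_mask, dtype=bool)}
    for i, m in enumerate(scene.protrusion_masks):
        regions[f"protrusion_{i}"] = np.asarray(m, dtype=bool)
    means = {k: _mean_in(img, v) for k, v in regions.items()}
    normalized = {k: v / cyst_mean for k, v in means.items()}
    ratios = {}
    for i in range(len(scene.protrusion_masks)):
        try:
            ratios[i] = localized_translation_ratio(
                scene, channel, i, width_um, background_sigma_px)
        except ParameterError:
            continue
    return IntensityReport(region_means=means, normalized=normalized,
                           localized_ratios=ratios)
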