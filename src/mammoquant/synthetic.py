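"""Synthetic scenes with exact ground truth for every analysis stage.

Three generators emulate the study conditions so the whole pipeline is
testable without animal images or deposited MS runs:

* :func:`generate_wholemount` — a dark bifurcating ductal tree on a
  lighter, noisy stromal background with a nipple origin and an optional
  darker lymph-node blob, rendered as an 8-bit RGB scan. Ground truth
  (mask, fork points, extension, area) is *measured on the rendered mask*,
  never taken from generative intent.
* :func:`generate_cyst_timelapse` — cysts with finger-like protrusions
  whose per-compartment mean intensities follow a configurable ratio, with
  per-protrusion birth/death frames for lifetime tracking.
* :func:`generate_abundance_matrix` — zero-inflated log-normal protein
  abundance tables for a 3-group x 5-sample screen with planted
  fold-changes and a provenance flag for original zeros.

Every generator is deterministic for a fixed seed (bit-identical output).
Intensities are 8-bit; noise is additive Gaussian then clipped to
[0, 255], so noise tests should use a small sd relative to the contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw, morphology

from .errors import GenerationError, ParameterError
from .images import RasterImage
from .protrusion import CystScene
from .proteomics import AbundanceMatrix

# per-channel gains giving the scan a carmine-like hue; shared by tree,
# stroma and node so contrast polarity is identical in every channel
_RGB_GAINS = (1.0, 0.82, 0.88)


# ---------------------------------------------------------------- trees --

@dataclass
class TreeGenParams:
    """Parameters of the bifurcating-tree whole-mount generator.

    Defaults draw a pubertal-style tree: ~10.5 µm pixels (2400 dpi scan),
    dark epithelium (60) on light stroma (200) with a darker lymph node
    (30), seven bifurcations, and mild scanner noise.
    """

    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 10.5
    nipple_px: tuple[int, int] = (256, 28)
    n_bifurcations: int = 7
    segment_length_px: float = 60.0
    branch_angle_deg: float = 46.0
    duct_width_px: int = 5
    tree_intensity: float = 60.0
    stroma_intensity: float = 200.0
    noise_sd: float = 8.0
    ln_center_px: tuple[int, int] | None = (100, 410)
    ln_radius_px: float = 28.0
    ln_intensity: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tree_intensity < self.stroma_intensity:
            raise ParameterError("tree must be darker than stroma")
        if self.ln_center_px is not None and \
                not self.ln_intensity < self.tree_intensity:
            raise ParameterError("lymph node must be darker than the tree")
        if self.n_bifurcations < 0 or self.noise_sd < 0:
            raise ParameterError("n_bifurcations and noise_sd must be >= 0")
        if self.duct_width_px < 1 or self.segment_length_px <= 0:
            raise ParameterError("duct width/segment length must be positive")
        r, c = self.nipple_px
        if not (0 <= r < self.image_size_px[0]
                and 0 <= c < self.image_size_px[1]):
            raise ParameterError("nipple must lie inside the image")


@dataclass
class WholeMountTruth:
    """Ground truth of a generated whole mount, measured on the mask."""

    tree_mask: np.ndarray
    branchpoints_px: np.ndarray  # (n, 2) fork centers, (row, col)
    nipple_px: tuple[int, int]
    ln_centroid_px: tuple[float, float] | None
    true_area_um2: float
    true_extension_um: float


def _segment_pixels(p0, p1, shape, width, label) -> np.ndarray:
    """Centerline pixels of one duct segment; errors if out of canvas."""
    margin = width / 2 + 1
    for q in (p0, p1):
        if not (margin <= q[0] < shape[0] - margin
                and margin <= q[1] < shape[1] - margin):
            raise GenerationError(
                f"segment {label} from {tuple(np.round(p0, 1))} to "
                f"{tuple(np.round(p1, 1))} exceeds the canvas")
    rr, cc = draw.line(int(round(p0[0])), int(round(p0[1])),
                       int(round(p1[0])), int(round(p1[1])))
    return rr, cc


def generate_wholemount(
    params: TreeGenParams,
) -> tuple[RasterImage, WholeMountTruth]:
    """Render a whole-mount-like RGB scan plus exact ground truth.

    The tree is a breadth-first bifurcating random walk: each active tip
    either forks (while bifurcations remain) into two children at
    ±branch_angle/2 with jitter, or terminates. Fork centers are recorded
    as the true branch points. Truth extension and area are re-measured on
    the rendered mask.
    """
    rng = np.random.default_rng(params.seed)
    last_err: GenerationError | None = None
    for _restart in range(8):  # re-draw the whole layout if it jams
        try:
            mask, forks = _layout_tree(params, rng)
            break
        except GenerationError as err:
            last_err = err
    else:
        raise last_err
    shape = params.image_size_px

    base = np.full(shape, params.stroma_intensity, dtype=float)
    base[mask] = params.tree_intensity
    ln_centroid = None
    if params.ln_center_px is not None:
        rr, cc = draw.disk(params.ln_center_px, params.ln_radius_px,
                           shape=shape)
        ln = np.zeros(shape, dtype=bool)
        ln[rr, cc] = True
        ln &= ~mask
        base[ln] = params.ln_intensity
        ln_centroid = tuple(np.column_stack(np.nonzero(ln)).mean(axis=0))

    rgb = np.empty((*shape, 3), dtype=np.uint8)
    for ch, gain in enumerate(_RGB_GAINS):
        noisy = base * gain + rng.normal(0, params.noise_sd, shape)
        rgb[..., ch] = np.clip(noisy, 0, 255).astype(np.uint8)

    truth = WholeMountTruth(
        tree_mask=mask,
        branchpoints_px=np.asarray(forks, dtype=float).reshape(-1, 2),
        nipple_px=params.nipple_px,
        ln_centroid_px=ln_centroid,
        true_area_um2=_mask_area_um2(mask, params.pixel_size_um),
        true_extension_um=_mask_extension_um(
            mask, params.nipple_px, params.pixel_size_um))
    return RasterImage(rgb, params.pixel_size_um), truth


def _layout_tree(
    params: TreeGenParams, rng: np.random.Generator
) -> tuple[np.ndarray, list[np.ndarray]]:
    """One attempt at laying out the bifurcating tree without overlaps."""
    shape = params.image_size_px
    h = params.duct_width_px // 2
    footprint = morphology.disk(h)
    # clearance so unrelated ducts never touch, even after a closing step
    clearance = morphology.disk(h + 6)
    allow_r = 4 * max(h, 1) + 4  # overlap allowed this close to the start
    occupied = np.zeros(shape, dtype=bool)
    mask = np.zeros(shape, dtype=bool)

    half_angle = math.radians(params.branch_angle_deg) / 2
    tips = [(np.asarray(params.nipple_px, float), 0.0, 0)]  # pos, angle, depth
    forks: list[np.ndarray] = []
    n_forks = 0
    seg_id = 0
    while tips:
        pos, base_ang, depth = tips.pop(0)
        last_err: GenerationError | None = None
        for attempt in range(60):
            # progressively shorter and more deflected candidates, so a
            # crowded tip can still find room
            length = params.segment_length_px * (0.88 ** depth) \
                * rng.uniform(0.9, 1.1) * max(0.45, 1.0 - 0.02 * attempt)
            ang = base_ang + rng.uniform(-0.09, 0.09) * (1 + 0.3 * attempt)
            end = pos + length * np.array([math.sin(ang), math.cos(ang)])
            try:
                rr, cc = _segment_pixels(pos, end, shape,
                                         params.duct_width_px, seg_id)
            except GenerationError as err:
                last_err = err
                continue
            # collision test in a local window around the segment
            pad = h + 8
            r0, r1 = max(rr.min() - pad, 0), min(rr.max() + pad + 1, shape[0])
            c0, c1 = max(cc.min() - pad, 0), min(cc.max() + pad + 1, shape[1])
            line = np.zeros((r1 - r0, c1 - c0), dtype=bool)
            line[rr - r0, cc - c0] = True
            swath = ndi.binary_dilation(line, structure=clearance)
            win_rows, win_cols = np.indices(line.shape)
            near_start = (win_rows + r0 - pos[0]) ** 2 + \
                (win_cols + c0 - pos[1]) ** 2 <= allow_r ** 2
            if (swath & occupied[r0:r1, c0:c1] & ~near_start).any():
                continue  # would overlap an unrelated duct: re-jitter
            break
        else:
            raise last_err or GenerationError(
                f"segment {seg_id} cannot be placed without duct overlap")
        thick = ndi.binary_dilation(line, structure=footprint)
        occupied[r0:r1, c0:c1] |= thick
        mask[r0:r1, c0:c1] |= thick
        seg_id += 1
        if n_forks < params.n_bifurcations:
            n_forks += 1
            spread = half_angle * rng.uniform(0.85, 1.15)
            # rendered ducts of half-width h overlap past the centerline
            # junction; the tree visibly forks h/tan(spread) further along
            fork = end + (h / math.tan(spread)) * np.array(
                [math.sin(ang), math.cos(ang)])
            forks.append(fork)
            tips.append((end, ang - spread, depth + 1))
            tips.append((end, ang + spread, depth + 1))
    return mask, forks


def _mask_extension_um(mask, nipple_px, pixel_size_um) -> float:
    """Brute-force longest nipple-to-boundary distance on the mask."""
    boundary = mask & ~ndi.binary_erosion(mask)
    pts = np.column_stack(np.nonzero(boundary))
    d = np.hypot(pts[:, 0] - nipple_px[0], pts[:, 1] - nipple_px[1])
    return float(d.max()) * pixel_size_um


def _mask_area_um2(mask, pixel_size_um) -> float:
    """Boundary-hull area of the mask at the default shrink factor."""
    from .morphometrics import tree_boundary_and_area
    return tree_boundary_and_area(mask, pixel_size_um)[1]


# ---------------------------------------------------------------- cysts --

@dataclass
class ProtrusionSpec:
    length_px: float
    width_px: float
    birth_frame: int
    death_frame: int


@dataclass
class CystGenParams:
    """Parameters of the cyst time-lapse generator.

    Defaults emulate a 30-minute-interval bright-field/fluorescence time
    lapse of one cyst with finger-like protrusions whose mean intensity is
    ``compartment_ratio`` times the body mean, plus Gaussian noise of
    ``noise_sd`` (in absolute intensity units; the study-like setting is
    5% of ``base_intensity``).
    """

    image_size_px: tuple[int, int] = (224, 224)
    body_radius_px: float = 60.0
    shell_px: float = 20.0
    protrusion_specs: list[ProtrusionSpec] = field(default_factory=list)
    compartment_ratio: float = 1.8
    base_intensity: float = 100.0
    noise_sd: float = 5.0
    frame_interval_h: float = 0.5
    n_frames: int = 1
    pixel_size_um: float = 0.65
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if not self.compartment_ratio > 0:
            raise ParameterError("compartment_ratio must be > 0")
        if self.noise_sd < 0 or self.base_intensity <= 0:
            raise ParameterError("intensity parameters must be positive")
        for i, s in enumerate(self.protrusion_specs):
            if not 0 <= s.birth_frame <= s.death_frame < self.n_frames:
                raise ParameterError(
                    f"protrusion {i}: need birth <= death < n_frames")


def _finger_mask(shape, center, radius, angle, length, width) -> np.ndarray:
    """Rectangle from just inside the body rim outward along ``angle``."""
    u = np.array([math.sin(angle), math.cos(angle)])
    v = np.array([math.cos(angle), -math.sin(angle)])
    a = np.asarray(center, float) + (radius - 2) * u
    b = a + (length + 2) * u
    half = width / 2
    corners = np.array([a + half * v, b + half * v, b - half * v,
                        a - half * v])
    rr, cc = draw.polygon(corners[:, 0], corners[:, 1], shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def generate_cyst_timelapse(
    params: CystGenParams, channel: str = "signal"
) -> tuple[list[CystScene], pd.DataFrame]:
    """Render a cyst time lapse plus a per-protrusion truth table.

    Protrusion *i* exists exactly in frames [birth, death]; its true
    lifetime is ``(death - birth + 1) * frame_interval_h`` and its true
    maximum length ``length_px * pixel_size_um`` (fingers are straight).
    Protrusions are laid out at evenly spaced angles so they never touch.

    The reported body mask is drawn just inside the outer cell layer, as an
    analyst outlines it; fluorescent signal extends ``shell_px`` beyond the
    mask so a rim band around the body samples real signal.
    """
    rng = np.random.default_rng(params.seed)
    shape = params.image_size_px
    center = (shape[0] / 2, shape[1] / 2)
    rr, cc = draw.disk(center, params.body_radius_px, shape=shape)
    body = np.zeros(shape, dtype=bool)
    body[rr, cc] = True
    rr, cc = draw.disk(center, params.body_radius_px + params.shell_px,
                       shape=shape)
    painted = np.zeros(shape, dtype=bool)
    painted[rr, cc] = True

    n = max(len(params.protrusion_specs), 1)
    angles = [2 * math.pi * i / n for i in range(n)]
    fingers = []
    for spec, ang in zip(params.protrusion_specs, angles):
        f = _finger_mask(shape, center, params.body_radius_px, ang,
                         spec.length_px, spec.width_px) & ~body
        margin = f & (np.zeros(shape, bool) | _border(shape))
        if margin.any() or not f.any():
            raise GenerationError("protrusion leaves the canvas")
        fingers.append(f)

    frames = []
    for t in range(params.n_frames):
        alive = [i for i, s in enumerate(params.protrusion_specs)
                 if s.birth_frame <= t <= s.death_frame]
        img = np.zeros(shape, dtype=float)
        img[painted] = params.base_intensity
        for i in alive:
            img[fingers[i]] = params.base_intensity * params.compartment_ratio
        if params.noise_sd > 0:
            img = img + rng.normal(0, params.noise_sd, shape)
        img = np.clip(img, 0, None)
        frames.append(CystScene(
            channels={channel: img}, body_mask=body.copy(),
            protrusion_masks=[fingers[i].copy() for i in alive],
            pixel_size_um=params.pixel_size_um))

    truth = pd.DataFrame(
        [{"protrusion": i,
          "birth_frame": s.birth_frame,
          "death_frame": s.death_frame,
          "lifetime_h": (s.death_frame - s.birth_frame + 1)
          * params.frame_interval_h,
          "max_length_um": s.length_px * params.pixel_size_um}
         for i, s in enumerate(params.protrusion_specs)])
    return frames, truth


def _border(shape) -> np.ndarray:
    b = np.zeros(shape, dtype=bool)
    b[0, :] = b[-1, :] = b[:, 0] = b[:, -1] = True
    return b


# ----------------------------------------------------------- abundances --

@dataclass
class PlantedEffect:
    """``fold_change`` multiplies ``group_b`` relative to ``group_a``."""

    protein_index: int
    group_a: str
    group_b: str
    fold_change: float


@dataclass
class AbundanceGenParams:
    """Zero-inflated log-normal abundance generator.

    Defaults emulate a label-free screen of three groups x five biological
    replicates: protein baselines spread over orders of magnitude
    (``protein_log_spread``, natural-log sd across proteins) with
    within-group biological/technical noise ``log_sd`` (~25% CV) and a
    dropout probability producing exact zeros.
    """

    n_proteins: int = 2000
    groups: list[tuple[str, int]] = field(default_factory=lambda: [
        ("4wk_wt", 5), ("5wk_wt", 5), ("5wk_mut", 5)])
    log_mean: float = 13.8
    log_sd: float = 0.25
    protein_log_spread: float = 1.5
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_prob < 1:
            raise ParameterError("dropout_prob must be in [0, 1)")
        sizes = dict(self.groups)
        for e in self.planted_effects:
            if not e.fold_change > 0:
                raise ParameterError("fold_change must be > 0")
            if not 0 <= e.protein_index < self.n_proteins:
                raise ParameterError("planted effect protein out of range")
            for g in (e.group_a, e.group_b):
                if sizes.get(g, 0) < 2:
                    raise ParameterError(
                        f"group {g!r} needs >= 2 samples to carry an effect")


def generate_abundance_matrix(
    params: AbundanceGenParams,
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Simulate an ion-intensity matrix plus a table of planted effects.

    Non-dropout entries are strictly positive; dropout entries are exact
    zeros recorded in ``original_zero`` so observation filters act on the
    pre-imputation state.
    """
    rng = np.random.default_rng(params.seed)
    labels = [g for g, n in params.groups for _ in range(n)]
    sample_ids = [f"{g}_{i+1}" for g, n in params.groups for i in range(n)]
    n_samp = len(labels)
    mu = rng.normal(params.log_mean, params.protein_log_spread,
                    params.n_proteins)
    values = np.exp(mu[:, None]
                    + rng.normal(0, params.log_sd,
                                 (params.n_proteins, n_samp)))
    col_of = {g: np.array([i for i, l in enumerate(labels) if l == g])
              for g, _ in params.groups}
    for e in params.planted_effects:
        values[e.protein_index, col_of[e.group_b]] *= e.fold_change

    zero = rng.random(values.shape) < params.dropout_prob
    values[zero] = 0.0

    matrix = AbundanceMatrix(
        values=values,
        protein_ids=[f"P{i:05d}" for i in range(params.n_proteins)],
        sample_ids=sample_ids, group_labels=labels, original_zero=zero)
    truth = pd.DataFrame(
        [{"protein_index": e.protein_index,
          "protein_id": matrix.protein_ids[e.protein_index],
          "group_a": e.group_a, "group_b": e.group_b,
          "fold_change": e.fold_change,
          "expected_log2_b_over_a": math.log2(e.fold_change)}
         for e in params.planted_effects])
    return matrix, truth
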