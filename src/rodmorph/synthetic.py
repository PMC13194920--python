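"""Synthetic spherocylinder scenes with exact ground truth.

Generates scenes of non-overlapping rod-shaped cells (spherocylinders of
known width, tip-to-tip length, position and orientation), rasterized as
exact instance-label masks at a fine render resolution (default 15 nm/px),
together with rendered fluorescent-membrane images or z-stacks: point
emitters are placed on a random subset of each cell's membrane contour
(default 90% retention), blurred with a Gaussian point-spread function, and
optionally corrupted with Poisson shot noise and Gaussian read noise.
Scenes are finally rescaled to a coarser output resolution (default
65 nm/px) by exact area-weighted resampling, emulating the pixel size of
typical widefield microscopy.

Because every cell's generating parameters are known exactly, these scenes
serve as ground truth for the measurement, correction and benchmarking
modules without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import ImageStack, LabelMask


@dataclass
class SceneSpec:
    """Parameters of a synthetic membrane scene.

    Widths and lengths are in µm; ``width_um`` may be a single value or a
    ``(low, high)`` range sampled uniformly per cell. ``length_um`` is the
    tip-to-tip length (caps included). Orientations are sampled uniformly
    in ``orientation_range_deg``. The point-spread function is an isotropic
    Gaussian of σ = 0.21·λ/NA per plane, broadened with defocus for
    z-stacks.
    """

    n_cells: int = 5
    width_um: float | tuple[float, float] = (0.53, 1.04)
    length_um: float = 4.0
    orientation_range_deg: tuple[float, float] = (0.0, 180.0)
    render_pixel_size: float = 0.015
    output_pixel_size: float = 0.065
    contour_retention: float = 0.9
    wavelength_um: float = 0.6
    numerical_aperture: float = 1.49
    refractive_index: float = 1.5
    emitter_intensity: float = 1000.0
    poisson_noise: bool = False
    gaussian_noise_sd: float = 0.0
    canvas_um: tuple[float, float] = (12.0, 12.0)
    margin_um: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        w = self.width_um
        lo, hi = (w, w) if np.isscalar(w) else w
        if not (0 < lo <= hi):
            raise ValueError("widths must be positive")
        if hi > self.length_um:
            raise ValueError("width must not exceed tip-to-tip length")
        if not (0 < self.contour_retention <= 1):
            raise ValueError("contour retention must lie in (0, 1]")
        if self.render_pixel_size > self.output_pixel_size:
            raise ValueError("render pixel size must be ≤ output pixel size")

    @property
    def psf_sigma_um(self) -> float:
        """In-focus Gaussian PSF width: 0.21·λ/NA (µm)."""
        return 0.21 * self.wavelength_um / self.numerical_aperture


@dataclass
class CellTruth:
    """Generating parameters of one synthetic cell (µm, degrees)."""

    label: int
    center_um: tuple[float, float]  # (row, col) in µm from the top-left corner
    theta_deg: float
    width_um: float
    length_um: float


@dataclass
class SyntheticScene:
    """A generated scene: ground truth plus render-resolution label mask."""

    spec: SceneSpec
    cells: list[CellTruth]
    labels: LabelMask                      # at render resolution
    membrane: ImageStack | None = None     # rendered image or z-stack
    z_offsets_um: np.ndarray = field(default_factory=lambda: np.array([0.0]))


class PlacementError(RuntimeError):
    pass


def _segment_endpoints(cell: CellTruth) -> tuple[np.ndarray, np.ndarray]:
    """Endpoints of the cylindrical axis (cap centers), in µm (row, col)."""
    half = (cell.length_um - cell.width_um) / 2.0
    th = math.radians(cell.theta_deg)
    d = np.array([math.sin(th), math.cos(th)])
    c = np.array(cell.center_um)
    return c - half * d, c + half * d


def _point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point (…, 2) to the segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(points - a, axis=-1)
    t = np.clip(((points - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    return np.linalg.norm(points - proj, axis=-1)


def _segments_clearance(c1: CellTruth, c2: CellTruth, n_samples: int = 33) -> float:
    """Minimum distance between two cells' axis segments (sampled)."""
    a1, b1 = _segment_endpoints(c1)
    a2, b2 = _segment_endpoints(c2)
    t = np.linspace(0, 1, n_samples)
    pts1 = a1 + t[:, None] * (b1 - a1)
    d = _point_segment_distance(pts1, a2, b2)
    return float(d.min())


def generate_scene(spec: SceneSpec, render_membrane: bool = False,
                   z_offsets_um=None) -> SyntheticScene:
    """Place non-overlapping spherocylinders and rasterize exact label masks.

    Placement is by rejection sampling; a cell is accepted when its axis
    keeps a clearance of (w1+w2)/2 + margin from every placed cell and its
    footprint stays inside the canvas. Identical seeds give identical
    scenes. Raises :class:`PlacementError` after 10⁴ failed attempts.
    """
    rng = np.random.default_rng(spec.seed)
    w = spec.width_um
    lo, hi = (float(w), float(w)) if np.isscalar(w) else map(float, w)
    th_lo, th_hi = spec.orientation_range_deg
    canvas_um = np.asarray(spec.canvas_um, dtype=float)

    cells: list[CellTruth] = []
    attempts = 0
    while len(cells) < spec.n_cells:
        if attempts >= 10_000:
            raise PlacementError(
                f"could not place {spec.n_cells} cells in 10000 attempts; enlarge canvas_um"
            )
        attempts += 1
        width = rng.uniform(lo, hi) if hi > lo else lo
        theta = rng.uniform(th_lo, th_hi)
        pad = spec.length_um / 2.0 + spec.margin_um
        center = rng.uniform(pad, canvas_um - pad)
        cand = CellTruth(label=len(cells) + 1, center_um=(float(center[0]), float(center[1])),
                         theta_deg=float(theta), width_um=float(width),
                         length_um=float(spec.length_um))
        ok = all(
            _segments_clearance(cand, other)
            >= (cand.width_um + other.width_um) / 2.0 + spec.margin_um
            for other in cells
        )
        if ok:
            cells.append(cand)

    px = spec.render_pixel_size
    shape = tuple(int(round(s / px)) for s in canvas_um)
    labels = np.zeros(shape, dtype=np.int32)
    for cell in cells:
        _rasterize_cell(labels, cell, px)
    mask = LabelMask(labels=labels, pixel_size=px, source_path="synthetic")
    scene = SyntheticScene(spec=spec, cells=cells, labels=mask)
    if render_membrane:
        scene = render_membrane_stack(scene, z_offsets_um=z_offsets_um)
    return scene


def _rasterize_cell(labels: np.ndarray, cell: CellTruth, px: float) -> None:
    """Mark pixels whose centers lie within w/2 of the cell's axis segment."""
    a, b = _segment_endpoints(cell)
    r = cell.width_um / 2.0
    lo = np.floor((np.minimum(a, b) - r) / px - 1).astype(int)
    hi = np.ceil((np.maximum(a, b) + r) / px + 1).astype(int)
    lo = np.clip(lo, 0, np.array(labels.shape) - 1)
    hi = np.clip(hi, 0, np.array(labels.shape))
    rows = (np.arange(lo[0], hi[0]) + 0.5) * px
    cols = (np.arange(lo[1], hi[1]) + 0.5) * px
    grid = np.stack(np.meshgrid(rows, cols, indexing="ij"), axis=-1)
    inside = _point_segment_distance(grid, a, b) <= r
    block = labels[lo[0]:hi[0], lo[1]:hi[1]]
    block[inside] = cell.label


def _contour_points(cell: CellTruth, dz_um: float, spacing_um: float) -> np.ndarray:
    """Membrane contour of the cell's cross-section at height dz above the
    mid-plane, sampled at roughly ``spacing_um`` arc-length steps (µm).

    The 3D spherocylinder cut at height dz (|dz| < w/2) is again a stadium
    shape: same axis, cross-section radius √((w/2)² − dz²). Planes at
    |dz| ≥ w/2 contribute nothing.
    """
    r0 = cell.width_um / 2.0
    if abs(dz_um) >= r0:
        return np.empty((0, 2))
    r = math.sqrt(r0**2 - dz_um**2)
    a, b = _segment_endpoints(cell)
    axis = b - a
    L = float(np.linalg.norm(axis))
    u = axis / L if L > 0 else np.array([0.0, 1.0])
    n_vec = np.array([-u[1], u[0]])

    pts = []
    # two straight flanks
    n_side = max(int(round(L / spacing_um)), 1)
    t = np.linspace(0, 1, n_side, endpoint=False)
    for sign in (+1, -1):
        pts.append(a + t[:, None] * axis + sign * r * n_vec)
    # two semicircular ends
    n_arc = max(int(round(math.pi * r / spacing_um)), 2)
    phi = np.linspace(-math.pi / 2, math.pi / 2, n_arc, endpoint=False)
    for center, sign in ((b, +1), (a, -1)):
        # forward-facing semicircle around the outward axis direction
        arc = center + sign * np.cos(phi)[:, None] * u * r + np.sin(phi)[:, None] * n_vec * r
        pts.append(arc)
    return np.concatenate(pts)


def render_membrane_stack(scene: SyntheticScene, z_offsets_um=None,
                          rng: np.random.Generator | None = None) -> SyntheticScene:
    """Render fluorescent-membrane planes for the scene.

    Per z-plane and cell, point emitters are placed on a random subset
    (``contour_retention``, default 90%) of the cross-section contour
    points, binned to the render grid, and blurred with the Gaussian PSF
    (σ broadened with defocus as σ(dz) = √(σ₀² + (0.5·dz·NA/n)²)).
    Optional Poisson and Gaussian noise are applied per plane.
    """
    spec = scene.spec
    if z_offsets_um is None:
        z_offsets_um = np.array([0.0])
    z_offsets_um = np.asarray(z_offsets_um, dtype=float)
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    px = spec.render_pixel_size
    shape = scene.labels.shape
    spacing = px  # ~1 render px between contour points

    # emitter maps per membrane z-slice (the same grid as the focal planes,
    # so a single-plane render uses only the mid-plane ring)
    emitters = np.zeros((z_offsets_um.size,) + shape)
    for zi, dz in enumerate(z_offsets_um):
        for cell in scene.cells:
            contour = _contour_points(cell, dz, spacing)
            if len(contour) == 0:
                continue
            keep = round(spec.contour_retention * len(contour))
            idx = rng.choice(len(contour), size=keep, replace=False)
            pix = np.floor(contour[idx] / px).astype(int)
            valid = ((pix[:, 0] >= 0) & (pix[:, 0] < shape[0])
                     & (pix[:, 1] >= 0) & (pix[:, 1] < shape[1]))
            np.add.at(emitters[zi], (pix[valid, 0], pix[valid, 1]), spec.emitter_intensity)

    # widefield image formation: each focal plane collects light from every
    # membrane slice, blurred by a defocus-broadened PSF
    planes = np.zeros_like(emitters)
    for zi, z_focus in enumerate(z_offsets_um):
        for ze, z_emit in enumerate(z_offsets_um):
            if not emitters[ze].any():
                continue
            defocus = 0.5 * abs(z_focus - z_emit) * spec.numerical_aperture / spec.refractive_index
            sigma_px = math.hypot(spec.psf_sigma_um, defocus) / px
            planes[zi] += ndimage.gaussian_filter(emitters[ze], sigma=sigma_px)
        if spec.poisson_noise:
            planes[zi] = rng.poisson(np.clip(planes[zi], 0, None)).astype(float)
        if spec.gaussian_noise_sd > 0:
            planes[zi] = planes[zi] + rng.normal(0, spec.gaussian_noise_sd, size=shape)
    membrane = ImageStack(planes=planes, pixel_size=px,
                          z_spacing=float(np.median(np.diff(z_offsets_um)))
                          if z_offsets_um.size > 1 else None)
    return replace(scene, membrane=membrane, z_offsets_um=z_offsets_um)


def _overlap_matrix(n_out: int, n_in: int, factor: float) -> np.ndarray:
    """Row-stochastic matrix of fractional overlaps for 1D area-weighted
    resampling: output pixel i covers input interval [i·f, (i+1)·f)."""
    w = np.zeros((n_out, n_in))
    for i in range(n_out):
        lo, hi = i * factor, min((i + 1) * factor, n_in)
        j0, j1 = int(math.floor(lo)), int(math.ceil(hi))
        for j in range(j0, min(j1, n_in)):
            w[i, j] = min(hi, j + 1) - max(lo, j)
        total = w[i].sum()
        if total > 0:
            w[i] /= total
    return w


def _area_resample(img: np.ndarray, factor: float) -> np.ndarray:
    """Exact area-weighted downsampling of a 2D image by ``factor`` (≥1)."""
    n_out = (max(int(round(img.shape[0] / factor)), 1),
             max(int(round(img.shape[1] / factor)), 1))
    wr = _overlap_matrix(n_out[0], img.shape[0], factor)
    wc = _overlap_matrix(n_out[1], img.shape[1], factor)
    return wr @ img @ wc.T


def rescale_scene(scene: SyntheticScene, output_pixel_size: float | None = None) -> SyntheticScene:
    """Rescale the scene to the output pixel size (default from the spec).

    Intensity planes are block-averaged with exact area weighting; label
    masks are decided per output pixel by majority vote (the label, or
    background, covering the largest area fraction). Ground-truth cell
    parameters are unchanged. A scale factor of 1 is the identity.
    """
    spec = scene.spec
    if output_pixel_size is None:
        output_pixel_size = spec.output_pixel_size
    factor = output_pixel_size / scene.labels.pixel_size
    if factor < 1:
        raise ValueError("output pixel size must be ≥ render pixel size")
    if factor == 1:
        return scene

    label_ids = scene.labels.instance_labels
    coverage = [_area_resample((scene.labels.labels == 0).astype(float), factor)]
    for lab in label_ids:
        coverage.append(_area_resample((scene.labels.labels == lab).astype(float), factor))
    winner = np.argmax(np.stack(coverage), axis=0)
    ids = np.concatenate([[0], label_ids])
    out_labels = ids[winner].astype(np.int32)
    out_mask = LabelMask(labels=out_labels, pixel_size=output_pixel_size,
                         source_path=scene.labels.source_path)

    membrane = None
    if scene.membrane is not None:
        planes = np.stack([_area_resample(p, factor) for p in scene.membrane.planes])
        membrane = ImageStack(planes=planes, pixel_size=output_pixel_size,
                              z_spacing=scene.membrane.z_spacing)
    return replace(scene, labels=out_mask, membrane=membrane)


def apparent_ridge_width(
    image: np.ndarray,
    cell: CellTruth,
    pixel_size: float,
    n_samples: int = 7,
) -> float:
    """Apparent cell width from the membrane-ridge separation (µm).

    Emulates active-contour annotation of membrane images: at several
    positions along the central half of the cell axis, an intensity profile
    is taken perpendicular to the axis, and the apparent width at that
    position is the distance between the two membrane peaks flanking the
    axis. The median over positions is returned. Robust to defocus blur,
    which broadens the walls symmetrically without moving their peaks.
    Returns 0 when no membrane signal is found.
    """
    from .morphometry import extract_intensity_profile

    a, b = _segment_endpoints(cell)
    axis = (b - a)
    norm = np.linalg.norm(axis)
    u = axis / norm if norm > 0 else np.array([0.0, 1.0])
    n_vec = np.array([-u[1], u[0]])
    # window of 1.5 w centered on the axis: the wall peak sits at 0.5 w,
    # while the placement margin keeps neighboring cells' walls outside
    length_px = int(round(1.5 * cell.width_um / pixel_size))
    widths = []
    for t in np.linspace(0.3, 0.7, n_samples):
        center_um = a + t * axis
        center_px = center_um / pixel_size
        try:
            prof = extract_intensity_profile(image, tuple(center_px), tuple(n_vec), length_px)
        except ValueError:
            continue
        mid = length_px // 2
        left, right = prof[:mid], prof[mid:]
        if left.max() <= 0 or right.max() <= 0:
            continue
        left_peak = _subpixel_peak(prof, int(np.argmax(left)))
        right_peak = _subpixel_peak(prof, mid + int(np.argmax(right)))
        widths.append((right_peak - left_peak) * pixel_size)
    return float(np.median(widths)) if widths else 0.0


def _subpixel_peak(profile: np.ndarray, index: int) -> float:
    """Parabolic refinement of a peak position from its three-sample
    neighborhood; falls back to the integer index at the array ends."""
    if index <= 0 or index >= len(profile) - 1:
        return float(index)
    y0, y1, y2 = profile[index - 1], profile[index], profile[index + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(index)
    shift = 0.5 * (y0 - y2) / denom
    return float(index + np.clip(shift, -0.5, 0.5))


def analytic_spherocylinder_metrics(width_um: float, tip_to_tip_um: float) -> dict[str, float]:
    """Closed-form size metrics of an ideal spherocylinder.

    A cylinder of diameter w and length (L − w) capped by two hemispheres:

        S = π·w·(L − w) + π·w²          (lateral + sphere surface)
        V = π·w²·(L − w)/4 + π·w³/6     (cylinder + sphere volume)

    At w = L the shape degenerates to a sphere (S = π·w², V = π·w³/6).
    """
    w, L = float(width_um), float(tip_to_tip_um)
    if not 0 < w <= L:
        raise ValueError("need 0 < width ≤ tip-to-tip length")
    return {
        "length": L,
        "width": w,
        "surface": math.pi * w * (L - w) + math.pi * w**2,
        "volume": math.pi * w**2 * (L - w) / 4.0 + math.pi * w**3 / 6.0,
    }


def ideal_label_mask(width_um: float, tip_to_tip_um: float, pixel_size: float = 0.065,
                     theta_deg: float = 0.0, pad_um: float = 0.5) -> tuple[LabelMask, CellTruth]:
    """Rasterize a single ideal spherocylinder directly at ``pixel_size``.

    Convenience for measurement-recovery tests: returns the exact digital
    footprint of one cell (label 1) plus its generating parameters.
    """
    cell = CellTruth(label=1, center_um=(0.0, 0.0), theta_deg=theta_deg,
                     width_um=width_um, length_um=tip_to_tip_um)
    half_extent = tip_to_tip_um / 2.0 + pad_um
    cell = replace(cell, center_um=(half_extent, half_extent))
    n = int(math.ceil(2 * half_extent / pixel_size))
    labels = np.zeros((n, n), dtype=np.int32)
    _rasterize_cell(labels, cell, pixel_size)
    return LabelMask(labels=labels, pixel_size=pixel_size, source_path="synthetic"), cell
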