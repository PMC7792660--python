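"""Synthetic inputs with known ground truth.

Every input the pipeline consumes can be generated here, so the whole
chain is testable without any download:

* **PVS phantoms** — bright tubular structures (diameter < 3 mm) with a
  Gaussian radial intensity profile on a noisy darker background inside an
  ellipsoidal white-matter-like ROI, on the anisotropic 1 x 1 x 2 mm grid
  of an axial T2w acquisition. Ground truth records every tube.
* **Motion stripes** — parallel bright line artefacts, the appearance of
  motion-corrupted scans that real pipelines must reject at QC.
* **Retinal phantoms** — binary arteriole/venule maps with straight
  vessels of known width radiating from an optic disc across the Zone B
  measurement ring, plus the table of true widths at the ring.
* **Fractal fixtures** — rasters of known box-counting dimension (line,
  filled square, Sierpinski triangle) to calibrate the FD estimator.
* **Cohort tables** — a single-latent-factor Gaussian copula in which PVS
  burden loads negatively and retinal caliber / fractal dimension load
  positively on a latent microvascular-health factor, so higher PVS burden
  co-occurs with narrower arterioles and sparser retinal branching.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import validate_cohort
from .image import BinaryMask, Volume3D

__all__ = [
    "GroundTruthPVS",
    "CohortSimParams",
    "generate_pvs_phantom",
    "add_motion_stripes",
    "tube_mask",
    "ground_truth_mask",
    "RetinalPhantom",
    "generate_retinal_phantom",
    "generate_fractal_fixture",
    "generate_cohort",
    "spearman_to_pearson",
    "write_phantom",
]


# ---------------------------------------------------------------------------
# PVS phantoms
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthPVS:
    """One synthetic perivascular space: a capsule of known geometry."""

    center: tuple[float, float, float]   # mm
    direction: tuple[float, float, float]  # unit vector
    length: float                        # mm (axis length, excluding caps)
    radius: float                        # mm
    peak_intensity: float                # added contrast at the axis

    def __post_init__(self) -> None:
        if not (2 * self.radius < 3):
            raise ValueError("PVS diameter must be < 3 mm")
        if self.length < 2 * self.radius:
            raise ValueError("length must be >= diameter")
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("direction must be a unit vector")

    @property
    def endpoints(self):
        c = np.asarray(self.center)
        d = np.asarray(self.direction)
        half = 0.5 * self.length
        return c - half * d, c + half * d


def _voxel_center_grids(shape, voxel_size):
    h = np.asarray(voxel_size, dtype=float)
    axes = [np.arange(n) * h[i] for i, n in enumerate(shape)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_roi(shape, voxel_size, fill: float = 0.82) -> BinaryMask:
    """Centered ellipsoid ROI occupying ``fill`` of each physical half-extent."""
    gx, gy, gz = _voxel_center_grids(shape, voxel_size)
    h = np.asarray(voxel_size, dtype=float)
    extent = (np.asarray(shape) - 1) * h
    c = extent / 2
    a = fill * extent / 2
    val = ((gx - c[0]) / a[0]) ** 2 + ((gy - c[1]) / a[1]) ** 2 + ((gz - c[2]) / a[2]) ** 2
    return BinaryMask(val <= 1.0, tuple(voxel_size))


def _segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between 3D segments p1-q1 and p2-q2."""
    d1, d2 = q1 - p1, q2 - p2
    r = p1 - p2
    a, e, f = d1 @ d1, d2 @ d2, d2 @ r
    c, b = d1 @ r, d1 @ d2
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0, 1) if denom > 1e-12 else 0.0
    t = np.clip((b * s + f) / e, 0, 1) if e > 1e-12 else 0.0
    s = np.clip((b * t - c) / a, 0, 1) if a > 1e-12 else 0.0
    closest1 = p1 + s * d1
    closest2 = p2 + t * d2
    return float(np.linalg.norm(closest1 - closest2))


def _distance_to_segment(points, p, q):
    """Distances from an (..., 3) array of points to segment p-q."""
    d = q - p
    l2 = d @ d
    t = np.clip(((points - p) @ d) / l2, 0.0, 1.0) if l2 > 0 else 0.0
    proj = p + t[..., None] * d
    return np.linalg.norm(points - proj, axis=-1)


def _render_tube(data, tube: GroundTruthPVS, voxel_size, cutoff_sigmas: float = 3.5):
    """Add one tube's Gaussian-profile intensity (SD = radius/2) in place."""
    h = np.asarray(voxel_size, dtype=float)
    sigma = tube.radius / 2.0
    p, q = tube.endpoints
    pad = tube.radius + cutoff_sigmas * sigma
    lo = np.maximum(np.floor((np.minimum(p, q) - pad) / h).astype(int), 0)
    hi = np.minimum(np.ceil((np.maximum(p, q) + pad) / h).astype(int) + 1, data.shape)
    slices = tuple(slice(l, u) for l, u in zip(lo, hi))
    grids = np.meshgrid(*[np.arange(l, u) * h[i] for i, (l, u) in enumerate(zip(lo, hi))],
                        indexing="ij")
    pts = np.stack(grids, axis=-1)
    dist = _distance_to_segment(pts, p, q)
    data[slices] += tube.peak_intensity * np.exp(-dist ** 2 / (2 * sigma ** 2))


def _tube_visible_on_grid(p, q, radius, shape, voxel_size) -> bool:
    """True when the tube's own noiseless render has a single 26-connected
    component of >= 2 voxels above half its peak intensity.

    This is what makes the ground-truth count well defined: a thin tube
    lying between slice planes of an anisotropic grid can have no voxel
    centre near its axis at all, and would be invisible at any noise
    level.
    """
    from scipy import ndimage as _ndi

    h = np.asarray(voxel_size, dtype=float)
    sigma = radius / 2.0
    half_peak_r = sigma * np.sqrt(2.0 * np.log(2.0))
    pad = half_peak_r + max(h)
    lo = np.maximum(np.floor((np.minimum(p, q) - pad) / h).astype(int), 0)
    hi = np.minimum(np.ceil((np.maximum(p, q) + pad) / h).astype(int) + 1, shape)
    if np.any(hi <= lo):
        return False
    grids = np.meshgrid(*[np.arange(l, u) * h[i] for i, (l, u) in enumerate(zip(lo, hi))],
                        indexing="ij")
    pts = np.stack(grids, axis=-1)
    mask = _distance_to_segment(pts, p, q) <= half_peak_r
    if mask.sum() < 2:
        return False
    _, n = _ndi.label(mask, structure=_ndi.generate_binary_structure(3, 3))
    return n == 1


def generate_pvs_phantom(
    n_tubes: int,
    shape=(128, 128, 64),
    voxel_size=(1.0, 1.0, 2.0),
    background: float = 100.0,
    peak_range=(60.0, 100.0),
    radius_range=(0.8, 1.4),
    length_range=(6.0, 14.0),
    noise_sd: float = 2.0,
    min_separation: float = 3.0,
    seed: int = 0,
    max_attempts_per_tube: int = 5000,
):
    """Render a tube phantom with unambiguous ground truth.

    Tubes are placed inside an ellipsoidal ROI with pairwise *surface*
    separation >= ``min_separation`` mm and are required to be visible on
    the sampled grid (their noiseless half-peak footprint is a single
    26-connected component of >= 2 voxels), so the ground-truth component
    count is well defined. Each tube is a bright capsule with a Gaussian
    radial profile (peak at the axis, SD = radius/2) on a uniform
    background; i.i.d. Gaussian noise is added last.

    Returns ``(volume, roi, tubes)``. Raises if the requested count cannot
    be placed at the required separation within a bounded number of
    attempts (never silently truncates).
    """
    if n_tubes < 0:
        raise ValueError("n_tubes must be >= 0")
    rng = np.random.default_rng(seed)
    roi = _ellipsoid_roi(shape, voxel_size)
    h = np.asarray(voxel_size, dtype=float)
    extent = (np.asarray(shape) - 1) * h
    c_roi = extent / 2
    a_roi = 0.82 * extent / 2

    tubes: list[GroundTruthPVS] = []
    segments: list[tuple[np.ndarray, np.ndarray, float]] = []
    for i in range(n_tubes):
        placed = False
        for _ in range(max_attempts_per_tube):
            radius = rng.uniform(*radius_range)
            length = rng.uniform(*length_range)
            # uniform direction on the sphere
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            center = c_roi + (rng.uniform(-1, 1, size=3)) * a_roi
            p, q = center - 0.5 * length * d, center + 0.5 * length * d
            # both endpoints (with margin) inside the ROI ellipsoid
            margin = radius + 1.0
            ok = True
            for end in (p, q):
                if np.sum(((end - c_roi) / (a_roi - margin)) ** 2) > 1.0:
                    ok = False
                    break
            if not ok:
                continue
            for (p2, q2, r2) in segments:
                if _segment_distance(p, q, p2, q2) < radius + r2 + min_separation:
                    ok = False
                    break
            if not ok:
                continue
            if not _tube_visible_on_grid(p, q, radius, shape, voxel_size):
                continue
            tube = GroundTruthPVS(tuple(center), tuple(d), length, radius,
                                  rng.uniform(*peak_range))
            tubes.append(tube)
            segments.append((p, q, radius))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place tube {i + 1}/{n_tubes} at separation "
                f">= {min_separation} mm after {max_attempts_per_tube} attempts")

    data = np.full(shape, background, dtype=np.float64)
    for tube in tubes:
        _render_tube(data, tube, voxel_size)
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=shape)
    return Volume3D(data, tuple(voxel_size)), roi, tubes


def tube_mask(tube: GroundTruthPVS, shape, voxel_size) -> np.ndarray:
    """Boolean grid of the tube's flat-ended cylinder: voxel centres within
    ``radius`` of the axis line, axial projection within the length."""
    h = np.asarray(voxel_size, dtype=float)
    p, q = tube.endpoints
    d = np.asarray(tube.direction)
    pad = tube.radius + max(h)
    lo = np.maximum(np.floor((np.minimum(p, q) - pad) / h).astype(int), 0)
    hi = np.minimum(np.ceil((np.maximum(p, q) + pad) / h).astype(int) + 1, shape)
    out = np.zeros(shape, dtype=bool)
    grids = np.meshgrid(*[np.arange(l, u) * h[i] for i, (l, u) in enumerate(zip(lo, hi))],
                        indexing="ij")
    pts = np.stack(grids, axis=-1)
    rel = pts - np.asarray(tube.center)
    axial = rel @ d
    radial = np.linalg.norm(rel - axial[..., None] * d, axis=-1)
    inside = (radial <= tube.radius) & (np.abs(axial) <= tube.length / 2.0)
    out[tuple(slice(l, u) for l, u in zip(lo, hi))] = inside
    return out


def ground_truth_mask(tubes, shape, voxel_size) -> np.ndarray:
    """Union of all tube masks."""
    out = np.zeros(shape, dtype=bool)
    for t in tubes:
        out |= tube_mask(t, shape, voxel_size)
    return out


def add_motion_stripes(volume: Volume3D, n_stripes: int, amplitude: float,
                       seed: int = 0, stripe_sigma_mm: float = 0.9) -> Volume3D:
    """Superimpose parallel bright line artefacts across the volume.

    All stripes share one in-plane direction (they are parallel, as motion
    artefacts are); each is an infinite line with a Gaussian cross profile.
    ``amplitude = 0`` returns the volume unchanged.
    """
    if n_stripes < 1:
        raise ValueError("n_stripes must be >= 1")
    out = volume.copy()
    if amplitude == 0:
        return out
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, np.pi)
    d = np.array([np.cos(theta), np.sin(theta), 0.0])
    # perpendicular frame: ghost replications repeat at regular offsets
    u = np.array([-d[1], d[0], 0.0])
    w = np.array([0.0, 0.0, 1.0])
    h = np.asarray(volume.voxel_size, dtype=float)
    extent = (np.asarray(volume.shape) - 1) * h
    center = extent / 2
    gx, gy, gz = _voxel_center_grids(volume.shape, volume.voxel_size)
    pts = np.stack([gx, gy, gz], axis=-1)
    # jittered grid of perpendicular offsets keeps the stripes distinct
    n_u = int(np.ceil(np.sqrt(n_stripes)))
    n_w = int(np.ceil(n_stripes / n_u))
    span_u, span_w = 0.8 * extent[:2].min(), 0.8 * extent[2]
    step_u, step_w = span_u / n_u, span_w / n_w
    offsets = []
    for i in range(n_u):
        for j in range(n_w):
            if len(offsets) >= n_stripes:
                break
            ou = (i - (n_u - 1) / 2) * step_u + rng.uniform(-0.2, 0.2) * step_u
            ow = (j - (n_w - 1) / 2) * step_w + rng.uniform(-0.2, 0.2) * step_w
            offsets.append((ou, ow))
    for ou, ow in offsets:
        origin = center + ou * u + ow * w
        rel = pts - origin
        proj = rel @ d
        dist = np.linalg.norm(rel - proj[..., None] * d, axis=-1)
        out.data += amplitude * np.exp(-dist ** 2 / (2 * stripe_sigma_mm ** 2))
    return out


def write_phantom(outdir, volume: Volume3D, roi: BinaryMask, tubes) -> None:
    """Write a phantom as NIfTI-1 volumes plus a JSON ground-truth sidecar."""
    from .image import write_mask, write_volume

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(volume, outdir / "t2w.nii.gz")
    write_mask(roi, outdir / "roi.nii.gz")
    payload = [
        {"center": list(t.center), "direction": list(t.direction),
         "length": t.length, "radius": t.radius, "peak_intensity": t.peak_intensity}
        for t in tubes
    ]
    (outdir / "ground_truth.json").write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Retinal phantoms
# ---------------------------------------------------------------------------

@dataclass
class RetinalPhantom:
    artery_map: np.ndarray       # bool 2D
    vein_map: np.ndarray         # bool 2D
    widths: pd.DataFrame         # columns: vessel_type, angle_deg, width_px
    od_center: tuple[float, float]
    od_diameter: float


def _render_rays(size, od_center, r_start, angles, widths) -> np.ndarray:
    """Render radial vessels of constant width as a boolean raster."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cx, cy = od_center
    px = xx - cx
    py = yy - cy
    out = np.zeros((size, size), dtype=bool)
    for ang, w in zip(angles, widths):
        d = np.array([np.cos(ang), np.sin(ang)])
        proj = px * d[0] + py * d[1]
        perp = np.abs(px * d[1] - py * d[0])
        out |= (proj >= r_start) & (perp <= w / 2.0)
    return out


def generate_retinal_phantom(
    n_arterioles: int = 6,
    n_venules: int = 6,
    image_size: int = 512,
    od_center=None,
    od_diameter: float = 120.0,
    arteriole_width=(10.0, 2.0),
    venule_width=(14.0, 2.5),
    min_width: float = 4.0,
    seed: int = 0,
) -> RetinalPhantom:
    """Binary vessel maps with known widths crossing the Zone B ring.

    Vessels are straight rays of constant width emanating from the optic
    disc boundary at distinct angles (arterioles and venules
    interleaved). Angular placement keeps every vessel's footprint
    disjoint throughout the Zone B annulus so each ring crossing is
    unambiguous. Width parameters are (mean, SD) of a normal truncated to
    [min_width, mean + 3 SD] in px. The returned table records each
    vessel's true width where it crosses the ring.
    """
    if n_arterioles < 6 or n_venules < 6:
        raise ValueError("big-six selection needs >= 6 vessels of each type")
    od_center = od_center or (image_size / 2.0, image_size / 2.0)
    outer_r = od_diameter * 1.0   # Zone B outer radius: 1.0 OD diameters
    if (min(od_center) - outer_r) < 0 or (max(od_center) + outer_r) > image_size - 1:
        raise ValueError("Zone B ring falls outside the image bounds")
    rng = np.random.default_rng(seed)
    n_total = n_arterioles + n_venules
    is_artery = np.zeros(n_total, dtype=bool)
    is_artery[0::2] = True
    if is_artery.sum() != n_arterioles:
        is_artery[:] = False
        is_artery[:n_arterioles] = True
        rng.shuffle(is_artery)
    a_w = np.clip(rng.normal(*arteriole_width, size=n_arterioles), min_width,
                  arteriole_width[0] + 3 * arteriole_width[1])
    v_w = np.clip(rng.normal(*venule_width, size=n_venules), min_width,
                  venule_width[0] + 3 * venule_width[1])
    widths = np.empty(n_total)
    widths[is_artery] = a_w
    widths[~is_artery] = v_w
    # angular footprints must stay disjoint down to the Zone B inner radius
    inner_r = 0.5 * od_diameter
    half_angles = np.arcsin(np.minimum(widths / 2.0 / inner_r, 1.0))
    spacing = 2 * np.pi / n_total
    margin = 0.02
    max_foot = float(half_angles.max())
    if spacing < 2 * max_foot + margin:
        raise ValueError("too many / too wide vessels: footprints overlap in Zone B")
    jitter_amp = (spacing - 2 * max_foot - margin) / 2.0
    base = np.arange(n_total) * spacing
    angles = (base + rng.uniform(-jitter_amp, jitter_amp, size=n_total)
              + rng.uniform(0, 2 * np.pi))
    r_start = 0.45 * od_diameter
    artery_map = _render_rays(image_size, od_center, r_start, angles[is_artery], widths[is_artery])
    vein_map = _render_rays(image_size, od_center, r_start, angles[~is_artery], widths[~is_artery])
    table = pd.DataFrame({
        "vessel_type": np.where(is_artery, "artery", "vein"),
        "angle_deg": np.rad2deg(angles) % 360.0,
        "width_px": widths,
    })
    return RetinalPhantom(artery_map, vein_map, table, tuple(od_center), float(od_diameter))


# ---------------------------------------------------------------------------
# Fractal fixtures
# ---------------------------------------------------------------------------

def generate_fractal_fixture(kind: str, size: int = 128, depth: int | None = None) -> np.ndarray:
    """Deterministic raster of known box-counting dimension.

    ``line`` (FD 1), ``filled_square`` (FD 2) and ``sierpinski`` (the
    Sierpinski triangle, FD log 3 / log 2 ~ 1.585). ``size`` must be a
    power of two so box-counting grids tile exactly; for the triangle,
    ``depth`` bounds the recursion (default: full resolution).
    """
    if size < 4 or (size & (size - 1)) != 0:
        raise ValueError("size must be a power of two >= 4")
    if kind == "line":
        img = np.zeros((size, size), dtype=bool)
        img[size // 2, :] = True
        return img
    if kind == "filled_square":
        return np.ones((size, size), dtype=bool)
    if kind == "sierpinski":
        max_depth = int(np.log2(size))
        depth = max_depth if depth is None else min(depth, max_depth)
        shift = max_depth - depth
        i, j = np.indices((size, size))
        return ((i >> shift) & (j >> shift)) == 0
    raise ValueError(f"unknown fractal kind {kind!r}")


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def spearman_to_pearson(rho_s: float) -> float:
    """Latent Pearson correlation of a bivariate normal whose Spearman
    correlation equals ``rho_s``: rho_P = 2 sin(pi rho_s / 6)."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


#: default marginal means/SDs calibrated to the printed cohort descriptives
DEFAULT_MARGINALS: dict[str, tuple[float, float]] = {
    "pvs_count": (254.4, 90.13),
    "pvs_total_volume": (3197.0, 1404.06),
    "pvs_mean_length": (3.91, 0.53),
    "pvs_mean_width": (1.99, 0.34),
    "pvs_mean_size": (13.49, 4.70),
    "wmh_pct_icv": (0.81, 0.89),
    "left_crae": (30.95, 2.78),
    "left_crve": (42.10, 3.99),
    "left_avr": (0.74, 0.08),
    "left_fda": (1.61, 0.06),
    "left_fdv": (1.59, 0.05),
    "right_crae": (31.27, 2.46),
    "right_crve": (41.93, 3.89),
    "right_avr": (0.75, 0.07),
    "right_fda": (1.57, 0.06),
    "right_fdv": (1.56, 0.06),
}

#: loadings on the latent microvascular-health factor; PVS burden loads
#: negatively, retinal caliber and branching complexity positively, so the
#: induced cross-correlations are negative (e.g. count x left CRAE:
#: -0.88 x 0.2257 ~ -0.199 latent Pearson, ~ -0.19 Spearman)
DEFAULT_LOADINGS: dict[str, float] = {
    "pvs_count": -0.88,
    "pvs_total_volume": -0.92,
    "pvs_mean_length": -0.85,
    "pvs_mean_width": -0.87,
    "pvs_mean_size": -0.84,
    "wmh_pct_icv": -0.25,
    "left_crae": 0.2257,
    "left_crve": 0.06,
    "left_avr": 0.16,
    "left_fda": 0.16,
    "left_fdv": 0.14,
    "right_crae": 0.13,
    "right_crve": 0.08,
    "right_avr": 0.04,
    "right_fda": 0.12,
    "right_fdv": 0.06,
}

#: prevalences of the binary risk factors (fractions of the cohort)
DEFAULT_PREVALENCES: dict[str, float] = {
    "hypertension": 0.4331,
    "diabetes": 0.0892,
    "hypercholesterolemia": 0.3491,
    "cvd": 0.2625,
    "smoking": 0.0761,
    "stroke": 0.1732,
}

#: additive standardised shift smoking applies to PVS enlargement metrics
DEFAULT_SMOKING_EFFECTS: dict[str, float] = {
    "pvs_mean_width": 0.14,
    "pvs_mean_size": 0.15,
    "pvs_total_volume": 0.13,
}


@dataclass
class CohortSimParams:
    """Single-latent-factor Gaussian-copula cohort model.

    Each continuous variable j is ``lambda_j * F + sqrt(1 - lambda_j^2) *
    eps_j`` on the z scale (F = latent microvascular health), then mapped
    to its target marginal. The implied correlation of variables i, j is
    ``lambda_i * lambda_j``; the implied matrix is positive semi-definite
    iff every |lambda| <= 1.
    """

    n_subjects: int = 381
    loadings: dict = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    smoking_effects: dict = field(default_factory=lambda: dict(DEFAULT_SMOKING_EFFECTS))
    age_mean: float = 72.47
    age_sd: float = 0.69
    female_fraction: float = 0.4882
    lognormal_vars: tuple = ("wmh_pct_icv",)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for k, v in self.loadings.items():
            if abs(v) > 1:
                raise ValueError(
                    f"loading {k}={v} exceeds 1: residual variance 1-lambda^2 = "
                    f"{1 - v ** 2:.3f} < 0, implied correlation matrix not PSD "
                    f"(offending eigenvalue {1 - v ** 2:.3f})")
        lam = np.array([self.loadings.get(v, 0.0) for v in self.marginals])
        sigma = np.outer(lam, lam)
        np.fill_diagonal(sigma, 1.0)
        evals = np.linalg.eigvalsh(sigma)
        if evals.min() < -1e-10:
            raise ValueError(
                f"implied correlation matrix is not PSD (min eigenvalue {evals.min():.3g})")
        for k, p in self.prevalences.items():
            if not (0 <= p <= 1):
                raise ValueError(f"prevalence of {k!r} must lie in [0, 1], got {p}")


def generate_cohort(params: CohortSimParams | None = None) -> pd.DataFrame:
    """Draw a cohort table with the configured association structure.

    Returns a validated DataFrame with subject id, inclusion flag, age,
    sex (1 = female), the six binary risk factors, brain PVS aggregates
    and per-eye retinal metrics. Smoking adds its configured standardised
    shift to PVS enlargement metrics before the marginal transform.
    """
    params = params or CohortSimParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_subjects

    latent = rng.normal(size=n)
    risks = {k: (rng.uniform(size=n) < p).astype(int) for k, p in params.prevalences.items()}
    smoking = risks.get("smoking", np.zeros(n, dtype=int))

    cols: dict[str, np.ndarray] = {
        "subject_id": np.array([f"S{i:04d}" for i in range(n)]),
        "included": np.ones(n, dtype=int),
        "age": params.age_mean + params.age_sd * rng.normal(size=n),
        "sex": (rng.uniform(size=n) < params.female_fraction).astype(int),
    }
    cols.update(risks)

    for var, (mean, sd) in params.marginals.items():
        lam = float(params.loadings.get(var, 0.0))
        z = lam * latent + np.sqrt(max(0.0, 1.0 - lam ** 2)) * rng.normal(size=n)
        z = z + params.smoking_effects.get(var, 0.0) * smoking
        if var in params.lognormal_vars:
            # lognormal with matched mean/SD; monotone, so Spearman survives
            s2 = np.log(1.0 + (sd / mean) ** 2)
            mu = np.log(mean) - s2 / 2.0
            cols[var] = np.exp(mu + np.sqrt(s2) * z)
        else:
            cols[var] = mean + sd * z
    return validate_cohort(pd.DataFrame(cols))
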