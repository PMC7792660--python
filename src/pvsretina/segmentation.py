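"""Thresholding, connected-component labelling and automated QC.

The vesselness map is thresholded inside the centrum semiovale ROI, the
resulting mask is labelled (26-connectivity by default: thin oblique tubes
on an anisotropic grid fragment under 6-connectivity), and an automated
quality-control step stands in for the visual accept/reject check a
trained operator would perform — in particular it rejects scans whose
segmentations are dominated by parallel line artefacts, the appearance of
motion-corrupted acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import PipelineConfig, QCParams
from .frangi import frangi_vesselness
from .image import BinaryMask, Volume3D
from .morphometry import PVSComponent, components_from_labels

__all__ = ["LabelledComponents", "QCVerdict", "segment", "label_components", "qc_check",
           "segment_subject"]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class LabelledComponents:
    """Labelled segmentation: 0 = background, labels consecutive 1..n."""

    labels: np.ndarray
    n_components: int
    connectivity: int
    voxel_size: tuple[float, float, float]

    def components(self, min_voxels: int = 1, max_width_mm: float | None = None) -> list[PVSComponent]:
        return components_from_labels(self.labels, self.voxel_size, min_voxels, max_width_mm)


@dataclass
class QCVerdict:
    accepted: bool
    reasons: list[str]
    warnings: list[str]
    metrics: dict


def segment(vesselness: Volume3D, roi: BinaryMask, threshold: float) -> BinaryMask:
    """Binary PVS mask: voxel is PVS iff vesselness >= threshold and in ROI."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    roi.check_alignment(vesselness)
    return BinaryMask((vesselness.data >= threshold) & roi.data, vesselness.voxel_size)


def segment_hysteresis(vesselness: Volume3D, roi: BinaryMask,
                       threshold: float, low_threshold: float) -> BinaryMask:
    """Hysteresis segmentation: detect at ``threshold``, extend down to
    ``low_threshold`` through connected voxels.

    Thin tubes lying obliquely to a thick-slice grid bead along their
    axis through partial-volume dips; extending each detection through
    connected weaker-response voxels bridges those dips without admitting
    isolated noise, which must still clear the detection threshold.
    """
    from skimage.filters import apply_hysteresis_threshold

    if not (0 < low_threshold < threshold < 1):
        raise ValueError("need 0 < low_threshold < threshold < 1")
    roi.check_alignment(vesselness)
    mask = apply_hysteresis_threshold(vesselness.data, low_threshold, threshold)
    return BinaryMask(mask & roi.data, vesselness.voxel_size)


def label_components(mask: BinaryMask, connectivity: int = 26) -> LabelledComponents:
    """Standard connected-component labelling at 6/18/26 connectivity."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    labels, n = ndimage.label(mask.data, structure=_STRUCTURES[connectivity])
    return LabelledComponents(labels, int(n), connectivity, mask.voxel_size)


def _principal_direction(coords_mm: np.ndarray):
    """Unit principal axis of a coordinate cloud, or None when too small
    or too isotropic for the direction to mean anything."""
    if coords_mm.shape[0] < 3:
        return None
    centred = coords_mm - coords_mm.mean(axis=0)
    cov = centred.T @ centred / coords_mm.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    if evals[2] <= 0 or evals[1] / evals[2] > 0.8:
        return None
    return evecs[:, 2]


def _perp_residual(coords: np.ndarray) -> float:
    """Rms perpendicular residual of a total-least-squares line fit."""
    centred = coords - coords.mean(axis=0)
    evals = np.linalg.eigvalsh(centred.T @ centred / coords.shape[0])
    return float(np.sqrt(max(evals[0] + evals[1], 0.0)))


def _collinear(coords_a: np.ndarray, coords_b: np.ndarray,
               resid_tol_mm: float, resid_rise_mm: float) -> bool:
    """True when two voxel clouds are fragments of one straight tube.

    The union must fit a single line about as well as each fragment does:
    the rms perpendicular residual of a total-least-squares line through
    all points must stay within ``resid_tol_mm`` (of the order of a tube
    radius) and must not rise more than ``resid_rise_mm`` above the worse
    of the two fragments' own residuals. Two distinct tubes — whose axes
    are kept apart by the minimum separation — fail on both counts unless
    they happen to be collinear end to end, in which case no geometric
    criterion could tell them apart.
    """
    union_resid = _perp_residual(np.vstack([coords_a, coords_b]))
    if union_resid > resid_tol_mm:
        return False
    rise = union_resid - max(_perp_residual(coords_a), _perp_residual(coords_b))
    return rise <= resid_rise_mm


def resolve_hysteresis_labels(vesselness: Volume3D, roi: BinaryMask,
                              threshold: float, low_threshold: float,
                              connectivity: int = 26,
                              link_gap_mm: float = 4.0,
                              link_resid_mm: float = 1.35,
                              link_resid_rise_mm: float = 0.25) -> LabelledComponents:
    """Hysteresis labelling with geometric link arbitration.

    Voxels at or above ``threshold`` are detections (seeds); connected
    weaker voxels (>= ``low_threshold``) extend them, each claimed by its
    nearest seed. Thin tubes lying obliquely to a thick-slice grid bead
    through partial-volume dips, so one vessel can surface as several
    nearby fragments; conversely two distinct vessels can sit within a
    halo's reach of each other. The two cases are distinguished
    geometrically: component pairs closer than ``link_gap_mm`` are merged
    only when they are collinear — the union fits a single straight line
    (see :func:`_collinear`). Weak-only regions (touching no seed) are
    dropped.
    """
    if not (0 < low_threshold < threshold < 1):
        raise ValueError("need 0 < low_threshold < threshold < 1")
    roi.check_alignment(vesselness)
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    from scipy.spatial import cKDTree

    struct = _STRUCTURES[connectivity]
    v = vesselness.data
    high = (v >= threshold) & roi.data
    low = (v >= low_threshold) & roi.data
    high_labels, n_high = ndimage.label(high, structure=struct)
    if n_high == 0:
        return LabelledComponents(np.zeros_like(high_labels), 0, connectivity,
                                  vesselness.voxel_size)
    h = np.asarray(vesselness.voxel_size)

    # weak voxels: claimed by the nearest seed of their low-threshold region
    low_labels, _ = ndimage.label(low, structure=struct)
    final = high_labels.copy()
    for low_lab, sl in enumerate(ndimage.find_objects(low_labels), start=1):
        if sl is None:
            continue
        region = low_labels[sl] == low_lab
        members = np.unique(high_labels[sl][region])
        members = members[members > 0]
        if members.size == 0:
            continue
        weak_vox = np.argwhere(region & (high_labels[sl] == 0))
        if weak_vox.size == 0:
            continue
        offset = np.array([s.start for s in sl])
        vox = weak_vox + offset
        if members.size == 1:
            final[tuple(vox.T)] = members[0]
            continue
        pts = vox * h
        best = np.full(len(pts), int(members[0]))
        best_d = cKDTree(np.argwhere(high_labels == members[0]) * h).query(pts)[0]
        for m in members[1:]:
            d = cKDTree(np.argwhere(high_labels == m) * h).query(pts)[0]
            closer = d < best_d
            best[closer] = int(m)
            best_d = np.minimum(best_d, d)
        final[tuple(vox.T)] = best

    # pairwise linking of nearby collinear fragments
    coords = {m: np.argwhere(final == m) * h for m in range(1, n_high + 1)}
    cents = {m: c.mean(axis=0) for m, c in coords.items()}
    trees = {m: cKDTree(c) for m, c in coords.items()}
    parent = np.arange(n_high + 1)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members = sorted(coords)
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            # cheap centroid prefilter before the exact gap query
            if np.linalg.norm(cents[a] - cents[b]) > link_gap_mm + 20.0:
                continue
            gap = trees[a].query(coords[b])[0].min()
            if gap > link_gap_mm:
                continue
            if _collinear(coords[a], coords[b], link_resid_mm, link_resid_rise_mm):
                parent[find(a)] = find(b)

    roots = np.array([find(i) for i in range(n_high + 1)])
    uniq = np.unique(roots[1:])
    remap = np.zeros(n_high + 1, dtype=np.int32)
    remap[uniq] = np.arange(1, uniq.size + 1)
    return LabelledComponents(remap[roots[final]], int(uniq.size), connectivity,
                              vesselness.voxel_size)


def _dominant_parallel_fraction(components: list[PVSComponent], angle_deg: float) -> float:
    """Fraction of components whose principal direction lies within
    ``angle_deg`` of the dominant orientation (sign-invariant)."""
    dirs = np.array([c.principal_direction for c in components])
    # dominant orientation = leading eigenvector of the orientation tensor
    tensor = dirs.T @ dirs
    _, vecs = np.linalg.eigh(tensor)
    dominant = vecs[:, -1]
    cosang = np.abs(dirs @ dominant)
    return float(np.mean(cosang >= np.cos(np.deg2rad(angle_deg))))


def qc_check(mask: BinaryMask, roi: BinaryMask, volume: Volume3D,
             params: QCParams | None = None,
             components: LabelledComponents | None = None) -> QCVerdict:
    """Automated accept/reject heuristics for one subject's segmentation.

    Rejects when (a) the segmented fraction of the ROI exceeds a ceiling,
    (b) the component count exceeds a ceiling, or (c) too many components
    share one dominant orientation — the signature of parallel motion
    stripes mistaken for PVS. An empty mask is accepted with a warning.
    """
    params = params or QCParams()
    params.validate()
    roi.check_alignment(mask)
    reasons: list[str] = []
    warnings: list[str] = []

    roi_voxels = int(roi.data.sum())
    seg_voxels = int((mask.data & roi.data).sum())
    frac = seg_voxels / roi_voxels if roi_voxels else 0.0
    if frac > params.max_roi_fraction:
        reasons.append(
            f"segmented fraction {frac:.3f} of ROI exceeds ceiling {params.max_roi_fraction}")

    if components is None:
        components = label_components(mask)
    n = components.n_components
    if n > params.max_components:
        reasons.append(f"component count {n} exceeds ceiling {params.max_components}")

    parallel_frac = np.nan
    if n >= params.stripe_min_components:
        comps = [c for c in components.components(min_voxels=3)]
        if len(comps) >= params.stripe_min_components:
            parallel_frac = _dominant_parallel_fraction(comps, params.stripe_angle_deg)
            if parallel_frac > params.stripe_fraction:
                reasons.append(
                    "parallel-structure artefact: fraction "
                    f"{parallel_frac:.2f} of components share one orientation")

    if seg_voxels == 0:
        warnings.append("no PVS detected")

    metrics = {"roi_fraction": frac, "n_components": n, "parallel_fraction": parallel_frac}
    return QCVerdict(not reasons, reasons, warnings, metrics)


def segment_subject(volume: Volume3D, roi: BinaryMask, config: PipelineConfig | None = None):
    """Full single-subject segmentation: Frangi -> threshold -> label -> QC.

    Returns ``(labelled, qc_verdict, pvs_mask)``.
    """
    config = config or PipelineConfig()
    config.validate()
    vmap = frangi_vesselness(volume, config.frangi, roi)
    if config.frangi.low_threshold is not None:
        labelled = resolve_hysteresis_labels(vmap, roi, config.frangi.threshold,
                                             config.frangi.low_threshold,
                                             config.components.connectivity)
        mask = BinaryMask(labelled.labels > 0, vmap.voxel_size)
    else:
        mask = segment(vmap, roi, config.frangi.threshold)
        labelled = label_components(mask, config.components.connectivity)
    verdict = qc_check(mask, roi, volume, config.qc, components=labelled)
    return labelled, verdict, mask
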