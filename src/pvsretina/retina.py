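"""Retinal vascular summary measures.

Five summary parameters per eye, computed independently for left and
right eyes (retinal symmetry cannot be assumed):

* **CRAE / CRVE** — central retinal artery / vein equivalent: the six
  widest arterioles (venules) crossing Zone B (the annulus 0.5-1.0
  optic-disc diameters from the disc centre) are combined pairwise,
  widest with narrowest, as ``w = k * sqrt(w_big^2 + w_small^2)`` with
  branching coefficient k (0.88 arterioles, 0.95 venules by default),
  iterating 6 -> 3 -> 2 (odd list: median carried forward) -> 1.
* **AVR** — the arteriole-to-venule ratio CRAE / CRVE, exactly.
* **FDa / FDv** — monofractal box-counting fractal dimension of the
  binarised arteriolar / venular map: the negative slope of
  log N(s) vs log s over a geometric ladder of box sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


from .config import RetinaParams

__all__ = [
    "RetinalWidths",
    "RetinalMetrics",
    "ZoneBGeometry",
    "select_big_six",
    "summarize_caliber",
    "box_counting_fd",
    "measure_ring_widths",
    "compute_retinal_metrics",
]


@dataclass
class RetinalWidths:
    """Measured vessel widths for one eye, tagged by vessel type."""

    eye: str                      # "left" or "right"
    arteriole_widths: list
    venule_widths: list

    def __post_init__(self) -> None:
        if self.eye not in ("left", "right"):
            raise ValueError("eye must be 'left' or 'right'")
        for name, widths in (("arteriole", self.arteriole_widths),
                             ("venule", self.venule_widths)):
            if any(w <= 0 for w in widths):
                raise ValueError(f"{name} widths must all be positive")


@dataclass
class RetinalMetrics:
    """Per-eye summary: CRAE, CRVE (measurement units), AVR, FDa, FDv."""

    eye: str
    crae: float
    crve: float
    avr: float
    fda: float
    fdv: float

    def to_row(self) -> dict:
        return {f"{self.eye}_{k}": getattr(self, k) for k in ("crae", "crve", "avr", "fda", "fdv")}


@dataclass
class ZoneBGeometry:
    """Zone B measurement annulus around the optic disc (px units)."""

    od_center: tuple[float, float]
    od_diameter: float
    inner_od: float = 0.5
    outer_od: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.inner_od < self.outer_od):
            raise ValueError("zone B radii must satisfy 0 < inner < outer")
        if self.od_diameter <= 0:
            raise ValueError("optic-disc diameter must be positive")

    @property
    def inner_radius(self) -> float:
        return self.inner_od * self.od_diameter

    @property
    def outer_radius(self) -> float:
        return self.outer_od * self.od_diameter


def select_big_six(widths) -> np.ndarray:
    """The six largest widths; ties broken by input order (first wins).

    Fewer than six measurable vessels makes the eye unmeasurable (one of
    the documented image-rejection reasons) and is a reported failure.
    """
    w = np.asarray(widths, dtype=float)
    if w.ndim != 1:
        raise ValueError("widths must be a flat list")
    if w.size < 6:
        raise ValueError(f"insufficient vessels: need >= 6 widths, got {w.size}")
    # stable sort descending: first occurrence wins on ties
    order = np.argsort(-w, kind="stable")[:6]
    return w[np.sort(order)]


def summarize_caliber(six_widths, branching_coefficient: float) -> float:
    """Single equivalent caliber from six widths by iterative pairing.

    Sort; combine widest with narrowest as ``k * sqrt(wb^2 + ws^2)``;
    repeat on the shrinking list (6 -> 3, then the odd list carries its
    median forward, -> 2 -> 1). Deterministic and order-invariant.
    """
    k = float(branching_coefficient)
    if k <= 0:
        raise ValueError("branching coefficient must be positive")
    w = np.asarray(six_widths, dtype=float)
    if w.size != 6:
        raise ValueError(f"expected exactly six widths, got {w.size}")
    if np.any(w <= 0):
        raise ValueError("widths must all be positive")
    current = np.sort(w)
    while current.size > 1:
        current = np.sort(current)
        n_pairs = current.size // 2
        combined = [k * float(np.hypot(current[-1 - i], current[i])) for i in range(n_pairs)]
        if current.size % 2:
            combined.append(float(current[n_pairs]))  # odd list: carry the median
        current = np.asarray(combined)
    return float(current[0])


def box_counting_fd(binary_map, box_sizes=None, params: RetinaParams | None = None):
    """Monofractal box-counting dimension of a binary 2D raster.

    Counts occupied boxes N(s) over a geometric ladder of box sizes s
    (default: powers of two from 2 up to min(shape) / 4) and returns
    ``(fd, r_squared)`` from the least-squares fit of log N(s) on log s.
    Requires at least 4 box sizes spanning at least 2 octaves.
    """
    img = np.asarray(binary_map).astype(bool)
    if img.ndim != 2:
        raise ValueError("expected a 2D raster")
    if not img.any():
        raise ValueError("empty map: fractal dimension undefined")
    if box_sizes is None:
        params = params or RetinaParams()
        s_max = min(img.shape) // params.fd_box_divisor
        box_sizes = []
        s = params.fd_min_box
        while s <= s_max:
            box_sizes.append(s)
            s *= 2
    box_sizes = sorted(int(s) for s in box_sizes)
    if len(box_sizes) < 4 or box_sizes[-1] < 4 * box_sizes[0]:
        raise ValueError("need >= 4 box sizes spanning >= 2 octaves")
    counts = []
    for s in box_sizes:
        ny = -(-img.shape[0] // s)
        nx = -(-img.shape[1] // s)
        padded = np.zeros((ny * s, nx * s), dtype=bool)
        padded[: img.shape[0], : img.shape[1]] = img
        blocks = padded.reshape(ny, s, nx, s).any(axis=(1, 3))
        counts.append(int(blocks.sum()))
    counts = np.asarray(counts, dtype=float)
    if np.all(counts == counts[0]):
        raise ValueError("degenerate box counts: all N(s) equal")
    logs = np.log(np.asarray(box_sizes, dtype=float))
    logn = np.log(counts)
    slope, intercept = np.polyfit(logs, logn, 1)
    pred = slope * logs + intercept
    ss_res = float(np.sum((logn - pred) ** 2))
    ss_tot = float(np.sum((logn - logn.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(-slope), r2


def measure_ring_widths(binary_map, geometry: ZoneBGeometry,
                        n_samples: int = 8192) -> np.ndarray:
    """Widths of vessels crossing the mid-Zone-B circle, from the raster.

    Samples the circle of radius (inner + outer)/2 at fine angular
    resolution; each contiguous foreground run is one vessel crossing and
    its arc length approximates the vessel width (exact in the limit for
    vessels radial to the disc). Returns the widths in px, one per run.
    """
    img = np.asarray(binary_map).astype(bool)
    r = 0.5 * (geometry.inner_radius + geometry.outer_radius)
    cx, cy = geometry.od_center
    if (cx - r) < 0 or (cy - r) < 0 or (cx + r) >= img.shape[1] or (cy + r) >= img.shape[0]:
        raise ValueError("Zone B ring falls outside the image bounds")
    theta = np.linspace(0, 2 * np.pi, n_samples, endpoint=False)
    xs = np.clip(np.round(cx + r * np.cos(theta)).astype(int), 0, img.shape[1] - 1)
    ys = np.clip(np.round(cy + r * np.sin(theta)).astype(int), 0, img.shape[0] - 1)
    on = img[ys, xs]
    if not on.any():
        return np.array([])
    # rotate so the scan starts off-vessel, keeping runs contiguous
    if on.all():
        return np.array([2 * np.pi * r])
    start = int(np.argmin(on))
    on = np.roll(on, -start)
    edges = np.flatnonzero(np.diff(on.astype(int)))
    starts = edges[::2] + 1
    ends = edges[1::2] + 1
    arc = 2 * np.pi * r / n_samples
    return (ends - starts) * arc


def compute_retinal_metrics(widths: RetinalWidths, artery_map=None, vein_map=None,
                            params: RetinaParams | None = None) -> RetinalMetrics:
    """CRAE, CRVE, AVR and (when maps are given) FDa/FDv for one eye.

    Any failed sub-measure marks the eye unmeasurable by propagating its
    error; AVR is CRAE / CRVE exactly.
    """
    params = params or RetinaParams()
    params.validate()
    crae = summarize_caliber(select_big_six(widths.arteriole_widths), params.k_arteriole)
    crve = summarize_caliber(select_big_six(widths.venule_widths), params.k_venule)
    avr = crae / crve
    fda = fdv = np.nan
    if artery_map is not None:
        if vein_map is not None and np.shape(artery_map) != np.shape(vein_map):
            raise ValueError("artery and vein maps must share a shape")
        fda = box_counting_fd(artery_map, params=params)[0]
    if vein_map is not None:
        fdv = box_counting_fd(vein_map, params=params)[0]
    return RetinalMetrics(widths.eye, crae, crve, avr, fda, fdv)
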