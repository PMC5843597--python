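"""Chamber and wall segmentation from contrast-enhanced CT.

Three stages mirror the wall-mapping procedures:

1. *Delineation* — declarative PV cut planes and a basal plane separate the
   pulmonary veins and the mitral annulus from the LA body; the isocentre
   (interior seed) is set automatically to the centroid of the
   above-threshold contrast-filled region.
2. *Inner boundary* — 6-connected region growing from the isocentre over
   voxels above the lumen threshold, optionally refined by snapping the
   surface to the position of maximal 3D Sobel gradient magnitude (off by
   default: on a thin wall the partial-volume effect displaces the
   composite gradient ridge outward into the wall, so ridge-snapping
   inflates the chamber at exactly the sites this tool measures).
3. *Outer boundary* — outward band dilation from the inner boundary with an
   Otsu threshold recomputed over the growing band's HU histogram, iterated
   to a fixed point of the wall-voxel set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import CTVolume

__all__ = [
    "Plane", "CutPlane", "DelineationConfig", "Delineation",
    "ChamberSegmentation", "WallSegmentation",
    "delineate", "segment_inner", "segment_outer",
    "otsu_threshold", "otsu_on_values", "sobel_gradient",
    "boundary_voxels", "rasterize_clip",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


class SegmentationError(RuntimeError):
    pass


def _unit(v) -> tuple[float, float, float]:
    a = np.asarray(v, dtype=float)
    n = np.linalg.norm(a)
    if n == 0:
        raise ValueError("plane normal must be nonzero")
    a = a / n
    return (float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class Plane:
    """Oriented plane in world mm; the positive (normal) side is clipped."""
    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self):
        object.__setattr__(self, "point", tuple(float(x) for x in self.point))
        object.__setattr__(self, "normal", _unit(self.normal))


@dataclass(frozen=True)
class CutPlane(Plane):
    """PV cut plane: clipping is restricted to a lateral ``radius`` (mm)
    around the axis through ``point`` along ``normal``, so only the vein
    stub is removed, not distant wall at the same azimuth.  ``lumen_radius``
    is the vein's inner radius: the part of the clipped region within it
    is the ostium opening and becomes a map hole."""
    name: str = ""
    radius: float | None = None
    lumen_radius: float | None = None

    def __init__(self, name, point, normal, radius=None, lumen_radius=None):
        super().__init__(point, normal)
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "radius", None if radius is None else float(radius))
        object.__setattr__(self, "lumen_radius",
                           None if lumen_radius is None else float(lumen_radius))


@dataclass
class DelineationConfig:
    pv_planes: list[CutPlane]
    basal_plane: Plane | None = None
    seed_point: tuple[int, int, int] | None = None

    def to_dict(self) -> dict:
        return {
            "pv_planes": [
                {"name": p.name, "point": list(p.point), "normal": list(p.normal),
                 "radius": p.radius, "lumen_radius": p.lumen_radius}
                for p in self.pv_planes],
            "basal_plane": None if self.basal_plane is None else {
                "point": list(self.basal_plane.point),
                "normal": list(self.basal_plane.normal)},
            "seed_point": None if self.seed_point is None else list(self.seed_point),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DelineationConfig":
        planes = [CutPlane(p.get("name", f"PV{i}"), p["point"], p["normal"],
                           p.get("radius"), p.get("lumen_radius"))
                  for i, p in enumerate(d["pv_planes"])]
        b = d.get("basal_plane")
        basal = None if b is None else Plane(b["point"], b["normal"])
        seed = d.get("seed_point")
        return cls(planes, basal, None if seed is None else tuple(int(x) for x in seed))


@dataclass
class Delineation:
    """Resolved delineation on a specific grid: the isocentre voxel and the
    boolean grid of clipped (PV-side / beyond-basal) voxels."""
    isocentre: tuple[int, int, int]
    config: DelineationConfig
    clipped: np.ndarray


@dataclass
class ChamberSegmentation:
    chamber_mask: np.ndarray
    inner_boundary: np.ndarray  # (N, 3) voxel indices, chamber-side surface
    lumen_threshold: float


@dataclass
class WallSegmentation:
    wall_mask: np.ndarray
    outer_boundary: np.ndarray  # (N, 3) voxel indices
    otsu_threshold: float
    n_iterations: int
    threshold_trace: list[float] = field(default_factory=list)


# --------------------------------------------------------------------------- #
# primitives
# --------------------------------------------------------------------------- #

def otsu_threshold(counts, centers) -> float:
    """Two-class Otsu on a histogram: the bin boundary maximizing the
    between-class variance, ties broken toward the lower threshold."""
    counts = np.asarray(counts, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if counts.ndim != 1 or counts.shape != centers.shape:
        raise ValueError("counts and centers must be 1D arrays of equal length")
    if np.count_nonzero(counts) < 2:
        raise ValueError("histogram needs >= 2 nonempty bins")
    total = counts.sum()
    mtot = float((counts * centers).sum())
    w0 = np.cumsum(counts)[:-1]
    m0 = np.cumsum(counts * centers)[:-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    var_b = np.full(w0.shape, -np.inf)
    mu0 = np.divide(m0, w0, out=np.zeros_like(m0), where=w0 > 0)
    mu1 = np.divide(mtot - m0, w1, out=np.zeros_like(m0), where=w1 > 0)
    var_b[valid] = (w0 * w1 * (mu0 - mu1) ** 2)[valid]
    t = int(np.argmax(var_b))  # first maximum -> lower boundary on ties
    return float(0.5 * (centers[t] + centers[t + 1]))


def otsu_on_values(values, bins: int = 256) -> float:
    values = np.asarray(values)
    counts, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return otsu_threshold(counts, centers)


def sobel_gradient(data: np.ndarray | CTVolume) -> np.ndarray:
    """3D Sobel gradient magnitude (separable 3x3x3 smoothing x derivative
    kernels per axis; borders by edge replication)."""
    if isinstance(data, CTVolume):
        data = data.data
    data = np.asarray(data, dtype=np.float32)
    g2 = np.zeros(data.shape, dtype=np.float32)
    for axis in range(3):
        g = ndimage.sobel(data, axis=axis, mode="nearest")
        g2 += g * g
    return np.sqrt(g2)


def boundary_voxels(mask: np.ndarray, outside: np.ndarray) -> np.ndarray:
    """(N, 3) indices of ``mask`` voxels with a 6-neighbour in ``outside``."""
    adj = ndimage.binary_dilation(outside, structure=_STRUCT6) & mask
    return np.argwhere(adj)


def _plane_side(shape, spacing, origin, plane: Plane,
                radius: float | None = None) -> np.ndarray:
    from .volume import voxel_centres
    xg, yg, zg = voxel_centres(shape, spacing, origin)
    n = np.asarray(plane.normal)
    p0 = np.asarray(plane.point)
    s = (xg - p0[0]) * n[0] + (yg - p0[1]) * n[1] + (zg - p0[2]) * n[2]
    side = s > 0
    if radius is None and isinstance(plane, CutPlane):
        radius = plane.radius
    if radius is not None:
        dx, dy, dz = xg - p0[0], yg - p0[1], zg - p0[2]
        lat2 = (dx * dx + dy * dy + dz * dz) - s * s
        side = side & (lat2 <= radius ** 2)
    return np.broadcast_to(side, shape).copy() if side.shape != shape else side


def ostium_mask(config: DelineationConfig, shape, spacing, origin) -> np.ndarray:
    """Voxels inside the vein-lumen openings (the ostia): within each cut
    plane's ``lumen_radius`` of its axis, from slightly behind the plane
    (the wall opening straddles a tilted surface) out along the vein.
    Contour voxels falling inside this region become map HOLE pixels — a
    purely geometric criterion, so surface noise cannot fragment it."""
    from .volume import voxel_centres
    out = np.zeros(shape, dtype=bool)
    xg, yg, zg = voxel_centres(shape, spacing, origin)
    for plane in config.pv_planes:
        r = plane.lumen_radius if plane.lumen_radius is not None else plane.radius
        if r is None:
            out |= _plane_side(shape, spacing, origin, plane)
            continue
        n = np.asarray(plane.normal)
        p0 = np.asarray(plane.point)
        dx, dy, dz = xg - p0[0], yg - p0[1], zg - p0[2]
        s = dx * n[0] + dy * n[1] + dz * n[2]
        lat2 = (dx * dx + dy * dy + dz * dz) - s * s
        out |= np.broadcast_to((lat2 <= r * r) & (s >= -2.0 * r), shape)
    return out


def rasterize_clip(config: DelineationConfig, shape, spacing, origin) -> np.ndarray:
    """Boolean grid of voxels excluded from all downstream stages: the PV
    side of each cut plane and everything beyond the basal plane."""
    lo = np.asarray(origin)
    hi = lo + np.asarray(shape) * np.asarray(spacing)
    clipped = np.zeros(shape, dtype=bool)
    planes = [*config.pv_planes] + (
        [config.basal_plane] if config.basal_plane is not None else [])
    for plane in planes:
        p = np.asarray(plane.point)
        if np.any(p < lo) or np.any(p > hi):
            name = getattr(plane, "name", "basal")
            raise SegmentationError(f"cut plane '{name}' misses the volume")
        clipped |= np.broadcast_to(_plane_side(shape, spacing, origin, plane), shape)
    return clipped


# --------------------------------------------------------------------------- #
# procedures
# --------------------------------------------------------------------------- #

def delineate(volume: CTVolume, config: DelineationConfig) -> Delineation:
    """Procedure 1: resolve cut planes on the grid and set the isocentre to
    the centroid of the unclipped above-threshold (contrast-filled) region,
    the threshold being a two-class Otsu over the full volume."""
    clipped = rasterize_clip(config, volume.shape, volume.spacing, volume.origin)
    thr = otsu_on_values(volume.data)
    bright = (volume.data >= thr) & ~clipped
    if config.seed_point is not None:
        iso = tuple(int(i) for i in config.seed_point)
    else:
        if not bright.any():
            raise SegmentationError("no contrast-filled region above Otsu threshold")
        iso = tuple(int(round(c)) for c in
                    np.array(np.nonzero(bright)).mean(axis=1))
    if not all(0 <= iso[a] < volume.shape[a] for a in range(3)):
        raise SegmentationError("isocentre outside the volume")
    if volume.data[iso] < thr or clipped[iso]:
        raise SegmentationError("isocentre not in contrast-filled chamber")
    return Delineation(isocentre=iso, config=config, clipped=clipped)


def _shift(a: np.ndarray, axis: int, step: int, fill):
    out = np.full_like(a, fill)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if step > 0:
        dst[axis], src[axis] = slice(step, None), slice(None, -step)
    else:
        dst[axis], src[axis] = slice(None, step), slice(-step, None)
    out[tuple(dst)] = a[tuple(src)]
    return out


def _sobel_snap(data, mask, clipped, grad=None):
    """Snap the surface of ``mask`` onto the Sobel gradient ridge.

    Each boundary voxel makes one decision along its dominant outward
    6-neighbour direction (the one whose outward neighbour has the highest
    gradient magnitude): among {inward, current, outward} positions the
    maximal gradient wins, with ties keeping the current boundary — so an
    ideal two-level step image is left untouched, while a blurred edge
    settles on the voxel nearest the true interface.
    """
    g = sobel_gradient(data) if grad is None else grad
    neg = np.float32(-np.inf)
    best_out = np.full(mask.shape, neg, dtype=np.float32)
    best_in = np.full(mask.shape, neg, dtype=np.float32)
    best_dir = np.full(mask.shape, -1, dtype=np.int8)
    any_bnd = np.zeros_like(mask)
    for k, (axis, step) in enumerate([(a, s) for a in range(3) for s in (1, -1)]):
        # value at b+d is _shift(x, -step)[b]
        nb_mask = _shift(mask, axis, -step, False)
        bnd = mask & ~nb_mask
        if not bnd.any():
            continue
        any_bnd |= bnd
        g_out = _shift(g, axis, -step, neg)
        better = bnd & (g_out > best_out)
        best_out[better] = g_out[better]
        best_dir[better] = k
        g_in = _shift(g, axis, step, neg)
        best_in[better] = g_in[better]
    out_wins = any_bnd & (best_out > g) & (best_out > best_in)
    in_wins = any_bnd & ~out_wins & (best_in > g) & (best_in >= best_out)
    add = np.zeros_like(mask)
    for k, (axis, step) in enumerate([(a, s) for a in range(3) for s in (1, -1)]):
        sel = out_wins & (best_dir == k)
        if sel.any():
            add |= _shift(sel, axis, step, False)
    add &= ~mask & ~clipped
    return (mask & ~in_wins) | add


def segment_inner(volume: CTVolume, delin: Delineation,
                  lumen_threshold: float | None = None,
                  sobel_refine: bool = False) -> ChamberSegmentation:
    """Procedure 2: 6-connected region growing from the isocentre over
    unclipped voxels with HU >= the lumen threshold (default: the upper
    threshold of a three-class Otsu split of the full volume), then Sobel
    gradient refinement of the surface."""
    from skimage.filters import threshold_multiotsu

    data = volume.data
    if lumen_threshold is None:
        try:
            lumen_threshold = float(threshold_multiotsu(data, classes=3)[1])
        except ValueError:
            # fewer than three distinct grey levels (ideal two-level image)
            lumen_threshold = otsu_on_values(data)
    grow = (data >= lumen_threshold) & ~delin.clipped
    labels, _ = ndimage.label(grow, structure=_STRUCT6)
    seed_label = labels[tuple(delin.isocentre)]
    if seed_label == 0:
        raise SegmentationError("empty growth: isocentre below lumen threshold")
    mask = labels == seed_label
    if _touches_border(mask):
        raise SegmentationError("chamber leak: grown region touches the volume "
                                "border (lumen threshold too low)")
    if sobel_refine:
        mask = _sobel_snap(data, mask, delin.clipped)
        labels, _ = ndimage.label(mask, structure=_STRUCT6)
        mask = labels == labels[tuple(delin.isocentre)]
    inner = boundary_voxels(mask, ~mask)
    return ChamberSegmentation(chamber_mask=mask, inner_boundary=inner,
                               lumen_threshold=float(lumen_threshold))


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any()
                or mask[:, -1].any() or mask[:, :, 0].any() or mask[:, :, -1].any())


def segment_outer(volume: CTVolume, chamber: ChamberSegmentation,
                  delin: Delineation, r_max: float = 10.0,
                  max_iterations: int = 200, bins: int = 128) -> WallSegmentation:
    """Procedure 3: iterative outward band growth from the inner boundary.

    At iteration *k* the candidate band is every unclipped non-chamber voxel
    within *k* 6-connected dilations of the inner boundary and within
    ``r_max`` mm; a two-class Otsu threshold over the band's HU histogram
    separates wall from surrounding tissue, and the wall is the
    above-threshold part of the band 6-connected to the inner boundary.
    Iteration stops at a fixed point of the wall set ("convergence to the
    outer boundary") or when the band has swept ``r_max``.
    """
    data = volume.data
    shape = volume.shape
    inner_mask = np.zeros(shape, dtype=bool)
    inner_mask[tuple(chamber.inner_boundary.T)] = True
    cdt = ndimage.distance_transform_cdt(~inner_mask, metric="taxicab")
    edt = ndimage.distance_transform_edt(~inner_mask, sampling=volume.spacing)
    eligible = ~chamber.chamber_mask & ~delin.clipped & (edt <= r_max)
    near_inner = ndimage.binary_dilation(inner_mask, structure=_STRUCT6)

    min_sp = min(volume.spacing)
    wall = np.zeros(shape, dtype=bool)
    thr: float | None = None
    trace: list[float] = []
    converged = False
    k = 0
    while True:
        k += 1
        if k > max_iterations:
            raise SegmentationError(
                f"outer-boundary growth did not converge within {max_iterations} "
                f"iterations; threshold trace: {trace}")
        band = eligible & (cdt <= k)
        vals = data[band]
        if vals.size == 0:
            break
        lo, hi = float(vals.min()), float(vals.max())
        if hi > lo:
            thr = otsu_on_values(vals, bins=bins)
            cand = band & (data >= thr)
        else:
            thr = None  # single-valued band: keep everything, grow further
            cand = band
        trace.append(np.nan if thr is None else thr)
        labels, _ = ndimage.label(cand, structure=_STRUCT6)
        ids = np.unique(labels[near_inner & cand])
        ids = ids[ids > 0]
        new_wall = np.isin(labels, ids) if ids.size else np.zeros(shape, dtype=bool)
        if new_wall.any() and np.array_equal(new_wall, wall):
            wall = new_wall
            converged = True
            break
        wall = new_wall
        if k * min_sp > r_max:
            break
    if thr is None:
        raise SegmentationError("wall/background not separable: band histogram "
                                "is degenerate (single HU value)")
    outside = ~(wall | chamber.chamber_mask) & ~delin.clipped
    outer = boundary_voxels(wall, outside)
    if outer.size == 0:
        raise SegmentationError("empty outer boundary")
    return WallSegmentation(wall_mask=wall, outer_boundary=outer,
                            otsu_threshold=float(thr), n_iterations=k,
                            threshold_trace=trace)
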