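"""Geometric quantification of a mapped LA and gold-vs-measurement comparison.

Indices: chamber and wall volume (voxel integration), height (slice span of
the segmented chamber), central/basal circumference length (CCL/BCL: summed
arc weights of the mid-height and basal map rows), per-PV ostium area
(summed arc-weight x row-spacing over each map hole), and the thickness
summaries used clinically — arc-weighted mean and heterogeneity.

"Heterogeneity" is implemented as the arc-weighted standard deviation of
the map thickness; the definition is isolated here so alternative
dispersion summaries (IQR, coefficient of variation) can be substituted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import thickness as th
from .unwrap import EMPTY, WallMap

__all__ = ["GeometricIndices", "MapComparison", "HoleComponent",
           "compute_indices", "label_pv_holes", "compare_maps", "index_errors",
           "weighted_mean_thickness", "heterogeneity"]


@dataclass
class GeometricIndices:
    chamber_volume: float  # cm^3
    wall_volume: float     # cm^3
    height: float          # mm
    ccl: float             # mm
    bcl: float             # mm
    pv_areas: dict         # name -> mm^2
    mean_thickness: float  # mm
    heterogeneity: float   # mm

    def as_dict(self) -> dict:
        d = {"chamber_volume_cm3": self.chamber_volume,
             "wall_volume_cm3": self.wall_volume,
             "height_mm": self.height, "ccl_mm": self.ccl, "bcl_mm": self.bcl,
             "mean_thickness_mm": self.mean_thickness,
             "heterogeneity_mm": self.heterogeneity}
        for k, v in self.pv_areas.items():
            d[f"pv_area_{k}_mm2"] = v
        return d


@dataclass
class HoleComponent:
    name: str | None
    pixels: np.ndarray  # (N, 2) row/col
    area: float         # mm^2


@dataclass
class MapComparison:
    difference: np.ndarray                  # measurement - gold, NaN off support
    profile_pair: tuple[np.ndarray, np.ndarray]
    absolute_error: dict = field(default_factory=dict)
    relative_error: dict = field(default_factory=dict)


def weighted_mean_thickness(wmap: WallMap) -> float:
    m = wmap.filled_mask()
    w = wmap.arc_weights[m]
    return float(np.sum(w * wmap.grid[m]) / np.sum(w))


def heterogeneity(wmap: WallMap) -> float:
    """Arc-weighted standard deviation of map thickness (mm)."""
    m = wmap.filled_mask()
    w = wmap.arc_weights[m]
    t = wmap.grid[m]
    mu = np.sum(w * t) / np.sum(w)
    return float(np.sqrt(np.sum(w * (t - mu) ** 2) / np.sum(w)))


def _row_sum(wmap: WallMap, row: int) -> float:
    mapped = wmap.mapped_mask()[row]
    return float(np.sum(wmap.arc_weights[row][mapped]))


def label_pv_holes(wmap: WallMap, delin=None, merge_radius: int = 2,
                   min_area: float = 5.0) -> list[HoleComponent]:
    """Group the map's HOLE pixels into PV ostium components.

    With a delineation, each hole pixel is assigned to the PV whose cut
    plane is nearest to its 3D backref voxel — a geometric grouping that is
    robust to the row fragmentation surface noise induces and to ostia that
    nearly touch in map space.  Without one, components are 8-connected
    pixel groups with horizontal wraparound across the map seam (pixels
    within a Chebyshev distance of ``merge_radius`` are joined, and groups
    below ``min_area`` mm^2, far below any plausible ostium, are dropped as
    speckle).
    """
    holes = wmap.hole_mask()
    if not holes.any():
        raise ValueError("map contains no HOLE pixels")
    if delin is not None and getattr(delin.config, "pv_planes", None):
        return _holes_by_nearest_plane(wmap, holes, delin)
    n_rows, width = holes.shape
    # union-find over pixels; wraparound joins column 0 with column width-1
    coords = np.argwhere(holes)
    index = {tuple(c): i for i, c in enumerate(coords)}
    parent = list(range(len(coords)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    mr = max(1, int(merge_radius))
    for (r, c), i in index.items():
        for dr in range(-mr, mr + 1):
            for dc in range(-mr, mr + 1):
                if dr == 0 and dc == 0:
                    continue
                nb = (r + dr, (c + dc) % width)
                if nb in index:
                    union(i, index[nb])

    groups: dict[int, list[int]] = {}
    for i in range(len(coords)):
        groups.setdefault(find(i), []).append(i)

    comps = []
    for members in groups.values():
        px = coords[np.array(members)]
        area = float(np.sum(wmap.arc_weights[tuple(px.T)]) * wmap.row_spacing)
        comps.append(HoleComponent(name=None, pixels=px, area=area))
    comps = [c for c in comps if c.area >= min_area] or comps
    comps.sort(key=lambda h: -h.area)
    return comps


def _holes_by_nearest_plane(wmap: WallMap, holes: np.ndarray,
                            delin) -> list[HoleComponent]:
    from .volume import world_coords

    planes = list(delin.config.pv_planes)
    coords = np.argwhere(holes)
    vox = wmap.backref[tuple(coords.T)]
    world = world_coords(vox, wmap.spacing, wmap.origin)
    dists = np.stack([np.linalg.norm(world - np.asarray(p.point), axis=1)
                      for p in planes], axis=1)
    nearest = np.argmin(dists, axis=1)
    best = dists[np.arange(len(coords)), nearest]
    # a hole pixel far from every ostium centre is stray speckle
    bounds = np.array([2.0 * (p.lumen_radius or p.radius or np.inf) + 2.0
                       for p in planes])
    ok = best <= bounds[nearest]
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} hole pixels lie far from every "
                      "PV cut plane; ignored")
    comps = []
    for i, plane in enumerate(planes):
        px = coords[ok & (nearest == i)]
        if len(px) == 0:
            warnings.warn(f"no hole pixels assigned to {plane.name}")
            continue
        area = float(np.sum(wmap.arc_weights[tuple(px.T)]) * wmap.row_spacing)
        comps.append(HoleComponent(name=plane.name, pixels=px, area=area))
    comps.sort(key=lambda h: -h.area)
    return comps


def compute_indices(chamber, wall_seg, field_, wmap: WallMap, delin) -> GeometricIndices:
    """Assemble the geometric index panel from one pipeline run."""
    sp = wmap.spacing
    cham_vol = th.chamber_volume(chamber.chamber_mask, sp)
    wall_vol = th.wall_volume(wall_seg.wall_mask, sp, chamber_mask=chamber.chamber_mask)
    n_rows = wmap.grid.shape[0]
    height = (int(wmap.row_slices[-1]) - int(wmap.row_slices[0]) + 1) * wmap.row_spacing
    ccl = _row_sum(wmap, n_rows // 2)
    bcl = _row_sum(wmap, n_rows - 1)
    comps = label_pv_holes(wmap, delin)
    if len(comps) != 4 or any(c.name is None for c in comps):
        raise ValueError(
            f"PV areas need exactly 4 named hole components; found "
            f"{[(c.name, len(c.pixels)) for c in comps]}")
    pv_areas = {c.name: c.area for c in comps}
    return GeometricIndices(
        chamber_volume=cham_vol, wall_volume=wall_vol, height=height,
        ccl=ccl, bcl=bcl, pv_areas=pv_areas,
        mean_thickness=weighted_mean_thickness(wmap),
        heterogeneity=heterogeneity(wmap))


def index_errors(measurement: dict, gold: dict):
    """Absolute (measurement - gold) and relative (percent of gold) errors;
    positive means overestimation."""
    absolute, relative = {}, {}
    for k in gold:
        if k not in measurement:
            continue
        g, m = gold[k], measurement[k]
        if not (np.isscalar(g) and np.isscalar(m)):
            continue
        absolute[k] = m - g
        relative[k] = (m - g) / g * 100.0 if g != 0 else np.nan
    return absolute, relative


def _row_arc_positions(wmap: WallMap, row: int):
    """(columns, normalized arc position in [-0.5, 0.5) anchored at xc)."""
    mapped = wmap.mapped_mask()[row]
    cols = np.flatnonzero(mapped)
    w = wmap.arc_weights[row, cols]
    # pixel centres along the contour, measured from the left edge of the row
    centres = np.cumsum(w) - w / 2.0
    total = w.sum()
    ixc = int(np.searchsorted(cols, wmap.xc))
    anchor = centres[ixc] if ixc < len(cols) and cols[ixc] == wmap.xc else centres[0]
    pos = (centres - anchor) / total
    pos = (pos + 0.5) % 1.0 - 0.5
    return cols, pos


def compare_maps(measurement: WallMap, gold: WallMap,
                 indices_measurement: GeometricIndices | None = None,
                 indices_gold: GeometricIndices | None = None,
                 profile_row: int | None = None) -> MapComparison:
    """Per-pixel difference map (measurement - gold) on the gold map's grid,
    matching rows by CT slice index and columns by normalized arc length
    about the centre column (nearest-neighbour resampling); optional index
    error tables with the overestimation-positive sign convention."""
    gz = {int(z): r for r, z in enumerate(gold.row_slices)}
    mz = {int(z): r for r, z in enumerate(measurement.row_slices)}
    common = sorted(set(gz) & set(mz))
    if not common:
        raise ValueError("maps have no common slices")

    diff = np.full(gold.grid.shape, np.nan)
    for z in common:
        rg, rm = gz[z], mz[z]
        gcols, gpos = _row_arc_positions(gold, rg)
        mcols, mpos = _row_arc_positions(measurement, rm)
        morder = np.argsort(mpos)
        mpos_s, mcols_s = mpos[morder], mcols[morder]
        nearest = np.searchsorted(mpos_s, gpos)
        nearest = np.clip(nearest, 0, len(mpos_s) - 1)
        prev = np.clip(nearest - 1, 0, len(mpos_s) - 1)
        use_prev = np.abs(gpos - mpos_s[prev]) < np.abs(mpos_s[nearest] - gpos)
        pick = np.where(use_prev, prev, nearest)
        gv = gold.grid[rg, gcols]
        mv = measurement.grid[rm, mcols_s[pick]]
        ok = (gv > EMPTY + 0.5) & (mv > EMPTY + 0.5)
        diff[rg, gcols[ok]] = mv[ok] - gv[ok]

    if np.all(np.isnan(diff)):
        raise ValueError("maps have disjoint supports")

    if profile_row is None:
        profile_row = gold.grid.shape[0] // 2
    zrow = int(gold.row_slices[profile_row])
    if zrow in mz:
        rg, rm = gz[zrow], mz[zrow]
        gcols, gpos = _row_arc_positions(gold, rg)
        gprof = gold.grid[rg, gcols]
        mprof = gprof + diff[rg, gcols]
    else:
        gprof = np.array([])
        mprof = np.array([])

    absolute, relative = {}, {}
    if indices_measurement is not None and indices_gold is not None:
        absolute, relative = index_errors(indices_measurement.as_dict(),
                                          indices_gold.as_dict())
    return MapComparison(difference=diff, profile_pair=(gprof, mprof),
                        absolute_error=absolute, relative_error=relative)
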