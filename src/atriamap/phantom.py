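"""Digital left-atrium phantoms and simulated CT acquisition.

The phantom is a dome-shaped surface of revolution (the LA body) with four
cylindrical pulmonary-vein (PV) tubes, rasterised to a truth-labelled voxel
grid.  The mid-wall surface is described by a radial profile R(zeta) (zeta
is normalized height, 0 at the roof, 1 at the base) and the wall is the set
of points within half the local design thickness of that surface, measured
along the surface normal — so transmural thickness equals the design
profile by construction.  The base (mitral annulus) is an open disc.

A paired simulated CT volume is produced by an HU lookup (contrast-filled
lumen bright, wall soft-tissue, background dark), an isotropic Gaussian
point-spread function modelling the partial-volume effect, and additive
Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume import CTVolume, voxel_centres

__all__ = [
    "LABEL_BACKGROUND", "LABEL_LUMEN", "LABEL_WALL", "LABEL_PV_LUMEN", "LABEL_PV_WALL",
    "RadialProfile", "WallProfile", "PVSpec", "PhantomSpec", "TruthLabels", "CTParams",
    "voxelize_phantom", "simulate_ct", "gold_standard_map",
    "homogeneous_spec", "gradient_spec", "auto_delineation",
]

LABEL_BACKGROUND = 0
LABEL_LUMEN = 1
LABEL_WALL = 2
LABEL_PV_LUMEN = 3
LABEL_PV_WALL = 4

PV_NAMES = ("RSPV", "RIPV", "LSPV", "LIPV")


# --------------------------------------------------------------------------- #
# geometry descriptors
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class RadialProfile:
    """Mid-wall radius of the LA body as a function of normalized height.

    A superellipse of revolution: ``(1-zeta)**e + (R/R_base)**e = 1`` with
    zeta in [0, 1] (0 = roof, 1 = base).  ``exponent=2`` is the default
    elliptical dome: radius 0 at the roof, the basal radius at the base.
    """

    exponent: float = 2.0

    def radius(self, zeta, r_base: float) -> np.ndarray:
        z = np.clip(np.asarray(zeta, dtype=float), 0.0, 1.0)
        e = self.exponent
        return r_base * (1.0 - (1.0 - z) ** e) ** (1.0 / e)

    def polyline(self, z_roof: float, z_base: float, r_base: float,
                 ds: float = 0.01):
        """(r, z) samples of the profile curve at ~uniform arc spacing ``ds``.

        Returns (points (N,2), zeta (N,)).  Parameterized by the superellipse
        angle so the apex region is sampled as densely as the flank.
        """
        n = max(2048, int(4.0 * (z_base - z_roof + r_base) / ds))
        phi = np.linspace(0.0, math.pi / 2.0, n)
        p = 2.0 / self.exponent
        r = r_base * np.sin(phi) ** p
        zeta = 1.0 - np.cos(phi) ** p
        z = z_roof + zeta * (z_base - z_roof)
        pts = np.column_stack([r, z])
        # resample to uniform chord length to bound the nearest-point error
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        tgt = np.arange(0.0, arc[-1] + ds, ds)
        ri = np.interp(tgt, arc, r)
        zi = np.interp(tgt, arc, z)
        zti = np.interp(tgt, arc, zeta)
        return np.column_stack([ri, zi]), zti


@dataclass(frozen=True)
class WallProfile:
    """Design wall thickness (mm) as a function of normalized height zeta.

    ``constant(t)`` or ``linear(t_roof, t_base)`` (linear interpolation from
    roof to base, the paper-style gradient configuration).
    """

    t_roof: float
    t_base: float

    @classmethod
    def constant(cls, t: float) -> "WallProfile":
        return cls(t, t)

    @classmethod
    def linear(cls, t_roof: float, t_base: float) -> "WallProfile":
        return cls(t_roof, t_base)

    def thickness(self, zeta) -> np.ndarray:
        z = np.clip(np.asarray(zeta, dtype=float), 0.0, 1.0)
        return self.t_roof + (self.t_base - self.t_roof) * z

    @property
    def minimum(self) -> float:
        return min(self.t_roof, self.t_base)

    @property
    def maximum(self) -> float:
        return max(self.t_roof, self.t_base)


@dataclass(frozen=True)
class PVSpec:
    """One pulmonary-vein tube: a straight horizontal cylinder attached to
    the LA body at a given azimuth and normalized height above the base."""

    name: str
    azimuth_deg: float
    attach_height: float  # normalized height above the base (0 = base, 1 = roof)
    inner_diameter: float = 8.0
    length: float = 10.0
    wall_thickness: float = 1.0


def _default_pvs() -> tuple[PVSpec, ...]:
    # two right / two left superior-inferior pairs; superior veins higher
    return (
        PVSpec("RSPV", azimuth_deg=45.0, attach_height=0.75),
        PVSpec("RIPV", azimuth_deg=315.0, attach_height=0.55),
        PVSpec("LSPV", azimuth_deg=135.0, attach_height=0.75),
        PVSpec("LIPV", azimuth_deg=225.0, attach_height=0.55),
    )


@dataclass(frozen=True)
class PhantomSpec:
    height: float = 30.0
    basal_diameter: float = 30.0
    radial_profile: RadialProfile = field(default_factory=RadialProfile)
    wall_profile: WallProfile = field(default_factory=lambda: WallProfile.constant(1.0))
    pv_specs: tuple[PVSpec, ...] = field(default_factory=_default_pvs)
    spacing: tuple[float, float, float] = (0.25, 0.25, 0.25)
    margin: float = 1.5  # background padding around the body, mm

    def __post_init__(self):
        from .volume import _as_triplet
        object.__setattr__(self, "spacing", _as_triplet(self.spacing))
        self.validate()

    def validate(self) -> None:
        if self.height <= 0:
            raise ValueError("height must be > 0")
        if self.basal_diameter <= 0:
            raise ValueError("basal_diameter must be > 0")
        thicknesses = [self.wall_profile.minimum, self.wall_profile.maximum] + [
            pv.wall_thickness for pv in self.pv_specs]
        if not all(0.2 <= t <= 5.0 for t in thicknesses):
            raise ValueError("wall thicknesses must lie in [0.2, 5.0] mm")
        if len(self.pv_specs) != 4:
            raise ValueError("exactly 4 PV tubes are required")
        names = [pv.name for pv in self.pv_specs]
        if len(set(names)) != 4:
            raise ValueError("PV names must be distinct")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be > 0 on all axes")
        if max(self.spacing) > self.wall_profile.minimum / 2.0 + 1e-12:
            raise ValueError(
                f"spacing {max(self.spacing):g} mm too coarse: must be <= min wall "
                f"thickness / 2 = {self.wall_profile.minimum / 2.0:g} mm so the wall "
                "is at least two voxels thick")

    # derived geometry ------------------------------------------------------ #
    @property
    def r_base(self) -> float:
        return self.basal_diameter / 2.0

    @property
    def z_roof_mid(self) -> float:
        """z of the mid-surface apex: the roof wall cap reaches up to z = 0,
        so the outer envelope spans exactly [0, height]."""
        return self.wall_profile.t_roof / 2.0

    def z_of_zeta(self, zeta):
        return self.z_roof_mid + np.asarray(zeta, float) * (self.height - self.z_roof_mid)

    def zeta_of_z(self, z):
        return (np.asarray(z, float) - self.z_roof_mid) / (self.height - self.z_roof_mid)

    def radius(self, zeta) -> np.ndarray:
        return self.radial_profile.radius(zeta, self.r_base)

    def pv_frame(self, pv: PVSpec):
        """(attach point A, unit axis u) of a PV tube in world mm."""
        zeta = 1.0 - pv.attach_height
        theta = math.radians(pv.azimuth_deg)
        u = np.array([math.cos(theta), math.sin(theta), 0.0])
        r_a = float(self.radius(zeta))
        a = np.array([r_a * u[0], r_a * u[1], float(self.z_of_zeta(zeta))])
        return a, u

    def grid_geometry(self):
        """(shape, origin) of the rasterisation grid covering body + PV stubs."""
        half_t = self.wall_profile.maximum / 2.0
        half_xy = self.r_base + half_t
        for pv in self.pv_specs:
            a, _ = self.pv_frame(pv)
            reach = math.hypot(a[0], a[1]) + pv.length + pv.inner_diameter / 2.0 + pv.wall_thickness
            half_xy = max(half_xy, reach)
        half_xy += self.margin
        z_lo = -self.margin
        z_hi = self.height + self.margin
        sx, sy, sz = self.spacing
        nx = int(math.ceil(2 * half_xy / sx))
        ny = int(math.ceil(2 * half_xy / sy))
        nz = int(math.ceil((z_hi - z_lo) / sz))
        origin = (-nx * sx / 2.0, -ny * sy / 2.0, z_lo)
        return (nx, ny, nz), origin


@dataclass
class TruthLabels:
    """Ground-truth label grid for a phantom: 0 background, 1 chamber lumen,
    2 LA wall, 3 PV lumen, 4 PV wall."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    @property
    def shape(self):
        return self.labels.shape


@dataclass(frozen=True)
class CTParams:
    """Simulated-acquisition parameters.

    ``psf_fwhm`` is the isotropic Gaussian point-spread function width that
    generates the partial-volume effect; ``noise_sigma`` the additive HU
    noise.  HU defaults model a contrast-filled chamber against soft tissue.
    """

    hu_lumen: float = 350.0
    hu_wall: float = 50.0
    hu_background: float = -50.0
    psf_fwhm: float = 0.8
    noise_sigma: float = 15.0
    rng_seed: int = 0

    def __post_init__(self):
        if not (self.hu_lumen > self.hu_wall > self.hu_background):
            raise ValueError("require hu_lumen > hu_wall > hu_background")
        if self.psf_fwhm < 0 or self.noise_sigma < 0:
            raise ValueError("psf_fwhm and noise_sigma must be >= 0")


# --------------------------------------------------------------------------- #
# signed distance to the mid-wall surface
# --------------------------------------------------------------------------- #

class _MidSurface:
    """Nearest-point queries against the (r, z) profile curve of the body."""

    def __init__(self, spec: PhantomSpec, ds: float | None = None):
        self.spec = spec
        if ds is None:
            ds = min(spec.spacing) / 20.0
        pts, zeta = spec.radial_profile.polyline(spec.z_roof_mid, spec.height,
                                                 spec.r_base, ds=ds)
        self._tree = cKDTree(pts)
        self._zeta = zeta

    def signed_distance(self, r, z):
        """(signed distance to mid surface, zeta of nearest point).

        Negative inside (lumen side), positive outside.  Large batches are
        answered from a fine (r, z) lookup grid (the geometry is a surface
        of revolution, so the field is two-dimensional); the bilinear
        interpolation error is far below the voxel spacing.
        """
        r = np.asarray(r, dtype=float)
        z = np.asarray(z, dtype=float)
        if r.size > 500_000:
            d, zeta_near = self._query_gridded(r.ravel(), z.ravel())
        else:
            d, idx = self._tree.query(
                np.column_stack([r.ravel(), z.ravel()]), workers=-1)
            zeta_near = self._zeta[idx]
        h = self.spec.height
        z0 = self.spec.z_roof_mid
        zloc = np.clip(self.spec.zeta_of_z(z.ravel()), 0.0, 1.0)
        inside = (z.ravel() > z0) & (z.ravel() < h) & (
            r.ravel() < self.spec.radius(zloc))
        s = np.where(inside, -d, d)
        return s.reshape(r.shape), zeta_near.reshape(r.shape)

    def _query_gridded(self, r, z, step: float = 0.05):
        r_ax = np.arange(0.0, r.max() + 2 * step, step)
        z_ax = np.arange(z.min() - step, z.max() + 2 * step, step)
        rg, zg = np.meshgrid(r_ax, z_ax, indexing="ij")
        d, idx = self._tree.query(
            np.column_stack([rg.ravel(), zg.ravel()]), workers=-1)
        dg = d.reshape(rg.shape)
        zg_near = self._zeta[idx].reshape(rg.shape)
        ri = np.clip(r / step, 0, len(r_ax) - 1)
        zi = np.clip((z - z_ax[0]) / step, 0, len(z_ax) - 1)
        coords = np.vstack([ri, zi])
        d_out = ndimage.map_coordinates(dg, coords, order=1)
        zeta_out = ndimage.map_coordinates(zg_near, coords, order=1)
        return d_out, np.clip(zeta_out, 0.0, 1.0)


# --------------------------------------------------------------------------- #
# operations
# --------------------------------------------------------------------------- #

def voxelize_phantom(spec: PhantomSpec) -> TruthLabels:
    """Rasterise a phantom to truth labels by testing each voxel centre
    against the analytic surfaces (no anti-aliasing; the partial-volume
    effect enters only through :func:`simulate_ct`)."""
    spec.validate()
    shape, origin = spec.grid_geometry()
    xg, yg, zg = voxel_centres(shape, spec.spacing, origin)
    x = np.broadcast_to(xg, shape).ravel()
    y = np.broadcast_to(yg, shape).ravel()
    z = np.broadcast_to(zg, shape).ravel()

    surf = _MidSurface(spec)
    r = np.hypot(x, y)
    s, zeta = surf.signed_distance(r, z)
    t_half = spec.wall_profile.thickness(zeta) / 2.0

    below_base = z >= spec.height  # open basal disc: nothing below the annulus
    labels = np.zeros(x.shape, dtype=np.uint8)
    labels[(s < -t_half) & ~below_base] = LABEL_LUMEN
    labels[(np.abs(s) <= t_half) & ~below_base] = LABEL_WALL

    for pv in spec.pv_specs:
        a, u = spec.pv_frame(pv)
        t_attach = float(spec.wall_profile.thickness(1.0 - pv.attach_height))
        s_in = t_attach + 2.0  # inward extension so the tube meets the lumen
        px, py, pz = x - a[0], y - a[1], z - a[2]
        axial = px * u[0] + py * u[1] + pz * u[2]
        rho2 = px * px + py * py + pz * pz - axial * axial
        ri = pv.inner_diameter / 2.0
        ro = ri + pv.wall_thickness
        in_reach = (axial >= -s_in) & (axial <= pv.length)
        lum = in_reach & (rho2 < ri * ri)
        labels[lum & (labels != LABEL_LUMEN)] = LABEL_PV_LUMEN
        wal = in_reach & (rho2 >= ri * ri) & (rho2 < ro * ro)
        labels[wal & (labels == LABEL_BACKGROUND)] = LABEL_PV_WALL

    return TruthLabels(labels.reshape(shape), spec.spacing, origin)


def simulate_ct(truth: TruthLabels, params: CTParams) -> CTVolume:
    """HU lookup -> Gaussian PSF blur -> additive noise (seeded).

    With ``psf_fwhm=0`` and ``noise_sigma=0`` the output is exactly the
    label-to-HU lookup.
    """
    lut = np.array([params.hu_background, params.hu_lumen, params.hu_wall,
                    params.hu_lumen, params.hu_wall], dtype=np.float32)
    hu = lut[truth.labels]
    if params.psf_fwhm > 0:
        sigma_mm = params.psf_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        sigma_vox = [sigma_mm / s for s in truth.spacing]
        hu = ndimage.gaussian_filter(hu, sigma=sigma_vox, mode="nearest")
    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.rng_seed)
        hu = hu + rng.normal(0.0, params.noise_sigma, size=hu.shape).astype(np.float32)
    return CTVolume(hu.astype(np.float32), truth.spacing, truth.origin,
                    meta={"source": "simulate_ct", "rng_seed": params.rng_seed})


def auto_delineation(spec: PhantomSpec):
    """Derive the delineation config (PV cut planes + basal plane) from the
    phantom geometry, replacing the manual step used on clinical scans.

    Each PV cut plane sits where the tube axis pierces the *inner* wall
    surface (found by bisection on the signed mid-surface distance), with
    the normal along the tube axis and a lateral clip radius covering the
    tube cross-section, so the clipped region is exactly the vein stub.
    """
    from .segmentation import CutPlane, DelineationConfig, Plane

    surf = _MidSurface(spec)
    planes = []
    for pv in spec.pv_specs:
        a, u = spec.pv_frame(pv)
        t_attach = float(spec.wall_profile.thickness(1.0 - pv.attach_height))

        def f(step):
            p = a - step * u
            s, zeta = surf.signed_distance(np.hypot(p[0], p[1]), p[2])
            return float(s) + float(spec.wall_profile.thickness(zeta)) / 2.0

        lo, hi = 0.0, 2.0 * t_attach + 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if f(mid) > 0:
                lo = mid
            else:
                hi = mid
        point = a - 0.5 * (lo + hi) * u
        radius = pv.inner_diameter / 2.0 + pv.wall_thickness + 1.0
        planes.append(CutPlane(pv.name, tuple(point), tuple(u), radius,
                               lumen_radius=pv.inner_diameter / 2.0))
    basal = Plane((0.0, 0.0, spec.height), (0.0, 0.0, 1.0))
    return DelineationConfig(pv_planes=planes, basal_plane=basal)


def gold_standard_map(truth: TruthLabels, spec: PhantomSpec):
    """Expand the truth-labelled phantom directly onto the 2D wall map,
    bypassing HU segmentation: the result is the gold-standard map the
    measurement pipeline is judged against."""
    from . import segmentation as seg
    from . import thickness as th
    from . import unwrap

    config = auto_delineation(spec)
    clipped = seg.rasterize_clip(config, truth.shape, truth.spacing, truth.origin)
    clipped |= (truth.labels == LABEL_PV_LUMEN) | (truth.labels == LABEL_PV_WALL)

    chamber_mask = (truth.labels == LABEL_LUMEN) & ~clipped
    wall_mask = (truth.labels == LABEL_WALL) & ~clipped
    inner = seg.boundary_voxels(chamber_mask, ~chamber_mask)
    outside = ~(chamber_mask | wall_mask) & ~clipped
    outer = seg.boundary_voxels(wall_mask, outside)
    if inner.size == 0 or outer.size == 0:
        raise ValueError("degenerate truth labels: empty boundary")

    field_ = th.compute_thickness(inner, outer, truth.shape, truth.spacing)
    iso = np.rint(np.array(np.nonzero(chamber_mask)).mean(axis=1)).astype(int)
    delin = seg.Delineation(isocentre=tuple(iso), config=config, clipped=clipped)
    chamber = seg.ChamberSegmentation(chamber_mask=chamber_mask, inner_boundary=inner,
                                      lumen_threshold=float("nan"))
    ostium_open = seg.ostium_mask(config, truth.shape, truth.spacing,
                                  truth.origin)
    return unwrap.build_wall_map(chamber, field_, delin, truth.spacing,
                                 hole_mask=ostium_open, origin=truth.origin)


# --------------------------------------------------------------------------- #
# canonical study phantoms
# --------------------------------------------------------------------------- #

def homogeneous_spec(thickness: float, spacing: float = 0.25, **kw) -> PhantomSpec:
    """Homogeneous-wall study phantom (1.0 mm and 2.0 mm configurations)."""
    return PhantomSpec(wall_profile=WallProfile.constant(thickness),
                       spacing=(spacing,) * 3, **kw)


def gradient_spec(t_roof: float = 0.5, t_base: float = 1.6,
                  spacing: float = 0.25, **kw) -> PhantomSpec:
    """Gradient-wall study phantom: thin at the roof, thickening to the base."""
    return PhantomSpec(wall_profile=WallProfile.linear(t_roof, t_base),
                       spacing=(spacing,) * 3, **kw)
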