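"""Readers and writers for the formats the pipeline touches.

Volumes and label grids go through NIfTI-1 (spacing in the header); DICOM
series are read-only input; thickness fields and wall maps are plain CSV
with JSON sidecars; delineations and phantom specs are YAML.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import (CTParams, PhantomSpec, PVSpec, RadialProfile, TruthLabels,
                      WallProfile)
from .segmentation import DelineationConfig
from .thickness import ThicknessField
from .unwrap import EMPTY, HOLE, WallMap
from .volume import CTVolume

__all__ = [
    "read_volume", "write_volume", "read_labels", "write_labels",
    "read_delineation", "write_delineation", "read_field", "write_field",
    "read_map", "write_map", "write_indices", "write_comparison",
    "render_map", "phantom_spec_from_dict", "phantom_spec_to_dict",
]


# --------------------------------------------------------------------------- #
# volumes
# --------------------------------------------------------------------------- #

def _affine(spacing, origin):
    a = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    a[:3, 3] = origin
    return a


def write_volume(path, volume: CTVolume) -> Path:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32),
                          _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return Path(path)


def write_labels(path, truth: TruthLabels) -> Path:
    img = nib.Nifti1Image(np.asarray(truth.labels, dtype=np.uint8),
                          _affine(truth.spacing, truth.origin))
    img.header.set_zooms(truth.spacing)
    nib.save(img, str(path))
    return Path(path)


def read_labels(path) -> TruthLabels:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return TruthLabels(np.asarray(img.dataobj, dtype=np.uint8), spacing, origin)


def read_volume(path) -> CTVolume:
    """Load a CT volume from a NIfTI file or a DICOM series directory.

    DICOM slices are rescaled to HU (slope/intercept), sorted by position
    along the stack normal, and assembled in the package's (x, y, z) axis
    order regardless of file order on disk.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    data = np.asarray(img.dataobj, dtype=np.float32)
    return CTVolume(data, spacing, origin, meta={"source": str(path)})


def _read_dicom_series(directory: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "pixel_array"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no readable DICOM slices in {directory}")
    mod = getattr(slices[0], "Modality", "CT")
    if mod != "CT":
        warnings.warn(f"modality {mod!r} is not CT; values may not be HU")

    orientations = {tuple(np.round(np.asarray(s.ImageOrientationPatient, float), 5))
                    for s in slices}
    if len(orientations) > 1:
        raise ValueError("mixed-orientation DICOM series")
    row_dir, col_dir = np.asarray(slices[0].ImageOrientationPatient,
                                  float).reshape(2, 3)
    normal = np.cross(row_dir, col_dir)
    pos = np.array([np.dot(np.asarray(s.ImagePositionPatient, float), normal)
                    for s in slices])
    order = np.argsort(pos)
    pos = pos[order]
    slices = [slices[i] for i in order]
    steps = np.diff(pos)
    if len(steps) and (steps.max() - steps.min()) > 1e-3:
        gaps = np.where(np.abs(steps - np.median(steps)) > 1e-3)[0]
        raise ValueError(f"missing or unevenly spaced slices after indices "
                         f"{gaps.tolist()}")
    dz = float(np.median(steps)) if len(steps) else 1.0

    arrs = []
    for s in slices:
        a = s.pixel_array.astype(np.float32)
        slope = float(getattr(s, "RescaleSlope", 1.0))
        inter = float(getattr(s, "RescaleIntercept", 0.0))
        arrs.append(a * slope + inter)
    # pixel_array is (rows, cols) = (y, x); internal order is (x, y, z)
    data = np.stack([a.T for a in arrs], axis=2)
    ps = [float(v) for v in slices[0].PixelSpacing]  # (row, col) = (y, x)
    spacing = (ps[1], ps[0], dz)
    origin = tuple(float(v) for v in slices[0].ImagePositionPatient)
    return CTVolume(data, spacing, origin,
                    meta={"source": str(directory), "n_slices": len(slices)})


# --------------------------------------------------------------------------- #
# delineation / phantom configs (YAML)
# --------------------------------------------------------------------------- #

def write_delineation(path, config: DelineationConfig) -> Path:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)
    return Path(path)


def read_delineation(path) -> DelineationConfig:
    with open(path) as fh:
        return DelineationConfig.from_dict(yaml.safe_load(fh))


def phantom_spec_to_dict(spec: PhantomSpec) -> dict:
    return {
        "height": spec.height,
        "basal_diameter": spec.basal_diameter,
        "radial_exponent": spec.radial_profile.exponent,
        "wall_profile": {"t_roof": spec.wall_profile.t_roof,
                         "t_base": spec.wall_profile.t_base},
        "pv_specs": [pv.__dict__.copy() for pv in spec.pv_specs],
        "spacing": list(spec.spacing),
        "margin": spec.margin,
    }


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    kw = {}
    if "height" in d:
        kw["height"] = float(d["height"])
    if "basal_diameter" in d:
        kw["basal_diameter"] = float(d["basal_diameter"])
    if "radial_exponent" in d:
        kw["radial_profile"] = RadialProfile(float(d["radial_exponent"]))
    if "wall_profile" in d:
        wp = d["wall_profile"]
        kw["wall_profile"] = WallProfile(float(wp["t_roof"]), float(wp["t_base"]))
    if "pv_specs" in d:
        kw["pv_specs"] = tuple(PVSpec(**pv) for pv in d["pv_specs"])
    if "spacing" in d:
        kw["spacing"] = d["spacing"]
    if "margin" in d:
        kw["margin"] = float(d["margin"])
    return PhantomSpec(**kw)


def ct_params_from_dict(d: dict) -> CTParams:
    return CTParams(**d)


# --------------------------------------------------------------------------- #
# thickness fields (CSV + JSON)
# --------------------------------------------------------------------------- #

def write_field(path, field: ThicknessField) -> Path:
    path = Path(path)
    df = pd.DataFrame({"x": field.coords[:, 0], "y": field.coords[:, 1],
                       "z": field.coords[:, 2], "thickness_mm": field.values})
    df.to_csv(path, index=False)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump({"spacing": list(field.spacing), "shape": list(field.shape)}, fh)
    return path


def read_field(path) -> ThicknessField:
    path = Path(path)
    df = pd.read_csv(path)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return ThicknessField(coords=df[["x", "y", "z"]].to_numpy(dtype=int),
                          values=df["thickness_mm"].to_numpy(dtype=float),
                          spacing=tuple(meta["spacing"]),
                          shape=tuple(meta["shape"]))


# --------------------------------------------------------------------------- #
# wall maps (CSV matrix + JSON sidecar)
# --------------------------------------------------------------------------- #

def write_map(prefix, wmap: WallMap) -> Path:
    """Write ``<prefix>.csv`` (thickness matrix, EMPTY=-1 / HOLE=-2),
    ``<prefix>_arc.csv``, ``<prefix>_backref.csv`` and ``<prefix>.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(str(prefix) + ".csv", wmap.grid, delimiter=",", fmt="%.6g")
    np.savetxt(str(prefix) + "_arc.csv", wmap.arc_weights, delimiter=",",
               fmt="%.6g")
    br = wmap.backref.reshape(-1, 3)
    np.savetxt(str(prefix) + "_backref.csv", br, delimiter=",", fmt="%d")
    with open(str(prefix) + ".json", "w") as fh:
        json.dump({"xc": wmap.xc,
                   "row_slices": [int(z) for z in wmap.row_slices],
                   "row_spacing": wmap.row_spacing,
                   "spacing": list(wmap.spacing),
                   "origin": list(wmap.origin),
                   "shape": list(wmap.grid.shape)}, fh)
    return prefix


def read_map(prefix) -> WallMap:
    prefix = Path(prefix)
    with open(str(prefix) + ".json") as fh:
        meta = json.load(fh)
    shape = tuple(meta["shape"])
    grid = np.loadtxt(str(prefix) + ".csv", delimiter=",").reshape(shape)
    arc = np.loadtxt(str(prefix) + "_arc.csv", delimiter=",").reshape(shape)
    backref = np.loadtxt(str(prefix) + "_backref.csv", delimiter=",",
                         dtype=int).reshape(shape + (3,))
    return WallMap(grid=grid, backref=backref, arc_weights=arc,
                   xc=int(meta["xc"]),
                   row_slices=np.asarray(meta["row_slices"], dtype=int),
                   row_spacing=float(meta["row_spacing"]),
                   spacing=tuple(meta["spacing"]),
                   origin=tuple(meta.get("origin", (0.0, 0.0, 0.0))))


# --------------------------------------------------------------------------- #
# results
# --------------------------------------------------------------------------- #

def write_masks(path, result) -> Path:
    """Segmentation label volume: 1 chamber, 2 wall, 3 clipped."""
    lab = np.zeros(result.volume.shape, dtype=np.uint8)
    lab[result.wall.wall_mask] = 2
    lab[result.chamber.chamber_mask] = 1
    lab[result.delineation.clipped] = 3
    img = nib.Nifti1Image(lab, _affine(result.volume.spacing, result.volume.origin))
    img.header.set_zooms(result.volume.spacing)
    nib.save(img, str(path))
    return Path(path)


def write_indices(path, indices) -> Path:
    d = indices.as_dict()
    pd.DataFrame([d]).to_csv(path, index=False)
    return Path(path)


def write_comparison(prefix, comparison) -> Path:
    prefix = Path(prefix)
    np.savetxt(str(prefix) + "_difference.csv", comparison.difference,
               delimiter=",", fmt="%.6g")
    gold, meas = comparison.profile_pair
    pd.DataFrame({"gold_mm": gold, "measurement_mm": meas}).to_csv(
        str(prefix) + "_profile.csv", index=False)
    with open(str(prefix) + "_errors.json", "w") as fh:
        json.dump({"absolute_error": comparison.absolute_error,
                   "relative_error_percent": comparison.relative_error},
                  fh, indent=2, sort_keys=True)
    return prefix


def render_map(path, wmap: WallMap, title: str = "LA wall thickness (mm)") -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = np.ma.masked_less(wmap.grid, EMPTY + 0.5)
    holes = np.isclose(wmap.grid, HOLE)
    fig, ax = plt.subplots(figsize=(10, 4))
    im = ax.imshow(shown, origin="upper", aspect="auto", cmap="turbo")
    hole_overlay = np.ma.masked_where(~holes, np.ones_like(wmap.grid))
    ax.imshow(hole_overlay, origin="upper", aspect="auto", cmap="gray_r",
              vmin=0, vmax=1)
    ax.set_xlabel("contour position (pixels, centre column = ostium-free seam)")
    ax.set_ylabel("slice (roof at top)")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="mm")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
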