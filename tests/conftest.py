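"""Shared fixtures: phantoms at two resolutions and a synthetic cylinder.

The fine (0.25 mm) phantoms match the study geometry and are session-scoped
because voxelization and gold-map expansion take tens of seconds; unit
tests use the coarse (0.5 mm) phantom wherever the property under test is
resolution-independent.
"""

from __future__ import annotations

import numpy as np
import pytest

import atriamap as am
from atriamap import phantom as ph
from atriamap import segmentation as seg
from atriamap import thickness as th
from atriamap import unwrap as uw


@pytest.fixture(scope="session")
def coarse_spec():
    return ph.homogeneous_spec(2.0, spacing=0.5)


@pytest.fixture(scope="session")
def coarse_truth(coarse_spec):
    return ph.voxelize_phantom(coarse_spec)


@pytest.fixture(scope="session")
def coarse_gold_map(coarse_truth, coarse_spec):
    return ph.gold_standard_map(coarse_truth, coarse_spec)


@pytest.fixture(scope="session")
def grad_spec_fine():
    return ph.gradient_spec(spacing=0.25)


@pytest.fixture(scope="session")
def grad_truth_fine(grad_spec_fine):
    return ph.voxelize_phantom(grad_spec_fine)


@pytest.fixture(scope="session")
def grad_gold_fine(grad_truth_fine, grad_spec_fine):
    return ph.gold_standard_map(grad_truth_fine, grad_spec_fine)


@pytest.fixture(scope="session")
def h2_spec_fine():
    return ph.homogeneous_spec(2.0, spacing=0.25)


@pytest.fixture(scope="session")
def h2_truth_fine(h2_spec_fine):
    return ph.voxelize_phantom(h2_spec_fine)


@pytest.fixture(scope="session")
def h2_gold_fine(h2_truth_fine, h2_spec_fine):
    return ph.gold_standard_map(h2_truth_fine, h2_spec_fine)


def make_cylinder_map(radius_mm=15.0, height_mm=20.0, spacing=0.5,
                      thickness_mm=1.0):
    """Wall map of a right circular cylinder shell: the closed-form unwrap
    fixture (rectangular map, row arc sums ~ 2*pi*r)."""
    sp = float(spacing)
    n_xy = int(2 * (radius_mm + 3) / sp)
    n_z = int(height_mm / sp)
    shape = (n_xy, n_xy, n_z)
    origin = (-n_xy * sp / 2, -n_xy * sp / 2, 0.0)
    xs = origin[0] + (np.arange(n_xy) + 0.5) * sp
    r2 = xs[:, None] ** 2 + xs[None, :] ** 2
    disc = r2 <= radius_mm ** 2
    chamber_mask = np.repeat(disc[:, :, None], n_z, axis=2)
    inner = seg.boundary_voxels(chamber_mask, ~chamber_mask)
    field = th.ThicknessField(coords=inner,
                              values=np.full(len(inner), thickness_mm),
                              spacing=(sp, sp, sp), shape=shape)
    iso = (n_xy // 2, n_xy // 2, n_z // 2)
    delin = seg.Delineation(isocentre=iso,
                            config=seg.DelineationConfig(pv_planes=[]),
                            clipped=np.zeros(shape, dtype=bool))
    chamber = seg.ChamberSegmentation(chamber_mask, inner, float("nan"))
    wmap = uw.build_wall_map(chamber, field, delin, (sp, sp, sp), origin=origin)
    return wmap, radius_mm, height_mm


@pytest.fixture(scope="session")
def cylinder_map():
    return make_cylinder_map()


def row_arc_mean(wmap, row):
    """Arc-weighted mean thickness of one map row (NaN when empty)."""
    m = wmap.filled_mask()[row]
    if not m.any():
        return float("nan")
    w = wmap.arc_weights[row][m]
    return float(np.sum(w * wmap.grid[row][m]) / np.sum(w))


def filled_rows(wmap):
    return [r for r in range(wmap.shape[0]) if wmap.filled_mask()[r].any()]
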