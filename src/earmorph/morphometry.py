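"""Cartilage morphometry: volume (Cg.V), surface (Cg.S) and thickness (Cg.Th).

The three metrics characterize a segmented cartilage mask as a physical
object: total volume in mm^3, closed surface area in mm^2, and the mean of a
model-independent per-voxel thickness map in mm.  Thickness at a point is the
diameter of the largest sphere that contains the point and fits entirely
inside the foreground (the maximal-inscribed-sphere definition standard for
sheet-like tissue); it is computed on an isotropic grid, so anisotropic masks
are resampled first (to ``min(spacing)/2`` by default) and the spacing used
is recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

from .volume_io import VoxelGrid, resample_isotropic

__all__ = [
    "MorphometryResult",
    "ThicknessMap",
    "cartilage_volume",
    "cartilage_surface",
    "thickness_map",
    "mean_thickness",
    "morphometry_all",
    "append_result_csv",
    "export_thickness_ply",
]

#: Gaussian pre-smoothing (in voxels) applied to the binary field before the
#: 0.5 isosurface is extracted.  One voxel of smoothing removes the staircase
#: faceting that otherwise inflates curved surface areas by ~9%.
SURFACE_SMOOTH_SIGMA_VOX = 1.0

RESULT_CSV_HEADER = "specimen_id,cg_v_mm3,cg_s_mm2,cg_th_mm,sx,sy,sz"


def _prepare_isotropic(grid: VoxelGrid, target: float | None) -> VoxelGrid:
    """Isotropic grid for morphometry.

    Already-isotropic input is used as-is.  Anisotropic input defaults to
    ``min(spacing) / 2``: linear interpolation of the indicator field carries
    sub-voxel boundary information, and measuring on the twice-finer grid
    halves the distance-transform discretisation bias of the thickness
    metric (mirrors contouring on upscaled slices followed by isotropic
    rescaling).
    """
    if target is None:
        if grid.is_isotropic():
            return grid
        target = min(grid.spacing) / 2.0
    return resample_isotropic(grid, target)


@dataclass(frozen=True)
class MorphometryResult:
    """One specimen's Cg.V (mm^3), Cg.S (mm^2) and Cg.Th (mm)."""

    specimen_id: str
    cg_v: float
    cg_s: float
    cg_th: float
    spacing_used: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.cg_v < 0 or self.cg_s < 0 or self.cg_th < 0:
            raise ValueError("morphometric values must be non-negative")


@dataclass
class ThicknessMap:
    """Per-voxel local thickness in mm over the foreground (background = 0)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    @property
    def foreground_values(self) -> np.ndarray:
        return self.values[self.mask]


def cartilage_volume(grid: VoxelGrid) -> float:
    """Cg.V: foreground voxel count times voxel volume, in mm^3."""
    return float(grid.data.sum()) * grid.voxel_volume


def cartilage_surface(grid: VoxelGrid) -> float:
    """Cg.S: area of the triangulated 0.5-isosurface of the mask, in mm^2.

    The binary field is padded and smoothed with a one-voxel Gaussian before
    marching cubes; anisotropic spacing is honoured by the mesh coordinates.
    Falls back to the raw binary field if smoothing erases the object
    (possible for single-voxel-thin structures).
    """
    if not grid.data.any():
        return 0.0
    f = np.pad(grid.data.astype(np.float64), 2)
    smooth = ndimage.gaussian_filter(f, SURFACE_SMOOTH_SIGMA_VOX)
    if smooth.max() <= 0.5:
        smooth = f
    verts, faces, _, _ = measure.marching_cubes(smooth, level=0.5, spacing=grid.spacing_zyx)
    return float(measure.mesh_surface_area(verts, faces))


def _local_thickness(
    mask: np.ndarray,
    h: float,
    max_levels: int | None = None,
    tail_fraction: float = 0.0,
) -> np.ndarray:
    """Maximal-inscribed-sphere thickness on an isotropic grid of pitch h.

    Sphere radii are taken as the Euclidean distance from candidate centres
    to the voxelized surface (EDT to background voxel centres minus h/2);
    candidate centres are the foreground voxel centres augmented with face
    midpoints, which recovers medial maxima that fall between voxel centres
    (a slab of thickness t then maps to t, a single voxel to h).  A covering
    pass over descending diameters assigns every foreground voxel the
    diameter of the largest sphere containing it, using one background-EDT
    per diameter level.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=np.float64)
    if not mask.any():
        return out
    d = ndimage.distance_transform_edt(mask, sampling=h)
    r = np.where(mask, d - h / 2.0, -1e6)  # finite background sentinel
    v = np.where(mask, 2.0 * r, 0.0)
    for ax in range(3):
        # the 1-Lipschitz radius field may peak between face-adjacent
        # samples where the medial surface crosses the segment; extrapolate
        # the one-sided slopes linearly and take their intersection
        # (slopes 1 from both sides -> (r1 + r2 + h) / 2; flat along the
        # axis -> max(r1, r2), so plateaus are not inflated)
        r2 = np.roll(r, -1, axis=ax)
        r0 = np.roll(r, 1, axis=ax)
        r3 = np.roll(r, -2, axis=ax)
        s1 = np.clip((r - r0) / h, 0.0, 1.0)
        s2 = np.clip((r2 - r3) / h, 0.0, 1.0)
        both = (s1 > 0) & (s2 > 0)
        denom = np.where(both, s1 + s2, 1.0)
        peak = np.where(both, (s2 * r + s1 * r2 + s1 * s2 * h) / denom, -1e6)
        mid = np.maximum(peak, np.maximum(r, r2))
        ok = mask & np.roll(mask, -1, axis=ax)
        cand = np.where(ok, 2.0 * mid, 0.0)
        v = np.maximum(v, cand)
        v = np.maximum(v, np.roll(cand, 1, axis=ax))
    fg_pos = mask & (v > 0)
    vals = np.unique(v[fg_pos])
    if max_levels is None:
        # diameter quantization to h/3 bins (at least 16 across the span):
        # the bin-midpoint rounding below is unbiased and its error is well
        # below the voxel-scale uncertainty of the metric itself
        span = float(vals[-1] - vals[0])
        max_levels = min(128, max(int(np.ceil(span / (h / 3.0))), 16))
    if len(vals) > max_levels:
        edges = np.linspace(vals[0], vals[-1], max_levels + 1)
        idx = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, max_levels - 1)
        mid_of_bin = (edges[:-1] + edges[1:]) / 2.0
        v = np.where(fg_pos, mid_of_bin[idx], v)
        vals = np.unique(v[fg_pos])
    unassigned = mask.copy()
    # optionally let the last ``tail_fraction`` of voxels (thin edge bands
    # needing many small-diameter levels) fall back to their own-sphere
    # lower bound; the induced mean error is bounded by
    # tail_fraction * level span.  Off by default (exact covering).
    tail = tail_fraction * int(mask.sum())
    for lev in vals[::-1]:
        if int(unassigned.sum()) <= tail:
            break
        covered_dist = ndimage.distance_transform_edt(v < lev, sampling=h)
        new = unassigned & (covered_dist <= lev / 2.0 + 1e-9)
        out[new] = lev
        unassigned &= ~new
    # leftovers: own-sphere diameter (exact for isolated voxels)
    out[unassigned] = np.maximum(v[unassigned], h)
    return out


def thickness_map(
    grid: VoxelGrid,
    max_levels: int | None = None,
    isotropic_target: float | None = None,
    tail_fraction: float = 0.0,
) -> ThicknessMap:
    """Model-independent per-voxel thickness map of a mask.

    Anisotropic input is resampled to an isotropic grid internally (sphere
    fitting assumes isotropy); see :func:`_prepare_isotropic` for the
    default target.

    Raises
    ------
    ValueError
        If the mask has no foreground.
    """
    if not grid.data.any():
        raise ValueError("no foreground: thickness map undefined for an empty mask")
    iso = _prepare_isotropic(grid, isotropic_target)
    h = iso.spacing[0]
    # crop to the foreground bounding box (plus 1) to keep the EDTs small
    obj = ndimage.find_objects(iso.data.astype(np.int8), max_label=1)[0]
    sl = tuple(
        slice(max(s.start - 1, 0), min(s.stop + 1, n))
        for s, n in zip(obj, iso.data.shape)
    )
    sub = iso.data[sl]
    th_sub = _local_thickness(sub, h, max_levels=max_levels, tail_fraction=tail_fraction)
    values = np.zeros(iso.data.shape, dtype=np.float64)
    values[sl] = th_sub
    return ThicknessMap(values=values, spacing=iso.spacing, mask=iso.data)


def mean_thickness(tmap: ThicknessMap) -> float:
    """Cg.Th: mean thickness over foreground voxels (volume-weighted on an
    isotropic grid), in mm."""
    vals = tmap.foreground_values
    if vals.size == 0:
        raise ValueError("empty thickness map")
    return float(vals.mean())


def morphometry_all(
    grid: VoxelGrid, specimen_id: str = "", isotropic_target: float | None = None
) -> MorphometryResult:
    """Compute Cg.V, Cg.S and Cg.Th on the isotropically-resampled mask."""
    if not grid.data.any():
        return MorphometryResult(specimen_id, 0.0, 0.0, 0.0, grid.spacing)
    iso = _prepare_isotropic(grid, isotropic_target)
    tmap = thickness_map(iso)
    return MorphometryResult(
        specimen_id=specimen_id,
        cg_v=cartilage_volume(iso),
        cg_s=cartilage_surface(iso),
        cg_th=mean_thickness(tmap),
        spacing_used=iso.spacing,
    )


def append_result_csv(result: MorphometryResult, path: str | Path) -> None:
    """Append one result row (units: mm^3, mm^2, mm) to a CSV file."""
    path = Path(path)
    new = not path.exists()
    with path.open("a") as fh:
        if new:
            fh.write(RESULT_CSV_HEADER + "\n")
        sx, sy, sz = result.spacing_used
        fh.write(
            f"{result.specimen_id},{result.cg_v:.6f},{result.cg_s:.6f},"
            f"{result.cg_th:.6f},{sx},{sy},{sz}\n"
        )


def export_thickness_ply(tmap: ThicknessMap, path: str | Path) -> Path:
    """Write the 0.5-isosurface as a PLY mesh with per-vertex thickness."""
    import trimesh

    grid = VoxelGrid(tmap.mask, tmap.spacing)
    f = np.pad(grid.data.astype(np.float64), 2)
    smooth = ndimage.gaussian_filter(f, SURFACE_SMOOTH_SIGMA_VOX)
    if smooth.max() <= 0.5:
        smooth = f
    verts, faces, _, _ = measure.marching_cubes(smooth, level=0.5, spacing=grid.spacing_zyx)
    # vertices are in padded physical coordinates; sample nearest foreground voxel
    idx = np.round(verts / np.array(grid.spacing_zyx) - 2).astype(int)
    idx = np.clip(idx, 0, np.array(tmap.values.shape) - 1)
    vth = tmap.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.vertex_attributes["thickness_mm"] = vth.astype(np.float32)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(str(path))
    return path
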