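"""Dose-grid containers and DVH / geometric QA metrics.

Grids are axis-aligned boxes of cubic-ish voxels: ``origin`` is the box
corner in cm, voxel centers sit at ``origin + (k + 0.5) * spacing``, and
voxel extents are half-open.  Structure masks live on the same lattice.

Metrics:

* cumulative DVH on voxel ranks (no binning loss) and the D_x% quantities
  read from it,
* homogeneity index HI = (D2% - D98%) / D_average over the chamber,
* conformity index COIN relating reference-isodose coverage of the
  chamber to coverage of a dilated shell around it,
* beam-chamber intersection tests and per-plan intersection fraction,
* beam-dose summation, combined per-beam statistical uncertainty, and
  the percent relative RMS difference between paired dose values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "DoseGrid",
    "StructureMask",
    "DVHCurve",
    "LatticeMismatchError",
    "cumulative_dvh",
    "dose_at_volume",
    "homogeneity_index",
    "expand_mask",
    "conformity_index",
    "beam_intersects_chamber",
    "intersection_fraction",
    "sum_beam_doses",
    "combined_uncertainty",
    "percent_rms_difference",
    "read_dose_raster",
    "write_dose_raster",
    "read_rtdose",
    "mask_from_rtstruct",
]


class LatticeMismatchError(ValueError):
    """Grids or masks do not share origin/spacing/dims."""


@dataclass
class DoseGrid:
    """3D voxelized dose in Gy with optional scalar Type-A uncertainty (%)."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    values: np.ndarray
    rel_uncertainty_pct: float | None = None

    def __post_init__(self) -> None:
        self.origin = tuple(float(x) for x in self.origin)
        self.spacing = tuple(float(x) for x in self.spacing)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("dose values must be a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("dose values must be finite and non-negative")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1D center coordinates per axis (cm)."""
        return tuple(
            self.origin[i] + (np.arange(self.dims[i]) + 0.5) * self.spacing[i]
            for i in range(3)
        )

    def same_lattice(self, other: "DoseGrid | StructureMask") -> bool:
        shape = other.values.shape if isinstance(other, DoseGrid) else other.voxels.shape
        return (
            shape == self.values.shape
            and np.allclose(other.origin, self.origin, atol=1e-9)
            and np.allclose(other.spacing, self.spacing, atol=1e-9)
        )


@dataclass
class StructureMask:
    """Boolean voxel mask (chamber contour, shell, ...) on a DoseGrid lattice."""

    name: str
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.origin = tuple(float(x) for x in self.origin)
        self.spacing = tuple(float(x) for x in self.spacing)
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask voxels must be a 3D array")

    @property
    def volume_cc(self) -> float:
        return float(self.voxels.sum()) * float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


def _check_lattice(grid: DoseGrid, mask: StructureMask) -> None:
    if not grid.same_lattice(mask):
        raise LatticeMismatchError(
            f"mask '{mask.name}' is not on the dose grid lattice"
        )


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH: fraction of structure volume receiving >= each dose."""

    dose_edges: np.ndarray          # Gy, ascending (unique voxel doses)
    cum_volume_fraction: np.ndarray  # non-increasing, starts at 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "dose_edges", np.asarray(self.dose_edges, dtype=float))
        object.__setattr__(
            self, "cum_volume_fraction", np.asarray(self.cum_volume_fraction, dtype=float)
        )


def cumulative_dvh(grid: DoseGrid, mask: StructureMask) -> DVHCurve:
    """Exact voxel-rank cumulative DVH of the masked dose values."""
    _check_lattice(grid, mask)
    doses = grid.values[mask.voxels]
    if doses.size == 0:
        raise ValueError(f"mask '{mask.name}' is empty")
    sorted_asc = np.sort(doses)
    edges = np.unique(sorted_asc)
    # fraction of voxels with dose >= edge
    frac = 1.0 - np.searchsorted(sorted_asc, edges, side="left") / doses.size
    return DVHCurve(dose_edges=edges, cum_volume_fraction=frac)


def dose_at_volume(dvh: DVHCurve, volume_pct: float) -> float:
    """D_x%: the highest dose received by at least *volume_pct* of the volume.

    Voxel-rank convention, no interpolation: the largest DVH edge whose
    coverage fraction is >= volume_pct / 100.  D100% is the minimum voxel
    dose; D2% / D98% are the near-maximum / near-minimum doses.
    """
    if not 0 < volume_pct <= 100:
        raise ValueError(f"volume_pct must be in (0, 100], got {volume_pct}")
    target = volume_pct / 100.0
    ok = dvh.cum_volume_fraction >= target - 1e-12
    return float(dvh.dose_edges[ok][-1])


def homogeneity_index(grid: DoseGrid, chamber_mask: StructureMask) -> float:
    """HI = (D2% - D98%) / D_average over the chamber volume; 0 = uniform."""
    _check_lattice(grid, chamber_mask)
    doses = grid.values[chamber_mask.voxels]
    if doses.size == 0:
        raise ValueError("empty chamber mask")
    davg = float(doses.mean())
    if davg <= 0:
        raise ValueError("average chamber dose is zero; HI undefined")
    dvh = cumulative_dvh(grid, chamber_mask)
    return (dose_at_volume(dvh, 2.0) - dose_at_volume(dvh, 98.0)) / davg


def expand_mask(mask: StructureMask, margin_cm: float) -> StructureMask:
    """Euclidean dilation of *mask* by *margin_cm*, including the original.

    A voxel belongs to the expanded mask when its center lies within
    *margin_cm* of some voxel center of the original mask.
    """
    if margin_cm < 0:
        raise ValueError("margin must be >= 0")
    if margin_cm == 0 or not mask.voxels.any():
        expanded = mask.voxels.copy()
    else:
        dist = ndimage.distance_transform_edt(~mask.voxels, sampling=mask.spacing)
        expanded = dist <= margin_cm + 1e-9
    return StructureMask(
        name=f"{mask.name}+{margin_cm:g}cm",
        origin=mask.origin,
        spacing=mask.spacing,
        voxels=expanded,
    )


def conformity_index(
    grid: DoseGrid,
    chamber_mask: StructureMask,
    shell_mask: StructureMask,
) -> float:
    """COIN of the reference isodose (mean chamber dose) against a shell.

    ``COIN = (V_chamber>=RI / V_chamber) * (V_chamber>=RI / V_shell>=RI)``
    with RI the mean dose over the chamber.  1 means the isodose covers
    exactly the chamber and nothing else in the shell (steep gradients);
    low values mean the surrounding shell is also covered, so chamber
    positioning is less critical.
    """
    _check_lattice(grid, chamber_mask)
    _check_lattice(grid, shell_mask)
    if not chamber_mask.voxels.any():
        raise ValueError("empty chamber mask")
    if np.any(chamber_mask.voxels & ~shell_mask.voxels):
        raise ValueError("shell mask must contain the chamber mask")
    ri = float(grid.values[chamber_mask.voxels].mean())
    covered = grid.values >= ri
    ptv_small = int(chamber_mask.voxels.sum())
    ptv_small_ri = int((chamber_mask.voxels & covered).sum())
    ptv_coin_ri = int((shell_mask.voxels & covered).sum())
    if ptv_coin_ri == 0:
        raise ValueError("reference isodose covers no shell voxel; COIN undefined")
    return (ptv_small_ri / ptv_small) * (ptv_small_ri / ptv_coin_ri)


def _reference_dose(
    beam_dose: DoseGrid, chamber_mask: StructureMask, gantry_deg: float | None
) -> float:
    """Reference level for the intersection test.

    Without a beam axis, the beam's whole-grid maximum.  With a gantry
    angle, the maximum over the transverse slab through the chamber center
    (the beam's lateral profile at chamber depth), so that depth
    attenuation of obliquely incident beams does not masquerade as a
    lateral miss.
    """
    if gantry_deg is None:
        return float(beam_dose.values.max())
    theta = np.radians(gantry_deg)
    axis = np.array([np.sin(theta), 0.0, np.cos(theta)])  # iso -> source
    idx = np.argwhere(chamber_mask.voxels)
    centers = np.asarray(beam_dose.origin) + (idx + 0.5) * np.asarray(beam_dose.spacing)
    iso = centers.mean(axis=0)
    xs, ys, zs = beam_dose.voxel_centers()
    proj = (
        (xs[:, None, None] - iso[0]) * axis[0]
        + (ys[None, :, None] - iso[1]) * axis[1]
        + (zs[None, None, :] - iso[2]) * axis[2]
    )
    slab = np.abs(proj) <= max(beam_dose.spacing) + 1e-9
    return float(beam_dose.values[slab].max()) if slab.any() else float(beam_dose.values.max())


def beam_intersects_chamber(
    beam_dose: DoseGrid,
    chamber_mask: StructureMask,
    frac_of_max: float = 0.5,
    gantry_deg: float | None = None,
) -> bool:
    """True when the beam's high-dose region reaches the chamber contour.

    Quantitative surrogate for visual inspection: the beam intersects when
    any chamber voxel receives at least ``frac_of_max`` (default 50%) of
    the beam's reference dose — the grid maximum, or, when *gantry_deg* is
    given, the maximum at the chamber's depth (see :func:`_reference_dose`).
    """
    if not 0 < frac_of_max < 1:
        raise ValueError("frac_of_max must be in (0, 1)")
    _check_lattice(beam_dose, chamber_mask)
    if not chamber_mask.voxels.any():
        raise ValueError("empty chamber mask")
    ref = _reference_dose(beam_dose, chamber_mask, gantry_deg)
    if ref <= 0:
        return False
    return bool(np.any(beam_dose.values[chamber_mask.voxels] >= frac_of_max * ref))


def intersection_fraction(
    beam_doses: Sequence[DoseGrid],
    chamber_mask: StructureMask,
    frac_of_max: float = 0.5,
    gantry_angles_deg: Sequence[float] | None = None,
) -> float:
    """Fraction of the plan's beams whose dose intersects the chamber."""
    if not beam_doses:
        raise ValueError("need at least one beam dose grid")
    if gantry_angles_deg is None:
        angles: Sequence[float | None] = [None] * len(beam_doses)
    else:
        if len(gantry_angles_deg) != len(beam_doses):
            raise ValueError("one gantry angle per beam dose required")
        angles = list(gantry_angles_deg)
    hits = sum(
        beam_intersects_chamber(bd, chamber_mask, frac_of_max, ang)
        for bd, ang in zip(beam_doses, angles)
    )
    return hits / len(beam_doses)


def sum_beam_doses(beam_doses: Sequence[DoseGrid]) -> DoseGrid:
    """Voxelwise sum of per-beam dose grids on one common lattice."""
    if not beam_doses:
        raise ValueError("need at least one beam dose grid")
    first = beam_doses[0]
    total = np.zeros_like(first.values)
    for bd in beam_doses:
        if not first.same_lattice(bd):
            raise LatticeMismatchError("beam dose grids are on different lattices")
        total += bd.values
    return DoseGrid(origin=first.origin, spacing=first.spacing, values=total)


def combined_uncertainty(per_beam_pct: Sequence[float], n: int | None = None) -> float:
    """Combined statistical uncertainty of a plan's summed chamber dose (%).

    For n beams with per-beam relative uncertainties i (in percent of
    comparable per-beam doses): ``sqrt(sum i^2) / n``; with equal i this is
    ``i / sqrt(n)``.
    """
    vals = np.asarray(list(per_beam_pct), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one per-beam uncertainty")
    if n is None:
        n = vals.size
    if n != vals.size:
        raise ValueError(f"n ({n}) must equal the number of entries ({vals.size})")
    if np.any(vals < 0) or not np.all(np.isfinite(vals)):
        raise ValueError("uncertainties must be finite and >= 0")
    return float(np.sqrt(np.sum(vals**2)) / n)


def percent_rms_difference(pairs: Iterable[tuple[float, float]]) -> float:
    """Percent relative RMS difference of (computed, reference) dose pairs."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one pair")
    computed, reference = arr[:, 0], arr[:, 1]
    if np.any(reference <= 0):
        raise ValueError("reference doses must be > 0")
    rel_pct = (computed - reference) / reference * 100.0
    return float(np.sqrt(np.mean(rel_pct**2)))


# ---------------------------------------------------------------------------
# File formats: plain-text raster fixtures, DICOM RTDOSE, RTSTRUCT masks
# ---------------------------------------------------------------------------

_RASTER_MAGIC = "imrtqa-raster 1"


def write_dose_raster(grid: DoseGrid, path: str | Path) -> None:
    """Write a grid to the plain-text raster fixture format.

    Header lines (magic, dims, spacing, origin, optional uncertainty)
    followed by whitespace-separated dose values in C (x-major) order.
    """
    with open(path, "w") as fh:
        fh.write(f"# {_RASTER_MAGIC}\n")
        fh.write("dims: %d %d %d\n" % grid.dims)
        fh.write("spacing: %r %r %r\n" % grid.spacing)
        fh.write("origin: %r %r %r\n" % grid.origin)
        if grid.rel_uncertainty_pct is not None:
            fh.write(f"rel_uncertainty_pct: {grid.rel_uncertainty_pct!r}\n")
        fh.write("data:\n")
        grid.values.reshape(-1).tofile(fh, sep="\n", format="%r")
        fh.write("\n")


def read_dose_raster(path: str | Path) -> DoseGrid:
    """Read a grid written by :func:`write_dose_raster`."""
    header: dict[str, str] = {}
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != f"# {_RASTER_MAGIC}":
            raise ValueError(f"{path}: not an imrtqa raster file")
        for line in fh:
            line = line.strip()
            if line == "data:":
                break
            key, _, rest = line.partition(":")
            header[key.strip()] = rest.strip()
        else:
            raise ValueError(f"{path}: missing data section")
        values = np.array(fh.read().split(), dtype=float)
    dims = tuple(int(x) for x in header["dims"].split())
    spacing = tuple(float(x) for x in header["spacing"].split())
    origin = tuple(float(x) for x in header["origin"].split())
    unc = header.get("rel_uncertainty_pct")
    if values.size != int(np.prod(dims)):
        raise ValueError(f"{path}: expected {np.prod(dims)} values, got {values.size}")
    return DoseGrid(
        origin=origin,
        spacing=spacing,
        values=values.reshape(dims),
        rel_uncertainty_pct=float(unc) if unc is not None else None,
    )


def read_rtdose(path: str | Path) -> DoseGrid:
    """Read a DICOM RTDOSE file (mm converted to cm, scaled to Gy).

    The DICOM pixel array is indexed (frame=z, row=y, col=x); it is
    transposed to this package's (x, y, z) order.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    scale = float(getattr(ds, "DoseGridScaling", 1.0))
    values = ds.pixel_array.astype(float) * scale  # (z, y, x)
    values = np.ascontiguousarray(values.transpose(2, 1, 0))
    ipp = [float(x) for x in ds.ImagePositionPatient]  # mm, first-voxel center
    row_sp, col_sp = (float(x) for x in ds.PixelSpacing)  # (row=y, col=x)
    offsets = [float(x) for x in ds.GridFrameOffsetVector]
    if len(offsets) > 1:
        dz = offsets[1] - offsets[0]
    else:
        dz = float(getattr(ds, "SliceThickness", 1.0) or 1.0)
    spacing_cm = (col_sp / 10.0, row_sp / 10.0, dz / 10.0)
    origin_cm = tuple(
        ipp[i] / 10.0 - 0.5 * spacing_cm[i] for i in range(3)
    )
    return DoseGrid(origin=origin_cm, spacing=spacing_cm, values=values)


def mask_from_rtstruct(path: str | Path, grid: DoseGrid, roi_name: str) -> StructureMask:
    """Rasterize one RTSTRUCT ROI onto *grid* (voxel-center-in-polygon).

    Each CLOSED_PLANAR contour (mm) is assigned to the nearest grid slice
    and filled on the voxel centers of that slice.
    """
    import pydicom
    from matplotlib.path import Path as MplPath

    ds = pydicom.dcmread(str(path))
    roi_number = None
    for roi in getattr(ds, "StructureSetROISequence", []):
        if str(roi.ROIName) == roi_name:
            roi_number = int(roi.ROINumber)
    if roi_number is None:
        raise ValueError(f"ROI '{roi_name}' not found in {path}")
    contours = None
    for rc in getattr(ds, "ROIContourSequence", []):
        if int(rc.ReferencedROINumber) == roi_number:
            contours = getattr(rc, "ContourSequence", [])
    if contours is None:
        raise ValueError(f"ROI '{roi_name}' has no contour data")

    xs, ys, zs = grid.voxel_centers()
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    voxels = np.zeros(grid.dims, dtype=bool)
    for contour in contours:
        data = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3) / 10.0
        k = int(np.argmin(np.abs(zs - data[0, 2])))
        inside = MplPath(data[:, :2]).contains_points(pts).reshape(xx.shape)
        voxels[:, :, k] |= inside
    return StructureMask(name=roi_name, origin=grid.origin, spacing=grid.spacing, voxels=voxels)
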