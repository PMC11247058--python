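"""ROI densitometry of clot CT scans.

Non-contrast (NCCT) clot density and the contrast-enhanced (CECT) density
increase — an in-vitro proxy for clinical thrombus perviousness — are read
from Hounsfield-unit grids with a fixed ROI protocol: three circular
regions of interest, each with a diameter half the sample diameter, placed
on distinct axial slices and centred on the per-slice clot centroid (three
equal ROIs of that size cannot be pairwise disjoint within a single
circular cross-section, so non-overlap is guaranteed by slice separation).
The reported density is the unweighted mean of the per-ROI mean HU; the
CECT density increase is the CECT minus the NCCT density over identical ROI
geometry and may be negative.

Grids are (z, y, x) with per-axis voxel size in mm; voxel-in-disc
membership uses the centre-of-voxel rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "CTImage",
    "ROISpec",
    "DensityResult",
    "place_rois",
    "roi_voxel_mask",
    "roi_mean_density",
    "cect_increase",
    "measure_scan_pair",
    "load_hu_grid",
]


@dataclass(frozen=True)
class CTImage:
    """HU grid with voxel size (mm, per axis z/y/x) and clot mask."""

    hu: np.ndarray
    voxel_size: Tuple[float, float, float]
    clot_mask: np.ndarray

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu)
        mask = np.asarray(self.clot_mask)
        if hu.ndim != 3:
            raise ValueError("hu grid must be 3-D (z, y, x)")
        if hu.shape != mask.shape:
            raise ValueError("clot_mask shape must match hu grid")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive per axis")


@dataclass(frozen=True)
class ROISpec:
    """One circular in-plane ROI: axial slice, centre (x, y) in mm, diameter mm."""

    slice_index: int
    center: Tuple[float, float]
    diameter: float


@dataclass(frozen=True)
class DensityResult:
    """ROI-averaged densities for one scan or scan pair (HU)."""

    ncct_density: float
    cect_density: float | None = None
    cect_increase: float | None = None
    roi_means: Tuple[float, ...] = ()
    rois: Tuple[ROISpec, ...] = ()


def _slice_centroid(mask2d: np.ndarray, voxel_yx: Tuple[float, float]) -> Tuple[float, float]:
    """Clot centroid of one slice in mm (x, y), centre-of-voxel convention."""
    yy, xx = np.nonzero(mask2d)
    dy, dx = voxel_yx
    return (float((xx.mean() + 0.5) * dx), float((yy.mean() + 0.5) * dy))


def _disc_sel(shape_yx, voxel_yx, center, diameter) -> np.ndarray:
    dy, dx = voxel_yx
    ny, nx = shape_yx
    cx, cy = center
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dy
    xx, yy = np.meshgrid(x, y)
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= (diameter / 2.0) ** 2


def roi_voxel_mask(image: CTImage, roi: ROISpec) -> np.ndarray:
    """Boolean in-plane membership mask for one ROI (centre-of-voxel rule)."""
    _, dy, dx = image.voxel_size
    return _disc_sel(image.hu.shape[1:], (dy, dx), roi.center, roi.diameter)


def place_rois(
    image: CTImage,
    sample_diameter: float,
    n: int = 3,
    seed: int | None = None,
) -> List[ROISpec]:
    """Place ``n`` ROIs of diameter ``sample_diameter / 2`` on distinct slices.

    Each ROI is centred on the clot centroid of its slice; a slice qualifies
    only if the full disc lies inside the clot mask there. Qualifying slices
    are sampled evenly over the clot extent (the protocol is deterministic;
    ``seed`` is accepted for interface symmetry with the generators).

    Raises ``ValueError`` when fewer than ``n`` slices can inscribe the ROI.
    """
    roi_diameter = sample_diameter / 2.0
    _, dy, dx = image.voxel_size
    valid: List[ROISpec] = []
    for iz in range(image.hu.shape[0]):
        m = image.clot_mask[iz]
        if not m.any():
            continue
        center = _slice_centroid(m, (dy, dx))
        sel = _disc_sel(m.shape, (dy, dx), center, roi_diameter)
        if sel.any() and bool(np.all(m[sel])):
            valid.append(ROISpec(slice_index=iz, center=center, diameter=roi_diameter))
    if len(valid) < n:
        raise ValueError(
            f"clot too small for ROI protocol: only {len(valid)} slice(s) can "
            f"inscribe a {roi_diameter:.2f} mm disc; need {n}"
        )
    idx = np.linspace(0, len(valid) - 1, n).round().astype(int)
    return [valid[i] for i in idx]


def roi_mean_density(image: CTImage, rois: Sequence[ROISpec]) -> Tuple[float, List[float]]:
    """Per-ROI mean HU and their unweighted overall mean.

    Returns ``(overall_mean, per_roi_means)``; an ROI containing no voxel
    raises.
    """
    means: List[float] = []
    for roi in rois:
        sel = roi_voxel_mask(image, roi)
        if not sel.any():
            raise ValueError(f"ROI on slice {roi.slice_index} contains no voxels")
        means.append(float(image.hu[roi.slice_index][sel].mean()))
    return float(np.mean(means)), means


def cect_increase(ncct: DensityResult, cect: DensityResult) -> float:
    """CECT density minus NCCT density over identical ROI geometry (HU)."""
    if ncct.rois != cect.rois:
        raise ValueError("NCCT and CECT densities use different ROI geometry")
    if cect.cect_density is None:
        raise ValueError("cect argument carries no CECT density")
    return cect.cect_density - ncct.ncct_density


def measure_scan_pair(
    ncct_img: CTImage,
    cect_img: CTImage,
    sample_diameter: float,
    n_rois: int = 3,
) -> DensityResult:
    """ROI protocol over an aligned NCCT/CECT pair -> full :class:`DensityResult`."""
    rois = place_rois(ncct_img, sample_diameter, n=n_rois)
    ncct_mean, ncct_roi_means = roi_mean_density(ncct_img, rois)
    cect_mean, _ = roi_mean_density(cect_img, rois)
    return DensityResult(
        ncct_density=ncct_mean,
        cect_density=cect_mean,
        cect_increase=cect_mean - ncct_mean,
        roi_means=tuple(ncct_roi_means),
        rois=tuple(rois),
    )


def load_hu_grid(path: Union[str, Path]) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    """Read an HU grid and voxel size from NIfTI (.nii/.nii.gz) or TIFF.

    TIFF files carry no reliable voxel metadata; 1 mm isotropic is assumed
    and should be overridden by the caller.
    """
    path = Path(path)
    if path.suffix in {".nii", ".gz"}:
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
        # nibabel axes are (x, y, z); reorder to (z, y, x)
        data = np.transpose(data, (2, 1, 0))
        zooms = img.header.get_zooms()[:3]
        voxel = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        return data, voxel
    import tifffile

    data = np.asarray(tifffile.imread(str(path)), dtype=float)
    if data.ndim == 2:
        data = data[None]
    return data, (1.0, 1.0, 1.0)
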