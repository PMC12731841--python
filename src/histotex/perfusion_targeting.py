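"""Semi-quantitative DCE-MRI analysis and perfusion-targeted treatment masks.

From a 4D dynamic contrast-enhanced series this module computes percentage
signal enhancement, the baseline-subtracted initial area under the
enhancement curve (first two minutes after injection, trapezoidal rule),
its muscle-normalized variant, a maximum intensity projection (MIP) across
transverse slices, and tertile exclusion masks: treating the two-thirds of
tumor voxels with the lowest (or highest) perfusion by excluding the
opposite third, then dropping any treatment cell of a 1.2 mm lattice over
an 18 mm analysis region that contains an excluded voxel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("histotex")


@dataclass
class DCESeries:
    """4D DCE signal S(x, y, z, t) with frame times in seconds."""

    signal: np.ndarray
    times: np.ndarray
    baseline_frames: tuple[int, ...]
    voxel_spacing: float = 1.0   # mm, in-plane isotropic

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, t)")
        if self.signal.shape[3] != self.times.size:
            raise ValueError("times length must match the time axis")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.baseline_frames) < 1:
            raise ValueError("need at least one baseline frame")

    def baseline(self) -> np.ndarray:
        """Per-voxel pre-contrast signal: mean over baseline frames."""
        return self.signal[..., list(self.baseline_frames)].mean(axis=3)


@dataclass
class AUCMap:
    auc: np.ndarray                       # 3D, signal * seconds
    auc_norm: np.ndarray | None = None    # 3D, dimensionless
    muscle_auc: float | None = None


@dataclass
class MIPImage:
    values: np.ndarray                    # 2D (x, y)


@dataclass
class TreatmentCell:
    index: tuple[int, int]
    n_voxels: int
    included: bool


@dataclass
class TreatmentCellGrid:
    region_diameter: float                # mm
    cell_mm: float
    n_per_axis: int
    cells: list[TreatmentCell]
    cell_of_voxel: np.ndarray             # 2D int, -1 outside region


@dataclass
class ExclusionResult:
    excluded: np.ndarray                  # 2D bool over the MIP grid
    treated: np.ndarray                   # 2D bool: tumor minus excluded
    n_tumor_voxels: int
    treated_fraction: float               # exact kept / n
    treated_percent_floor: int            # floor(100 * kept / n)


def percent_enhancement(series: DCESeries,
                        roi: np.ndarray | None = None) -> np.ndarray:
    """Percentage signal enhancement 100 (S(t) - S0) / S0.

    With ``roi`` (3D boolean), returns one curve for the ROI-mean signal;
    without it, a per-voxel 4D array.
    """
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        sig = series.signal[roi].mean(axis=0)
        s0 = sig[list(series.baseline_frames)].mean()
        if s0 <= 0:
            raise ValueError("baseline signal must be positive")
        return 100.0 * (sig - s0) / s0
    s0 = series.baseline()
    if np.any(s0 <= 0):
        raise ValueError("baseline signal must be positive in every voxel")
    return 100.0 * (series.signal - s0[..., None]) / s0[..., None]


def auc_initial(series: DCESeries, injection_time: float,
                window: float = 120.0) -> AUCMap:
    """Initial area under the enhancement curve, trapezoidal rule.

    Integrates the baseline-subtracted signal over
    [injection_time, injection_time + window]; if the series ends earlier,
    integration stops at the last frame with a warning.
    """
    t_end = injection_time + window
    if t_end > series.times[-1]:
        logger.warning("AUC window end %.0f s beyond last frame %.0f s; "
                       "integrating to last frame", t_end, series.times[-1])
        t_end = float(series.times[-1])
    in_win = (series.times >= injection_time) & (series.times <= t_end)
    if in_win.sum() < 2:
        raise ValueError("need at least 2 frames inside the AUC window")
    t = series.times[in_win]
    enh = series.signal[..., in_win] - series.baseline()[..., None]
    auc = np.trapezoid(enh, t, axis=3)
    return AUCMap(auc=auc)


def normalize_auc(auc_map: AUCMap, muscle_roi: np.ndarray) -> AUCMap:
    """Divide the AUC by the mean AUC of a muscle reference region."""
    muscle_roi = np.asarray(muscle_roi, dtype=bool)
    if not muscle_roi.any():
        raise ValueError("empty muscle ROI")
    muscle = float(auc_map.auc[muscle_roi].mean())
    if muscle <= 0:
        raise ValueError("muscle AUC must be positive")
    return AUCMap(auc=auc_map.auc, auc_norm=auc_map.auc / muscle,
                  muscle_auc=muscle)


def mip_transverse(auc_map: AUCMap) -> MIPImage:
    """Maximum intensity projection across transverse slices (z axis).

    Projects the normalized AUC when available, else the raw AUC.
    """
    vol = auc_map.auc_norm if auc_map.auc_norm is not None else auc_map.auc
    return MIPImage(values=vol.max(axis=2))


def exclusion_mask(mip: MIPImage, tumor_footprint: np.ndarray,
                   mode: str = "low_target") -> ExclusionResult:
    """Tertile exclusion over the tumor's MIP footprint.

    ``low_target`` excludes the third of voxels with the *highest* MIP
    values (the low-perfusion two-thirds are treated); ``high_target``
    mirrors it. Ties are broken by stable (value, voxel index) ordering.
    """
    if mode not in ("low_target", "high_target"):
        raise ValueError("mode must be 'low_target' or 'high_target'")
    foot = np.asarray(tumor_footprint, dtype=bool)
    if foot.shape != mip.values.shape:
        raise ValueError("tumor footprint shape must match the MIP")
    idx = np.nonzero(foot.ravel())[0]
    n = idx.size
    if n < 3:
        raise ValueError("need at least 3 tumor voxels")
    vals = mip.values.ravel()[idx]
    if np.all(vals == vals[0]):
        logger.warning("all MIP values equal; tertile split falls back to "
                       "stable voxel order")
    order = np.argsort(vals, kind="stable")      # ascending; stable in index
    n_excluded = n - (2 * n) // 3                # the "third" of voxels
    if mode == "low_target":
        cut = idx[order[n - n_excluded:]]
    else:
        cut = idx[order[:n_excluded]]
    excluded = np.zeros(foot.shape, dtype=bool)
    excluded.ravel()[cut] = True
    treated = foot & ~excluded
    kept = int(treated.sum())
    return ExclusionResult(excluded=excluded, treated=treated,
                           n_tumor_voxels=n,
                           treated_fraction=kept / n,
                           treated_percent_floor=int(100 * kept // n))


def lift_to_volume(mask2d: np.ndarray, tumor3d: np.ndarray) -> np.ndarray:
    """Lift a 2D (x, y) mask back to all z of each column, within the tumor."""
    return np.asarray(mask2d, bool)[:, :, None] & np.asarray(tumor3d, bool)


def build_cell_grid(region_diameter: float = 18.0, cell_mm: float = 1.2,
                    voxel_spacing: float = 1.0,
                    grid_shape: tuple[int, int] | None = None,
                    center: tuple[float, float] | None = None
                    ) -> TreatmentCellGrid:
    """Lattice of square treatment cells over a circular analysis region.

    The square bounding the region is split into round(diameter / cell)
    cells per axis (15 x 15 for 18 mm / 1.2 mm), centered on the region;
    cells fully outside the disc are dropped. With ``grid_shape`` given,
    every voxel center inside the disc is assigned to exactly one cell.
    """
    if region_diameter <= 0 or cell_mm <= 0 or voxel_spacing <= 0:
        raise ValueError("sizes must be positive")
    if cell_mm > region_diameter:
        raise ValueError("cell size cannot exceed the region diameter")
    n_axis = int(round(region_diameter / cell_mm))
    radius = region_diameter / 2.0

    if grid_shape is None:
        grid_shape = (int(np.ceil(region_diameter / voxel_spacing)),) * 2
    h, w = grid_shape
    if center is None:
        center = (h / 2.0, w / 2.0)   # voxel units

    # voxel center coordinates in mm relative to the region center
    r_mm = (np.arange(h) + 0.5 - center[0]) * voxel_spacing
    c_mm = (np.arange(w) + 0.5 - center[1]) * voxel_spacing
    rr = r_mm[:, None] * np.ones((1, w))
    cc = np.ones((h, 1)) * c_mm[None, :]
    in_region = rr ** 2 + cc ** 2 <= radius ** 2

    half = n_axis * cell_mm / 2.0
    ci = np.floor((rr + half) / cell_mm).astype(int)
    cj = np.floor((cc + half) / cell_mm).astype(int)
    np.clip(ci, 0, n_axis - 1, out=ci)
    np.clip(cj, 0, n_axis - 1, out=cj)
    flat = ci * n_axis + cj
    cell_of_voxel = np.where(in_region, flat, -1)

    # keep cells that intersect the disc (by voxel membership, plus any
    # cell whose square overlaps the disc when no voxel grid sampling hits)
    cells: list[TreatmentCell] = []
    counts = np.bincount(flat[in_region].ravel(), minlength=n_axis * n_axis)
    for a in range(n_axis):
        for b in range(n_axis):
            n_vox = int(counts[a * n_axis + b])
            # cell corner closest to the center decides disc overlap
            r_lo, r_hi = a * cell_mm - half, (a + 1) * cell_mm - half
            c_lo, c_hi = b * cell_mm - half, (b + 1) * cell_mm - half
            near_r = min(abs(r_lo), abs(r_hi)) if r_lo * r_hi > 0 else 0.0
            near_c = min(abs(c_lo), abs(c_hi)) if c_lo * c_hi > 0 else 0.0
            if near_r ** 2 + near_c ** 2 <= radius ** 2:
                cells.append(TreatmentCell(index=(a, b), n_voxels=n_vox,
                                           included=True))
    return TreatmentCellGrid(region_diameter=region_diameter, cell_mm=cell_mm,
                             n_per_axis=n_axis, cells=cells,
                             cell_of_voxel=cell_of_voxel)


def apply_cell_exclusion(grid: TreatmentCellGrid,
                         excl: ExclusionResult) -> TreatmentCellGrid:
    """Drop every treatment cell containing at least one excluded voxel.

    Returns a new grid with updated ``included`` flags; the cell-level
    treated volume can only shrink relative to the voxel-level one.
    """
    if grid.cell_of_voxel.shape != excl.excluded.shape:
        raise ValueError("cell grid and exclusion mask shapes differ")
    bad = np.unique(grid.cell_of_voxel[excl.excluded])
    bad = set(int(b) for b in bad if b >= 0)
    cells = [TreatmentCell(index=c.index, n_voxels=c.n_voxels,
                           included=c.included and
                           (c.index[0] * grid.n_per_axis + c.index[1]) not in bad)
             for c in grid.cells]
    return TreatmentCellGrid(region_diameter=grid.region_diameter,
                             cell_mm=grid.cell_mm,
                             n_per_axis=grid.n_per_axis, cells=cells,
                             cell_of_voxel=grid.cell_of_voxel)


def cell_level_treated_fraction(grid: TreatmentCellGrid,
                                tumor_footprint: np.ndarray) -> float:
    """Fraction of tumor-footprint voxels lying in included cells."""
    foot = np.asarray(tumor_footprint, dtype=bool)
    included = {c.index[0] * grid.n_per_axis + c.index[1]
                for c in grid.cells if c.included}
    cells = grid.cell_of_voxel
    ok = foot & (cells >= 0) & np.isin(cells, sorted(included))
    n = int(foot.sum())
    if n == 0:
        raise ValueError("empty tumor footprint")
    return float(ok.sum()) / n
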