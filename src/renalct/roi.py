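"""ROI placement protocols and attenuation measurement.

Three ROI variants are implemented, following the measurement protocol for
small renal tumors on thin-slice four-phase CT:

* **ROI (1)** — circular, 50–100 mm², centered on a strongly enhancing
  region of the tumor in the corticomedullary phase (CMP);
* **ROI (2)** — circular, 10–20 mm², inside the most enhancing patch itself;
* **ROI (3)** — whole-tumor ROI on the largest cross-section, its edge kept
  2–3 mm inside the tumor boundary, defined on the excretory phase (EP)
  where the boundary is clearest and copied to the other phases.

Enhancing-patch candidates are detected as bright connected components in
the CMP tumor interior; elongated components (thin curvilinear structures,
i.e. intratumoral vessels) and voxels flagged as cyst/calcification are
excluded, mirroring the placement rules. Each ROI yields the within-ROI
mean (AVT) and, for ROI (3), the SD of attenuation (HDT); measurements are
averaged over enhancing regions, three adjacent slices, repeated readings
and observers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .metrics import PHASES, PhaseMeasurement, QuantRecord
from .phantom import FourPhaseVolume

__all__ = [
    "ROIGeometry",
    "ROIMeasurement",
    "ProtocolConfig",
    "ProtocolResult",
    "RegionTooSmallError",
    "MarginTooLargeError",
    "IncompleteFourPhaseError",
    "detect_enhancement_regions",
    "place_fixed_area_roi",
    "place_whole_tumor_roi",
    "measure_roi",
    "measure_lesion_protocol",
]


class RegionTooSmallError(ValueError):
    """The target region cannot host an ROI of the requested minimum area."""


class MarginTooLargeError(ValueError):
    """The tumor cross-section is too small for the requested safety margin."""


class IncompleteFourPhaseError(ValueError):
    """A phase is missing; the four-phase protocol cannot be applied."""


@dataclass
class ROIGeometry:
    """A planar circular ROI: slice index + in-plane center and radius."""

    slice_index: int
    center_row: float  # pixel units
    center_col: float
    radius_mm: float
    phase: str = ""
    shape: str = "circle"

    @property
    def area_mm2(self) -> float:
        return float(np.pi * self.radius_mm**2)

    def pixel_mask(self, shape_2d: tuple[int, int],
                   spacing: tuple[float, float, float]) -> np.ndarray:
        """Boolean in-plane mask of pixels whose centers fall in the circle."""
        _, dy, dx = spacing
        rows = np.arange(shape_2d[0])[:, None]
        cols = np.arange(shape_2d[1])[None, :]
        d2 = ((rows - self.center_row) * dy) ** 2 + \
             ((cols - self.center_col) * dx) ** 2
        return d2 <= self.radius_mm**2

    def with_slice(self, slice_index: int, phase: str | None = None
                   ) -> "ROIGeometry":
        return ROIGeometry(slice_index=slice_index, center_row=self.center_row,
                           center_col=self.center_col, radius_mm=self.radius_mm,
                           phase=self.phase if phase is None else phase,
                           shape=self.shape)


@dataclass
class ROIMeasurement:
    """Mean and SD of attenuation over the pixels of one ROI."""

    mean_hu: float
    sd_hu: float
    pixel_count: int
    area_mm2: float

    def __post_init__(self) -> None:
        if self.sd_hu < 0 or self.pixel_count < 1:
            raise ValueError("invalid ROI measurement")


def measure_roi(phase_grid: np.ndarray, roi: ROIGeometry,
                spacing: tuple[float, float, float],
                ddof: int = 0) -> ROIMeasurement:
    """Mean and population SD (``ddof=0``) of HU over the ROI pixels.

    Raises
    ------
    ValueError
        If the ROI extends outside the grid.
    """
    dz, dy, dx = spacing
    nz, ny, nx = phase_grid.shape
    if not (0 <= roi.slice_index < nz):
        raise ValueError("ROI slice outside the grid")
    if (roi.center_row * dy - roi.radius_mm < -dy / 2
            or roi.center_col * dx - roi.radius_mm < -dx / 2
            or roi.center_row * dy + roi.radius_mm > (ny - 0.5) * dy
            or roi.center_col * dx + roi.radius_mm > (nx - 0.5) * dx):
        raise ValueError("ROI extends outside the grid")
    mask = roi.pixel_mask((ny, nx), spacing)
    vals = phase_grid[roi.slice_index][mask]
    if vals.size == 0:
        raise ValueError("ROI covers no pixel centers")
    return ROIMeasurement(mean_hu=float(vals.mean()),
                          sd_hu=float(vals.std(ddof=ddof)),
                          pixel_count=int(vals.size),
                          area_mm2=float(vals.size * dy * dx))


def _component_elongation(comp: np.ndarray,
                          spacing: tuple[float, float, float]) -> float:
    """Length-to-width ratio of a connected component.

    Width is twice the deepest inscribed distance ``t`` (from the Euclidean
    distance transform); effective length is volume / (pi t^2), which stays
    large for curved tubes where principal-axis moments would not.
    """
    edt = ndimage.distance_transform_edt(comp, sampling=spacing)
    t = float(edt.max())
    if t == 0:
        return np.inf
    volume = float(comp.sum()) * float(np.prod(spacing))
    length = volume / (np.pi * t * t)
    return length / (2.0 * t)


def detect_enhancement_regions(volume_cmp: np.ndarray, tumor_mask: np.ndarray,
                               spacing: tuple[float, float, float],
                               exclude_mask: np.ndarray | None = None,
                               percentile: float = 90.0,
                               min_voxels: int = 20,
                               elongation_max: float = 3.0,
                               smooth_sigma_mm: float = 0.8,
                               return_excluded: bool = False):
    """Connected strongly enhancing regions inside the tumor on CMP.

    The grid is lightly Gaussian-smoothed (``smooth_sigma_mm``) so that
    voxel noise does not fragment or bridge components; voxels above the
    ``percentile`` of within-tumor smoothed CMP intensity form candidates.
    Components smaller than ``min_voxels`` are dropped, elongated ones
    (length/width > ``elongation_max``) are classed as vessels and
    excluded, and voxels under ``exclude_mask`` (cysts, calcification) are
    never included. An empty list is a valid result.

    Raises
    ------
    ValueError
        If the tumor mask is empty.
    """
    if not np.any(tumor_mask):
        raise ValueError("tumor mask is empty")
    interior = tumor_mask.copy()
    if exclude_mask is not None:
        interior &= ~exclude_mask
    grid = volume_cmp
    if smooth_sigma_mm > 0:
        grid = ndimage.gaussian_filter(
            volume_cmp, sigma=[smooth_sigma_mm / s for s in spacing])
    vals = grid[interior]
    # percentile rule alone always flags ~10% of voxels even in a
    # homogeneous tumor; combine it with a robust noise floor so only
    # genuinely elevated voxels survive
    med = np.median(vals)
    robust_sd = 1.4826 * np.median(np.abs(vals - med))
    thr = max(np.percentile(vals, percentile), med + 3.0 * robust_sd)
    candidates = (grid >= thr) & interior
    labeled, n = ndimage.label(candidates)
    patches, vessels = [], []
    for lab in range(1, n + 1):
        comp = labeled == lab
        if comp.sum() < min_voxels:
            continue
        if _component_elongation(comp, spacing) > elongation_max:
            vessels.append(comp)
        else:
            patches.append(comp)
    patches.sort(key=lambda m: -int(m.sum()))
    if return_excluded:
        return patches, vessels
    return patches


def _best_slice(mask: np.ndarray) -> int:
    return int(np.argmax(mask.reshape(mask.shape[0], -1).sum(axis=1)))


def _circle_pixel_count(center_rc, radius_mm, shape_2d, spacing) -> int:
    g = ROIGeometry(0, center_rc[0], center_rc[1], radius_mm)
    return int(g.pixel_mask(shape_2d, spacing).sum())


def place_fixed_area_roi(region_mask: np.ndarray,
                         area_range_mm2: tuple[float, float],
                         spacing: tuple[float, float, float],
                         intensity: np.ndarray | None = None,
                         support_mask: np.ndarray | None = None,
                         phase: str = "") -> ROIGeometry:
    """Circular ROI of constrained area at a region's (weighted) centroid.

    The ROI is centered on the intensity-weighted centroid of the region's
    largest cross-section and takes the largest radius that (a) keeps the
    pixelated area within ``area_range_mm2`` and (b) stays inside
    ``support_mask`` (default: the region itself — pass the tumor mask to
    let a 50–100 mm² ROI extend beyond a small bright patch).

    Raises
    ------
    RegionTooSmallError
        If no circle of at least the minimum area fits; callers fall back
        to the largest inscribed circle.
    """
    amin, amax = area_range_mm2
    _, dy, dx = spacing
    if not np.any(region_mask):
        raise RegionTooSmallError("empty region")
    s = _best_slice(region_mask)
    region2d = region_mask[s]
    support2d = (support_mask[s] if support_mask is not None else region2d)
    rr, cc = np.nonzero(region2d)
    if intensity is not None:
        w = intensity[s][region2d].astype(float)
        w = w - w.min() + 1e-9
    else:
        w = np.ones(rr.size)
    center = (float(np.average(rr, weights=w)), float(np.average(cc, weights=w)))
    ci, cj = int(round(center[0])), int(round(center[1]))
    edt = ndimage.distance_transform_edt(support2d, sampling=(dy, dx))
    if not support2d[ci, cj]:
        # centroid in a hole (e.g. central cyst): recenter on the deepest
        # support pixel of the region instead
        inside = region2d & support2d
        if not np.any(inside):
            raise RegionTooSmallError("region has no pixel inside the support")
        masked = np.where(inside, edt, -1.0)
        ci, cj = np.unravel_index(int(np.argmax(masked)), masked.shape)
        center = (float(ci), float(cj))
    r_fit = float(edt[ci, cj]) - 0.5 * max(dy, dx)
    r = min(r_fit, float(np.sqrt(amax / np.pi)))
    pa = dy * dx
    while r > 0:
        count = _circle_pixel_count(center, r, region2d.shape, spacing)
        if count * pa <= amax:
            break
        r -= 0.1 * min(dy, dx)
    if r <= 0:
        raise RegionTooSmallError("no positive-radius circle fits the support")
    count = _circle_pixel_count(center, r, region2d.shape, spacing)
    if count * pa < amin:
        raise RegionTooSmallError(
            f"largest admissible circle covers {count * pa:.1f} mm^2 "
            f"< requested minimum {amin} mm^2")
    return ROIGeometry(slice_index=s, center_row=center[0],
                       center_col=center[1], radius_mm=r, phase=phase)


def largest_inscribed_circle(mask: np.ndarray,
                             spacing: tuple[float, float, float],
                             slice_index: int | None = None,
                             center_rc: tuple[float, float] | None = None,
                             max_radius_mm: float | None = None,
                             phase: str = "") -> ROIGeometry:
    """Largest circle inside a mask cross-section (fallback placement).

    With ``center_rc`` given, the circle is centered there and the radius is
    the inscribed distance at that point; otherwise the deepest interior
    point of the chosen slice is used.
    """
    _, dy, dx = spacing
    s = _best_slice(mask) if slice_index is None else slice_index
    m2d = mask[s]
    if not np.any(m2d):
        raise RegionTooSmallError("empty cross-section")
    edt = ndimage.distance_transform_edt(m2d, sampling=(dy, dx))
    if center_rc is None:
        ci, cj = np.unravel_index(int(np.argmax(edt)), edt.shape)
        center_rc = (float(ci), float(cj))
    ci, cj = int(round(center_rc[0])), int(round(center_rc[1]))
    if edt[ci, cj] <= 0:
        # requested center lies outside the mask: use the deepest point
        ci, cj = np.unravel_index(int(np.argmax(edt)), edt.shape)
        center_rc = (float(ci), float(cj))
    r = float(edt[ci, cj]) - 0.5 * max(dy, dx)
    if max_radius_mm is not None:
        r = min(r, max_radius_mm)
    if r <= 0:
        raise RegionTooSmallError("no inscribed circle at the requested center")
    return ROIGeometry(slice_index=s, center_row=center_rc[0],
                       center_col=center_rc[1], radius_mm=r, phase=phase)


def place_whole_tumor_roi(tumor_mask: np.ndarray, margin_mm: float,
                          spacing: tuple[float, float, float],
                          phase: str = "EP") -> ROIGeometry:
    """Whole-tumor circular ROI on the largest cross-sectional slice.

    The circle is centered at the deepest interior point of that slice and
    its radius is the inscribed distance minus ``margin_mm``, so every ROI
    pixel stays at least the margin inside the tumor boundary.

    Raises
    ------
    MarginTooLargeError
        If the cross-section cannot accommodate the margin.
    """
    if not np.any(tumor_mask):
        raise ValueError("tumor mask is empty")
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    _, dy, dx = spacing
    s = _best_slice(tumor_mask)
    edt = ndimage.distance_transform_edt(tumor_mask[s], sampling=(dy, dx))
    ci, cj = np.unravel_index(int(np.argmax(edt)), edt.shape)
    r = float(edt[ci, cj]) - margin_mm
    if r < min(dy, dx):
        raise MarginTooLargeError(
            f"tumor cross-section too small for a {margin_mm} mm margin")
    return ROIGeometry(slice_index=s, center_row=float(ci),
                       center_col=float(cj), radius_mm=r, phase=phase)


@dataclass
class ProtocolConfig:
    """Tunable parameters of the measurement protocol."""

    roi1_range: tuple[float, float] = (50.0, 100.0)  # mm^2
    roi2_range: tuple[float, float] = (10.0, 20.0)  # mm^2
    roi3_margin_mm: float = 2.5  # midpoint of the 2-3 mm rule
    adjacent_slices: int = 1  # ROI slice +/- 1 -> three adjacent sections
    repeats: int = 2  # each section measured at least twice
    roi3_repeats: int = 3  # whole-tumor ROI measured three times
    n_observers: int = 2
    observer_noise_sd: float = 1.0  # HU, reading-to-reading variability
    detect_percentile: float = 90.0
    detect_min_voxels: int = 20
    detect_smooth_sigma_mm: float = 0.8
    elongation_max: float = 3.0
    sd_ddof: int = 0  # population SD for heterogeneity
    reference_area_mm2: float = 80.0  # cortex/psoas ROI target area
    seed: int | None = None


@dataclass
class ProtocolResult:
    """Raw protocol output for one lesion."""

    record: QuantRecord
    geometries: dict = field(default_factory=dict)
    n_regions: int = 0


def _grand_mean(values: list[float]) -> float:
    return float(np.mean(values))


def measure_lesion_protocol(volume: FourPhaseVolume,
                            config: ProtocolConfig | None = None,
                            lesion_id: str = "L001",
                            label: str | None = None) -> ProtocolResult:
    """Run the full three-ROI, four-phase measurement protocol on one volume.

    ROI (1)/(2) are placed on CMP (per enhancing region) and their geometry
    copied to the other phases; ROI (3) is defined on EP and copied
    likewise. Per ROI variant and phase, readings are averaged over
    enhancing regions x three adjacent slices x repeats x observers as a
    flat grand mean. Observer/repeat variability is simulated as independent
    Gaussian reading noise of ``config.observer_noise_sd`` HU.

    Raises
    ------
    IncompleteFourPhaseError
        If any of the four phases is missing.
    """
    cfg = config or ProtocolConfig()
    missing = [ph for ph in PHASES if ph not in volume.phases]
    if missing:
        raise IncompleteFourPhaseError(f"missing phases: {missing}")
    rng = np.random.default_rng(cfg.seed)
    sp = volume.spacing
    tumor = volume.masks["tumor"]
    cysts = volume.masks.get("cysts")
    cmp_grid = volume.phases["CMP"]

    patches, vessel_like = detect_enhancement_regions(
        cmp_grid, tumor, sp, exclude_mask=cysts,
        percentile=cfg.detect_percentile, min_voxels=cfg.detect_min_voxels,
        elongation_max=cfg.elongation_max,
        smooth_sigma_mm=cfg.detect_smooth_sigma_mm, return_excluded=True)
    support = tumor.copy()
    if cysts is not None:
        support &= ~cysts
    for v in vessel_like:
        support &= ~v
    regions = patches if patches else [support]

    roi2_list, roi1_list = [], []
    for reg in regions:
        try:
            roi2 = place_fixed_area_roi(reg, cfg.roi2_range, sp,
                                        intensity=cmp_grid, support_mask=reg,
                                        phase="CMP")
        except RegionTooSmallError:
            roi2 = largest_inscribed_circle(
                reg, sp, max_radius_mm=np.sqrt(cfg.roi2_range[1] / np.pi),
                phase="CMP")
        roi2_list.append(roi2)
        try:
            roi1 = place_fixed_area_roi(reg, cfg.roi1_range, sp,
                                        intensity=cmp_grid,
                                        support_mask=support, phase="CMP")
        except RegionTooSmallError:
            rr, cc = np.nonzero(reg[_best_slice(reg)])
            roi1 = largest_inscribed_circle(
                support, sp, slice_index=_best_slice(reg),
                center_rc=(float(rr.mean()), float(cc.mean())),
                max_radius_mm=np.sqrt(cfg.roi1_range[1] / np.pi), phase="CMP")
        roi1_list.append(roi1)

    roi3 = place_whole_tumor_roi(tumor, cfg.roi3_margin_mm, sp, phase="EP")
    cortex = volume.masks["cortex"]
    psoas = volume.masks["psoas"]
    ref_r = float(np.sqrt(cfg.reference_area_mm2 / np.pi))
    cortex_roi = largest_inscribed_circle(cortex, sp, max_radius_mm=ref_r,
                                          phase="CMP")
    psoas_slice = (roi3.slice_index
                   if np.any(psoas[roi3.slice_index])
                   else _best_slice(psoas))
    psoas_roi = largest_inscribed_circle(psoas, sp, slice_index=psoas_slice,
                                         max_radius_mm=ref_r, phase="EP")

    def _read(grid, roi_at_slice) -> ROIMeasurement:
        return measure_roi(grid, roi_at_slice, sp, ddof=cfg.sd_ddof)

    def _noise() -> float:
        if cfg.observer_noise_sd == 0:
            return 0.0
        return float(rng.normal(0.0, cfg.observer_noise_sd))

    nz = volume.shape[0]
    phase_meas: dict[str, PhaseMeasurement] = {}
    for ph in PHASES:
        grid = volume.phases[ph]
        avt_by_variant = {}
        for variant, roi_list in ((1, roi1_list), (2, roi2_list)):
            readings = []
            for roi in roi_list:
                for s in range(roi.slice_index - cfg.adjacent_slices,
                               roi.slice_index + cfg.adjacent_slices + 1):
                    if not (0 <= s < nz):
                        continue
                    base = _read(grid, roi.with_slice(s, phase=ph)).mean_hu
                    for _ in range(cfg.repeats):
                        for _ in range(cfg.n_observers):
                            readings.append(base + _noise())
            avt_by_variant[variant] = _grand_mean(readings)
        avt3_readings, hdt_readings = [], []
        for _ in range(cfg.roi3_repeats):
            for _ in range(cfg.n_observers):
                m = _read(grid, roi3.with_slice(roi3.slice_index, phase=ph))
                avt3_readings.append(m.mean_hu + _noise())
                hdt_readings.append(max(m.sd_hu + _noise(), 0.0))
        avc_readings = []
        for _ in range(cfg.repeats):
            for _ in range(cfg.n_observers):
                avc_readings.append(
                    _read(grid, cortex_roi.with_slice(
                        cortex_roi.slice_index, phase=ph)).mean_hu + _noise())
        hdp_readings = []
        for _ in range(cfg.roi3_repeats):
            for _ in range(cfg.n_observers):
                m = _read(grid, psoas_roi.with_slice(psoas_roi.slice_index,
                                                     phase=ph))
                hdp_readings.append(max(m.sd_hu + _noise(), 0.0))
        phase_meas[ph] = PhaseMeasurement(
            avt_roi1=avt_by_variant[1], avt_roi2=avt_by_variant[2],
            avt_roi3=_grand_mean(avt3_readings), avc=_grand_mean(avc_readings),
            hdt=_grand_mean(hdt_readings), hdp=_grand_mean(hdp_readings))

    record = QuantRecord(lesion_id=lesion_id, label=label, phases=phase_meas)
    return ProtocolResult(
        record=record,
        geometries={"roi1": roi1_list, "roi2": roi2_list, "roi3": roi3,
                    "cortex": cortex_roi, "psoas": psoas_roi},
        n_regions=len(patches))
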