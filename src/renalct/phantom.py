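"""Synthetic cohorts and four-phase CT lesion phantoms.

Two generators with a shared calibration:

* :func:`simulate_cohort` draws a *tabular* cohort — demographics, morphology
  flags and every quantitative ROI parameter — from published per-class
  marginal means/SDs and categorical frequencies of a reference cohort of
  74 ccRCC and 31 fat-poor AML (AML.wovf) lesions. Quantitative columns are
  drawn from (optionally equicorrelated) normal marginals, so derived-ratio
  columns are not arithmetically linked to their inputs in this path; the
  voxel path below produces internally consistent records.

* :func:`simulate_lesion_volume` builds a *voxel* phantom: four co-registered
  HU grids (pre-contrast PCP, corticomedullary CMP, nephrographic NP,
  excretory EP) containing a spherical tumor with optional enhancement
  patches (compact bright blobs near the margin), thin curvilinear vessels,
  non-enhancing cysts and a hypoattenuating pseudocapsule rim, plus
  homogeneous renal-cortex and psoas reference regions, with ground-truth
  masks for every structure. The intensity model is deliberately simple —
  piecewise-constant tissue HU plus i.i.d. Gaussian noise — because the
  heterogeneity metric downstream is a within-ROI SD.

A single integer seed governs all draws; per-lesion sub-seeds are spawned
deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .metrics import ENHANCED_PHASES, PHASES

__all__ = [
    "CohortConfig",
    "LesionSpec",
    "FourPhaseVolume",
    "simulate_cohort",
    "simulate_lesion_volume",
    "simulate_observer_measurements",
    "lesion_spec_for_class",
    "generate_lesions",
    "PUBLISHED_QUANT",
    "PUBLISHED_FREQ",
    "PUBLISHED_N",
]

CLASSES = ("ccRCC", "AML.wovf")
PUBLISHED_N = {"ccRCC": 74, "AML.wovf": 31}

#: Published per-class (mean, SD) of each quantitative column,
#: keyed ``column -> {class: (mean, sd)}``. HU for AVT/NEV/HDT, % for
#: RER/SHR, years for age, cm for size.
PUBLISHED_QUANT: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"ccRCC": (54.61, 11.44), "AML.wovf": (51.00, 10.71)},
    "size_cm": {"ccRCC": (2.80, 0.71), "AML.wovf": (2.70, 0.62)},
    # pre-contrast phase
    "AVT_PCP_1": {"ccRCC": (32.78, 6.50), "AML.wovf": (38.33, 5.47)},
    "AVT_PCP_2": {"ccRCC": (34.73, 6.08), "AML.wovf": (40.17, 6.43)},
    "AVT_PCP_3": {"ccRCC": (30.28, 5.78), "AML.wovf": (32.72, 9.18)},
    "HDT_PCP": {"ccRCC": (11.60, 2.42), "AML.wovf": (12.78, 4.91)},
    "SHR_PCP": {"ccRCC": (150.12, 38.98), "AML.wovf": (166.87, 60.86)},
    # corticomedullary phase
    "AVT_CMP_1": {"ccRCC": (166.15, 40.61), "AML.wovf": (147.58, 27.16)},
    "NEV_CMP_1": {"ccRCC": (133.37, 40.30), "AML.wovf": (108.94, 28.39)},
    "RER_CMP_1": {"ccRCC": (88.22, 19.03), "AML.wovf": (76.23, 14.59)},
    "AVT_CMP_2": {"ccRCC": (216.91, 43.87), "AML.wovf": (181.18, 32.67)},
    "NEV_CMP_2": {"ccRCC": (182.31, 45.15), "AML.wovf": (140.68, 33.75)},
    "RER_CMP_2": {"ccRCC": (116.21, 17.48), "AML.wovf": (89.39, 14.48)},
    "AVT_CMP_3": {"ccRCC": (127.99, 41.55), "AML.wovf": (115.54, 31.79)},
    "NEV_CMP_3": {"ccRCC": (95.47, 34.12), "AML.wovf": (85.40, 29.43)},
    "RER_CMP_3": {"ccRCC": (66.85, 19.44), "AML.wovf": (60.75, 14.96)},
    "HDT_CMP": {"ccRCC": (39.58, 8.38), "AML.wovf": (29.04, 6.92)},
    "SHR_CMP": {"ccRCC": (412.11, 116.92), "AML.wovf": (290.53, 85.78)},
    # nephrographic phase
    "AVT_NP_1": {"ccRCC": (108.05, 22.28), "AML.wovf": (108.77, 21.26)},
    "NEV_NP_1": {"ccRCC": (75.27, 22.51), "AML.wovf": (70.13, 21.61)},
    "RER_NP_1": {"ccRCC": (72.84, 12.38), "AML.wovf": (67.16, 7.94)},
    "AVT_NP_2": {"ccRCC": (129.11, 24.69), "AML.wovf": (116.90, 21.80)},
    "NEV_NP_2": {"ccRCC": (94.25, 25.98), "AML.wovf": (78.02, 26.48)},
    "RER_NP_2": {"ccRCC": (87.36, 12.75), "AML.wovf": (71.83, 8.49)},
    "AVT_NP_3": {"ccRCC": (92.89, 27.15), "AML.wovf": (93.20, 23.71)},
    "NEV_NP_3": {"ccRCC": (62.67, 25.87), "AML.wovf": (60.48, 21.26)},
    "RER_NP_3": {"ccRCC": (62.52, 17.48), "AML.wovf": (57.28, 10.16)},
    "HDT_NP": {"ccRCC": (25.03, 5.86), "AML.wovf": (20.19, 5.21)},
    "SHR_NP": {"ccRCC": (304.39, 80.20), "AML.wovf": (259.94, 64.79)},
    # excretory phase
    "AVT_EP_1": {"ccRCC": (87.56, 16.61), "AML.wovf": (87.72, 12.03)},
    "NEV_EP_1": {"ccRCC": (54.77, 17.10), "AML.wovf": (49.07, 13.18)},
    "RER_EP_1": {"ccRCC": (63.73, 9.27), "AML.wovf": (60.52, 10.64)},
    "AVT_EP_2": {"ccRCC": (101.46, 18.53), "AML.wovf": (97.05, 14.63)},
    "NEV_EP_2": {"ccRCC": (66.86, 19.54), "AML.wovf": (56.56, 18.08)},
    "RER_EP_2": {"ccRCC": (73.95, 10.30), "AML.wovf": (65.74, 11.32)},
    "AVT_EP_3": {"ccRCC": (80.49, 17.99), "AML.wovf": (78.64, 19.51)},
    "NEV_EP_3": {"ccRCC": (50.67, 17.70), "AML.wovf": (45.92, 16.21)},
    "RER_EP_3": {"ccRCC": (57.88, 11.35), "AML.wovf": (53.85, 11.32)},
    "HDT_EP": {"ccRCC": (19.79, 4.72), "AML.wovf": (16.00, 4.40)},
    "SHR_EP": {"ccRCC": (247.34, 66.58), "AML.wovf": (204.87, 54.68)},
}

#: Published per-class frequencies of the categorical variables,
#: expressed as the probability of the first level listed.
PUBLISHED_FREQ: dict[str, dict] = {
    "gender": {"levels": ("male", "female"),
               "p": {"ccRCC": 48 / 74, "AML.wovf": 7 / 31}},
    "location": {"levels": ("left", "right"),
                 "p": {"ccRCC": 37 / 74, "AML.wovf": 17 / 31}},
    "growth_pattern": {"levels": ("endophytic", "exophytic"),
                       "p": {"ccRCC": 42 / 74, "AML.wovf": 12 / 31}},
    "pseudocapsule": {"levels": (1, 0),
                      "p": {"ccRCC": 25 / 74, "AML.wovf": 2 / 31}},
    "cystic": {"levels": (1, 0),
               "p": {"ccRCC": 36 / 74, "AML.wovf": 6 / 31}},
    "angular": {"levels": (1, 0),
                "p": {"ccRCC": 9 / 74, "AML.wovf": 13 / 31}},
}

#: Homogeneous reference-tissue HU per phase (renal cortex back-solved from
#: the published AVT/RER relation; psoas muscle flat across phases).
DEFAULT_CORTEX_HU = {"PCP": 32.0, "CMP": 188.3, "NP": 148.3, "EP": 137.4}
DEFAULT_PSOAS_HU = 50.0
#: Per-phase image noise SD (HU), calibrated so the psoas SD reproduces the
#: published heterogeneity denominators (HDP = SHR back-solved from HDT).
DEFAULT_IMAGE_NOISE = {"PCP": 7.7, "CMP": 9.6, "NP": 8.2, "EP": 8.0}
BACKGROUND_HU = -80.0
CYST_HU = 12.0
CAPSULE_HU = 15.0
VESSEL_HU = {"PCP": 45.0, "CMP": 250.0, "NP": 160.0, "EP": 110.0}
#: Fraction of the CMP patch contrast persisting in later phases.
PATCH_PHASE_SCALE = {"PCP": 0.0, "CMP": 1.0, "NP": 0.4, "EP": 0.25}

DEFAULT_SPACING = (1.0, 0.7, 0.7)  # (slice thickness, row, col) mm
MAX_DIAMETER_MM = 40.0  # inclusion rule: small renal tumors only


@dataclass
class CohortConfig:
    """Calibration of the tabular cohort simulator.

    ``quant`` maps column -> class -> (mean, sd); ``freq`` maps categorical
    column -> {"levels": (first, second), "p": {class: P(first level)}}.
    ``correlation`` is a single equicorrelation level shared by all pairs of
    quantitative features within a lesion (published calibration gives
    marginals only, hence the default 0).
    """

    n_ccrcc: int = PUBLISHED_N["ccRCC"]
    n_aml: int = PUBLISHED_N["AML.wovf"]
    quant: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in PUBLISHED_QUANT.items()})
    freq: dict = field(default_factory=lambda: {
        k: {"levels": v["levels"], "p": dict(v["p"])}
        for k, v in PUBLISHED_FREQ.items()})
    correlation: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_ccrcc <= 0 or self.n_aml <= 0:
            raise ValueError("class sizes must be positive")
        if not (0.0 <= self.correlation < 1.0):
            raise ValueError("correlation must lie in [0, 1)")
        for col, per_class in self.quant.items():
            for cls, (_, sd) in per_class.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {col}/{cls}")
        for col, spec in self.freq.items():
            for cls, p in spec["p"].items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"frequency outside [0, 1] for {col}/{cls}")


def _correlated_normals(rng: np.random.Generator, n: int, p: int,
                        rho: float) -> np.ndarray:
    """n x p standard normals with equicorrelation rho (rho in [0, 1))."""
    z = rng.standard_normal((n, p))
    if rho == 0.0 or p == 1:
        return z
    shared = rng.standard_normal((n, 1))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * z


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a tabular lesion cohort from the configured calibration.

    Returns one row per lesion with demographics, morphology flags and all
    quantitative columns; deterministic under a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    quant_cols = list(config.quant)
    frames = []
    offset = 0
    for cls, n in (("ccRCC", config.n_ccrcc), ("AML.wovf", config.n_aml)):
        z = _correlated_normals(rng, n, len(quant_cols), config.correlation)
        data = {"lesion_id": [f"L{offset + i + 1:03d}" for i in range(n)],
                "label": cls}
        for j, col in enumerate(quant_cols):
            mean, sd = config.quant[col][cls]
            data[col] = mean + sd * z[:, j]
        for col, spec in config.freq.items():
            first, second = spec["levels"]
            take_first = rng.random(n) < spec["p"][cls]
            values = np.where(take_first, first, second)
            if isinstance(first, int):
                values = values.astype(int)
            data[col] = values
        frames.append(pd.DataFrame(data))
        offset += n
    df = pd.concat(frames, ignore_index=True)
    front = ["lesion_id", "label", "age", "size_cm"] + list(config.freq)
    return df[front + [c for c in df.columns if c not in front]]


@dataclass
class LesionSpec:
    """Geometry and intensity parameters of one voxel lesion phantom."""

    label: str = "ccRCC"
    diameter_mm: float = 25.0
    #: homogeneous tumor HU per phase (before structures and noise)
    phase_hu: dict[str, float] = field(default_factory=lambda: {
        "PCP": 30.0, "CMP": 128.0, "NP": 93.0, "EP": 80.0})
    n_patches: int = 3
    patch_radius_mm: float = 2.5
    patch_contrast_hu: float = 85.0
    n_vessels: int = 1
    cyst_fraction: float = 0.0
    pseudocapsule: bool = False
    #: per-phase global image noise SD (HU); scalar broadcasts to all phases
    noise_sd: float | dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IMAGE_NOISE))
    #: extra textural noise inside the tumor, per phase (HU)
    tumor_noise_sd: float | dict[str, float] = 0.0
    cortex_hu: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CORTEX_HU))
    psoas_hu: float = DEFAULT_PSOAS_HU

    def noise(self, phase: str) -> float:
        s = self.noise_sd
        return float(s[phase]) if isinstance(s, dict) else float(s)

    def tumor_noise(self, phase: str) -> float:
        s = self.tumor_noise_sd
        return float(s[phase]) if isinstance(s, dict) else float(s)

    def validate(self) -> None:
        if not (0.0 < self.diameter_mm <= MAX_DIAMETER_MM):
            raise ValueError(
                f"tumor diameter must be in (0, {MAX_DIAMETER_MM}] mm")
        if not (0.0 <= self.cyst_fraction < 1.0):
            raise ValueError("cyst fraction must lie in [0, 1)")
        for ph in PHASES:
            if self.noise(ph) < 0 or self.tumor_noise(ph) < 0:
                raise ValueError("noise SDs must be >= 0")


@dataclass
class FourPhaseVolume:
    """Co-registered four-phase HU grids with ground-truth masks.

    ``phases`` maps phase label -> (nz, ny, nx) float array; ``masks`` holds
    boolean arrays for tumor, patches, vessels, cysts, pseudocapsule, cortex
    and psoas, all on the same grid. ``spacing`` is (slice, row, col) in mm.
    """

    phases: dict[str, np.ndarray]
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {g.shape for g in self.phases.values()}
        shapes |= {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all grids and masks must share one shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.phases.values())).shape


def _mm_grids(shape, spacing):
    nz, ny, nx = shape
    dz, dy, dx = spacing
    z = np.arange(nz)[:, None, None] * dz
    y = np.arange(ny)[None, :, None] * dy
    x = np.arange(nx)[None, None, :] * dx
    return z, y, x


def _sphere(z, y, x, center_mm, radius_mm):
    cz, cy, cx = center_mm
    return ((z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2) <= radius_mm**2


def simulate_lesion_volume(spec: LesionSpec, seed: int | None = None,
                           shape: tuple[int, int, int] | None = None,
                           spacing: tuple[float, float, float] = DEFAULT_SPACING,
                           ) -> FourPhaseVolume:
    """Render one four-phase lesion phantom from a :class:`LesionSpec`.

    The grid is auto-sized to hold the tumor plus cortex/psoas reference
    regions unless ``shape`` is given explicitly.

    Raises
    ------
    ValueError
        If the spec is invalid or the tumor does not fit the requested shape.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    dz, dy, dx = spacing
    r = spec.diameter_mm / 2.0
    if shape is None:
        nz = int(np.ceil(2 * r / dz)) + 14
        ny = int(np.ceil(2 * r / dy)) + 30
        nx = int(np.ceil(2 * r / dx)) + 48
        shape = (nz, ny, nx)
    nz, ny, nx = shape
    extent = (nz * dz, ny * dy, nx * dx)
    if 2 * r + 6 > min(extent[0], extent[1]) or 2 * r + 20 > extent[2]:
        raise ValueError("tumor diameter exceeds the volume extent")

    z, y, x = _mm_grids(shape, spacing)
    center = (nz * dz / 2.0, ny * dy / 2.0, r + 4.0)
    tumor = _sphere(z, y, x, center, r)

    # pseudocapsule: thin hypoattenuating rim just inside the boundary
    capsule = np.zeros(shape, dtype=bool)
    if spec.pseudocapsule:
        capsule = tumor & ~_sphere(z, y, x, center, r - 1.6)
    r_inner = r - (1.6 if spec.pseudocapsule else 0.0)

    def _random_center(radial_lo, radial_hi):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        rad = rng.uniform(radial_lo, radial_hi) * r_inner
        return (center[0] + u[0] * rad,
                center[1] + u[1] * rad, center[2] + u[2] * rad)

    # cysts: non-enhancing low-HU blobs in the interior
    cysts = np.zeros(shape, dtype=bool)
    if spec.cyst_fraction > 0:
        n_cysts = 1 + int(spec.cyst_fraction > 0.15)
        rc = min(0.45 * r_inner,
                 r * (spec.cyst_fraction / n_cysts) ** (1.0 / 3.0))
        for _ in range(n_cysts):
            c = _random_center(0.0, 0.35)
            cysts |= _sphere(z, y, x, c, rc)
        cysts &= tumor

    # enhancement patches: compact blobs near the tumor margin
    patches = np.zeros(shape, dtype=bool)
    patch_centers: list[tuple[float, float, float]] = []
    attempts = 0
    while len(patch_centers) < spec.n_patches and attempts < 200:
        attempts += 1
        c = _random_center(0.45, min(0.75, (r_inner - spec.patch_radius_mm
                                            - 0.5) / max(r_inner, 1e-9)))
        if any(np.linalg.norm(np.subtract(c, p)) <
               2 * spec.patch_radius_mm + 2.0 for p in patch_centers):
            continue
        blob = _sphere(z, y, x, c, spec.patch_radius_mm)
        if np.any(blob & cysts):
            continue
        patch_centers.append(c)
        patches |= blob
    patches &= tumor & ~cysts

    # vessels: thin arc-shaped tubes in the equatorial slab
    vessels = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_vessels):
        theta0 = rng.uniform(0, 2 * np.pi)
        span = rng.uniform(np.pi / 2, 5 * np.pi / 6)
        arc_r = 0.55 * r_inner
        zi = int(round(center[0] / dz + rng.integers(-2, 3)))
        for theta in np.arange(theta0, theta0 + span, 0.25 / max(arc_r, 1.0)):
            yi = int(round((center[1] + arc_r * np.sin(theta)) / dy))
            xi = int(round((center[2] + arc_r * np.cos(theta)) / dx))
            if 0 <= zi < nz and 0 <= yi < ny and 0 <= xi < nx:
                vessels[zi, max(yi - 1, 0):yi + 1, max(xi - 1, 0):xi + 1] = True
    vessels &= tumor & ~cysts & ~patches

    capsule &= ~(vessels | patches | cysts)

    # reference tissues outside the tumor
    cortex = np.zeros(shape, dtype=bool)
    x0 = center[2] + r + 5.0
    cortex[(z > center[0] - 12) & (z < center[0] + 12)
           & (y > center[1] - 15) & (y < center[1] + 15)
           & (x > x0) & (x < x0 + 9)] = True
    psoas = np.zeros(shape, dtype=bool)
    psoas[((y - (center[1])) ** 2 + (x - (x0 + 16)) ** 2 < 8.0**2)
          & (z > 1) & (z < nz * dz - 1)] = True
    psoas &= ~cortex

    grids: dict[str, np.ndarray] = {}
    for ph in PHASES:
        g = np.full(shape, BACKGROUND_HU, dtype=np.float64)
        g[psoas] = spec.psoas_hu
        g[cortex] = spec.cortex_hu[ph]
        g[tumor] = spec.phase_hu[ph]
        g[capsule] = CAPSULE_HU
        g[vessels] = VESSEL_HU[ph]
        g[patches] = (spec.phase_hu[ph]
                      + PATCH_PHASE_SCALE[ph] * spec.patch_contrast_hu)
        g[cysts] = CYST_HU
        sd = spec.noise(ph)
        if sd > 0:
            g += rng.normal(0.0, sd, size=shape)
        tsd = spec.tumor_noise(ph)
        if tsd > 0:
            g[tumor] += rng.normal(0.0, tsd, size=int(tumor.sum()))
        grids[ph] = g

    masks = {"tumor": tumor, "patches": patches, "vessels": vessels,
             "cysts": cysts, "pseudocapsule": capsule, "cortex": cortex,
             "psoas": psoas}
    return FourPhaseVolume(phases=grids, spacing=spacing, masks=masks)


def simulate_observer_measurements(truth: pd.DataFrame, noise_sd: float,
                                   n_observers: int = 2, n_repeats: int = 1,
                                   seed: int | None = None) -> pd.DataFrame:
    """Per-observer, per-repeat perturbed copies of true lesion measurements.

    ``truth`` is a lesions x features table (index = lesion id). Returns a
    long table with columns lesion_id, observer, repeat, feature, value,
    where value = truth + N(0, noise_sd), for ICC-style agreement studies.

    Raises
    ------
    ValueError
        If ``noise_sd < 0`` or fewer than 2 observers are requested.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_observers < 2:
        raise ValueError("agreement studies need >= 2 observers")
    rng = np.random.default_rng(seed)
    rows = []
    for obs in range(1, n_observers + 1):
        for rep in range(1, n_repeats + 1):
            noise = rng.normal(0.0, noise_sd, size=truth.shape)
            perturbed = truth.to_numpy(dtype=float) + noise
            for i, lesion in enumerate(truth.index):
                for j, feat in enumerate(truth.columns):
                    rows.append((lesion, obs, rep, feat, perturbed[i, j]))
    return pd.DataFrame(rows, columns=["lesion_id", "observer", "repeat",
                                       "feature", "value"])


def lesion_spec_for_class(label: str, rng: np.random.Generator,
                          heterogeneity: bool = True) -> LesionSpec:
    """Draw a voxel-phantom spec calibrated to one lesion class.

    Whole-tumor base HU per phase follows the published whole-tumor-ROI
    attenuation marginals of the class; structural heterogeneity (patch
    count/contrast, cysts, pseudocapsule) is stronger for ccRCC, matching
    its higher measured SD. With ``heterogeneity=False`` the lesion is a
    homogeneous noisy sphere (useful for parameter-recovery checks).
    """
    if label not in CLASSES:
        raise ValueError(f"unknown class {label!r}")
    mean_d, sd_d = (28.0, 7.1) if label == "ccRCC" else (27.0, 6.2)
    diameter = float(np.clip(rng.normal(mean_d, sd_d), 16.0, MAX_DIAMETER_MM))
    phase_hu = {}
    for ph in PHASES:
        m, s = PUBLISHED_QUANT[f"AVT_{ph}_3"][label]
        phase_hu[ph] = float(rng.normal(m, s))
    tumor_noise = {}
    for ph in PHASES:
        hdt_m, hdt_s = PUBLISHED_QUANT[f"HDT_{ph}"][label]
        target = max(rng.normal(hdt_m, hdt_s), DEFAULT_IMAGE_NOISE[ph] + 0.5)
        if heterogeneity and ph in ENHANCED_PHASES:
            # structures (patches, vessels, cysts) carry about half of the
            # enhanced-phase heterogeneity; unstructured texture the rest
            target *= 0.5
        tumor_noise[ph] = float(
            np.sqrt(max(target**2 - DEFAULT_IMAGE_NOISE[ph] ** 2, 0.25)))
    if not heterogeneity:
        return LesionSpec(label=label, diameter_mm=diameter,
                          phase_hu=phase_hu, n_patches=0, n_vessels=0,
                          cyst_fraction=0.0, pseudocapsule=False,
                          tumor_noise_sd=tumor_noise)
    if label == "ccRCC":
        contrast = float(np.clip(rng.normal(85.0, 15.0), 40.0, None))
        cystic = rng.random() < PUBLISHED_FREQ["cystic"]["p"]["ccRCC"]
        cyst_fraction = float(rng.uniform(0.08, 0.25)) if cystic else 0.0
        capsule = rng.random() < PUBLISHED_FREQ["pseudocapsule"]["p"]["ccRCC"]
        n_patches = int(rng.integers(2, 5))
    else:
        contrast = float(np.clip(rng.normal(45.0, 10.0), 20.0, None))
        cystic = rng.random() < PUBLISHED_FREQ["cystic"]["p"]["AML.wovf"]
        cyst_fraction = float(rng.uniform(0.05, 0.12)) if cystic else 0.0
        capsule = rng.random() < PUBLISHED_FREQ["pseudocapsule"]["p"]["AML.wovf"]
        n_patches = int(rng.integers(1, 3))
    return LesionSpec(label=label, diameter_mm=diameter, phase_hu=phase_hu,
                      n_patches=n_patches, patch_contrast_hu=contrast,
                      n_vessels=1, cyst_fraction=cyst_fraction,
                      pseudocapsule=capsule, tumor_noise_sd=tumor_noise)


def generate_lesions(n_ccrcc: int, n_aml: int, seed: int = 0,
                     heterogeneity: bool = True):
    """Yield ``(lesion_id, label, spec, volume)`` for a phantom cohort.

    One seed sequence governs the whole cohort; each lesion gets a spawned
    child seed, so cohorts are reproducible and lesions independent.
    """
    ss = np.random.SeedSequence(seed)
    labels = ["ccRCC"] * n_ccrcc + ["AML.wovf"] * n_aml
    children = ss.spawn(len(labels))
    for i, (label, child) in enumerate(zip(labels, children)):
        rng = np.random.default_rng(child)
        spec = lesion_spec_for_class(label, rng, heterogeneity=heterogeneity)
        vol = simulate_lesion_volume(spec, seed=child.spawn(1)[0])
        yield f"P{i + 1:03d}", label, spec, vol
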