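"""File round-tripping: NIfTI phantom volumes, CSV lesion tables, JSON configs.

Volumes are written as one NIfTI file per phase plus a single
integer-labeled companion NIfTI for the ground-truth masks and a JSON
sidecar (spacing, axis order, label map). Interior structures are disjoint
subsets of the tumor by construction, so the labeled volume round-trips the
mask dictionary losslessly: higher label numbers take priority and the
tumor mask is recovered as the union of tumor-interior labels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import FourPhaseVolume
from .metrics import PHASES

__all__ = [
    "LABEL_MAP",
    "RunConfig",
    "SchemaError",
    "write_volume",
    "read_volume",
    "write_cohort",
    "read_cohort",
    "get_run_logger",
]

#: Mask label encoding; later entries overwrite earlier ones when painting.
LABEL_MAP = {"tumor": 1, "pseudocapsule": 2, "vessels": 3, "patches": 4,
             "cysts": 5, "cortex": 6, "psoas": 7}
#: Labels whose union reconstructs the tumor mask.
TUMOR_LABELS = (1, 2, 3, 4, 5)


class SchemaError(ValueError):
    """A table or config file does not match the expected schema."""


def _affine(spacing) -> np.ndarray:
    dz, dy, dx = spacing
    return np.diag([dz, dy, dx, 1.0])


def write_volume(volume: FourPhaseVolume, outdir, stem: str) -> None:
    """Write a four-phase volume as per-phase NIfTI + labeled mask + sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = _affine(volume.spacing)
    for ph, grid in volume.phases.items():
        nib.save(nib.Nifti1Image(grid.astype(np.float32), aff),
                 outdir / f"{stem}_{ph}.nii")
    labels = np.zeros(volume.shape, dtype=np.int16)
    for name, lab in LABEL_MAP.items():
        if name in volume.masks:
            labels[volume.masks[name]] = lab
    nib.save(nib.Nifti1Image(labels, aff), outdir / f"{stem}_labels.nii")
    meta = {"stem": stem, "spacing_mm": list(volume.spacing),
            "axis_order": "slice,row,col", "phases": list(volume.phases),
            "label_map": LABEL_MAP}
    (outdir / f"{stem}_meta.json").write_text(json.dumps(meta, indent=2))


def read_volume(outdir, stem: str) -> FourPhaseVolume:
    """Read a volume written by :func:`write_volume`."""
    outdir = Path(outdir)
    meta = json.loads((outdir / f"{stem}_meta.json").read_text())
    spacing = tuple(meta["spacing_mm"])
    phases = {}
    for ph in meta["phases"]:
        img = nib.load(outdir / f"{stem}_{ph}.nii")
        phases[ph] = np.asarray(img.dataobj, dtype=np.float64)
    labels = np.asarray(nib.load(outdir / f"{stem}_labels.nii").dataobj)
    masks = {"tumor": np.isin(labels, TUMOR_LABELS)}
    for name, lab in meta["label_map"].items():
        if name != "tumor":
            masks[name] = labels == lab
    return FourPhaseVolume(phases=phases, spacing=spacing, masks=masks)


REQUIRED_COLUMNS = ("lesion_id", "label")
VALID_LABELS = ("ccRCC", "AML.wovf")


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a lesion table as UTF-8 comma-separated CSV with header."""
    _validate_cohort(table)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and schema-check a lesion table CSV.

    Raises
    ------
    SchemaError
        On missing required columns, duplicate ids or unknown class labels.
    """
    try:
        table = pd.read_csv(path)
    except Exception as err:  # malformed CSV
        raise SchemaError(f"cannot parse CSV {path}: {err}") from err
    _validate_cohort(table)
    return table


def _validate_cohort(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"lesion table missing required columns: {missing}")
    if table["lesion_id"].duplicated().any():
        dupes = table.loc[table["lesion_id"].duplicated(), "lesion_id"]
        raise SchemaError(f"duplicate lesion ids: {sorted(set(dupes))}")
    bad = set(table["label"].dropna().unique()) - set(VALID_LABELS)
    if bad:
        raise SchemaError(f"unknown class labels: {sorted(bad)}")


@dataclass
class RunConfig:
    """Seeds and parameters of one pipeline run (JSON round-trippable)."""

    seed: int = 0
    n_ccrcc: int = 74
    n_aml: int = 31
    correlation: float = 0.0
    alpha: float = 0.05
    phases: list[str] = field(default_factory=lambda: list(PHASES))
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        try:
            data = json.loads(Path(path).read_text())
        except json.JSONDecodeError as err:
            raise SchemaError(f"malformed config JSON {path}: {err}") from err
        return cls(**data)


def get_run_logger(path=None, name: str = "renalct") -> logging.Logger:
    """Plain-text run logger recording placement and dispatch decisions."""
    logger = logging.getLogger(name)
    logger.setLevel(logging.INFO)
    if path is not None:
        handler = logging.FileHandler(path, mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        logger.addHandler(handler)
    return logger
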