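"""Derived quantitative parameters of contrast-enhanced renal CT.

Raw per-lesion inputs are mean/SD attenuation values (Hounsfield units, HU)
measured with three ROI protocols across the four scan phases — pre-contrast
(PCP), corticomedullary (CMP), nephrographic (NP) and excretory (EP):

* ``AVT`` — mean attenuation of the tumor within an ROI,
* ``AVC`` — mean attenuation of adjacent, homogeneously enhancing renal cortex,
* ``HDT`` / ``HDP`` — heterogeneity of tumor / psoas, the within-ROI SD of
  attenuation under the whole-tumor ROI (ROI 3) / a psoas ROI.

From these the derived parameters are

* ``NEV = AVT_phase − AVT_PCP`` (net enhancement value, HU; enhanced phases),
* ``RER = AVT / AVC × 100`` (relative enhancement ratio, %),
* ``SHR = HDT / HDP × 100`` (standardized heterogeneous ratio, %).

``assemble_quant_table`` flattens per-lesion records into the analysis table
whose column names (``AVT_CMP_2``, ``RER_NP_2``, ``SHR_CMP``, ...) are used
throughout the statistics and modeling modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Scan phase order.
PHASES = ("PCP", "CMP", "NP", "EP")
#: Post-contrast phases for which NEV/RER are defined.
ENHANCED_PHASES = ("CMP", "NP", "EP")
#: ROI protocol variants: 1 = small (50–100 mm²), 2 = smaller (10–20 mm²),
#: 3 = whole-tumor (edge 2–3 mm inside the tumor boundary).
ROI_VARIANTS = (1, 2, 3)


def compute_nev(avt_enhanced: float, avt_pcp: float) -> float:
    """Net enhancement value: enhanced-phase AVT minus pre-contrast AVT (HU).

    Negative values are allowed and signal de-enhancement.
    """
    return np.subtract(avt_enhanced, avt_pcp)


def compute_rer(avt: float, avc: float) -> float:
    """Relative enhancement ratio: AVT / AVC x 100 (percent).

    Raises
    ------
    ZeroDivisionError
        If the cortex attenuation ``avc`` is zero.
    """
    if np.any(np.asarray(avc) == 0):
        raise ZeroDivisionError("cortex attenuation (AVC) is zero; RER undefined")
    return np.divide(avt, avc) * 100.0


def compute_shr(hdt: float, hdp: float) -> float:
    """Standardized heterogeneous ratio: HDT / HDP x 100 (percent).

    Psoas SD (``hdp``) standardizes the tumor SD against image noise.

    Raises
    ------
    ZeroDivisionError
        If the psoas SD ``hdp`` is zero.
    """
    if np.any(np.asarray(hdp) == 0):
        raise ZeroDivisionError("psoas SD (HDP) is zero; SHR undefined")
    return np.divide(hdt, hdp) * 100.0


@dataclass
class PhaseMeasurement:
    """Raw ROI measurements of one lesion in one phase (all HU)."""

    avt_roi1: float
    avt_roi2: float
    avt_roi3: float
    avc: float
    hdt: float
    hdp: float

    def avt(self, variant: int) -> float:
        return {1: self.avt_roi1, 2: self.avt_roi2, 3: self.avt_roi3}[variant]


@dataclass
class QuantRecord:
    """Per-lesion raw measurements across phases, plus derived parameters.

    ``phases`` maps a phase label to its :class:`PhaseMeasurement`; a lesion
    with fewer than the four phases is flagged incomplete when assembled
    (mirroring the exclusion of incomplete four-phase exams).
    """

    lesion_id: str
    label: str | None = None
    phases: dict[str, PhaseMeasurement] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return all(ph in self.phases for ph in PHASES)

    def derived_columns(self, ndigits: int | None = None) -> dict[str, float]:
        """Flatten to the analysis-table columns.

        Ratio parameters (RER, SHR) are optionally rounded to ``ndigits``
        for presentation output; pass ``None`` to keep full precision.
        """
        cols: dict[str, float] = {}

        def _r(x: float) -> float:
            return round(x, ndigits) if ndigits is not None else x

        for ph, m in self.phases.items():
            for k in ROI_VARIANTS:
                cols[f"AVT_{ph}_{k}"] = m.avt(k)
            cols[f"AVC_{ph}"] = m.avc
            cols[f"HDT_{ph}"] = m.hdt
            cols[f"HDP_{ph}"] = m.hdp
            cols[f"SHR_{ph}"] = _r(compute_shr(m.hdt, m.hdp))
        pcp = self.phases.get("PCP")
        for ph in ENHANCED_PHASES:
            m = self.phases.get(ph)
            if m is None:
                continue
            for k in ROI_VARIANTS:
                if pcp is not None:
                    cols[f"NEV_{ph}_{k}"] = compute_nev(m.avt(k), pcp.avt(k))
                cols[f"RER_{ph}_{k}"] = _r(compute_rer(m.avt(k), m.avc))
        return cols


def assemble_quant_table(
    records: list[QuantRecord], ndigits: int | None = 2
) -> pd.DataFrame:
    """Assemble per-lesion records into one analysis table.

    One row per lesion; lesions missing any of the four phases keep their
    available columns but are flagged ``complete=False``.

    Raises
    ------
    ValueError
        On duplicate lesion identifiers.
    """
    ids = [r.lesion_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate lesion identifiers: {dupes}")
    rows = []
    for r in records:
        row: dict[str, object] = {"lesion_id": r.lesion_id, "label": r.label,
                                  "complete": r.complete}
        row.update(r.derived_columns(ndigits=ndigits))
        rows.append(row)
    return pd.DataFrame(rows)
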