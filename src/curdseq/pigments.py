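"""Spectrophotometric chlorophyll quantification (MacKinney coefficients).

Chlorophyll a and b concentrations in an 80% acetone extract are linear in
the absorbances at 645 and 663 nm:

    chl_a = 12.7 * OD663 - 2.69 * OD645      (μg/mL)
    chl_b = 22.9 * OD645 - 4.48 * OD663      (μg/mL)

Per-fresh-weight values scale the extract concentrations by the extraction
geometry (extract volume over tissue mass), 1 mL per 50 mg by default,
i.e. a factor of 20 (μg/mL → μg/g FW).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

# rows: (chl_a, chl_b); columns: (OD645, OD663)
MACKINNEY = np.array([[-2.69, 12.7], [22.9, -4.48]])


@dataclass(frozen=True)
class PigmentResult:
    """Chlorophyll content derived from one pair of OD readings."""

    chl_a_extract: float  # μg/mL in the acetone extract
    chl_b_extract: float  # μg/mL
    chl_a_fw: float  # μg/g fresh weight
    chl_b_fw: float  # μg/g FW
    total_fw: float  # μg/g FW
    ratio_ab: float  # chl a / chl b; NaN when chl_b is 0
    valid: bool  # False when a computed concentration is negative


def chlorophyll_from_od(
    od645: float,
    od663: float,
    volume_ml: float = 1.0,
    mass_g: float = 0.05,
) -> PigmentResult:
    """Convert OD readings to chlorophyll content.

    A negative computed concentration means the reading pair lies outside
    the model's domain (e.g. turbidity or instrument error); the result is
    returned with ``valid=False`` rather than raising.
    """
    if od645 < 0 or od663 < 0:
        raise ValueError("OD readings must be >= 0")
    if volume_ml <= 0 or mass_g <= 0:
        raise ValueError("volume_ml and mass_g must be > 0")
    chl_a, chl_b = MACKINNEY @ np.array([od645, od663])
    scale = volume_ml / mass_g
    chl_a_fw = chl_a * scale
    chl_b_fw = chl_b * scale
    ratio = chl_a_fw / chl_b_fw if chl_b_fw > 0 else math.nan
    return PigmentResult(
        chl_a_extract=float(chl_a),
        chl_b_extract=float(chl_b),
        chl_a_fw=float(chl_a_fw),
        chl_b_fw=float(chl_b_fw),
        total_fw=float(chl_a_fw + chl_b_fw),
        ratio_ab=float(ratio),
        valid=bool(chl_a >= -1e-12 and chl_b >= -1e-12),
    )


def process_readings(readings: pd.DataFrame) -> pd.DataFrame:
    """Process a table of readings (sample_id, od645, od663[, volume_ml, mass_g])."""
    rows = []
    for _, row in readings.iterrows():
        res = chlorophyll_from_od(
            float(row["od645"]),
            float(row["od663"]),
            float(row.get("volume_ml", 1.0)),
            float(row.get("mass_g", 0.05)),
        )
        rows.append({"sample_id": row["sample_id"], **res.__dict__})
    return pd.DataFrame(rows)


def process_readings_file(path: str | Path) -> pd.DataFrame:
    return process_readings(pd.read_csv(path, sep="\t"))
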