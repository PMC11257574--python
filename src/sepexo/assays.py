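"""Quantitative beta-galactosidase activity from yeast two-hybrid ONPG assays.

Two standard liquid-assay conventions are provided: activity per mg of
protein from a cleared lysate (Amberg-style, nmol/min/mg) and culture-OD
normalized Miller-style units.  The constants are used verbatim as printed
in the protocols; no unit re-derivation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "BetaGalMeasurement",
    "beta_gal_activity_amberg",
    "beta_gal_units_miller",
    "activities_from_csv",
]


@dataclass
class BetaGalMeasurement:
    """One ONPG reaction; only the fields of the chosen method are used."""

    od420: float
    time_min: float
    extract_volume_ml: float = 1.0
    protein_mg_ml: float | None = None  # Amberg method
    od595: float | None = None  # Miller method


def beta_gal_activity_amberg(m: BetaGalMeasurement) -> float:
    """activity (nmol/min/mg) = OD420 x 1.7 / [0.0045 x protein x volume x time]."""
    if m.protein_mg_ml is None:
        raise ValueError("Amberg activity needs protein_mg_ml")
    if m.od420 < 0:
        raise ValueError("OD420 must be non-negative")
    for name, v in (
        ("protein_mg_ml", m.protein_mg_ml),
        ("extract_volume_ml", m.extract_volume_ml),
        ("time_min", m.time_min),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return m.od420 * 1.7 / (0.0045 * m.protein_mg_ml * m.extract_volume_ml * m.time_min)


def beta_gal_units_miller(
    od420: float, time_min: float, volume_ml: float, od595: float
) -> float:
    """units = 1000 x OD420 / [T x V x OD595]."""
    if od420 < 0:
        raise ValueError("OD420 must be non-negative")
    for name, v in (("time_min", time_min), ("volume_ml", volume_ml), ("od595", od595)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return 1000.0 * od420 / (time_min * volume_ml * od595)


def activities_from_csv(path_in: str | Path, path_out: str | Path) -> pd.DataFrame:
    """Append an activity column to a CSV of measurements (one per row).

    Rows with a ``protein_mg_ml`` value get Amberg activity; rows with an
    ``od595`` value get Miller units; the ``method`` column records which.
    """
    df = pd.read_csv(path_in)
    activities, methods = [], []
    for _, row in df.iterrows():
        if "protein_mg_ml" in df.columns and pd.notna(row.get("protein_mg_ml")):
            activities.append(
                beta_gal_activity_amberg(
                    BetaGalMeasurement(
                        od420=row["od420"],
                        time_min=row["time_min"],
                        extract_volume_ml=row.get("extract_volume_ml", 1.0),
                        protein_mg_ml=row["protein_mg_ml"],
                    )
                )
            )
            methods.append("amberg")
        elif "od595" in df.columns and pd.notna(row.get("od595")):
            activities.append(
                beta_gal_units_miller(
                    row["od420"], row["time_min"], row["volume_ml"], row["od595"]
                )
            )
            methods.append("miller")
        else:
            raise ValueError("row needs either protein_mg_ml or od595")
    out = df.assign(activity=activities, method=methods)
    out.to_csv(path_out, index=False)
    return out
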