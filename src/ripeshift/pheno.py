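"""Derived agronomic and biochemical metrics of the field experiment.

Anthocyanin B-ring hydroxylation classes: cyanidin and peonidin glucosides
are 3'4'-substituted (di-OH); delphinidin, petunidin and malvidin glucosides
are 3'4'5'-substituted (tri-OH).  Leaf-area metrics and the heat-exposure
statistic (hours a berry-skin logger spent strictly above a temperature
threshold) are plain arithmetic on the field tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DI_OH_ANTHOCYANINS = ("cyanidin", "peonidin")
TRI_OH_ANTHOCYANINS = ("delphinidin", "petunidin", "malvidin")


@dataclass
class AnthocyaninProfile:
    """Monoglucoside anthocyanin percentages (% of total) and total content."""

    delphinidin: float
    cyanidin: float
    petunidin: float
    peonidin: float
    malvidin: float
    total_mg_per_g: float | None = None

    def __post_init__(self) -> None:
        pcts = [self.delphinidin, self.cyanidin, self.petunidin, self.peonidin, self.malvidin]
        if any(p < 0 for p in pcts):
            raise ValueError("anthocyanin percentages must be >= 0")
        total = sum(pcts)
        if not 99.0 <= total <= 101.0:
            raise ValueError(f"anthocyanin percentages sum to {total}, outside [99, 101]")


def hydroxylation_fractions(profile: AnthocyaninProfile) -> tuple[float, float]:
    """(di-OH %, tri-OH %) of total anthocyanins.

    di-OH = cyanidin + peonidin; tri-OH = delphinidin + petunidin + malvidin.
    Their sum equals the sum of the five individual percentages.
    """
    di = profile.cyanidin + profile.peonidin
    tri = profile.delphinidin + profile.petunidin + profile.malvidin
    return di, tri


@dataclass
class LeafAreaRecord:
    """Final leaf areas per vine (m²) and yield per vine (kg)."""

    main_m2: float
    lateral_m2: float
    yield_kg: float | None = None

    def __post_init__(self) -> None:
        if self.main_m2 < 0 or self.lateral_m2 < 0:
            raise ValueError("leaf areas must be >= 0")


def total_leaf_area(record: LeafAreaRecord) -> float:
    """Total final leaf area per vine: main + lateral (m²)."""
    return record.main_m2 + record.lateral_m2


def leaf_to_fruit_ratio(record: LeafAreaRecord) -> float:
    """Leaf-area-to-yield ratio (m²/kg)."""
    if not record.yield_kg:
        raise ValueError("yield must be positive to compute the leaf-to-fruit ratio")
    return total_leaf_area(record) / record.yield_kg


def round_half_up(x: float, decimals: int = 1) -> float:
    """Table-style presentation rounding (half away from zero is not needed
    for the non-negative quantities here)."""
    factor = 10 ** decimals
    return math.floor(x * factor + 0.5) / factor


def hours_above_threshold(series: pd.DataFrame, threshold_C: float = 30.0) -> float:
    """Hours a uniformly sampled temperature series spent strictly above
    ``threshold_C``: (number of readings > threshold) x sampling interval."""
    ts = pd.to_datetime(series["timestamp"])
    if len(ts) < 2:
        raise ValueError("need >= 2 readings")
    deltas = ts.diff().dropna()
    if deltas.nunique() != 1:
        raise ValueError("temperature series is not uniformly sampled")
    interval_h = deltas.iloc[0].total_seconds() / 3600.0
    n_above = int((series["temperature_C"] > threshold_C).sum())
    return n_above * interval_h


def read_temperature_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def derived_phenotype_table(
    anthocyanins: dict[str, AnthocyaninProfile],
    leaf_areas: dict[str, LeafAreaRecord],
) -> pd.DataFrame:
    """Per-treatment derived metrics, presentation-rounded to 1 decimal
    alongside the raw values."""
    rows = []
    for treatment in sorted(set(anthocyanins) | set(leaf_areas)):
        row: dict[str, float | str] = {"treatment": treatment}
        if treatment in anthocyanins:
            di, tri = hydroxylation_fractions(anthocyanins[treatment])
            row.update(di_oh_pct=di, tri_oh_pct=tri,
                       di_oh_pct_rounded=round_half_up(di), tri_oh_pct_rounded=round_half_up(tri))
        if treatment in leaf_areas:
            rec = leaf_areas[treatment]
            total = total_leaf_area(rec)
            row.update(total_leaf_area_m2=total, total_leaf_area_m2_rounded=round_half_up(total))
            if rec.yield_kg:
                row["leaf_area_per_yield_m2_kg"] = leaf_to_fruit_ratio(rec)
        rows.append(row)
    return pd.DataFrame(rows).set_index("treatment")
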