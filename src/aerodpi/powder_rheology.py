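"""Bulk/tapped density reduction: Hausner ratio, Carr index, flowability.

The Hausner ratio HR = rho_t/rho_b and the Carr (compressibility) index
CI = (rho_t - rho_b)/rho_t * 100 are standard surrogates for powder
flowability; the two are linked exactly by HR = 1/(1 - CI/100).  The Carr
index is mapped onto the pharmacopoeial flow-character scale (USP <1174>).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DensityMeasurement",
    "hausner_ratio",
    "carr_index",
    "flowability_class",
    "reduce_replicates",
    "read_density_csv",
    "rheology_report",
    "FLOW_SCALE",
]


@dataclass(frozen=True)
class DensityMeasurement:
    """One bulk/tapped density replicate, g/cm³."""

    bulk_density: float
    tapped_density: float
    replicate_id: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.bulk_density <= self.tapped_density):
            raise ValueError(
                "require 0 < bulk <= tapped density, got "
                f"({self.bulk_density}, {self.tapped_density})"
            )


def hausner_ratio(m: DensityMeasurement) -> float:
    """Tapped-to-bulk density ratio; >= 1 for any physical powder."""
    return m.tapped_density / m.bulk_density


def carr_index(m: DensityMeasurement) -> float:
    """Compressibility index (rho_t - rho_b)/rho_t * 100, in [0, 100)."""
    return (m.tapped_density - m.bulk_density) / m.tapped_density * 100.0


# USP <1174> flow-character scale: (upper CI bound inclusive, label).
FLOW_SCALE: tuple[tuple[float, str], ...] = (
    (10.0, "excellent"),
    (15.0, "good"),
    (20.0, "fair"),
    (25.0, "passable"),
    (31.0, "poor"),
    (37.0, "very poor"),
    (np.inf, "very, very poor"),
)


def flowability_class(ci: float) -> str:
    """Map a Carr index (%) to the pharmacopoeial flow-character label.

    Boundary values are assigned to the lower (better) class.
    """
    if ci < 0:
        raise ValueError(f"Carr index must be >= 0, got {ci}")
    for upper, label in FLOW_SCALE:
        if ci <= upper:
            return label
    raise AssertionError("unreachable")


def reduce_replicates(
    measurements: list[DensityMeasurement],
    ratios_first: bool = True,
) -> dict[str, float]:
    """Aggregate replicates of one sample into mean HR, CI and densities.

    ratios_first=True computes HR/CI per replicate then averages (the
    convention that reproduces the small offsets between printed mean ratios
    and ratios of printed mean densities); False averages the densities
    first and takes a single ratio.
    """
    if not measurements:
        raise ValueError("no replicates supplied")
    rb = float(np.mean([m.bulk_density for m in measurements]))
    rt = float(np.mean([m.tapped_density for m in measurements]))
    if ratios_first:
        hr = float(np.mean([hausner_ratio(m) for m in measurements]))
        ci = float(np.mean([carr_index(m) for m in measurements]))
    else:
        pooled = DensityMeasurement(rb, rt)
        hr, ci = hausner_ratio(pooled), carr_index(pooled)
    return {
        "bulk_g_cm3": rb,
        "tapped_g_cm3": rt,
        "hausner_ratio": hr,
        "carr_index": ci,
        "flowability": flowability_class(ci),
    }


def read_density_csv(path) -> list[DensityMeasurement]:
    """Read replicates from CSV columns label,replicate,bulk_g_cm3,tapped_g_cm3."""
    df = pd.read_csv(path)
    return [
        DensityMeasurement(
            r.bulk_g_cm3, r.tapped_g_cm3, replicate_id=int(r.replicate),
            label=str(r.label),
        )
        for r in df.itertuples()
    ]


def rheology_report(
    measurements: list[DensityMeasurement], ratios_first: bool = True
) -> pd.DataFrame:
    """Per-sample flowability table (one row per label)."""
    rows = []
    labels = list(dict.fromkeys(m.label for m in measurements))
    for label in labels:
        group = [m for m in measurements if m.label == label]
        rows.append({"label": label, **reduce_replicates(group, ratios_first)})
    return pd.DataFrame(rows)
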