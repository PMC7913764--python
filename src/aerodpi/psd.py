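"""Particle-size-distribution statistics from laser-diffraction quantiles.

Laser diffraction reports a volume-weighted size distribution summarized by
the quantiles D[0.1], D[0.5] (volume median) and D[0.9].  The distribution
width is the Span, (D90 - D10)/D50; Span < 2 is conventionally read as a
narrow ("monodisperse") inhalation powder.  A lognormal parametric family is
provided so synthetic powders can be generated and so a specific surface
area (SSA) can be estimated from the spherical Sauter mean diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "PSDQuantiles",
    "LognormalPSD",
    "span",
    "quantiles_from_lognormal",
    "lognormal_from_quantiles",
    "sauter_mean_diameter",
    "specific_surface_area",
    "read_psd_csv",
    "psd_report",
]

_Z90 = norm.ppf(0.9)  # 1.2816


@dataclass(frozen=True)
class PSDQuantiles:
    """Volume-distribution quantiles of a powder or suspension, in µm."""

    d10: float
    d50: float
    d90: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.d10 <= self.d50 <= self.d90):
            raise ValueError(
                f"require 0 < d10 <= d50 <= d90, got "
                f"({self.d10}, {self.d50}, {self.d90})"
            )


@dataclass(frozen=True)
class LognormalPSD:
    """Lognormal volume distribution: volume-median diameter (µm) and GSD."""

    median: float
    gsd: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError(f"median must be positive, got {self.median}")
        if self.gsd < 1:
            raise ValueError(f"gsd must be >= 1, got {self.gsd}")


def span(q: PSDQuantiles) -> float:
    """Distribution width (D90 - D10)/D50; dimensionless.

    High Span denotes a broad volume size distribution.
    """
    if q.d50 == 0:
        raise ValueError("d50 must be non-zero")
    return (q.d90 - q.d10) / q.d50


def quantiles_from_lognormal(p: LognormalPSD) -> PSDQuantiles:
    """D10/D50/D90 of a lognormal volume distribution.

    d_q = median * gsd**z_q with z_q the standard-normal quantile.
    """
    ln_gsd = np.log(p.gsd)
    d10 = p.median * np.exp(-_Z90 * ln_gsd)
    d90 = p.median * np.exp(_Z90 * ln_gsd)
    return PSDQuantiles(d10=d10, d50=p.median, d90=d90, label=p.label)


def lognormal_from_quantiles(q: PSDQuantiles) -> LognormalPSD:
    """Least-squares lognormal fit to the three printed quantiles.

    The median is taken as D50; ln(gsd) is the average of the two
    symmetric-quantile estimates ln(d90/d50)/z and ln(d50/d10)/z.
    """
    ln_gsd = 0.5 * (np.log(q.d90 / q.d50) + np.log(q.d50 / q.d10)) / _Z90
    return LognormalPSD(median=q.d50, gsd=float(np.exp(max(ln_gsd, 0.0))), label=q.label)


def sauter_mean_diameter(p: LognormalPSD) -> float:
    """Sauter mean D32 (µm) of a lognormal volume distribution.

    For a volume (mass) distribution with volume-median diameter d_v50 and
    geometric SD g, Hatch–Choate gives D32 = d_v50 * exp(-0.5 * ln(g)**2):
    the count-median is d_v50*exp(-3 ln²g) and D32 = count-median
    * exp(2.5 ln²g).  Verified against numerical moment integration.
    """
    ln2 = np.log(p.gsd) ** 2
    return p.median * np.exp(-0.5 * ln2)


def specific_surface_area(p: LognormalPSD, true_density: float) -> float:
    """Volume-specific surface area (m²/g) of spheres, SSA = 6/(rho*D32).

    Parameters
    ----------
    true_density : particle (true) density in g/cm³.

    Instrument SSA values are matched only qualitatively: the instrument
    reports a surface area from the full measured distribution and an
    internal shape model, not from a three-quantile lognormal summary.
    """
    if true_density <= 0:
        raise ValueError(f"density must be positive, got {true_density}")
    d32_um = sauter_mean_diameter(p)
    # 6/(rho [g/cm3] * d [cm]) -> cm2/g; 1 m2/g = 1e4 cm2/g
    return 6.0 / (true_density * d32_um * 1e-4) / 1e4


def read_psd_csv(path) -> list[PSDQuantiles]:
    """Read quantile triples from CSV columns label,d10_um,d50_um,d90_um."""
    df = pd.read_csv(path)
    return [
        PSDQuantiles(r.d10_um, r.d50_um, r.d90_um, label=str(r.label))
        for r in df.itertuples()
    ]


def psd_report(
    quantiles: list[PSDQuantiles],
    true_density: float | None = None,
) -> pd.DataFrame:
    """Tabulate quantiles, Span and (optionally) lognormal SSA per sample."""
    rows = []
    for q in quantiles:
        row = {
            "label": q.label,
            "d10_um": q.d10,
            "d50_um": q.d50,
            "d90_um": q.d90,
            "span": span(q),
        }
        if true_density is not None:
            row["ssa_m2_g"] = specific_surface_area(
                lognormal_from_quantiles(q), true_density
            )
        rows.append(row)
    return pd.DataFrame(rows)
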