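"""Dissolution-profile reduction and diffusion-cell flux/permeability.

Dissolution: a dose is dispersed in a small vessel (default 50 mL of
simulated lung medium); at each sampling time a fixed aliquot (default
5 mL) is withdrawn and replaced with fresh medium.  The replacement dilutes
the vessel, so the cumulative released percentage uses the standard
withdrawal correction

    C_corr,n = C_n + (Vs/V) * sum_{i<n} C_i

Diffusion: in a horizontal diffusion cell the steady flux through the
membrane is J = m/(A*t) (µg/cm²/h) and the apparent permeability
coefficient Kp = J/Cd (cm/h), with Cd the donor-phase drug concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DissolutionRun",
    "DiffusionRun",
    "corrected_release_percent",
    "flux",
    "permeability_coefficient",
    "diffusion_report",
    "read_timeseries_csv",
]

DEFAULT_TIMES_MIN = (5.0, 10.0, 15.0, 30.0, 60.0)


@dataclass(frozen=True)
class DissolutionRun:
    """One paddle-dissolution time series with withdrawal bookkeeping.

    measured_conc are the concentrations (µg/mL) actually read in each
    withdrawn aliquot, i.e. after the dilution from earlier replacements.
    """

    times: tuple[float, ...] = DEFAULT_TIMES_MIN
    measured_conc: tuple[float, ...] = ()
    vessel_volume: float = 50.0
    sample_volume: float = 5.0
    dose: float = 1500.0
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(self.times))
        object.__setattr__(self, "measured_conc", tuple(self.measured_conc))
        if len(self.times) != len(self.measured_conc):
            raise ValueError("times and measured_conc must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if any(c < 0 for c in self.measured_conc):
            raise ValueError("concentrations must be non-negative")
        if not (self.vessel_volume > self.sample_volume >= 0):
            raise ValueError("require vessel_volume > sample_volume >= 0")
        if self.dose <= 0:
            raise ValueError("dose must be positive")


def corrected_release_percent(r: DissolutionRun) -> np.ndarray:
    """Cumulative released drug (% of dose) with withdrawal correction."""
    c = np.asarray(r.measured_conc, dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(c)[:-1]])
    c_corr = c + (r.sample_volume / r.vessel_volume) * csum
    return c_corr * r.vessel_volume / r.dose * 100.0


@dataclass(frozen=True)
class DiffusionRun:
    """Cumulative permeated mass (µg) through a membrane over time (min)."""

    times: tuple[float, ...]
    cumulative_mass: tuple[float, ...]
    area: float = 0.785
    donor_conc: float = 1500.0 / 9.0
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(self.times))
        object.__setattr__(self, "cumulative_mass", tuple(self.cumulative_mass))
        if len(self.times) != len(self.cumulative_mass):
            raise ValueError("times and cumulative_mass must have equal length")
        if np.any(np.diff(self.cumulative_mass) < 0):
            raise ValueError("cumulative_mass must be non-decreasing")
        if self.area <= 0:
            raise ValueError("membrane area must be positive")


def flux(m: float, area: float, duration: float) -> float:
    """Steady flux J = m/(A*t), µg/cm²/h (m in µg, A in cm², t in h)."""
    if area <= 0 or duration <= 0:
        raise ValueError("area and duration must be positive")
    return m / (area * duration)


def permeability_coefficient(J: float, donor_conc: float) -> float:
    """Apparent permeability Kp = J/Cd, cm/h (Cd in µg/cm³)."""
    if donor_conc <= 0:
        raise ValueError("donor concentration must be positive")
    return J / donor_conc


def diffusion_report(runs: list[DiffusionRun]) -> pd.DataFrame:
    """Flux over the full run and Kp per sample; flags inconsistent rows."""
    rows = []
    for r in runs:
        t_h = (r.times[-1] - r.times[0]) / 60.0 if len(r.times) > 1 else r.times[-1] / 60.0
        m = r.cumulative_mass[-1]
        J = flux(m, r.area, t_h)
        rows.append(
            {
                "label": r.label,
                "flux_ug_cm2_h": J,
                "kp_cm_h": permeability_coefficient(J, r.donor_conc),
            }
        )
    return pd.DataFrame(rows)


def read_timeseries_csv(path) -> pd.DataFrame:
    """Read a (time_min, value) two-column CSV."""
    df = pd.read_csv(path)
    if not {"time_min", "value"} <= set(df.columns):
        raise ValueError("expected columns time_min,value")
    return df
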