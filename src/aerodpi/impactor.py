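"""Andersen cascade impactor (ACI) data reduction.

An eight-stage ACI operated at 28.3 L/min classifies an inhaled aerosol by
aerodynamic diameter; the drug mass recovered from the device, capsules,
induction port (throat), stages 0-7 and the terminal filter is reduced to:

* ED  - emitted dose: everything leaving device and capsules
        (induction port + stages + filter)
* EF  - emitted fraction, ED / loaded dose * 100
* MMAD, GSD - from a probit (log-probability) regression of the cumulative
        mass fraction undersize against the log stage cut-off diameter:
        probit(F_i) = a + b*log10(d_i); MMAD = 10^(-a/b), GSD = 10^(1/b)
* FPD - fine particle dose, sized mass * fitted lognormal CDF at 5 µm
* FPF - fine particle fraction, FPD / ED * 100

The induction port has no calibrated cut-off and is excluded from the
sizing regression; it is included in the emitted dose.

`CascadeImpactorModel` wraps one run; `fit()` returns an
`AerodynamicResults` with the metrics, regression diagnostics and a
`summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ACI_CUTOFFS_28LPM",
    "STAGE_LABELS",
    "ImpactorRun",
    "AerodynamicResults",
    "CascadeImpactorModel",
    "emitted_dose",
    "emitted_fraction",
    "cumulative_undersize",
    "fit_mmad_gsd",
    "fine_particle_dose",
    "fine_particle_fraction",
    "inhaled_volume",
    "scale_cutoffs",
    "read_impactor_csv",
]

# Effective cut-off diameters (µm) at 28.3 L/min, stages 0-7 then filter.
ACI_CUTOFFS_28LPM: tuple[float, ...] = (9.0, 5.8, 4.7, 3.3, 2.1, 1.1, 0.7, 0.4, 0.0)
STAGE_LABELS: tuple[str, ...] = (
    "stage0", "stage1", "stage2", "stage3", "stage4", "stage5", "stage6",
    "stage7", "filter",
)


def scale_cutoffs(flow_rate: float, reference_flow: float = 28.3) -> tuple[float, ...]:
    """Rescale stage cut-offs to another flow rate (d50 ~ Q**-1/2)."""
    k = (reference_flow / flow_rate) ** 0.5
    return tuple(c * k for c in ACI_CUTOFFS_28LPM)


@dataclass(frozen=True)
class ImpactorRun:
    """Per-location drug masses (µg) for one ACI experiment."""

    mass_device: float
    mass_capsules: float
    mass_induction_port: float
    mass_per_stage: tuple[float, ...]  # stages 0-7 then filter
    loaded_api: float
    flow_rate: float = 28.3
    inhalation_time: float = 4.0
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "mass_per_stage", tuple(self.mass_per_stage))
        if len(self.mass_per_stage) != len(ACI_CUTOFFS_28LPM):
            raise ValueError(
                f"expected {len(ACI_CUTOFFS_28LPM)} stage masses "
                f"(stages 0-7 + filter), got {len(self.mass_per_stage)}"
            )
        masses = (self.mass_device, self.mass_capsules, self.mass_induction_port,
                  *self.mass_per_stage)
        if any(m < 0 for m in masses) or self.loaded_api < 0:
            raise ValueError("masses must be non-negative")

    @property
    def total_recovered(self) -> float:
        return (self.mass_device + self.mass_capsules + self.mass_induction_port
                + sum(self.mass_per_stage))

    @property
    def sized_mass(self) -> float:
        """Mass on calibrated stages + filter (excludes induction port)."""
        return float(sum(self.mass_per_stage))


def emitted_dose(run: ImpactorRun) -> float:
    """ED (µg): drug leaving device and capsules and reaching the impactor."""
    return run.mass_induction_port + run.sized_mass


def emitted_fraction(ed: float, loaded: float) -> float:
    """EF (%): emitted dose over loaded drug mass."""
    if loaded <= 0:
        raise ValueError("loaded dose must be positive")
    return ed / loaded * 100.0


def cumulative_undersize(run: ImpactorRun) -> list[tuple[float, float]]:
    """(cut-off µm, cumulative mass fraction below) per calibrated stage.

    The fraction at cut-off d_i is the sized mass collected on stages with
    cut-offs strictly below d_i, over the total sized mass; the filter
    (cut-off 0) anchors the distribution.  Non-decreasing in d by
    construction.
    """
    sized = run.sized_mass
    if sized <= 0:
        raise ValueError("no mass on calibrated stages")
    masses = np.asarray(run.mass_per_stage, dtype=float)
    # mass below stage i's cut-off = everything on deeper stages
    below = np.concatenate([np.cumsum(masses[::-1])[::-1][1:], [0.0]])
    return [
        (c, float(b / sized)) for c, b in zip(ACI_CUTOFFS_28LPM[:-1], below[:-1])
    ]


def fit_mmad_gsd(cum: list[tuple[float, float]]) -> tuple[float, float, dict]:
    """Probit regression of cumulative undersize on log10 cut-off.

    Points with fraction exactly 0 or 1 are dropped (probit undefined).
    Returns (MMAD µm, GSD, diagnostics dict with slope/intercept/r2/n).
    """
    pts = [(d, f) for d, f in cum if 0.0 < f < 1.0 and d > 0]
    if len(pts) < 2:
        raise ValueError("need at least 2 cumulative points strictly in (0, 1)")
    x = np.log10([d for d, _ in pts])
    y = stats.norm.ppf([f for _, f in pts])
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise ValueError("non-positive probit slope: degenerate size distribution")
    mmad = 10.0 ** (-res.intercept / res.slope)
    gsd = 10.0 ** (1.0 / res.slope)
    diag = {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "n_points": len(pts),
    }
    return float(mmad), float(gsd), diag


def fine_particle_dose(run: ImpactorRun, mmad: float, gsd: float) -> float:
    """FPD (µg): sized mass times the fitted lognormal CDF at 5.0 µm."""
    if mmad <= 0 or gsd < 1:
        raise ValueError("invalid aerodynamic fit")
    if gsd == 1.0:
        frac = 1.0 if mmad <= 5.0 else 0.0
    else:
        frac = float(stats.norm.cdf(np.log(5.0 / mmad) / np.log(gsd)))
    return run.sized_mass * frac


def fine_particle_fraction(fpd: float, ed: float) -> float:
    """FPF (%): fine particle dose over emitted dose."""
    if ed <= 0:
        raise ValueError("emitted dose must be positive")
    return fpd / ed * 100.0


def inhaled_volume(flow_rate: float, inhalation_time: float) -> float:
    """Air volume (L) drawn through the impactor: Q (L/min) * t (s) / 60."""
    if flow_rate < 0 or inhalation_time < 0:
        raise ValueError("flow and time must be non-negative")
    return flow_rate * inhalation_time / 60.0


@dataclass(frozen=True)
class AerodynamicResults:
    """Fitted aerodynamic metrics of one ACI run."""

    run: ImpactorRun
    ed: float
    ef: float
    fpd: float
    fpf: float
    mmad: float
    gsd: float
    diagnostics: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "ED_ug": self.ed,
            "EF_pct": self.ef,
            "FPD_ug": self.fpd,
            "FPF_pct": self.fpf,
            "MMAD_um": self.mmad,
            "GSD": self.gsd,
        }

    def summary(self) -> str:
        lines = [
            f"Cascade impactor reduction: {self.run.label or '(unlabelled run)'}",
            "-" * 58,
            f"  loaded API          {self.run.loaded_api:10.1f} ug",
            f"  emitted dose (ED)   {self.ed:10.1f} ug",
            f"  emitted frac (EF)   {self.ef:10.2f} %",
            f"  fine particle dose  {self.fpd:10.1f} ug  (< 5 um)",
            f"  fine particle frac  {self.fpf:10.2f} %  (FPD/ED)",
            f"  MMAD                {self.mmad:10.3f} um",
            f"  GSD                 {self.gsd:10.3f}",
            f"  probit fit          r^2 = {self.diagnostics.get('r_squared', float('nan')):.4f}, "
            f"n = {self.diagnostics.get('n_points', 0)}",
        ]
        return "\n".join(lines)


class CascadeImpactorModel:
    """One ACI run to be reduced to aerodynamic metrics.

    Examples
    --------
    >>> model = CascadeImpactorModel(run)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, run: ImpactorRun):
        self.run = run

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, loaded_api: float, **kwargs
    ) -> "CascadeImpactorModel":
        """Build from a (location, mass_ug) table.

        Locations: device, capsule, throat, stage0..stage7, filter.
        """
        m = dict(zip(df["location"].astype(str), df["mass_ug"].astype(float)))
        run = ImpactorRun(
            mass_device=m.get("device", 0.0),
            mass_capsules=m.get("capsule", 0.0),
            mass_induction_port=m.get("throat", 0.0),
            mass_per_stage=tuple(m.get(s, 0.0) for s in STAGE_LABELS),
            loaded_api=loaded_api,
            **kwargs,
        )
        return cls(run)

    def fit(self) -> AerodynamicResults:
        run = self.run
        ed = emitted_dose(run)
        ef = emitted_fraction(ed, run.loaded_api)
        cum = cumulative_undersize(run)
        mmad, gsd, diag = fit_mmad_gsd(cum)
        fpd = fine_particle_dose(run, mmad, gsd)
        fpf = fine_particle_fraction(fpd, ed)
        return AerodynamicResults(
            run=run, ed=ed, ef=ef, fpd=fpd, fpf=fpf, mmad=mmad, gsd=gsd,
            diagnostics=diag,
        )


def read_impactor_csv(path, loaded_api: float, **kwargs) -> CascadeImpactorModel:
    """Read a per-run CSV with columns location,mass_ug."""
    return CascadeImpactorModel.from_dataframe(
        pd.read_csv(path), loaded_api=loaded_api, **kwargs
    )
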