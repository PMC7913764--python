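"""Synthetic fixture generation for every stage of the pipeline.

Each generator is the forward (inverse) model of exactly one reduction in
this package, so noiseless round trips close: e.g. contact angles computed
from known surface-energy components invert back to those components, and
stage masses laid down from a lognormal APSD reduce back to the generating
MMAD/GSD.  Fixtures are emitted in the same CSV/JSON schemas the readers
consume, together with a ground-truth JSON for recovery tests.

Default parameter ranges follow the magnitudes typical of spray-dried
inhalation powders: volume medians 1-5 µm, bulk densities 0.1-0.3 g/cm³,
MMAD 1.5-2.4 µm; noise SDs default to the order of the replicate SDs such
measurements usually show.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import impactor as imp
from . import psd as psdmod
from . import solid_state
from .surface_energy import DIIODOMETHANE, WATER, SurfaceEnergy, forward_contact_angle

__all__ = ["FixtureSpec", "generate", "KINDS"]

KINDS = (
    "psd", "rheology", "contact_angles", "diffractogram", "dissolution",
    "impactor_run", "apsd",
)


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate: kind, generating parameters, noise level, seed."""

    kind: str
    parameters: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; one of {KINDS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _gen_psd(p: dict, noise: float, rng) -> tuple[pd.DataFrame, dict]:
    median = p.get("median_um", 3.8)
    gsd = p.get("gsd", 1.6)
    n_rep = p.get("replicates", 3)
    label = p.get("label", "synthetic_powder")
    q = psdmod.quantiles_from_lognormal(psdmod.LognormalPSD(median, gsd))
    rows = []
    for i in range(n_rep):
        d10, d50, d90 = np.sort(
            np.array([q.d10, q.d50, q.d90]) * np.exp(noise * rng.standard_normal(3))
        )
        rows.append(
            {"label": f"{label}_r{i}", "d10_um": d10, "d50_um": d50, "d90_um": d90}
        )
    truth = {"median_um": median, "gsd": gsd,
             "span": psdmod.span(q)}
    return pd.DataFrame(rows), truth


def _gen_rheology(p: dict, noise: float, rng) -> tuple[pd.DataFrame, dict]:
    bulk = p.get("bulk_g_cm3", 0.16)
    tapped = p.get("tapped_g_cm3", 0.27)
    n_rep = p.get("replicates", 3)
    label = p.get("label", "synthetic_powder")
    rows = []
    for i in range(n_rep):
        b = bulk * np.exp(noise * rng.standard_normal())
        t = tapped * np.exp(noise * rng.standard_normal())
        t = max(t, b)  # tapping cannot decrease density
        rows.append({"label": label, "replicate": i,
                     "bulk_g_cm3": b, "tapped_g_cm3": t})
    truth = {
        "hausner_ratio": tapped / bulk,
        "carr_index": (tapped - bulk) / tapped * 100.0,
    }
    return pd.DataFrame(rows), truth


def _gen_contact_angles(p: dict, noise: float, rng) -> tuple[pd.DataFrame, dict]:
    gsd_ = p.get("gamma_d", 42.34)
    gsp = p.get("gamma_p", 31.03)
    n_rep = p.get("replicates", 3)
    label = p.get("label", "synthetic_solid")
    energy = SurfaceEnergy(gamma_d=gsd_, gamma_p=gsp)
    rows = []
    for liquid in (WATER, DIIODOMETHANE):
        theta = forward_contact_angle(energy, liquid)
        for i in range(n_rep):
            rows.append(
                {
                    "label": label,
                    "liquid": liquid.name,
                    "theta_deg": float(np.clip(theta + noise * rng.standard_normal(),
                                               0.0, 179.9)),
                    "replicate": i,
                }
            )
    truth = {"gamma_d": gsd_, "gamma_p": gsp, **energy.as_dict()}
    return pd.DataFrame(rows), truth


def _gen_diffractogram(p: dict, noise: float, rng) -> tuple[pd.DataFrame, dict]:
    crystallinity = p.get("crystallinity_pct", 71.0)
    amplitude = p.get("amplitude", 1000.0)
    sigma = p.get("peak_sigma_deg", 0.05)
    baseline = p.get("baseline", 50.0)
    tt = np.arange(3.0, 40.0 + 1e-9, 0.010)

    def pattern(scale):
        y = np.full_like(tt, baseline)
        for c in solid_state.MX_PEAKS:
            y = y + scale * amplitude * np.exp(-0.5 * ((tt - c) / sigma) ** 2)
        return np.clip(y + noise * rng.standard_normal(tt.size), 0.0, None)

    ref = pattern(1.0)
    sample = pattern(crystallinity / 100.0)
    df = pd.DataFrame({"two_theta": tt, "reference": ref, "sample": sample})
    truth = {"crystallinity_pct": crystallinity}
    return df, truth


def _gen_dissolution(p: dict, noise: float, rng) -> tuple[pd.DataFrame, dict]:
    """First-order release sampled through the withdrawal protocol.

    True cumulative release R(t) = R_inf (1 - exp(-k t)); the measured
    aliquot concentration accounts for drug already removed by earlier
    withdrawals:  C_n = (dose*R_n/100 - sum_{i<n} Vs*C_i) / V.
    """
    k = p.get("rate_per_min", 0.12)
    r_inf = p.get("release_inf_pct", 85.0)
    times = tuple(p.get("times_min", (5.0, 10.0, 15.0, 30.0, 60.0)))
    dose = p.get("dose_ug", 1500.0)
    v = p.get("vessel_ml", 50.0)
    vs = p.get("sample_ml", 5.0)
    conc, removed = [], 0.0
    truth_release = []
    for t in times:
        r = r_inf * (1.0 - np.exp(-k * t))
        truth_release.append(r)
        c = (dose * r / 100.0 - removed) / v
        c = max(c * (1.0 + noise * rng.standard_normal()), 0.0)
        conc.append(c)
        removed += vs * c
    df = pd.DataFrame({"time_min": times, "value": conc})
    truth = {"release_pct": truth_release, "rate_per_min": k,
             "release_inf_pct": r_inf, "dose_ug": dose,
             "vessel_ml": v, "sample_ml": vs}
    return df, truth


def _gen_impactor_run(p: dict, noise: float, rng) -> tuple[pd.DataFrame, dict]:
    mmad = p.get("mmad_um", 2.0)
    gsd = p.get("gsd", 2.0)
    ed = p.get("ed_ug", 5000.0)
    throat_frac = p.get("throat_fraction", 0.15)
    device_frac = p.get("device_fraction", 0.20)
    loaded = p.get("loaded_ug", ed / (1.0 - device_frac))
    sized = ed * (1.0 - throat_frac)
    edges = np.array(imp.ACI_CUTOFFS_28LPM)  # stage0..7, filter(0)
    cdf_at = stats.norm.cdf(np.log(edges[:-1] / mmad) / np.log(gsd))
    # stage i collects mass between its own cut-off and the next larger one
    below = np.append(cdf_at, 0.0)  # CDF at each location's lower bound
    upper = np.insert(cdf_at, 0, 1.0)  # CDF at each location's upper bound
    frac = upper - below
    masses = sized * frac
    masses = np.clip(masses * np.exp(noise * rng.standard_normal(masses.size)), 0.0, None)
    rows = [
        {"location": "device", "mass_ug": loaded - ed},
        {"location": "capsule", "mass_ug": 0.0},
        {"location": "throat", "mass_ug": ed * throat_frac},
    ]
    rows += [
        {"location": loc, "mass_ug": m}
        for loc, m in zip(imp.STAGE_LABELS, masses)
    ]
    truth = {"mmad_um": mmad, "gsd": gsd, "ed_ug": ed, "loaded_ug": loaded,
             "sized_ug": float(masses.sum())}
    return pd.DataFrame(rows), truth


def _gen_apsd(p: dict, noise: float, rng) -> tuple[pd.DataFrame, dict]:
    mmad = p.get("mmad_um", 2.0) * np.exp(noise * rng.standard_normal())
    gsd = max(p.get("gsd", 2.0) * np.exp(noise * rng.standard_normal()), 1.0)
    df = pd.DataFrame([{"mmad_um": mmad, "gsd": gsd}])
    return df, {"mmad_um": float(mmad), "gsd": float(gsd)}


_GENERATORS = {
    "psd": _gen_psd,
    "rheology": _gen_rheology,
    "contact_angles": _gen_contact_angles,
    "diffractogram": _gen_diffractogram,
    "dissolution": _gen_dissolution,
    "impactor_run": _gen_impactor_run,
    "apsd": _gen_apsd,
}


def generate(spec: FixtureSpec, out_dir: str | Path | None = None):
    """Generate one fixture; returns (DataFrame, ground-truth dict).

    With ``out_dir`` the table is also written as ``<kind>.csv`` and the
    ground truth as ``<kind>_truth.json`` in the schemas the package
    readers consume.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    df, truth = _GENERATORS[spec.kind](dict(spec.parameters), spec.noise_sd, rng)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"{spec.kind}.csv", index=False, float_format="%.10g")
        with open(out / f"{spec.kind}_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return df, truth
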