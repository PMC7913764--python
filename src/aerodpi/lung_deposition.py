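"""Stochastic Monte Carlo regional lung deposition of an inhaled aerosol.

Each simulated particle is drawn from the aerodynamic particle size
distribution (APSD), passes an empirical oral/nasal extrathoracic filter,
and is then tracked down one randomly sampled root-to-terminal path of an
asymmetric branching airway tree (per-generation diameters and lengths are
lognormal around tabulated medians, branching and gravity angles uniform in
tabulated ranges).  In every airway segment the particle deposits with a
probability combining three mechanisms, each an analytic single-tube form:

* inertial impaction      P_i(Stokes number, branching angle)
* gravitational settling  P_s(settling velocity, inclination, residence)
* Brownian diffusion      P_d(diffusion coefficient, residence)

combined as P = 1 - (1-P_i)(1-P_s)(1-P_d).  Penetration depth is set by
the inhaled volume still available when the particle enters; during the
breath-hold only settling and diffusion act, in the airway reached at end
of inhalation; exhalation retraces the path.  Regional tallies
(extrathoracic, bronchial, acinar, exhaled) are exact integer counts, so
the fractions conserve mass to machine precision.

The absolute regional fractions depend on the morphometry table and the
empirical extrathoracic curve shipped here; they are intended for
qualitative ordering (e.g. breath-hold and size effects), not to reproduce
any particular published deposition table.

All internal physics is CGS at body conditions (37 °C).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .impactor import AerodynamicResults, CascadeImpactorModel, ImpactorRun

__all__ = [
    "BreathingPattern",
    "AirwaySegment",
    "GenerationStats",
    "AirwayGeometry",
    "Particle",
    "DepositionResult",
    "LungDepositionModel",
    "sample_airway_path",
    "deposition_probability_segment",
    "extrathoracic_deposition",
    "simulate_deposition",
    "cunningham_slip",
    "settling_velocity",
    "diffusion_coefficient",
]

# --- air & particle physics at body conditions (CGS) ---
_MU_AIR = 1.90e-4       # dynamic viscosity of air at 37 C, poise
_MFP_UM = 0.0712        # mean free path, µm
_K_BOLTZ = 1.380649e-16  # erg/K
_T_BODY = 310.0          # K
_G_CM_S2 = 981.0

# empirical extrathoracic curve P = 1 - 1/(a*(d_ae^2 Q)^b + 1),
# d_ae in µm, Q in L/min; oral coefficients of the Rudolf-type
# mouth-throat impaction-parameter fit; nasal shipped but untested.
ET_COEFFS = {"oral": (1.1e-4, 1.4), "nasal": (3.0e-3, 1.0)}


def cunningham_slip(d_um):
    """Cunningham slip correction for aerodynamic diameter d (µm)."""
    d = np.asarray(d_um, dtype=float)
    kn2 = 2.0 * _MFP_UM / d  # 2*Knudsen
    return 1.0 + kn2 * (1.257 + 0.4 * np.exp(-0.55 * d / _MFP_UM))


def settling_velocity(d_um, density: float = 1.0):
    """Stokes terminal settling velocity (cm/s); density in g/cm³."""
    d_cm = np.asarray(d_um, dtype=float) * 1e-4
    return density * d_cm**2 * _G_CM_S2 * cunningham_slip(d_um) / (18.0 * _MU_AIR)


def diffusion_coefficient(d_um):
    """Brownian diffusion coefficient (cm²/s), Stokes-Einstein."""
    d_cm = np.asarray(d_um, dtype=float) * 1e-4
    return _K_BOLTZ * _T_BODY * cunningham_slip(d_um) / (3.0 * np.pi * _MU_AIR * d_cm)


def _prob_impaction(d_um, density, velocity, diameter_cm, branch_deg):
    """Yeh-Schum bifurcation impaction probability.

    Stk = rho d^2 Cc U / (18 mu D); P = 1 - (2/pi) acos(x) + (1/pi) sin(2 acos(x))
    with x = theta*Stk clipped to [0, 1] (theta in radians).
    """
    d_cm = np.asarray(d_um, dtype=float) * 1e-4
    stk = (
        density * d_cm**2 * cunningham_slip(d_um) * velocity
        / (18.0 * _MU_AIR * diameter_cm)
    )
    x = np.clip(np.radians(branch_deg) * stk, 0.0, 1.0)
    ac = np.arccos(x)
    return np.clip(1.0 - (2.0 / np.pi) * ac + (1.0 / np.pi) * np.sin(2.0 * ac), 0.0, 1.0)


def _prob_sedimentation_flow(d_um, density, residence_s, diameter_cm, gravity_deg):
    """Yeh-Schum settling in laminar tube flow, exponential form.

    P = 1 - exp(-(8/pi) v_ts t cos(phi)/D), phi = inclination from horizontal.
    """
    vts = settling_velocity(d_um, density)
    cosphi = np.cos(np.radians(gravity_deg))
    arg = (8.0 / np.pi) * vts * residence_s * np.abs(cosphi) / diameter_cm
    return 1.0 - np.exp(-arg)


def _prob_sedimentation_still(d_um, density, t_s, diameter_cm, gravity_deg):
    """Quiescent (breath-hold) settling in a tube cross-section."""
    vts = settling_velocity(d_um, density)
    cosphi = np.cos(np.radians(gravity_deg))
    arg = (4.0 / np.pi) * vts * t_s * np.abs(cosphi) / diameter_cm
    return 1.0 - np.exp(-arg)


def _prob_diffusion_flow(d_um, length_cm, flow_cm3_s):
    """Gormley-Kennedy diffusional deposition in laminar tube flow.

    mu = D_B L / Q; small-mu branch below 0.009.
    """
    mu = diffusion_coefficient(d_um) * length_cm / np.maximum(flow_cm3_s, 1e-30)
    small = 5.50 * mu ** (2.0 / 3.0) - 3.77 * mu
    large = (
        1.0
        - 0.819 * np.exp(-11.5 * mu)
        - 0.0975 * np.exp(-70.1 * mu)
        - 0.0325 * np.exp(-179.0 * mu)
    )
    return np.clip(np.where(mu < 0.009, small, large), 0.0, 1.0)


def _prob_diffusion_still(d_um, t_s, diameter_cm):
    """Quiescent diffusion to the wall, first cylindrical Fourier mode."""
    radius = diameter_cm / 2.0
    return 1.0 - np.exp(-5.784 * diffusion_coefficient(d_um) * t_s / radius**2)


def _combine(*probs):
    q = 1.0
    for p in probs:
        q = q * (1.0 - np.clip(p, 0.0, 1.0))
    return 1.0 - q


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BreathingPattern:
    """Breathing manoeuvre driving the simulation.

    inhaled_volume in L, times in s; ``exhalation_time=None`` mirrors the
    inhalation time.  Mode selects the extrathoracic filter curve.
    """

    inhaled_volume: float = 1.7
    inhalation_time: float = 3.2
    breath_hold: float = 5.0
    exhalation_time: float | None = None
    mode: str = "oral"

    def __post_init__(self) -> None:
        if self.inhaled_volume <= 0:
            raise ValueError("inhaled volume must be positive")
        times = (self.inhalation_time, self.breath_hold,
                 self.exhalation_time if self.exhalation_time is not None else 0.0)
        if any(t < 0 for t in times) or self.inhalation_time == 0:
            raise ValueError("times must be non-negative, inhalation time positive")
        if self.mode not in ET_COEFFS:
            raise ValueError(f"mode must be one of {sorted(ET_COEFFS)}")

    @property
    def t_exhale(self) -> float:
        return self.exhalation_time if self.exhalation_time is not None else self.inhalation_time

    @property
    def flow_cm3_s(self) -> float:
        return self.inhaled_volume * 1000.0 / self.inhalation_time

    @property
    def flow_l_min(self) -> float:
        return self.inhaled_volume / self.inhalation_time * 60.0


@dataclass(frozen=True)
class GenerationStats:
    """Statistical morphometry of one airway generation class."""

    generation: int
    region: str  # "bronchial" | "acinar"
    diameter_cm: float
    length_cm: float
    sigma_g: float = 1.0
    branch_angle_deg: tuple[float, float] = (0.0, 0.0)
    gravity_angle_deg: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.diameter_cm <= 0 or self.length_cm <= 0:
            raise ValueError("diameter and length must be positive")
        if self.sigma_g < 1:
            raise ValueError("geometric SD must be >= 1")
        if self.region not in ("bronchial", "acinar"):
            raise ValueError("region must be 'bronchial' or 'acinar'")


@dataclass(frozen=True)
class AirwaySegment:
    """One concrete sampled airway on a particle's path."""

    generation: int
    region: str
    diameter_cm: float
    length_cm: float
    branch_angle_deg: float
    gravity_angle_deg: float


@dataclass(frozen=True)
class AirwayGeometry:
    """A randomized dichotomous airway tree, one stats entry per generation."""

    generations: tuple[GenerationStats, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "generations", tuple(self.generations))
        if not self.generations:
            raise ValueError("geometry needs at least one generation")

    @classmethod
    def from_dict(cls, payload: dict) -> "AirwayGeometry":
        gens = [
            GenerationStats(
                generation=g["generation"],
                region=g["region"],
                diameter_cm=g["diameter_cm"],
                length_cm=g["length_cm"],
                sigma_g=g.get("sigma_g", 1.0),
                branch_angle_deg=tuple(g.get("branch_angle_deg", (0.0, 0.0))),
                gravity_angle_deg=tuple(g.get("gravity_angle_deg", (0.0, 0.0))),
            )
            for g in payload["generations"]
        ]
        return cls(tuple(gens))

    @classmethod
    def from_json(cls, path) -> "AirwayGeometry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls, frc_cm3: float = 3300.0) -> "AirwayGeometry":
        """Shipped adult morphometry, isotropically rescaled to the given FRC.

        The rescaling lumps the alveolar volume into the duct volumes so
        that the cumulative tree volume used for penetration bookkeeping
        equals the functional residual capacity.
        """
        payload = json.loads(
            resources.files("aerodpi.data").joinpath("airway_geometry.json").read_text()
        )
        geom = cls.from_dict(payload)
        scale = (frc_cm3 / geom.total_volume_cm3()) ** (1.0 / 3.0)
        return geom.scaled(scale)

    def scaled(self, factor: float) -> "AirwayGeometry":
        return AirwayGeometry(
            tuple(
                replace(g, diameter_cm=g.diameter_cm * factor,
                        length_cm=g.length_cm * factor)
                for g in self.generations
            )
        )

    def cumulative_volume_cm3(self) -> np.ndarray:
        """Cumulative median tree volume from the mouth through each generation."""
        vols = np.array(
            [
                2 ** (i) * np.pi * (g.diameter_cm / 2.0) ** 2 * g.length_cm
                for i, g in enumerate(self.generations)
            ]
        )
        return np.cumsum(vols)

    def total_volume_cm3(self) -> float:
        return float(self.cumulative_volume_cm3()[-1])

    @property
    def regions(self) -> np.ndarray:
        return np.array([g.region for g in self.generations])


@dataclass(frozen=True)
class Particle:
    """An aerosol particle specified by aerodynamic diameter (µm)."""

    d_ae: float
    density: float = 1.0  # aerodynamic convention: unit-density sphere

    def __post_init__(self) -> None:
        if self.d_ae <= 0 or self.density <= 0:
            raise ValueError("diameter and density must be positive")


def sample_airway_path(geometry: AirwayGeometry, rng_seed) -> list[AirwaySegment]:
    """Draw one random root-to-terminal path through the tree.

    Per generation: diameter and length lognormal around the tabulated
    medians with the tabulated geometric SD; branching and gravity angles
    uniform in their ranges.  Reproducible under a fixed seed; a zero-width
    geometric SD (sigma_g = 1) returns the median geometry.
    """
    rng = np.random.default_rng(rng_seed)
    path = []
    for g in geometry.generations:
        s = np.log(g.sigma_g)
        path.append(
            AirwaySegment(
                generation=g.generation,
                region=g.region,
                diameter_cm=g.diameter_cm * np.exp(s * rng.standard_normal()),
                length_cm=g.length_cm * np.exp(s * rng.standard_normal()),
                branch_angle_deg=rng.uniform(*g.branch_angle_deg),
                gravity_angle_deg=rng.uniform(*g.gravity_angle_deg),
            )
        )
    return path


def deposition_probability_segment(
    p: Particle, segment: AirwaySegment, flow_cm3_s: float, residence_s: float
) -> float:
    """Combined single-segment deposition probability under laminar flow.

    P = 1 - (1-P_imp)(1-P_sed)(1-P_diff); each mechanism clipped to [0, 1].
    ``flow_cm3_s`` is the airflow through this single airway.
    """
    area = np.pi * (segment.diameter_cm / 2.0) ** 2
    velocity = flow_cm3_s / area
    p_i = _prob_impaction(p.d_ae, p.density, velocity, segment.diameter_cm,
                          segment.branch_angle_deg)
    p_s = _prob_sedimentation_flow(p.d_ae, p.density, residence_s,
                                   segment.diameter_cm, segment.gravity_angle_deg)
    p_d = _prob_diffusion_flow(p.d_ae, segment.length_cm, flow_cm3_s)
    return float(_combine(p_i, p_s, p_d))


def extrathoracic_deposition(d_ae, flow_l_min: float, mode: str = "oral",
                             coeffs: tuple[float, float] | None = None):
    """Empirical mouth-throat (or nasal) deposition probability.

    Monotone non-decreasing in the impaction parameter d_ae² * Q
    (µm² L/min): P = 1 - 1/(a x^b + 1).
    """
    if flow_l_min <= 0:
        raise ValueError("flow must be positive")
    a, b = coeffs if coeffs is not None else ET_COEFFS[mode]
    x = np.asarray(d_ae, dtype=float) ** 2 * flow_l_min
    return 1.0 - 1.0 / (a * np.power(x, b, where=x > 0, out=np.zeros_like(x)) + 1.0)


@dataclass(frozen=True)
class DepositionResult:
    """Regional deposited fractions (percent of inhaled particles)."""

    extrathoracic: float
    bronchial: float
    acinar: float
    exhaled: float
    n_particles: int
    se: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def lung(self) -> float:
        return self.bronchial + self.acinar

    def as_dict(self) -> dict[str, float]:
        return {
            "extrathoracic_pct": self.extrathoracic,
            "lung_pct": self.lung,
            "bronchial_pct": self.bronchial,
            "acinar_pct": self.acinar,
            "exhaled_pct": self.exhaled,
        }

    def summary(self) -> str:
        def fmt(name, value):
            se = self.se.get(name)
            tail = f"  +/- {se:5.2f}" if se is not None else ""
            return f"  {name:<14}{value:8.2f} %{tail}"

        lines = [
            f"Regional deposition (n = {self.n_particles} particles"
            + (f", seed = {self.seed})" if self.seed is not None else ")"),
            "-" * 44,
            fmt("extrathoracic", self.extrathoracic),
            fmt("lung", self.lung),
            fmt("bronchial", self.bronchial),
            fmt("acinar", self.acinar),
            fmt("exhaled", self.exhaled),
        ]
        return "\n".join(lines)


def _resolve_apsd(apsd) -> tuple[float, float]:
    """Accept (MMAD, GSD), an ImpactorRun, or AerodynamicResults."""
    if isinstance(apsd, AerodynamicResults):
        return apsd.mmad, apsd.gsd
    if isinstance(apsd, ImpactorRun):
        res = CascadeImpactorModel(apsd).fit()
        return res.mmad, res.gsd
    mmad, gsd = apsd
    if mmad <= 0 or gsd < 1:
        raise ValueError(f"invalid APSD (MMAD={mmad}, GSD={gsd})")
    return float(mmad), float(gsd)


def simulate_deposition(
    apsd,
    breathing: BreathingPattern,
    geometry: AirwayGeometry | None = None,
    n_particles: int = 10_000,
    seed: int | None = None,
    density: float = 1.0,
    include_extrathoracic: bool = True,
) -> DepositionResult:
    """Monte Carlo regional deposition of an aerosol.

    Parameters
    ----------
    apsd : (MMAD µm, GSD) tuple, ImpactorRun or AerodynamicResults
        Aerodynamic size distribution the particles are drawn from.
    include_extrathoracic : bool
        Disable to expose the pure airway model (used by the analytic
        single-tube oracle).

    Notes
    -----
    One seeded Generator with a fixed draw order (particle sizes →
    extrathoracic uniforms → geometry → inhalation uniforms → breath-hold
    uniform → exhalation uniforms) makes runs that differ only in
    breath-hold time share all random numbers, so breath-hold comparisons
    use common random numbers.
    """
    if n_particles < 1:
        raise ValueError("need at least one particle")
    geometry = geometry if geometry is not None else AirwayGeometry.default()
    mmad, gsd = _resolve_apsd(apsd)
    gens = geometry.generations
    G = len(gens)
    n = int(n_particles)
    rng = np.random.default_rng(seed)

    # --- fixed draw order (see Notes) ---
    d_ae = mmad * np.exp(np.log(gsd) * rng.standard_normal(n))
    u_et = rng.random(n)
    z_d = rng.standard_normal((n, G))
    z_l = rng.standard_normal((n, G))
    sig = np.log([g.sigma_g for g in gens])
    blo = np.array([g.branch_angle_deg[0] for g in gens])
    bhi = np.array([g.branch_angle_deg[1] for g in gens])
    glo = np.array([g.gravity_angle_deg[0] for g in gens])
    ghi = np.array([g.gravity_angle_deg[1] for g in gens])
    branch = rng.uniform(blo, bhi, (n, G))
    grav = rng.uniform(glo, ghi, (n, G))
    tau = rng.random(n)
    u_inh = rng.random((n, G))
    u_hold = rng.random(n)
    u_exh = rng.random((n, G))

    med_d = np.array([g.diameter_cm for g in gens])
    med_l = np.array([g.length_cm for g in gens])
    diam = med_d * np.exp(sig * z_d)
    length = med_l * np.exp(sig * z_l)

    # penetration depth: generations fully entered with the air volume
    # still inhalable after the particle's entry time fraction tau
    cumvol = geometry.cumulative_volume_cm3()
    avail = breathing.inhaled_volume * 1000.0 * (1.0 - tau)
    g_end = np.clip(np.searchsorted(cumvol, avail, side="right"), 1, G)  # count

    gen_idx = np.arange(G)
    reach = gen_idx[None, :] < g_end[:, None]

    def phase_probs(flow_total_cm3_s):
        q_seg = flow_total_cm3_s / 2.0**gen_idx  # dichotomous flow split
        vel = q_seg / (np.pi * (diam / 2.0) ** 2)
        t_res = length / vel
        p_i = _prob_impaction(d_ae[:, None], density, vel, diam, branch)
        p_s = _prob_sedimentation_flow(d_ae[:, None], density, t_res, diam, grav)
        p_d = _prob_diffusion_flow(d_ae[:, None], length, q_seg)
        return _combine(p_i, p_s, p_d)

    p_inh = phase_probs(breathing.flow_cm3_s)
    hit_inh = (u_inh < p_inh) & reach
    dep_inh_any = hit_inh.any(axis=1)
    dep_inh_gen = np.where(dep_inh_any, hit_inh.argmax(axis=1), -1)

    if include_extrathoracic:
        et = u_et < extrathoracic_deposition(d_ae, breathing.flow_l_min, breathing.mode)
    else:
        et = np.zeros(n, dtype=bool)

    in_airways = ~et
    fate = np.full(n, "exhaled", dtype=object)
    fate[et] = "extrathoracic"

    regions = geometry.regions
    dep1 = in_airways & dep_inh_any
    fate[dep1] = regions[dep_inh_gen[dep1]]

    # breath-hold: settling + diffusion in the airway reached at end of inhalation
    survivors = in_airways & ~dep_inh_any
    hold_idx = g_end - 1
    rows = np.arange(n)
    d_hold = diam[rows, hold_idx]
    g_hold = grav[rows, hold_idx]
    p_hold = _combine(
        _prob_sedimentation_still(d_ae, density, breathing.breath_hold, d_hold, g_hold),
        _prob_diffusion_still(d_ae, breathing.breath_hold, d_hold),
    )
    dep_hold = survivors & (u_hold < p_hold)
    fate[dep_hold] = regions[hold_idx[dep_hold]]

    # exhalation retraces the path; first hit encountered = deepest hit
    survivors = survivors & ~dep_hold
    p_exh = phase_probs(breathing.inhaled_volume * 1000.0 / breathing.t_exhale)
    hit_exh = (u_exh < p_exh) & reach
    any_exh = hit_exh.any(axis=1)
    deepest = G - 1 - hit_exh[:, ::-1].argmax(axis=1)
    dep_exh = survivors & any_exh
    fate[dep_exh] = regions[deepest[dep_exh]]

    counts = {
        k: int(np.sum(fate == k))
        for k in ("extrathoracic", "bronchial", "acinar", "exhaled")
    }
    pct = {k: 100.0 * v / n for k, v in counts.items()}
    se = {k: 100.0 * np.sqrt(p / 100 * (1 - p / 100) / n) for k, p in pct.items()}
    se["lung"] = 100.0 * np.sqrt(
        (pct["bronchial"] + pct["acinar"]) / 100
        * (1 - (pct["bronchial"] + pct["acinar"]) / 100) / n
    )
    return DepositionResult(
        extrathoracic=pct["extrathoracic"],
        bronchial=pct["bronchial"],
        acinar=pct["acinar"],
        exhaled=pct["exhaled"],
        n_particles=n,
        se=se,
        seed=seed,
    )


class LungDepositionModel:
    """Model object pairing an APSD with a breathing pattern and geometry.

    ``simulate`` (alias ``fit``) runs the Monte Carlo and returns a
    `DepositionResult`.

    Examples
    --------
    >>> model = LungDepositionModel((2.0, 2.0), BreathingPattern(breath_hold=10))
    >>> res = model.simulate(n_particles=50_000, seed=1)
    >>> print(res.summary())
    """

    def __init__(self, apsd, breathing: BreathingPattern | None = None,
                 geometry: AirwayGeometry | None = None, density: float = 1.0):
        self.apsd = apsd
        self.breathing = breathing if breathing is not None else BreathingPattern()
        self.geometry = geometry if geometry is not None else AirwayGeometry.default()
        self.density = density

    def simulate(self, n_particles: int = 10_000, seed: int | None = None,
                 include_extrathoracic: bool = True) -> DepositionResult:
        return simulate_deposition(
            self.apsd, self.breathing, self.geometry, n_particles=n_particles,
            seed=seed, density=self.density,
            include_extrathoracic=include_extrathoracic,
        )

    fit = simulate
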