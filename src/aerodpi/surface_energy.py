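"""Solid surface free energy from two-liquid contact angles (Wu model).

The Wu harmonic-mean combining rule relates the contact angle theta of a
probe liquid (with known dispersive/polar surface-tension components
gamma_l^d, gamma_l^p) on a solid with unknown components gamma_s^d,
gamma_s^p:

    (1 + cos theta) gamma_l =
        4 gamma_s^d gamma_l^d / (gamma_s^d + gamma_l^d)
      + 4 gamma_s^p gamma_l^p / (gamma_s^p + gamma_l^p)

Measuring theta with two chemically distinct liquids (one predominantly
polar, one apolar) gives a 2x2 nonlinear system for the solid components.
Derived quantities: total energy gamma_s = gamma_s^d + gamma_s^p, polarity
Pol = gamma_s^p/gamma_s*100 (%), and the work of cohesion Wc = 2 gamma_s,
the energy to split a column of the material.  All energies in mN/m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "ProbeLiquid",
    "ContactAngleObservation",
    "SurfaceEnergy",
    "WATER",
    "DIIODOMETHANE",
    "wu_residual",
    "solve_wu",
    "forward_contact_angle",
    "polarity",
    "cohesion_work",
    "WuConvergenceError",
]


class WuConvergenceError(RuntimeError):
    """No admissible root of the Wu system was found."""


@dataclass(frozen=True)
class ProbeLiquid:
    """A probe liquid with known surface-tension components (mN/m)."""

    name: str
    gamma_d: float
    gamma_p: float

    def __post_init__(self) -> None:
        if self.gamma_d < 0 or self.gamma_p < 0:
            raise ValueError("liquid components must be non-negative")
        if self.gamma_d + self.gamma_p <= 0:
            raise ValueError("total liquid surface tension must be positive")

    @property
    def gamma_total(self) -> float:
        return self.gamma_d + self.gamma_p


# Literature component values for the standard probe pair.
WATER = ProbeLiquid("water", gamma_d=22.6, gamma_p=50.2)
DIIODOMETHANE = ProbeLiquid("diiodomethane", gamma_d=49.0, gamma_p=1.8)


@dataclass(frozen=True)
class ContactAngleObservation:
    """A sessile-drop contact angle (degrees) of one probe liquid."""

    liquid: ProbeLiquid
    theta: float

    def __post_init__(self) -> None:
        if not (0 <= self.theta < 180):
            raise ValueError(f"theta must be in [0, 180), got {self.theta}")


@dataclass(frozen=True)
class SurfaceEnergy:
    """Solid surface free-energy decomposition with derived quantities."""

    gamma_d: float
    gamma_p: float
    label: str = ""

    @property
    def gamma_total(self) -> float:
        return self.gamma_d + self.gamma_p

    @property
    def polarity(self) -> float:
        return polarity(self.gamma_p, self.gamma_total)

    @property
    def cohesion_work(self) -> float:
        return cohesion_work(self.gamma_total)

    def as_dict(self) -> dict[str, float]:
        return {
            "gamma_d": self.gamma_d,
            "gamma_p": self.gamma_p,
            "gamma_total": self.gamma_total,
            "cohesion_work": self.cohesion_work,
            "polarity": self.polarity,
        }


def _harmonic_term(gs: float, gl: float) -> float:
    # limit convention: term -> 0 when both components vanish
    denom = gs + gl
    if denom == 0:
        return 0.0
    return 4.0 * gs * gl / denom


def wu_residual(theta: float, liquid: ProbeLiquid, gsd: float, gsp: float) -> float:
    """Left minus right side of the Wu equation, mN/m; zero iff it holds.

    theta in degrees; gsd/gsp are candidate solid components.
    """
    lhs = (1.0 + np.cos(np.radians(theta))) * liquid.gamma_total
    rhs = _harmonic_term(gsd, liquid.gamma_d) + _harmonic_term(gsp, liquid.gamma_p)
    return lhs - rhs


def forward_contact_angle(energy: SurfaceEnergy, liquid: ProbeLiquid) -> float:
    """Contact angle (degrees) the Wu model predicts for a solid/liquid pair.

    Inverse of the solver; raises if the predicted cos(theta) exceeds 1
    (complete wetting, no finite contact angle).
    """
    rhs = _harmonic_term(energy.gamma_d, liquid.gamma_d) + _harmonic_term(
        energy.gamma_p, liquid.gamma_p
    )
    cos_theta = rhs / liquid.gamma_total - 1.0
    if cos_theta > 1.0 + 1e-12:
        raise ValueError(
            f"complete wetting predicted (cos theta = {cos_theta:.4f} > 1)"
        )
    return float(np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0))))


def _wu_system(x, obs_a: ContactAngleObservation, obs_b: ContactAngleObservation):
    gsd, gsp = x
    return [
        wu_residual(obs_a.theta, obs_a.liquid, gsd, gsp),
        wu_residual(obs_b.theta, obs_b.liquid, gsd, gsp),
    ]


def solve_wu(
    obs_polar: ContactAngleObservation,
    obs_apolar: ContactAngleObservation,
    bounds: tuple[float, float] = (0.0, 200.0),
    tol: float = 1e-10,
    label: str = "",
) -> SurfaceEnergy:
    """Invert the two-liquid Wu system for the solid components.

    Uses a hybrid Powell/Newton root find (scipy) multi-started from a
    coarse grid over [0, 100]^2; components are clipped to the physical
    region [0, bounds[1]].  Both residuals of the returned solution are
    below 1e-8 mN/m.  If several grid starts converge to distinct roots the
    one with the smallest absolute residual sum is returned with a warning.
    """
    la, lb = obs_polar.liquid, obs_apolar.liquid
    if (la.gamma_d, la.gamma_p) == (lb.gamma_d, lb.gamma_p):
        raise ValueError("two distinct probe liquids are required")
    if la.gamma_p <= 0 and lb.gamma_p <= 0:
        raise ValueError("at least one probe liquid must have a polar component")

    lo, hi = bounds
    roots: list[np.ndarray] = []
    for g0 in np.linspace(5.0, 95.0, 4):
        for p0 in np.linspace(5.0, 95.0, 4):
            sol = optimize.root(
                _wu_system, [g0, p0], args=(obs_polar, obs_apolar), method="hybr"
            )
            if not sol.success:
                continue
            x = np.clip(sol.x, lo, hi)
            res = _wu_system(x, obs_polar, obs_apolar)
            if max(abs(res[0]), abs(res[1])) < 1e-8:
                if not any(np.allclose(x, r, atol=1e-6) for r in roots):
                    roots.append(x)
    if not roots:
        raise WuConvergenceError(
            "no root of the Wu system found in "
            f"[{lo}, {hi}]^2 for angles ({obs_polar.theta}, {obs_apolar.theta})"
        )
    if len(roots) > 1:
        warnings.warn(
            f"{len(roots)} distinct Wu roots found; returning the one with "
            "the smallest residual sum",
            stacklevel=2,
        )
        roots.sort(
            key=lambda x: sum(abs(r) for r in _wu_system(x, obs_polar, obs_apolar))
        )
    gsd, gsp = (float(v) for v in roots[0])
    return SurfaceEnergy(gamma_d=gsd, gamma_p=gsp, label=label)


def polarity(gsp: float, gs: float) -> float:
    """Polar fraction of the total surface free energy, percent."""
    if gs <= 0:
        raise ValueError(f"total surface energy must be positive, got {gs}")
    return gsp / gs * 100.0


def cohesion_work(gs: float) -> float:
    """Work of cohesion Wc = 2*gamma_s, mN/m."""
    if gs < 0:
        raise ValueError(f"surface energy must be non-negative, got {gs}")
    return 2.0 * gs
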