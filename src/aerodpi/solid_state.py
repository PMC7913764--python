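"""Crystallinity index from characteristic-peak areas of X-ray diffractograms.

Amorphization during milling and spray-drying reduces the intensity of a
drug's characteristic Bragg reflections.  The residual crystallinity of a
processed sample is estimated as the ratio of the summed characteristic-peak
areas (above a local linear baseline) to the same areas in a physical
mixture of identical composition, times 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Diffractogram",
    "PeakSet",
    "MX_PEAKS",
    "LEU_PEAKS",
    "integrate_peaks",
    "crystallinity_percent",
    "read_xy",
    "write_xy",
]

# Characteristic reflection centers (degrees 2-theta).
MX_PEAKS = (6.6, 11.4, 13.1, 13.5, 15.1, 18.7, 19.3, 25.9, 26.4)
LEU_PEAKS = (6.12, 24.39, 30.61)


@dataclass(frozen=True)
class Diffractogram:
    """An XRPD scan: ascending 2-theta grid (deg) and intensities (counts)."""

    two_theta: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        tt = np.asarray(self.two_theta, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        if tt.shape != it.shape or tt.ndim != 1:
            raise ValueError("two_theta and intensity must be equal-length 1-D")
        if not np.all(np.diff(tt) > 0):
            raise ValueError("two_theta must be strictly increasing")
        if np.any(it < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "two_theta", tt)
        object.__setattr__(self, "intensity", it)


@dataclass(frozen=True)
class PeakSet:
    """Peak centers (deg 2-theta) with a common integration half-width."""

    centers: tuple[float, ...] = MX_PEAKS
    window: float = 0.25

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window half-width must be positive")
        object.__setattr__(self, "centers", tuple(self.centers))


def _peak_area(d: Diffractogram, center: float, window: float) -> float:
    lo, hi = center - window, center + window
    if lo < d.two_theta[0] or hi > d.two_theta[-1]:
        raise ValueError(
            f"peak window [{lo:.2f}, {hi:.2f}] outside scan range "
            f"[{d.two_theta[0]:.2f}, {d.two_theta[-1]:.2f}]"
        )
    mask = (d.two_theta >= lo) & (d.two_theta <= hi)
    x, y = d.two_theta[mask], d.intensity[mask]
    if x.size < 2:
        return 0.0
    # local linear baseline between window edges
    baseline = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    area = np.trapezoid(y - baseline, x)
    return max(float(area), 0.0)


def integrate_peaks(d: Diffractogram, p: PeakSet) -> float:
    """Total area (counts*deg) of the characteristic peaks above baseline."""
    return sum(_peak_area(d, c, p.window) for c in p.centers)


def crystallinity_percent(
    sample: Diffractogram,
    reference: Diffractogram,
    p: PeakSet | None = None,
    per_peak_mean: bool = False,
) -> float:
    """Residual crystallinity of `sample` relative to `reference`, percent.

    Default is the ratio of summed peak areas; ``per_peak_mean=True``
    instead averages the per-peak area ratios (peaks with zero reference
    area are skipped).  Assumes equal drug loading in sample and reference.
    """
    p = p or PeakSet()
    if sample.two_theta.shape != reference.two_theta.shape or not np.allclose(
        sample.two_theta, reference.two_theta
    ):
        raise ValueError("sample and reference must share the same scan grid")
    if per_peak_mean:
        ratios = []
        for c in p.centers:
            ref_area = _peak_area(reference, c, p.window)
            if ref_area > 0:
                ratios.append(_peak_area(sample, c, p.window) / ref_area)
        if not ratios:
            raise ValueError("reference has zero area at every peak")
        return float(np.mean(ratios)) * 100.0
    ref_total = integrate_peaks(reference, p)
    if ref_total <= 0:
        raise ValueError("reference peak area is zero")
    return integrate_peaks(sample, p) / ref_total * 100.0


def read_xy(path, label: str = "") -> Diffractogram:
    """Read a two-column (2-theta, intensity) text file."""
    data = np.loadtxt(path)
    return Diffractogram(data[:, 0], data[:, 1], label=label)


def write_xy(path, d: Diffractogram) -> None:
    np.savetxt(path, np.column_stack([d.two_theta, d.intensity]), fmt="%.6g")
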