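"""Finite-difference derivatives of radial profiles and scalar edge metrics.

Three scalars summarize the peripheral intensity peak of a profile I(u):

* outer_slope — global maximum of dI/du: the rising transition from the
  background outside the nucleus up to the peak;
* inner_slope — minimum of dI/du over u in [0, domain_cap]: the descending
  transition from the peak into the nucleoplasm (negative at a real edge);
* peak_curvature — minimum of d2I/du2 over u in [0, domain_cap]: most
  negative at a sharp peak.

The restriction to the outer 40% of the domain keeps the inner-slope and
curvature extrema at the nuclear periphery rather than at interior chromatin
structure. Derivatives use central differences at interior points and
one-sided differences at the endpoints, with step h = 1/(n-1) in normalized
units; the second derivative applies the same scheme twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ringprof import RadialProfile

__all__ = ["EdgeMetrics", "finite_difference", "extract_metrics"]


@dataclass
class EdgeMetrics:
    """Edge-sharpness summary of one profile (units: relative intensity per
    unit normalized distance, squared for the curvature)."""

    outer_slope: float
    inner_slope: float
    peak_curvature: float
    domain_cap: float = 0.4
    smoothing: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "outer_slope": self.outer_slope,
            "inner_slope": self.inner_slope,
            "peak_curvature": self.peak_curvature,
        }


def _values(profile: RadialProfile | np.ndarray) -> np.ndarray:
    v = profile.values if isinstance(profile, RadialProfile) else np.asarray(profile, dtype=float)
    if v.ndim != 1 or len(v) < 3:
        raise ValueError("profile must be a 1-D vector of length >= 3")
    return v


def finite_difference(profile: RadialProfile | np.ndarray, order: int = 1) -> np.ndarray:
    """First or second finite-difference derivative with respect to u."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    v = _values(profile)
    h = 1.0 / (len(v) - 1)
    d = np.gradient(v, h, edge_order=1)
    if order == 2:
        d = np.gradient(d, h, edge_order=1)
    return d


def _moving_average(v: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return v
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(v, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(v)]
    return out


def extract_metrics(
    profile: RadialProfile | np.ndarray,
    domain_cap: float = 0.4,
    smoothing: int = 0,
) -> EdgeMetrics:
    """Extract the three edge metrics from a (normalized) profile.

    ``domain_cap`` is inclusive: samples at u == domain_cap participate in the
    restricted extrema. ``smoothing`` (odd moving-average width, 0 = none)
    is applied before differentiation and recorded in the result.
    """
    v = _values(profile)
    v = _moving_average(v, smoothing)
    u = np.linspace(0.0, 1.0, len(v))
    in_cap = u <= domain_cap
    if not in_cap.any():
        raise ValueError("restricted domain [0, domain_cap] contains no samples")
    d1 = finite_difference(v, 1)
    d2 = finite_difference(v, 2)
    return EdgeMetrics(
        outer_slope=float(d1.max()),
        inner_slope=float(d1[in_cap].min()),
        peak_curvature=float(d2[in_cap].min()),
        domain_cap=domain_cap,
        smoothing=smoothing,
    )
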