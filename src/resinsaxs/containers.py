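"""Core value objects shared across the package.

Units are fixed package-wide: momentum transfer ``q`` in 1/nm, real-space
distances in nm.  All containers validate their invariants on construction,
so downstream code can rely on (for example) a strictly increasing q grid
without re-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ScatteringCurve",
    "RadialDensity",
    "FractalParams",
    "HullBasis",
    "DENSITY_KINDS",
]

DENSITY_KINDS = ("pair_density", "radial_density", "background_corrected")


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class ScatteringCurve:
    """A 1D scattering curve I(q) sampled on a strictly increasing q grid.

    Parameters
    ----------
    q : array_like
        Momentum transfer in 1/nm, strictly increasing, all positive.
        q = 4*pi*sin(theta)/lambda for scattering angle 2*theta.
    intensity : array_like
        Intensity in arbitrary units, nonnegative.
    sigma : array_like, optional
        Per-point uncertainty, strictly positive where present.
    meta : dict
        Free-form provenance labels.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = _as_1d_float(self.q, "q")
        self.intensity = _as_1d_float(self.intensity, "intensity")
        if self.q.size == 0:
            raise ValueError("empty q grid")
        if np.any(self.q <= 0):
            raise ValueError("all q must be > 0")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.intensity.shape != self.q.shape:
            raise ValueError("intensity and q must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")
        if self.sigma is not None:
            self.sigma = _as_1d_float(self.sigma, "sigma")
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma and q must have equal length")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be > 0 where present")

    def __len__(self) -> int:
        return self.q.size

    def scaled(self, factor: float) -> "ScatteringCurve":
        """Return a copy with intensity (and sigma) multiplied by ``factor``."""
        sigma = None if self.sigma is None else self.sigma * abs(factor)
        return ScatteringCurve(self.q.copy(), self.intensity * factor, sigma,
                               dict(self.meta))

    def resampled(self, q_new: np.ndarray) -> "ScatteringCurve":
        """Linear resampling onto a new q grid (inside the current support)."""
        q_new = _as_1d_float(q_new, "q_new")
        intensity = np.interp(q_new, self.q, self.intensity)
        sigma = None if self.sigma is None else np.interp(q_new, self.q, self.sigma)
        meta = dict(self.meta)
        meta["resampled"] = True
        return ScatteringCurve(q_new, intensity, sigma, meta)


@dataclass
class RadialDensity:
    """A density profile on a real-space distance grid [nm].

    ``kind`` distinguishes pair densities p(r), radial densities p'(R)
    (material density versus distance from the strand backbone), and signed
    background-corrected profiles.  Only the last may carry negative values.
    """

    r: np.ndarray
    density: np.ndarray
    kind: str = "pair_density"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = _as_1d_float(self.r, "r")
        self.density = _as_1d_float(self.density, "density")
        if self.r.size == 0:
            raise ValueError("empty r grid")
        if self.r[0] < 0:
            raise ValueError("r must be nonnegative")
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("r must be increasing")
        if self.density.shape != self.r.shape:
            raise ValueError("density and r must have equal length")
        if self.kind not in DENSITY_KINDS:
            raise ValueError(f"kind must be one of {DENSITY_KINDS}, got {self.kind!r}")
        if self.kind != "background_corrected" and np.any(self.density < -1e-12):
            raise ValueError(f"negative density not allowed for kind={self.kind!r}")

    def area(self) -> float:
        """Trapezoid integral of the density over its grid."""
        return float(np.trapezoid(self.density, self.r))

    def normalized(self) -> "RadialDensity":
        """Unit-area copy (raises on zero total area)."""
        a = self.area()
        if a == 0:
            raise ValueError("cannot normalize a zero-area density")
        return RadialDensity(self.r.copy(), self.density / a, self.kind, dict(self.meta))


@dataclass
class FractalParams:
    """Mass-fractal network parameters.

    df : fractal dimension of the pair density p_S(r) ~ r^df * exp(-kappa*r).
    kappa : screening parameter in 1/nm; 0 encodes the unscreened
        pure-power-law limit S(q) ~ q^-(df+1).
    """

    df: float
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if not self.df > 0:
            raise ValueError("df must be > 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


@dataclass
class HullBasis:
    """Discretized spherical-hull operator mapping p'(R) to I(q)*q^(df+1).

    matrix[i, j] = 4*pi*R_j**2 * w_j * K(q_i*R_j)**2 with the thin-shell
    kernel K(x) = J_{1/2}(x)/x^{1/2} and trapezoid quadrature weights w_j.
    """

    r_grid: np.ndarray
    q_grid: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.r_grid = _as_1d_float(self.r_grid, "r_grid")
        self.q_grid = _as_1d_float(self.q_grid, "q_grid")
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.q_grid.size, self.r_grid.size):
            raise ValueError("matrix shape must be (len(q_grid), len(r_grid))")
        if np.any(self.matrix < 0):
            raise ValueError("hull matrix entries must be >= 0")
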