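"""Synthetic ground-truth generators for every pipeline stage.

No raw experimental data ship with this package, so each analysis stage is
validated against generated inputs whose true parameters are known: point
sets of known correlation dimension, filament-network images with punched
pores, power-law-times-form-factor scattering series, bi-Langmuir uptake
tables, and toy bead models of a Y-shaped antibody and a compact ligand
domain.  Every generator returns a :class:`SyntheticTruth` record from which
the artifact can be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .containers import FractalParams, RadialDensity, ScatteringCurve
from .complexes import CentroidModel
from .isotherm import BiLangmuirParams, IsothermData, bi_langmuir_q
from .pipeline import ConcentrationSeries, SeriesSample
from .transforms import build_hull_matrix, structure_factor_closed

__all__ = [
    "SyntheticTruth",
    "gen_point_sets",
    "gen_network_image",
    "gen_saxs_series",
    "gen_frames",
    "gen_isotherm_data",
    "gen_toy_antibody_and_domain",
    "DEFAULT_ISOTHERM_PARAMS",
    "DEFAULT_ISOTHERM_C_GRID",
]

#: Default two-site truth for synthetic uptake data.  Chosen by Fisher
#: identifiability analysis over the batch concentration range
#: 0.01-10 mg/ml: a high-affinity site saturating early (b1*C >= 1 from the
#: lowest level) and a dominant low-affinity site still rising at the top
#: level keep all four parameters estimable from 12 points.
DEFAULT_ISOTHERM_PARAMS = BiLangmuirParams(q1m=20.0, b1=100.0, q2m=80.0, b2=0.5)

#: Default uptake design: batch triplicates at four decades of C [mg/ml].
DEFAULT_ISOTHERM_C_GRID = tuple(np.repeat([0.01, 0.1, 1.0, 10.0], 3))


@dataclass
class SyntheticTruth:
    """Complete generating record of one synthetic artifact."""

    kind: str
    params: Dict = field(default_factory=dict)
    seed: Optional[int] = None

    def as_dict(self) -> Dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [conv(x) for x in v]
            return v

        return {"kind": self.kind, "seed": self.seed, "params": conv(self.params)}


# ---------------------------------------------------------------------------
# Point sets of known correlation dimension
# ---------------------------------------------------------------------------

def gen_point_sets(
    kind: str,
    n: int,
    size: float = 1.0,
    seed: Optional[int] = None,
    n_clusters: int = 10,
    cluster_sigma: float = 0.02,
) -> Tuple[np.ndarray, SyntheticTruth]:
    """I.i.d. point sets for calibrating the pair-density dimension estimator.

    kinds: ``uniform_2d`` (square of side ``size``), ``line_1d`` (segment of
    length ``size``), ``ball_3d`` (solid ball of radius ``size``),
    ``sphere_shell`` (spherical surface of radius ``size``), ``clustered``
    (2D Gaussian clusters).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    if kind == "uniform_2d":
        pts = rng.uniform(0.0, size, size=(n, 2))
    elif kind == "line_1d":
        pts = rng.uniform(0.0, size, size=(n, 1))
    elif kind == "ball_3d":
        u = rng.standard_normal((n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = size * rng.uniform(0.0, 1.0, size=n) ** (1.0 / 3.0)
        pts = u * r[:, None]
    elif kind == "sphere_shell":
        u = rng.standard_normal((n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts = size * u
    elif kind == "clustered":
        centers = rng.uniform(0.0, size, size=(n_clusters, 2))
        which = rng.integers(0, n_clusters, size=n)
        pts = centers[which] + cluster_sigma * size * rng.standard_normal((n, 2))
    else:
        raise ValueError(f"unknown point-set kind {kind!r}")
    truth = SyntheticTruth(kind=f"point_set:{kind}", seed=seed,
                           params={"n": n, "size": size,
                                   "n_clusters": n_clusters,
                                   "cluster_sigma": cluster_sigma})
    return pts, truth


# ---------------------------------------------------------------------------
# Network images
# ---------------------------------------------------------------------------

def gen_network_image(
    width: int = 512,
    n_strands: int = 40,
    strand_thickness: float = 6.0,
    pore_diameter: float = 0.0,
    n_pores: int = 0,
    seed: Optional[int] = None,
    fg_value: int = 100,
    bg_value: int = 255,
) -> Tuple[np.ndarray, SyntheticTruth]:
    """Grayscale filament-network image with optional punched disk pores.

    Filaments are full-width chords of random position and orientation with
    the given thickness, drawn dark (``fg_value``) on a white background;
    pores are disks of diameter ``pore_diameter`` punched back to background
    inside the network.  The truth records the measured foreground fraction.
    """
    if width < 8:
        raise ValueError("width must be >= 8 pixels")
    if strand_thickness <= 0:
        raise ValueError("strand_thickness must be > 0")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:width, 0:width].astype(float)
    fg = np.zeros((width, width), dtype=bool)
    for _ in range(n_strands):
        x0, y0 = rng.uniform(0, width, size=2)
        theta = rng.uniform(0, np.pi)
        nx, ny = -np.sin(theta), np.cos(theta)  # unit normal of the line
        dist = np.abs((xx - x0) * nx + (yy - y0) * ny)
        fg |= dist <= strand_thickness / 2.0
    pore_centers = []
    if n_pores > 0 and pore_diameter > 0:
        for _ in range(n_pores):
            cx, cy = rng.uniform(0, width, size=2)
            pore_centers.append((cx, cy))
            fg &= (xx - cx) ** 2 + (yy - cy) ** 2 > (pore_diameter / 2.0) ** 2
    image = np.where(fg, fg_value, bg_value).astype(np.uint8)
    truth = SyntheticTruth(
        kind="network_image", seed=seed,
        params={
            "width": width, "n_strands": n_strands,
            "strand_thickness": strand_thickness,
            "pore_diameter": pore_diameter, "n_pores": n_pores,
            "pore_centers": pore_centers,
            "foreground_fraction": float(fg.mean()),
            "fg_value": fg_value, "bg_value": bg_value,
        },
    )
    return image, truth


# ---------------------------------------------------------------------------
# Scattering series
# ---------------------------------------------------------------------------

def _gaussian_shell(r: np.ndarray, center: float, width: float) -> np.ndarray:
    g = np.exp(-0.5 * ((r - center) / width) ** 2)
    return g / np.trapezoid(g, r)


def gen_saxs_series(
    loads: Sequence[float] = (0.1, 0.25, 0.45, 0.65, 0.85, 1.0),
    df: float = 0.8,
    kappa: float = 0.0,
    noise_frac: float = 0.02,
    q_grid: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
    c_eq: Optional[Sequence[float]] = None,
    r_max: float = 20.0,
    n_r: int = 80,
    strand_peak: float = 5.5,
    strand_width: float = 1.0,
    layer_peak: float = 9.0,
    layer_width: float = 1.5,
    flat_fraction: float = 0.05,
    gain_range: Tuple[float, float] = (0.5, 2.0),
) -> Tuple[ConcentrationSeries, SyntheticTruth]:
    """Synthetic resin + antibody-layer scattering series with known truth.

    The blank is the fractal structure factor S(q) = q^-(df+1) (optionally
    screened) times the hull form factor of a strand shell peaked at
    ``strand_peak`` nm, plus a flat structure-only floor; each sample adds an
    antibody layer peaked at ``layer_peak`` nm scaled by its load, and is
    multiplied by a random per-sample gain to emulate uncalibrated intensity.
    Noise is multiplicative Gaussian with relative width ``noise_frac``.
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    if len(loads) < 1:
        raise ValueError("need at least one sample load")
    rng = np.random.default_rng(seed)
    if q_grid is None:
        q_grid = np.logspace(np.log10(0.05), np.log10(7.0), 200)
    q_grid = np.asarray(q_grid, dtype=float)
    r = np.linspace(r_max / n_r, r_max, n_r)
    strand = _gaussian_shell(r, strand_peak, strand_width)
    layer = _gaussian_shell(r, layer_peak, layer_width)
    basis = build_hull_matrix(q_grid, r)
    s_q = structure_factor_closed(q_grid, FractalParams(df=df, kappa=kappa))
    flat = flat_fraction * float(np.max(basis.matrix @ strand))

    def make_curve(density: np.ndarray, gain: float) -> ScatteringCurve:
        ideal = gain * (basis.matrix @ density + flat) * s_q
        if noise_frac > 0:
            intensity = ideal * (1.0 + noise_frac * rng.standard_normal(ideal.size))
            intensity = np.maximum(intensity, 1e-12 * ideal.max())
            sigma = noise_frac * ideal
            sigma = np.maximum(sigma, 1e-12 * sigma.max())
            return ScatteringCurve(q_grid, intensity, sigma)
        return ScatteringCurve(q_grid, ideal)

    blank = make_curve(strand, gain=1.0)
    if c_eq is None:
        c_eq = np.geomspace(0.01, 6.0, len(loads))
    gains = rng.uniform(gain_range[0], gain_range[1], size=len(loads))
    samples = []
    for k, (load, c, g) in enumerate(zip(loads, c_eq, gains)):
        curve = make_curve(strand + load * layer, gain=float(g))
        samples.append(SeriesSample(curve=curve, c_eq=float(c), q_ads=float(load),
                                    label=f"sample_{k + 1}"))
    series = ConcentrationSeries(blank=blank, samples=samples)
    truth = SyntheticTruth(
        kind="saxs_series", seed=seed,
        params={
            "loads": list(loads), "c_eq": list(c_eq), "gains": gains,
            "df": df, "kappa": kappa, "noise_frac": noise_frac,
            "r_grid": r, "strand_density": strand, "layer_density": layer,
            "strand_peak": strand_peak, "strand_width": strand_width,
            "layer_peak": layer_peak, "layer_width": layer_width,
            "flat_background": flat, "q_min": float(q_grid[0]),
            "q_max": float(q_grid[-1]), "n_q": int(q_grid.size),
        },
    )
    return series, truth


def gen_frames(
    curve: ScatteringCurve,
    n_frames: int = 10,
    counts_scale: float = 1e4,
    seed: Optional[int] = None,
) -> Tuple[List[ScatteringCurve], SyntheticTruth]:
    """Poisson-noise exposure frames of a true curve (detector emulation)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    peak = curve.intensity.max()
    frames = []
    for _ in range(n_frames):
        counts = rng.poisson(curve.intensity / peak * counts_scale)
        frames.append(ScatteringCurve(curve.q, counts * peak / counts_scale))
    truth = SyntheticTruth(kind="frames", seed=seed,
                           params={"n_frames": n_frames,
                                   "counts_scale": counts_scale})
    return frames, truth


# ---------------------------------------------------------------------------
# Isotherm tables
# ---------------------------------------------------------------------------

def gen_isotherm_data(
    params: BiLangmuirParams = DEFAULT_ISOTHERM_PARAMS,
    c_grid: Sequence[float] = DEFAULT_ISOTHERM_C_GRID,
    noise_frac: float = 0.03,
    seed: Optional[int] = None,
) -> Tuple[IsothermData, SyntheticTruth]:
    """Bi-Langmuir uptake points with multiplicative relative noise."""
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    rng = np.random.default_rng(seed)
    c = np.asarray(c_grid, dtype=float)
    q = bi_langmuir_q(c, params)
    if noise_frac > 0:
        q = q * (1.0 + noise_frac * rng.standard_normal(c.size))
        q = np.maximum(q, 0.0)
    data = IsothermData(c, q, meta={"noise_frac": noise_frac})
    truth = SyntheticTruth(
        kind="isotherm", seed=seed,
        params={"q1m": params.q1m, "b1": params.b1, "q2m": params.q2m,
                "b2": params.b2, "noise_frac": noise_frac, "c_grid": c},
    )
    return data, truth


# ---------------------------------------------------------------------------
# Toy bead structures
# ---------------------------------------------------------------------------

def _bead_sphere(center: np.ndarray, radius: float, spacing: float) -> np.ndarray:
    k = int(np.floor(radius / spacing))
    axis = spacing * np.arange(-k, k + 1)
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    grid = grid[np.linalg.norm(grid, axis=1) <= radius]
    return grid + center


def gen_toy_antibody_and_domain(
    scale: float = 1.0,
    seed: Optional[int] = None,
    bead_spacing: float = 0.6,
) -> Tuple[CentroidModel, CentroidModel, SyntheticTruth]:
    """Synthetic bead stand-ins for an IgG antibody and a protein-A domain.

    These are geometric toys, not crystal structures: the antibody is a
    Y-shaped three-lobe bead model (lobe diameter ~5 nm, overall extent
    ~13 nm, matching the hydrodynamic scale of an IgG1 whose pair density
    peaks near 3 and 7 nm), with its consensus-site anchor on the stem (Fc)
    lobe surface; the domain is a compact ~2.5 nm bead blob with terminal
    and binding-face anchors.  They let the assembly machinery run without
    any structure download.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    s = scale
    lobe_r = 2.5 * s
    spacing = bead_spacing * s
    stem_center = np.array([0.0, 0.0, -4.0 * s])
    arm_centers = [np.array([-3.0 * s, 0.0, 3.0 * s]),
                   np.array([3.0 * s, 0.0, 3.0 * s])]
    beads = [_bead_sphere(stem_center, lobe_r, spacing)]
    beads += [_bead_sphere(c, lobe_r, spacing) for c in arm_centers]
    ab_pts = np.vstack(beads)
    antibody = CentroidModel(
        ab_pts,
        np.full(ab_pts.shape[0], "antibody_1", dtype=object),
        anchors={"consensus_site": stem_center + np.array([0.0, 0.0, -lobe_r])},
        meta={"toy": True, "lobe_radius": lobe_r},
    )
    dom_r = 1.25 * s
    dom_pts = _bead_sphere(np.zeros(3), dom_r, spacing)
    domain = CentroidModel(
        dom_pts,
        np.full(dom_pts.shape[0], "ligand_domain_1", dtype=object),
        anchors={
            "n_term": np.array([0.0, 0.0, -dom_r]),
            "c_term": np.array([0.0, 0.0, dom_r]),
            "binding_face": np.array([dom_r, 0.0, 0.0]),
        },
        meta={"toy": True, "radius": dom_r},
    )
    truth = SyntheticTruth(
        kind="toy_structures", seed=seed,
        params={"scale": scale, "bead_spacing": bead_spacing,
                "antibody_beads": int(ab_pts.shape[0]),
                "domain_beads": int(dom_pts.shape[0]),
                "lobe_radius": lobe_r, "domain_radius": dom_r},
    )
    return antibody, domain, truth
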