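"""Experimental-curve pipeline: from a concentration series of scattering
curves to a normalized surface-excess isotherm.

Stages, in order: average detector frames; estimate the structure exponent
Df from the low-q slope of the blank (bare resin) curve; divide out the
fractal structure factor (multiply by q^(Df+1)); invert each corrected curve
to a radial density p'(R); scale every sample density onto the resin density
over the small-R window (default 6 nm) where only the agarose strand
scatters; subtract the resin density; integrate 4*pi*R^2*p'(R) to a surface
excess; normalize the excess series by its value at the highest equilibrium
concentration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .containers import FractalParams, RadialDensity, ScatteringCurve
from .transforms import InversionConfig, ShellInversion

__all__ = [
    "SeriesSample",
    "ConcentrationSeries",
    "SurfaceExcessIsotherm",
    "StructureExponentFit",
    "average_frames",
    "estimate_structure_exponent",
    "correct_by_structure_factor",
    "normalize_to_resin",
    "background_subtract",
    "surface_excess",
    "assemble_excess_isotherm",
    "concentration_difference_density",
]

logger = logging.getLogger(__name__)


@dataclass
class SeriesSample:
    """One measured sample: curve, equilibrium concentration, uptake, label."""

    curve: ScatteringCurve
    c_eq: float
    q_ads: float = float("nan")
    label: str = ""


@dataclass
class ConcentrationSeries:
    """Blank (resin-only) curve plus a concentration series of samples.

    All curves are resampled once onto the blank's q grid at construction
    (logged) so every later stage can assume a common grid.
    """

    blank: ScatteringCurve
    samples: List[SeriesSample]

    def __post_init__(self) -> None:
        for s in self.samples:
            if s.curve.q.shape != self.blank.q.shape or not np.allclose(
                s.curve.q, self.blank.q
            ):
                logger.info("resampling sample %r onto the blank q grid", s.label)
                s.curve = s.curve.resampled(self.blank.q)


@dataclass
class SurfaceExcessIsotherm:
    """Normalized surface excess versus equilibrium concentration."""

    points: List[Tuple[float, float]]
    reference_label: str = ""

    def __post_init__(self) -> None:
        if self.points:
            ref = max(self.points, key=lambda p: p[0])
            all_zero = all(p[1] == 0.0 for p in self.points)
            if not all_zero and abs(ref[1] - 1.0) > 1e-9:
                raise ValueError("the reference point must have excess exactly 1")


@dataclass
class StructureExponentFit:
    """Low-q power-law fit of a blank curve: Df with diagnostics."""

    params: FractalParams
    slope: float
    goodness: float
    q_window: Tuple[float, float]


def average_frames(
    frames: Sequence[ScatteringCurve], outlier_z: float = 3.0
) -> ScatteringCurve:
    """Pointwise mean of repeated exposure frames with outlier rejection.

    A frame is discarded when the median of its deviation from the pointwise
    median curve exceeds ``outlier_z`` robust standard deviations (a guard
    against radiation-damaged exposures).  The propagated uncertainty is the
    pointwise standard deviation over kept frames divided by sqrt(n_kept).
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    q = frames[0].q
    for f in frames[1:]:
        if f.q.shape != q.shape or not np.allclose(f.q, q):
            raise ValueError("frames must share a common q grid")
    stack = np.array([f.intensity for f in frames])
    if len(frames) == 1:
        keep = np.array([True])
    else:
        med = np.median(stack, axis=0)
        dev = np.median(stack - med, axis=1)
        mad = np.median(np.abs(dev - np.median(dev)))
        robust_sd = 1.4826 * mad
        if robust_sd == 0:
            keep = np.ones(len(frames), dtype=bool)
        else:
            keep = np.abs(dev - np.median(dev)) <= outlier_z * robust_sd
    if not keep.any():
        raise ValueError("all frames rejected as outliers")
    kept = stack[keep]
    mean = kept.mean(axis=0)
    if kept.shape[0] > 1:
        sd = kept.std(axis=0, ddof=1) / np.sqrt(kept.shape[0])
        sigma = np.where(sd > 0, sd, np.nan)
        sigma = None if np.all(np.isnan(sigma)) else np.nan_to_num(
            sigma, nan=max(sd[sd > 0].min(), 1e-300) if np.any(sd > 0) else 1.0
        )
    else:
        sigma = None
    return ScatteringCurve(q, mean, sigma,
                           meta={"n_frames": len(frames), "n_kept": int(keep.sum())})


def estimate_structure_exponent(
    blank: ScatteringCurve,
    q_window: Optional[Tuple[float, float]] = None,
) -> StructureExponentFit:
    """Structure exponent Df from the low-q slope of the blank resin curve.

    Df = |slope of log I vs log q| - 1 over ``q_window`` (default: the
    lowest decade of the measured q range).
    """
    if q_window is None:
        q_window = (float(blank.q[0]), float(10.0 * blank.q[0]))
    lo, hi = q_window
    sel = (blank.q >= lo) & (blank.q <= hi) & (blank.intensity > 0)
    if sel.sum() < 5:
        raise ValueError("fewer than 5 usable points in the q window")
    x = np.log(blank.q[sel])
    y = np.log(blank.intensity[sel])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    df = abs(float(slope)) - 1.0
    return StructureExponentFit(
        params=FractalParams(df=df, kappa=0.0),
        slope=float(slope),
        goodness=max(0.0, min(1.0, r2)),
        q_window=(float(lo), float(hi)),
    )


def correct_by_structure_factor(
    curve: ScatteringCurve, fractal: FractalParams
) -> ScatteringCurve:
    """Divide out the unscreened fractal structure factor S(q) = q^-(df+1).

    Multiplies intensity (and sigma) by q^(df+1), leaving the form-factor
    proxy P(q).
    """
    factor = curve.q ** (fractal.df + 1.0)
    sigma = None if curve.sigma is None else curve.sigma * factor
    meta = dict(curve.meta)
    meta["structure_corrected_df"] = fractal.df
    return ScatteringCurve(curve.q, curve.intensity * factor, sigma, meta)


def undo_structure_factor_correction(
    curve: ScatteringCurve, fractal: FractalParams
) -> ScatteringCurve:
    """Inverse of :func:`correct_by_structure_factor`."""
    factor = curve.q ** (-(fractal.df + 1.0))
    sigma = None if curve.sigma is None else curve.sigma * factor
    return ScatteringCurve(curve.q, curve.intensity * factor, sigma, dict(curve.meta))


def _match_scale(density: RadialDensity, resin: RadialDensity, r_match: float) -> float:
    if density.r.shape != resin.r.shape or not np.allclose(density.r, resin.r):
        raise ValueError("density and resin must share a common r grid")
    win = density.r <= r_match
    ref = resin.density[win]
    tgt = density.density[win]
    if not np.any(ref != 0):
        raise ValueError(f"resin density is identically zero on [0, {r_match}] nm")
    denom = float(tgt @ tgt)
    if denom == 0:
        raise ValueError("sample density is identically zero on the matching window")
    return float(tgt @ ref) / denom


def normalize_to_resin(
    density: RadialDensity, resin: RadialDensity, r_match: float = 6.0
) -> RadialDensity:
    """Scale a sample density onto the resin density over [0, r_match] nm.

    Antibody does not penetrate the agarose strand, so below ``r_match`` a
    sample's radial density must match the bare resin's; the least-squares
    scale c* = argmin_c sum_{R<=r_match} (c*density - resin)^2 removes the
    unknown per-sample intensity gain.
    """
    c_star = _match_scale(density, resin, r_match)
    if c_star <= 0:
        raise ValueError(f"non-positive normalization scale c*={c_star}")
    out = RadialDensity(density.r.copy(), density.density * c_star, density.kind,
                        dict(density.meta))
    out.meta.update({"normalization_scale": c_star, "r_match": r_match})
    return out


def background_subtract(
    normalized: RadialDensity, resin: RadialDensity
) -> RadialDensity:
    """Subtract the resin radial density from a normalized sample density."""
    if normalized.r.shape != resin.r.shape or not np.allclose(normalized.r, resin.r):
        raise ValueError("grid mismatch between sample and resin densities")
    return RadialDensity(
        normalized.r.copy(),
        normalized.density - resin.density,
        kind="background_corrected",
        meta=dict(normalized.meta),
    )


def surface_excess(corrected: RadialDensity) -> float:
    """Surface excess Gamma = integral of 4*pi*R^2*p'(R) dR (trapezoid)."""
    if corrected.kind != "background_corrected":
        raise ValueError("surface excess requires a background-corrected density")
    return float(np.trapezoid(4.0 * np.pi * corrected.r**2 * corrected.density,
                              corrected.r))


def assemble_excess_isotherm(
    series: ConcentrationSeries,
    fractal: Optional[FractalParams] = None,
    config: Optional[InversionConfig] = None,
    r_match: float = 6.0,
    q_window: Optional[Tuple[float, float]] = None,
) -> Tuple[SurfaceExcessIsotherm, dict]:
    """Run the full pipeline on a concentration series.

    Per sample: structure-factor correction, inversion, normalization to the
    resin density on [0, r_match], background subtraction, surface excess;
    finally the excess values are normalized by the value at the highest
    equilibrium concentration.  Returns the isotherm plus a per-stage
    artifact dict for audit.
    """
    if not series.samples:
        raise ValueError("series contains no samples")
    config = config or InversionConfig()
    artifacts: dict = {}

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if fractal is None:
        fit = stage("estimate_structure_exponent",
                    estimate_structure_exponent, series.blank, q_window)
        fractal = fit.params
        artifacts["structure_exponent"] = fit
    resin_res = stage(
        "invert_blank",
        lambda: ShellInversion(series.blank, fractal, config).fit(),
    )
    resin = resin_res.density
    artifacts["resin_density"] = resin
    artifacts["samples"] = {}

    # one regularization weight for the whole series: the blank's choice is
    # reused so every density sees the identical smoothing operator, which
    # the small-R normalization window relies on
    from dataclasses import replace as _replace

    sample_config = _replace(config, alpha=resin_res.alpha)

    raw_excess: List[Tuple[float, float, str]] = []
    for s in series.samples:
        inv = stage(
            f"invert[{s.label}]",
            lambda c=s.curve: ShellInversion(c, fractal, sample_config).fit(),
        )
        norm = stage(f"normalize[{s.label}]",
                     normalize_to_resin, inv.density, resin, r_match)
        corr = stage(f"subtract[{s.label}]", background_subtract, norm, resin)
        gamma = stage(f"excess[{s.label}]", surface_excess, corr)
        artifacts["samples"][s.label] = {
            "inversion": inv, "normalized": norm, "corrected": corr, "gamma": gamma,
        }
        raw_excess.append((s.c_eq, gamma, s.label))

    ref = max(raw_excess, key=lambda t: t[0])
    artifacts["raw_excess"] = raw_excess
    if ref[1] == 0:
        # a series of blanks: every excess is (numerically) zero
        points = [(c, 0.0) for c, g, _ in raw_excess]
    else:
        points = [(c, g / ref[1]) for c, g, _ in raw_excess]
    return SurfaceExcessIsotherm(points=points, reference_label=ref[2]), artifacts


def concentration_difference_density(
    curve_hi: ScatteringCurve,
    curve_lo: ScatteringCurve,
    fractal: FractalParams,
    weight: Optional[float] = None,
    config: Optional[InversionConfig] = None,
    r_tail: Optional[float] = None,
) -> RadialDensity:
    """Density of the concentration difference of two curves (de-tailing).

    Inverting the difference curve I_hi - w * I_lo removes contributions the
    two samples share (e.g. parasitic structure tails), leaving the
    concentration-dependent monomer signal.  When ``weight`` is not given it
    is fitted so the two inverted densities match beyond ``r_tail`` (default
    0.6 * r_max) — the region where the shared tail dominates — with the
    same least-squares scale machinery used against the resin.
    """
    if curve_hi.q.shape != curve_lo.q.shape or not np.allclose(curve_hi.q, curve_lo.q):
        raise ValueError("curves must share a common q grid")
    config = config or InversionConfig()
    if weight is None:
        if r_tail is None:
            r_tail = 0.6 * config.r_max
        d_hi = ShellInversion(curve_hi, fractal, config).fit().density
        d_lo = ShellInversion(curve_lo, fractal, config).fit().density
        tail = d_hi.r >= r_tail
        num = float(d_lo.density[tail] @ d_hi.density[tail])
        den = float(d_lo.density[tail] @ d_lo.density[tail])
        if den == 0:
            raise ValueError("no tail signal to match the weight on")
        weight = num / den
    diff = curve_hi.intensity - weight * curve_lo.intensity
    neg_mass = -np.sum(diff[diff < 0])
    pos_mass = np.sum(diff[diff > 0])
    if pos_mass == 0 and neg_mass == 0:
        r = config.r_grid()
        return RadialDensity(r, np.zeros_like(r), kind="radial_density",
                             meta={"weight": float(weight)})
    if neg_mass > pos_mass:
        raise ValueError("difference curve is negative-dominated; check the weight")
    if np.any(diff < 0):
        warnings.warn("difference curve clipped at zero where negative", stacklevel=2)
        diff = np.maximum(diff, 0.0)
    dcurve = ScatteringCurve(curve_hi.q, diff, meta={"difference_weight": float(weight)})
    res = ShellInversion(dcurve, fractal, config).fit()
    out = res.density
    out.meta["weight"] = float(weight)
    return out
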