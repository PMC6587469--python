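# Methods

This note documents the models implemented in `resinsaxs`, their
assumptions, the defaults that matter, what the synthetic-data generators
do and do not emulate, and the numerical choices made where the design was
genuinely open.

## Scattering model

The system is antibody bound to tetrameric protein-A ligands that are
covalently attached to agarose strands of a chromatography resin.  Two
length scales separate: the antibody–ligand complex (a few to ~20 nm) and
the fractal arrangement of such complexes across the resin network (tens to
hundreds of nm).  On that assumption the intensity factorizes,
`I(Q) = P(Q) S(Q)`, with no cross term.

**Structure factor.**  The network's pair density is modelled as
`p_S(r) = r^Df exp(−κr)` with fractal dimension `Df > 0` and screening
parameter `κ ≥ 0` (units 1/nm).  Its transform against the spherical
kernel `J_{1/2}(Qr)/(Qr)^{1/2} = √(2/π)·sin(Qr)/(Qr)` has the exact closed
form

```
S(Q) = √(2/π) Γ(Df) sin(Df·arctan(Q/κ)) / (Q (κ² + Q²)^(Df/2)),   κ > 0,
```

verified in the tests against adaptive quadrature to a relative error
below 1e−6 for `Df ∈ {0.5, 0.74, 0.8, 1.5}` and `κ ∈ {0.01, 0.1, 1}`.
Two checks pin the convention: the `Df → 0` limit reproduces
`∫ e^{−κr} sin(Qr)/r dr = arctan(Q/κ)` and the `Q → 0` limit reproduces
the moment `√(2/π) Γ(Df+1)/κ^{Df+1}`.  `κ = 0` encodes the unscreened
limit and returns the pure power law `Q^−(Df+1)` with unit prefactor; all
proportionality constants are deliberately unit — absolute scale is
carried by the normalization stage.  Note the κ → 0 closed form and the
κ = 0 power law differ by a constant; only shapes are meaningful here.

**Form factor and the hull basis.**  Radial symmetry about the strand
backbone is enforced by expanding the scatterer on thin spherical hulls:
a hull of radius `R` has pair density `p_p(r,R) = r/(2R²)` on `[0, 2R]`
(unit area) and scattering amplitude `K(QR)` with `K(x) = √(2/π) sin(x)/x`.
Discretized with trapezoid weights `w_j` on an `R` grid this gives the
linear operator

```
A[i, j] = 4π R_j² w_j K(q_i R_j)²,     y = I(q)·q^(Df+1) ≈ A p'.
```

Default `R` grid: 0.25 nm spacing up to `r_max` (40 nm by default; the
synthetic studies use 20 nm, which comfortably contains strand plus
adsorbed layer and keeps the operator well conditioned).  All q are in
1/nm, all distances in nm; `d = 2π/Q` converts between them.

**Inversion.**  `ShellInversion` solves

```
min_{p ≥ 0, c ≥ 0}  ‖W(A p + c·1 − y)‖² + α s ‖D₂ p‖²
```

with `W` the inverse per-point uncertainties of `y` (uniform when the
curve has no sigma), `D₂` the second-difference roughness operator, and
`s` the squared largest singular value of `WA` so that `α` is a
dimensionless smoothing weight.  The constant column `c` absorbs any flat
component of the corrected intensity — a structure-only curve (pure power
law) therefore inverts to `p' ≈ 0` rather than to spurious small-R hulls.
Nonnegativity is enforced with bounded least squares
(`scipy.optimize.lsq_linear`).

When `α` is not fixed by the caller it is chosen from a 17-point
logarithmic grid (1e−7 … 10) by a residual-plateau rule: the largest `α`
whose residual stays within 10% of the minimum achievable over the grid.
The residual is flat (noise- or discretization-limited) left of the corner
of the regularization path and rises steeply beyond it, so this picks the
corner robustly for noisy and noiseless data alike; classical L-curve
curvature heuristics proved unstable across those two regimes.  The
condition number of the weighted operator is reported on the results
object rather than silently accepted (typical values are large — the
basis is deliberately redundant and the regularization carries the
stabilization).

## Concentration-series pipeline

Stages, in order, for a blank (bare resin) curve and samples at increasing
antibody concentration, all resampled once onto the blank's q grid at
ingestion:

1. **Frame averaging** (for multi-exposure acquisitions): pointwise mean
   after discarding frames whose median deviation from the pointwise
   median curve exceeds 3 robust standard deviations — a guard against
   radiation-damaged exposures; propagated sigma is sd/√n.
2. **Structure exponent**: `Df = |slope of log I vs log q| − 1` over the
   lowest decade of q of the blank (configurable window).  The window must
   lie where the structure factor dominates, i.e. below the form-factor
   shoulder `q ≈ 1/R_strand`.
3. **Correction**: multiply by `q^(Df+1)` (κ = 0 convention; the screened
   form is available but off by default).
4. **Inversion** of every curve.  The blank's `α` is reused for all
   samples of the series so the whole series sees one smoothing operator —
   the window matching below is meaningless if each curve is smoothed
   differently.
5. **Normalization**: antibody does not penetrate the cross-linked strand,
   so each sample density must match the resin density below
   `r_match = 6 nm`; "match" is operationalized as a single multiplicative
   scale `c* = argmin_c Σ_{R ≤ 6} (c·p_sample − p_resin)²`.  Normalizing
   an already-normalized density returns scale 1.
6. **Background subtraction**: pointwise `p_sample − p_resin`; the result
   may be signed.
7. **Surface excess**: `Γ = ∫ 4πR² p'(R) dR` by trapezoid rule; the
   series is normalized by Γ at the highest equilibrium concentration.

**De-tailing** (`concentration_difference_density`): two solution curves
at different concentrations share parasitic long-distance tails that do
not scale with concentration.  The weight `w` in `I_hi − w·I_lo` is fitted
so the two inverted densities match beyond `0.6·r_max` (where the shared
tail dominates); subtracting then cancels the tail and leaves the monomer
signal.  A negative-dominated difference is rejected, small negative
excursions are clipped with a warning.

## Fractal image analysis

A micrograph is binarized (Otsu by default, fixed threshold optional;
foreground = darker pixels = polymer network).  10,000 sites are drawn
i.i.d. with replacement either restricted to the network or from the whole
frame (white noise).  The pair density of the sites — all pairs, or a
seeded uniform subsample when above `max_pairs` (default 1e7) — is fitted
on log–log axes over the smallest decade of r containing at least 5
populated bins.  Bins are weighted by their counts (Poisson: the variance
of log count is ≈ 1/count).  In this convention a uniform D-dimensional
set gives `Df = D − 1`: 2D white noise → 1.0, a line → 0.0, a 3D ball
→ 2.0.

For compact observation windows the pair density carries a finite-domain
boundary correction, `p(r) ∝ r^Df (1 − c r + …)`.  Setting
`boundary_order ≥ 1` adds nuisance terms `b_k r^k` to the fit, which
absorb that correction and let the window extend well beyond the strict
small-r regime without biasing Df — used for the 3D calibration, where
the small-r bins alone are too sparse at 10,000 points.

**Pore-size fluctuation.**  The network and white-noise pair densities are
renormalized to unit area (the same amount of relative distances) and
subtracted.  A heterogeneity of size `d` enriches the network's pair
density below `d`; through the shared normalization it depletes it
everywhere else, and a single image additionally carries quenched
fluctuations of the specific pore arrangement at all scales.  The robust
pore observable is therefore the initial contiguous positive excess at
small r; the summary reports where it first falls below 1% (configurable)
of its maximum.  On synthetic punched-pore images this tracks the pore
diameter with single-realization scatter of roughly ±20%, so the test
asserts the mean over a fixed panel of six seeded images.

## Adsorption isotherm

Batch depletion uptake uses the mass balance
`q = (C₀ − C_eq)(V_total − V_resin)/V_resin`; the resin displaces liquid,
so the liquid volume excludes it (a `liquid_volume="total"` flag restores
the naive convention).  The two-site model

```
q(C) = q1m·b1·C/(1 + b1·C) + q2m·b2·C/(1 + b2·C),   b1 ≥ b2 by convention
```

is fitted by bounded nonlinear least squares in log-parameter space from
32 seeded log-uniform starts (the two-site likelihood has flat valleys
when the sites are weakly separated); data-driven bounds span the observed
q and C ranges.  Standard errors come from the residual Jacobian on the
natural scale; AICc compares against the nested single-site Langmuir fit.
Residuals are unweighted by default; relative weighting (1/q) is
appropriate — and used in the recovery studies — when the noise is
multiplicative.

**Synthetic default.**  The generator's default truth
(`q1m = 20, b1 = 100, q2m = 80, b2 = 0.5`, C in mg/ml, q in mg/ml resin)
and its design (triplicates at C = 0.01, 0.1, 1, 10 mg/ml; 12 points over
the 0.01–10 mg/ml batch range) were chosen by Fisher-information analysis
so that all four parameters are identifiable at 3% relative noise: the
high-affinity site saturates from the lowest level while the
capacity-dominant low-affinity site is still rising at the top level
(asymptotic relative standard errors all below 0.10).  Many superficially
similar quadruples — including equal-capacity sites with a weak `b2` —
leave `b2` with a Cramér–Rao floor above 25% under the same conditions, so
no estimator could recover them to 10%; recovery claims are only
meaningful on an identifiable design.  Total capacity (100 mg/ml resin)
and the rectangular high-affinity branch are in the range reported for
protein-A resins.

## Rigid-body assemblies

All entities are rigid per-residue (or per-bead) centroid sets in nm:
an agarose strand — beads on a cylinder surface (default radius 6 nm,
matching the resin density maximum at 5–6 nm read as the minimum strand
radius) plus its axis, the radial reference R = 0; four copies of the
ligand domain chained N-to-C terminus as a random walk (uniform rotations
via unit quaternions, linker 1.0 nm, loop-like folds allowed); antibodies
docked with their Fc consensus-site anchor 0.5 nm from a domain's
binding-face anchor along the domain's outward normal (tilted uniformly
within 30°), body facing away, spin uniform about the contact axis, one
antibody per domain.

Acceptance is purely geometric — no energy model: an assembly is accepted
iff no two centroids of *different* entities are closer than the clash
cutoff (0.4 nm, ≈ van der Waals contact at centroid resolution);
intra-entity pairs are exempt.  The chain builder enforces the same cutoff
between all domain pairs during growth, and the covalent strand attachment
places the first N-anchor one contact distance off the strand surface, so
construction and final filter agree.  Under these defaults the clash-free
acceptance rate falls monotonically with stoichiometry (roughly 13% / 3% /
1% for 1:1 / 2:1 / 3:1 with the toy bead models), which is the geometric
content of the steric exclusion of high stoichiometries.

Radial densities of accepted assemblies are histograms of non-agarose
centroid distances from the strand axis; similarity to an experimental
profile is the L2 distance after unit-area normalization on the union
grid (symmetric; zero iff identical).  Ranking reports each library's best
member, with ties broken toward fewer antibodies, then lower domain
indices.  Whether the original similarity assessment was visual or metric
is unknowable; the L2 metric is this package's choice.

**Toy structures.**  `gen_toy_antibody_and_domain` builds synthetic bead
stand-ins (not crystal structures): a Y-shaped three-lobe antibody (lobe
diameter 5 nm, extent ~13 nm — the hydrodynamic scale of an IgG whose
pair density peaks near 3 and 7 nm and extends to ~12 nm) and a compact
2.5 nm domain blob, with documented anchors.  Bead spacing 0.6 nm mimics
the density of residue centroids so the clash cutoff acts at comparable
resolution.  They carry no internal structure beyond the lobe geometry,
so structure-derived anchors (the 3/7 nm pair-density maxima of a real
IgG, the ~21 nm extent of real 2:1 complexes) can only be checked against
actual PDB entries placed under `data/structures/`.

## Synthetic scattering series

`gen_saxs_series` emulates the measurement: blank = (hull operator applied
to a strand shell, Gaussian, peak 5.5 nm, width 1 nm) plus a flat
structure-only floor (5% of the form-factor maximum), all times `S(Q)`
with `Df = 0.8`; each sample adds an antibody-layer shell (peak 9 nm,
width 1.5 nm) scaled by its load, times a random per-sample gain
(log-range 0.5–2) that the normalization stage must undo.  Noise is
multiplicative Gaussian, default 2% (Poisson frames available separately
via `gen_frames`).  The default q grid spans 0.003–7 1/nm: the low end
sits well below the strand form-factor shoulder so that the lowest decade
is structure-dominated, which is what the low-Q slope estimator assumes;
on instruments with a higher q_min the fit window must be placed
accordingly.  What the generator does *not* emulate: instrument smearing,
buffer/capillary backgrounds beyond the flat term, inter-particle
cross-terms, concentration-dependent layer shapes, and detector artifacts
— passing tests show the chain is consistent and invertible under the
model's own assumptions, not that real data meet them.

## Known limitations

- The inversion's hull basis enforces radial symmetry; anisotropic
  adsorbate arrangements project onto it.
- The κ = 0 correction is a pure power law; curvature in the true
  structure factor leaks into the recovered densities at the lowest q.
- Surface excess is relative (arbitrary units); only ratios across a
  series are meaningful.
- Rigid-body libraries ignore antibody flexibility, glycans and
  energetics; acceptance rates depend on the coarse bead resolution
  through the clash cutoff.
- The fractal dimension estimator assumes a single power-law regime within
  its fit window; crossovers bias the slope.
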