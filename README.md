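# resinsaxs

Small-angle X-ray scattering (SAXS) analysis of protein adsorption on
fractal chromatography resins — the "pearl necklace" picture of antibodies
bound to tetrameric protein-A ligands on agarose strands.

Protein-A affinity chromatography is the workhorse capture step for
monoclonal antibody purification, yet how antibodies arrange themselves on
the immobilized tetrameric ligand chain (how many bind per chain, to which
domain, how far from the strand) is hard to observe directly.  `resinsaxs`
implements a complete analysis chain for researchers studying such
protein–surface systems:

- **Scattering model.** The measured intensity factorizes as
  `I(Q) = P(Q) · S(Q)`.  The resin's cross-linked agarose network imposes a
  mass-fractal structure factor: its pair density follows
  `p_S(r) ∝ r^Df · exp(−κr)`, whose sine transform is, for κ > 0,

  ```
  S(Q) = √(2/π) · Γ(Df) · sin(Df · arctan(Q/κ)) / (Q · (κ² + Q²)^(Df/2)),
  ```

  reducing to the pure power law `S(Q) ∝ Q^−(Df+1)` as κ → 0.  The form
  factor is expanded on thin spherical hulls of radius `R` centred on the
  strand backbone, each with pair density `p_p(r, R) ∝ r/R² · H(2R − r)`,
  giving the linear working equation

  ```
  I(Q) · Q^(Df+1)  ∝  ∫ dR 4πR² p'(R) |J_{1/2}(QR)/(QR)^{1/2}|².
  ```

  `p'(R)` — the radial density of material versus distance from the strand
  axis — is recovered by nonnegative Tikhonov-regularized inversion
  (`ShellInversion`, a statsmodels-style model whose `fit()` returns a
  results object).

- **Pipeline.** For a blank-resin curve plus a concentration series:
  estimate `Df` from the low-Q slope, divide out `S(Q)`, invert each curve,
  scale every sample density onto the resin density below 6 nm (antibody
  does not penetrate the strand), subtract the resin background, and
  integrate `4πR²p'(R)` into a surface excess Γ.  Normalized by its value
  at the highest concentration this yields a surface-excess adsorption
  isotherm directly from scattering.

- **Adsorption model.** Batch depletion uptake
  `q = (C₀ − C_eq)(V_total − V_resin)/V_resin` and the two-site
  (bi-)Langmuir isotherm `q(C) = Σᵢ q_{i,m} bᵢC/(1 + bᵢC)` with multistart
  bounded fitting and AICc comparison against the nested single-site model
  (`BiLangmuir`).

- **Fractal image analysis.** Binarize a micrograph of the resin network,
  sample 10,000 sites from the network and from the whole frame (white
  noise), and estimate the fractal dimension `Df` as the small-r log–log
  slope of the pair density (a uniform D-dimensional set gives
  `Df = D − 1`); the difference of the two pair densities yields a
  pore-size scale.

- **Rigid-body modelling.** Per-residue centroid models from PDB/mmCIF
  structures, random-walk tetramer ligand chains on a coarse agarose
  strand, antibody docking at the Fc consensus site, purely geometric clash
  filtering (no energy model), libraries per stoichiometry (1:1, 2:1, 3:1),
  and L2 ranking of their radial densities against experimental profiles.

Every stage has a synthetic-data generator with a complete ground-truth
record (`resinsaxs.synthetic`), so the whole chain is testable offline.

## Worked example

Run the full pipeline on a synthetic six-sample concentration series and
fit a noisy synthetic uptake table:

```python
import numpy as np
from resinsaxs import InversionConfig, fit_bi_langmuir
from resinsaxs.synthetic import gen_saxs_series, gen_isotherm_data
from resinsaxs.pipeline import assemble_excess_isotherm

q = np.logspace(np.log10(0.003), np.log10(7.0), 240)
series, truth = gen_saxs_series(seed=42, q_grid=q)
iso, art = assemble_excess_isotherm(series, config=InversionConfig(r_max=20.0))

fit = art["structure_exponent"]
print(f"structure exponent Df = {fit.params.df:.3f}  (R^2 = {fit.goodness:.4f})")
resin = art["resin_density"]
print(f"resin density peak at R = {resin.r[np.argmax(resin.density)]:.2f} nm")
for (c, e) in iso.points:
    print(f"  C = {c:6.3f} mg/ml   Gamma/Gamma_max = {e:.3f}")

data, _ = gen_isotherm_data(noise_frac=0.03, seed=7)
res = fit_bi_langmuir(data, seed=0, weights=1.0 / np.maximum(data.q, 1e-9))
print(res.summary())
```

prints

```
structure exponent Df = 0.803  (R^2 = 0.9998)
resin density peak at R = 5.50 nm
  C =  0.010 mg/ml   Gamma/Gamma_max = 0.100
  C =  0.036 mg/ml   Gamma/Gamma_max = 0.262
  C =  0.129 mg/ml   Gamma/Gamma_max = 0.448
  C =  0.464 mg/ml   Gamma/Gamma_max = 0.654
  C =  1.669 mg/ml   Gamma/Gamma_max = 0.840
  C =  6.000 mg/ml   Gamma/Gamma_max = 1.000

Bi-Langmuir isotherm fit
========================
observations: 12   starts: 32 (converged 32)

            estimate     std err
q1m            18.96       0.434   [mg/ml resin]
b1               111        5.89   [ml/mg]
q2m            80.57        1.41   [mg/ml resin]
b2            0.5343      0.0285   [ml/mg]

RSS:  0.00250261   AICc: -87.99
nested Langmuir: qm=45.92, b=18.34, RSS=1.43162, AICc=-20.18
AICc prefers: two-site
```

The recovered structure exponent (0.803, true 0.8), the strand radius read
off the resin density peak (5.5 nm), the normalized surface-excess isotherm
tracking the generated antibody loads, and the two-site fit recovering the
generator's parameters (q1m = 20, b1 = 100, q2m = 80, b2 = 0.5) against a
decisively rejected single-site alternative are exactly the quantities the
analysis is built to deliver on measured data.

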