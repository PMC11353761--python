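# arealaw

Gas-phase standard molar entropy of small organic molecules, predicted from
the geometry of their van der Waals surface.

Thermodynamic entropy measures missing information about a system's
microstates. For several very different physical systems that information
scales with *surface area* rather than volume, and the same area law turns
out to describe molecules: the entropy of a gas-phase molecule is, to good
approximation, an affine function of its surface area, with corrections for
how strongly the surface is deformed away from sphericity by chemical
bonds. `arealaw` implements that model end to end — surface construction,
curvature statistics, entropy prediction, and the machinery to calibrate
the model against experimental entropies — for computational chemists who
need entropies in seconds rather than the CPU-hours of rigid-rotor /
harmonic-oscillator calculations (e.g. for docking, QSAR or virtual
screening workflows).

## The model

A molecule with atom centres rᵢ and van der Waals radii aᵢ defines a smooth
density

```
G(x) = Σᵢ exp(−(|x − rᵢ| − aᵢ) / σ),          σ = 0.1
```

whose level set G = 1 is the molecular surface (exactly the vdW sphere for
an isolated atom). The surface is triangulated by marching cubes on a
0.075 Å grid; at every vertex the principal curvatures κ₁ ≥ κ₂ are
evaluated analytically from ∇G and the Hessian of G, and combined into the
Koenderink shape index

```
S = (2/π)·arctan((κ₁ + κ₂)/(κ₁ − κ₂)) ∈ [−1, 1].
```

Triangles are classed as *spherical* (S ≥ 0.99, free atomic surface),
*positive deformation* (0 ≤ S < 0.99, two-atom bond necks) or *negative
deformation* (S < 0, junctions of several bonds). Binning each signed group
into 64 bins with probabilities pᵢ = kᵢ/k gives the entropy model

```
S_tharea = S₀ + a·A_spherical + b·Σ p⁺ln p⁺·Aₜ + c·Σ p⁻ln p⁻·Aₜ   [J/mol·K]
```

The p·ln p sums are non-positive, so with b, c > 0 bonds always reduce the
predicted entropy — bonded atoms move in a correlated way and carry less
missing information than free ones. Nested baselines `S = S₀ + a·A` (area
only) and `S = S₀ + v·V` (volume only) are included for comparison, as is
the dimensionless ultraviolet-cutoff coefficient C_UV = a·L²/(N_A k_B) with
L = 1.1 Å that connects the area slope to the analogous constants of other
area laws (1/4, 0.30).

Because the model is linear in (S₀, a, b, c), ordinary least squares is the
exact calibration; a real-coded genetic algorithm (fitness 1/RMSE,
crossover 0.75, mutation 0.25, bounds ±200/±100/±50/±50, 100 generations)
reproduces the original calibration protocol and is validated against the
OLS optimum. Confidence intervals come from a 100-replicate percentile
bootstrap.

## Worked example

```python
>>> import arealaw as al
>>> cfg = al.PipelineConfig()                      # σ=0.1, c=1, 0.075 Å grid
>>> h = al.make_fixture(al.FixtureSpec(kind="single_sphere", radius=1.1))
>>> d = al.compute_descriptor(h, cfg)
>>> round(d.total_area, 3), round(d.total_volume, 3)
(15.183, 5.56)                      # 4πr² = 15.205 Å², (4/3)πr³ = 5.575 Å³
>>> round(al.predict_stharea(d, al.load_default_coefficients()), 2)
151.05                              # = S₀ + a·A = 104.32 + 3.078·15.18
```

A single hydrogen atom is a pure closed-form oracle: its surface is the
1.1 Å sphere, entirely in the spherical class, so only the S₀ and a terms
contribute. From the shell:

```
$ arealaw predict mols.smi --grid-spacing 0.15
 id  total_area  area_spherical  frac_neg_percent    stharea      sarea
  C   44.557287        6.908566          0.000000 103.997320 205.637595
CCO   74.866520       16.775846         10.297043 126.610037 264.679980
```

`total_area` is the triangulated surface area (Å²), the class fractions
show how much of it is spherical / bond-deformed, and `stharea` / `sarea`
are the deformation-corrected and area-only predictions (J/mol·K) with the
packaged coefficients. `arealaw surface c1ccccc1` exports an OBJ/PLY mesh
with per-vertex shape index (and the 9-category Koenderink colouring) for
inspection; on benzene the negative-S band traces the ring centre and the
junctions between C–H bond necks.

A note on the packaged coefficients: they are the published calibration of
this model against 1942 experimental gas-phase entropies (190–1040
J/mol·K), shipped with their 95% bootstrap bounds. Descriptor conventions
(histogram normalization, curvature discretization) are not fully pinned
down by the published description, and deformation aggregates are sensitive
to them, so predictions on real molecules with the packaged deformation
coefficients should be treated with care; for quantitative work recalibrate
on your own data with `arealaw fit` (CSV columns `id, smiles,
s_expt_jmolk`), which refits S₀, a, b, c to *your* descriptor pipeline.
The area-only baseline transfers well (n-decane: predicted 537.5 vs
experimental 545.7 J/mol·K).

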