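# Methods

## Model

The package predicts gas-phase standard molar entropy (25 °C, J/mol·K)
from the geometry of a molecule's smooth van der Waals surface. The
underlying hypothesis is an area law: the missing information about a
molecule's microstates scales with its surface area, and deviations of the
surface from sphericity — which mark chemical bonds and therefore
correlated atomic motion — reduce it. The working form is

    S_tharea = S0 + a·A_sph + b·Σ_{t: 0≤S_t<0.99} p(S_t)·ln p(S_t)·A_t
                         + c·Σ_{t: S_t<0}        p(S_t)·ln p(S_t)·A_t

summed over mesh triangles t with area A_t and shape index S_t. A_sph is
the area with S ≥ 0.99. S0 carries units of entropy; a, b, c of entropy
per Å². The p·ln p aggregates are ≤ 0 by construction, so with b, c > 0
the deformation terms only lower the prediction relative to a fully
spherical surface. Two nested baselines, S = S0 + a·A_total and
S = S0 + v·V, quantify what the curvature corrections add.

Assumptions worth keeping in mind:

* one conformer represents the molecule (justified below),
* each element has a single, environment-independent vdW radius,
* positive and negative deformations contribute independently,
* temperature enters only through the fitted constants.

## Surface construction

Density field: G(x) = Σᵢ exp(−(|x−rᵢ|−aᵢ)/σ) with smoothing σ = 0.1
(dimensionless scale factor applied to distances in Å; smaller σ = sharper
surface detail) and isovalue c = 1.0. For an isolated atom the level set
is exactly the sphere |x−r| = a.

Grid: uniform spacing 0.075 Å, padding 2.0 Å beyond every atom sphere
(the field decays as e^(−d/σ), i.e. ~e^(−20) at the box edge). The grid
origin is snapped *down to a multiple of the spacing*, anchoring the
sampling lattice in space rather than to the molecule: translating a
molecule by a non-grid vector then genuinely re-discretizes the surface,
which is what the rigid-motion robustness checks measure (observed: area
changes < 0.01%, predictions < 0.1%).

Triangulation: marching cubes (scikit-image, Lewiner variant) applied to
**ln G at level ln c**. The level set is mathematically identical to
G = c, but marching cubes places vertices by *linear* interpolation along
cell edges, and G varies exponentially with distance on the scale of
σ ≈ the grid spacing. ln G is exactly linear in the radial coordinate of
an isolated atom, so interpolating it removes almost all placement bias:
on the single-H sphere the area error drops from ≈0.5% (interpolating G)
to ≈0.14%, and the 0.075→0.125 Å coarsening changes areas of 20–60-atom
surfaces by ≈0.1–0.2% instead of >1%. All disconnected surface components
(e.g. salts) are kept and pooled.

Curvature: at every mesh vertex the gradient g and Hessian H of G are
evaluated in closed form and combined with the standard implicit-surface
formulas

    H_mean  = (gᵀHg − |g|²·tr H) / (2|g|³)
    K_gauss = (gᵀ·adj(H)·g) / |g|⁴
    κ₁,₂    = H_mean ± √max(H_mean²−K_gauss, 0)

signed so that a single-atom sphere is convex with κ₁ = κ₂ = +1/r
(outward normal along decreasing G; G > c inside). Vertices are used as
placed by edge interpolation — they sit within O(spacing²) of the true
isosurface and the sphere oracle shows curvature errors < 0.1%, so no
projection step is applied. The shape index is computed as
(2/π)·arctan2(κ₁+κ₂, κ₁−κ₂), which yields the umbilic limit ±1 and the
flat-point convention S = 0 without special-casing. Vertices with
|∇G| < 10⁻¹² are flagged degenerate and excluded; a triangle inherits the
mean shape index of its remaining vertices and is dropped from statistics
only if all three vertices are degenerate.

## Shape statistics

The per-triangle shape index is the arithmetic mean of its vertex values.
Classes: spherical S ≥ 0.99 (threshold inclusive), positive 0 ≤ S < 0.99
(S = 0 belongs here), negative S < 0. Histograms use 64 uniform bins per
signed group — 64 over [0, 0.99) and 64 over [−1, 0) — because the two
groups enter the model independently. Probabilities are normalized by the
*total* triangle count k of the mesh (including spherical triangles), and
p·ln p is taken as 0 for empty bins. The logarithm is natural by default
(`log_base` accepts "2" and "10" for sensitivity checks; refitted
coefficients absorb the base change). Class area fractions are
area-weighted by default, with count weighting available.

## Molecule preparation

SMILES are parsed with RDKit, protonated explicitly, embedded with ETKDGv3
under a caller-supplied seed and relaxed with the Universal Force Field
(an intentional simplification: no semi-empirical refinement step, so
geometries are UFF-quality throughout). Disconnected fragments are laid
side by side with a 2.5 Å gap before optimization; all fragments feed one
density field. Radii come from a packaged CSV of environment-independent
vdW radii (Bondi/Rowland–Taylor consistent set; hydrogen pinned at
1.1 Å); users may supply an override table.

Conformer studies embed up to `max_n` conformers, UFF-minimize them,
order by energy, and greedily keep conformers whose pairwise heavy-atom
RMSD (after optimal superposition) is ≥ 0.50 Å. Heavy atoms only, because
hydrogen placement is toolkit-dependent. Across RMSD-filtered conformers
of flexible molecules the spread of S_tharea, 100·(max−min)/mean, is well
below the percent level, which is why a single conformer suffices.

## Calibration

The model is linear in (S0, a, b, c), so ordinary least squares
(`fit_ols`) is the exact RMSE minimizer and serves as the deterministic
reference. The genetic algorithm (`fit_ga`) reproduces the original
calibration protocol — fitness 1/RMSE, crossover probability 0.75,
mutation probability 0.25, bounds ±200/±100/±50/±50 for S0/a/b/c, 100
generations, population 200 (within the 100–250 protocol range). Details
the protocol leaves open were chosen as: real-valued encoding, size-3
tournament selection, 5% elitism, uniform crossover, and Gaussian mutation
whose per-gene step scales with the spread of the fitter half of the
current population, so the search contracts geometrically around the
optimum. On well-conditioned data the GA lands within 10⁻⁵ relative of the
OLS RMSE; a best individual on a parameter bound is logged as a warning.

Uncertainty: percentile bootstrap (default 100 case-resampled refits, 95%
level). Replicates on which the fitter fails are dropped, with an error
if more than 20% fail. Note a statistical point that matters when reading
recovery experiments: the event "all four true coefficients lie inside
their marginal 95% intervals simultaneously" has probability ≈ 0.95⁴ ≈
81% (less with 100-replicate interval noise) unless coefficient errors
are near-perfectly correlated. The acceptance suite reports joint coverage
of ~70–75% on the synthetic corpus, which is the expected behaviour of
correct intervals, while per-coefficient coverage is ~90–96%.

Evaluation metrics: RMSE, R² = 1 − SS_res/SS_tot, MAPE =
mean(100·|pred−obs|/obs), distance correlation (classical double-centred
V-statistic, implemented in-package), and the pairwise relative-entropy
RMSE over all n(n−1)/2 pair differences, computed through the identity
Σ_{i<j}(eᵢ−eⱼ)² = n·Σe² − (Σe)² and invariant to constant prediction
offsets.

Fits are exposed both as functions over `CalibrationRecord` lists and as
the scikit-learn estimator `AreaLawEntropyRegressor` (fit/predict,
clonable, pipeline-compatible); `SurfaceDescriptorTransformer` turns
molecules into the five-column descriptor matrix so a
`Pipeline([transformer, regressor])` goes from SMILES to entropies.

## Synthetic data generator

`synthetic_regression_records` emulates the calibration corpus: total
areas uniform in 120–900 Å², class splits jittered around the observed
61.7/23.9/14.4% partition (Dirichlet with those concentrations), and
deformation aggregates proportional to class areas, scaled so the
noiseless model value spans the experimental range 190–1040 J/mol·K
(descriptors are redrawn when it does not; truncation acts on the design
only, so the response remains exactly linear-model-plus-noise and both
fitters are unbiased). Default noise sd 20 J/mol·K ≈ the residual scale
of the published calibration. What the generator does *not* emulate:
correlations between descriptor components induced by real chemistry,
measurement-error heteroscedasticity, and the long right tail of large
flexible molecules — so parameter-recovery results certify the fitting
machinery, not the physical model.

Surface fixtures: `single_sphere` (closed-form oracle), `fused_dimer`
(controllable overlap; at 50 Å separation a two-component additivity
check), `random_cluster` (connected blob of table-radius atoms chained at
1–3 Å separations, min 1 Å between centres — molecule-like without
requiring embedding).

## Problem sizes and numerical tolerances

Routine verification uses: the single-H sphere at study defaults
(≈8 000 triangles; area/volume/curvature within 1% of closed form, in
practice ≤ 0.15%); derivative checks on 10 random multi-atom fields × 100
points against central differences (h = 10⁻⁴ Å, relative error < 10⁻⁵,
observed ~10⁻⁷); parameter recovery with n = 300 records × 50 repetitions;
rigid-motion and coarseness checks on a 24-atom cluster. Orchestration
tests run at a coarser 0.15 Å grid since they exercise plumbing, not
numerics.

## Known limitations

* The packaged deformation coefficients (S0 = 104.32, a = 3.078,
  b = 6.910, c = 21.456) come from a published calibration whose exact
  descriptor conventions (histogram normalization, curvature
  discretization, geometry refinement) are not fully recoverable. The
  aggregates Σ p·ln p·A are sensitive to those conventions, and
  cross-checks against literature entropies of methane, ethanol, benzene
  and n-decane show that with *this* pipeline's descriptors the packaged
  deformation model underpredicts, while the area-only baseline transfers
  well (decane 537.5 vs 545.7 J/mol·K experimental). Quantitative use of
  the deformation model therefore requires recalibration on the user's
  data; all fitting machinery for that is included.
* The ultraviolet-cutoff coefficient computed with CODATA constants is
  0.448 (a = 3.078) and 0.283 (a = 1.948); the originally reported 0.41
  and 0.26 differ by ≈8%, presumably from different constants or
  rounding. The function returns the formula value.
* Solvent-excluded surfaces, solvation entropy, tautomer/protomer
  enumeration and quantum-chemical refinements are out of scope; the
  method addresses gas-phase entropy of small, mostly rigid organics.
  For large flexible molecules the single-conformer assumption and the
  fixed radius table are the first things to revisit.
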