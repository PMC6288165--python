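# Methods

This document records the statistical model, the synthetic-data
generator, the numerical choices behind the inference stack, and known
limitations.

## 1. Design and data model

The reference design is a common-garden provenance trial: 4 regions of
origin (leading edge `LE`, continental interior `CI`, southern interior
`SI`, trailing edge `TE`) × 5 provenances per region × 3 planting sites
× 2 blocks per site × 1 tree per provenance-block cell = 120 trees,
minus 3 trees lost to mortality = **117 trees**. Rings are measured for
1996–2005 (10 years) giving **1170 tree-year records**, and the 20
provenances × 3 sites × 10 years give **600 provenance-site-year**
aggregate rows. Each tree contributes 4 measurement radii per year,
per-ring tracheid cell files, annual height increments, and tree-year
δ¹³C / δ¹⁸O values.

## 2. Derived quantities

- **BAI.** Ring widths are averaged across the 4 radii *first*, the
  mean-width series is cumulated to radii, and
  `BAI_t = π(r_t² − r_{t−1}²)`. The telescoping identity
  `Σ BAI = π r_T²` holds exactly and is enforced in tests at 1e-9
  relative tolerance.
- **Hydraulic diameter.** `D_h = Σd⁵ / Σd⁴` over lumen diameters `d`.
  Note that `∂D_h/∂d_i > 0` iff `d_i > (4/5)·D_h`: enlarging a lumen
  already far below the hydraulic mean *decreases* `D_h`. The tests
  assert this derivative-sign property rather than naive monotonicity.
- **ci/ca and iWUE.** With `a = −4.4‰` (diffusion) and `b = −27‰`
  (carboxylation), `ci/ca = (δ¹³C_plant − δ¹³C_air + a)/(b − a)` and
  `iWUE = ca (1 − ci/ca) · 0.625` (the 0.625 converts A/gs on a CO₂
  basis to a water basis, gs(H₂O) = 1.6·gs(CO₂)). No clamping is
  applied: `ci/ca` outside (0, 1) is flagged, not silently corrected.
- **Lloret indices.** With pre = {1999, 2000, 2001}, drought = {2002},
  post = {2003, 2004, 2005} (window means of BAI):
  `Rt = Dr/Pre`, `Rc = Post/Dr`, `Rs = Post/Pre`, `RRs = (Post − Dr)/Pre`.
  The identities `Rs = Rt·Rc` and `RRs = Rs − Rt` hold by construction;
  all four are invariant to rescaling the BAI series except `RRs`'s
  additive form, which is scale-free as a ratio of differences.
- **Dual-isotope diagnosis.** Within each group, the Pearson (optionally
  Spearman) correlation between tree-year δ¹³C and δ¹⁸O is tested at
  `alpha`; significantly positive → `stomatal-control`, significantly
  negative → `photosynthesis-control`, otherwise `indeterminate`.

## 3. Population inference

Trait models are linear mixed models fit by REML with `statsmodels`
`MixedLM`: fixed effect = region (or provenance), random intercepts for
site-block (6 levels) and, when tree-years repeat, a variance component
for tree; anatomy traits additionally carry a fixed distance-from-apex
slope. Numerical choices:

- **Optimizer chain.** `bfgs → lbfgs → cg`; a fit is accepted only if
  the optimizer converged, the fixed-effects covariance block is
  positive semi-definite, and the residual scale is non-degenerate
  (≥ 1e-8 of the response variance).
- **Deterministic-data guard.** Before fitting, an OLS probe
  (fixed + block) is run; if its residual sum of squares is ≤ 1e-10 of
  the total sum of squares the data are treated as deterministic and the
  probe's exact adjusted means are used directly — MixedLM otherwise
  shrinks toward artefactual values on zero-noise inputs.
- **Degrees of freedom.** Contrasts use Wald-z (normal approximation);
  the manifest records `df_method` so consumers know no small-sample
  correction is applied. With 6 blocks this is mildly anticonservative
  in tiny designs (see §5).
- **Multiplicity.** Benjamini–Hochberg FDR adjustment is applied within
  each family: the pairwise contrasts of one trait, or the cells of one
  correlation matrix. `bh_adjust` is checked against an independent
  hand-stepped step-up oracle.
- **LS means.** Treatment-coded fixed effects with block dummies
  averaged at 1/n_blocks, so means are adjusted for block imbalance
  (relevant because the 3 missing trees unbalance the design).
- **AIC under REML.** `statsmodels` reports NaN; the package computes
  `−2·llf + 2·(k_fixed + k_variance + 1)` manually.

## 4. Synthetic generator

Each trait is simulated as

```
value = grand mean + region offset + provenance effect + site offset
        + block effect + tree effect + year effect
        + drought term (multiplicative or additive) + residual
```

with independent substreams per (seed, label) via
`np.random.default_rng([seed, digest(label)])`, so adding a trait never
perturbs another trait's draws. Defaults worth noting:

- **δ¹³C grand mean −24.0‰.** A more typical −26‰ with air at −8‰
  puts `ci/ca ≈ 0.99` and measurement noise pushes it above 1
  (physically inadmissible, negative iWUE). −24‰ keeps `ci/ca` in
  0.88–0.95 so downstream iWUE is well-defined for every simulated
  tree-year.
- **Drought signature (2002).** Trailing-edge trees thicken walls
  (×1.15), shrink lumens (×0.85) and build fewer cells (×0.7); the
  leading edge thins walls (×0.9); interior regions show the largest
  isotopic enrichment (+1.2 / +1.0‰ δ¹³C). This mimics the qualitative
  contrast between drought-adapted and mesic populations.
- **Isotope coupling.** δ¹³C and δ¹⁸O residuals share a latent stomatal
  signal with loading `c` (default 0.7), giving an expected correlation
  `r = c² = 0.49`.
- **Atmosphere.** A small built-in table of plausible annual CO₂ and
  δ¹³C_air values for 1990–2010 (or a linear model) — synthetic, not a
  published record.

The generator emulates design structure, variance partitioning, a
drought pulse and isotope coupling. It does **not** emulate temporal
autocorrelation beyond a smooth age trend, spatial correlation within
sites, competition, or measurement-method biases.

## 5. Validation studies

Implemented in `droughtrings.validation` and exercised by both the test
suite and `scripts/acceptance.py`:

- **Parameter recovery** (200 replicates, full 117-tree design): region
  offsets (−0.5, 0, 0, +0.5) residual-SD units; contrast estimates are
  required to be within 3 Monte-Carlo standard errors of truth.
- **Type-I error** (1000 replicates): under a null generator the
  per-family false-positive rate of the BH-adjusted contrasts must fall
  in the 95% binomial interval around 0.05. The study uses a reduced
  factorial (4 regions × 3 provenances × 1 site × 2 blocks × 3 trees =
  72 trees): large enough for the Wald-z approximation to hold (a
  32-tree variant shows visible z-inflation, ~0.06), small enough for
  1000 replicates in seconds.
- **Dual-isotope operating characteristics** (200 replicates, 290
  pairs/series — one regional tree-year pool): coupling 0.7 must be
  labelled `stomatal-control` in ≥95% of replicates; independent series
  must be `indeterminate` at ≈95%.

## 6. Known limitations

- Wald-z contrasts ignore finite-sample degrees of freedom; with few
  blocks the nominal level is approximate (quantified in §5).
- `ci/ca` near or above 1 (physically inadmissible) is flagged but the
  algebra is still applied; consumers should filter on the flag.
- The `.rwl` reader handles the common decadal Tucson layout with
  999/−9999 terminators only, not headered or long-format variants.
- Drought windows must not overlap and every window year must be present
  in a tree's series; trees with gaps are reported, not imputed.
- The synthetic atmosphere table is illustrative; real analyses should
  supply measured CO₂ and δ¹³C_air series.
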