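# Methods

## Scope and design

`croprank` evaluates water–nitrogen management strategies for a winter
wheat – summer maize rotation at the annual scale. One evaluation panel is
a set of strategies sharing an irrigation *system* context (drip or
micro-sprinkler, each panel also carrying the flood-irrigated baselines),
scored on 11 indicators per rotation year and ranked by entropy-weighted
TOPSIS. Panels are evaluated separately per system and per year — never
pooled — because the treatment structure is unbalanced (flood irrigation
exists only for the conventional baseline and its zero-N control) and
prices/volumes differ between years.

## Synthetic trial generator

The generator emulates the *statistical* structure of a split-plot field
trial, not its physiology:

- **Grain yield**: per (treatment, season) cell, Normal(mean, sd) truncated
  at 0, with sd defaulting to 3% of the cell mean — a typical plot-level CV
  for well-managed cereal trials. Replicates default to 3.
- **Dry matter**: grain divided by a per-plot grain-to-biomass ratio,
  Normal(0.77, 0.01) clipped to (0.2, 0.8). The 0.77 default is
  deliberately higher than textbook harvest indices: it is what the
  published annual sequestration (~10,900 kg C ha⁻¹, i.e. ~24,700 kg ha⁻¹
  dry matter) implies against the published annual grain yield
  (~19,100 kg ha⁻¹). The generator reproduces the published numbers'
  internal logic rather than a textbook value.
- **Plant N uptake**: dry matter × tissue concentration × (1 + 2% Gaussian
  noise). Tissue N concentration follows a Mitscherlich-type saturation,
  `base + (max − base)(1 − exp(−k·N))`, with defaults base = 0.008,
  max = 0.0095 kg N per kg dry matter and k = 0.015 ha kg⁻¹ chosen so the
  difference-method NUE of the best strategy lands in the published 21–35%
  band. The response is monotone non-decreasing, so zero-noise NUE is
  never negative.
- **Reproducibility**: every (treatment, season) cell draws from its own
  RNG substream derived deterministically from (seed, CRC32 of the
  treatment id, CRC32 of the season id); adding or removing a treatment
  does not perturb any other cell, and a fixed seed is bit-reproducible.

What a green test on synthetic data establishes: that the pipeline's
arithmetic, plumbing and ranking behave correctly for data with the
configured means and noise. What it does not establish: anything about
real soil–crop processes — there is no weather, phenology, soil N dynamics
or spatial layout, and treatment effects are purely additive cell means.

### Bundled calibration

The default configuration sets T4 (60% basal controlled-release urea + 40%
top-dressed urea under the optimized 195 kg N ha⁻¹ rate) highest in every
season and system, with a ~5–6% yield margin over the nearest optimized
competitors (T6/T7). That margin is the smallest that is both
LSD-significant at the 3% plot noise with 3 replicates and consistent with
the published closeness gap to second place (≈0.06); the conventional
baseline T1 trails T4 by the published relative gaps (4.6% in first-year
wheat, 0.75% in first-year maize). Prices (2.8/2.6 CNY kg⁻¹ wheat/maize in
year one, 2.4/2.3 in year two) and itemized costs (land rent
15,000 CNY ha⁻¹ yr⁻¹, machinery 1,600, seed 750/900, fertilizer 2,600
optimized / 1,100 zero-N, water 0.6 CNY m⁻³) put the best strategy's annual
net near the published ~24,300 CNY ha⁻¹. Micro-sprinkler volumes are set
~10–15% above drip, which reproduces the published 4.5–5.6% emission gap
between the two systems.

## Indicators and ledgers

- **WUE** divides by the irrigation volume of the treatment's own method in
  that season; a non-positive volume is a hard error (rain-fed plots must
  be configured explicitly, never divided silently).
- **NUE** uses the zero-N control of the same irrigation system (flood
  strategies pair with the flood control, drip/sprinkler with the optimized
  control). For controls NUE is a typed undefined value (`None`); it is
  imputed as 0 — the worst benefit value — only at matrix assembly, with a
  logged warning, so control rows stay in the 9-alternative panel.
  Negative NUE is retained and logged, not clipped.
- **Economic ledger**: land rent is annual and attributed half to each
  season, so the annual sum counts it exactly once. The closure identity
  `net = revenue − Σcosts` is enforced at construction to 1e-9 relative.
- **Carbon ledger**: the sequestration coefficient is always computed as
  1.63 × 0.27 (= 0.4401), never hard-coded as 0.44. The fertilizer
  emission factor (0.8956 kg C kg⁻¹) is applied to the nitrogen input mass
  (2 × the per-season N rate per rotation year); applied to total N+P+K
  mass it would overshoot the published 506–641 kg C ha⁻¹ annual band.
  The accounting boundary is fertilizer manufacture + irrigation
  electricity only.
- **Pump flow**: the source trial describes its pump as "40 L h⁻¹ at
  5.5 kW", which cannot be literal — one 1,950 m³ ha⁻¹ irrigation would
  need ~49,000 pumping hours. The default is 40 m³ h⁻¹, which yields
  realistic electricity use and the published emission magnitudes; the
  literal reading remains selectable (`CarbonParams(pump_flow=0.04)`).

## Entropy-weighted TOPSIS

Stages: orient cost columns to benefit → entropy weights on the oriented
raw matrix → column-wise vector (cosine) normalization → weighting → ideal
solutions as column max/min → Euclidean distances → closeness
C = D⁻/(D⁺ + D⁻) → ranks (descending closeness; exact ties share the
minimum rank and are logged; input order breaks the ordering).

Numerical choices:

- Entropy uses column proportions pᵢⱼ = xᵢⱼ/Σᵢxᵢⱼ with 0·ln 0 := 0, so
  weights are invariant to per-column rescaling. Columns containing
  negatives (possible for negative NUE) are shifted by their minimum first;
  the shift is recorded in the weight provenance. Constant or all-zero
  columns get weight 0 with a warning; an all-constant matrix is an error.
- **Cost-to-benefit transform**: the default is the *reciprocal* (1/x).
  The alternative max-minus-x transform maps the worst alternative of every
  cost column to exactly 0, which inflates the relative dispersion of a
  near-constant cost column (CV ~5% becomes ~130%); under proportion
  entropy and vector normalization that single column then dominates both
  the weights and the ideal-solution distances, and zero-input controls win
  the ranking on cost savings alone — the opposite of the published
  pattern, where the controls rank last. The reciprocal preserves relative
  dispersion and reproduces the published qualitative ordering (best
  strategy first, controls and conventional practice last). Max-minus
  remains available via `evaluate(..., cost_transform="max-minus")`; it
  requires strictly positive entries for the reciprocal and is the
  documented default of the standalone `orient_matrix` operation.
- The worst solution is the column *minimum* of the weighted normalized
  matrix (the published formula block typesets both ideals with the same
  symbol; the minimum reading is the only coherent one).
- Two identical alternatives in an otherwise varying matrix are fine (they
  tie); a matrix in which *all* alternatives are identical has no defined
  closeness and is an error.

## Known limitations

- The generator cannot reproduce year-two WUE figures as published: the
  published 9.42 kg m⁻³ wheat WUE with the published 1,080 m³ ha⁻¹ volume
  implies a wheat yield above any published yield. The package reproduces
  the self-consistent year-one case (8,532.5/1,950 = 4.38 kg m⁻³) and
  leaves year-two WUE to follow from the configured yields.
- Absolute closeness values on synthetic data are higher than the published
  ones (≈0.88 vs 0.702 for the winner): the published evaluation's exact
  11-indicator input values are not available, so only the ordering
  pattern, not the closeness scale, is calibrated.
- No ANOVA/LSD lettering, no soil/weather simulation, no equipment
  amortization, no N₂O/CH₄ or CO₂-equivalent accounting.
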