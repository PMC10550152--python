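# Methods

`meadowtrade` analyses a long-running blocked fertilizer trial in an upland
hay meadow: four nutrient regimes — no fertilizer, farmyard manure (FYM),
low-rate 20:10:10 mineral fertilizer (NPK), and both together (FYM+NPK) —
replicated within blocks, scored on twelve indicators spanning forage
production and biodiversity, and compared by block-constrained randomization
tests. This note records the model, the choices made where the design was
genuinely open, and what the synthetic data does and does not emulate.

## Indicators

Each plot is scored on twelve indicators in three groups:

| group  | indicator | units | source records |
|--------|-----------|-------|----------------|
| plant  | `diversity_plants` | nats | Shannon–Weiner index over percent cover |
| plant  | `forb_richness` | count | distinct forb species with positive cover |
| plant  | `nectar_productivity` | μl/plot | Σ flowers × per-flower nectar (literature reference table) |
| insect | `bumblebee_abundance` | count | pollinator records flagged as bumblebees |
| insect | `diversity_pollinators` | nats | Shannon index over pollinator counts |
| insect | `diversity_herbivores` | nats | Shannon index over reared leaf-miner adults |
| insect | `diversity_parasitoids` | nats | Shannon index over emerged parasitoids |
| insect | `percent_parasitism` | % | parasitoid emergences / total emergences × 100 |
| forage | `ash` | % DM | assay |
| forage | `crude_protein` | % DM | assay |
| forage | `metabolizable_energy` | MJ/kg DM | assay |
| forage | `mean_dry_matter` | g/m² | arithmetic mean over assay years |

Conventions that the data alone does not fix:

* **Shannon base** — natural log (diversity in nats), the ecological
  convention.
* **Parasitism denominator** — all emergences (miners + parasitoids) by
  default, so the indicator lies in [0, 100]; miner-adults-only is a
  configuration switch because both conventions occur in the rearing
  literature. Zero emergences make the indicator *undefined* (an error),
  which is distinct from an observed 0 %.
* **Unknown nectar species** — a hard error by default; a skip-with-warning
  mode exists for exploration, because silently treating a missing reference
  entry as zero would bias the indicator downward.
* **Missing assay years** — the dry-matter mean is taken over the years
  present, with a warning; never imputed.

An indicator-independence screen flags any pair with |Pearson r| ≥ 0.90;
the composite treats indicators as separate signals, so a flagged pair is a
prompt to drop or merge, not an automatic action.

## Composite scoring

Columns are z-scored (sample SD) and then min-max rescaled to [0, 1]. Both
steps are affine per column, hence order-preserving: treatment rankings on
any single indicator, and all permutation p-values, are identical on the
raw and transformed scales. The rescaled scale is used because composite
scores are conventionally reported in 0–1.

Weights: forage carries 50 % of the composite, plant community 25 %, insect
community 25 %, equal within groups — so 0.125 per forage indicator, 1/12
per plant indicator, 0.05 per insect indicator. A treatment's composite
weighted mean is `Σ w_i x̄_i` over its twelve per-indicator means; its
trade-off spread is the weighted SD `sqrt(Σ w_i (x̄_i − x̄_w)²)` (population
form; an unbiased reliability-weights variant is an option). The *optimal*
regime maximizes the weighted mean while minimizing the weighted SD — a low
spread means the composite is not bought by excelling on one group while
collapsing on another.

Open choices made here: the composite is computed on per-indicator
*treatment means* (averaging plots first), matching the group-mean logic of
the scoring; averaging per-plot composites instead is a configuration
switch. Rescaling happens before averaging across replicates; both orders
are order-preserving per column but differ slightly in the reported values.

## Randomization inference

Under the null of no treatment effect, treatment labels are exchangeable
within blocks. Every randomization therefore re-shuffles the labels
independently inside each block — preserving each block's treatment
multiset and hence the spatial structure — and recomputes the contrast
statistic; 10,000 randomizations by default. Supported statistics:
difference in treatment means of one indicator, difference in arithmetic
group means, and difference in composite weighted mean or weighted SD.

* `p_greater` is the proportion of randomizations in which the observed
  statistic is ≥ the randomized one (ties count as exceedances by default;
  a half-tie rule gives exact complementarity `p(A,B) + p(B,A) = 1` and is
  used wherever symmetry is asserted). Significance: `p_greater < 0.05` or
  `> 0.95`, a two-tailed level of 0.10.
* A two-sided p-value `(#{|null| ≥ |obs|} + 1)/(R + 1)` with add-one
  correction is reported alongside (standard permutation practice, avoids
  zero p-values).
* One pool of shuffles is shared by all statistics and all treatment pairs
  of a run: whole rows are permuted, preserving cross-indicator
  correlation. Per-indicator independent shuffling is available as a flag.
* For a lower-is-better statistic (weighted SD), a significantly *negative*
  observed difference is the favourable outcome; results carry a note.

Numerical care: the observed statistic is computed as row 0 of the same
batched matrix product as the null sample, so a shuffle that reproduces the
observed assignment yields a bitwise-identical statistic and ties are
detected exactly (different BLAS kernel shapes otherwise differ in the last
bits and silently break tie handling).

An exhaustive enumeration of all within-block arrangements (feasible up to
10⁶ arrangements) provides exact probabilities and serves as the oracle the
Monte-Carlo test is verified against; on a 2-block × 2-treatment × 2-rep
design there are 6² = 36 arrangements and the Monte-Carlo p at R = 10⁵ sits
within 3 Monte-Carlo SEs of the exact value.

No multiple-testing correction is applied across the 204-row contrast
table; the table reports per-contrast exceedance probabilities.

## Synthetic data

The generator emulates the trial's structure — by default 3 blocks × 4
treatments × 2 replicates = 24 plots — with an indicator-first model:

    target = baseline + treatment_effect + block_effect + residual,

block effects `N(0, block_sd)` shared within a block, residuals
`N(0, residual_sd)`, truncated to each indicator's physical range
(percent-type indicators to [0, 100]; a rearing sample of E emergences
additionally needs at least one emergence in each class, so parasitism
targets are truncated to [100/E, 100(E−1)/E]). Raw tables are then built to
*realize* the targets:

* Shannon targets via geometric rank-abundance communities
  `p_i ∝ exp(−λ i)` with λ solved by bisection — entropy decreases
  monotonically from ln S to 0 as λ grows;
* count communities quantized by largest-remainder apportionment so totals
  are exact (80 rearing emergences and ~400 pollinators per plot by
  default, chosen to match the order of magnitude of a season's rearing and
  netting effort);
* nectar targets realized with two synthetic flower species worth 1.0 and
  0.01 μl/flower (resolution 0.005 μl);
* integer indicators (forb richness, bumblebee counts) by rounding;
* dry matter spread over four assay years with a mean-preserving pattern.

Because counts quantize, the dataset stores both the intended targets and
the **realized** indicator values recomputed from the final tables; tests
compare against the realized truth, which downstream assembly reproduces
exactly (to 1e-12). Quantization error is bounded by community size:
negligible for plants/pollinators, up to ~0.3 nats for the ~16-individual
parasitoid communities, 0.625 percentage points for parasitism.

Default effect sizes follow the qualitative pattern of long-term nutrient
addition in hay meadows — fertilization raises yield, crude protein and
metabolizable energy while eroding forbs, nectar, and bumblebees; FYM
raises parasitism; FYM+NPK hits the plant community hardest — with
magnitudes set once to plausible field values (e.g. baseline 300 g/m² dry
matter, +130 under FYM; 12 forb species, −5 under FYM+NPK).

What the generator does *not* emulate: spatial autocorrelation beyond
additive block effects, year-to-year weather variation, species identities
shared realistically across plots, or overdispersed counts. Passing tests
therefore demonstrate the correctness and calibration of the *pipeline*
under a known additive-Gaussian truth, not robustness to every feature of
field data.

Calibration and power under these study conditions (verified by the
acceptance suite): on zero-effect datasets the two-tailed rejection rate at
the 0.05/0.95 rule is within the binomial 95 % CI of 0.10 (200 datasets,
R = 1000); a single-treatment shift of 2 residual SDs on all four forage
indicators is detected by the composite weighted-mean test in ≥ 19 of 20
datasets.

## Nutrient loads and feed budgets

Nutrient accounting is linear: manure rate × per-tonne composition plus
mineral input, per nutrient; of the manure-derived load only a fraction
(default 20 %) is plant-available in the application year, while mineral
input counts in full. The four standard regimes are 12 t/ha/yr manure with
6 / 3.5 / 8 kg N / P₂O₅ / K₂O per tonne, and 20:10:10 mineral fertilizer at
25 / 12.5 / 12.5 kg/ha/yr; note the combined regime's potash total computes
to 108.5 kg/ha/yr (96 + 12.5), which is sometimes quoted rounded to 108.

Feed budgets: plot yields in g DM/m² extrapolate to kg DM/ha (× 10);
animals per hectare over a feeding period is
`floor(yield × utilization / (allowance × days))`, with the exact quotient
reported alongside. Daily allowances and adequacy thresholds are
parameters, not constants: the library refuses to assume a feeding-period
length, because published stocking figures are not reproducible without
one. The analysis scripts use 9.2 kg DM/d for a 600 kg spring-calving
suckler cow, 1.4 kg DM/d for mixed-age ewes (150 % scanning), a 120-day
overwintering period (a typical upland winter housing span, chosen once as
this project's convention), and crude-protein adequacy thresholds of 10 %
(cattle) and 8 % (sheep). The proprietary ration software behind such
allowance figures is not re-implemented; allowances enter as data.

## Known limitations

* The composite depends on the 50/25/25 weighting; alternative
  multifunctionality weightings are out of scope beyond the configurable
  scheme.
* Randomization p-values are exceedance probabilities per contrast;
  familywise error across the 204-row table is not controlled.
* The generator's additive-Gaussian truth cannot express
  indicator-indicator dependence within a plot beyond what the shared block
  and treatment structure induces.
* Reproducing the original study's published composite numbers requires its
  supplementary plot-level workbook, which is not redistributed here; the
  importer (`meadowtrade.s1_import`) plus a user-supplied column mapping
  covers that case.
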