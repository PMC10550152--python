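# meadowtrade

Trade-off analysis of grassland fertilizer regimes: do you fertilize a hay
meadow for forage, or leave it lean for biodiversity — and is there a regime
that buys most of both?

`meadowtrade` is a tested pipeline for answering that question on data from
a blocked fertilizer trial (by default 3 blocks × 4 regimes — no fertilizer,
farmyard manure (FYM), low-rate 20:10:10 mineral fertilizer (NPK), and
FYM+NPK — × 2 replicate plots). It is written for grassland and
agri-environment researchers who have plot-level species, rearing, flower
and forage records and want the whole chain from raw tables to inference:

1. **Indicators** — twelve per-plot scores: plant Shannon diversity
   H = −Σ pᵢ ln pᵢ, forb richness, nectar productivity (Σ flowers ×
   μl/flower), bumblebee abundance, Shannon diversity of pollinators,
   leaf-mining herbivores and parasitoids, percent parasitism, and four
   forage measures (ash, crude protein, metabolizable energy, mean
   dry-matter yield), plus a |r| ≥ 0.90 collinearity screen.
2. **Composite** — indicators are z-scored, min-max rescaled to [0, 1] and
   combined per treatment as a weighted mean (forage 50 %, plants 25 %,
   insects 25 %) with a weighted SD measuring trade-off spread; the optimal
   regime maximizes the mean while minimizing the spread.
3. **Randomization inference** — treatment labels are re-shuffled *within
   blocks* (10,000 times by default) to build null distributions for every
   indicator, group average and composite statistic; a contrast is
   significant when its exceedance probability leaves the 0.05/0.95 tails.
   An exhaustive within-block enumeration doubles as an exact oracle.
4. **Livestock** — fertilizer nutrient loads (kg N/P₂O₅/K₂O per ha and
   year, with plant-available fractions) and feed budgets: animals per
   hectare = ⌊yield × utilization / (allowance × feeding days)⌋ with
   crude-protein adequacy flags.

A synthetic-data generator with known ground truth (`meadowtrade.synthetic`)
emulates the trial design end to end, so every stage is testable without
field data.

## Worked example

Run the numbered analysis scripts from the repository root (each writes its
tables under `results/`):

```bash
python analysis/01_simulate.py       # synthetic 24-plot trial, seed 7
python analysis/02_indicators.py     # plots x 12 matrix + correlation screen
python analysis/03_composite.py      # weighted composite per regime
python analysis/04_randomization.py  # 204-row contrast table, R = 10,000
python analysis/05_livestock.py      # nutrient loads + feed budgets
```

`03_composite.py` prints, for the default synthetic trial:

```
composite scores on the rescaled 0-1 scale:
           weighted_mean  weighted_sd  group_mean_forage  group_mean_plant  group_mean_insect
treatment
NoFert             0.410        0.252              0.207             0.797              0.430
FYM                0.617        0.137              0.625             0.601              0.617
NPK                0.495        0.147              0.442             0.704              0.392
FYM+NPK            0.529        0.238              0.729             0.260              0.397

highest weighted mean: FYM (0.62, weighted SD 0.14)
smallest trade-off spread (weighted SD): FYM (0.14)
```

Read: manure gives the best overall compromise — the highest weighted mean
*and* the least spread across indicators — while FYM+NPK scores well on
forage (0.73) at a steep cost to the plant community (0.26), the classic
production–biodiversity trade-off. `04_randomization.py` confirms the
composite contrasts (e.g. P(FYM weighted mean > no-fertilizer) = 1.000,
significant), and `05_livestock.py` turns yields into stocking capacity:

```
treatment           species  yield_kg_dm_ha  animals_per_ha  cp_adequate
   NoFert     ewe_mixed_age         2919.13              17        False
      FYM     ewe_mixed_age         4289.89              25         True
      NPK     ewe_mixed_age         3887.65              23         True
  FYM+NPK     ewe_mixed_age         4663.62              27         True
```

— 17 ewes per hectare of winter hay without fertilizer versus 25 under
manure (120-day feeding period, 1.4 kg DM/d), with unfertilized hay falling
short of the crude-protein threshold.

The same pipeline is scriptable via the CLI
(`meadowtrade simulate --seed 7 --out d/ && meadowtrade run --config
d/config.yaml`) or the library API; see `docs/methods.md` for the model,
parameter and design details. Plot-level data from the original published
trial can be analysed by exporting its supplementary workbook through
`meadowtrade.s1_import.load_indicator_workbook` with a column mapping.

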