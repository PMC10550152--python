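"""Generate the synthetic 24-plot fertilizer-trial dataset.

Three blocks x four nutrient regimes (no-fertilizer, FYM, NPK, FYM+NPK) x
two replicate plots, with the default effect model: fertilization raises
forage yield and quality while eroding forbs, nectar and bumblebees, FYM
boosting parasitism and FYM+NPK hitting the plant community hardest.
Writes the raw plot tables (plant covers, pollinators, rearing outcomes,
flowers + nectar reference, forage assays) plus a config echo.
"""

import meadowtrade as mt
from helpers import DATA_DIR, SEED

dataset = mt.generate_dataset(mt.DesignSpec(seed=SEED))
paths = mt.export_dataset(dataset, DATA_DIR)

print(f"seed {SEED}: wrote {len(paths)} files to {DATA_DIR}")
print(f"plots: {len(dataset.plots)}  "
      f"plant records: {len(dataset.plant_community)}  "
      f"rearing emergences: {len(dataset.rearing_outcomes)}  "
      f"pollinator records: {len(dataset.pollinator_records)}")
truth = dataset.truth_indicators.groupby("treatment")[
    ["forb_richness", "crude_protein", "mean_dry_matter"]
].mean().round(2)
print("ground-truth treatment means (3 of 12 indicators):")
print(truth.to_string())
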