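"""Nutrient loads of the four regimes and livestock feed budgets.

Nutrient accounting: manure at 12 t/ha/yr (6 / 3.5 / 8 kg N / P2O5 / K2O
per tonne, 20 % plant-available) and 20:10:10 mineral fertilizer at
25 / 12.5 / 12.5 kg/ha/yr. Feed budgets extrapolate each regime's mean
dry-matter yield to kg DM/ha and count the 600 kg suckler cows
(9.2 kg DM/d) and mixed-age ewes (1.4 kg DM/d) supportable per hectare over
a 120-day overwintering period, with crude-protein adequacy thresholds of
10 % (cattle) and 8 % (sheep).
"""

import pandas as pd

from helpers import RESULTS, ensure_dataset
from meadowtrade.indicators import assemble_indicator_matrix
from meadowtrade.io import write_matrix
from meadowtrade.livestock import (
    FeedParams,
    feed_budget_table,
    nutrient_loads,
    standard_regimes,
)

loads = pd.DataFrame(
    [{"treatment": name, **vars(nutrient_loads(regime))}
     for name, regime in standard_regimes().items()]
)
write_matrix(loads, RESULTS / "nutrient_loads.csv")
print("nutrient loads (kg/ha/yr):")
print(loads.round(1).to_string(index=False))

matrix = assemble_indicator_matrix(ensure_dataset())
params = [
    FeedParams(species="suckler_cow_600kg", allowance=9.2, feeding_days=120,
               cp_requirement=10.0),
    FeedParams(species="ewe_mixed_age", allowance=1.4, feeding_days=120,
               cp_requirement=8.0),
]
budgets = feed_budget_table(matrix, params)
write_matrix(budgets, RESULTS / "feed_budgets.csv")
print("\nfeed budgets (120-day winter, per hectare of hay):")
print(budgets.drop(columns=["me_adequate"]).round(2).to_string(index=False))
inadequate = budgets[~budgets["cp_adequate"].astype(bool)]
if len(inadequate):
    pairs = ", ".join(f"{r.treatment}/{r.species}" for r in inadequate.itertuples())
    print(f"\ncrude protein below requirement for: {pairs}")
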