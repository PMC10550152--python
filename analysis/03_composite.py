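"""Score each fertilizer regime with the 50/25/25 weighted composite.

Indicators are z-scored and min-max rescaled to [0, 1]; each treatment's
composite is the weighted mean of its twelve per-indicator means (forage
50 %, plant community 25 %, insect community 25 %), with the weighted SD
measuring the trade-off spread. The optimum regime maximizes the weighted
mean while minimizing the weighted SD.
"""

from helpers import RESULTS, ensure_dataset
from meadowtrade.composite import standardize_and_rescale, treatment_composites
from meadowtrade.indicators import assemble_indicator_matrix
from meadowtrade.io import write_matrix

matrix = assemble_indicator_matrix(ensure_dataset())
scores = treatment_composites(standardize_and_rescale(matrix))
write_matrix(scores.reset_index(), RESULTS / "composite_scores.csv")

print("composite scores on the rescaled 0-1 scale:")
print(scores.round(3).to_string())
ranked = scores.sort_values("weighted_mean", ascending=False)
best = ranked.index[0]
print(f"\nhighest weighted mean: {best} "
      f"({ranked['weighted_mean'].iloc[0]:.2f}, weighted SD {ranked.loc[best, 'weighted_sd']:.2f})")
least_spread = scores["weighted_sd"].idxmin()
print(f"smallest trade-off spread (weighted SD): {least_spread} "
      f"({scores.loc[least_spread, 'weighted_sd']:.2f})")
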