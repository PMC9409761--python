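"""Variance components, heritability and expected selection gain per trait.

GV = accession MS - residual MS, PV = GV + EV; GCV/PCV express the genetic
and total standard deviations as a percent of the trait mean; h2 = GV/PV;
GA = k * h2 * sigma_p is the expected gain from keeping the best 5 %
(k = 2.063), and GAM expresses it as a percent of the mean.
"""

from phenodiv import paper_like_fixture, variability_table

trial, _ = paper_like_fixture(seed=1)
table = variability_table(trial)

cols = ["trait", "mean", "PV", "GV", "GCV", "GCV_cat", "PCV", "PCV_cat",
        "h2", "h2_cat", "GA", "GAM", "GAM_cat"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print("\nTraits rated H for both heritability and GAM (e.g. fruit weight) are")
print("under mostly additive genetic control: phenotypic selection on them is")
print("expected to be effective. L/L traits are dominated by environment.")
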