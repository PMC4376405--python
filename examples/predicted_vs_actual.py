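"""Compare software-predicted and laboratory-measured product profiles.

Loads the packaged predicted/measured tables for the six products, computes
actual-minus-predicted differences, and flags rows where the published
difference was evidently taken on unrounded values.
"""

from rutfopt import compare_predicted_actual, fixtures

table = compare_predicted_actual(fixtures.measured_products()).to_frame()
product_a = table[table["product"] == "A"]
print(product_a.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
flagged = table[table.flag]
print(f"\n{len(flagged)} of {len(table)} rows flagged: their published differences")
print("disagree with differencing the printed values at printed precision,")
print("meaning the source differenced unrounded laboratory values.")
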