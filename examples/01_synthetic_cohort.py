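"""Generate a synthetic donor cohort and compute the weighted response.

Builds a 17-donor panel (10/4/3 across three condition groups) with
log-normal donor heterogeneity and a planted super-responder, then computes
the deviance-weighted day-9 fold-expansion vector Y across the 12
conditions.
"""

import numpy as np

from nksynergy.synthetic_data import SyntheticSpec, generate_dataset
from nksynergy.weighting import combined_Y, deviance_weights, donor_variances

spec = SyntheticSpec(seed=11)
table = generate_dataset(spec)

group_a = table.group("A")
var = donor_variances(table, day=9, group=group_a)
weights = deviance_weights(var, "A")

print("Group A donor cross-condition variances and weights (day 9):")
for donor, v, w in zip(weights.donor_ids, weights.variances, weights.weights):
    tag = "  <- super-responder, damped" if donor == spec.super_responder.donor_id else ""
    print(f"  donor {donor:2d}: sigma^2 = {v:9.2f}   weight = {w:.4f}{tag}")

Y = combined_Y(table, day=9)
print("\nWeighted day-9 fold expansion per condition:")
print(np.array2string(Y.values, precision=2))
print(
    "\nEach entry is a convex combination of donor fold expansions; donors whose "
    "variance sits near the cohort's robust center dominate, so the planted "
    "super-responder barely moves Y at its condition."
)
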