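"""Bootstrap the regression coefficients and call synergies.

Donors are resampled with replacement within their groups (10/4/3); the
deviance weights and the weighted response are recomputed per replicate and
the model refit on the retained predictors.  A cross-phase product like
"S3·Sb~" (STAT3 in priming x NF-kB in post-priming) is called a synergy
when |<beta>/sigma_beta| > 2 with positive mean, an antagonism when the
mean is negative.
"""

from nksynergy.imputation_maps import reference_optimal_map
from nksynergy.inference import bootstrap_beta
from nksynergy.synthetic_data import SyntheticSpec, generate_dataset, synthetic_condition_registry

table = generate_dataset(SyntheticSpec(seed=0, noise_scale=0.03, donor_log_scale_sd=0.1))
conditions = [c for c in synthetic_condition_registry() if c.condition_id <= 12]

bb = bootstrap_beta(table, reference_optimal_map(), "multiplicative", conditions, n=500, seed=3)
print(bb.table().round(3).to_string())
print(
    f"\n{sum(c == 'synergy' for c in bb.calls)} of {len(bb.labels)} retained "
    "predictors are called synergies (ratio > 2, positive mean): these are the "
    "cross-phase factor pairs whose joint activation robustly raises expansion "
    "across donor resamples."
)
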