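"""Cross-validated pollution score: fold weights, pooling, calibrated p.

Subjects are split into 10 batches; Cox weights fitted on 9 batches score
the held-out batch, so every score is out-of-fold.  Held-out per-IQR
estimates are pooled by inverse-variance weighting and the combined p-value
is calibrated with the harmonic-mean-p method.
"""

import warnings

from airscore import CohortConfig, cross_validated_score, generate_cohort
from airscore.config import MODEL2_COVARIATES

cohort = generate_cohort(CohortConfig(n_subjects=30_000, seed=2))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    cv = cross_validated_score(cohort, list(MODEL2_COVARIATES), k=10, seed=2)

print("per-fold held-out estimates:")
print(cv.per_fold_table().round(4).to_string(index=False))
pooled = cv.pooled
print(
    f"\npooled HR per IQR: {pooled.hr:.3f} "
    f"(95% CI {pooled.ci_low:.3f}-{pooled.ci_high:.3f})"
)
print(f"harmonic mean p  : {pooled.hmp_raw:.4g}")
print(f"calibrated p     : {pooled.p_calibrated:.4g}")
print("\npooled quartile contrasts (Q1 reference):")
print(cv.pooled_table().round(4).to_string(index=False))
# With the default calibration (true per-IQR HR 1.13) the pooled estimate
# scatters around 1.13 and the Q4 contrast around 1.26.
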