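"""Optimal-cutoff stratification and Cox models on a synthetic cohort.

Draws a 200-case cohort whose hazard depends on planted TLS density
(protective) and necrosis density (adverse), finds the optimal log-rank
cutoff for each parameter, builds the three T+NR prognostic groups, and
fits a multivariate Cox model with pT/pN.
"""

import numpy as np

import lungquant as lq
from lungquant.survival import encode_stage_covariates

cohort = lq.generate_cohort(lq.SyntheticCohortSpec(n_cases=200), seed=9)

groups = {}
for param in ("tls_td", "necr_td"):
    res = lq.find_optimal_cutoff(
        cohort[param], cohort["time_os"], cohort["event_os"], parameter=param
    )
    groups[param] = lq.dichotomize(cohort[param], res.cutoff)
    print(f"{param}: optimal cutoff {res.cutoff:.4f} "
          f"(chi2 p={res.p_value:.2e}, low/high = {res.n_low}/{res.n_high})")

cohort["pg"] = [lq.assign_prognostic_group(t, n)
                for t, n in zip(groups["tls_td"], groups["necr_td"])]
print("\nprognostic groups:", cohort["pg"].value_counts().to_dict())
for pg in ("PG1", "PG2", "PG3"):
    sub = cohort[cohort["pg"] == pg]
    km = lq.km_estimate(sub["time_os"], sub["event_os"])
    print(f"  {pg}: S(48 months) = {float(km.survival_at(48.0)):.2f}")

fit = cohort[["time_os", "event_os", "pT", "pN"]].copy()
fit["necr_high"] = (groups["necr_td"] == "high").astype(float)
enc = encode_stage_covariates(fit)
covs = [c for c in enc.columns if c not in ("time_os", "event_os")]
res = lq.cox_fit(enc, "time_os", "event_os", covs)
eff = res.effect("necr_high")
print(f"\nmultivariate Cox (with pT/pN): necrosis-high HR = "
      f"{eff.hazard_ratio:.2f} [{eff.ci_lower:.2f}, {eff.ci_upper:.2f}], "
      f"p = {eff.p_value:.1e}")
# PG1 (TLS-high / necrosis-low) should show the best survival and PG3 the
# worst; the necrosis effect stays significant after pT/pN adjustment
# because the generator planted it as an independent hazard term.
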