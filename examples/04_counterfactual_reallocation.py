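"""The what-if reallocation: how much disparity is down to setting mix?

Direct standardization: give the unhoused group the independent-living
distribution over service settings while keeping unhoused within-setting
treatment rates.  The elimination share says what fraction of the observed
rate gap would close under that reallocation.

First the desk-scale arithmetic from the published operand rates, then the
same decomposition measured on a synthetic cohort against its planted truth.
"""

import warnings

import moudflow as mf

warnings.filterwarnings("ignore")

# --- published operands ----------------------------------------------------
r_independent, r_unhoused, r_counterfactual = 44.92, 28.56, 43.20
d_obs = mf.point_difference(r_independent, r_unhoused)
d_cf = mf.point_difference(r_independent, r_counterfactual)
share = 100 * (d_obs - d_cf) / d_obs
print("from the published rates:")
print(f"  observed disparity      {d_obs:5.2f} points")
print(f"  counterfactual disparity {d_cf:4.2f} points")
print(f"  elimination share       {share:5.2f} %  "
      "(the gap is overwhelmingly a setting-mix gap)")

# --- synthetic cohort ------------------------------------------------------
config = mf.default_config(n_admissions=200_000, seed=19)
est, truth = mf.recover_from_synthetic(config)
print("\non a 200k-admission synthetic cohort (estimate vs planted truth):")
print(f"  unhoused rate           {est.observed_rate_target:5.2f} % "
      f"(truth {truth.expected_rate_by_group['Homeless']:.2f} %)")
print(f"  counterfactual rate     {est.counterfactual_rate:5.2f} % "
      f"(truth {truth.expected_counterfactual_rate:.2f} %)")
print(f"  elimination share       {est.elimination_share:5.2f} % "
      f"(truth {truth.expected_elimination_share:.2f} %)")
print("\nThe estimate is a sample version of the closed-form truth; the share"
      "\nis a ratio of small differences, so it carries visible sampling noise.")
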