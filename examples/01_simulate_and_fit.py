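"""Generate a synthetic diagnostic cohort and fit the probability model.

Draws 5,000 records from the desk-scale study conditions (20 diseases, 30
symptoms, Zipf priors, two symptom couplings at rho = 0.9), fits Laplace-
smoothed priors and conditionals, and compares a few of them with the
generator's ground truth.
"""

from depnb import desk_spec, fit_probability_model, generate_cohort

spec = desk_spec(m=5000, rho=0.9, seed=1)
cohort, truth = generate_cohort(spec)
model = fit_probability_model(cohort)

print(f"cohort: m={cohort.m} records, k={cohort.k} diseases, "
      f"V={len(cohort.symptom_vocabulary)} symptoms")
theta = truth.spec.effective_theta()
for d, f in [("D000", 0), ("D001", 1)]:
    print(f"P({d}): estimated {model.prior(d):.4f} vs true {truth.spec.priors[f]:.4f}")
for s, v in [("S00", 0), ("S01", 1)]:
    print(f"P({s}|D000): estimated {model.conditional(s, 'D000'):.4f} "
          f"vs true {theta[0, v]:.4f}")
# The estimated values track the generator's truth to a couple of decimals;
# the small gap is Laplace shrinkage plus sampling noise.
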