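"""Score the skin-youthfulness phenotype and classify subjects.

SAS = median clinician rating; delta = chronological age - SAS;
r_delta = residual of delta regressed on age.  Among subjects aged
>= 50, the top decile of r_delta is SY and the lower half non-SY.
"""

from skinyouth import SimulationConfig, assign_phenotypes, compute_delta, generate_cohort

# The two canonical example subjects: one who looks 15 years older than
# their age (delta -15), one who looks their age (delta +1).
print("delta(CA=65, SAS=80) =", compute_delta(65, 80))
print("delta(CA=60, SAS=59) =", compute_delta(60, 59))

cohort, truth = generate_cohort(
    SimulationConfig(seed=1, rater_sd=1.5, delta_noise_base=3.0, delta_noise_age=0.25)
)
assignments, fit = assign_phenotypes(cohort)

print(f"\ndelta-on-age slope: {fit.slope:.3f} years/year "
      f"(delta spreads out with age)")
print(assignments["class"].value_counts().to_string())

labeled = set(assignments.index[assignments["class"] == "SY"])
overlap = len(labeled & truth.true_sy_subjects)
print(f"\n{overlap}/{len(labeled)} subjects labeled SY are truly SY "
      "in the generator's ground truth")
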