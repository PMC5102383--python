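"""Simulate a study cohort with known ground truth.

Generates 122 subjects aged 18-89 with four clinician skin-age ratings
each, plus a 5000-gene 3'-seq count matrix with planted age- and
youthfulness-responsive genes.
"""

from skinyouth import SimulationConfig, simulate_study

cohort, counts, truth = simulate_study(SimulationConfig(seed=1))

print(f"cohort: {len(cohort)} subjects, ages {cohort['age'].min():.0f}-"
      f"{cohort['age'].max():.0f}")
print(f"counts: {counts.shape[0]} genes x {counts.shape[1]} samples "
      f"(stage={counts.stage})")
print(f"median library size: {counts.values.sum().median()/1e6:.1f}M reads")
print(f"planted: {len(truth.age_gene_signs)} age genes, "
      f"{len(truth.sy_gene_signs)} youthfulness genes, "
      f"{len(truth.true_sy_subjects)} truly skin-youthful subjects")
print(cohort[["age", "batch", "rater_1", "rater_2", "bmi"]].head())

# The rater columns are integer skin-age scores; their spread around the
# chronological age widens with age, which is exactly the structure the
# residual phenotype downstream is designed to handle.
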