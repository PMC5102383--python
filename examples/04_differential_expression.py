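"""Detect age-associated and youthfulness-associated genes.

Age genes: per-gene OLS on chronological age, variance-moderated t,
Benjamini-Hochberg FDR < 0.01.  Youthfulness genes: expression is first
residualized on age, then regressed on the SY / non-SY indicator, with
genes called at unadjusted p < 0.01.
"""

from skinyouth import (
    SimulationConfig,
    assign_phenotypes,
    detect_age_genes,
    detect_sy_genes,
    simulate_study,
)
from skinyouth.preprocess import preprocess_counts

cohort, counts, truth = simulate_study(SimulationConfig(seed=1))
assignments, _ = assign_phenotypes(cohort)
m = preprocess_counts(counts, batches=cohort["batch"])
ages = cohort["age"].to_numpy()

up, down, age_table = detect_age_genes(m, ages, fdr=0.01)
planted = set(truth.age_gene_signs)
hits = set(up) | set(down)
print(f"age genes at FDR<0.01: {len(up)} up, {len(down)} down "
      f"({len(hits & planted)}/{len(planted)} planted genes recovered)")

classes = assignments.loc[list(m.sample_ids), "class"].to_numpy()
up_sy, down_sy, sy_table = detect_sy_genes(m, ages, classes, p_cut=0.01)
planted_sy = set(truth.sy_gene_signs)
hits_sy = set(up_sy) | set(down_sy)
print(f"SY genes at p<0.01: {len(up_sy)} up, {len(down_sy)} down "
      f"({len(hits_sy & planted_sy)}/{len(planted_sy)} planted recovered)")

print("\nmost significant SY genes (beta = log2 difference SY - non-SY):")
print(sy_table.head(5)[["beta", "t", "p", "fdr"]].to_string())
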