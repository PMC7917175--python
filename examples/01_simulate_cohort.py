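"""Generate a paired synthetic tumor cohort and inspect its planted structure.

The generator emulates an immune-gene FPKM matrix with k planted subtypes,
block-correlated gene modules, subtype-dependent survival and mutation
burden, APC infiltration scores, tumor purity, and a matched normal-tissue
matrix — everything downstream stages consume.
"""

from immunoscape import GeneratorConfig, generate_paired_cohorts

cfg = GeneratorConfig(n_samples=120, n_validation=60, n_genes=300)
disc, valid = generate_paired_cohorts(cfg, seed=7)

print(f"discovery expression: {disc.expression.shape[0]} genes x "
      f"{disc.expression.shape[1]} samples ({disc.expression.scale_tag})")
print(f"validation cohort:    {valid.expression.shape[1]} samples")
print("planted subtype sizes:",
      disc.truth.subtype_label.value_counts().sort_index().to_dict())
print(f"events observed: {int(disc.clinical.os_event.sum())} "
      f"of {len(disc.clinical)} patients "
      f"(censoring {1 - disc.clinical.os_event.mean():.0%})")
print(f"mutation records: {len(disc.mutations.records)}; "
      f"planted antigens: {disc.truth.antigen_genes}")
# The two cohorts share gene-level model parameters (centroids, modules),
# so subtypes discovered in one should be reproducible in the other.
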