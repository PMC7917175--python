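"""Score immune signatures per sample with ssGSEA and test subtype association.

Each sample's genes are ranked by expression; a signature's enrichment score
contrasts a rank-weighted ECDF over its genes (weight rank^0.25) with the
uniform ECDF over the rest.  ANOVA across subtypes with BH correction flags
differential signatures (q < 0.01).
"""

from immunoscape import (GeneratorConfig, generate_cohort,
                         generate_signature_sets, preprocess_expression,
                         run_consensus)
from immunoscape.ssgsea import group_differential, ssgsea_scores

cfg = GeneratorConfig(n_samples=120, delta=1.0)
bundle = generate_cohort(cfg, seed=3)
expr = preprocess_expression(bundle.expression)
sigs = generate_signature_sets(cfg, seed=3, n_null=5, set_size=25)

scores = ssgsea_scores(expr, sigs)
print(f"score matrix: {scores.scores.shape[0]} samples x "
      f"{scores.scores.shape[1]} signatures ({scores.normalization_tag})")

assoc = group_differential(scores.scores, bundle.truth.subtype_label)
print(assoc.round(4))
aligned_f = assoc.loc[assoc.index.str.startswith("aligned"), "statistic"]
null_f = assoc.loc[assoc.index.str.startswith("null"), "statistic"]
print(f"mean ANOVA F: aligned {aligned_f.mean():.1f}  null {null_f.mean():.1f}")
# Module-aligned signatures typically separate subtypes most strongly.
# Background ("null") sets are not perfectly flat: single-sample rank
# scoring lets coherent module shifts perturb every gene's rank, so at this
# cohort size even null sets can reach significance — the distinguishing
# feature is the effect size, not the p-value alone.
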