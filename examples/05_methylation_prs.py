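"""Candidate-CpG association scan and the clump-and-threshold polygenic
score on toy data."""
import numpy as np
import pandas as pd

from artgrowth import GeneratorConfig, generate_cohort
from artgrowth.measures import bonferroni_threshold
from artgrowth.methylation import candidate_cpg_scan, clump_and_score
from artgrowth.synthetic import simulate_genotypes

cohort = generate_cohort(GeneratorConfig(seed=6))
assoc, _ = candidate_cpg_scan(cohort.subjects, ["cpg_cg03904042"])
a = assoc[0]
print(f"CpG scan: beta={a.beta:+.3f} SD, p={a.p:.2e}, n={a.n}")
print(f"  Bonferroni bound for 187 candidates: "
      f"{bonferroni_threshold(0.05, 187):.1e}; passes: {a.passes_bonferroni}")

geno, meta = simulate_genotypes(n_subjects=400, n_snps=60, seed=7)
rng = np.random.default_rng(8)
eth = pd.Series(rng.choice(["chinese", "malay", "indian"], 400))
anchors = pd.DataFrame({"birth_weight": rng.normal(3.2, 0.4, 400),
                        "bmi": rng.normal(16, 2, 400)})
prs = clump_and_score(geno, meta, eth, anchors)
print("PRS thresholds chosen per ethnicity:", prs.chosen_thresholds)
for g, grp in prs.scores.groupby("ethnicity"):
    print(f"  {g}: standardized mean {grp.standardized.mean():+.1e}, "
          f"var {grp.standardized.var(ddof=0):.3f}, "
          f"{len(prs.retained_snps[g])} SNPs retained")
# Scores are standardized to mean 0 / variance 1 within each ethnicity;
# the two clumping rounds keep the most significant variant per window.
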