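"""Estimate genome-wide hypothesis priors and reuse them per locus.

Simulates 300 loci whose hypothesis labels are drawn from a known mixture,
estimates the five mixture proportions by EM over the locus Bayes factors,
and applies them as empirical priors in the per-locus posterior.
"""

import numpy as np

from condcoloc import SimScenario, build_locus_bf, coloc_posterior, estimate_priors, harmonize, simulate_genomewide

truth_pi = [0.70, 0.10, 0.10, 0.05, 0.05]
scenario = SimScenario(seed=5, n_variants=30, n_samples=5000, gwas_n=5000,
                       effect_mode="prior")
loci = simulate_genomewide(truth_pi, 300, scenario)

lbfs = []
for k, (gwas, eqtl, t) in enumerate(loci):
    pair = harmonize(gwas, eqtl, (scenario.chrom, 1, 10**12))
    lbfs.append(build_locus_bf(pair, locus_id=f"locus_{k}"))

priors = estimate_priors(lbfs)
print("true mixture Π0..Π4:", truth_pi)
labels = [t["hypothesis"] for _, _, t in loci]
print("drawn frequencies:  ", [round(labels.count(h) / len(loci), 3)
                               for h in ("H0", "H1", "H2", "H3", "H4")])
print("EM estimate:        ", np.round(priors.pi, 3).tolist())
print(f"EM iterations: {len(priors.log_likelihood_trace)}, "
      f"final log-likelihood {priors.log_likelihood_trace[-1]:.1f}")

posteriors = [coloc_posterior(l, priors) for l in lbfs]
best = int(np.argmax([r.pph[4] for r in posteriors]))
print(f"\nstrongest colocalization: locus {best} (true {labels[best]}), "
      f"PPH = {np.round(posteriors[best].pph, 3).tolist()}")
# The estimate tracks the drawn frequencies; with only 300 loci expect a few
# points of sampling noise on each component.  Per-locus posteriors reuse the
# estimated proportions as priors, so weak loci shrink toward H0 while
# well-powered shared signals still reach high PPH4.
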