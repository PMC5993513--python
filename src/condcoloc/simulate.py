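"""Synthetic genotypes, expression and paired summary statistics with known
ground truth.

The generator provides everything the mapping and colocalization machinery
needs for testing without access-restricted cohort data:

* block-structured genotype dosages — within each LD block, haplotypes come
  from a compound-symmetric latent Gaussian (correlation ``rho``) thresholded
  at the allele frequency, so the target between-variant correlation is
  controlled in closed form and blocks are independent;
* expression as a linear model on planted causal dosages plus Gaussian noise;
* paired GWAS/eQTL summary statistics for a locus generated under any of the
  five colocalization hypotheses (H0 neither trait associated, H1 GWAS only,
  H2 eQTL only, H3 distinct causal variants, H4 one shared causal variant),
  with the summary statistics computed by per-variant marginal regression on
  the simulated samples — the same route real summary statistics take.

Every draw flows through one :class:`numpy.random.Generator` seeded from the
scenario, so a scenario is fully reproducible.  Allele pairs are drawn
non-palindromic so harmonization keeps every simulated variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .eqtl import ExpressionMatrix, GenotypeMatrix, marginal_scan
from .sumstats import SumstatRecord

HYPOTHESIS_LABELS = ("H0", "H1", "H2", "H3", "H4")

#: non-palindromic allele pairs used for simulated variants
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))


@dataclass
class SimScenario:
    """Study conditions for one synthetic locus or cohort.

    Defaults mirror the data regime the methods target: common variants
    (MAF ≥ 0.05 after QC-style filtering), moderate LD blocks, cohorts of a
    few hundred samples, and per-signal effects around 5-10% of expression
    variance — the scale at which conditional signals are detectable but not
    trivial.
    """

    seed: int = 0
    n_samples: int = 500  # eQTL cohort size
    n_variants: int = 30
    maf_range: tuple[float, float] = (0.05, 0.5)
    block_size: int = 10
    rho: float = 0.7  # within-block haplotype correlation (latent scale)
    noise_sd: float = 1.0
    gwas_n: int = 500
    eqtl_var_explained: float = 0.10  # per planted signal
    gwas_var_explained: float = 0.10
    chrom: str = "1"
    start_pos: int = 1_000_000
    spacing: int = 1_000
    #: how locus-pair causal effect sizes are set: "variance" plants a fixed
    #: effect at the stated variance explained (controlled experiments);
    #: "prior" draws beta ~ N(0, w) with w drawn uniformly from
    #: effect_prior_w — the generative model the empirical-Bayes mixture
    #: estimation assumes (genome-wide runs)
    effect_mode: str = "variance"
    effect_prior_w: float | tuple[float, ...] = (0.01, 0.1, 0.5)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# genotypes


def _block_haplotypes(rng, n_hap: int, block_mafs: np.ndarray, rho: float) -> np.ndarray:
    """Haplotype alleles for one block via a compound-symmetric latent Gaussian."""
    if not 0.0 <= rho < 1.0:
        raise ValueError("within-block correlation rho must be in [0, 1)")
    m = block_mafs.size
    shared = rng.standard_normal((n_hap, 1))
    indep = rng.standard_normal((n_hap, m))
    latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep
    thresh = norm.isf(block_mafs)  # allele carried when latent exceeds threshold
    return (latent > thresh).astype(float)


def simulate_genotypes(
    scenario: SimScenario,
    rng: np.random.Generator | None = None,
    n_samples: int | None = None,
    mafs: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Diploid dosages with block LD structure, reproducible from the seed.

    ``mafs`` fixes the per-variant allele frequencies (used to share
    frequencies between the eQTL and GWAS cohorts of one locus); otherwise
    they are drawn uniformly from ``scenario.maf_range``.
    """
    rng = scenario.rng() if rng is None else rng
    n = scenario.n_samples if n_samples is None else n_samples
    m = scenario.n_variants
    if mafs is None:
        mafs = rng.uniform(*scenario.maf_range, size=m)
    hap1 = np.empty((n, m))
    hap2 = np.empty((n, m))
    for lo in range(0, m, scenario.block_size):
        hi = min(lo + scenario.block_size, m)
        hap1[:, lo:hi] = _block_haplotypes(rng, n, mafs[lo:hi], scenario.rho)
        hap2[:, lo:hi] = _block_haplotypes(rng, n, mafs[lo:hi], scenario.rho)
    dosages = hap1 + hap2
    pos = scenario.start_pos + scenario.spacing * np.arange(m)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    variant_ids = [f"{scenario.chrom}:{p}" for p in pos]
    geno = GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        variant_ids=variant_ids,
        chrom=np.full(m, scenario.chrom, dtype=object),
        pos=pos,
        dosages=dosages,
    )
    geno.alleles = [_ALLELE_PAIRS[i] for i in pair_idx]  # (effect, other) per variant
    return geno


# ---------------------------------------------------------------------------
# expression / traits


def beta_for_variance_explained(dosage: np.ndarray, ve: float, total_var: float = 1.0) -> float:
    """Effect size giving a planted signal the target share of trait variance."""
    v = dosage.var()
    if v <= 0:
        raise ValueError("monomorphic dosage cannot carry an effect")
    return float(np.sqrt(ve * total_var / v))


def simulate_trait(
    geno: GenotypeMatrix,
    planted: Sequence[tuple[int, float]],
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """y = Σ beta_k · dosage_k + N(0, noise_sd²)."""
    y = rng.normal(0.0, noise_sd, size=len(geno.sample_ids))
    for idx, beta in planted:
        y = y + beta * geno.dosages[:, idx]
    return y


def simulate_expression(
    geno: GenotypeMatrix,
    planted_per_gene: dict[str, Sequence[tuple[int, float]]],
    noise_sd: float,
    rng: np.random.Generator,
) -> tuple[ExpressionMatrix, dict[str, dict]]:
    """Expression matrix for several genes with planted cis-eQTL.

    Returns the matrix and a truth manifest recording, per gene, the planted
    (variant index, variant id, beta) triples and the realized fraction of
    expression variance each planted signal explains.
    """
    gene_ids = list(planted_per_gene)
    values = np.empty((len(gene_ids), len(geno.sample_ids)))
    truth: dict[str, dict] = {}
    for gi, gene in enumerate(gene_ids):
        planted = list(planted_per_gene[gene])
        y = simulate_trait(geno, planted, noise_sd, rng)
        values[gi] = y
        total = y.var()
        truth[gene] = {
            "planted": [
                {
                    "variant_index": int(idx),
                    "variant_id": geno.variant_ids[idx],
                    "beta": float(beta),
                    "realized_r2": float((beta ** 2) * geno.dosages[:, idx].var() / total),
                }
                for idx, beta in planted
            ]
        }
    expr = ExpressionMatrix(gene_ids=gene_ids, sample_ids=list(geno.sample_ids), values=values)
    return expr, truth


# ---------------------------------------------------------------------------
# summary statistics


def marginal_sumstats(geno: GenotypeMatrix, y: np.ndarray) -> list[SumstatRecord]:
    """Per-variant marginal regression summary statistics for one trait."""
    beta, se, p = marginal_scan(y, geno.dosages)
    mafs = geno.maf()
    n = len(geno.sample_ids)
    alleles = getattr(geno, "alleles", None) or [("A", "G")] * len(geno.variant_ids)
    return [
        SumstatRecord(
            variant_id=vid, chrom=str(geno.chrom[j]), pos=int(geno.pos[j]),
            effect_allele=alleles[j][0], other_allele=alleles[j][1],
            beta=float(beta[j]), se=float(se[j]), p=float(p[j]),
            maf=float(max(mafs[j], 1e-6)), n=float(n),
        )
        for j, vid in enumerate(geno.variant_ids)
    ]


# ---------------------------------------------------------------------------
# locus pairs under the five hypotheses


def _pick_causals(scenario: SimScenario, rng, hypothesis: str, r2_cap: float = 0.05):
    """Causal variant indices (gwas_idx, eqtl_idx) for the hypothesis.

    H3 places the two causal variants in different LD blocks so their
    population r² is ~0 (well under the cap); a single-block locus cannot
    satisfy H3 and raises.
    """
    m = scenario.n_variants
    n_blocks = int(np.ceil(m / scenario.block_size))
    if hypothesis == "H0":
        return None, None
    if hypothesis == "H1":
        return int(rng.integers(m)), None
    if hypothesis == "H2":
        return None, int(rng.integers(m))
    if hypothesis == "H4":
        j = int(rng.integers(m))
        return j, j
    if hypothesis == "H3":
        if n_blocks < 2:
            raise ValueError("H3 needs at least two LD blocks to cap causal r2")
        b1, b2 = rng.choice(n_blocks, size=2, replace=False)
        j1 = int(b1 * scenario.block_size + rng.integers(min(scenario.block_size, m - b1 * scenario.block_size)))
        j2 = int(b2 * scenario.block_size + rng.integers(min(scenario.block_size, m - b2 * scenario.block_size)))
        return j1, j2
    raise ValueError(f"unknown hypothesis {hypothesis!r}")


def simulate_locus_pair(
    hypothesis: str,
    scenario: SimScenario,
    rng: np.random.Generator | None = None,
) -> tuple[list[SumstatRecord], list[SumstatRecord], dict]:
    """Paired GWAS and eQTL summary statistics for one locus.

    Two independent cohorts (sizes ``gwas_n`` and ``n_samples``) are drawn
    from the same LD structure and allele frequencies; causal variants are
    planted per the hypothesis and each cohort's trait is scanned by marginal
    regression.  Returns (gwas records, eqtl records, truth record).
    """
    rng = scenario.rng() if rng is None else rng
    mafs = rng.uniform(*scenario.maf_range, size=scenario.n_variants)
    g_idx, e_idx = _pick_causals(scenario, rng, hypothesis)

    geno_e = simulate_genotypes(scenario, rng=rng, mafs=mafs)
    geno_g = simulate_genotypes(scenario, rng=rng, n_samples=scenario.gwas_n, mafs=mafs)
    geno_g.alleles = geno_e.alleles  # one variant catalogue for both cohorts

    def _effect(geno, idx, ve):
        if scenario.effect_mode == "prior":
            w_set = np.atleast_1d(scenario.effect_prior_w)
            w = float(rng.choice(w_set))
            return float(rng.normal(0.0, np.sqrt(w) * scenario.noise_sd))
        if scenario.effect_mode != "variance":
            raise ValueError(f"unknown effect_mode {scenario.effect_mode!r}")
        return beta_for_variance_explained(
            geno.dosages[:, idx], ve, total_var=scenario.noise_sd ** 2 / max(1e-12, 1 - ve)
        )

    planted_e = []
    if e_idx is not None:
        planted_e = [(e_idx, _effect(geno_e, e_idx, scenario.eqtl_var_explained))]
    planted_g = []
    if g_idx is not None:
        planted_g = [(g_idx, _effect(geno_g, g_idx, scenario.gwas_var_explained))]
    # H4 shares the causal variant; in prior mode it shares the drawn effect
    # magnitude only through the variant, each trait's beta drawn separately

    y_e = simulate_trait(geno_e, planted_e, scenario.noise_sd, rng)
    y_g = simulate_trait(geno_g, planted_g, scenario.noise_sd, rng)
    truth = {
        "hypothesis": hypothesis,
        "causal_gwas": None if g_idx is None else geno_g.variant_ids[g_idx],
        "causal_eqtl": None if e_idx is None else geno_e.variant_ids[e_idx],
    }
    return marginal_sumstats(geno_g, y_g), marginal_sumstats(geno_e, y_e), truth


def simulate_genomewide(
    pi: Sequence[float],
    n_loci: int,
    scenario: SimScenario,
    rng: np.random.Generator | None = None,
) -> list[tuple[list[SumstatRecord], list[SumstatRecord], dict]]:
    """Locus pairs with hypotheses drawn from the mixture proportions Π0..Π4.

    Each locus gets distinct variant positions (so loci never collide) and
    its truth record carries the drawn label.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (5,) or abs(pi.sum() - 1.0) > 1e-8 or np.any(pi < 0):
        raise ValueError("pi must be a length-5 simplex")
    if n_loci < 50:
        import logging

        logging.getLogger(__name__).warning("simulate_genomewide: n_loci < 50")
    rng = scenario.rng() if rng is None else rng
    labels = rng.choice(5, size=n_loci, p=pi)
    out = []
    for k, lab in enumerate(labels):
        sc = replace(
            scenario,
            start_pos=scenario.start_pos + k * (scenario.n_variants + 10) * scenario.spacing,
        )
        gwas, eqtl, truth = simulate_locus_pair(HYPOTHESIS_LABELS[lab], sc, rng=rng)
        truth["locus_index"] = k
        out.append((gwas, eqtl, truth))
    return out
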