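"""Empirical-Bayes colocalization of GWAS and eQTL association signals.

For each locus (a gene's cis-region, or its intersection with a GWAS locus)
the engine assesses five mutually exclusive hypotheses about the pattern of
causal variants for the two traits:

* H0 — neither trait has a causal variant in the region;
* H1 — GWAS association only;
* H2 — eQTL association only;
* H3 — both traits associated, distinct causal variants;
* H4 — both traits associated, one shared causal variant (colocalization).

Evidence per SNP is a Wakefield asymptotic Bayes factor (WABF) computed from
the signed z-score and the sampling variance V of the effect estimate,
averaged on the Bayes-factor scale over three effect-prior variances
W ∈ {0.01, 0.1, 0.5}.  Under a uniform prior on the causal position within
the locus, per-SNP Bayes factors combine into locus-level Bayes factors for
H1-H4 against H0.  The five mixture proportions Π0..Π4 are estimated once
from all loci by maximum likelihood (EM on the simplex) and reused as priors
in the per-locus posterior:  PPH_i ∝ Π_i · BF_i.

All Bayes-factor arithmetic is carried on the natural-log scale with
log-sum-exp stabilization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")

#: effect-size prior variances averaged over in the WABF
W_SET_DEFAULT = (0.01, 0.1, 0.5)

#: fixed locus-level hypothesis priors used when no empirical estimate is wanted
DEFAULT_PRIORS = (0.989, 0.005, 0.005, 0.0005, 0.0005)

#: smoothing floor keeping EM away from absorbing states on the simplex
PRIOR_FLOOR = 1e-6


@dataclass
class SnpBayesFactors:
    variant_id: str
    log_bf_gwas: float
    log_bf_eqtl: float


@dataclass
class LocusBF:
    """Locus-level natural-log Bayes factors for H1..H4 relative to H0."""

    locus_id: str
    gene_id: str
    focal: int | str  # conditional order of the focal eQTL signal, or "marginal"
    n_snps: int
    lbf: np.ndarray  # length 4: H1, H2, H3, H4
    low_confidence: bool = False

    def lbf_full(self) -> np.ndarray:
        """Length-5 vector with lbf(H0) = 0 prepended."""
        return np.concatenate([[0.0], self.lbf])


@dataclass
class HypothesisPriors:
    """Simplex of five mixture proportions Π0..Π4."""

    pi: np.ndarray
    log_likelihood_trace: list[float] = field(default_factory=list)
    degenerate: bool = False

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (5,) or np.any(self.pi < 0):
            raise ValueError("priors must be five nonnegative proportions")
        if not math.isclose(self.pi.sum(), 1.0, rel_tol=0, abs_tol=1e-8):
            raise ValueError("priors must sum to 1")

    @classmethod
    def default(cls) -> "HypothesisPriors":
        return cls(np.array(DEFAULT_PRIORS))

    @classmethod
    def uniform(cls) -> "HypothesisPriors":
        return cls(np.full(5, 0.2))


@dataclass
class ColocResult:
    locus_id: str
    gene_id: str
    focal: int | str
    n_snps: int
    pph: np.ndarray  # PPH0..PPH4
    low_confidence: bool = False

    @property
    def pph4(self) -> float:
        return float(self.pph[4])


# ---------------------------------------------------------------------------
# Wakefield Bayes factors


def wabf(z: float, V: float, W: float) -> float:
    """Natural-log Wakefield asymptotic Bayes factor for association vs null.

    With shrinkage r = W/(V+W):  log BF = ½·log(1−r) + r·z²/2.  This is the
    exact marginal-likelihood ratio of beta-hat ~ N(beta, V) under a
    N(0, W) effect prior versus the point null; W = 0 gives log BF = 0.
    """
    if V <= 0:
        raise ValueError("sampling variance V must be positive")
    if W < 0:
        raise ValueError("prior variance W must be nonnegative")
    r = W / (V + W)
    return 0.5 * math.log1p(-r) + r * z * z / 2.0


def avg_wabf(z, V, W_set: Sequence[float] = W_SET_DEFAULT):
    """log of the arithmetic mean of WABFs over the prior-variance grid.

    Averaging is on the Bayes-factor scale (log-mean-exp), so the result is
    bounded between the smallest and largest individual log BFs.  Accepts
    scalars or aligned arrays of z and V.
    """
    z = np.asarray(z, dtype=float)
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0):
        raise ValueError("sampling variance V must be positive")
    r = np.array([w / (V + w) for w in W_set])  # len(W_set) × shape(z)
    lbf = 0.5 * np.log1p(-r) + r * z * z / 2.0
    out = logsumexp(lbf, axis=0) - math.log(len(W_set))
    return float(out) if out.ndim == 0 else out


def snp_bayes_factors(
    variant_ids: Sequence[str],
    z_gwas: np.ndarray,
    v_gwas: np.ndarray,
    z_eqtl: np.ndarray,
    v_eqtl: np.ndarray,
    W_set: Sequence[float] = W_SET_DEFAULT,
) -> list[SnpBayesFactors]:
    la = avg_wabf(z_gwas, v_gwas, W_set)
    lb = avg_wabf(z_eqtl, v_eqtl, W_set)
    return [
        SnpBayesFactors(v, float(a), float(b))
        for v, a, b in zip(variant_ids, np.atleast_1d(la), np.atleast_1d(lb))
    ]


# ---------------------------------------------------------------------------
# locus-level Bayes factors


def _logdiffexp(la: float, lb: float) -> float:
    """log(exp(la) - exp(lb)) for la >= lb, -inf when the difference vanishes."""
    if lb == -np.inf:
        return la
    d = lb - la
    if d >= 0:  # numerically equal or inverted: the difference is ~0
        return -np.inf
    return la + math.log1p(-math.exp(d))


def locus_bf(
    snp_bfs: Sequence[SnpBayesFactors],
    locus_id: str = "locus",
    gene_id: str = "gene",
    focal: int | str = "marginal",
) -> LocusBF:
    """Combine per-SNP Bayes factors into locus Bayes factors for H1..H4.

    With per-SNP GWAS BFs a_j and eQTL BFs b_j and a uniform prior over the
    causal position within the locus (K SNPs):

    * BF(H1) = Σ a_j / K
    * BF(H2) = Σ b_j / K
    * BF(H4) = Σ a_j·b_j / K                       (shared causal SNP)
    * BF(H3) = (Σa_j · Σb_j − Σ a_j·b_j) / (K(K−1)) (distinct causal SNPs)

    For K = 1 no two distinct causal positions exist and lbf(H3) = −inf.
    """
    K = len(snp_bfs)
    if K < 1:
        raise ValueError("locus needs at least one SNP")
    la = np.array([s.log_bf_gwas for s in snp_bfs])
    lb = np.array([s.log_bf_eqtl for s in snp_bfs])
    logK = math.log(K)
    lsum_a = float(logsumexp(la))
    lsum_b = float(logsumexp(lb))
    lsum_ab = float(logsumexp(la + lb))
    lbf1 = lsum_a - logK
    lbf2 = lsum_b - logK
    lbf4 = lsum_ab - logK
    if K == 1:
        lbf3 = -np.inf
    else:
        lbf3 = _logdiffexp(lsum_a + lsum_b, lsum_ab) - math.log(K * (K - 1))
    return LocusBF(
        locus_id=locus_id, gene_id=gene_id, focal=focal, n_snps=K,
        lbf=np.array([lbf1, lbf2, lbf3, lbf4]),
    )


# ---------------------------------------------------------------------------
# priors


def priors_from_per_snp(p1: float, p2: float, p12: float, n_snps: int) -> HypothesisPriors:
    """Convert classic per-SNP causal priors to locus-level hypothesis priors.

    With K SNPs and per-SNP probabilities p1 (GWAS only), p2 (eQTL only),
    p12 (shared), the standard configuration counting gives unnormalized
    hypothesis masses Π0 = 1, Π1 = K·p1, Π2 = K·p2, Π3 = K(K−1)·p1·p2,
    Π4 = K·p12, normalized to the simplex.
    """
    K = n_snps
    w = np.array([1.0, K * p1, K * p2, K * (K - 1) * p1 * p2, K * p12])
    return HypothesisPriors(w / w.sum())


def estimate_priors(
    loci: Sequence[LocusBF],
    init: HypothesisPriors | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> HypothesisPriors:
    """Maximum-likelihood hypothesis mixture proportions by EM.

    Maximizes  Σ_k log Σ_i Π_i exp(lbf_ik)  (lbf_H0 ≡ 0) over the simplex:
    E-step responsibilities γ_ik ∝ Π_i·exp(lbf_ik), M-step Π_i = mean_k γ_ik
    with a floor of ``PRIOR_FLOOR`` per component.  The log-likelihood is
    non-decreasing across iterations; convergence when the gain drops below
    ``tol``.  A flat likelihood (all lbf zero) returns ``init`` unchanged,
    flagged degenerate.
    """
    if init is None:
        init = HypothesisPriors.uniform()
    if len(loci) < 50:
        logger.warning("estimate_priors: only %d loci; estimates may be unstable", len(loci))
    L = np.stack([l.lbf_full() for l in loci])  # n_loci × 5, may contain -inf
    if np.allclose(L[np.isfinite(L)], 0.0):
        logger.warning("estimate_priors: flat likelihood, returning initial priors")
        return HypothesisPriors(init.pi.copy(), degenerate=True)

    pi = init.pi.copy()
    trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            log_joint = np.log(pi)[None, :] + L
        ll_per_locus = logsumexp(log_joint, axis=1)
        ll = float(ll_per_locus.sum())
        trace.append(ll)
        if ll < prev_ll - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
        gamma = np.exp(log_joint - ll_per_locus[:, None])
        pi = gamma.mean(axis=0)
        pi = np.maximum(pi, PRIOR_FLOOR)
        pi = pi / pi.sum()
    return HypothesisPriors(pi, log_likelihood_trace=trace)


# ---------------------------------------------------------------------------
# posteriors


def coloc_posterior(locus: LocusBF, priors: HypothesisPriors) -> ColocResult:
    """Posterior hypothesis probabilities:  PPH_i ∝ Π_i · exp(lbf_i)."""
    with np.errstate(divide="ignore"):
        log_post = np.log(priors.pi) + locus.lbf_full()
    pph = np.exp(log_post - logsumexp(log_post))
    pph = pph / pph.sum()
    return ColocResult(
        locus_id=locus.locus_id, gene_id=locus.gene_id, focal=locus.focal,
        n_snps=locus.n_snps, pph=pph, low_confidence=locus.low_confidence,
    )


# ---------------------------------------------------------------------------
# end-to-end driver


def build_locus_bf(
    pair,
    locus_id: str = "locus",
    gene_id: str = "gene",
    focal: int | str = "marginal",
    gwas_trait_type: str = "quantitative",
    eqtl_trait_type: str = "quantitative",
    gwas_pheno_var: float | str = 1.0,
    eqtl_pheno_var: float | str = 1.0,
    W_set: Sequence[float] = W_SET_DEFAULT,
    min_snps: int = 10,
) -> LocusBF:
    """LocusBF from a :class:`~condcoloc.sumstats.HarmonizedPair`.

    Per record, z = beta/se when available (else from p with beta's sign)
    and V from :func:`~condcoloc.sumstats.sampling_variance`.  Fewer than
    ``min_snps`` overlapping SNPs flags the result low-confidence; it is
    still computed.
    """
    from .sumstats import sampling_variance

    g_records = [g for g, _ in pair.records]
    e_records = [e for _, e in pair.records]
    if not g_records:
        raise ValueError("no overlapping SNPs after harmonization")
    vids = [e.variant_id for e in e_records]
    zg = np.array([g.zscore for g in g_records])
    ze = np.array([e.zscore for e in e_records])
    vg = np.array([
        sampling_variance(g, gwas_trait_type, gwas_pheno_var, peers=g_records)
        for g in g_records
    ])
    ve = np.array([
        sampling_variance(e, eqtl_trait_type, eqtl_pheno_var, peers=e_records)
        for e in e_records
    ])
    bfs = snp_bayes_factors(vids, zg, vg, ze, ve, W_set)
    out = locus_bf(bfs, locus_id=locus_id, gene_id=gene_id, focal=focal)
    if out.n_snps < min_snps:
        out.low_confidence = True
        logger.warning("locus %s/%s: only %d overlapping SNPs", locus_id, gene_id, out.n_snps)
    return out


def run_coloc2(
    harmonized_units: Iterable[tuple[str, str, int | str, "object"]],
    prior_mode: str = "empirical",
    user_priors: HypothesisPriors | None = None,
    **bf_kwargs,
) -> tuple[list[ColocResult], HypothesisPriors]:
    """Colocalize a collection of (locus_id, gene_id, focal, HarmonizedPair).

    ``prior_mode``: ``"empirical"`` estimates the five mixture proportions
    once across all units by EM and applies them per locus; ``"default"``
    uses the fixed locus-level priors; ``"user"`` requires ``user_priors``.
    Returns the per-unit results and the priors actually used.
    """
    units = list(harmonized_units)
    lbfs = [
        build_locus_bf(pair, locus_id=lid, gene_id=gid, focal=focal, **bf_kwargs)
        for lid, gid, focal, pair in units
    ]
    if prior_mode == "empirical":
        priors = estimate_priors(lbfs)
    elif prior_mode == "default":
        priors = HypothesisPriors.default()
    elif prior_mode == "user":
        if user_priors is None:
            raise ValueError("prior_mode='user' requires user_priors")
        priors = user_priors
    else:
        raise ValueError(f"unknown prior_mode {prior_mode!r}")
    results = [coloc_posterior(l, priors) for l in lbfs]
    return results, priors
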