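"""Forward-stepwise conditional cis-eQTL mapping and signal isolation.

A cis-eQTL scan regresses one gene's covariate-adjusted expression on each
variant's dosage within the gene's cis window (gene body ± 1 Mb).  Genome-wide
significance is controlled with a Benjamini-Hochberg step-up cutoff computed
per chromosome over all first-pass cis tests; that cutoff is then reused as a
fixed p-value threshold at every conditional step, where previously selected
eSNPs enter the model as covariates.  Each selected signal can afterwards be
isolated with an "all-but-one" scan: the cis-region is re-scanned conditioning
on every selected eSNP except the focal one, yielding summary statistics for
that signal alone — the input the colocalization engine expects.

All per-variant regressions are full-model OLS: the reported coefficient,
standard error and two-sided t-test p-value for the dosage term are identical
(by the Frisch-Waugh-Lovell identity, used here for speed) to those from the
joint regression of expression on dosage plus all conditioning covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Dosage matrix (samples × variants) with per-variant metadata.

    Dosages are expected alternate-allele counts in [0, 2]; missing entries
    should be mean-imputed per variant before analysis (see
    :meth:`mean_impute`).
    """

    sample_ids: list[str]
    variant_ids: list[str]
    chrom: np.ndarray  # per-variant chromosome labels
    pos: np.ndarray  # per-variant positions (1-based)
    dosages: np.ndarray  # samples × variants, float

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.variant_ids):
            raise ValueError("dosage matrix dimensions inconsistent with metadata")

    def mean_impute(self) -> None:
        """Replace missing dosages by the per-variant mean, in place."""
        col_mean = np.nanmean(self.dosages, axis=0)
        idx = np.where(np.isnan(self.dosages))
        self.dosages[idx] = np.take(col_mean, idx[1])

    def maf(self) -> np.ndarray:
        f = self.dosages.mean(axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def cis_index(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of variants within [start, end] on ``chrom`` (1-based inclusive)."""
        return np.where((self.chrom == chrom) & (self.pos >= start) & (self.pos <= end))[0]


@dataclass
class ExpressionMatrix:
    """Covariate-adjusted residual expression, genes × samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("expression matrix dimensions inconsistent")

    def gene(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass
class EqtlStep:
    order: int  # 1-based conditional order (1 = primary)
    esnp_id: str
    beta: float
    se: float
    p: float
    p_threshold_used: float


@dataclass
class EqtlModel:
    """Ordered conditionally independent eSNPs for one gene."""

    gene_id: str
    steps: list[EqtlStep] = field(default_factory=list)
    cis_window: tuple[str, int, int] | None = None

    @property
    def esnp_ids(self) -> list[str]:
        return [s.esnp_id for s in self.steps]

    def __len__(self) -> int:
        return len(self.steps)


@dataclass
class IsolatedSignal:
    """Cis-wide scan for one signal, conditioning on all co-signals.

    ``stats`` has one row per cis variant: (variant_id, beta, se, p).
    """

    gene_id: str
    focal_order: int
    conditioned_on: list[str]
    variant_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray


def read_vcf_dosages(path, maf_min: float = 0.0) -> GenotypeMatrix:
    """Genotype dosages from a VCF: the DS FORMAT field when present, else
    summed GT alleles.  Missing genotypes become NaN (mean-impute after).
    Variants with MAF below ``maf_min`` after reading are dropped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    vids, chroms, positions, rows = [], [], [], []
    for var in vcf:
        ds = var.format("DS") if "DS" in (var.FORMAT or []) else None
        if ds is not None:
            dos = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gt = np.array([g[:2] for g in var.genotypes], dtype=float)
            gt[gt < 0] = np.nan
            dos = gt.sum(axis=1)
        vids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        positions.append(int(var.POS))
        rows.append(dos)
    geno = GenotypeMatrix(
        sample_ids=sample_ids, variant_ids=vids,
        chrom=np.array(chroms, dtype=object), pos=np.array(positions),
        dosages=np.array(rows).T,
    )
    if maf_min > 0:
        geno.mean_impute()
        keep = np.where(geno.maf() >= maf_min)[0]
        geno = GenotypeMatrix(
            sample_ids=geno.sample_ids,
            variant_ids=[geno.variant_ids[i] for i in keep],
            chrom=geno.chrom[keep], pos=geno.pos[keep],
            dosages=geno.dosages[:, keep],
        )
    return geno


# ---------------------------------------------------------------------------
# regression primitives


def _with_intercept(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None or covariates.size == 0:
        return np.ones((n, 1))
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != n:
        covariates = covariates.T
    return np.column_stack([np.ones(n), covariates])


def _residualize(y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of y (vector or matrix of columns) on the column space of C."""
    coef, *_ = np.linalg.lstsq(C, y, rcond=None)
    return y - C @ coef


def marginal_scan(
    expr: np.ndarray,
    dosages: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant OLS of expression on dosage, adjusting for covariates.

    Vectorized over the columns of ``dosages``.  Equivalent to fitting, for
    each variant j, the full model ``expr ~ 1 + covariates + dosage_j`` and
    reporting the dosage coefficient with its t-test p-value on
    ``n - rank(C) - 1`` degrees of freedom.  Monomorphic variants (zero
    dosage variance) get beta 0, se inf, p 1.
    """
    expr = np.asarray(expr, dtype=float)
    n = expr.shape[0]
    C = _with_intercept(covariates, n)
    y = _residualize(expr, C)
    X = _residualize(np.asarray(dosages, dtype=float), C)
    df = n - C.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough samples for the conditioning set")
    sxx = np.einsum("ij,ij->j", X, X)
    sxy = X.T @ y
    mono = sxx <= 1e-12
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = sxy / sxx_safe
    rss = y @ y - beta * sxy
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.where(np.abs(beta) > 0, np.inf, 0.0))
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    beta = np.where(mono, 0.0, beta)
    se = np.where(mono, np.inf, se)
    p = np.where(mono, 1.0, p)
    # guard the t tail at extreme statistics: keep p strictly positive
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return beta, se, p


def fit_snp_gene(
    expr: np.ndarray,
    dosage: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """OLS association of one variant with one gene: (beta, se, p)."""
    beta, se, p = marginal_scan(expr, np.asarray(dosage, dtype=float)[:, None], covariates)
    return float(beta[0]), float(se[0]), float(p[0])


def bh_threshold(pvals: Sequence[float], fdr: float) -> float:
    """Benjamini-Hochberg step-up p-value cutoff.

    Returns the largest sorted p(i) with p(i) <= i*fdr/m, or 0.0 when no
    test passes; everything at or below the cutoff is declared significant.
    """
    p = np.sort(np.asarray(pvals, dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value list")
    m = p.size
    crit = fdr * np.arange(1, m + 1) / m
    passing = np.where(p <= crit)[0]
    return float(p[passing[-1]]) if passing.size else 0.0


# ---------------------------------------------------------------------------
# stepwise selection


def stepwise_conditional(
    gene_id: str,
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    covariates: np.ndarray | None,
    p_threshold: float,
    cis_window: tuple[str, int, int],
    max_steps: int = 10,
    gene_tss: int | None = None,
    collinearity_r2: float = 0.99,
) -> EqtlModel:
    """Forward stepwise selection of conditionally independent cis-eQTL.

    At each step the full cis window is re-scanned conditioning on the eSNPs
    already selected; the minimum-p variant is added while its p-value stays
    below ``p_threshold`` (the fixed threshold carried over from the
    first-pass BH cutoff), stopping otherwise or at ``max_steps``.  Ties at
    the minimum p are broken by distance to the gene TSS (when given), then
    variant id.  A candidate with squared correlation above
    ``collinearity_r2`` to the selected dosages is skipped.
    """
    chrom, start, end = cis_window
    cis_idx = geno.cis_index(chrom, start, end)
    if cis_idx.size == 0:
        raise ValueError(f"gene {gene_id}: no cis variants in window")
    y = expr.gene(gene_id)
    X = geno.dosages[:, cis_idx]
    vids = [geno.variant_ids[i] for i in cis_idx]
    vpos = geno.pos[cis_idx]

    model = EqtlModel(gene_id=gene_id, cis_window=cis_window)
    selected: list[int] = []  # local indices into cis_idx
    while len(model) < max_steps:
        cond = np.column_stack(
            ([np.atleast_2d(covariates).reshape(len(y), -1)] if covariates is not None else [])
            + [X[:, selected]]
        ) if (covariates is not None or selected) else None
        beta, se, p = marginal_scan(y, X, cond)
        p_search = p.copy()
        p_search[selected] = np.inf
        while True:
            j = _argmin_with_ties(p_search, vpos, vids, gene_tss)
            if j is None or not np.isfinite(p_search[j]) or p_search[j] >= p_threshold:
                j = None
                break
            if selected and _max_r2(X[:, j], X[:, selected]) > collinearity_r2:
                logger.info(
                    "gene %s: %s collinear with selected set, skipped", gene_id, vids[j]
                )
                p_search[j] = np.inf
                continue
            break
        if j is None:
            break
        model.steps.append(
            EqtlStep(
                order=len(model) + 1, esnp_id=vids[j],
                beta=float(beta[j]), se=float(se[j]), p=float(p[j]),
                p_threshold_used=p_threshold,
            )
        )
        selected.append(j)
    return model


def _argmin_with_ties(p, vpos, vids, gene_tss):
    finite = np.isfinite(p)
    if not finite.any():
        return None
    pmin = p[finite].min()
    ties = np.where(p == pmin)[0]
    if ties.size == 1:
        return int(ties[0])
    if gene_tss is not None:
        dist = np.abs(vpos[ties] - gene_tss)
        ties = ties[dist == dist.min()]
    return int(min(ties, key=lambda i: vids[i]))


def _max_r2(x: np.ndarray, X_sel: np.ndarray) -> float:
    xc = x - x.mean()
    denom_x = xc @ xc
    if denom_x <= 0:
        return 1.0
    Xc = X_sel - X_sel.mean(axis=0)
    denom = np.einsum("ij,ij->j", Xc, Xc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (xc @ Xc) ** 2 / (denom_x * denom)
    r2 = np.where(denom <= 0, 1.0, r2)
    return float(np.max(r2)) if r2.size else 0.0


def all_but_one(
    gene_id: str,
    model: EqtlModel,
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    covariates: np.ndarray | None,
    focal_order: int,
) -> IsolatedSignal:
    """Isolate one signal: cis-wide scan conditioning on every other eSNP.

    At the focal eSNP itself the returned (beta, se, p) equal the focal
    coefficient of the single joint regression containing all model eSNPs —
    the same linear model, so the identity is exact.
    """
    if not 1 <= focal_order <= len(model):
        raise ValueError(f"focal_order {focal_order} out of range for model of size {len(model)}")
    chrom, start, end = model.cis_window
    cis_idx = geno.cis_index(chrom, start, end)
    y = expr.gene(gene_id)
    X = geno.dosages[:, cis_idx]
    vids = [geno.variant_ids[i] for i in cis_idx]
    others = [s.esnp_id for s in model.steps if s.order != focal_order]
    other_cols = np.column_stack(
        [geno.dosages[:, geno.variant_ids.index(v)] for v in others]
    ) if others else None
    parts = []
    if covariates is not None:
        parts.append(np.atleast_2d(covariates).reshape(len(y), -1))
    if other_cols is not None:
        parts.append(other_cols)
    cond = np.column_stack(parts) if parts else None
    beta, se, p = marginal_scan(y, X, cond)
    return IsolatedSignal(
        gene_id=gene_id, focal_order=focal_order, conditioned_on=others,
        variant_ids=vids, beta=beta, se=se, p=p,
    )


# ---------------------------------------------------------------------------
# replication and pi1


def replicate_models(
    models: Sequence[EqtlModel],
    geno_rep: GenotypeMatrix,
    expr_rep: ExpressionMatrix,
    covariates_rep: np.ndarray | None,
) -> tuple[dict[str, list[tuple[int, str, float]]], list[str]]:
    """Refit discovery stepwise models in a replication cohort.

    Returns ``(per_gene_step_pvalues, omitted_genes)``.  For each model step
    the focal coefficient p-value comes from the joint regression of the
    replication expression on all of that model's eSNP dosages plus
    covariates.  A gene whose any eSNP is absent from the replication
    genotypes is omitted entirely (a missing marker invalidates the models
    conditional on it).
    """
    rep_index = {v: i for i, v in enumerate(geno_rep.variant_ids)}
    results: dict[str, list[tuple[int, str, float]]] = {}
    omitted: list[str] = []
    for model in models:
        if not model.steps:
            continue
        if any(v not in rep_index for v in model.esnp_ids) or model.gene_id not in expr_rep.gene_ids:
            omitted.append(model.gene_id)
            continue
        y = expr_rep.gene(model.gene_id)
        cols = np.column_stack([geno_rep.dosages[:, rep_index[v]] for v in model.esnp_ids])
        step_ps = []
        for k, step in enumerate(model.steps):
            others = np.delete(cols, k, axis=1)
            parts = []
            if covariates_rep is not None:
                parts.append(np.atleast_2d(covariates_rep).reshape(len(y), -1))
            if others.shape[1]:
                parts.append(others)
            cond = np.column_stack(parts) if parts else None
            _, _, p = marginal_scan(y, cols[:, [k]], cond)
            step_ps.append((step.order, step.esnp_id, float(p[0])))
        results[model.gene_id] = step_ps
    return results, omitted


def estimate_pi1(
    pvals: Sequence[float],
    lambda_grid: Sequence[float] | None = None,
) -> float:
    """Storey estimate of the proportion of true associations, pi1 = 1 - pi0.

    pi0(lambda) = #{p > lambda} / ((1 - lambda) m) is computed over the
    lambda grid (default 0.05..0.95 step 0.05) and smoothed with a cubic
    spline; pi0 is the smoothed value at the largest lambda, clipped to
    [0, 1].  Requires at least 50 p-values.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size < 50:
        raise ValueError("estimate_pi1 needs at least 50 p-values")
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.96, 0.05)
    lam = np.asarray(lambda_grid, dtype=float)
    m = p.size
    if np.allclose(p, p[0]):
        logger.warning("estimate_pi1: degenerate input (all p identical)")
        return 1.0 if p[0] < lam.min() else 0.0
    pi0_lam = np.array([(p > l).sum() / ((1.0 - l) * m) for l in lam])
    if lam.size >= 4:
        from scipy.interpolate import UnivariateSpline

        spl = UnivariateSpline(lam, pi0_lam, k=3)
        pi0 = float(spl(lam.max()))
    else:
        pi0 = float(pi0_lam[-1])
    pi0 = min(max(pi0, 0.0), 1.0)
    return 1.0 - pi0
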