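"""Reading, validation and harmonization of GWAS / eQTL summary statistics.

Association summary statistics arrive as tab-delimited tables with
heterogeneous column names and allele conventions.  Colocalization needs the
two traits' statistics expressed for the *same* effect allele at every shared
variant, and a per-SNP sampling variance V = Var(beta-hat) for the Bayes
factor machinery.  This module provides:

* :class:`SumstatRecord` — one variant's association summary for one trait;
* :func:`read_sumstats` — tolerant reader with a user column mapping;
* :func:`harmonize` — allele/strand alignment of two record sets in a region;
* :func:`sampling_variance` / :func:`estimate_sdY` — V from the standard
  error when present, else from MAF, N (and case fraction or phenotypic SD).

Coordinates are 1-based inclusive (VCF convention).  Case-control betas are
taken to be log odds ratios; no conversion is attempted.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")

#: default MAF ceiling above which a palindromic variant is ambiguous
PALINDROME_MAF_DEFAULT = 0.42


@dataclass
class SumstatRecord:
    """One variant's association summary for a single trait.

    ``beta``/``se`` are on the trait scale (log odds ratio for case-control
    traits); ``maf`` is the minor allele frequency in (0, 0.5]; ``s`` is the
    case fraction for case-control traits and ``None`` for quantitative ones.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float | None = None
    se: float | None = None
    p: float | None = None
    maf: float | None = None
    n: float | None = None
    s: float | None = None

    def validate(self) -> str | None:
        """Return a reason string if any invariant fails, else ``None``."""
        ea, oa = self.effect_allele, self.other_allele
        if ea not in _VALID_ALLELES or oa not in _VALID_ALLELES:
            return "invalid allele"
        if ea == oa:
            return "effect allele equals other allele"
        if self.p is not None and not (0.0 < self.p <= 1.0):
            return "p out of range"
        if self.se is not None and not self.se > 0:
            return "se not positive"
        if self.maf is not None and not (0.0 < self.maf <= 0.5):
            return "maf out of range"
        if self.s is not None and not (0.0 < self.s < 1.0):
            return "case fraction out of range"
        has_beta_se = self.beta is not None and self.se is not None
        has_p_maf_n = self.p is not None and self.maf is not None and self.n is not None
        if not (has_beta_se or has_p_maf_n):
            return "neither (beta, se) nor (p, maf, n) present"
        return None

    @property
    def zscore(self) -> float:
        """Signed z-score: beta/se when both present, else from p with beta's sign."""
        from scipy.stats import norm

        if self.beta is not None and self.se is not None:
            return self.beta / self.se
        sign = 1.0 if (self.beta is None or self.beta >= 0) else -1.0
        return sign * float(norm.isf(self.p / 2.0))

    def is_palindromic(self) -> bool:
        return _COMPLEMENT[self.effect_allele] == self.other_allele

    def allele_set(self) -> frozenset[str]:
        return frozenset((self.effect_allele, self.other_allele))


@dataclass
class HarmonizedPair:
    """Matched GWAS/eQTL records for one region, aligned to a common effect allele."""

    region: tuple[str, int, int]  # chrom, start, end (1-based inclusive)
    records: list[tuple[SumstatRecord, SumstatRecord]] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# reading


def _open_text(path):
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rt")
    return open(p, "rt")


_NUMERIC_FIELDS = ("beta", "se", "p", "maf", "n", "s")
_MANDATORY = ("variant_id", "chrom", "pos", "effect_allele", "other_allele")


def read_sumstats(
    path,
    column_map: dict[str, str],
    trait_type: Literal["quantitative", "case_control"] = "quantitative",
) -> list[SumstatRecord]:
    """Read a delimited summary-statistics table into validated records.

    ``column_map`` maps canonical field names (``variant_id``, ``chrom``,
    ``pos``, ``effect_allele``, ``other_allele``, and optionally ``beta``,
    ``se``, ``p``, ``maf``, ``n``, ``s``) to header names in the file.  Rows
    violating the record invariants are skipped with a logged reason; a
    missing mandatory column is a hard error.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    for fieldname in _MANDATORY:
        col = column_map.get(fieldname)
        if col is None or col not in df.columns:
            raise ValueError(f"missing mandatory column for field '{fieldname}'")

    records: list[SumstatRecord] = []
    n_skipped = 0
    for _, row in df.iterrows():
        kwargs: dict = {}
        bad_reason = None
        for fieldname in _MANDATORY:
            kwargs[fieldname] = row[column_map[fieldname]]
        try:
            kwargs["pos"] = int(kwargs["pos"])
        except (TypeError, ValueError):
            bad_reason = "unparseable position"
        kwargs["chrom"] = str(kwargs["chrom"])
        kwargs["variant_id"] = str(kwargs["variant_id"])
        kwargs["effect_allele"] = str(kwargs["effect_allele"]).upper()
        kwargs["other_allele"] = str(kwargs["other_allele"]).upper()
        for fieldname in _NUMERIC_FIELDS:
            col = column_map.get(fieldname)
            if col is None or col not in df.columns:
                continue
            val = row[col]
            if val is None or (isinstance(val, float) and math.isnan(val)):
                continue
            try:
                kwargs[fieldname] = float(val)
            except (TypeError, ValueError):
                bad_reason = f"unparseable {fieldname}"
        if trait_type == "quantitative":
            kwargs.pop("s", None)
        if bad_reason is None:
            rec = SumstatRecord(**kwargs)
            bad_reason = rec.validate()
            if bad_reason is None:
                records.append(rec)
                continue
        n_skipped += 1
        logger.info("skipped %s: %s", kwargs.get("variant_id"), bad_reason)
    if n_skipped:
        logger.warning("read_sumstats: skipped %d invalid rows", n_skipped)
    return records


def write_harmonized_tsv(pair: HarmonizedPair, path) -> None:
    """Write matched pairs as the merged TSV consumed by the coloc engine."""
    import pandas as pd

    rows = []
    for g, e in pair.records:
        rows.append(
            dict(
                variant_id=g.variant_id, chrom=g.chrom, pos=g.pos,
                ea=g.effect_allele, oa=g.other_allele,
                beta_gwas=g.beta, se_gwas=g.se, p_gwas=g.p,
                beta_eqtl=e.beta, se_eqtl=e.se, p_eqtl=e.p,
                maf=e.maf if e.maf is not None else g.maf,
                n_gwas=g.n, n_eqtl=e.n,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# harmonization


def _dedupe(records: Sequence[SumstatRecord], dropped: list[tuple[str, str]]):
    """Keep one record per (chrom, pos, allele set); smaller p wins."""
    best: dict[tuple, SumstatRecord] = {}
    for rec in records:
        key = (rec.chrom, rec.pos, rec.allele_set())
        prev = best.get(key)
        if prev is None:
            best[key] = rec
        else:
            keep, drop = (rec, prev) if (rec.p or 1.0) < (prev.p or 1.0) else (prev, rec)
            best[key] = keep
            dropped.append((drop.variant_id, "duplicate variant"))
    return best


def _flip(rec: SumstatRecord) -> SumstatRecord:
    """Swap alleles and negate the effect (same association, other allele)."""
    return SumstatRecord(
        variant_id=rec.variant_id, chrom=rec.chrom, pos=rec.pos,
        effect_allele=rec.other_allele, other_allele=rec.effect_allele,
        beta=None if rec.beta is None else -rec.beta,
        se=rec.se, p=rec.p, maf=rec.maf, n=rec.n, s=rec.s,
    )


def harmonize(
    gwas: Sequence[SumstatRecord],
    eqtl: Sequence[SumstatRecord],
    region: tuple[str, int, int],
    palindrome_policy: str | tuple[str, float] = ("keep_if_maf_below", PALINDROME_MAF_DEFAULT),
) -> HarmonizedPair:
    """Align GWAS records to eQTL allele orientation within a region.

    Variants are matched on (chrom, pos, unordered allele set), directly or
    after strand complementation.  When the GWAS effect allele is the eQTL
    other allele the GWAS beta sign is flipped and its alleles swapped.
    Palindromic variants (A/T, C/G) are ambiguous under strand flips:
    ``"drop"`` removes them; ``("keep_if_maf_below", t)`` keeps them matched
    by allele labels only when both traits' MAF is below ``t`` (frequency
    informative), else drops them.  Idempotent: harmonizing an already
    harmonized pair changes nothing.
    """
    chrom, start, end = region
    if isinstance(palindrome_policy, str):
        if palindrome_policy == "drop":
            pal_keep_t = -1.0
        else:
            raise ValueError(f"unknown palindrome policy {palindrome_policy!r}")
    else:
        name, pal_keep_t = palindrome_policy
        if name != "keep_if_maf_below":
            raise ValueError(f"unknown palindrome policy {name!r}")

    dropped: list[tuple[str, str]] = []
    in_region = lambda r: r.chrom == chrom and start <= r.pos <= end
    g_best = _dedupe([r for r in gwas if in_region(r)], dropped)
    e_best = _dedupe([r for r in eqtl if in_region(r)], dropped)

    # index GWAS by position for allele-set lookup (direct and complemented)
    g_by_pos: dict[tuple[str, int], list[SumstatRecord]] = {}
    for rec in g_best.values():
        g_by_pos.setdefault((rec.chrom, rec.pos), []).append(rec)

    records: list[tuple[SumstatRecord, SumstatRecord]] = []
    matched_gwas_ids: set[int] = set()
    for e_rec in sorted(e_best.values(), key=lambda r: r.pos):
        candidates = g_by_pos.get((e_rec.chrom, e_rec.pos), [])
        g_match = None
        complemented = False
        for g_rec in candidates:
            if g_rec.allele_set() == e_rec.allele_set():
                g_match, complemented = g_rec, False
                break
        if g_match is None:
            comp_set = frozenset(_COMPLEMENT[a] for a in e_rec.allele_set())
            for g_rec in candidates:
                if g_rec.allele_set() == comp_set:
                    g_match, complemented = g_rec, True
                    break
        if g_match is None:
            dropped.append((e_rec.variant_id, "no GWAS match"))
            continue
        matched_gwas_ids.add(id(g_match))

        if e_rec.is_palindromic():
            informative = (
                e_rec.maf is not None and g_match.maf is not None
                and e_rec.maf < pal_keep_t and g_match.maf < pal_keep_t
            )
            if not informative:
                dropped.append((e_rec.variant_id, "palindromic"))
                continue
            # frequencies informative: trust the allele labels as given
            aligned = g_match if g_match.effect_allele == e_rec.effect_allele else _flip(g_match)
        elif complemented:
            comp_ea = _COMPLEMENT[g_match.effect_allele]
            g_comp = SumstatRecord(
                variant_id=g_match.variant_id, chrom=g_match.chrom, pos=g_match.pos,
                effect_allele=comp_ea, other_allele=_COMPLEMENT[g_match.other_allele],
                beta=g_match.beta, se=g_match.se, p=g_match.p,
                maf=g_match.maf, n=g_match.n, s=g_match.s,
            )
            aligned = g_comp if comp_ea == e_rec.effect_allele else _flip(g_comp)
        else:
            aligned = g_match if g_match.effect_allele == e_rec.effect_allele else _flip(g_match)
        records.append((aligned, e_rec))

    for g_rec in g_best.values():
        if id(g_rec) not in matched_gwas_ids:
            dropped.append((g_rec.variant_id, "no eQTL match"))
    return HarmonizedPair(region=region, records=records, dropped=dropped)


# ---------------------------------------------------------------------------
# sampling variance of beta-hat


def sampling_variance(
    record: SumstatRecord,
    trait_type: Literal["quantitative", "case_control"] = "quantitative",
    pheno_var: float | Literal["estimate"] = 1.0,
    peers: Sequence[SumstatRecord] | None = None,
) -> float:
    """Sampling variance V of the effect estimate for one variant.

    When a standard error is reported, ``V = se**2`` (direct measurement wins).
    Otherwise, for a quantitative trait ``V ≈ sdY² / (2·n·maf·(1−maf))`` with
    ``sdY² = pheno_var`` (or estimated from ``peers`` via :func:`estimate_sdY`
    when ``pheno_var == "estimate"``); for a case-control trait on the
    log-odds scale ``V ≈ 1 / (2·n·s·(1−s)·2·maf·(1−maf))``.
    """
    if record.se is not None:
        return record.se ** 2
    if record.maf is None or record.n is None:
        raise ValueError("cannot form variance: need se or (maf, n)")
    two_pq = 2.0 * record.maf * (1.0 - record.maf)
    if trait_type == "case_control":
        if record.s is None:
            raise ValueError("cannot form variance: case fraction s required")
        return 1.0 / (record.n * record.s * (1.0 - record.s) * 2.0 * two_pq)
    if pheno_var == "estimate":
        if peers is None:
            raise ValueError("pheno_var='estimate' requires peer records")
        pheno_var = estimate_sdY(peers) ** 2
    return float(pheno_var) / (record.n * two_pq)


def estimate_sdY(records: Iterable[SumstatRecord]) -> float:
    """Phenotypic SD from summary statistics of a quantitative trait.

    For each SNP, ``se² · 2·n·maf·(1−maf)`` estimates sdY² (up to the small
    variance explained by the SNP); the regression-through-origin of these
    products against 1 has slope equal to their mean, and sqrt(slope) is the
    returned sdY.  Requires at least 20 SNPs with se, maf and n.
    """
    vals = [
        r.se ** 2 * 2.0 * r.n * r.maf * (1.0 - r.maf)
        for r in records
        if r.se is not None and r.maf is not None and r.n is not None
    ]
    if len(vals) < 20:
        raise ValueError(
            "estimate_sdY needs >= 20 records with se, maf and n; "
            "pass an explicit pheno_var instead"
        )
    slope = float(np.mean(vals))  # regression of vals on 1 through the origin
    if slope <= 0:
        raise ValueError("non-positive sdY^2 estimate")
    return math.sqrt(slope)
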