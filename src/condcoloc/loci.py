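"""GWAS locus definition, eQTL-locus overlap, and TSS distance summaries.

Loci are defined by greedy LD clumping: the most significant remaining SNP
below the p-value threshold becomes a lead, the locus spans every variant
with squared dosage correlation r² at or above the threshold to the lead,
contained variants are removed, and finally overlapping (including nested)
intervals are merged.  Intervals are 1-based closed on both ends; BED export
converts to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .eqtl import EqtlModel, GenotypeMatrix
from .sumstats import SumstatRecord

logger = logging.getLogger(__name__)


@dataclass
class GwasLocus:
    locus_id: str
    lead_snp: str
    lead_p: float
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    merged_from: list[str] = field(default_factory=list)
    fallback_window: bool = False

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def to_bed(self) -> tuple[str, int, int]:
        """0-based half-open interval for BED export."""
        return self.chrom, self.start - 1, self.end


def _r2_to_lead(dosages: np.ndarray, lead_col: np.ndarray) -> np.ndarray:
    lead_c = lead_col - lead_col.mean()
    denom_lead = lead_c @ lead_c
    Xc = dosages - dosages.mean(axis=0)
    denom = np.einsum("ij,ij->j", Xc, Xc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (lead_c @ Xc) ** 2 / (denom_lead * denom)
    return np.where((denom <= 0) | (denom_lead <= 0), 0.0, r2)


def define_loci(
    gwas: Sequence[SumstatRecord],
    ld_source: GenotypeMatrix,
    p_thresh: float = 1e-6,
    r2_thresh: float = 0.6,
    exclude: Sequence[tuple[str, int, int]] = (),
    fallback_kb: float = 250.0,
) -> list[GwasLocus]:
    """Greedy LD-clumped GWAS loci, merged and filtered against exclusions.

    A lead SNP missing from ``ld_source`` yields a fallback locus of
    ``lead ± fallback_kb`` kilobases, flagged.  Loci intersecting any
    interval in ``exclude`` (e.g. the MHC) are dropped after merging.
    """
    ld_index = {v: i for i, v in enumerate(ld_source.variant_ids)}
    remaining = [r for r in gwas if r.p is not None and r.p < p_thresh]
    remaining.sort(key=lambda r: (r.p, r.variant_id))
    pre: list[GwasLocus] = []
    used: set[str] = set()
    while remaining:
        lead = remaining.pop(0)
        if lead.variant_id in used:
            continue
        used.add(lead.variant_id)
        if lead.variant_id not in ld_index:
            half = int(fallback_kb * 1000)
            locus = GwasLocus(
                locus_id=f"locus_{len(pre)+1}", lead_snp=lead.variant_id, lead_p=lead.p,
                chrom=lead.chrom, start=max(1, lead.pos - half), end=lead.pos + half,
                fallback_window=True,
            )
            logger.warning("lead %s absent from LD source; ±%g kb fallback", lead.variant_id, fallback_kb)
        else:
            same_chrom = [r for r in gwas if r.chrom == lead.chrom and r.variant_id in ld_index]
            cols = np.column_stack([ld_source.dosages[:, ld_index[r.variant_id]] for r in same_chrom])
            r2 = _r2_to_lead(cols, ld_source.dosages[:, ld_index[lead.variant_id]])
            friends = [r for r, rr in zip(same_chrom, r2) if rr >= r2_thresh]
            positions = [r.pos for r in friends] + [lead.pos]
            locus = GwasLocus(
                locus_id=f"locus_{len(pre)+1}", lead_snp=lead.variant_id, lead_p=lead.p,
                chrom=lead.chrom, start=min(positions), end=max(positions),
            )
            for r in friends:
                used.add(r.variant_id)
        pre.append(locus)
        # only the lead's LD friends are consumed; an independent lead inside
        # the interval still seeds its own locus and is handled by merging
        remaining = [r for r in remaining if r.variant_id not in used]

    merged = merge_loci(pre)
    out = []
    for locus in merged:
        hits_exclusion = any(
            locus.chrom == c and not (locus.end < s or locus.start > e)
            for c, s, e in exclude
        )
        if hits_exclusion:
            logger.info("locus %s dropped: intersects exclusion", locus.locus_id)
            continue
        out.append(locus)
    for i, locus in enumerate(out, 1):
        locus.locus_id = f"locus_{i}"
    return out


def merge_loci(loci: Sequence[GwasLocus]) -> list[GwasLocus]:
    """Merge overlapping or nested intervals; the best lead (smallest p) wins."""
    by_chrom: dict[str, list[GwasLocus]] = {}
    for l in loci:
        by_chrom.setdefault(l.chrom, []).append(l)
    merged: list[GwasLocus] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda l: (l.start, l.end))
        current: GwasLocus | None = None
        for l in group:
            if current is None:
                current = GwasLocus(**{**l.__dict__, "merged_from": [l.locus_id]})
                continue
            if l.start <= current.end:  # overlap or nesting (closed intervals)
                current.end = max(current.end, l.end)
                current.merged_from.append(l.locus_id)
                if l.lead_p < current.lead_p:
                    current.lead_snp, current.lead_p = l.lead_snp, l.lead_p
            else:
                merged.append(current)
                current = GwasLocus(**{**l.__dict__, "merged_from": [l.locus_id]})
        if current is not None:
            merged.append(current)
    return merged


def overlap_table(
    loci: Sequence[GwasLocus],
    models: Sequence[EqtlModel],
    variant_positions: dict[str, tuple[str, int]],
) -> dict[str, dict[str, dict[str, int]]]:
    """Per-locus tabulation of genes with eSNPs inside the locus interval.

    ``variant_positions`` maps eSNP id → (chrom, pos).  Returns
    ``{locus_id: {gene_id: {"primary": k1, "conditional": k2}}}``; boundaries
    are closed on both ends.  Invariant to the ordering of loci and models.
    """
    out: dict[str, dict[str, dict[str, int]]] = {l.locus_id: {} for l in loci}
    for model in models:
        for step in model.steps:
            if step.esnp_id not in variant_positions:
                continue
            chrom, pos = variant_positions[step.esnp_id]
            kind = "primary" if step.order == 1 else "conditional"
            for locus in loci:
                if locus.contains(chrom, pos):
                    gene_counts = out[locus.locus_id].setdefault(
                        model.gene_id, {"primary": 0, "conditional": 0}
                    )
                    gene_counts[kind] += 1
    return out


def tss_distance(
    models: Sequence[EqtlModel],
    annotation: dict[str, tuple[str, int, int, str]],
    variant_positions: dict[str, tuple[str, int]],
) -> tuple[list[tuple[str, int, str, int]], dict[int, float]]:
    """Absolute eSNP-to-TSS distances and the per-order medians.

    ``annotation`` maps gene id → (chrom, start, end, strand); the TSS is the
    interval start on the + strand and the end on the − strand.  Genes absent
    from the annotation are excluded with a log message.  Returns
    ``(rows, median_by_order)`` where rows are
    (gene_id, order, esnp_id, abs_distance_bp).
    """
    rows: list[tuple[str, int, str, int]] = []
    for model in models:
        ann = annotation.get(model.gene_id)
        if ann is None:
            logger.info("gene %s missing from annotation; excluded", model.gene_id)
            continue
        _, start, end, strand = ann
        tss = start if strand == "+" else end
        for step in model.steps:
            if step.esnp_id not in variant_positions:
                continue
            _, pos = variant_positions[step.esnp_id]
            rows.append((model.gene_id, step.order, step.esnp_id, abs(pos - tss)))
    medians: dict[int, float] = {}
    for order in sorted({r[1] for r in rows}):
        medians[order] = float(np.median([r[3] for r in rows if r[1] == order]))
    return rows, medians
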