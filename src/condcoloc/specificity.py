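"""Tau expression-specificity across tissues, cell types or developmental
periods.

Raw (nonnegative) expression is first summarized per context as
log2(stat + 1), where stat is the median across samples for tissue and
developmental-period panels or the mean for single-cell panels.  Tau for a
gene with summarized profile x over n contexts is

    tau = sum_i (1 - x_i / max(x)) / (n - 1)

giving 0 for a perfectly uniform profile and 1 for expression confined to a
single context.  Tau is invariant to rescaling the summarized profile.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ContextProfile:
    """Per-context summarized (log-scale, nonnegative) expression for one gene."""

    gene_id: str
    contexts: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.contexts) < 2:
            raise ValueError("Tau needs at least two contexts")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("summarized values must be finite and nonnegative")


def summarize_contexts(
    expr: pd.DataFrame,
    context_of: dict[str, str] | pd.Series,
    stat: str = "median",
    drop_missing: bool = True,
) -> list[ContextProfile]:
    """Summarize raw expression per context as log2(stat + 1).

    ``expr`` is genes × samples with nonnegative raw values (counts, CPM,
    FPKM — not residualized expression, which can be negative and is
    rejected).  ``context_of`` maps each sample column to its context label.
    ``stat`` is ``"median"`` (tissue/developmental convention) or ``"mean"``
    (single-cell convention).  With ``drop_missing`` genes that are entirely
    NaN in a context lose that context from their profile rather than it
    being zero-filled.
    """
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    if (expr.to_numpy(dtype=float, na_value=0.0) < 0).any():
        raise ValueError("negative raw expression: Tau requires nonnegative abundance")
    contexts = pd.Series(context_of)
    grouped = expr.T.groupby(contexts)
    summarized = grouped.median().T if stat == "median" else grouped.mean().T
    summarized = np.log2(summarized + 1.0)
    profiles = []
    for gene_id, row in summarized.iterrows():
        vals = row
        if drop_missing:
            vals = vals.dropna()
        if len(vals) < 2:
            logger.info("gene %s: fewer than two contexts after filtering", gene_id)
            continue
        profiles.append(ContextProfile(str(gene_id), list(vals.index), vals.to_numpy()))
    return profiles


def tau(profile: ContextProfile) -> float:
    """Specificity in [0, 1]; NaN (with a warning) for an all-zero profile."""
    x = profile.values
    xmax = x.max()
    if xmax <= 0:
        logger.warning("gene %s: all-zero profile, Tau undefined", profile.gene_id)
        return math.nan
    xhat = x / xmax
    return float((1.0 - xhat).sum() / (len(x) - 1))
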