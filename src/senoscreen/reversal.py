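"""DEG-intersection reversal analysis.

Given two DEG tables from the same gene universe — e.g. control vs
drug-induced senescence (CVSD) and senescent vs compound-treated (DVSO) —
this module intersects their passing gene sets, classifies each shared
gene as *reversed* when its fold changes disagree in sign (up under
senescence induction and down under treatment, or vice versa), and
summarizes the fraction reversed. The per-gene table, ordered by the
first contrast's fold change, is heatmap-ready.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["ReversalSummary", "intersect_degs", "classify_reversal"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReversalSummary:
    """Intersection and per-gene reversal status of two DEG contrasts.

    ``genes`` has one row per shared passing gene with columns ``gene``,
    ``log2fc_a``, ``log2fc_b`` and (after classification) ``reversed``.
    ``reversal_fraction`` is NaN until classified, and stays NaN when the
    intersection is empty.
    """

    n_a: int
    n_b: int
    n_shared: int
    genes: pd.DataFrame
    reversal_fraction: float = math.nan

    def __post_init__(self) -> None:
        if self.n_shared > min(self.n_a, self.n_b):
            raise ValueError("n_shared cannot exceed either pass-set size")


def intersect_degs(degs_a: pd.DataFrame, degs_b: pd.DataFrame) -> ReversalSummary:
    """Intersect the passing genes of two DEG tables.

    Both tables must come from :func:`~senoscreen.connectivity.call_degs`
    (or match its schema) over the same gene universe. The shared table is
    ordered by ``log2fc_a`` descending so it can be written straight into a
    heatmap.
    """
    pass_a = degs_a.index[degs_a["passes"]]
    pass_b = degs_b.index[degs_b["passes"]]
    shared = pass_a.intersection(pass_b)
    genes = pd.DataFrame(
        {
            "gene": shared,
            "log2fc_a": degs_a.loc[shared, "log2fc"].to_numpy(),
            "log2fc_b": degs_b.loc[shared, "log2fc"].to_numpy(),
        }
    ).sort_values("log2fc_a", ascending=False, kind="mergesort").reset_index(drop=True)
    return ReversalSummary(
        n_a=len(pass_a), n_b=len(pass_b), n_shared=len(shared), genes=genes
    )


def classify_reversal(
    summary: ReversalSummary, require_magnitude: float | None = None
) -> ReversalSummary:
    """Flag each shared gene as reversed and compute the reversed fraction.

    A gene is reversed iff its two fold changes disagree in sign. A zero
    fold change on a shared gene counts as not reversed (logged). The
    optional ``require_magnitude`` additionally demands
    ``|log2fc| > require_magnitude`` in *both* contrasts — off by default
    since passing genes already clear the fold-change gate.
    """
    genes = summary.genes.copy()
    a = genes["log2fc_a"].to_numpy()
    b = genes["log2fc_b"].to_numpy()
    zero = (a == 0) | (b == 0)
    if zero.any():
        logger.warning("%d shared gene(s) with zero fold change: not reversed", zero.sum())
    rev = (np.sign(a) != np.sign(b)) & ~zero
    if require_magnitude is not None:
        rev &= (np.abs(a) > require_magnitude) & (np.abs(b) > require_magnitude)
    genes["reversed"] = rev
    fraction = float(rev.mean()) if len(genes) else math.nan
    return replace(summary, genes=genes, reversal_fraction=fraction)
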