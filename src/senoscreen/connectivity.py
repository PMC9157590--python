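"""Signature construction and KS-based connectivity (anti-aging) scoring.

The screen mirrors the classic Connectivity Map construction: an aging
signature (up/down DEG sets from an old-vs-young contrast) is matched
against each compound's ranked differential profile with the unweighted
two-sided Kolmogorov–Smirnov enrichment statistic, and the combined score
is signed so that *positive = the compound reverses the signature*
(signature-up genes pushed toward the bottom of the profile and
signature-down genes toward the top). A permutation null over random
same-size tag sets turns the ranking into an inferential one.

DEG calling uses a Welch (unequal-variance) t-test with the double
threshold |linear fold change| > 1.20 and p < 0.05; Benjamini–Hochberg
q-values are emitted for reference but do not gate the pass flag.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ConnectivityResult, ExpressionMatrix, GeneSignature, RankedProfile

__all__ = [
    "FOLD_CHANGE_THRESHOLD",
    "P_THRESHOLD",
    "call_degs",
    "signature_from_degs",
    "ks_enrichment",
    "antiaging_score",
    "permutation_pvalues",
    "rank_compounds",
    "screen",
]

logger = logging.getLogger(__name__)

#: linear fold-change gate for DEG calling (pass iff |linear FC| > 1.20)
FOLD_CHANGE_THRESHOLD = 1.20
#: raw p-value gate for DEG calling
P_THRESHOLD = 0.05
#: minimum signature/profile overlap required per side for scoring
DEFAULT_MIN_OVERLAP = 3


# ---------------------------------------------------------------------------
# DEG calling and signature construction
# ---------------------------------------------------------------------------

def call_degs(matrix: ExpressionMatrix, group_a: str, group_b: str) -> pd.DataFrame:
    """Call differentially expressed genes between two groups.

    ``log2fc`` is mean(group_b) - mean(group_a) on the log2 scale (so for an
    aging contrast pass young as ``group_a`` and old as ``group_b``).
    P-values come from a two-sided Welch t-test per gene; a gene passes iff
    ``|linear FC| > 1.20`` and ``p < 0.05``. Genes with zero variance in
    both groups and equal means get p = 1 by convention.

    Returns a DataFrame indexed by gene with columns ``log2fc``,
    ``p_value``, ``q_value`` (Benjamini–Hochberg), ``direction`` and
    ``passes``.
    """
    a_cols = matrix.samples_in(group_a)
    b_cols = matrix.samples_in(group_b)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError(
            f"need >=2 samples per group for a variance estimate; got "
            f"{len(a_cols)} in {group_a!r}, {len(b_cols)} in {group_b!r}"
        )
    a = matrix.values[a_cols].to_numpy(float)
    b = matrix.values[b_cols].to_numpy(float)
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    # degenerate genes: zero variance in both groups
    degenerate = np.isnan(p)
    p = np.where(degenerate & (log2fc == 0), 1.0, p)
    p = np.where(degenerate & (log2fc != 0), 0.0, p)
    q = stats.false_discovery_control(p)
    passes = (np.abs(log2fc) > np.log2(FOLD_CHANGE_THRESHOLD)) & (p < P_THRESHOLD)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "passes": passes,
        },
        index=matrix.gene_ids,
    )


def signature_from_degs(
    degs: pd.DataFrame, max_per_side: int = 150, name: str = "signature"
) -> GeneSignature:
    """Build an up/down signature from the passing genes of a DEG table.

    If a side holds more than ``max_per_side`` genes, the smallest-p genes
    are kept, ties broken by gene id so the selection is deterministic.
    Raises if either side is empty after filtering.
    """
    if degs.empty:
        raise ValueError("DEG table is empty")
    sides: dict[str, frozenset[str]] = {}
    for direction in ("up", "down"):
        side = degs[(degs["passes"]) & (degs["direction"] == direction)]
        if side.empty:
            raise ValueError(
                f"no passing {direction}-regulated genes; cannot build a signature side"
            )
        # smallest p first, gene id breaks ties deterministically
        order = sorted(side.index, key=lambda g: (side.at[g, "p_value"], g))
        sides[direction] = frozenset(order[:max_per_side])
    return GeneSignature(up=sides["up"], down=sides["down"], name=name)


# ---------------------------------------------------------------------------
# KS enrichment and the anti-aging score
# ---------------------------------------------------------------------------

def _ks_from_positions(positions: np.ndarray, n: int) -> float:
    """Unweighted two-sided KS enrichment from sorted 1-based tag positions.

    With t tags at positions pos(1) < ... < pos(t) in a list of N genes:
    a = max_j [ j/t - pos(j)/N ], b = max_j [ pos(j)/N - (j-1)/t ];
    returns a if a >= b else -b.
    """
    t = len(positions)
    j = np.arange(1, t + 1, dtype=np.int64)
    pos = positions.astype(np.int64)
    # integer numerators over the common denominator t*n keep the a-vs-b
    # comparison (and the a >= b tie) exact
    a_num = int(np.max(j * n - pos * t))
    b_num = int(np.max(pos * t - (j - 1) * n))
    denom = t * n
    return a_num / denom if a_num >= b_num else -b_num / denom


def ks_enrichment(
    profile: RankedProfile,
    tags: Iterable[str],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> float:
    """Kolmogorov–Smirnov enrichment of a tag set in a ranked profile.

    Positive scores mean the tags concentrate near the top (most
    up-regulated end) of the profile, negative near the bottom; the value
    is the maximum deviation of the tag-rank running sum, in [-1, 1].
    Tags absent from the profile are dropped with a warning; fewer than
    ``min_overlap`` matched tags is an error.
    """
    tag_set = set(tags)
    index = {g: i + 1 for i, g in enumerate(profile.genes)}  # 1-based ranks
    matched = sorted(index[g] for g in tag_set if g in index)
    dropped = len(tag_set) - len(matched)
    if dropped:
        logger.warning(
            "profile %s: %d tag gene(s) absent from profile, dropped",
            profile.compound_id,
            dropped,
        )
    if len(matched) < min_overlap:
        raise ValueError(
            f"profile {profile.compound_id}: only {len(matched)} tag gene(s) overlap "
            f"the profile; need at least {min_overlap}"
        )
    return _ks_from_positions(np.asarray(matched), len(profile))


def antiaging_score(
    profile: RankedProfile,
    sig: GeneSignature,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> ConnectivityResult:
    """Two-sided connectivity score of a profile against a signature.

    ``es_up``/``es_down`` are the KS enrichments of the signature's up and
    down sets in the profile. When they agree in sign the profile is not
    coherently connected and the score is 0; otherwise
    ``raw = es_up - es_down`` and ``antiaging_score = -raw/2``, so +1 means
    perfect reversal (signature-down genes at the very top, signature-up
    genes at the very bottom) and -1 perfect mimicry.
    """
    if not sig.up or not sig.down:
        raise ValueError("signature must have nonempty up and down sets for scoring")
    es_up = ks_enrichment(profile, sig.up, min_overlap)
    es_down = ks_enrichment(profile, sig.down, min_overlap)
    if np.sign(es_up) == np.sign(es_down):
        raw = 0.0
    else:
        raw = es_up - es_down
    return ConnectivityResult(
        compound_id=profile.compound_id,
        es_up=es_up,
        es_down=es_down,
        raw_score=raw,
        antiaging_score=-raw / 2.0,
    )


# ---------------------------------------------------------------------------
# Permutation null and ranking
# ---------------------------------------------------------------------------

def _null_scores(
    n_genes: int, n_up: int, n_down: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Anti-aging scores of random disjoint same-size tag-set pairs.

    For the unweighted KS statistic only tag *positions* matter, so the
    null depends on the profile solely through (N, |up|, |down|) and one
    sample serves every profile over the same gene universe.
    """
    out = np.empty(n_perm)
    for i in range(n_perm):
        pos = rng.choice(n_genes, size=n_up + n_down, replace=False) + 1
        es_up = _ks_from_positions(np.sort(pos[:n_up]), n_genes)
        es_down = _ks_from_positions(np.sort(pos[n_up:]), n_genes)
        raw = 0.0 if np.sign(es_up) == np.sign(es_down) else es_up - es_down
        out[i] = -raw / 2.0
    return out


def permutation_pvalues(
    results: Sequence[ConnectivityResult],
    profiles: Sequence[RankedProfile],
    sig: GeneSignature,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[ConnectivityResult]:
    """Attach two-sided permutation p-values to connectivity results.

    For each compound, ``perm_p = (1 + #{null |score| >= |observed|}) /
    (1 + n_perm)`` where the null redraws random disjoint tag-set pairs of
    the same sizes on the profile's gene universe (add-one correction keeps
    p > 0).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    by_id = {p.compound_id: p for p in profiles}
    rng = np.random.default_rng(seed)
    null_cache: dict[tuple[int, int, int], np.ndarray] = {}
    out = []
    for res in results:
        profile = by_id[res.compound_id]
        index = set(profile.genes)
        key = (
            len(profile),
            len([g for g in sig.up if g in index]),
            len([g for g in sig.down if g in index]),
        )
        if key not in null_cache:
            null_cache[key] = _null_scores(*key, n_perm=n_perm, rng=rng)
        null = null_cache[key]
        perm_p = (1 + int(np.sum(np.abs(null) >= abs(res.antiaging_score)))) / (1 + n_perm)
        out.append(
            ConnectivityResult(
                compound_id=res.compound_id,
                es_up=res.es_up,
                es_down=res.es_down,
                raw_score=res.raw_score,
                antiaging_score=res.antiaging_score,
                perm_p=perm_p,
                rank=res.rank,
            )
        )
    return out


def rank_compounds(results: Sequence[ConnectivityResult]) -> list[ConnectivityResult]:
    """Rank compounds: 1 = largest anti-aging score.

    Ties broken by smaller permutation p-value, then compound id, so the
    ranking is a deterministic permutation of 1..n.
    """
    def sort_key(r: ConnectivityResult):
        p = r.perm_p if r.perm_p is not None else 1.0
        return (-r.antiaging_score, p, r.compound_id)

    ordered = sorted(results, key=sort_key)
    return [
        ConnectivityResult(
            compound_id=r.compound_id,
            es_up=r.es_up,
            es_down=r.es_down,
            raw_score=r.raw_score,
            antiaging_score=r.antiaging_score,
            perm_p=r.perm_p,
            rank=i + 1,
        )
        for i, r in enumerate(ordered)
    ]


def screen(
    profiles: Sequence[RankedProfile],
    sig: GeneSignature,
    n_perm: int = 1000,
    seed: int = 0,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """Score, test and rank a whole compendium against a signature.

    Convenience wrapper chaining :func:`antiaging_score`,
    :func:`permutation_pvalues` and :func:`rank_compounds`; returns a tidy
    DataFrame ordered by rank.
    """
    results = [antiaging_score(p, sig, min_overlap) for p in profiles]
    results = permutation_pvalues(results, profiles, sig, n_perm=n_perm, seed=seed)
    results = rank_compounds(results)
    return pd.DataFrame(
        [
            {
                "rank": r.rank,
                "compound_id": r.compound_id,
                "antiaging_score": r.antiaging_score,
                "es_up": r.es_up,
                "es_down": r.es_down,
                "raw_score": r.raw_score,
                "perm_p": r.perm_p,
            }
            for r in results
        ]
    ).set_index("rank")
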