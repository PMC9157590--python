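"""Core data containers shared across the pipeline.

Expression data lives in a genes x samples :class:`pandas.DataFrame` wrapped
with its sample->group design; gene signatures are disjoint up/down sets;
compound profiles are full-universe ranked gene lists; yeast mother-cell
histories are ordered budding timelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "RankedProfile",
    "ConnectivityResult",
    "BuddingTimeline",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2-scale expression values (genes x samples) with a group design.

    Parameters
    ----------
    values
        Numeric DataFrame indexed by unique gene ids, columns are sample ids.
    design
        Series mapping every sample id (column of ``values``) to a group label.
    """

    values: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing[:5]}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def samples_in(self, group: str) -> list[str]:
        """Sample ids belonging to ``group``, in column order."""
        members = set(self.design.index[self.design == group])
        return [s for s in self.values.columns if s in members]


@dataclass(frozen=True)
class GeneSignature:
    """Disjoint up/down gene sets describing a transcriptional state.

    For an aging signature, ``up`` holds genes elevated in the aged state and
    ``down`` genes reduced in it.
    """

    up: frozenset[str]
    down: frozenset[str]
    name: str = "signature"

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        overlap = self.up & self.down
        if overlap:
            raise ValueError(
                f"up/down sets must be disjoint; shared genes: {sorted(overlap)[:5]}"
            )

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down


@dataclass(frozen=True)
class RankedProfile:
    """A compound's differential expression profile as a ranked gene list.

    Genes are ordered most up-regulated first, strictly by descending score
    with lexicographic gene-id tie-break, so every downstream rank statistic
    is reproducible bit-for-bit.
    """

    compound_id: str
    genes: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError(f"profile {self.compound_id}: duplicate genes")
        if len(self.genes) != len(self.scores):
            raise ValueError(f"profile {self.compound_id}: genes/scores length mismatch")
        for i in range(len(self.scores) - 1):
            s0, s1 = self.scores[i], self.scores[i + 1]
            if s0 < s1 or (s0 == s1 and self.genes[i] > self.genes[i + 1]):
                raise ValueError(
                    f"profile {self.compound_id}: not sorted by (descending score, gene id)"
                )

    @classmethod
    def from_scores(cls, compound_id: str, scores: Mapping[str, float]) -> "RankedProfile":
        """Build a profile from an unordered gene -> score mapping."""
        items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(
            compound_id=compound_id,
            genes=tuple(g for g, _ in items),
            scores=tuple(float(s) for _, s in items),
        )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class ConnectivityResult:
    """Connectivity scores for one compound against a signature.

    ``antiaging_score`` is positive when the compound's profile reverses the
    signature (signature-up genes pushed down and vice versa), zero when the
    two one-sided enrichment scores agree in sign.
    """

    compound_id: str
    es_up: float
    es_down: float
    raw_score: float
    antiaging_score: float
    perm_p: float | None = None
    rank: int | None = None


@dataclass(frozen=True)
class BuddingTimeline:
    """One yeast mother cell's ordered budding events.

    ``bud_times`` are hours from load; strictly increasing. ``fate`` is
    ``"death"`` if the mother was observed to die, ``"censored"`` if
    observation ended first.
    """

    mother_id: str
    bud_times: tuple[float, ...]
    fate: str = "death"
    condition: str = "control"

    def __post_init__(self) -> None:
        if self.fate not in ("death", "censored"):
            raise ValueError(f"fate must be 'death' or 'censored', got {self.fate!r}")
        times = np.asarray(self.bud_times, dtype=float)
        if times.size and not np.all(np.diff(times) > 0):
            raise ValueError(f"mother {self.mother_id}: bud times not strictly increasing")
        object.__setattr__(self, "bud_times", tuple(float(t) for t in times))

    @property
    def divisions(self) -> int:
        """Replicative lifespan: number of budding events recorded."""
        return len(self.bud_times)
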