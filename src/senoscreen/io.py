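"""Readers and writers for the pipeline's interchange formats.

Expression matrices travel as GCT 1.2 (with plain TSV as fallback), gene
signatures as GMT (paired ``<stem>_UP`` / ``<stem>_DN`` records merge into
one signature), lifespan cohorts and budding timelines as documented CSV
schemas, and compound profiles as two-column TSV (gene, score). All
readers reject malformed input with specific errors rather than coercing.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .datatypes import BuddingTimeline, ExpressionMatrix, GeneSignature, RankedProfile
from .survival import COHORT_COLUMNS

__all__ = [
    "read_gct",
    "write_gct",
    "read_tsv_matrix",
    "read_gmt",
    "write_gmt",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_timelines_csv",
    "write_timelines_csv",
    "read_profile_tsv",
    "write_profile_tsv",
]

logger = logging.getLogger(__name__)

TIMELINE_COLUMNS = ["mother_id", "bud_time_h", "fate", "condition"]

_UP_SUFFIX = re.compile(r"[._-](UP)$", re.IGNORECASE)
_DN_SUFFIX = re.compile(r"[._-](DN|DOWN)$", re.IGNORECASE)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_gct(path, design: Mapping[str, str] | pd.Series | None = None) -> ExpressionMatrix:
    """Read a GCT 1.2 expression matrix.

    The file must start with ``#1.2`` and a ``n_genes<TAB>n_samples``
    dimension line; the dimension line must match the parsed matrix and
    gene ids must be unique. ``design`` maps samples to groups; if omitted,
    groups are inferred from sample names of the form ``<group>_<i>``.
    """
    path = Path(path)
    with path.open() as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ValueError(f"{path}: malformed GCT dimension line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        table = pd.read_csv(fh, sep="\t")
    if table.shape[0] != n_genes:
        raise ValueError(
            f"{path}: dimension line says {n_genes} genes but {table.shape[0]} rows present"
        )
    if table.shape[1] != n_samples + 2:
        raise ValueError(
            f"{path}: dimension line says {n_samples} samples but "
            f"{table.shape[1] - 2} data columns present"
        )
    name_col = table.columns[0]
    if table[name_col].duplicated().any():
        dups = table[name_col][table[name_col].duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids: {dups[:5]}")
    values = table.set_index(name_col).iloc[:, 1:]  # drop Description column
    values.index.name = "gene"
    return ExpressionMatrix(values=values, design=_coerce_design(values.columns, design))


def write_gct(matrix: ExpressionMatrix, path) -> None:
    """Write an expression matrix as GCT 1.2."""
    path = Path(path)
    values = matrix.values
    with path.open("w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{values.shape[0]}\t{values.shape[1]}\n")
        fh.write("NAME\tDescription\t" + "\t".join(values.columns) + "\n")
        for gene, row in values.iterrows():
            fh.write(gene + "\tna\t" + "\t".join(repr(v) for v in row) + "\n")


def read_tsv_matrix(path, design=None) -> ExpressionMatrix:
    """Read a plain TSV matrix (first column gene ids, one column per sample)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    table.index.name = "gene"
    return ExpressionMatrix(values=table, design=_coerce_design(table.columns, design))


def _coerce_design(samples, design) -> pd.Series:
    if design is None:
        groups = [s.rsplit("_", 1)[0] for s in samples]
        return pd.Series(groups, index=list(samples), name="group")
    if isinstance(design, Mapping):
        design = pd.Series(design)
    return design.rename("group")


# ---------------------------------------------------------------------------
# gene signatures (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, GeneSignature]:
    """Read GMT gene sets, merging paired UP/DN records into signatures.

    Records named ``<stem>_UP`` and ``<stem>_DN`` (or ``.UP``/``.DOWN``
    variants) merge into one :class:`GeneSignature` keyed by the stem; an
    unpaired record becomes a signature with only that side populated.
    Duplicate genes within a record are deduplicated with a warning; a
    record with no genes, or an up/down overlap after merging, is an error.
    """
    path = Path(path)
    sides: dict[str, dict[str, frozenset[str]]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT record with no genes")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: GMT record {name!r} has no genes")
            if len(genes) != len(set(genes)):
                logger.warning("%s:%d: duplicate genes in %r deduplicated", path, lineno, name)
            gene_set = frozenset(genes)
            if _UP_SUFFIX.search(name):
                stem, side = _UP_SUFFIX.sub("", name), "up"
            elif _DN_SUFFIX.search(name):
                stem, side = _DN_SUFFIX.sub("", name), "down"
            else:
                stem, side = name, "up"
            entry = sides.setdefault(stem, {})
            if side in entry:
                raise ValueError(f"{path}: duplicate {side}-record for signature {stem!r}")
            entry[side] = gene_set
    return {
        stem: GeneSignature(
            up=entry.get("up", frozenset()),
            down=entry.get("down", frozenset()),
            name=stem,
        )
        for stem, entry in sides.items()
    }


def write_gmt(signatures: Iterable[GeneSignature] | GeneSignature, path) -> None:
    """Write signatures as paired ``<name>_UP`` / ``<name>_DN`` GMT records."""
    if isinstance(signatures, GeneSignature):
        signatures = [signatures]
    with Path(path).open("w") as fh:
        for sig in signatures:
            if sig.up:
                fh.write("\t".join([f"{sig.name}_UP", "na", *sorted(sig.up)]) + "\n")
            if sig.down:
                fh.write("\t".join([f"{sig.name}_DN", "na", *sorted(sig.down)]) + "\n")


# ---------------------------------------------------------------------------
# cohorts, timelines, profiles
# ---------------------------------------------------------------------------

def read_cohort_csv(path) -> pd.DataFrame:
    """Read a lifespan cohort CSV (subject_id, duration_days, event, group)."""
    table = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: cohort CSV missing columns {missing}")
    if (table["duration_days"] <= 0).any():
        raise ValueError(f"{path}: nonpositive durations")
    if not table["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event column must be 0/1")
    return table


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def read_timelines_csv(path) -> list[BuddingTimeline]:
    """Read budding timelines from long-format CSV.

    Columns ``mother_id, bud_time_h, fate, condition``; one row per budding
    event, fate/condition constant within a mother.
    """
    table = pd.read_csv(path)
    missing = [c for c in TIMELINE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: timeline CSV missing columns {missing}")
    timelines = []
    for (mother, fate, condition), sub in table.groupby(
        ["mother_id", "fate", "condition"], sort=True
    ):
        times = tuple(sub["bud_time_h"].sort_values())
        timelines.append(
            BuddingTimeline(
                mother_id=str(mother), bud_times=times, fate=fate, condition=condition
            )
        )
    return timelines


def write_timelines_csv(timelines: Sequence[BuddingTimeline], path) -> None:
    rows = [
        {
            "mother_id": tl.mother_id,
            "bud_time_h": t,
            "fate": tl.fate,
            "condition": tl.condition,
        }
        for tl in timelines
        for t in tl.bud_times
    ]
    pd.DataFrame(rows, columns=TIMELINE_COLUMNS).to_csv(path, index=False)


def read_profile_tsv(path, compound_id: str | None = None) -> RankedProfile:
    """Read one compound profile from two-column TSV (gene, score)."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise ValueError(f"{path}: profile TSV needs two columns (gene, score)")
    gene_col, score_col = table.columns[:2]
    if table[gene_col].duplicated().any():
        raise ValueError(f"{path}: duplicate genes in profile")
    scores = dict(zip(table[gene_col].astype(str), table[score_col].astype(float)))
    return RankedProfile.from_scores(compound_id or path.stem, scores)


def write_profile_tsv(profile: RankedProfile, path) -> None:
    pd.DataFrame({"gene": profile.genes, "score": profile.scores}).to_csv(
        path, sep="\t", index=False
    )
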