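"""Reference resources consumed by the enrichment analysis.

Three tables drive CAVE: a repository frequency map giving, per genomic
position, how many tumors in a large cancer-sequencing repository
(GENIE/TCGA-style export) carry a mutation there; a validated
cancer-position set used as a truth set for enrichment; and a
deleterious/non-deleterious label table for missense variants produced
by an upstream functional classifier.  Positions are matched literally
as (chrom, pos) — genome-build reconciliation is out of scope and must
be done upstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Position = tuple[str, int]


@dataclass
class FrequencyMap:
    """(chrom, pos) -> repository recurrence count.

    Positions absent from the map have an implicit count of 0; the
    per-position score used downstream is ``log2(count + 1)`` (counts
    are kept raw internally because rank tests are invariant to the
    monotone transform — the log scale is for display).
    """

    counts: dict[Position, int]
    source_name: str = "repository"

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.counts.items() if v < 0}
        if bad:
            raise ValueError(f"negative repository counts: {list(bad)[:3]}")

    def count(self, chrom: str, pos: int) -> int:
        return self.counts.get((chrom, int(pos)), 0)

    def score(self, chrom: str, pos: int) -> float:
        return math.log2(self.count(chrom, pos) + 1)

    def counts_for(self, positions: Iterable[Position]) -> np.ndarray:
        return np.array([self.counts.get((c, int(p)), 0) for c, p in positions], dtype=float)

    def scores_for(self, positions: Iterable[Position]) -> np.ndarray:
        return np.log2(self.counts_for(positions) + 1.0)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class PositionSet:
    """A named, duplicate-free set of genomic positions."""

    positions: frozenset[Position]
    name: str = "positions"

    def __contains__(self, item: Position) -> bool:
        return item in self.positions

    def __len__(self) -> int:
        return len(self.positions)

    def __iter__(self):
        return iter(sorted(self.positions))


VALID_LABELS = frozenset({"D", "ND"})


@dataclass
class LabelTable:
    """(chrom, pos, ref, alt) -> 'D' (deleterious) or 'ND'."""

    labels: dict[tuple[str, int, str, str], str]

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values() if v not in VALID_LABELS}
        if bad:
            raise ValueError(f"labels must be in {sorted(VALID_LABELS)}, got {sorted(bad)}")

    def get(self, chrom: str, pos: int, ref: str, alt: str) -> str | None:
        return self.labels.get((chrom, int(pos), ref, alt))

    def __len__(self) -> int:
        return len(self.labels)


def load_frequency_map(
    table_path: str | Path,
    chrom_col: str = "chrom",
    pos_col: str = "pos",
    aggregate: bool | None = None,
    source_name: str | None = None,
) -> FrequencyMap:
    """Load a repository export into a frequency map.

    Two dialects are supported: one row per reported tumor variant
    (``aggregate=True`` groups rows and counts them) or pre-aggregated
    rows carrying a ``count`` column (``aggregate=False``).  The default
    (``None``) auto-detects: a ``count`` column means pre-aggregated.
    """
    df = pd.read_csv(table_path, sep="\t", comment="#", dtype={chrom_col: str})
    for col in (chrom_col, pos_col):
        if col not in df.columns:
            raise ValueError(f"{table_path}: missing column {col!r}")
    pos_numeric = pd.to_numeric(df[pos_col], errors="coerce")
    bad = df.index[pos_numeric.isna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(f"{table_path}: unparseable position at line {bad[0] + 2}")
    df[pos_col] = pos_numeric.astype(int)

    if aggregate is None:
        aggregate = "count" not in df.columns
    if aggregate:
        grouped = df.groupby([chrom_col, pos_col], sort=True).size()
    else:
        if "count" not in df.columns:
            raise ValueError(f"{table_path}: pre-aggregated mode needs a 'count' column")
        grouped = df.groupby([chrom_col, pos_col], sort=True)["count"].sum()
    counts = {(str(c), int(p)): int(n) for (c, p), n in grouped.items()}
    return FrequencyMap(counts=counts, source_name=source_name or str(Path(table_path).stem))


def write_frequency_map(fmap: FrequencyMap, path: str | Path) -> None:
    rows = sorted(fmap.counts.items())
    pd.DataFrame(
        [(c, p, n) for (c, p), n in rows], columns=["chrom", "pos", "count"]
    ).to_csv(path, sep="\t", index=False)


def load_position_set(table_path: str | Path, name: str | None = None) -> PositionSet:
    """Load a chrom/pos TSV; duplicate rows are collapsed with a warning."""
    df = pd.read_csv(table_path, sep="\t", comment="#", dtype={"chrom": str})
    for col in ("chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"{table_path}: missing column {col!r}")
    pairs = list(zip(df["chrom"].astype(str), df["pos"].astype(int)))
    uniq = frozenset(pairs)
    if len(uniq) < len(pairs):
        logger.warning(
            "%s: collapsed %d duplicate position rows", table_path, len(pairs) - len(uniq)
        )
    return PositionSet(positions=uniq, name=name or str(Path(table_path).stem))


def write_position_set(pset: PositionSet, path: str | Path) -> None:
    pd.DataFrame(sorted(pset.positions), columns=["chrom", "pos"]).to_csv(
        path, sep="\t", index=False
    )


def load_label_table(table_path: str | Path) -> LabelTable:
    """Load a chrom/pos/ref/alt/label TSV; labels must be D or ND."""
    df = pd.read_csv(table_path, sep="\t", comment="#", dtype={"chrom": str})
    needed = ["chrom", "pos", "ref", "alt", "label"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{table_path}: missing columns {missing}")
    labels: dict[tuple[str, int, str, str], str] = {}
    n_dup = 0
    for r in df.itertuples(index=False):
        lab = str(r.label)
        if lab not in VALID_LABELS:
            raise ValueError(
                f"{table_path}: invalid label {lab!r} at {r.chrom}:{r.pos} {r.ref}>{r.alt}"
            )
        key = (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        if key in labels:
            n_dup += 1
            if labels[key] != lab:
                raise ValueError(f"{table_path}: conflicting labels for {key}")
            continue
        labels[key] = lab
    if n_dup:
        logger.warning("%s: collapsed %d duplicate label rows", table_path, n_dup)
    return LabelTable(labels=labels)


def write_label_table(table: LabelTable, path: str | Path) -> None:
    rows = sorted(table.labels.items())
    pd.DataFrame(
        [(c, p, r, a, lab) for (c, p, r, a), lab in rows],
        columns=["chrom", "pos", "ref", "alt", "label"],
    ).to_csv(path, sep="\t", index=False)
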