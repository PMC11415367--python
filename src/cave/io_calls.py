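"""Cohort variant-call ingestion and per-position summaries.

Deep amplicon sequencing run with a permissive caller floor (0.05% VAF)
reports on the order of a thousand calls per sample, most of which are
polymerase or sequencing noise.  This module reads such calls from VCF
files (or a flat TSV interchange format), restricts them to
single-nucleotide variants with a usable allele frequency, and builds
the per-genomic-position table (max VAF across the cohort) on which the
threshold sweep operates.  Positions — not (position, alt) pairs — are
the unit of grouping downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_BASE_SET = frozenset(BASES)

#: the 12 raw substitution classes, lexicographic
SUBSTITUTION_CLASSES = tuple(
    f"{r}>{a}" for r in BASES for a in BASES if r != a
)

#: strand collapse onto the six pyrimidine-reference classes
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINE_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def collapse_class(subst: str) -> str:
    """Collapse a ref>alt class onto its pyrimidine-reference equivalent."""
    ref, alt = subst.split(">")
    if ref in ("A", "G"):
        return f"{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}"
    return subst


@dataclass(frozen=True)
class VariantCall:
    """One SNV call in one patient sample.

    ``pos`` follows the 1-based VCF convention; ``vaf`` is a fraction in
    [0, 1]; ``depth`` of 0 means unknown.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    depth: int = 0

    def __post_init__(self) -> None:
        if self.ref not in _BASE_SET or self.alt not in _BASE_SET:
            raise ValueError(
                f"ref/alt must be single bases in ACGT, got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1] at {self.chrom}:{self.pos}")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")

    @property
    def substitution(self) -> str:
        return f"{self.ref}>{self.alt}"


_CALL_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "vaf", "depth"]


@dataclass
class CohortCallSet:
    """All retained SNV calls of a cohort plus ingestion bookkeeping."""

    calls: list[VariantCall]
    caller_floor: float = 0.0005
    n_dropped_non_snv: int = 0
    n_dropped_below_floor: int = 0
    n_duplicates_collapsed: int = 0

    def __post_init__(self) -> None:
        bad = [c for c in self.calls if c.vaf < self.caller_floor]
        if bad:
            raise ValueError(
                f"{len(bad)} calls below the caller floor {self.caller_floor}"
            )

    def __len__(self) -> int:
        return len(self.calls)

    @property
    def samples(self) -> set[str]:
        return {c.sample_id for c in self.calls}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [(c.sample_id, c.chrom, c.pos, c.ref, c.alt, c.vaf, c.depth) for c in self.calls],
            columns=_CALL_COLUMNS,
        )
        return df.sort_values(
            ["sample_id", "chrom", "pos", "alt"], kind="mergesort"
        ).reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, caller_floor: float = 0.0005, **counts) -> "CohortCallSet":
        calls = [
            VariantCall(
                sample_id=str(r.sample_id),
                chrom=str(r.chrom),
                pos=int(r.pos),
                ref=str(r.ref),
                alt=str(r.alt),
                vaf=float(r.vaf),
                depth=int(getattr(r, "depth", 0) or 0),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(calls=calls, caller_floor=caller_floor, **counts)


def _collapse_duplicates(rows: list[VariantCall]) -> tuple[list[VariantCall], int]:
    """Keep the max-VAF call per (sample, chrom, pos, alt); count collapses."""
    best: dict[tuple, VariantCall] = {}
    n_dup = 0
    for c in rows:
        key = (c.sample_id, c.chrom, c.pos, c.alt)
        prev = best.get(key)
        if prev is None:
            best[key] = c
        else:
            n_dup += 1
            if c.vaf > prev.vaf:
                best[key] = c
    out = sorted(best.values(), key=lambda c: (c.sample_id, c.chrom, c.pos, c.alt))
    return out, n_dup


def _vaf_for_record(rec, sample_name, vaf_field: str, n_alts: int, path) -> list[float]:
    """Extract one VAF per alt allele from FORMAT (preferred) or INFO.

    Falls back to allele depths (AD) when the named field is absent.
    """
    val = None
    if sample_name is not None:
        fmt = rec.samples[sample_name]
        if vaf_field in fmt and fmt[vaf_field] is not None:
            val = fmt[vaf_field]
    if val is None and vaf_field in rec.info:
        val = rec.info[vaf_field]
    if val is not None:
        vals = list(val) if isinstance(val, (tuple, list)) else [val]
        if len(vals) == 1 and n_alts > 1:
            raise ValueError(
                f"field {vaf_field} has 1 value for {n_alts} alts at "
                f"{rec.chrom}:{rec.pos} in {path}"
            )
        return [float(v) for v in vals[:n_alts]]
    # derive from allele depths
    ad = None
    if sample_name is not None and "AD" in rec.samples[sample_name]:
        ad = rec.samples[sample_name]["AD"]
    if ad is not None and None not in ad:
        total = float(sum(ad))
        if total > 0:
            return [float(ad[i + 1]) / total for i in range(n_alts)]
    raise ValueError(
        f"no usable VAF: field {vaf_field!r} and AD both absent at "
        f"{rec.chrom}:{rec.pos} in {path}"
    )


def read_calls(
    vcf_paths: Sequence[str | Path],
    sample_ids: Sequence[str] | None = None,
    vaf_field: str = "AF",
    caller_floor: float = 0.0005,
) -> CohortCallSet:
    """Read per-patient VCFs into a cohort call set.

    Multi-allelic records are decomposed into one call per alt; non-SNV
    alleles (indels, MNVs, symbolic) are dropped and counted, as are
    calls below ``caller_floor``.  ``sample_ids``, when given, names the
    cohort sample for each file; otherwise the VCF sample column (or the
    file stem for site-only VCFs) is used.
    """
    import pysam

    if sample_ids is not None and len(sample_ids) != len(vcf_paths):
        raise ValueError("sample_ids must align with vcf_paths")

    kept: list[VariantCall] = []
    n_non_snv = 0
    n_floor = 0
    for i, path in enumerate(vcf_paths):
        try:
            vf = pysam.VariantFile(str(path))
        except Exception as exc:  # malformed header etc.
            raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
        vcf_samples = list(vf.header.samples)
        sample_col = vcf_samples[0] if vcf_samples else None
        sid = (
            sample_ids[i]
            if sample_ids is not None
            else (sample_col if sample_col is not None else Path(path).stem)
        )
        with vf:
            for rec in vf:
                alts = rec.alts or ()
                vafs = None
                for j, alt in enumerate(alts):
                    if (
                        len(rec.ref) != 1
                        or len(alt) != 1
                        or rec.ref not in _BASE_SET
                        or alt not in _BASE_SET
                    ):
                        n_non_snv += 1
                        continue
                    if vafs is None:
                        vafs = _vaf_for_record(rec, sample_col, vaf_field, len(alts), path)
                    vaf = vafs[j]
                    if vaf < caller_floor:
                        n_floor += 1
                        continue
                    kept.append(
                        VariantCall(
                            sample_id=sid,
                            chrom=str(rec.chrom),
                            pos=int(rec.pos),
                            ref=rec.ref,
                            alt=alt,
                            vaf=vaf,
                            depth=int(rec.info.get("DP", 0) or 0),
                        )
                    )
    kept, n_dup = _collapse_duplicates(kept)
    if n_dup:
        logger.warning("collapsed %d duplicate calls (same sample/position/alt)", n_dup)
    return CohortCallSet(
        calls=kept,
        caller_floor=caller_floor,
        n_dropped_non_snv=n_non_snv,
        n_dropped_below_floor=n_floor,
        n_duplicates_collapsed=n_dup,
    )


def read_calls_tsv(path: str | Path, caller_floor: float = 0.0005) -> CohortCallSet:
    """Read the flat TSV interchange format (see :func:`write_calls_tsv`)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"chrom": str, "sample_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in _CALL_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if "depth" not in df.columns:
        df["depth"] = 0
    below = df["vaf"] < caller_floor
    n_floor = int(below.sum())
    df = df.loc[~below]
    cs = CohortCallSet.from_frame(df, caller_floor=caller_floor)
    cs.n_dropped_below_floor = n_floor
    return cs


def write_calls_tsv(callset: CohortCallSet, path: str | Path) -> None:
    # default formatting is shortest-round-trip; the reader must use the
    # round_trip float parser for VAFs to survive exactly
    callset.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class CohortPositionTable:
    """Per-distinct-genomic-position cohort summary.

    One row per (chrom, pos) with the maximum VAF observed at that
    position across all samples, the number of samples contributing a
    call there, and the total call count.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        expected = ["chrom", "pos", "max_vaf", "n_samples_with_call", "n_calls"]
        if list(self.df.columns) != expected:
            raise ValueError(f"position table columns must be {expected}")

    def __len__(self) -> int:
        return len(self.df)

    def positions(self) -> set[tuple[str, int]]:
        return set(zip(self.df["chrom"], self.df["pos"]))

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CohortPositionTable":
        return cls(pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str}))


def build_position_table(callset: CohortCallSet) -> CohortPositionTable:
    """Aggregate a call set into its per-position table.

    Deterministically ordered by (chrom, pos); independent of the input
    call order and idempotent.
    """
    if len(callset) == 0:
        raise ValueError("cannot build a position table from an empty call set")
    df = callset.to_frame()
    agg = (
        df.groupby(["chrom", "pos"], sort=True)
        .agg(
            max_vaf=("vaf", "max"),
            n_samples_with_call=("sample_id", "nunique"),
            n_calls=("vaf", "size"),
        )
        .reset_index()
    )
    return CohortPositionTable(agg)


def mutational_spectrum(
    callset: CohortCallSet,
    vaf_bins: Sequence[tuple[float, float]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Substitution-class counts per VAF band.

    ``vaf_bins`` are half-open intervals (lo, hi].  Returns ``(raw,
    collapsed)``: raw has one row per bin and one column per 12-class
    substitution; collapsed folds purine-reference classes onto their
    pyrimidine-strand equivalents (so the Taq-signature AT>GC classes
    A>G and T>C both land in T>C).
    """
    for (lo1, hi1) in vaf_bins:
        if hi1 <= lo1:
            raise ValueError(f"bad bin ({lo1}, {hi1}]")
    for (lo1, hi1), (lo2, hi2) in zip(vaf_bins, vaf_bins[1:]):
        if lo2 < hi1:
            raise ValueError("vaf_bins must be non-overlapping and sorted")

    labels = [f"({lo:g},{hi:g}]" for lo, hi in vaf_bins]
    raw = pd.DataFrame(0, index=pd.Index(labels, name="vaf_bin"), columns=list(SUBSTITUTION_CLASSES))
    if len(callset):
        df = callset.to_frame()
        for label, (lo, hi) in zip(labels, vaf_bins):
            sel = df[(df["vaf"] > lo) & (df["vaf"] <= hi)]
            if len(sel):
                counts = (sel["ref"] + ">" + sel["alt"]).value_counts()
                for cls_name, n in counts.items():
                    raw.loc[label, cls_name] = int(n)
    collapsed = pd.DataFrame(0, index=raw.index, columns=list(PYRIMIDINE_CLASSES))
    for cls_name in SUBSTITUTION_CLASSES:
        collapsed[collapse_class(cls_name)] += raw[cls_name]
    return raw, collapsed


def at_gc_fraction(raw: pd.DataFrame, bin_label: str) -> float:
    """Fraction of calls in a spectrum bin that are AT>GC (A>G or T>C)."""
    row = raw.loc[bin_label]
    total = int(row.sum())
    if total == 0:
        return float("nan")
    return float(row["A>G"] + row["T>C"]) / total
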