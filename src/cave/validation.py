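"""Validation statistics for the threshold choice.

Three independent checks that positions/calls above a candidate VAF
threshold look like true cancer-associated variants rather than noise:

* enrichment of a validated cancer-position set among above-threshold
  cohort positions (difference-of-percentages curves);
* the deleterious / non-deleterious ratio of missense calls, labels
  taken from an upstream functional classifier;
* a simplified dN/dS per mutation class, with mutation-opportunity site
  counts from exhaustive enumeration of all possible CDS SNVs
  (Nei–Gojobori-style equal rates, or 12-class spectrum-corrected
  rates estimated from sub-floor noise calls).

Enrichment is counted in positions and the two ratio statistics in
calls — deliberately, matching the two different questions they answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_calls import CohortCallSet, CohortPositionTable, VariantCall
from .resources import LabelTable, PositionSet
from .transcript import TranscriptModel

SELECTION_CLASSES = ("missense", "nonsense", "splice")


def classify_call(call: VariantCall, model: TranscriptModel) -> str:
    """Mutation class of one call: splice > coding classes > noncoding."""
    if call.chrom != model.chrom:
        raise ValueError(f"call on {call.chrom} but model is {model.chrom}")
    return model.classify(call.pos, call.ref, call.alt)


def _classified_frame(callset: CohortCallSet, model: TranscriptModel) -> pd.DataFrame:
    """Call frame with a mutation_class column (classified per unique variant)."""
    df = callset.to_frame()
    uniq = df[["chrom", "pos", "ref", "alt"]].drop_duplicates()
    klass = {}
    for r in uniq.itertuples(index=False):
        if r.chrom != model.chrom:
            klass[(r.chrom, r.pos, r.ref, r.alt)] = "noncoding"
        else:
            klass[(r.chrom, r.pos, r.ref, r.alt)] = model.classify(r.pos, r.ref, r.alt)
    df["mutation_class"] = [
        klass[(c, p, rf, a)] for c, p, rf, a in zip(df.chrom, df.pos, df.ref, df.alt)
    ]
    return df


def enrichment_curve(
    table: CohortPositionTable,
    refset: PositionSet,
    thresholds: Sequence[float],
    boundary: str = "closed",
) -> pd.DataFrame:
    """Reference-set enrichment among above-threshold positions.

    Per threshold: ``pct_positions_above`` = 100*a/A (a above-threshold
    positions of A total), ``pct_set_recovered`` = 100*b/B (b of the B
    reference positions found among the above group), and their
    difference.  A positive difference means the above group explains
    more of the reference set than its sheer size would.
    """
    if len(refset) == 0:
        raise ValueError("reference set must be non-empty")
    df = table.df
    A = len(df)
    B = len(refset)
    max_vaf = df["max_vaf"].to_numpy()
    in_set = np.array([(c, int(p)) in refset for c, p in zip(df["chrom"], df["pos"])])
    rows = []
    for t in thresholds:
        mask = max_vaf >= t if boundary == "closed" else max_vaf > t
        a = int(mask.sum())
        b = int((mask & in_set).sum())
        pct_above = 100.0 * a / A
        pct_set = 100.0 * b / B
        rows.append((t, A, a, B, b, pct_above, pct_set, pct_set - pct_above))
    return pd.DataFrame(
        rows,
        columns=[
            "threshold",
            "n_total",
            "n_above",
            "set_size",
            "n_overlap",
            "pct_positions_above",
            "pct_set_recovered",
            "difference",
        ],
    )


def dnd_ratio_curve(
    callset: CohortCallSet,
    labels: LabelTable,
    model: TranscriptModel,
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Deleterious/non-deleterious ratio of missense calls per threshold.

    Counted in calls, above (vaf >= t) and below each threshold.
    Unlabeled missense calls are excluded from the ratio and reported in
    ``n_unlabeled``.  ``ratio`` is NaN with ``undefined=True`` when the
    side has no non-deleterious calls; ``log2_ratio_plus1`` is the
    display transform log2(ratio + 1).
    """
    df = _classified_frame(callset, model)
    mis = df[df["mutation_class"] == "missense"].copy()
    lab = [
        labels.get(c, p, r, a) for c, p, r, a in zip(mis.chrom, mis.pos, mis.ref, mis.alt)
    ]
    mis["label"] = lab
    vaf = mis["vaf"].to_numpy()
    is_d = (mis["label"] == "D").to_numpy()
    is_nd = (mis["label"] == "ND").to_numpy()
    unlabeled = mis["label"].isna().to_numpy()
    rows = []
    for t in thresholds:
        above = vaf >= t
        for side, m in (("above", above), ("below", ~above)):
            n_d = int((m & is_d).sum())
            n_nd = int((m & is_nd).sum())
            n_un = int((m & unlabeled).sum())
            if n_nd == 0:
                ratio = math.nan
                log2r = math.nan
                undefined = True
            else:
                ratio = n_d / n_nd
                log2r = math.log2(ratio + 1.0)
                undefined = False
            rows.append((t, side, n_d, n_nd, n_un, ratio, log2r, undefined))
    return pd.DataFrame(
        rows,
        columns=[
            "threshold",
            "side",
            "n_d",
            "n_nd",
            "n_unlabeled",
            "ratio",
            "log2_ratio_plus1",
            "undefined",
        ],
    )


def estimate_spectrum_rates(
    callset: CohortCallSet,
    model: TranscriptModel,
    max_vaf: float,
    pseudocount: float = 0.5,
) -> dict[str, float]:
    """12-class relative mutation rates from sub-``max_vaf`` CDS calls.

    Rates are substitution counts normalised by the number of CDS sites
    carrying the reference base, with a pseudocount so no class has
    rate zero.  Intended to be fed to :func:`dnds_simple` so a biased
    noise spectrum (e.g. Taq-like AT>GC excess) does not masquerade as
    selection.
    """
    ref_sites = {b: 0 for b in "ACGT"}
    for p in model.cds_positions:
        ref_sites[model.genomic_ref_base(p)] += 1
    counts = {f"{r}>{a}": pseudocount for r in "ACGT" for a in "ACGT" if r != a}
    df = callset.to_frame()
    sub = df[(df["vaf"] < max_vaf) & (df["chrom"] == model.chrom)]
    cds = model.cds_positions
    for r in sub.itertuples(index=False):
        if r.pos in cds:
            counts[f"{r.ref}>{r.alt}"] += 1.0
    return {k: v / max(ref_sites[k[0]], 1) for k, v in counts.items()}


def dnds_simple(
    callset: CohortCallSet,
    model: TranscriptModel,
    threshold: float,
    side: str,
    rates: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Simplified dN/dS per class for calls on one side of a threshold.

    For each class c in missense/nonsense/splice:
    ``dnds = (n_c / sites_c) / (n_syn / sites_syn)`` where sites are
    mutation opportunities from :meth:`TranscriptModel.site_counts`.
    With no synonymous call on the side the ratio is NaN and flagged
    ``undefined``.  ``se_log`` is the Poisson standard error of
    log(dnds), sqrt(1/n_c + 1/n_syn).
    """
    if side not in ("above", "below"):
        raise ValueError("side must be 'above' or 'below'")
    df = _classified_frame(callset, model)
    m = df["vaf"] >= threshold if side == "above" else df["vaf"] < threshold
    sel = df[m]
    sites = model.site_counts(rates=rates)
    n_syn = int((sel["mutation_class"] == "synonymous").sum())
    rows = []
    for klass in SELECTION_CLASSES:
        n_c = int((sel["mutation_class"] == klass).sum())
        if n_syn == 0 or sites[klass] == 0:
            dnds = math.nan
            se_log = math.nan
            undefined = True
        else:
            dnds = (n_c / sites[klass]) / (n_syn / sites["synonymous"])
            se_log = math.sqrt(1.0 / n_c + 1.0 / n_syn) if n_c > 0 else math.nan
            undefined = False
        rows.append(
            (
                threshold,
                side,
                klass,
                n_c,
                sites[klass],
                n_syn,
                sites["synonymous"],
                dnds,
                se_log,
                undefined,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "threshold",
            "side",
            "mutation_class",
            "n_observed",
            "sites_class",
            "n_synonymous",
            "sites_synonymous",
            "dnds",
            "se_log",
            "undefined",
        ],
    )


def dnds_curve(
    callset: CohortCallSet,
    model: TranscriptModel,
    thresholds: Sequence[float],
    rates: dict[str, float] | None = None,
) -> pd.DataFrame:
    """dN/dS for every threshold and both sides, one long table."""
    df = _classified_frame(callset, model)
    sites = model.site_counts(rates=rates)
    vaf = df["vaf"].to_numpy()
    klass_arr = df["mutation_class"].to_numpy()
    rows = []
    for t in thresholds:
        above = vaf >= t
        for side, m in (("above", above), ("below", ~above)):
            n_syn = int(((klass_arr == "synonymous") & m).sum())
            for klass in SELECTION_CLASSES:
                n_c = int(((klass_arr == klass) & m).sum())
                if n_syn == 0 or sites[klass] == 0:
                    dnds, se_log, undefined = math.nan, math.nan, True
                else:
                    dnds = (n_c / sites[klass]) / (n_syn / sites["synonymous"])
                    se_log = math.sqrt(1.0 / n_c + 1.0 / n_syn) if n_c > 0 else math.nan
                    undefined = False
                rows.append(
                    (t, side, klass, n_c, sites[klass], n_syn, sites["synonymous"], dnds, se_log, undefined)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "threshold",
            "side",
            "mutation_class",
            "n_observed",
            "sites_class",
            "n_synonymous",
            "sites_synonymous",
            "dnds",
            "se_log",
            "undefined",
        ],
    )
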