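"""Synthetic cohorts, repositories and label tables.

Everything the analysis consumes can be fabricated here with the
statistical structure the method assumes, so the full pipeline is
testable without any database download:

* a synthetic single-gene transcript model (CDS split over exons on one
  chromosome) plus intronic flanks forming the sequenced panel;
* a repository frequency table with power-law ("hotspot") recurrence
  counts over coding and splice positions, its top-k positions serving
  as the validated cancer-position set, and a missense label table in
  which variants at hotspot positions are mostly deleterious;
* per-sample noise calls (Poisson ~1000/sample at a 0.05% caller
  floor) whose VAFs follow a right-skewed scaled Beta law with a
  per-site error ceiling, and whose substitution spectrum carries a
  configurable Taq-like AT>GC excess;
* driver calls spiked at positions weighted by repository counts, with
  log-uniform VAFs above a driver floor, a small synonymous fraction
  and an explicit splice-driver fraction.

Ground truth (noise vs driver per call) is always emitted alongside so
tests never re-infer it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_calls import CohortCallSet, VariantCall, write_calls_tsv
from .resources import (
    FrequencyMap,
    LabelTable,
    PositionSet,
    write_frequency_map,
    write_label_table,
    write_position_set,
)
from .transcript import BASES, COMPLEMENT, TranscriptModel

from itertools import product as _product

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    "".join(c) for c in _product("ACGT", repeat=3) if "".join(c) not in _STOP_CODONS
)
#: transition partner of each base (the AT>GC classes are A>G and T>C)
_TRANSITION = {"A": "G", "T": "C"}


def make_transcript(
    seed: int = 7,
    n_codons: int = 394,
    n_exons: int = 6,
    chrom: str = "chr17",
    start: int = 7_670_000,
    intron_len: int = 200,
    splice_window: int = 2,
) -> TranscriptModel:
    """Deterministic synthetic gene of TP53-like size (default 394 codons).

    The reference CDS is drawn from sense codons only, so every codon
    translates and premature reference stops cannot occur.
    """
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(_SENSE_CODONS, size=n_codons))
    total = 3 * n_codons
    base = total // n_exons
    lengths = [base] * n_exons
    lengths[-1] += total - base * n_exons
    exons = []
    pos = start
    for L in lengths:
        exons.append((pos, pos + L - 1))
        pos += L + intron_len
    return TranscriptModel(
        chrom=chrom,
        strand="+",
        exons=tuple(exons),
        cds_sequence=seq,
        splice_window=splice_window,
    )


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the deep-amplicon setting the method targets: 96
    samples, ~1,000 noise calls each at a 0.05% caller floor, noise
    VAFs essentially confined below the 0.5% driver floor with a
    Taq-like AT>GC spectrum excess, drivers spiked at
    repository-weighted positions with log-uniform VAFs up to 50%, and
    a 183-position validated set cut from the top of a power-law
    repository.
    """

    n_samples: int = 96
    caller_floor: float = 0.0005
    # noise model
    noise_calls_per_sample: float = 1000.0
    noise_vaf_cap: float = 0.006
    site_ceiling_beta: tuple[float, float] = (1.2, 3.5)
    call_vaf_beta: tuple[float, float] = (1.5, 3.0)
    at_gc_weight: float | None = 0.6  # None => uniform over (position, alt)
    intron_pad: int = 10
    # driver model
    drivers_per_sample_mean: float = 1.5
    driver_vaf_floor: float = 0.005
    driver_vaf_max: float = 0.5
    driver_splice_prob: float = 0.08
    driver_syn_weight: float = 0.1
    # repository / resources
    repo_zipf_a: float = 1.0
    csd_size: int = 183
    label_noise: float = 0.1
    depth: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if not 0 < self.caller_floor < self.driver_vaf_floor:
            raise ValueError("caller_floor must lie in (0, driver_vaf_floor)")
        if self.at_gc_weight is not None and not 0 <= self.at_gc_weight <= 1:
            raise ValueError("at_gc_weight must be in [0, 1] or None")
        if not self.driver_vaf_floor < self.driver_vaf_max <= 1:
            raise ValueError("need driver_vaf_floor < driver_vaf_max <= 1")


def _panel_positions(model: TranscriptModel, pad: int) -> np.ndarray:
    """Sequenced positions: exons extended ``pad`` bp into the introns."""
    out: set[int] = set()
    for i, (s, e) in enumerate(model.exons):
        lo = s - pad if i > 0 else s
        hi = e + pad if i < len(model.exons) - 1 else e
        out.update(range(lo, hi + 1))
    return np.array(sorted(out), dtype=int)


def _panel_reference(model: TranscriptModel, panel: np.ndarray, rng) -> dict[int, str]:
    """Reference base per panel position; intronic bases are synthetic."""
    cds = model.cds_positions
    ref = {}
    intronic = [p for p in panel if p not in cds]
    intronic_bases = rng.choice(list(BASES), size=len(intronic))
    for p, b in zip(intronic, intronic_bases):
        ref[int(p)] = str(b)
    for p in panel:
        p = int(p)
        if p in cds:
            ref[p] = model.genomic_ref_base(p)
    return ref


def simulate_repository(
    config: SimulationConfig,
    model: TranscriptModel,
    rng: np.random.Generator | None = None,
) -> tuple[FrequencyMap, PositionSet, LabelTable]:
    """Fabricate the three reference resources.

    Counts follow a rank-based Zipf law over coding and splice
    positions: the position of recurrence rank r gets
    ``round(n / r**repo_zipf_a)`` reports (``repo_zipf_a = 0``
    degenerates to uniform counts).  Because repository recurrence is
    itself the product of selection for protein-damaging variants,
    ranks are assigned by a weighted shuffle favouring positions with
    more nonsynonymous mutation opportunities (splice-window positions
    count in full; fully degenerate codon positions sink to the tail).
    The validated set is the top ``csd_size`` positions by count;
    missense labels are D at validated positions and ND elsewhere,
    each flipped with probability ``label_noise``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    positions = sorted(model.cds_positions | model.splice_positions)
    n = len(positions)
    nonsyn_opportunity = {p: 3.0 for p in model.splice_positions}
    for pos, _, _, klass in model.possible_cds_snvs():
        nonsyn_opportunity.setdefault(pos, 0.0)
        if klass != "synonymous":
            nonsyn_opportunity[pos] += 1.0
    w = np.array([max(nonsyn_opportunity[p], 0.01) for p in positions])
    # Efraimidis–Spirakis weighted shuffle: larger weight -> earlier rank
    keys = rng.random(n) ** (1.0 / w)
    ranks = np.empty(n, dtype=int)
    ranks[np.argsort(-keys, kind="stable")] = np.arange(1, n + 1)
    counts = np.maximum(np.round(n / ranks.astype(float) ** config.repo_zipf_a), 1).astype(int)
    fmap = FrequencyMap(
        counts={(model.chrom, int(p)): int(c) for p, c in zip(positions, counts)},
        source_name="synthetic_repository",
    )
    order = sorted(zip(positions, counts), key=lambda pc: (-pc[1], pc[0]))
    top = frozenset((model.chrom, int(p)) for p, _ in order[: config.csd_size])
    csd = PositionSet(positions=top, name="synthetic_csd")

    labels = {}
    for pos, gref, alt, klass in model.possible_cds_snvs():
        if klass != "missense":
            continue
        base = "D" if (model.chrom, pos) in top else "ND"
        if rng.random() < config.label_noise:
            base = "ND" if base == "D" else "D"
        labels[(model.chrom, pos, gref, alt)] = base
    return fmap, csd, LabelTable(labels=labels)


def _noise_calls(
    config: SimulationConfig,
    panel: np.ndarray,
    panel_ref: dict[int, str],
    ceilings: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-sample Bernoulli noise over every possible panel SNV.

    A caller reports at most one record per (sample, position, alt), so
    noise is modelled as an independent error per possible substitution
    and sample.  Error probabilities are split between the AT>GC
    transition classes (A>G / T>C, Taq-like) and everything else so
    that the expected per-sample call count is ``noise_calls_per_sample``
    and the expected AT>GC fraction of calls is ``at_gc_weight``
    (``None`` = one uniform rate for all possible SNVs).
    """
    ref_arr = np.array([panel_ref[int(p)] for p in panel])
    # enumerate all possible (position, alt) combos of the panel
    combo_pos_idx = np.repeat(np.arange(len(panel)), 3)
    combo_alt = np.empty(3 * len(panel), dtype="U1")
    for i, r in enumerate(ref_arr):
        combo_alt[3 * i : 3 * i + 3] = [b for b in BASES if b != r]
    combo_ref = ref_arr[combo_pos_idx]
    is_ts = ((combo_ref == "A") & (combo_alt == "G")) | (
        (combo_ref == "T") & (combo_alt == "C")
    )
    n_combos = len(combo_alt)
    mean = config.noise_calls_per_sample
    if config.at_gc_weight is None:
        p = np.full(n_combos, min(mean / n_combos, 1.0))
    else:
        w = config.at_gc_weight
        n_ts = max(int(is_ts.sum()), 1)
        n_nt = max(n_combos - int(is_ts.sum()), 1)
        p = np.where(
            is_ts, min(w * mean / n_ts, 1.0), min((1.0 - w) * mean / n_nt, 1.0)
        )
    called = rng.random((config.n_samples, n_combos)) < p
    sample_idx, combo_idx = np.nonzero(called)
    c = ceilings[combo_pos_idx[combo_idx]]
    u = rng.beta(*config.call_vaf_beta, size=len(combo_idx))
    vaf = np.clip(config.caller_floor + (c - config.caller_floor) * u, config.caller_floor, None)
    return pd.DataFrame(
        {
            "sample_id": np.array([f"S{i:03d}" for i in range(config.n_samples)])[sample_idx],
            "pos": panel[combo_pos_idx[combo_idx]],
            "ref": combo_ref[combo_idx],
            "alt": combo_alt[combo_idx],
            "vaf": vaf,
            "origin": "noise",
        }
    )


def _driver_calls(
    config: SimulationConfig,
    model: TranscriptModel,
    fmap: FrequencyMap,
    panel_ref: dict[int, str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    cds_pos = np.array(sorted(model.cds_positions), dtype=int)
    spl_pos = np.array(sorted(model.splice_positions), dtype=int)
    w_cds = np.array([fmap.count(model.chrom, int(p)) for p in cds_pos], dtype=float)
    w_spl = np.array([fmap.count(model.chrom, int(p)) for p in spl_pos], dtype=float)
    if w_cds.sum() == 0:
        w_cds[:] = 1.0
    if w_spl.sum() == 0:
        w_spl[:] = 1.0
    w_cds /= w_cds.sum()
    w_spl /= w_spl.sum()

    # per-CDS-position alt menu with class-based weights (nonsyn 1, syn w_syn)
    alt_menu: dict[int, tuple[list[str], np.ndarray]] = {}
    for p in cds_pos:
        gref = model.genomic_ref_base(int(p))
        choices, weights = [], []
        for alt in BASES:
            if alt == gref:
                continue
            klass = model.classify(int(p), gref, alt)
            choices.append(alt)
            weights.append(config.driver_syn_weight if klass == "synonymous" else 1.0)
        w = np.asarray(weights, dtype=float)
        alt_menu[int(p)] = (choices, w / w.sum())

    k_per_sample = rng.poisson(config.drivers_per_sample_mean, size=config.n_samples)
    rows = []
    log_lo, log_hi = np.log(config.driver_vaf_floor), np.log(config.driver_vaf_max)
    for s in range(config.n_samples):
        for _ in range(int(k_per_sample[s])):
            if len(spl_pos) and rng.random() < config.driver_splice_prob:
                p = int(rng.choice(spl_pos, p=w_spl))
                gref = panel_ref[p]
                alt = str(rng.choice([b for b in BASES if b != gref]))
            else:
                p = int(rng.choice(cds_pos, p=w_cds))
                gref = panel_ref[p]
                choices, w = alt_menu[p]
                alt = str(choices[rng.choice(len(choices), p=w)])
            vaf = float(np.exp(rng.uniform(log_lo, log_hi)))
            rows.append((f"S{s:03d}", p, gref, alt, vaf, "driver"))
    return pd.DataFrame(
        rows, columns=["sample_id", "pos", "ref", "alt", "vaf", "origin"]
    )


def simulate_cohort(
    config: SimulationConfig,
    model: TranscriptModel,
    fmap: FrequencyMap,
    rng: np.random.Generator | None = None,
) -> tuple[CohortCallSet, pd.DataFrame]:
    """Generate the cohort call set plus its ground-truth table.

    Duplicate (sample, position, alt) calls are collapsed to the
    max-VAF one, mirroring ingestion; the returned truth table carries
    one row per retained call with its origin ("noise"/"driver").
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    panel = _panel_positions(model, config.intron_pad)
    panel_ref = _panel_reference(model, panel, rng)
    b1, b2 = config.site_ceiling_beta
    ceilings = config.caller_floor + (
        config.noise_vaf_cap - config.caller_floor
    ) * rng.beta(b1, b2, size=len(panel))

    noise = _noise_calls(config, panel, panel_ref, ceilings, rng)
    drivers = _driver_calls(config, model, fmap, panel_ref, rng)
    frames = [f for f in (noise, drivers) if len(f)]
    df = pd.concat(frames, ignore_index=True)
    df["chrom"] = model.chrom
    df["depth"] = config.depth
    # keep max-VAF row per (sample, pos, alt); drivers outrank colliding noise
    df = (
        df.sort_values(["sample_id", "chrom", "pos", "alt", "vaf"], kind="mergesort")
        .drop_duplicates(["sample_id", "chrom", "pos", "alt"], keep="last")
        .reset_index(drop=True)
    )
    truth = df[["sample_id", "chrom", "pos", "ref", "alt", "vaf", "origin"]].copy()
    callset = CohortCallSet.from_frame(
        df[["sample_id", "chrom", "pos", "ref", "alt", "vaf", "depth"]],
        caller_floor=config.caller_floor,
    )
    return callset, truth


_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID={chrom}>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcfs(callset: CohortCallSet, outdir: str | Path) -> list[Path]:
    """Write one minimal single-sample VCF per cohort sample."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = callset.to_frame()
    paths = []
    for sid, sub in df.groupby("sample_id", sort=True):
        path = outdir / f"{sid}.vcf"
        chrom = sub["chrom"].iloc[0]
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER.format(chrom=chrom, sample=sid))
            for r in sub.sort_values(["chrom", "pos", "alt"], kind="mergesort").itertuples(
                index=False
            ):
                fh.write(
                    f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                    f"DP={r.depth}\tGT:AF:DP\t0/1:{r.vaf:.6g}:{r.depth}\n"
                )
        paths.append(path)
    return paths


def write_simulation(
    config: SimulationConfig,
    outdir: str | Path,
    model: TranscriptModel | None = None,
    vcf: bool = False,
) -> dict[str, Path]:
    """Materialise a full synthetic study on disk.

    Writes calls.tsv, truth.tsv, frequency.tsv, csd.tsv, labels.tsv and
    transcript.json (plus per-sample VCFs under vcf/ when requested);
    byte-identical for identical config + seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if model is None:
        model = make_transcript()
    rng = np.random.default_rng(config.seed)
    fmap, csd, labels = simulate_repository(config, model, rng)
    callset, truth = simulate_cohort(config, model, fmap, rng)

    paths = {
        "calls": outdir / "calls.tsv",
        "truth": outdir / "truth.tsv",
        "frequency": outdir / "frequency.tsv",
        "csd": outdir / "csd.tsv",
        "labels": outdir / "labels.tsv",
        "transcript": outdir / "transcript.json",
    }
    write_calls_tsv(callset, paths["calls"])
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    write_frequency_map(fmap, paths["frequency"])
    write_position_set(csd, paths["csd"])
    write_label_table(labels, paths["labels"])
    model.to_json(paths["transcript"])
    if vcf:
        write_vcfs(callset, outdir / "vcf")
        paths["vcf_dir"] = outdir / "vcf"
    return paths


def fixture_config(seed: int = 0) -> SimulationConfig:
    """A small, fast cohort for fixtures and smoke tests."""
    return SimulationConfig(
        n_samples=8,
        noise_calls_per_sample=150.0,
        drivers_per_sample_mean=2.0,
        seed=seed,
    )
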