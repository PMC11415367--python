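"""End-to-end run orchestration and report output.

``run_cave`` ties the stages together: read calls, build the position
table, sweep thresholds against the repository frequency map, detect
the p-value-curve knee, and compute the three validation curves plus
the substitution spectrum.  All tables are written as TSV with a
config-hash provenance header; plots are regenerable from the tables
alone via ``render_plots``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io_calls, resources, validation
from .io_calls import CohortCallSet, CohortPositionTable
from .sweep import KneeEstimate, SweepResult, detect_knee, sweep as run_sweep, threshold_grid
from .transcript import TranscriptModel

logger = logging.getLogger(__name__)

DEFAULT_SPECTRUM_BINS = ((0.0, 0.005), (0.005, 0.01), (0.01, 1.0))


@dataclass
class RunConfig:
    """Validated inputs and options for one analysis run."""

    calls_tsv: str | None = None
    vcf_paths: tuple[str, ...] = ()
    frequency_path: str = ""
    csd_path: str | None = None
    labels_path: str | None = None
    transcript_path: str | None = None
    outdir: str = "cave_out"
    thresholds: tuple[float, float, float] = (0.002, 0.008, 0.0005)  # lo, hi, step
    caller_floor: float = 0.0005
    boundary: str = "closed"
    knee_method: str = "chord"
    vaf_field: str = "AF"
    spectrum_bins: tuple[tuple[float, float], ...] = DEFAULT_SPECTRUM_BINS
    seed: int = 0

    def validate(self) -> None:
        if not self.calls_tsv and not self.vcf_paths:
            raise ValueError("provide calls_tsv or vcf_paths")
        if not self.frequency_path:
            raise ValueError("a repository frequency table is required")
        for label, p in self.input_paths():
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} input not found: {p}")
        if self.boundary not in ("closed", "open"):
            raise ValueError("boundary must be 'closed' or 'open'")
        if self.knee_method not in ("chord", "second-diff"):
            raise ValueError("knee_method must be 'chord' or 'second-diff'")
        lo, hi, step = self.thresholds
        threshold_grid(lo, hi, step)  # raises on a bad grid

    def input_paths(self) -> list[tuple[str, str]]:
        out = []
        if self.calls_tsv:
            out.append(("calls", self.calls_tsv))
        out.extend(("vcf", p) for p in self.vcf_paths)
        out.append(("frequency", self.frequency_path))
        for label, p in (
            ("csd", self.csd_path),
            ("labels", self.labels_path),
            ("transcript", self.transcript_path),
        ):
            if p:
                out.append((label, p))
        return out

    def grid(self) -> np.ndarray:
        return threshold_grid(*self.thresholds)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        # outdir is excluded: where the report lands is not analytic state
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("vcf_paths",):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        if "thresholds" in data and isinstance(data["thresholds"], (list, tuple)):
            data["thresholds"] = tuple(float(x) for x in data["thresholds"])
        if "spectrum_bins" in data:
            data["spectrum_bins"] = tuple(tuple(b) for b in data["spectrum_bins"])
        return cls(**data)


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cave config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def run_cave(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns a summary dict (knee threshold, group sizes, file paths).
    Stages whose inputs were not provided (CSD, labels, transcript) are
    skipped with a log line.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    grid = config.grid()

    if config.calls_tsv:
        callset = io_calls.read_calls_tsv(config.calls_tsv, caller_floor=config.caller_floor)
    else:
        callset = io_calls.read_calls(
            list(config.vcf_paths),
            vaf_field=config.vaf_field,
            caller_floor=config.caller_floor,
        )
    logger.info(
        "loaded %d calls from %d samples (%d non-SNV, %d sub-floor dropped)",
        len(callset),
        len(callset.samples),
        callset.n_dropped_non_snv,
        callset.n_dropped_below_floor,
    )
    table = io_calls.build_position_table(callset)
    fmap = resources.load_frequency_map(config.frequency_path)

    files: dict[str, Path] = {}
    _write_tsv(callset.to_frame(), outdir / "calls.tsv", h)
    files["calls"] = outdir / "calls.tsv"
    _write_tsv(table.df, outdir / "position_table.tsv", h)
    files["position_table"] = outdir / "position_table.tsv"
    scores = table.df[["chrom", "pos", "max_vaf"]].copy()
    scores["repo_count"] = fmap.counts_for(zip(scores["chrom"], scores["pos"])).astype(int)
    scores["log2_count_plus1"] = np.log2(scores["repo_count"] + 1.0)
    _write_tsv(scores, outdir / "position_scores.tsv", h)
    files["position_scores"] = outdir / "position_scores.tsv"

    sw = run_sweep(table, fmap, thresholds=grid, boundary=config.boundary)
    _write_tsv(sw.df, outdir / "sweep.tsv", h)
    files["sweep"] = outdir / "sweep.tsv"

    knee = detect_knee(sw, method=config.knee_method)
    knee_row = pd.DataFrame(
        [
            {
                "knee_threshold": knee.knee_threshold,
                "method": knee.method,
                "low_confidence": knee.low_confidence,
                "max_distance": knee.max_distance,
            }
        ]
    )
    _write_tsv(knee_row, outdir / "knee.tsv", h)
    _write_tsv(knee.curve, outdir / "knee_curve.tsv", h)
    files["knee"] = outdir / "knee.tsv"

    raw, collapsed = io_calls.mutational_spectrum(callset, list(config.spectrum_bins))
    _write_tsv(raw.reset_index(), outdir / "spectrum_raw.tsv", h)
    _write_tsv(collapsed.reset_index(), outdir / "spectrum_collapsed.tsv", h)
    files["spectrum"] = outdir / "spectrum_raw.tsv"

    summary = {
        "n_calls": len(callset),
        "n_samples": len(callset.samples),
        "n_positions": len(table),
        "knee_threshold": knee.knee_threshold,
        "knee_low_confidence": knee.low_confidence,
    }

    if config.csd_path:
        csd = resources.load_position_set(config.csd_path, name="csd")
        enr = validation.enrichment_curve(table, csd, grid, boundary=config.boundary)
        _write_tsv(enr, outdir / "enrichment.tsv", h)
        files["enrichment"] = outdir / "enrichment.tsv"
        peak = enr.loc[enr["difference"].idxmax()]
        summary["enrichment_peak_threshold"] = float(peak["threshold"])
    else:
        logger.info("no CSD path given; skipping enrichment stage")

    model = None
    if config.transcript_path:
        model = TranscriptModel.from_json(config.transcript_path)

    if model is not None and config.labels_path:
        labels = resources.load_label_table(config.labels_path)
        ratio = validation.dnd_ratio_curve(callset, labels, model, grid)
        _write_tsv(ratio, outdir / "dnd_ratio.tsv", h)
        files["dnd_ratio"] = outdir / "dnd_ratio.tsv"
    elif config.labels_path:
        logger.info("labels given without a transcript model; skipping D/ND stage")

    if model is not None:
        rates = validation.estimate_spectrum_rates(callset, model, max_vaf=float(grid[0]))
        dnds = validation.dnds_curve(callset, model, grid, rates=rates)
        _write_tsv(dnds, outdir / "dnds.tsv", h)
        files["dnds"] = outdir / "dnds.tsv"
    else:
        logger.info("no transcript model; skipping dN/dS stage")

    render_plots(outdir)
    summary["files"] = {k: str(v) for k, v in files.items()}
    return summary


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def render_plots(outdir: str | Path) -> list[Path]:
    """(Re)generate the report figures from the TSVs in ``outdir``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    made = []

    sweep_path = outdir / "sweep.tsv"
    if sweep_path.exists():
        df = _read_tsv(sweep_path)
        tested = df[df["tested"].astype(bool)]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(100 * tested["threshold"], tested["p_value"], "o-", color="#1f497d")
        ax.set_yscale("log")
        ax.set_xlabel("VAF threshold (%)")
        ax.set_ylabel("two-sided rank-sum p-value")
        ax.set_title("Repository-score separation across VAF thresholds")
        knee_path = outdir / "knee.tsv"
        if knee_path.exists():
            knee = _read_tsv(knee_path)
            ax.axvline(100 * knee["knee_threshold"].iloc[0], ls="--", color="firebrick")
        fig.tight_layout()
        fig.savefig(outdir / "pvalue_curve.png", dpi=150)
        plt.close(fig)
        made.append(outdir / "pvalue_curve.png")

    enr_path = outdir / "enrichment.tsv"
    if enr_path.exists():
        df = _read_tsv(enr_path)
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        axes[0].plot(100 * df["threshold"], df["pct_positions_above"], "o-", color="firebrick",
                     label="% positions above")
        axes[0].plot(100 * df["threshold"], df["pct_set_recovered"], "o-", color="teal",
                     label="% reference set recovered")
        axes[0].legend()
        axes[0].set_xlabel("VAF threshold (%)")
        axes[0].set_ylabel("%")
        axes[1].plot(100 * df["threshold"], df["difference"], "o-", color="#333333")
        axes[1].set_xlabel("VAF threshold (%)")
        axes[1].set_ylabel("difference (pp)")
        fig.tight_layout()
        fig.savefig(outdir / "enrichment.png", dpi=150)
        plt.close(fig)
        made.append(outdir / "enrichment.png")

    knee_path = outdir / "knee.tsv"
    scores_path = outdir / "position_scores.tsv"
    if knee_path.exists() and scores_path.exists():
        # paired repository-score histograms above/below the knee threshold
        scores = _read_tsv(scores_path)
        knee_t = _read_tsv(knee_path)["knee_threshold"].iloc[0]
        above = scores[scores["max_vaf"] >= knee_t]
        below = scores[scores["max_vaf"] < knee_t]
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, grp, name, color in (
            (axes[0], above, "above threshold", "firebrick"),
            (axes[1], below, "below threshold", "steelblue"),
        ):
            ax.hist(grp["log2_count_plus1"], bins=30, color=color)
            ax.set_title(f"{name} (n={len(grp)} positions)")
            ax.set_xlabel("log2(repository count + 1)")
            ax.set_ylabel("positions")
        fig.suptitle(f"Repository recurrence at VAF threshold {100 * knee_t:g}%")
        fig.tight_layout()
        fig.savefig(outdir / "score_histograms.png", dpi=150)
        plt.close(fig)
        made.append(outdir / "score_histograms.png")
    return made
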