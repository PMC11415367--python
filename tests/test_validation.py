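"""Mutation-class assignment, enrichment, D/ND ratio and dN/dS."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import cave
from cave.io_calls import CohortCallSet, CohortPositionTable, VariantCall
from cave.resources import LabelTable, PositionSet
from cave.simulate import SimulationConfig, make_transcript
from cave.transcript import COMPLEMENT, TranscriptModel
from cave.validation import (
    classify_call,
    dnd_ratio_curve,
    dnds_simple,
    enrichment_curve,
    estimate_spectrum_rates,
)
from tests.conftest import simulate_study


class TestClassify:
    def test_explicit_codon_outcomes(self):
        # ATG GCC TGG CGA: M A W R
        model = TranscriptModel(
            chrom="chr1", strand="+", exons=((101, 112),), cds_sequence="ATGGCCTGGCGA",
        )
        assert model.classify(106, "C", "T") == "synonymous"  # GCC->GCT (Ala)
        assert model.classify(109, "G", "A") == "nonsense"  # TGG->TGA
        assert model.classify(102, "T", "C") == "missense"  # ATG->ACG (M->T)

    def test_splice_window_takes_precedence_and_is_intron_side_only(self):
        model = TranscriptModel(
            chrom="chr1", strand="+", exons=((101, 106), (201, 206)), cds_sequence="ATGGCCTGGCGA",
        )
        assert model.classify(108, "A", "G") == "splice"  # 2 bp past exon 1 end
        assert model.classify(199, "A", "G") == "splice"  # 2 bp before exon 2
        assert model.classify(109, "A", "G") == "noncoding"  # outside the window
        assert 99 not in model.splice_positions  # no intron upstream of exon 1

    def test_minus_strand_uses_complemented_alleles(self):
        # coding sequence ATG GCC -> genomic (reverse complement) GGCCAT
        model = TranscriptModel(
            chrom="chr1", strand="-", exons=((101, 106),), cds_sequence="ATGGCC",
        )
        # genomic pos 106 is the first coding base (A); genomic ref is T
        assert model.classify(106, "T", "G") == "missense"  # ATG -> CTG
        assert model.classify(101, "G", "A") == "synonymous"  # GCC -> GCT

    def test_reference_mismatch_names_position(self):
        model = TranscriptModel(
            chrom="chr1", strand="+", exons=((101, 106),), cds_sequence="ATGGCC",
        )
        with pytest.raises(ValueError, match="103"):
            model.classify(103, "C", "T")

    def test_classify_call_checks_chromosome(self, toy_model):
        call = VariantCall("s", "chrX", 1, "C", "T", 0.01)
        with pytest.raises(ValueError, match="chrX"):
            classify_call(call, toy_model)

    def test_agrees_with_biopython_translation_oracle(self, toy_model):
        """Every possible CDS SNV of a toy transcript, against Bio.Seq."""
        from Bio.Seq import Seq

        cds = toy_model.cds_sequence
        ref_protein = str(Seq(cds).translate())
        order = {p: i for i, p in enumerate(sorted(toy_model.cds_positions))}
        if toy_model.strand == "-":
            order = {p: len(order) - 1 - i for p, i in order.items()}
        n_checked = 0
        for pos, gref, alt, klass in toy_model.possible_cds_snvs():
            idx = order[pos]
            calt = alt if toy_model.strand == "+" else COMPLEMENT[alt]
            mutated = cds[:idx] + calt + cds[idx + 1 :]
            mut_protein = str(Seq(mutated).translate())
            aa0, aa1 = ref_protein[idx // 3], mut_protein[idx // 3]
            expected = (
                "synonymous" if aa1 == aa0 else "nonsense" if aa1 == "*" else "missense"
            )
            assert klass == expected, (pos, gref, alt)
            n_checked += 1
        assert n_checked == 3 * len(cds)

    def test_model_validation(self):
        with pytest.raises(ValueError, match="divisible"):
            TranscriptModel(chrom="c", strand="+", exons=((1, 4),), cds_sequence="ATGG")
        with pytest.raises(ValueError, match="length"):
            TranscriptModel(chrom="c", strand="+", exons=((1, 6),), cds_sequence="ATG")

    def test_json_round_trip(self, toy_model, tmp_path):
        path = tmp_path / "model.json"
        toy_model.to_json(path)
        assert TranscriptModel.from_json(path) == toy_model


def table_with_above(n_total, n_above, threshold=0.008):
    vafs = [threshold + 0.002] * n_above + [threshold / 4] * (n_total - n_above)
    df = pd.DataFrame(
        {
            "chrom": "chr17",
            "pos": np.arange(1, n_total + 1),
            "max_vaf": vafs,
            "n_samples_with_call": 1,
            "n_calls": 1,
        }
    )
    return CohortPositionTable(df)


class TestEnrichment:
    def test_published_style_worked_example(self):
        table = table_with_above(1227, 56)
        refset = PositionSet(
            frozenset(
                [("chr17", p) for p in range(1, 37)]  # 36 of the 56 above
                + [("chr17", p) for p in range(57, 204)]  # 147 below
            ),
            name="csd",
        )
        (point,) = enrichment_curve(table, refset, [0.008]).itertuples(index=False)
        assert round(point.pct_positions_above, 1) == 4.6
        assert round(point.pct_set_recovered, 1) == 19.7
        assert round(point.difference, 1) == 15.1

    def test_zero_threshold_difference_never_positive(self):
        table = table_with_above(100, 30)
        refset = PositionSet(frozenset([("chr17", p) for p in range(1, 21)]))
        (point,) = enrichment_curve(table, refset, [0.0]).itertuples(index=False)
        assert point.pct_positions_above == 100.0
        assert point.difference <= 0

    def test_disjoint_refset_difference_is_minus_pct_above(self):
        table = table_with_above(50, 10)
        refset = PositionSet(frozenset([("chr9", p) for p in range(1, 11)]))
        curve = enrichment_curve(table, refset, [0.001, 0.008])
        assert (curve["difference"] == -curve["pct_positions_above"]).all()

    def test_empty_refset_rejected(self):
        with pytest.raises(ValueError):
            enrichment_curve(table_with_above(5, 2), PositionSet(frozenset()), [0.01])

    def test_curve_reaches_maximum_by_driver_floor(self, gene_model):
        """Enrichment difference saturates at the spiked driver floor."""
        cfg = SimulationConfig(seed=9)
        _, fmap, csd, _, callset, _ = simulate_study(cfg, gene_model)
        table = cave.build_position_table(callset)
        curve = enrichment_curve(table, csd, cave.threshold_grid(0.002, 0.008, 0.0005))
        at_floor = curve.loc[curve["threshold"] == 0.005, "difference"].iloc[0]
        assert at_floor >= curve["difference"].max() - 0.5


def _pick_missense(model, n, vaf, sample="s"):
    picked = []
    for pos, gref, alt, klass in model.possible_cds_snvs():
        if klass == "missense":
            picked.append(VariantCall(sample, model.chrom, pos, gref, alt, vaf))
            if len(picked) == n:
                return picked
    raise AssertionError("not enough missense SNVs")


class TestDndRatio:
    def test_ratio_arithmetic(self, toy_model):
        calls = _pick_missense(toy_model, 5, vaf=0.01)
        labels = LabelTable(
            labels={
                (c.chrom, c.pos, c.ref, c.alt): lab
                for c, lab in zip(calls, ["D", "D", "D", "ND", "ND"])
            }
        )
        cs = CohortCallSet(calls=calls)
        curve = dnd_ratio_curve(cs, labels, toy_model, [0.005])
        above = curve[curve["side"] == "above"].iloc[0]
        assert above.ratio == pytest.approx(1.5)
        assert above.log2_ratio_plus1 == pytest.approx(math.log2(2.5))

    def test_no_nd_calls_flags_undefined(self, toy_model):
        calls = _pick_missense(toy_model, 3, vaf=0.01)
        labels = LabelTable(
            labels={(c.chrom, c.pos, c.ref, c.alt): "D" for c in calls}
        )
        curve = dnd_ratio_curve(CohortCallSet(calls=calls), labels, toy_model, [0.005])
        above = curve[curve["side"] == "above"].iloc[0]
        assert above.undefined and math.isnan(above.log2_ratio_plus1)

    def test_unlabeled_missense_excluded_and_counted(self, toy_model):
        calls = _pick_missense(toy_model, 4, vaf=0.01)
        labels = LabelTable(
            labels={
                (c.chrom, c.pos, c.ref, c.alt): lab
                for c, lab in zip(calls[:2], ["D", "ND"])
            }
        )
        curve = dnd_ratio_curve(CohortCallSet(calls=calls), labels, toy_model, [0.005])
        above = curve[curve["side"] == "above"].iloc[0]
        assert (above.n_d, above.n_nd, above.n_unlabeled) == (1, 1, 2)
        assert above.ratio == pytest.approx(1.0)


class TestDnds:
    def test_zero_synonymous_side_flagged(self, toy_model):
        calls = _pick_missense(toy_model, 3, vaf=0.01)
        out = dnds_simple(CohortCallSet(calls=calls), toy_model, 0.005, "above")
        assert out["undefined"].all()

    def test_uniform_mutation_neutral_within_three_se(self, gene_model):
        """Class-uniform noise shows no spurious selection signal."""
        cfg = SimulationConfig(
            n_samples=24,
            noise_calls_per_sample=500.0,
            drivers_per_sample_mean=0.0,
            at_gc_weight=None,
            seed=77,
        )
        _, _, _, _, callset, _ = simulate_study(cfg, gene_model)
        out = dnds_simple(callset, gene_model, 0.005, "below")
        for row in out.itertuples():
            assert not row.undefined
            assert abs(math.log(row.dnds)) <= 3 * row.se_log, row.mutation_class

    def test_missense_only_calls_show_positive_selection(self, toy_model):
        calls = _pick_missense(toy_model, 40, vaf=0.01)
        # add a couple of synonymous calls so the ratio is defined
        syn = [
            VariantCall("s", toy_model.chrom, pos, gref, alt, 0.01)
            for pos, gref, alt, klass in toy_model.possible_cds_snvs()
            if klass == "synonymous"
        ][:2]
        out = dnds_simple(CohortCallSet(calls=calls + syn), toy_model, 0.005, "above")
        by_class = out.set_index("mutation_class")
        assert by_class.loc["missense", "dnds"] > 1
        assert by_class.loc["nonsense", "n_observed"] == 0

    def test_spectrum_rates_reflect_at_gc_excess(self, small_study):
        model, _, _, _, callset, _ = small_study
        rates = estimate_spectrum_rates(callset, model, max_vaf=0.002)
        assert set(rates) == {f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a}
        transitions = (rates["A>G"] + rates["T>C"]) / 2
        others = np.mean([v for k, v in rates.items() if k not in ("A>G", "T>C")])
        assert transitions > 2 * others
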