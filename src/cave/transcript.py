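"""Minimal transcript model for mutation-class assignment.

A gene panel analysis needs just enough annotation to call a SNV
synonymous, missense, nonsense, splice-disrupting or noncoding: the CDS
exon intervals, the strand, and the reference CDS sequence in coding
orientation.  Splice assignment uses a configurable window (default
+/-2 bp, the canonical donor/acceptor dinucleotides) on the intron side
of internal exon boundaries and takes precedence over coding classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterator

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
BASES = ("A", "C", "G", "T")

# standard genetic code, coding-strand codons
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

CODING_CLASSES = ("synonymous", "missense", "nonsense")
MUTATION_CLASSES = ("synonymous", "missense", "nonsense", "splice", "noncoding")


@dataclass(frozen=True)
class TranscriptModel:
    """CDS intervals + strand + reference CDS sequence.

    ``exons`` are 1-based inclusive (start, end) genomic intervals in
    ascending genomic order; ``cds_sequence`` is given in coding
    orientation (i.e. already reverse-complemented for '-' strand
    genes) and must cover exactly the summed exon length, a multiple
    of 3.
    """

    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_sequence: str
    splice_window: int = 2

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for (s, e) in self.exons:
            if e < s:
                raise ValueError(f"bad exon interval ({s}, {e})")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError("exons must be sorted and non-overlapping")
        total = sum(e - s + 1 for s, e in self.exons)
        if total != len(self.cds_sequence):
            raise ValueError(
                f"CDS sequence length {len(self.cds_sequence)} != summed exon length {total}"
            )
        if total % 3 != 0:
            raise ValueError(f"CDS length {total} not divisible by 3")
        bad = set(self.cds_sequence) - set(BASES)
        if bad:
            raise ValueError(f"invalid bases in CDS sequence: {sorted(bad)}")
        if self.splice_window < 0:
            raise ValueError("splice_window must be >= 0")

    @cached_property
    def _cds_genomic_order(self) -> tuple[int, ...]:
        """Genomic positions of CDS bases, in coding (5'->3' mRNA) order."""
        pos = [p for s, e in self.exons for p in range(s, e + 1)]
        if self.strand == "-":
            pos.reverse()
        return tuple(pos)

    @cached_property
    def _pos_to_index(self) -> dict[int, int]:
        return {p: i for i, p in enumerate(self._cds_genomic_order)}

    @cached_property
    def splice_positions(self) -> frozenset[int]:
        """Intronic positions within the splice window of internal boundaries."""
        out: set[int] = set()
        w = self.splice_window
        for i, (s, e) in enumerate(self.exons):
            if i > 0:  # acceptor side of an intron
                out.update(range(s - w, s))
            if i < len(self.exons) - 1:  # donor side
                out.update(range(e + 1, e + 1 + w))
        return frozenset(out)

    @cached_property
    def cds_positions(self) -> frozenset[int]:
        return frozenset(self._pos_to_index)

    def coding_ref_base(self, pos: int) -> str:
        """Coding-strand reference base at a genomic CDS position."""
        return self.cds_sequence[self._pos_to_index[pos]]

    def genomic_ref_base(self, pos: int) -> str:
        base = self.coding_ref_base(pos)
        return base if self.strand == "+" else COMPLEMENT[base]

    def classify(self, pos: int, ref: str, alt: str) -> str:
        """Assign a mutation class to a genomic SNV.

        Splice takes precedence; coding classes follow codon
        translation on the coding strand.  A change away from a
        reference stop codon is reported as missense.  Reference-base
        mismatches inside the CDS raise.
        """
        if pos in self.splice_positions:
            return "splice"
        idx = self._pos_to_index.get(pos)
        if idx is None:
            return "noncoding"
        if self.strand == "-":
            ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        if self.cds_sequence[idx] != ref:
            raise ValueError(
                f"reference mismatch at {self.chrom}:{pos}: model has "
                f"{self.cds_sequence[idx]} (coding strand), call has {ref}"
            )
        codon_start = 3 * (idx // 3)
        codon = self.cds_sequence[codon_start : codon_start + 3]
        offset = idx - codon_start
        mutated = codon[:offset] + alt + codon[offset + 1 :]
        aa_ref = CODON_TABLE[codon]
        aa_alt = CODON_TABLE[mutated]
        if aa_alt == aa_ref:
            return "synonymous"
        if aa_alt == "*":
            return "nonsense"
        return "missense"

    def possible_cds_snvs(self) -> Iterator[tuple[int, str, str, str]]:
        """All 3L possible CDS SNVs as (pos, genomic ref, genomic alt, class)."""
        for pos in self._cds_genomic_order:
            gref = self.genomic_ref_base(pos)
            for alt in BASES:
                if alt == gref:
                    continue
                yield pos, gref, alt, self.classify(pos, gref, alt)

    def site_counts(self, rates: dict[str, float] | None = None) -> dict[str, float]:
        """Mutation-opportunity counts per class.

        Equal-rates by default: each possible SNV contributes 1 site.
        With a 12-class ``rates`` dict (keys like ``"A>G"``) each
        contributes its relative rate, a Nei–Gojobori-style weighting
        that absorbs a biased mutation spectrum.  Splice-window sites
        (3 alts per window position) have unknown intronic reference
        bases, so under ``rates`` they are weighted by the mean
        per-site rate of the CDS enumeration.
        """
        counts = {"synonymous": 0.0, "missense": 0.0, "nonsense": 0.0, "splice": 0.0}
        n_cds_snvs = 0
        total_w = 0.0
        for _, gref, alt, klass in self.possible_cds_snvs():
            w = 1.0 if rates is None else rates[f"{gref}>{alt}"]
            counts[klass] += w
            total_w += w
            n_cds_snvs += 1
        n_splice_sites = 3 * len(self.splice_positions)
        if rates is None:
            counts["splice"] = float(n_splice_sites)
        else:
            counts["splice"] = n_splice_sites * (total_w / n_cds_snvs)
        return counts

    def to_json(self, path: str | Path) -> None:
        payload = {
            "chrom": self.chrom,
            "strand": self.strand,
            "exons": [list(e) for e in self.exons],
            "cds_sequence": self.cds_sequence,
            "splice_window": self.splice_window,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TranscriptModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            chrom=payload["chrom"],
            strand=payload["strand"],
            exons=tuple(tuple(e) for e in payload["exons"]),
            cds_sequence=payload["cds_sequence"],
            splice_window=int(payload.get("splice_window", 2)),
        )
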