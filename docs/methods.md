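# Methods

## Problem setting and model

A targeted deep-sequencing cohort is reduced to SNV calls
`(sample, chrom, pos, ref, alt, VAF)`. Only single-nucleotide variants
are analysed; indels and MNVs are dropped (and counted) at ingestion.
The unit of the core statistic is the **distinct genomic position**:
per position the cohort keeps the maximum VAF observed in any patient.
This matters — a driver clone present in one patient at 2% places its
position in the upper group at every swept threshold, regardless of how
much noise the position attracts elsewhere.

The repository frequency map assigns every position a non-negative
recurrence count (absent positions count 0). The rank-sum comparison is
performed on raw counts; the monotone `log2(count+1)` transform changes
ranks nowhere and is used only for display. Statistically, the sweep
asks at each threshold whether upper-group positions are exchangeable
with lower-group positions with respect to repository recurrence. No
multiple-testing correction is applied across the grid: the curve's
*shape* is the object of interest, not any single test.

### Rank-sum test

Midranks throughout. For combined group sizes up to `exact_cap`
(default 20) the permutation null of the rank-sum statistic is
enumerated exactly by a subset-sum dynamic program over doubled
midranks (doubling makes tied midranks integral), so tied data get
exact p-values too. Larger groups use the tie-corrected normal
approximation without continuity correction. All-tied inputs give
p = 1. Reported p-values are floored at 1e-300 and should be read as
"p below floor", never compared as exact tiny floats.

### Knee detection

On the tested grid points, both the threshold axis and
−log10(p) are normalised to [0, 1] and the knee is the point of
maximum perpendicular distance from the chord joining the endpoints
(the Kneedle construction); `second-diff` (maximum discrete second
difference) is available as an alternative. A curve whose maximum
chord distance is below 0.05 in normalised units is effectively
straight and the estimate is flagged low-confidence. At least four
tested points are required.

### Validation statistics

*Enrichment*: per threshold, `pct_positions_above = 100·a/A` and
`pct_set_recovered = 100·b/B` with `A` cohort positions, `a` above
threshold, `B` reference-set positions, `b` in the intersection; the
difference `100·(b/B − a/A)` is never positive at threshold 0.
Counted in **positions**.

*D/ND ratio*: deleterious over non-deleterious **calls** among missense
calls, above (VAF ≥ t) and below each threshold; unlabeled missense
calls are excluded and reported. The ratio is flagged undefined when a
side has no ND calls; `log2(ratio+1)` is the display transform. The
two statistics deliberately use different units (positions vs calls),
matching the two different questions they answer.

*Simplified dN/dS*: `(n_c / sites_c) / (n_syn / sites_syn)` for class
c ∈ {missense, nonsense, splice}, where site counts are mutation
opportunities from exhaustive enumeration of all 3L possible CDS SNVs
of the transcript model; splice opportunities are 3 per splice-window
position (±2 bp of internal exon boundaries by default, the canonical
dinucleotides). This is a Nei–Gojobori-style equal-rates estimator:
it deliberately omits trinucleotide-context covariates, per-gene
covariate regression and confidence intervals of the full
maximum-likelihood treatments, and only its qualitative behaviour
(≈1 under neutrality, >1 under positive selection) is claimed.
`se_log = sqrt(1/n_c + 1/n_syn)` gives a Poisson standard error on the
log ratio for calibration checks.

With a biased mutation spectrum, equal rates misread mutability as
selection (transitions hit synonymous sites disproportionately). The
optional 12-class correction weights each possible SNV by a relative
rate estimated from sub-floor calls (counts per substitution class
normalised by CDS sites carrying the reference base, pseudocount 0.5).
This calibrates missense and nonsense exactly under the generator's
spectrum. Splice windows are intronic and their reference bases are
outside the transcript model, so their rate-weighted opportunity uses
the mean per-site CDS rate — an approximation that can leave a
residual bias of a few percent when the splice-window base composition
deviates from the CDS; with only ~20 window positions this is a known
limitation.

### Mutation-class assignment

Splice takes precedence over coding classes; coding classes come from
codon translation on the coding strand (standard genetic code), with
genomic alleles complemented for minus-strand models. A change away
from a reference stop codon is reported as missense. Reference
mismatches inside the CDS raise immediately — silent coordinate bugs
are worse than a hard stop.

## Synthetic study conditions

The generator's defaults are the study conditions the package is
tested under, chosen once:

| parameter | default | rationale |
|---|---|---|
| samples | 96 | one amplicon plate, the exploration-cohort scale |
| noise calls/sample | 1000 (expected) | permissive 0.05% caller floor |
| caller floor | 0.0005 | 0.05% VAF |
| noise VAF law | per-site ceiling `floor + (0.006−floor)·Beta(1.2, 3.5)`, per-call `floor + (ceiling−floor)·Beta(1.5, 3)` | right-skewed sub-0.5% errors; site-to-site error heterogeneity spreads per-position max VAF over the sub-floor range instead of piling it at the support edge |
| AT>GC weight | 0.6 | Taq-like transition excess below 0.5% VAF (`None` = class-uniform) |
| drivers/sample | Poisson(1.5) | roughly half of patients carry more than one variant |
| driver VAF | log-uniform [0.5%, 50%] | subclonal through clonal |
| driver splice fraction | 0.08 | recurrent splice-site drivers exist in *TP53*-like genes |
| driver synonymous weight | 0.1 | repositories contain few, not zero, synonymous reports; keeps above-threshold dN/dS defined |
| repository law | count ∝ rank⁻¹, ranks assigned ∝ nonsynonymous opportunity | hotspot recurrence is created by selection; a class-blind assignment would let fully degenerate codon positions be hotspots, which no cancer repository shows |
| validated set | top 183 positions by count | the scale of a curated pathogenic-position set |
| labels | D at validated positions, ND elsewhere, 10% flips | an imperfect upstream classifier |

Noise is generated as an independent Bernoulli error per sample and
possible panel SNV (a caller emits at most one record per sample,
position and alt), with per-class rates solved so the expected call
count and the expected AT>GC call fraction match the configuration.
Sampling calls with replacement instead would deflate the transition
fraction after duplicate collapse, because transition calls occupy
fewer (position, alt) combinations.

What the generator does **not** emulate: homopolymer/indel error modes,
strand bias, sample-to-sample depth variation, batch effects,
genome-build mismatches between cohort and repository, and repositories
whose counts mix cancer types with different driver spectra. Passing
tests therefore demonstrate parameter recovery under the stated noise
model, not clinical performance on real Ion Torrent data.

## Problem sizes used in the test suite

Knee recovery is measured over 20 seeded 96-sample cohorts
(~1000 noise calls each, drivers floored at 0.5%): the knee must land
within ±0.15 percentage points of 0.5% in ≥90% of seeds, and 10
driver-free cohorts must yield no threshold with p ≤ 0.01 in ≥90% of
seeds. Selection statistics are read on a 288-sample class-uniform
cohort so the synonymous driver count is stable (~12 expected events
rather than ~4); the above side is evaluated at 0.65% VAF, the first
grid point clear of the 0.6% noise-VAF support, since at exactly the
driver floor the upper call group still contains noise. The spectrum
check uses ~96,000 sub-0.5% calls against binomial 99% bounds.

## Design choices where the design was open

* **Boundary convention**: the upper group is closed (max VAF ≥ t);
  configurable to open. Only exact ties move.
* **Scores in the test**: raw repository counts, not log-transformed —
  rank invariance makes the choice cosmetic, so the cheaper one wins.
* **Duplicate calls** (same sample, position, alt): the max-VAF record
  is kept and the collapse is counted and logged.
* **p-value floor** 1e-300; **exact-enumeration cap** 20 (≈184k subsets
  worst case, still instant, and comfortably past where the normal
  approximation is accurate).
* **Enrichment peak vs saturation**: with drivers spread log-uniformly
  up to 50% VAF, the enrichment-difference curve saturates at the
  driver floor rather than peaking and decaying — drivers never leave
  the upper group within the swept range. The regression test therefore
  asserts the curve reaches within 0.5 points of its maximum by the
  floor, not the location of a literal argmax drifting along a flat
  tail.
* **Determinism**: one `numpy` Generator seeded from the configuration
  drives repository, panel and cohort generation in a fixed order;
  tables are written with shortest-round-trip floats and re-read with
  the `round_trip` parser, so identical config + seed is byte-identical
  end to end.

## Known limitations

Positions are matched to the repository literally as (chrom, pos) —
genome-build reconciliation must happen upstream. The dN/dS estimator
is intentionally simple (see above) and its splice-class spectrum
correction is approximate. The knee is a grid-resolution estimate; its
uncertainty is the grid step, and a low-confidence flag, not a
confidence interval, marks near-straight curves. VCF ingestion expects
an allele-frequency FORMAT/INFO field (default `AF`) or allele depths
(`AD`); callers that encode VAF elsewhere need the field name passed
explicitly.
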