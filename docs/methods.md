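# Methods

## Survival comparison

Each screen line (a genotype carrying a miRNA overexpression or an RNAi
construct) is compared to its control by the Mantel–Cox log-rank test on
Kaplan–Meier survival; both are delegated to `lifelines`. Flies alive at
the end of the study are right-censored at their last observation day —
the transfer protocol implies no other loss to follow-up. Median
survival is the smallest time with S(t) ≤ 0.5; when survival never
reaches 0.5 the median is reported as `inf`, which still orders
correctly against any finite control median in direction
classification. Ties between death times are handled by the standard
discrete-time hypergeometric variance.

A line's direction is `shorten` when p < α and its median lies below the
control's, `extend` when above, `none` when p ≥ α, with α = 0.05
throughout. A significant result with exactly equal medians is refused
(`ambiguous direction`) rather than guessed; no such case occurs in the
bundled tables. p-values display at 4 decimals with `<0.0001` below
1e-4.

## Signed averaging (Av(χ²))

Per-line χ² values are signed: negative only for `extend` lines.
Non-significant lines keep positive sign regardless of their median
trend — the only rule consistent with every bundled signed average
(checked against the CadN, CG11206, endoB and Sirt2 rows). Labels with
two or more lines take the arithmetic mean of signed values; a label
with a single line is halved, i.e. averaged with an assumed neutral
second line of 0. TargetScan seed-family strengths are the plain mean of
member Av(χ²) values. The same operation serves miRNA strengths and
RNAi-validation strengths (Av(χ²)IR).

Internal arithmetic is unrounded; display/export rounds half-up at 4
decimals via a decimal re-quantisation of the 8-decimal representation,
so means of table-precision inputs round on their exact decimal value.
Two bundled-table caveats, recorded here because tests document them:
the bundled Ero1L average is the exact rounding tie 3.10585 and the
published table prints one final-digit ulp lower (it carried unrounded
χ² intermediates); and the published miR-92a/310/312/313/92b family
value (72.245) is not the plain mean of its five printed members
(61.9967) — plain-mean semantics are implemented and the discrepancy is
not forced to agree.

## Database ingest

Canonical TSV dialects replace the original (now defunct) web services:
`mirna gene_id gene_name transcript_id raw_score` for MicroCosm, PicTar
and microRNA.org, and `mirna_or_family gene_id gene_name site_type
conservation count` for TargetScan, tied together by a manifest JSON.
microRNA.org raw scores are negative and are squared (a positive raw
score warns but is squared anyway). TargetScan sites score conserved
8mer/7mer-m8/7mer-1A = 10/6/4 and poorly conserved = 8/4/2 points,
summed over sites. Transcript records collapsing to one gene (keyed by
CG number; the symbol is display-only) **sum** their scores by default —
consistent with the ranking step's sum-over-miRNAs phrasing — with a
`max` rule available as a sensitivity switch, since the original
procedure does not state the collapse rule. Zero-score records are
dropped on ingest: "predicted by a database" means present with nonzero
score.

## Ranking and pooling

Step 1 multiplies each gene-level score by its miRNA's Av(χ²)
(predictions for unscreened miRNAs are skipped with a warning); step 2
sums over miRNAs per gene into Σ[(Score)·Av(χ²)]. Per database, Σ is
scaled so the maximum equals 100 and then weighted by the database's
coverage fraction (miRNAs present / miRNAs screened); normalisation
precedes weighting, and both are per-database. Negative Σ values
(possible through negative family strengths) are scaled by the same
positive maximum, preserving order; a database whose maximum Σ is not
positive is refused as degenerate. Pooling sums each gene's normalised
values over databases (absent databases contribute 0); ties in the
pooled score break lexicographically by gene_id, a deterministic
convention the original procedure never adjudicates. TargetScan
families are deliberately kept as single units, underweighting grouped
miRNAs relative to databases that list members separately. The Venn
census assigns each gene to exactly one exclusive region, so region
counts sum to the union size.

## RNAi validation

Av(χ²)IR uses the averaging rules above. Categories: `confirmed_2x`
(≥2 significant lines, all shortening), `contradicted_2x` (symmetric
for extension), `partial_*` (exactly one significant line), `no_effect`
(none significant). A gene with significant lines in *both* directions
is resolved to a partial category by the larger |χ²|, with a warning —
an extension beyond the published rules, which handle such rows only
through the sign of the average (one bundled row, endoB, hits this
path). Combined scores are prediction score × Av(χ²)IR; predicting
power is their plain sum over tested genes — the false-positive sign
penalty already lives inside Av(χ²)IR. Efficiency (power / number of
predicted targets) requires the per-database predicted-target totals to
be supplied explicitly; they are not recoverable from the bundled
tables, so efficiency is config-dependent output, not a reproduced
quantity.

## Synthetic screens

The generator emulates the study conditions: 44 miRNAs, 60 flies per
group, four databases covering 31/28/43/40 of 44 miRNAs, ~5.6% of genes
predicted by all four, and a configurable number of planted essential
genes. Survival is Weibull with shape 1 by default — i.e. exponential,
chosen for closed-form medians — with baseline hazard 0.0231/day
(control median ≈ 30 days, matching the screen's typical control
medians) and censoring at 60 days; miRNA hazard ratios draw
log-uniformly from (2, 6), a range that makes most lines individually
significant at n = 60, as in the published screen. Event times are kept
continuous rather than binned to the thrice-weekly observation grid.
Each miRNA is tested with one or two lines (uniformly), exercising the
halving rule. Background prediction scores are log-normal (μ = 1,
σ = 1); planted pairs receive the 99th-percentile score, separable
ground truth without degenerate ties. Planted genes are predicted by
all four databases and targeted by 4 miRNAs each; microRNA.org raw
scores are emitted negative and TargetScan predictions as greedy
site-list decompositions of the working score. One global seed spawns
hierarchical per-stream seeds (survival, databases, RNAi), so stages
regenerate independently and byte-identically.

What the generator does **not** emulate: realistic seed-match biology,
real databases' score distributions and inter-database correlation
structure, line-to-line expression variability within a genotype, and
age-dependent (non-proportional) hazards. Passing recovery tests
therefore shows the pipeline's arithmetic and ordering behave correctly
under the stated generative model, not that the databases themselves
are accurate on real screens.

## Problem sizes and numerical choices

The analysis scripts and tests run the synthetic pipeline at 2,000
genes with 20 planted essential genes (the package's chosen desk-scale
configuration; defaults remain 10,000/20). Calibration checks use 1,000
null survival pairs at n = 60/group for the log-rank type-I rate and 5
seeded replicates for planted-gene recovery. Degenerate inputs raise
explicit errors (`no records`, `no events`, `degenerate ranking`,
`not a predicted target`) rather than returning sentinel values.
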