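# Methods

## Scope and model

`pausekit` implements the downstream quantification of RNA polymerase II
(Pol II) promoter-proximal pausing from aligned, deduplicated ChIP-seq
tags. The central quantity is the **pausing index (PI)**: the ratio of
read density (reads per bp, scaled counts) in the TSS-proximal window to
read density in the gene body. High PI indicates engaged but paused
Pol II; a PI drop on stimulation indicates pause release into productive
elongation. Cohort-level inference uses a bootstrap difference of
medians with an empirical confidence interval and a one-sided empirical
P value.

## Windows and coordinates

All internal coordinates are 0-based half-open; GTF input (1-based
inclusive) and BED input (0-based half-open) are converted at the
boundary. Windows are strand-aware — transcript offset +x lies
downstream in the direction of transcription:

| window | transcript coordinates | length |
|---|---|---|
| TSS-proximal | `[-150, +150)` about the annotated TSS | 300 bp |
| gene body | `[+250, transcript 3' end)` | transcript length − 250 |
| flank (profiles) | `[-2000, +2500)` about the TSS | 4,500 bp |

The `(−150, +150)` region is interpreted as half-open with the TSS at
offset 150; the defining study does not state the endpoint convention,
and a 1-bp shift is immaterial at these window sizes. Windows are
clipped at chromosome position 0. Gene bodies shorter than 200 bp
(transcripts under 450 bp) are flagged and excluded from pausing
statistics rather than erroring; the threshold is a robustness choice —
densities over a handful of bases are dominated by single-read noise.

## Primary transcripts and read assignment

One primary transcript per gene is selected by maximum gene-body read
density, computed from the summed scaled Pol II counts of the two
contrast conditions (using both conditions makes the choice stable for
genes silent at baseline). Ties break by greater transcript length,
then lexicographically smaller transcript id, so the selection is
deterministic.

A read contributes to a window iff its alignment interval overlaps the
window by at least 1 bp; read strand is ignored (ChIP tags are
unstranded with respect to the template). Reads overlapping the
annotated spans of more than one gene are discarded entirely. The
multi-gene rule is enforced against transcript spans, not flank
windows: upstream flanks routinely reach into neighbouring genes and
would discard excessively. Counting is exact and vectorized — for
sorted read starts `S` and ends `E`, the number of reads overlapping
`[a, b)` is `#{S < b} − #{E ≤ a}` — and is verified against an
all-pairs brute-force scan in the test suite. Fragment extension is not
performed; tags are used as aligned.

## Library scaling

Counts are linearly scaled by `min(totals) / total` per library (a
factor ≤ 1), so every library's effective depth matches the smallest
library. Scaled counts may be fractional. PIs are invariant to the
factor (numerator and denominator share it); scaling matters for the
0.05 density filter, percent occupancy changes, and cross-library
comparisons.

## Filtering, classification, contrasts

Genes must exceed a gene-body density of 0.05 reads/bp (scaled) in at
least one condition of the contrast (policy `any`, configurable to
`all`); an `all` rule would exclude genes silent at baseline, which are
precisely the inducible genes of interest. A gene is classified
**activated** (pause released) when `PI(baseline)/PI(induced) > 2` —
identical to a ≥ 50% PI reduction. An optional extra gate requiring an
increased scaled gene-body count defaults off; whether the original
analysis applied it is ambiguous, so both are available. Percent
occupancy change is `100·(B − A)/max(A, pseudocount)` with a scaled
pseudocount floor of 1 read to keep silent-gene denominators positive.

## Peak calling

The enrichment caller is a deliberately simple sliding-window method
(500-bp windows, 100-bp step), not an emulation of any particular peak
finder: per window, the expected count is the depth-matched input
count floored at the genome-wide input mean per window; a window is a
candidate at ≥ fourfold enrichment with a Poisson upper-tail P
(observed raw IP count at mean `expected/ip_scale`) significant after
Benjamini–Hochberg at FDR 0.001; adjacent candidates merge, keeping the
most significant window's statistics. Peak gating of the gene universe
is optional (default off for synthetic data): the density filter alone
can serve as the gene gate.

## Bootstrap inference

For groups A and B, each bootstrap draw resamples |A| values from A and
|B| from B with replacement (unpaired, even when genes are shared — the
procedure resamples each empirical distribution independently); the
effect is `median(A_b) − median(B_b)`. The point effect is
`median(A) − median(B)`; the CI is the (2.5, 97.5) percentile pair of
the resampled effects with linear interpolation between order
statistics; under the null of a positive effect, the one-sided
empirical P is the fraction of non-positive resampled effects, with no
+1 smoothing (a `(k+1)/(n+1)` variant is available by flag). The
default resample count is 10^5; validation tests use 2,000 to keep
runtimes reasonable, which widens Monte-Carlo error but changes nothing
structural.

Each group's index stream is seeded from the user seed plus the group's
size and ordering pattern (the permutation that sorts it), never its
values. Consequences, all tested: identical seeds give bit-identical
results; adding a constant to a group shifts effect and CI bounds by
exactly that constant (to float rounding); swapping the groups exactly
negates the effect distribution, mirroring CI and P. One corner case:
if both groups have the same length *and* the same ordering pattern,
their index streams coincide and the resamples are coupled; this does
not arise for distinct per-gene metrics in annotation order, and for
degenerate constant inputs it yields the expected zero-width interval.

## Synthetic data generator

The generator is the test bed standing in for a real serum-induction
dataset. Per gene it draws Poisson read counts and places read anchors:
a truncated-normal paused peak centred 50 bp downstream of the TSS
(SD 30 bp) confined to the TSS-proximal window, a uniform gene-body
component, and uniform genome background. Conditions: `S0` baseline;
`S15` multiplies the body rate by the gene's release factor; and
`S15+inhibitor` blocks release (body rate stays at baseline) while
multiplying the TSS component by a retention factor of 1.3, emulating
Pol II accumulating at the TSS when release is pharmacologically
blocked — a fixture parameter, not a claim about the biology's
magnitude. DDR/elongation marks (γH2AX-like, S2 Pol II-like) carry only
the body-proportional component and are confined by construction to
transcript offsets `[-150, tx_length)`, reproducing the observation
that activation-coupled γH2AX stays within transcribed units. The input
mark is background only.

Default study conditions: 200 genes on one synthetic chromosome with
10-kb gaps, half activated at release factor 3, body rates uniform in
0.2–0.5 reads/bp, baseline expected PIs uniform in 2–8
(`lambda_tss = PI · 300 · lambda_body`), read length 36, background
0.1 reads/bp for the input library (giving it a depth comparable to the
IP libraries, as in a matched sequencing design) and 10% of that rate
inside IP libraries; library depth factors vary over 0.6–1.0 so that
scaling is always exercised. Expected densities and PIs are available
in closed form (`expected_pausing_index`), making parameter-recovery
tests exact up to sampling error.

What the generator does *not* emulate: mappability and sequence
content, fragment-length distributions, overlapping genes (available
only as a dedicated fixture), copy-number or chromatin-accessibility
structure in the input, and biological between-replicate variability.
Passing tests therefore demonstrate correctness of the quantification
and inference machinery under the generative model, not robustness to
every artefact of real ChIP-seq.

## Problem sizes in the validation suite

The bundled tests run a 60-gene three-condition dataset for pipeline
checks, a 200-gene panel for parameter recovery (sensitivity ≥ 0.9,
FPR ≤ 0.05 at the twofold threshold), 50 replicate libraries for PI
unbiasedness against the closed form, 500 replicates at n_boot = 2,000
for CI coverage, and 20-seed null simulations for the peak caller's FDR
bound. `scripts/acceptance.py` regenerates the default 200-gene
dataset, runs both the control and release-blocked contrasts at
n_boot = 10^5, and reports the headline numbers.

## Known limitations

* The peak caller is a minimal method suitable for strong, broad
  enrichment; it performs no local background estimation and will be
  anticonservative where input coverage is locally structured.
* PI is undefined at zero body density; everything downstream of the
  filter assumes the 0.05 gate has been applied.
* The bootstrap treats genes as exchangeable and ignores gene-gene
  correlation; reported CIs are conditional on the observed cohort.
* BAM input is supported but the BAM path treats each primary alignment
  as a tag; no mapping-quality filtering is applied (assumed upstream).
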