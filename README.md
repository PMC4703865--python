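# pausekit

Downstream analysis of RNA polymerase II (Pol II) promoter-proximal
pausing from ChIP-seq. Stimulus-inducible genes hold an engaged Pol II
just downstream of the transcription start site (TSS); on induction the
polymerase is released into the gene body. `pausekit` quantifies that
transition from aligned, deduplicated ChIP-seq tags (BED or BAM) and a
GTF annotation, for anyone comparing Pol II (or elongation-coupled
marks such as γH2AX or Ser2-phosphorylated Pol II) between conditions.

The core statistic is the **pausing index**

```
PI(g) = density_TSS(g) / density_body(g)
```

with the TSS-proximal window `[TSS−150, TSS+150)` and the gene body
`[TSS+250, transcript 3′ end)`, densities in reads/bp after linear
scaling of every library to the depth of the smallest one. A gene is
**activated** (pause released) in a baseline-vs-induced contrast when
`PI_baseline / PI_induced > 2`, i.e. the PI drops by at least 50%,
among genes whose body density exceeds 0.05 reads/bp. Cohort effects
are reported as bootstrap differences of medians with a centred 95%
empirical CI and a one-sided empirical P (fraction of resampled effects
crossing zero).

The package also provides a simple Poisson sliding-window peak caller
(fourfold enrichment over matched input, Benjamini–Hochberg FDR 0.001)
for optional gene gating, TSS-centred profile matrices, bedGraph track
export, and a synthetic-data generator with closed-form expected
densities and PIs that serves as the ground truth for every validation
test.

## Worked example

Generate a synthetic serum-induction dataset (200 genes, half of them
released threefold on induction) and run the full contrast:

```
pausekit make-fixtures --outdir data --n-genes 200 --seed 2
pausekit run --sheet data/libraries.tsv --gtf data/annotation.gtf \
    --baseline S0 --induced S15 --marks PolII,gH2AX \
    --n-boot 100000 --seed 1 --outdir report
```

which prints

```
200 genes, 200 pass filter, 100 activated; report under report
```

meaning: all 200 simulated genes exceeded the 0.05 body-density filter,
and exactly the 100 genes simulated with a threefold release factor
crossed the twofold PI-decrease threshold. `report/genes.tsv` holds the
per-gene table (densities, PIs per condition, PI ratio, TSS/body
percent changes, flags); `report/cohort_stats.json` holds the bootstrap
effects — for this run the activated set shows a median PI ratio near 3
(the simulated release factor) with a tight CI excluding 1, a positive
median gene-body occupancy change, and a positive γH2AX gene-body
change tracking the released polymerase.

The same steps are available as library calls (`pausekit.simulate_contrast`,
`pausekit.run_contrast`) and as stagewise subcommands (`quantify`,
`pause-index`, `contrast`, `bootstrap`, `profile`).

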