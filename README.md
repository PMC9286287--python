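# rhythmdiff

Differential circadian rhythmicity analysis for around-the-clock bulk
transcriptomes.

Circadian experiments commonly profile a tissue every 3 h across one
12:12 light–dark cycle in two conditions (genotypes, sexes, diets) and
ask not just *which genes cycle*, but *how cycling differs*: which
genes gain or lose a rhythm, which keep their rhythm but shift its peak
time, and how the population of peak phases moves around the clock.
`rhythmdiff` packages that analysis end to end for gene × sample
abundance tables (FPKM-like), together with a ground-truthed simulator
so every stage is verifiable without any external dataset.

## What it computes

- **Rhythm detection** (per condition): a JTK-style rank test. Each
  gene is compared to cosine references on the period grid {21, 24, 27} h
  (multiples of the 3 h sampling interval within 20–28 h) at all
  peak lags, via Kendall's S with an **exact** permutation null
  (Harding-type convolution over the reference's tie structure).
  Single-cycle series are optionally concatenated to 48 h, the
  standard trick to cut the rank test's false negatives on 8-point
  profiles. Outputs: exact p, within-gene Bonferroni adjP, BH q across
  genes, best period, peak lag (ZT), τ.
- **Rhythm comparison** (between conditions): fixed-24 h cosinor
  y = M + a·cos ωt + b·sin ωt per gene; H0: (a, b) equal in both
  conditions, tested by a nested-model F-test and by a Huber-robust
  Wald test, Fisher-combined into `meta_p`.
- **Classification**: an ordered decision table assigns each gene one
  of *rhythmic-both unchanged / phase change (|Δφ| > 6 h) / other
  difference / gained / lost / unclassified*, using thresholds
  adjP < 0.05 (primary) and < 0.1 (secondary), meta p at 0.01, phase at
  6 h — thresholds, inequality orientation and input column are all
  configurable data, not code.
- **Circular statistics**: mean vector (population peak time and
  resultant length R), Rayleigh uniformity test, dispersion-based 95%
  CI of the mean direction, 3 h-bin phase histograms, polar plots, and
  an exact rhythmic-gene enrichment test against a 16% background
  expectation.
- **Simulation**: cosinor profiles m·(1 + A·cos(2π(t − φ)/24)) with
  per-gene category truth (arrhythmic, unchanged, 12 h phase-flip,
  gained-at-ZT6, lost), night-peaking reference phases (von Mises
  around ZT20.5), pooled samples (mean of 3 noisy animals), log-normal
  or negative-binomial noise, bit-reproducible per-gene seed streams.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Simulate the default two-condition study (2000 genes, 8 × 3 h
timepoints, pools of 3) and run the whole pipeline:

```python
from rhythmdiff.pipeline import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(seed=0, outdir="demo_out"))
print(bundle["counts"])
```

```
category
rhythmic_both_unchanged            365
rhythmic_both_phase_change         219
rhythmic_both_other_difference      59
gained_in_g1_only                  151
lost_in_g1                          81
unclassified                      1125
```

The simulation programmed 400 unchanged, 200 phase-shifted, 140 gained,
60 lost and 1200 arrhythmic genes, so the counts above recover each
category with modest spill-over (the surplus "gained" calls are
arrhythmic genes whose duplicated-cycle rank test flukes past the
permissive 0.1 cutoff in one condition — the known cost of
concatenation). The circular summaries (`demo_out/summary_g1.tsv`) show
the programmed phase structure in the test condition:

```
category                   n   mean_phase_h      R     rayleigh_p   ci95
gained_in_g1_only        151           5.66  0.680        1.1e-29   [5.20, 6.13]
rhythmic_both_unchanged  365          20.41  0.643        2.3e-64   [20.01, 20.80]
rhythmic_both_phase_change 219         8.34  0.648        4.2e-39   [7.87, 8.82]
```

Gained rhythms cluster at mid-day (ZT ~6), the shared rhythmic core
peaks at night (ZT ~20.4), and the 12 h-flipped genes peak ~8 — all as
programmed. Every output TSV plus a manifest (config echo, seed,
SHA-256 per file) lands in `demo_out/`; rerunning with the same seed
reproduces the files byte-identically.

The same workflow is available from the shell:

```sh
rhythmdiff simulate --n-genes 2000 --seed 0 --outdir demo
rhythmdiff detect  --input demo/expression.tsv --group KO --output rhythm_KO.tsv
rhythmdiff compare --input demo/expression.tsv --group-a WT --group-b KO --output cmp.tsv
rhythmdiff run     --seed 0 --outdir demo_out
```

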