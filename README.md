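# tufscan

Wave correction of SNP-array intensities and detection of
denaturation-resistant ("Thermodynamically Ultra-Fastened", TUF) genome
regions.

## The problem

Short sequence elements of extreme C+G content can stay duplexed even under
aggressive melting conditions. An un-melted element anchors its melted
flanks, which re-anneal almost instantly when non-denaturing conditions
return, so primers and probes never gain access: amplification efficiency is
suppressed across a whole domain, not just inside the GC-rich element. On
genotyping arrays this shows up as *weak Illumina signal* regions — runs of
probes whose log R ratio (LRR) drops to an apparent copy-number-one level,
concordantly across the worst-performing samples. Because the suppression
requires an intact physical link between probe target and element, the
effect is strongest for freshly prepared, un-nicked DNA and disappears when
the template is fragmented (restriction digestion, sonication) — an unusual
situation in which *higher*-quality DNA gives worse data.

`tufscan` is aimed at analysts of array CNV/genotyping intensity data and at
assay designers who need to know whether a target amplicon sits in a TUF
domain and which pre-treatment will rescue it.

## The model

Per-sample wave correction regresses each sample's LRR on centered
polynomial GC and CpG content terms at multiple window scales *w* plus
within-chip stratum offsets:

    LRR_i = b0 + sum_w sum_p  b_GC(w,p) (g_wi - mean g_w)^p
               + sum_w sum_p  b_CpG(w,p) (c_wi - mean c_w)^p
               + gamma_strip(i) + e_i

fit by OLS after quantile normalization across samples. Per-term Z scores
(coefficient/SE) classify samples as extreme-positive, extreme-negative or
null (classical threshold |Z| > 30); the corrected LRR is the re-centered
residual.

The mechanistic suppression model ties the intensity deficit of probe *i* to
its distance d_i from the nearest intact high-GC element:

    delta_i = A * exp(-rho * d_i),      d_i <= D_max

where `rho` (nicks/bp) is the sample's nick density: exp(-rho d) is the
probability that no single-strand break falls between probe and element, so
the probe remains tethered. Fitting this decay yields per-sample estimates
(A-hat, rho-hat). A paralogue ratio test (PRT) readout follows the same law,
`ratio = R_eq (1 - min(A,1) exp(-rho d))`, reaching the equal-efficiency
ratio R_eq = 1.43 when the target is physically separated from the element.

A fully ground-truthed synthetic cohort generator (54 samples: 24
extreme-positive / 19 extreme-negative / 11 null by default) embodies the
model end to end and drives every test.

## Worked example

```python
from tufscan import (SimulationConfig, simulate_study, quantile_normalize,
                     WaveCorrector, classify_extreme_samples,
                     variance_report, table2_report)

cfg = SimulationConfig(seed=11)          # the default study: 2 Mb, 54 samples
study = simulate_study(cfg)
qn = quantile_normalize(study["intensity"].lrr)
wc = WaveCorrector(study["content"], strata=study["intensity"].strata,
                   degree=2).fit(qn)

print(variance_report(wc.models_).head(3).round(4).to_string(index=False))
labels = classify_extreme_samples(wc.models_, z_threshold=30)
print(labels.groupby("label", sort=False).size().to_string())
print(table2_report(wc.models_, study["prt"]).round(4).to_string())
```

prints

```
sample_id  variance_pre  variance_post  variance_ratio  prop_variance_explained
     s001          0.05         0.0112          0.2233                   0.7767
     s002          0.05         0.0108          0.2165                   0.7835
     s003          0.05         0.0109          0.2190                   0.7810
label
positive    24
negative    19
null        11
               GC                  CpG
        pearson_p spearman_p pearson_p spearman_p
window
1000000    0.0000     0.0000    0.0000     0.0000
...
100        0.0000     0.0000    0.0156     0.0625
50         0.0010     0.0006    0.1709     0.3597
```

Wave correction removes ~78% of the LRR variance of the affected samples
(`variance_ratio` ≈ 0.22), the max-|Z| classifier recovers the planted
24/19/11 class mix exactly, and the association table links per-sample wave
Z scores to PRT ratios: the planted 100 bp GC wave cell is strongly
significant, and the distance-decay suppression — itself a GC-correlated
effect — produces the additional large-window signal.

A command-line interface mirrors the library
(`tufscan simulate|content|correct|detect|associate|advise|run`); `tufscan
run --config cfg.yaml --outdir out --seed 1` executes the whole pipeline and
writes TSV/BED outputs plus a run manifest with checksums.

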