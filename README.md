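# periglioma

Analysis pipeline relating non-invasively measured brain activity to
radiological glioma growth, with a fully ground-truthed synthetic
cohort generator for end-to-end validation.

Diffuse glioma grows faster where surrounding cortex is more active:
peritumoral neuronal spiking and glutamatergic neurogliomal synapses
accelerate proliferation. This package implements the analysis that
tests whether *non-invasive* proxies of that activity — spectral
measures of source-reconstructed MEG — track radiological tumor growth
on routine MRI and progression-free survival. It is aimed at clinical
neurophysiology / neuro-oncology researchers who have regional brain
time-series and longitudinal tumor-volume tables, and at methodologists
who want a reproducible, simulatable version of the whole pipeline.

## The measures and models

For each subject, regional time-series (78 cortical regions by
default, arbitrary units) are split into 13.1 s epochs; the first ten
artifact-free epochs (or, alternatively, the ten epochs with the
largest 4–13 Hz peak) are selected. Per region, Welch spectra (Hamming
window) are averaged across the selected epochs, and three measures are
computed on the averaged spectrum:

* **broadband power** — the area under the power spectral density
  between 0.5 and 48 Hz;
* **offset** `b` and **slope** `χ` of the aperiodic component, from a
  peak-robust fit of

  `L(F) = b − log10(k + F^χ)`

  in log-power space, with the knee `k` fixed at 0 by default. The
  offset is a proxy for population spiking rate, the slope for the
  excitation/inhibition balance.

Measures are summarized globally, per hemisphere, over ten peritumoral
locations within 3 cm of the tumor rim, and over their mirror-image
contralateral homologues; peritumoral values are normalized by the
contralateral ones (element-wise ratio) to cancel pre-existing regional
differences.

Tumor growth is classified from the two MRIs surrounding the MEG:
volume changes < 1 ml are **stable**, > 5 ml **increasing**, and
changes between 1 and 5 ml are resolved by the next follow-up scan
(transient rises that settle — pseudoprogression — count as stable).

The statistical layer mirrors the clinical analysis: Spearman
correlations of activity with volume change, Mann–Whitney comparisons
between growth classes and against healthy controls, paired Wilcoxon
tests of peritumoral vs contralateral activity (with Cohen's D),
Benjamini–Hochberg FDR per test family, control-referenced z-scores,
multivariate Cox proportional-hazards models (age and WHO grade as
covariates) and Kaplan–Meier median splits.

The synthetic cohort generator produces all of the above with known
ground truth: 1/f^χ backgrounds with an alpha bump (spectrally shaped
Gaussian noise), injected high-amplitude artifacts, stable/increasing/
pseudoprogression volume trajectories, and proportional-hazards
progression times.

## Worked example

```bash
python examples/spectral_measures.py
```

prints

```
broadband power (0.5-48 Hz AUC): 50.31 a.u.^2
offset: true 1.20  fitted 1.224
slope:  true 1.40  fitted 1.414
15 spectral points flagged as the alpha peak and excluded from the aperiodic fit
```

— a single region synthesized with offset 1.2 and slope 1.4 plus a
strong 10 Hz alpha bump is epoched, averaged and fitted; the two-pass
fit excludes the alpha points and recovers both aperiodic parameters to
within a few hundredths. The other scripts in `examples/` walk through
cohort simulation, growth classification, peritumoral normalization
(paired Wilcoxon `W=13, p=0.0425`, effect size `D=0.65` on twelve
simulated patients) and survival analysis (a simulated hazard ratio of
2.0 per SD of activity recovered as `HR=1.79, 95% CI 1.55–2.08`).

A full run — simulate, analyze, write every table plus a markdown
report — is one command:

```bash
periglioma run --config examples/config.yaml --out results --seed 1
# or: periglioma simulate ... / periglioma analyze ... / periglioma report ...
```

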