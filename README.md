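# finclick

Detection and context modelling of **narrow-band high-frequency (NBHF)
echolocation clicks** of Yangtze finless porpoises
(*Neophocaena asiaeorientalis asiaeorientalis*) in captive settings.

Porpoises produce essentially one sound type — ultrasonic clicks with
peak frequencies between 87 and 145 kHz — so their per-minute click
count ("click density") is both a monitoring signal for welfare in
captivity and the raw material of wild population surveys. This package
implements, as a tested Python library:

1. **a click detector** for 576 kHz recordings: Kaiser-window FIR
   high-pass (β = 0.5, 80 kHz cut-off) → STFT (window 512, noverlap 256,
   nfft 512) → SVM classification of frame spectra → click events,
   per-minute click density, and click-train segmentation (≥5 clicks,
   inter-click intervals ≤ 200 ms);
2. **a context model** for the resulting counts: a Poisson GLMM with
   log link,

   `log μ = log(n_individuals) + Xβ + u_date + v_session + ε_minute`,

   i.e. an individuals offset, reference-coded context predictors
   (season, time of day, training, social grouping, enrichment split
   into four indicators, unusual events, visitors), crossed random
   intercepts for date and session, and an observation-level intercept
   correcting overdispersion — with VIF screening, AIC model selection,
   Wald χ² tests, Holm (sequential-Bonferroni) pairwise contrasts and
   percent-change reporting `100·(exp(β) − 1)`;
3. **a synthetic-data layer** that generates ground-truthed NBHF
   recordings (Gaussian-enveloped clicks in trains over noise, optional
   pool-echo model) and minute-count tables with exactly the model's
   statistical structure, so everything above is testable without any
   field data.

The GLMM estimator (Laplace approximation, bounded derivative-free
optimisation of the variance parameters) is written in-package and is
cross-checked in the test suite against `lme4::glmer` and against the
Poisson-GLM limit.

## Worked example

```python
from finclick.simulate import study_mimic_scenario, generate_minute_counts
from finclick.context import fit_context_model, percent_change

counts, annotations = generate_minute_counts(study_mimic_scenario(seed=7))
fit = fit_context_model(counts, annotations)   # ~15 s for 6480 minutes
print(round(percent_change(float(fit.coef["grouping[separated]"])), 1))
print(round(percent_change(float(fit.coef["training[during]"])), 1))
```

prints

```
138.0
313.8
```

— porpoises in this simulated study produce 138% more clicks per minute
when socially separated and 314% more during training/feeding sessions,
recovering the planted multipliers (×2.36 and ×4.12) from raw counts.
The `examples/` scripts walk through each capability — simulation
(`01`), detection on rendered audio (`02`, detects ~94% of planted
clicks at 15–25 dB SNR), classifier cross-validation (`03`, prints
`mean 5-fold CV accuracy: 100.00%` on the 2000-spectrum augmented set),
and the full context model with Wald tests (`04`).

A thin CLI wraps the same stages:

```bash
finclick simulate    --seed 1 --out-dir results/
finclick train-model --seed 1 --out-dir results/
finclick detect      --in results/recording.wav --model results/model.bin --out-dir results/
finclick analyze     --counts results/counts.csv --context results/annotations.csv --out-dir results/
```

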