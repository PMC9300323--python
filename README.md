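# midecode

Two-class motor-imagery EEG decoding for brain–computer interface (BCI)
research, plus the within-subject statistics of a transcranial-stimulation
study of motor-imagery accuracy.

Imagining a left- versus right-hand movement attenuates the sensorimotor
mu rhythm (~10 Hz) contralaterally — event-related desynchronization
(ERD).  `midecode` implements the classical decoding chain that exploits
this effect, for researchers who want a small, fully tested, end-to-end
reference pipeline:

1. **Band selection** — per-frequency discriminability
   r² = [ √(N₁N₂)/(N₁+N₂) · (mean P₁ − mean P₂) / std(P₁∪P₂) ]²,
   the squared point-biserial correlation between class label and per-trial
   band power; the filter band is the window of maximal mean r².
2. **Zero-phase band-pass filtering** (order-4 Butterworth,
   forward–backward).
3. **Common Spatial Patterns (CSP)** — with trace-normalized trial
   covariances R = XXᵀ/tr(XXᵀ), whitening P = λ^(−1/2)Uᵀ of the composite
   covariance R̄₁+R̄₂ = UλUᵀ, and projection W = BᵀP from
   P R̄₁ Pᵀ = B D Bᵀ; features are normalized variances
   fᵢ = var(Zᵢ)/Σⱼ var(Zⱼ) of the top/bottom filtered components.
4. **Fisher LDA** — closed form w ∝ (Σ₀+Σ₁)⁻¹(μ₀−μ₁) with the midpoint
   threshold wᵀ(μ₀+μ₁)/2.
5. **Repeated stratified cross-validation** with all fitting (band
   selection included) inside each fold.

Because the study's recordings were never released, the package ships a
**synthetic generator** with a known forward model X = AS + E that plants
ERD as a pure variance change, so every stage can be validated by parameter
recovery; and a **study-statistics module** that embeds the published
9-subject × 4-condition accuracy table and reproduces its summaries and
one-way repeated-measures ANOVA.

## Worked example

```python
from midecode import (PipelineConfig, SynthConfig, generate_mi_dataset,
                      run_pipeline, load_table3, rm_anova)

data, forward = generate_mi_dataset(
    SynthConfig(n_trials_per_class=100, erd_depth=0.8, noise_sd=0.1, seed=3))
result = run_pipeline(data, PipelineConfig(band="auto", cv_folds=5,
                                           cv_repeats=5, seed=3))
print(f"mean held-out accuracy: {result.accuracy_mean:.2f}%")
print(f"band used: {result.band_used[0]:.1f}-{result.band_used[1]:.1f} Hz")

res = rm_anova(load_table3())
print(f"F({res.df_between}, {res.df_error}) = {res.F:.3f}, p = {res.p:.2g}")
```

prints

```
mean held-out accuracy: 100.00%
band used: 7.8-11.8 Hz
F(3, 24) = 10.436, p = 0.00014
```

The planted ERD (depth 0.8, i.e. an 80% mu-power drop in the active class's
source) is large enough that the auto-selected band covers the 10 Hz mu
rhythm and the decoder separates the classes perfectly; the ANOVA line is
the published condition effect recomputed from the embedded table: the
stimulation condition significantly changes motor-imagery accuracy.

The `examples/` directory has one narrative script per capability
(simulation, band selection, CSP+LDA decoding, study statistics); each
prints its numbers with a note on what they mean.  A thin CLI mirrors the
library: `midecode simulate | r2-spectrum | evaluate | reproduce-stats`.
Datasets round-trip through a plain CSV bundle (lossless) or EDF (16-bit
quantized).

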