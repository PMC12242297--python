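# isocod

Bayesian errors-in-variables analysis of amino-acid nitrogen isotopes
(δ¹⁵N) in archaeological cod bone.

## The problem

Nitrogen isotopes in bone collagen record where an animal fed in its food
web, but three things confound their use as a long-term trophic archive
for archaeological fish: the δ¹⁵N baseline at the bottom of the food web
drifts in space and time, trophic level rises with fish size
(ontogenetic diet shift), and archaeological specimens carry wide,
stratigraphy-derived dating windows rather than point dates.
Compound-specific amino-acid measurements separate the first confound —
"trophic" amino acids (Glx, Ala, Asx, Pro, Val, Leu, Ile) enrich at each
trophic transfer while "source" amino acids (Phe, Lys) pass the baseline
through almost unchanged — so the difference Δ¹⁵N_Glx-Phe isolates the
trophic signal. The remaining two confounds are statistical, and this
package models them explicitly.

`isocod` provides, as a tested reusable pipeline:

* **osteometrics** — estimated total length (ETL) and its uncertainty
  from quadratic regressions of bone measurements on a modern reference
  collection, with normal priors fitted to relative size classes
  ("800−1000 mm") as the fallback;
* **qc** — atomic C:N screening (acceptable window [3.0, 3.6]),
  per-batch linear calibration of raw δ¹⁵N against reference standards,
  mass-balance reconstruction of bulk δ¹⁵N from the amino-acid values
  and their nitrogen fractions, and a 2σ estimated-vs-observed exclusion
  filter;
* **descriptives** — pairwise Pearson correlations with significance
  tests and correlation-matrix PCA of the amino-acid values;
* **trend** — the core inference (below), plus the trophic-position
  transform and posterior dating refinement;
* **synthetic** — a generator of synthetic assemblages with known ground
  truth, used by the recovery and calibration tests.

## The model

For a response `Y` (an amino-acid δ¹⁵N or a trophic-source difference,
in ‰), observed with known machine sd `η_i`:

    Y_i = s(t_i) + β₁ Z_i + η_i + ε_i,        ε_i ~ N(0, σ²)
    Z_i ~ N(x̄_i, σ²_{x,i})                    (latent true size)
    t_i ~ U(t0_i, t1_i)                        (latent true date)

`s` is either a penalized cubic B-spline (P-spline, second-order
difference penalty) or the linear form `α + β₀ t`. Latent sizes are
marginalized exactly into the observation variance; for the linear model
the uniform latent date also integrates in closed form, and for the
spline model the coefficients are conjugate Gaussian given the smoothing
parameter. The remaining ≤ 4 hyperparameters are sampled with an
affine-invariant ensemble sampler run as several independent ensembles
(R̂ / effective-sample-size diagnostics via ArviZ), and exact conditional
draws of the latent dates, sizes and spline coefficients are
reconstructed per posterior draw. For the spline model the dates are
fixed by an imputation strategy instead of sampled; a sensitivity
routine refits under midpoint / window-edge / random imputations and
flags trends that move beyond their own credible band.

Trophic position is obtained from a trophic-source offset `Y` by

    TP = (Y − 2.9) / TEF + 1,      TEF ~ N(6.6, 1.7) truncated at 0,

with one TEF draw per posterior draw, so TEF uncertainty propagates into
the TP band.

## Worked example

```python
import numpy as np
from isocod import (SynthConfig, TrendConfig, generate_assemblage,
                    fit_linear_eiv, refine_dating, predict_trend)

synth = SynthConfig(trend=("linear", {"slope": 0.01, "level": 19.4}), seed=42)
records, truth = generate_assemblage(synth)          # 150 bones, 500-2000 CE
fit = fit_linear_eiv(records, TrendConfig(seed=42))  # latent dates + sizes
b0 = fit.posterior["beta0"]
print(f"slope: {100*b0.mean():.2f} "
      f"[{100*np.quantile(b0,0.025):.2f}, {100*np.quantile(b0,0.975):.2f}] permil/century")
print(f"median sharpening: {refine_dating(fit).sharpening.median():.2f}")
print(predict_trend(fit, np.array([600.0, 1250.0, 1900.0])).frame.round(2))
```

prints

```
slope: 0.97 [0.92, 1.01] permil/century
median sharpening: 0.88
     t  mean  q2_5  q97_5  extrapolated  tp_mean  tp_q2_5  tp_q97_5
 600.0 13.13 12.80  13.44         False     2.69     2.02      4.29
1250.0 19.41 19.23  19.58         False     3.73     2.65      6.26
1900.0 25.69 25.35  26.01         False     4.76     3.28      8.24
```

The synthetic truth here is a 0.01 ‰/yr (1 ‰/century) rise in
Δ¹⁵N_Glx-Phe: the posterior interval covers it despite ±100-year dating
windows and noisy size priors. The sharpening ratio below 1 shows the
fitted trend feeding information back into the specimen dates, and the
`tp_*` columns give the trend re-expressed as trophic position with TEF
prior uncertainty included.

A command-line interface mirrors the library
(`isocod simulate | qc | size | describe | fit | predict | pipeline | report`);
`isocod pipeline --seed 7 --outdir out/` runs simulate → QC → size →
descriptives → model end to end and writes a hash manifest of every
artifact.

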