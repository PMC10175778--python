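# dwihist

Multi-model analysis of multi-b-value diffusion-weighted breast MRI:
voxel-wise model fitting, first-order ROI histogram radiomics, and the
cohort-level biomarker statistics used to relate diffusion parameters to
molecular prognostic factors (ER, PR, HER2, Ki-67, nodal status) and
molecular subtypes (Luminal, HER2-positive, triple-negative) of breast
cancer. Because no public dataset accompanies this study design, the
package ships a first-class synthetic lesion-cohort generator (Rician
magnitude noise, realistic group parameter distributions, screening
exclusions, morphology labels) on which the whole pipeline is exercised
and tested.

Audience: researchers in quantitative MRI / radiomics who want a tested,
reproducible reference implementation of the standard mono-exponential /
IVIM / DKI histogram-analysis battery, or a phantom framework to probe
its statistical behaviour.

## Models

For a voxel with unweighted signal S₀ and diffusion weighting b (s/mm²):

- **Mono-exponential** — S(b)/S₀ = exp(−b·ADC), fitted in closed form
  from b ∈ {0, 800};
- **IVIM** (intravoxel incoherent motion) —
  S(b)/S₀ = (1−f)·exp(−b·D) + f·exp(−b·(D\*+D)), fitted on
  b ∈ {0, 50, 100, 200, 400} by segmented initialization followed by
  joint bounded least squares;
- **DKI** (diffusion kurtosis) —
  ln S(b)/S₀ = −b·D<sub>app</sub> + (1/6)·b²·D<sub>app</sub>²·K<sub>app</sub>,
  fitted on all eight b-values (0–2000) in log-signal space.

Each ROI map (ADC, D, D\*, f, D<sub>app</sub>, K<sub>app</sub>) is
summarized by six first-order histogram metrics (mean, median, 25th/75th
percentile, skewness, non-excess kurtosis), giving 36 features per
lesion. The statistics stage runs Lilliefors normality screening,
Mann–Whitney group comparisons and Spearman correlations for eight
binary contrasts at α = 0.05/8, per-metric ROC analysis, logistic-
regression combination of the best metric per parameter into single- and
three-model scores with DeLong AUC comparisons, chi-squared contingency
analysis of DWI morphology codes, and two-reader ICC agreement.

## Worked example

Fit the kurtosis model to one noisy voxel generated at
D<sub>app</sub> = 1.2×10⁻³ mm²/s, K<sub>app</sub> = 0.9:

```python
import numpy as np
from dwihist import DiffusionKurtosisModel, dki_signal, FULL_SCHEME
from dwihist.phantom import rician

rng = np.random.default_rng(0)
clean = 1000 * dki_signal(1.2e-3, 0.9, FULL_SCHEME)   # Dapp, Kapp
noisy = rician(clean, sigma=1000 / 80, rng=rng)        # SNR 80 magnitude noise
res = DiffusionKurtosisModel(noisy).fit()
print(res.summary())
```

prints

```
DiffusionKurtosisModel fit
----------------------------------
    Dapp:  1.184 x1e-3 mm^2/s
    Kapp:  0.94985
     RSS: 8.696e-04  converged=True  n=8
```

i.e. at SNR 80 a single voxel recovers the generating diffusivity within
~1.3% and the kurtosis within ~5.5%; averaging over an ROI tightens this
further. The full pipeline runs from the command line:

```
dwihist all --seed 1 --n-lesions 8 --snr 50 --out run
# -> all: 129 files under run
```

which simulates the cohort (with its screening-exclusion audit), writes
per-lesion DWI volumes as NIfTI with FSL-style `.bval` sidecars, fits
the six parameter maps, and emits the metrics table, the group-
comparison / AUC / contingency / ICC analysis tables (CSV + JSON), a
fitted-vs-truth recovery report and a file manifest. Individual stages
(`simulate`, `fit`, `summarize`, `analyze`, `report`) can be re-run
separately on the same output directory.

## Layout

- `src/dwihist/schemes.py` — b-value schemes and bval sidecars
- `src/dwihist/models.py` — forward models and Model/Results fitting classes
- `src/dwihist/phantom.py` — synthetic cohorts, masks, truth fields, noise
- `src/dwihist/histogram.py` — first-order ROI metrics
- `src/dwihist/stats.py` — the statistical battery
- `src/dwihist/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — modelling assumptions, conventions, limitations
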