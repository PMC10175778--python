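# Methods notes

## Signal models and fitting

All diffusivities are carried internally in mm²/s and reported on the
conventional 10⁻³ mm²/s scale (tumour ADC ≈ 0.8–1.0 on that scale).
The three fitted models are nested descriptions of the normalized decay
S(b)/S₀:

| model | b-values (s/mm²) | estimator |
|---|---|---|
| mono-exponential | 0, 800 | closed form, ADC = −ln(S₈₀₀/S₀)/800, clipped at 0 |
| IVIM bi-exponential | 0–400 (5 shells) | segmented init + joint bounded NLLS, linear signal space |
| diffusion kurtosis | 0–2000 (8 shells) | linear least squares on ln S (the expansion is linear in D_app and D_app²·K_app), bounded refit only if the box is violated |

Fit boxes bracket the observed tumour ranges with ≥3× headroom:
D_app ∈ [0, 5×10⁻³] mm²/s, K_app ∈ [0, 5]; D ∈ [0, 3×10⁻³],
D\* ∈ [0, 0.1] mm²/s, f ∈ [0, 1]. The IVIM segmented stage fits
log-linearly over b ∈ {200, 400} (where pseudo-diffusion has decayed)
for D₀, reads f₀ off the extrapolated b=0 intercept, finds D\*₀ by a
bounded one-dimensional search, then refines all three jointly. When f
collapses to 0, D\* is unidentifiable: it is reported at its
initialization value and flagged (`dstar_identifiable=False`), and such
voxels are excluded from D\* histograms. Non-positive signals flag a
voxel unfittable rather than being clipped; flagged voxels are dropped
from histogram input per map.

Fitting each model in log- vs linear-signal space follows its noise
structure: the kurtosis expansion is exactly linear in log space, while
the IVIM perfusion term is additive in linear space.

Known estimator behaviour, characterized in the test suite:

- Mono-ADC and D_app are stable under magnitude noise: at SNR 50 the
  Monte-Carlo mean over 10⁴ voxels stays within 3% of truth.
- The joint IVIM fit on five low-b points is consistent (bias < 1% at
  SNR 1000) but at clinical SNR it trades D downward against an
  inflated perfusion fraction (at SNR 50, D ≈ −30% and f ≈ 0.23 for a
  true f of 0.06). This is the well-documented pathology of joint
  bi-exponential fitting at modest SNR and is why per-lesion medians,
  not single voxels, are the unit of analysis downstream.

## Synthetic cohort generator

The generator emulates the cohort structure the analysis assumes; it is
the package's own construction, not a reconstruction of any real data.

- **Cohort**: a screened pool (default 216) with multinomial molecular
  subtypes (Luminal A/B, HER2-positive, TN at 45:41:25:32), receptor
  statuses drawn consistently with the subtype definitions, nodal and
  Ki-67 statuses independent of diffusion parameters (mirroring the
  null findings for those contrasts), and lesion diameters
  N(2.48, 0.95²) cm. An ordered exclusion filter (non-mass enhancement,
  diameter < 1 cm, poor image quality) tags each excluded lesion with
  exactly the first matching criterion, so retained + excluded always
  equals screened.
- **Ground truth**: per-lesion means of (D, D\*, f, K) are drawn from
  ER-conditional Gaussians whose defaults equal the published
  between-lesion group summaries (e.g. D: 1.008±0.168 vs 1.147±0.223
  ×10⁻³ mm²/s for ER+/ER−); within-lesion fields are Gaussian random
  fields (default correlation length 2 voxels, coefficients of
  variation 10–30% by parameter) truncated inside the fit boxes. The
  within/between variance split is a free knob because only
  between-lesion spread is published; defaults were chosen once as
  plausible tumour heterogeneity and give non-degenerate skewness and
  kurtosis in ROI histograms.
- **Signal**: the generative decay is the hybrid
  S(b)/S₀ = (1−f)·exp(−b·D + (1/6)b²D²K) + f·exp(−b·(D\*+D)),
  chosen so each fitted model is exactly nested inside it (f=0, K=0 →
  mono; K=0 → IVIM; f=0 → kurtosis). Magnitude noise is Rician with
  σ = S₀/SNR (default SNR 50); at zero signal the floor is Rayleigh
  with mean σ√(π/2).
- **Morphology**: masks are disks, ellipses (axis ratio 1.3–2) or
  radially perturbed disks on a 2D grid, with an optional central
  necrotic hole excluded from the ROI; margin codes are sampled with
  ER-dependent probabilities calibrated to the published contingency
  counts so the chi-squared stage has real signal.
- **Second reader**: reader 2 = reader 1 + seeded Gaussian error, so
  the expected ICC(2,1) is the analytic variance ratio
  V_subject/(V_subject+V_error).

Because the hybrid signal contains kurtosis curvature at b ≤ 400, the
IVIM submodel is *mis-specified* with respect to the generator whenever
K > 0: even noiselessly, fitted f absorbs part of the curvature
(absolute error up to ~0.1–0.2) and D shifts down 10–20%. Conversely,
perfusion contaminates D_app upward by a few percent. Passing tests
therefore demonstrate recovery in each model's own nested limit and
well-behaved, characterized bias in the mixed regime — they do not
certify unbiased IVIM parameters on kurtotic tissue, which no estimator
on this b-scheme could deliver.

What the phantom does **not** emulate: anatomy (no breast background,
coil profiles, artifacts), 3D lesions (single-slice 2D ROIs, as in the
emulated design), motion/distortion, or any dependence of Ki-67/LNM on
diffusion. Conclusions about real-data performance are correspondingly
limited.

## Histogram conventions

Fixed so worked examples are exact: population moments (divide by n);
kurtosis non-excess m₄/m₂² (normal ≈ 3 — consistent with published
tumour values clustering near 3.3–4.1); skewness m₃/m₂^1.5; percentiles
by linear interpolation between order statistics. A constant ROI has
skewness 0 and kurtosis NaN (0/0). Columns follow the
`<map>_<metric>` convention, e.g. `Mono-ADC_mean`, `DKI-Kapp_75th`.

## Statistical battery

- Normality: Kolmogorov–Smirnov with estimated mean/SD uses the
  Lilliefors reference distribution (the naive KS table is
  anti-conservative when parameters are estimated).
- Mann–Whitney U: exact enumeration when n₁+n₂ ≤ 12 without ties,
  tie-corrected normal approximation otherwise; two-sided.
- AUC: Mann–Whitney concordance with half-weight ties; orientation is
  fixed (higher score → positive class), not folded, so sub-0.5 AUCs
  are reported as such. `positive_direction="less"` orients
  lower-is-positive markers (ADC in these cohorts).
- Best-metric selection: argmax AUC per parameter; exact ties break by
  the fixed order mean > median > 25th > 75th > kurtosis > skewness.
- Model combination: unpenalized maximum-likelihood logistic regression
  of the selected metrics; the combined score is the linear predictor
  and its AUC is computed **in-sample**. This mirrors the conventional
  single-cohort design and is optimistic; no cross-validation is
  attempted, by scope. Perfect separation is detected and flagged, with
  the diverging-direction score still returned.
- DeLong: paired structural-components variance, two-sided normal test;
  self-comparison yields p = 1 exactly.
- Chi-squared: Pearson, no continuity correction, empty rows/columns
  dropped with df adjusted; expected cells < 5 set a warning flag.
- ICC: two-way random effects, absolute agreement, single measures
  (ICC(2,1), via pingouin), banded at 0.40/0.60/0.75.
- Significance: α defaults to 0.05/8 = 0.00625 (Bonferroni over the
  eight contrasts), strict inequality at the boundary.

## Numerical and design choices

- All randomness flows through explicit seeds (`numpy` Generators /
  SeedSequence spawning); no hidden global state. Re-running a pipeline
  configuration reproduces every output bit-for-bit.
- The IVIM/DKI grid-search cross-checks in the tests use a coarse grid
  with one refinement pass (window ±3 coarse steps) — the bounded NLLS
  solutions match or beat the refined-grid optimum; a literal
  exhaustive fine grid over 2–3 parameters is not computable.
- Pipeline defaults (20 lesions, 32² in-plane grid, 1.5 mm voxels,
  SNR 50) are sized for routine experimentation; cohort-scale runs
  (143 lesions) use the same code path with `--n-lesions 143`.
- Tables are emitted as CSV plus a JSON machine summary so downstream
  checks are scriptable.

## Known limitations

- In-sample combined-model AUCs are optimistic (see above).
- The "Mono model" combination row is a monotone transform of its
  single selected metric, so its AUC equals that metric's AUC — the
  one-parameter case is degenerate by rank invariance.
- The b=800 shell defines ADC; the acquired b=1000 shell is not used by
  the mono model (it only enters the kurtosis fit).
- The phantom's group differences are driven through ER status only;
  contrasts correlated with ER (PR, subtype) inherit signal through the
  subtype-receptor coupling rather than through independent calibration.
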