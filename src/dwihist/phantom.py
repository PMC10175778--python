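"""Synthetic lesion-cohort generator.

No public dataset accompanies the study design this package implements,
so every analysis stage is exercised on phantoms built here: a screened
cohort with receptor statuses, molecular subtypes and morphology
labels; per-lesion 2D ROI masks (round / oval / irregular, optional
necrotic core which the ROI excludes); smooth within-lesion
ground-truth parameter fields; and multi-b DWI signal volumes under
magnitude (Rician) noise.

The generative signal is a hybrid of the three fitted models,

    S(b)/S0 = (1-f) * exp(-b*D + (1/6) b^2 D^2 K) + f * exp(-b*(D*+D)),

chosen because each fitted model is exactly nested inside it (f=0, K=0
gives the mono-exponential; K=0 gives IVIM; f=0 gives kurtosis).
Lesion-level parameter means are drawn from estrogen-receptor(ER)-
conditional Gaussians whose defaults are the published group
mean +/- SD values this cohort structure emulates, so fitted Mono-ADC
histograms come out stochastically lower in the ER-positive group.
All randomness flows through an explicit seed or Generator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .schemes import BValueScheme, FULL_SCHEME

__all__ = [
    "SUBTYPES", "LesionRecord", "GroupGaussian", "GroupParameterConfig",
    "NoiseModel", "CohortConfig", "sample_cohort", "cohort_to_frame",
    "ExclusionAudit", "apply_exclusion_filter", "default_exclusion_criteria",
    "render_lesion_mask", "gaussian_random_field", "make_truth_fields",
    "hybrid_signal", "rician", "simulate_dwi_series", "simulate_second_reader",
    "CONTRAST_ADC_GROUPS", "sample_two_group_gaussian",
]

SUBTYPES = ("LuminalA", "LuminalB", "HER2positive", "TN")

#: 3-level morphology codebooks (code -> label)
SHAPE_CODES = {1: "round", 2: "oval", 3: "irregular"}
MARGIN_CODES = {1: "smooth", 2: "spiculated", 3: "irregular"}
SIGNAL_CODES = {1: "heterogeneous", 2: "homogeneous", 3: "rim"}


# ---------------------------------------------------------------------------
# cohort records and configuration
# ---------------------------------------------------------------------------

@dataclass
class LesionRecord:
    """One lesion: receptor statuses, subtype, morphology, ground truth."""

    id: int
    er_status: bool
    pr_status: bool
    her2_status: bool
    ki67_status: bool
    lnm_status: bool
    subtype: str
    shape_label: int
    margin_label: int
    signal_label: int
    max_diameter: float  # cm
    #: lesion-mean generative parameters (mm²/s except f, K)
    true_D: float
    true_Dstar: float
    true_f: float
    true_K: float
    #: screening-stage flags consumed by the exclusion filter
    non_mass: bool = False
    poor_quality: bool = False

    def __post_init__(self):
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if self.subtype == "TN" and (self.er_status or self.pr_status
                                     or self.her2_status):
            raise ValueError("TN lesions must be ER/PR/HER2 negative")
        if self.subtype in ("LuminalA", "LuminalB") and not (
                self.er_status or self.pr_status):
            raise ValueError("Luminal lesions must be ER and/or PR positive")
        if self.subtype == "HER2positive" and not (
                self.her2_status and not self.er_status and not self.pr_status):
            raise ValueError("HER2-positive subtype means HER2+, ER-, PR-")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GroupGaussian:
    """Mean/SD (and group size) of a per-lesion Gaussian distribution."""

    mean: float
    sd: float
    n: int | None = None

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("SD must be positive")


#: Published between-lesion Mono-ADC group distributions (10⁻³ mm²/s)
#: for the contrasts whose discrimination the statistics stage targets:
#: (positive-class group, negative-class group); for the Luminal
#: contrast "positive" is the Luminal type.
CONTRAST_ADC_GROUPS: dict[tuple[str, str], tuple[GroupGaussian, GroupGaussian]] = {
    ("ER", "median"): (GroupGaussian(0.812, 0.122, 80), GroupGaussian(0.963, 0.163, 63)),
    ("ER", "mean"): (GroupGaussian(0.827, 0.126, 80), GroupGaussian(0.979, 0.163, 63)),
    ("PR", "mean"): (GroupGaussian(0.832, 0.131, 76), GroupGaussian(0.964, 0.165, 67)),
    ("PR", "median"): (GroupGaussian(0.817, 0.130, 76), GroupGaussian(0.948, 0.163, 67)),
    ("Luminal", "mean"): (GroupGaussian(0.830, 0.128, 86), GroupGaussian(0.991, 0.160, 57)),
}


def sample_two_group_gaussian(positive: GroupGaussian, negative: GroupGaussian,
                              rng) -> tuple[np.ndarray, np.ndarray]:
    """Draw one synthetic cohort of per-lesion values for a 2-group contrast.

    Returns ``(values, labels)`` with label 1 for the positive class.
    Group sizes are the ``n`` recorded on each :class:`GroupGaussian`.
    """
    rng = np.random.default_rng(rng)
    if positive.n is None or negative.n is None:
        raise ValueError("group sizes (n) must be set")
    vals = np.concatenate([
        rng.normal(positive.mean, positive.sd, positive.n),
        rng.normal(negative.mean, negative.sd, negative.n),
    ])
    labels = np.concatenate([np.ones(positive.n, int), np.zeros(negative.n, int)])
    return vals, labels


@dataclass(frozen=True)
class GroupParameterConfig:
    """ER-conditional generative parameter distributions.

    Keys are the four hybrid-model parameters; diffusivities are stored
    on the 10⁻³ mm²/s reporting scale (converted internally). Defaults
    are the published ER-group mean +/- SD rows for IVIM-D, IVIM-D*,
    IVIM-f and DKI-Kapp.
    """

    er_positive: dict = field(default_factory=lambda: {
        "D": GroupGaussian(1.008, 0.168), "Dstar": GroupGaussian(9.096, 4.040),
        "f": GroupGaussian(0.057, 0.030), "K": GroupGaussian(0.991, 0.148)})
    er_negative: dict = field(default_factory=lambda: {
        "D": GroupGaussian(1.147, 0.223), "Dstar": GroupGaussian(10.022, 4.871),
        "f": GroupGaussian(0.058, 0.028), "K": GroupGaussian(0.878, 0.124)})

    def group(self, er_status: bool) -> dict:
        return self.er_positive if er_status else self.er_negative


@dataclass(frozen=True)
class NoiseModel:
    """Magnitude-image noise: Rician with SNR = S0/sigma (inf = noiseless)."""

    kind: str = "rician"
    snr: float = 50.0

    def __post_init__(self):
        if self.kind != "rician":
            raise ValueError("only Rician magnitude noise is modeled")
        if not self.snr > 0:
            raise ValueError("snr must be positive (use math.inf for noiseless)")


@dataclass
class CohortConfig:
    """Screened-cohort composition and exclusion-stage probabilities.

    Defaults emulate a 216-patient screening pool whose exclusion stage
    removes non-mass enhancement, sub-centimetre and motion-degraded
    lesions, leaving a 143-lesion analysis cohort with subtype mix
    Luminal A / Luminal B / HER2-positive / TN = 45/41/25/32.
    """

    n_screened: int = 216
    p_non_mass: float = 34 / 216
    p_poor_quality: float = 23 / 216
    diameter_mean: float = 2.48    # cm
    diameter_sd: float = 0.95
    subtype_proportions: tuple = (45 / 143, 41 / 143, 25 / 143, 32 / 143)
    p_lnm: float = 49 / 143
    p_her2_in_luminal_b: float = 23 / 41
    p_ki67_nonluminal: float = 38 / 57
    #: margin code probabilities by ER status (smooth/spiculated/irregular),
    #: calibrated so the morphology contingency stage has real signal
    margin_probs_er_pos: tuple = (52 / 80, 13 / 80, 15 / 80)
    margin_probs_er_neg: tuple = (31 / 63, 4 / 63, 28 / 63)
    shape_probs: tuple = (24 / 143, 49 / 143, 70 / 143)
    signal_probs: tuple = (64 / 143, 55 / 143, 24 / 143)
    parameters: GroupParameterConfig = field(default_factory=GroupParameterConfig)

    def __post_init__(self):
        if self.n_screened < 0:
            raise ValueError("n_screened must be >= 0")
        for name in ("subtype_proportions", "margin_probs_er_pos",
                     "margin_probs_er_neg", "shape_probs", "signal_probs"):
            p = np.asarray(getattr(self, name), float)
            if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must be non-negative and sum to 1")


#: truncation box keeping ground truth inside the fit bounds (mm²/s)
_TRUTH_BOX = {"D": (0.2e-3, 2.8e-3), "Dstar": (2e-3, 90e-3),
              "f": (0.005, 0.5), "K": (0.05, 4.5)}


def _truncated_normal(g: GroupGaussian, lo, hi, rng, scale=1.0):
    for _ in range(1000):
        x = rng.normal(g.mean, g.sd) * scale
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(g.mean * scale, lo, hi))


def sample_cohort(config: CohortConfig, seed=None) -> list[LesionRecord]:
    """Draw a screened cohort of :class:`LesionRecord`.

    Subtypes are multinomial with the configured proportions; receptor
    statuses are drawn consistently with the sampled subtype (Luminal
    implies ER and/or PR positive, the HER2-positive subtype implies
    HER2+/ER-/PR-, TN implies all negative). Deterministic under seed.
    """
    rng = np.random.default_rng(seed)
    records = []
    for i in range(config.n_screened):
        subtype = SUBTYPES[rng.choice(4, p=config.subtype_proportions)]
        if subtype in ("LuminalA", "LuminalB"):
            er = bool(rng.random() < 0.95)
            pr = bool(rng.random() < 0.9) if er else True
            her2 = (bool(rng.random() < config.p_her2_in_luminal_b)
                    if subtype == "LuminalB" else False)
            ki67 = subtype == "LuminalB"
        elif subtype == "HER2positive":
            er = pr = False
            her2 = True
            ki67 = bool(rng.random() < config.p_ki67_nonluminal)
        else:  # TN
            er = pr = her2 = False
            ki67 = bool(rng.random() < config.p_ki67_nonluminal)
        margin_p = (config.margin_probs_er_pos if er
                    else config.margin_probs_er_neg)
        pars = config.parameters.group(er)
        records.append(LesionRecord(
            id=i,
            er_status=er, pr_status=pr, her2_status=her2, ki67_status=ki67,
            lnm_status=bool(rng.random() < config.p_lnm),
            subtype=subtype,
            shape_label=int(rng.choice([1, 2, 3], p=config.shape_probs)),
            margin_label=int(rng.choice([1, 2, 3], p=margin_p)),
            signal_label=int(rng.choice([1, 2, 3], p=config.signal_probs)),
            max_diameter=float(max(0.3, rng.normal(config.diameter_mean,
                                                   config.diameter_sd))),
            true_D=_truncated_normal(pars["D"], *_TRUTH_BOX["D"], rng, 1e-3),
            true_Dstar=_truncated_normal(pars["Dstar"], *_TRUTH_BOX["Dstar"], rng, 1e-3),
            true_f=_truncated_normal(pars["f"], *_TRUTH_BOX["f"], rng),
            true_K=_truncated_normal(pars["K"], *_TRUTH_BOX["K"], rng),
            non_mass=bool(rng.random() < config.p_non_mass),
            poor_quality=bool(rng.random() < config.p_poor_quality),
        ))
    return records


def cohort_to_frame(cohort: list[LesionRecord]) -> pd.DataFrame:
    """Cohort as a tidy table, one row per lesion."""
    return pd.DataFrame([r.to_dict() for r in cohort]).set_index("id")


# ---------------------------------------------------------------------------
# exclusion filtering
# ---------------------------------------------------------------------------

def default_exclusion_criteria() -> list[tuple[str, callable]]:
    """The screening exclusions, in their fixed order of precedence."""
    return [
        ("non_mass_enhancement", lambda r: r.non_mass),
        ("diameter_lt_1cm", lambda r: r.max_diameter < 1.0),
        ("poor_image_quality", lambda r: r.poor_quality),
    ]


@dataclass
class ExclusionAudit:
    """Who stayed, who left, and under exactly which criterion."""

    retained: list
    excluded: dict[str, list]
    n_screened: int

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.excluded.items()}

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def check_conservation(self) -> bool:
        return self.n_retained + sum(self.counts.values()) == self.n_screened


def apply_exclusion_filter(cohort, criteria=None) -> ExclusionAudit:
    """Apply ordered exclusion criteria; each record leaves at most once.

    ``criteria`` may be an ordered list of ``(name, predicate)`` pairs
    (default: the screening criteria above), or a mapping of criterion
    name to a fixed count — the bookkeeping mode used to audit published
    screening numbers, in which case ``cohort`` may be an integer pool
    size. A record matching several predicates is tagged only with the
    first, so retained + sum(excluded) always equals screened.
    """
    if isinstance(criteria, dict):  # count mode
        n = cohort if isinstance(cohort, int) else len(cohort)
        total = sum(criteria.values())
        if total > n:
            raise ValueError("exclusion counts exceed the screened pool")
        pool = list(range(n)) if isinstance(cohort, int) else list(cohort)
        excluded, start = {}, 0
        for name, k in criteria.items():
            excluded[name] = pool[start:start + k]
            start += k
        return ExclusionAudit(retained=pool[start:], excluded=excluded,
                              n_screened=n)

    if criteria is None:
        criteria = default_exclusion_criteria()
    retained, excluded = [], {name: [] for name, _ in criteria}
    for record in cohort:
        for name, pred in criteria:
            if pred(record):
                excluded[name].append(record)
                break
        else:
            retained.append(record)
    return ExclusionAudit(retained=retained, excluded=excluded,
                          n_screened=len(cohort))


# ---------------------------------------------------------------------------
# lesion masks and parameter fields
# ---------------------------------------------------------------------------

def render_lesion_mask(shape_label: int, diameter: float, grid_shape,
                       seed=None, necrotic_fraction: float = 0.0,
                       oval_ratio_range=(1.3, 2.0)) -> np.ndarray:
    """Rasterize a 2D ROI mask for one lesion.

    shape_label 1 -> disk of the given diameter (voxels); 2 -> ellipse
    with major axis = diameter and axis ratio drawn uniformly from
    ``oval_ratio_range``; 3 -> disk perturbed by seeded low-order radial
    Fourier noise. ``necrotic_fraction`` carves out a central hole of
    that radius fraction, mimicking ROI practice of excluding cystic or
    necrotic tumour portions.
    """
    if diameter < 2:
        raise ValueError("lesion diameter must span at least 2 voxels")
    if shape_label not in SHAPE_CODES:
        raise ValueError(f"shape_label must be 1, 2 or 3, got {shape_label}")
    rng = np.random.default_rng(seed)
    ny, nx = grid_shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    R = diameter / 2.0

    if shape_label == 1:
        mask = r <= R
    elif shape_label == 2:
        ratio = rng.uniform(*oval_ratio_range)
        ang = rng.uniform(0, np.pi)
        u = dx * np.cos(ang) + dy * np.sin(ang)
        v = -dx * np.sin(ang) + dy * np.cos(ang)
        mask = (u / R) ** 2 + (v / (R / ratio)) ** 2 <= 1.0
    else:
        modes = np.arange(2, 7)
        amp = rng.normal(0, 0.12, modes.size)
        phase = rng.uniform(0, 2 * np.pi, modes.size)
        wobble = np.sum(amp[:, None, None]
                        * np.cos(modes[:, None, None] * theta[None] + phase[:, None, None]),
                        axis=0)
        mask = r <= R * (1.0 + wobble)

    if necrotic_fraction > 0:
        mask &= r > R * necrotic_fraction
    if not mask.any():
        raise ValueError("rendered mask is empty; diameter too small for grid")
    return mask


def gaussian_random_field(grid_shape, mean: float, sd: float,
                          correlation_voxels: float = 2.0, seed=None) -> np.ndarray:
    """Smooth Gaussian field with the requested marginal mean and SD.

    White noise is smoothed with a Gaussian kernel of the given
    correlation length, then rescaled to unit marginal variance, so ROI
    histograms built from it have non-trivial spread, skewness and
    kurtosis rather than collapsing to a point mass.
    """
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(grid_shape)
    if correlation_voxels > 0:
        smooth = ndimage.gaussian_filter(white, correlation_voxels, mode="wrap")
        smooth /= smooth.std()
    else:
        smooth = white
    return mean + sd * smooth


#: default within-lesion SD as a fraction of the lesion mean
WITHIN_LESION_CV = {"D": 0.10, "Dstar": 0.25, "f": 0.30, "K": 0.10}


def make_truth_fields(record: LesionRecord, grid_shape, seed=None,
                      within_cv: dict | None = None,
                      correlation_voxels: float = 2.0) -> dict[str, np.ndarray]:
    """Within-lesion ground-truth fields for the four hybrid parameters.

    Each field is a Gaussian random field centred on the lesion mean
    with coefficient of variation ``within_cv`` (the within/between
    variance split is a free knob: the emulated study reports only
    between-lesion spread), truncated into the fit boxes.
    """
    cv = dict(WITHIN_LESION_CV, **(within_cv or {}))
    rng = np.random.default_rng(seed)
    fields = {}
    for key, mean in (("D", record.true_D), ("Dstar", record.true_Dstar),
                      ("f", record.true_f), ("K", record.true_K)):
        child = rng.integers(0, 2 ** 31 - 1)
        fld = gaussian_random_field(grid_shape, mean, cv[key] * mean,
                                    correlation_voxels, seed=child)
        fields[key] = np.clip(fld, *_TRUTH_BOX[key])
    return fields


# ---------------------------------------------------------------------------
# signal simulation
# ---------------------------------------------------------------------------

def hybrid_signal(D, Dstar, f, K, scheme) -> np.ndarray:
    """Generative relative signal: IVIM perfusion term x kurtosis tissue term.

    Arrays broadcast over voxels; the returned array gains a trailing
    b-axis. Reduces exactly to each fitted model in its nested limit.
    """
    b = scheme.array if isinstance(scheme, BValueScheme) else np.asarray(scheme, float)
    D, Dstar, f, K = (np.asarray(a, float)[..., None] for a in (D, Dstar, f, K))
    tissue = np.exp(-b * D + (b ** 2) * (D ** 2) * K / 6.0)
    perf = np.exp(-b * (Dstar + D))
    return (1.0 - f) * tissue + f * perf


def rician(signal: np.ndarray, sigma: float, rng) -> np.ndarray:
    """Magnitude of ``signal`` corrupted by complex Gaussian noise.

    At zero signal this is Rayleigh with mean sigma*sqrt(pi/2).
    """
    if sigma == 0:
        return np.asarray(signal, float).copy()
    rng = np.random.default_rng(rng)
    re = signal + rng.normal(0, sigma, np.shape(signal))
    im = rng.normal(0, sigma, np.shape(signal))
    return np.hypot(re, im)


def simulate_dwi_series(truth_fields: dict, mask: np.ndarray,
                        scheme: BValueScheme = FULL_SCHEME,
                        noise: NoiseModel = NoiseModel(snr=math.inf),
                        seed=None, s0: float = 1000.0) -> np.ndarray:
    """Noisy 4D DWI series (x, y, z, b) from ground-truth fields.

    ``truth_fields`` holds 2D or 3D arrays for D, Dstar, f, K; ``mask``
    marks lesion voxels (background stays at zero signal, so with noise
    it shows the Rayleigh floor). Noise sigma is ``s0 / snr``.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim == 2:
        mask = mask[..., None]
        truth_fields = {k: np.asarray(v)[..., None] for k, v in truth_fields.items()}
    rel = hybrid_signal(truth_fields["D"], truth_fields["Dstar"],
                        truth_fields["f"], truth_fields["K"], scheme)
    data = s0 * rel * mask[..., None]
    if math.isinf(noise.snr):
        return data
    return rician(data, s0 / noise.snr, np.random.default_rng(seed))


def simulate_second_reader(values, noise_sd: float, seed=None) -> np.ndarray:
    """Second-reader measurements: reader 1 plus seeded Gaussian error.

    With between-lesion variance V and reader-error variance
    ``noise_sd**2``, the expected two-way random single-measures
    agreement is V / (V + noise_sd**2).
    """
    if noise_sd < 0:
        raise ValueError("reader noise SD must be >= 0")
    arr = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    return arr + rng.normal(0.0, noise_sd, arr.shape)


def config_to_json(config: CohortConfig, seed=None) -> str:
    """Serialize a cohort configuration (with seed) for provenance."""
    d = asdict(config)
    d["seed"] = seed
    return json.dumps(d, indent=2, default=float)
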