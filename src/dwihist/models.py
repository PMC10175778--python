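"""Voxel-signal models for multi-b-value diffusion MRI.

Three nested descriptions of the normalized decay S(b)/S0 of the
diffusion-weighted signal with weighting b (s/mm²):

* mono-exponential:  S(b)/S0 = exp(-b·ADC)
* diffusion kurtosis: ln S(b)/S0 = -b·Dapp + (1/6)·b²·Dapp²·Kapp
* IVIM bi-exponential: S(b)/S0 = (1-f)·exp(-b·D) + f·exp(-b·(D*+D))

Diffusivities (ADC, D, D*, Dapp) are carried internally in mm²/s;
reporting and parameter maps use the conventional 10⁻³ mm²/s scale, on
which tumour ADC sits near 0.8-1.0. Kapp and f are unitless.

Each model follows the Model/Results idiom: construct from a signal
vector and a :class:`~dwihist.schemes.BValueScheme`, call ``fit()``, and
read estimates, fit quality and ``summary()`` off the Results object.
``fit_volume`` maps the per-voxel fits over an ROI of a 4D series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .schemes import BValueScheme, DKI_SCHEME, IVIM_SCHEME, MONO_SCHEME

__all__ = [
    "mono_signal",
    "dki_signal",
    "ivim_signal",
    "FitQuality",
    "MonoExponentialModel",
    "DiffusionKurtosisModel",
    "IVIMModel",
    "MonoResults",
    "DKIResults",
    "IVIMResults",
    "ParameterMapSet",
    "fit_volume",
    "MAP_NAMES",
    "DKI_BOUNDS",
    "IVIM_BOUNDS",
]

#: canonical map names, in fixed order
MAP_NAMES = ("Mono-ADC", "IVIM-D", "IVIM-Dstar", "IVIM-f", "DKI-Dapp", "DKI-Kapp")

#: fit boxes, bracketing the tumour parameter ranges with ample headroom
DKI_BOUNDS = {"Dapp": (0.0, 5e-3), "Kapp": (0.0, 5.0)}
IVIM_BOUNDS = {"D": (0.0, 3e-3), "Dstar": (0.0, 0.1), "f": (0.0, 1.0)}


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def _bvals(scheme) -> np.ndarray:
    if isinstance(scheme, BValueScheme):
        return scheme.array
    return np.asarray(scheme, dtype=float)


def mono_signal(adc: float, scheme) -> np.ndarray:
    """Relative signal exp(-b·ADC) over the scheme.

    Parameters
    ----------
    adc : diffusion coefficient, mm²/s (must be >= 0)
    scheme : BValueScheme or array of b-values, s/mm²
    """
    if adc < 0:
        raise ValueError(f"adc must be non-negative, got {adc}")
    return np.exp(-_bvals(scheme) * adc)


def dki_signal(dapp: float, kapp: float, scheme) -> np.ndarray:
    """Kurtosis-model relative signal exp(-b·Dapp + (1/6)b²·Dapp²·Kapp).

    With ``kapp=0`` this reduces exactly to :func:`mono_signal`. The
    quadratic log-signal expansion is only monotone for
    b < 3/(Dapp·Kapp); a ``UserWarning`` is emitted if the scheme
    extends past that bound.
    """
    if dapp < 0 or kapp < 0:
        raise ValueError("dapp and kapp must be non-negative")
    b = _bvals(scheme)
    if kapp > 0 and dapp > 0 and b.max() >= 3.0 / (dapp * kapp):
        warnings.warn(
            "b-values exceed the kurtosis-expansion validity bound "
            "b < 3/(Dapp*Kapp); signal is non-monotone over the scheme",
            UserWarning,
            stacklevel=2,
        )
    return np.exp(-b * dapp + (b ** 2) * (dapp ** 2) * kapp / 6.0)


def ivim_signal(d: float, dstar: float, f: float, scheme) -> np.ndarray:
    """IVIM relative signal (1-f)·exp(-b·D) + f·exp(-b·(D*+D)).

    ``f`` is the perfusion fraction in [0, 1]; ``d`` the tissue and
    ``dstar`` the pseudo-diffusion coefficient, mm²/s. ``f=0`` reduces
    exactly to :func:`mono_signal`.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"perfusion fraction f must lie in [0, 1], got {f}")
    if d < 0 or dstar < 0:
        raise ValueError("d and dstar must be non-negative")
    b = _bvals(scheme)
    return (1.0 - f) * np.exp(-b * d) + f * np.exp(-b * (dstar + d))


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitQuality:
    """Residual bookkeeping attached to every voxel fit."""

    residual_sum_squares: float
    converged: bool
    n_points_used: int

    def __post_init__(self):
        if np.isfinite(self.residual_sum_squares) and self.residual_sum_squares < 0:
            raise ValueError("residual_sum_squares must be >= 0")


class _Results:
    """Common surface of the per-voxel fit results."""

    model: "_SignalModel"
    quality: FitQuality
    _param_names: tuple[str, ...] = ()

    @property
    def params(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self._param_names}

    @property
    def converged(self) -> bool:
        return self.quality.converged

    def predict(self, scheme=None) -> np.ndarray:
        """Forward-model relative signal at the fitted parameters."""
        raise NotImplementedError

    def summary(self) -> str:
        lines = [f"{type(self.model).__name__} fit", "-" * 34]
        for name, value in self.params.items():
            unit = " x1e-3 mm^2/s" if name in ("adc", "D", "Dstar", "Dapp") else ""
            shown = value * 1e3 if unit else value
            lines.append(f"{name:>8s}: {shown: .6g}{unit}")
        q = self.quality
        lines.append(f"     RSS: {q.residual_sum_squares:.3e}  "
                     f"converged={q.converged}  n={q.n_points_used}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        pars = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return f"<{type(self).__name__} {pars} converged={self.converged}>"


@dataclass(frozen=True)
class MonoResults(_Results):
    adc: float
    quality: FitQuality = field(repr=False)
    model: "MonoExponentialModel" = field(repr=False)
    _param_names = ("adc",)

    def predict(self, scheme=None) -> np.ndarray:
        return mono_signal(self.adc, scheme if scheme is not None else self.model.scheme)


@dataclass(frozen=True)
class DKIResults(_Results):
    Dapp: float
    Kapp: float
    quality: FitQuality = field(repr=False)
    model: "DiffusionKurtosisModel" = field(repr=False)
    _param_names = ("Dapp", "Kapp")

    def predict(self, scheme=None) -> np.ndarray:
        sch = scheme if scheme is not None else self.model.scheme
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return dki_signal(self.Dapp, self.Kapp, sch)


@dataclass(frozen=True)
class IVIMResults(_Results):
    D: float
    Dstar: float
    f: float
    quality: FitQuality = field(repr=False)
    model: "IVIMModel" = field(repr=False)
    #: False when f collapsed to 0 and D* is unidentifiable (kept at its
    #: initialization value)
    dstar_identifiable: bool = True
    _param_names = ("D", "Dstar", "f")

    def predict(self, scheme=None) -> np.ndarray:
        sch = scheme if scheme is not None else self.model.scheme
        return ivim_signal(self.D, self.Dstar, self.f, sch)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class _SignalModel:
    """Base: holds one voxel's signal vector aligned to a scheme."""

    required_scheme: BValueScheme | None = None

    def __init__(self, signals, scheme: BValueScheme | None = None):
        if scheme is None:
            scheme = self.required_scheme
        if not isinstance(scheme, BValueScheme):
            scheme = BValueScheme(tuple(scheme))
        signals = np.asarray(signals, dtype=float)
        if signals.ndim != 1 or len(signals) != len(scheme):
            raise ValueError(
                f"signals (len {signals.size}) must be 1-D and aligned to the "
                f"scheme (len {len(scheme)})"
            )
        if scheme.values[0] != 0:
            raise ValueError("scheme must include b=0")
        self.signals = signals
        self.scheme = scheme
        self.s0 = signals[0]

    def _unfittable(self, results_cls, **nan_params):
        q = FitQuality(np.nan, False, 0)
        return results_cls(quality=q, model=self, **nan_params)


class MonoExponentialModel(_SignalModel):
    """Closed-form ADC from the {0, 800} s/mm² pair.

    ADC = -ln(S_800 / S_0) / 800, clipped at zero when the high-b signal
    exceeds S_0 (pure noise can push it there). No iteration involved.
    """

    required_scheme = MONO_SCHEME

    def fit(self) -> MonoResults:
        s0, sb = self.signals[0], self.signals[-1]
        if s0 <= 0 or sb <= 0:
            return self._unfittable(MonoResults, adc=np.nan)
        b_high = self.scheme.values[-1]
        adc = -np.log(sb / s0) / b_high
        clipped = adc < 0
        if clipped:
            warnings.warn(
                "signal at high b exceeds S0; ADC clipped to 0",
                UserWarning,
                stacklevel=2,
            )
            adc = 0.0
        resid = sb / s0 - np.exp(-b_high * adc)
        q = FitQuality(float(resid ** 2), True, 2)
        return MonoResults(adc=float(adc), quality=q, model=self)


class DiffusionKurtosisModel(_SignalModel):
    """Kurtosis fit on the full 8-value scheme, in log-signal space.

    The expansion ln S/S0 = -b·a + (1/6)·b²·c is linear in (a, c) =
    (Dapp, Dapp²·Kapp), so the primary solve is ordinary least squares on
    the log-signal; if the implied (Dapp, Kapp) leaves the box
    Dapp ∈ [0, 5×10⁻³], Kapp ∈ [0, 5], a bounded nonlinear refit of the
    same log-residuals enforces it.
    """

    required_scheme = DKI_SCHEME
    bounds = DKI_BOUNDS

    def fit(self) -> DKIResults:
        b = self.scheme.array
        s = self.signals
        good = s > 0
        if self.s0 <= 0 or not good[0] or good.sum() < 4:
            return self._unfittable(DKIResults, Dapp=np.nan, Kapp=np.nan)
        bb, y = b[good], np.log(s[good] / self.s0)
        X = np.column_stack([-bb, bb ** 2 / 6.0])
        (a, c), *_ = np.linalg.lstsq(X, y, rcond=None)
        lo_d, hi_d = self.bounds["Dapp"]
        lo_k, hi_k = self.bounds["Kapp"]
        kapp = c / a ** 2 if a > 0 else np.inf
        if lo_d <= a <= hi_d and lo_k <= kapp <= hi_k:
            dapp, kapp = float(a), float(kapp)
            converged = True
        else:
            def resid(p):
                d, k = p
                return (-bb * d + bb ** 2 * d ** 2 * k / 6.0) - y

            x0 = (np.clip(a, max(lo_d, 1e-6), hi_d),
                  np.clip(kapp if np.isfinite(kapp) else 0.0, lo_k, hi_k))
            sol = least_squares(resid, x0=x0, bounds=([lo_d, lo_k], [hi_d, hi_k]))
            dapp, kapp = map(float, sol.x)
            converged = sol.success
        rss = float(np.sum(((-bb * dapp + bb ** 2 * dapp ** 2 * kapp / 6.0) - y) ** 2))
        q = FitQuality(rss, bool(converged), int(good.sum()))
        return DKIResults(Dapp=dapp, Kapp=kapp, quality=q, model=self)


class IVIMModel(_SignalModel):
    """Segmented-then-joint IVIM fit on the {0,...,400} s/mm² subset.

    The bi-exponential is ill-conditioned, so the fit is seeded by the
    standard segmented scheme — a log-linear fit over the two highest
    b-values (200, 400 s/mm²) where the perfusion compartment has died
    off yields D₀ and, via its extrapolated b=0 intercept, f₀; a
    one-dimensional search with (D₀, f₀) held fixed yields D*₀ — and
    finished by a joint bounded least-squares solve of all three
    parameters in linear signal space, within
    D ∈ [0, 3×10⁻³], D* ∈ [0, 0.1], f ∈ [0, 1] (mm²/s).
    """

    required_scheme = IVIM_SCHEME
    bounds = IVIM_BOUNDS
    #: high-b subset used for the segmented D/f initialization
    segment_bvals = (200.0, 400.0)

    def fit(self) -> IVIMResults:
        s = self.signals
        if np.any(s <= 0):
            return self._unfittable(IVIMResults, D=np.nan, Dstar=np.nan, f=np.nan,
                                    dstar_identifiable=False)
        b = self.scheme.array
        y = s / self.s0
        (lo_d, hi_d) = self.bounds["D"]
        (lo_ds, hi_ds) = self.bounds["Dstar"]

        # -- segmented initialization
        seg = np.isin(b, self.segment_bvals)
        coef = np.polyfit(b[seg], np.log(y[seg]), 1)
        d0 = float(np.clip(-coef[0], lo_d + 1e-6, hi_d))
        f0 = float(np.clip(1.0 - np.exp(coef[1]), 0.0, 0.6))

        def dstar_sse(ds):
            return np.sum((ivim_signal(d0, ds, f0, b) - y) ** 2)

        ds0 = minimize_scalar(dstar_sse, bounds=(lo_ds + 1e-6, hi_ds),
                              method="bounded").x if f0 > 0 else 10e-3

        # -- joint bounded NLLS in linear signal space
        def resid(p):
            d, ds, f = p
            return ivim_signal(d, ds, f, b) - y

        sol = least_squares(
            resid,
            x0=(d0, float(ds0), f0),
            bounds=([lo_d, lo_ds, 0.0], [hi_d, hi_ds, 1.0]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        d, ds, f = map(float, sol.x)
        identifiable = f > 1e-6
        if not identifiable:
            ds = float(ds0)  # D* carries no information when f = 0
        q = FitQuality(float(np.sum(sol.fun ** 2)), bool(sol.success), len(b))
        return IVIMResults(D=d, Dstar=ds, f=f, quality=q, model=self,
                           dstar_identifiable=identifiable)


# ---------------------------------------------------------------------------
# volume fitting
# ---------------------------------------------------------------------------

@dataclass
class ParameterMapSet:
    """The six voxel-wise parameter maps plus per-map validity masks.

    Diffusivity maps (ADC, D, D*, Dapp) are stored in units of
    10⁻³ mm²/s; Kapp and f are unitless. ``valid[name]`` marks voxels
    whose fit converged; everything outside is NaN and must be dropped
    before histogram summarization.
    """

    maps: dict[str, np.ndarray]
    valid: dict[str, np.ndarray]
    mask: np.ndarray

    def values_in_roi(self, name: str) -> np.ndarray:
        """Valid voxel values of one map inside the ROI."""
        if name not in self.maps:
            raise KeyError(f"unknown map {name!r}; expected one of {MAP_NAMES}")
        sel = self.mask & self.valid[name]
        return self.maps[name][sel]


_DIFFUSIVITY_SCALE = 1e3  # mm²/s -> 10⁻³ mm²/s for reporting


def fit_volume(data: np.ndarray, scheme: BValueScheme, mask: np.ndarray,
               models: tuple[str, ...] = ("mono", "ivim", "dki")) -> ParameterMapSet:
    """Fit the selected models in every ROI voxel of a 4D series.

    Parameters
    ----------
    data : 4D array (x, y, z, b) aligned to ``scheme``
    scheme : full acquisition scheme; model subsets are extracted from it
    mask : 3D boolean ROI (must be non-empty, same grid as ``data``)
    models : any of {"mono", "ivim", "dki"}

    Returns
    -------
    ParameterMapSet with NaN outside the mask and at unfittable voxels.
    """
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if data.ndim != 4:
        raise ValueError("data must be 4-D (x, y, z, b)")
    if mask.shape != data.shape[:3]:
        raise ValueError(f"mask grid {mask.shape} != image grid {data.shape[:3]}")
    if data.shape[3] != len(scheme):
        raise ValueError("4th axis length must equal the scheme length")
    if not mask.any():
        raise ValueError("empty ROI mask")
    unknown = set(models) - {"mono", "ivim", "dki"}
    if unknown:
        raise ValueError(f"unknown model selector(s): {sorted(unknown)}")

    shape = data.shape[:3]
    maps = {n: np.full(shape, np.nan) for n in MAP_NAMES}
    valid = {n: np.zeros(shape, dtype=bool) for n in MAP_NAMES}

    sub = {
        "mono": (MONO_SCHEME, scheme.indices_of(MONO_SCHEME)),
        "ivim": (IVIM_SCHEME, scheme.indices_of(IVIM_SCHEME)),
        "dki": (DKI_SCHEME, scheme.indices_of(DKI_SCHEME)),
    }

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for idx in np.argwhere(mask):
            sig = data[tuple(idx)]
            if "mono" in models:
                sch, cols = sub["mono"]
                r = MonoExponentialModel(sig[cols], sch).fit()
                if r.converged:
                    maps["Mono-ADC"][tuple(idx)] = r.adc * _DIFFUSIVITY_SCALE
                    valid["Mono-ADC"][tuple(idx)] = True
            if "ivim" in models:
                sch, cols = sub["ivim"]
                r = IVIMModel(sig[cols], sch).fit()
                if r.converged:
                    maps["IVIM-D"][tuple(idx)] = r.D * _DIFFUSIVITY_SCALE
                    maps["IVIM-Dstar"][tuple(idx)] = r.Dstar * _DIFFUSIVITY_SCALE
                    maps["IVIM-f"][tuple(idx)] = r.f
                    valid["IVIM-D"][tuple(idx)] = True
                    valid["IVIM-f"][tuple(idx)] = True
                    valid["IVIM-Dstar"][tuple(idx)] = r.dstar_identifiable
            if "dki" in models:
                sch, cols = sub["dki"]
                r = DiffusionKurtosisModel(sig[cols], sch).fit()
                if r.converged:
                    maps["DKI-Dapp"][tuple(idx)] = r.Dapp * _DIFFUSIVITY_SCALE
                    maps["DKI-Kapp"][tuple(idx)] = r.Kapp
                    valid["DKI-Dapp"][tuple(idx)] = True
                    valid["DKI-Kapp"][tuple(idx)] = True

    return ParameterMapSet(maps=maps, valid=valid, mask=mask)
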