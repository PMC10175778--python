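"""First-order histogram summaries of parameter maps within an ROI.

Six metrics per map: mean, median, 25th and 75th percentiles (all in
map units), skewness and kurtosis (unitless). Conventions are fixed so
worked examples are exact:

* moments are population moments (divide by n, no bias correction);
* kurtosis is non-excess, m4/m2² (normal ≈ 3);
* skewness is m3/m2^{3/2};
* percentiles interpolate linearly between order statistics;
* a constant ROI has skewness 0 and kurtosis NaN (the ratio is 0/0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import MAP_NAMES, ParameterMapSet

__all__ = ["METRIC_NAMES", "HistogramSummary", "compute_histogram_summary",
           "summarize_lesion", "metric_column", "COLUMN_DICTIONARY"]

#: metric suffixes, in the fixed reporting order
METRIC_NAMES = ("mean", "median", "25th", "75th", "kurtosis", "skewness")


def metric_column(map_name: str, metric: str) -> str:
    """Column name convention, e.g. ``Mono-ADC_mean``."""
    return f"{map_name}_{metric}"


#: all 36 metric columns with plain-language definitions
COLUMN_DICTIONARY = {
    metric_column(m, k): f"{k} of the {m} map over valid ROI voxels"
    for m in MAP_NAMES for k in METRIC_NAMES
}


class HistogramSummary(dict):
    """The six first-order metrics of one ROI map (a thin dict)."""

    @property
    def mean(self):
        return self["mean"]

    @property
    def median(self):
        return self["median"]


def compute_histogram_summary(values) -> HistogramSummary:
    """Summarize the voxel-value distribution of one ROI map.

    ``values`` must contain at least one finite (non-flagged) voxel.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no valid voxels to summarize")
    p25, med, p75 = np.percentile(x, [25, 50, 75])
    if np.ptp(x) == 0:
        skew, kurt = 0.0, np.nan  # degenerate: m2 = 0
    else:
        skew = float(sps.skew(x, bias=True))
        kurt = float(sps.kurtosis(x, fisher=False, bias=True))
    return HistogramSummary(
        mean=float(x.mean()), median=float(med),
        **{"25th": float(p25), "75th": float(p75)},
        kurtosis=kurt, skewness=skew,
    )


def summarize_lesion(map_set: ParameterMapSet, lesion_id=None) -> pd.Series:
    """One row of 36 metrics (6 maps x 6 metrics) for a lesion's ROI.

    Voxels flagged unfittable in a given map are dropped for that map
    only. A map with zero valid ROI voxels raises, naming the map.
    """
    row = {}
    for name in MAP_NAMES:
        vals = map_set.values_in_roi(name)
        if vals.size == 0:
            raise ValueError(f"map {name!r} has no valid voxels in the ROI")
        summ = compute_histogram_summary(vals)
        for metric in METRIC_NAMES:
            row[metric_column(name, metric)] = summ[metric]
    return pd.Series(row, name=lesion_id)
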