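"""The cohort-level statistical battery.

Normality screening (Lilliefors-corrected Kolmogorov-Smirnov), two-group
Mann-Whitney comparisons, Spearman rank correlations against binary
status labels, single-metric and logistic-combination ROC analysis with
DeLong AUC comparisons, chi-squared contingency analysis of 3-level
morphology codes, and two-reader ICC agreement.

Eight binary contrasts are analysed throughout: ER, PR, HER2, Ki-67 and
lymph-node-metastasis status, plus Luminal vs non-Luminal, TN vs non-TN
and HER2-positive-type vs the rest. The family-wise significance level
defaults to 0.05/8 = 0.00625 (Bonferroni over the eight contrasts),
applied as a strict inequality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "DEFAULT_ALPHA", "CONTRASTS", "contrast_labels",
    "TestResult", "ROCResult", "ICCResult", "ContingencyResult",
    "ks_normality", "mann_whitney", "spearman_correlation",
    "roc_auc_single", "select_best_metric_per_parameter",
    "fit_logistic_combination", "delong_compare", "DeLongResult",
    "chi_squared_morphology", "icc_two_reader",
    "apply_significance_threshold",
]

#: Bonferroni-style threshold over the eight contrast families
DEFAULT_ALPHA = 0.05 / 8

#: the eight binary contrasts, in reporting order
CONTRASTS = ("ER", "PR", "HER2", "Ki67", "LNM", "Luminal", "TN", "HER2type")


def contrast_labels(cohort: pd.DataFrame) -> pd.DataFrame:
    """Binary label columns (1 = positive class) for all eight contrasts.

    Expects the cohort table emitted by the phantom (boolean status
    columns plus ``subtype``).
    """
    out = pd.DataFrame(index=cohort.index)
    out["ER"] = cohort["er_status"].astype(int)
    out["PR"] = cohort["pr_status"].astype(int)
    out["HER2"] = cohort["her2_status"].astype(int)
    out["Ki67"] = cohort["ki67_status"].astype(int)
    out["LNM"] = cohort["lnm_status"].astype(int)
    out["Luminal"] = cohort["subtype"].isin(["LuminalA", "LuminalB"]).astype(int)
    out["TN"] = (cohort["subtype"] == "TN").astype(int)
    out["HER2type"] = (cohort["subtype"] == "HER2positive").astype(int)
    return out


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_per_group: tuple
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class ROCResult:
    auc: float
    p_value: float  # vs the chance AUC of 0.5
    predictor: str
    n_per_group: tuple

    def __post_init__(self):
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC outside [0, 1]")


_ICC_BANDS = ((0.40, "poor"), (0.60, "fair"), (0.75, "good"), (1.01, "excellent"))


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci95: tuple
    n: int

    @property
    def band(self) -> str:
        """Qualitative agreement band (poor / fair / good / excellent)."""
        for upper, name in _ICC_BANDS:
            if self.icc < upper:
                return name
        return "excellent"


@dataclass(frozen=True)
class ContingencyResult:
    statistic: float
    p_value: float
    dof: int
    table: np.ndarray
    expected: np.ndarray
    low_expected: bool  # any expected cell < 5


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    difference: float
    z: float
    p_value: float


# ---------------------------------------------------------------------------
# univariate tests
# ---------------------------------------------------------------------------

def ks_normality(values, alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Kolmogorov-Smirnov normality screen with estimated mean and SD.

    Because location and scale are estimated from the sample, the naive
    KS reference distribution is anti-conservative; the Lilliefors
    correction is used instead.
    """
    x = np.asarray(values, float)
    if x.size < 3:
        raise ValueError("normality test needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant sample has no defined normality statistic")
    stat, p = lilliefors(x, dist="norm")
    return TestResult(float(stat), float(p), (x.size,), alpha)


def mann_whitney(group_a, group_b, alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Two-sided Mann-Whitney U comparison of two independent groups.

    Exact enumeration when n1+n2 <= 12 and there are no ties; the
    tie-corrected normal approximation otherwise.
    """
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue),
                      (a.size, b.size), alpha)


def spearman_correlation(values, labels, alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Spearman rank correlation of a metric against (binary) labels.

    Positive labels are coded 1, so rho > 0 means the metric rises with
    positive status.
    """
    x, y = np.asarray(values, float), np.asarray(labels, float)
    if x.size != y.size:
        raise ValueError("values and labels must be paired")
    if x.size < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no defined rank correlation")
    rho, p = sps.spearmanr(x, y)
    return TestResult(float(rho), float(p), (x.size,), alpha)


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

def _check_two_classes(labels) -> tuple[int, int]:
    y = np.asarray(labels).astype(int)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return n_pos, n_neg


def roc_auc_single(values, labels, predictor: str = "metric",
                   positive_direction: str = "greater") -> ROCResult:
    """Empirical AUC of one score against binary labels.

    The AUC is the Mann-Whitney concordance probability with ties given
    half weight. Orientation is fixed, not folded: with the default
    ``positive_direction="greater"`` a score that runs *lower* in the
    positive class yields AUC < 0.5 and is reported as such; pass
    ``"less"`` to orient a lower-is-positive marker above 0.5. The
    p-value tests AUC = 0.5 via the two-sided Mann-Whitney U.
    """
    x = np.asarray(values, float)
    y = np.asarray(labels).astype(int)
    n_pos, n_neg = _check_two_classes(y)
    if positive_direction not in ("greater", "less"):
        raise ValueError("positive_direction must be 'greater' or 'less'")
    score = x if positive_direction == "greater" else -x
    auc = float(roc_auc_score(y, score))
    p = float(sps.mannwhitneyu(score[y == 1], score[y == 0],
                               alternative="two-sided",
                               method="asymptotic").pvalue)
    return ROCResult(auc, p, predictor, (n_pos, n_neg))


#: metric precedence for resolving AUC ties
TIE_ORDER = ("mean", "median", "25th", "75th", "kurtosis", "skewness")


def select_best_metric_per_parameter(auc_table: pd.DataFrame) -> pd.Series:
    """Pick the highest-AUC histogram metric for each parameter map.

    ``auc_table`` is metrics (rows) x parameters (columns). Exact ties
    are broken by the fixed metric order mean > median > 25th > 75th >
    kurtosis > skewness so selection is deterministic.
    """
    missing = set(TIE_ORDER) - set(auc_table.index)
    if missing:
        raise ValueError(f"AUC table missing metrics: {sorted(missing)}")
    if auc_table.isna().any().any():
        raise ValueError("AUC table contains missing entries")
    ordered = auc_table.loc[list(TIE_ORDER)]
    best = {}
    for param in ordered.columns:
        col = ordered[param]
        best[param] = col.index[int(np.argmax(col.to_numpy()))]  # first max wins
    return pd.Series(best)


def fit_logistic_combination(predictors: pd.DataFrame, labels,
                             predictor_name: str = "combined"):
    """Maximum-likelihood logistic combination of selected metrics.

    Returns ``(scores, ROCResult, params, separation_flag)`` where
    ``scores`` is the in-sample linear predictor (its AUC is invariant
    to the logistic link). No penalty is applied, matching a plain
    logistic-regression combination; in-sample AUC is reported — an
    optimistic but conventional design, flagged in the docs. Perfect
    separation is detected and reported via the flag while the scores
    from the diverging direction are still returned.
    """
    X = pd.DataFrame(predictors).astype(float)
    y = np.asarray(labels).astype(int)
    n_pos, n_neg = _check_two_classes(y)
    if (X.nunique() <= 1).any():
        bad = X.columns[(X.nunique() <= 1)].tolist()
        raise ValueError(f"constant predictor(s): {bad}")
    if len(X) <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    design = sm.add_constant(X, has_constant="add")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            # (quasi-)separated data: Newton's Hessian degenerates; take
            # the diverging direction from a gradient method and flag it
            separation = True
            fit = sm.Logit(y, design).fit(disp=0, method="lbfgs", maxiter=500)
        separation |= any(issubclass(w.category, PerfectSeparationWarning)
                          for w in caught)
    scores = np.asarray(design @ fit.params, float)
    roc = roc_auc_single(scores, y, predictor=predictor_name)
    return scores, roc, fit.params, separation


# ---------------------------------------------------------------------------
# DeLong comparison of correlated AUCs
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_auc_var(scores: np.ndarray, y: np.ndarray):
    """AUC and the DeLong structural components for one score vector."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r, neg_r = _midrank(pos), _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n            # per-positive components
    v01 = 1.0 - (all_r[m:] - neg_r) / m      # per-negative components
    return auc, v10, v01


def delong_compare(scores_a, scores_b, labels) -> DeLongResult:
    """Two-sided DeLong test for the AUC difference of paired scores.

    Both score vectors must be measured on the same subjects with the
    same labels; the covariance of the two empirical AUCs is estimated
    from the shared structural components.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    y = np.asarray(labels).astype(int)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("paired comparison needs equal-length score vectors")
    n_pos, n_neg = _check_two_classes(y)
    if n_pos < 2 or n_neg < 2:
        raise ValueError("DeLong variance needs >= 2 subjects per class")
    auc_a, v10_a, v01_a = _delong_auc_var(a, y)
    auc_b, v10_b, v01_b = _delong_auc_var(b, y)
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n_pos \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n_neg
    diff = auc_a - auc_b
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
    return DeLongResult(float(auc_a), float(auc_b), float(diff), float(z), p)


# ---------------------------------------------------------------------------
# contingency and agreement
# ---------------------------------------------------------------------------

def chi_squared_morphology(labels_3level=None, contrast=None,
                           table=None) -> ContingencyResult:
    """Pearson chi-squared on a (binary contrast) x (3-level code) table.

    Call with either the raw ``labels_3level``/``contrast`` vectors or a
    prebuilt 2x3 ``table``. No continuity correction (df = 2 in the full
    case). Empty rows or columns are dropped with the df adjusted
    accordingly; a warning flag marks any expected cell below 5.
    """
    if table is None:
        if labels_3level is None or contrast is None:
            raise ValueError("provide labels and contrast, or a table")
        tab = pd.crosstab(np.asarray(contrast).astype(int),
                          np.asarray(labels_3level).astype(int)).to_numpy()
    else:
        tab = np.asarray(table, float)
    if tab.sum() <= 0:
        raise ValueError("contingency table is empty")
    tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
    if min(tab.shape) < 2:
        raise ValueError("contingency table is degenerate after dropping "
                         "empty rows/columns")
    chi2, p, dof, expected = sps.chi2_contingency(tab, correction=False)
    return ContingencyResult(float(chi2), float(p), int(dof), tab,
                             expected, bool((expected < 5).any()))


def icc_two_reader(reader1, reader2) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-measures ICC.

    The ICC(2,1) variant treats the two readers as a random sample of
    raters and penalizes systematic reader offsets. Banded per the
    0.40 / 0.60 / 0.75 thresholds.
    """
    import pingouin as pg

    r1, r2 = np.asarray(reader1, float), np.asarray(reader2, float)
    if r1.size != r2.size:
        raise ValueError("readers must rate the same subjects")
    if r1.size < 5:
        raise ValueError("ICC needs at least 5 paired measurements")
    if np.ptp(np.concatenate([r1, r2])) == 0:
        raise ValueError("constant measurements carry no agreement information")
    long = pd.DataFrame({
        "subject": np.tile(np.arange(r1.size), 2),
        "reader": np.repeat(["r1", "r2"], r1.size),
        "value": np.concatenate([r1, r2]),
    })
    res = pg.intraclass_corr(long, targets="subject", raters="reader",
                             ratings="value").set_index("Type")
    # two-way random, absolute agreement, single measures; pingouin
    # labels it ICC2 or ICC(A,1) depending on version
    key = "ICC2" if "ICC2" in res.index else "ICC(A,1)"
    row = res.loc[key]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    return ICCResult(float(row["ICC"]), tuple(row[ci_col]), int(r1.size))


def apply_significance_threshold(results, alpha: float = DEFAULT_ALPHA):
    """Re-flag a collection of TestResults at a given alpha (strict <)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if isinstance(results, TestResult):
        return replace(results, alpha=alpha)
    return [replace(r, alpha=alpha) for r in results]
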