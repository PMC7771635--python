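"""Evaluation statistics: segmentation overlap, shape errors, scalar agreement.

Segmentation quality is summarized per label from the voxel confusion table
(Dice, accuracy, sensitivity, specificity, precision).  Scalar scores from
two measurement routes (e.g. automatic vs manual fibrosis burdens) are
compared with the intraclass correlation coefficient — the one-way
random-effects, single-rater form ICC(1,1), which measures absolute
agreement — alongside Pearson correlation, RMSE and Bland-Altman limits.

ICC(1,1) comes from the one-way ANOVA decomposition of an n-subjects x
k-raters table:

    ICC = (MSB - MSW) / (MSB + (k - 1) MSW)

with confidence bounds from the F distribution.  Agreement bands: 0.41-0.60
moderate, 0.61-0.80 good, above 0.80 excellent.

Shapiro-Wilk, one-way ANOVA and the logistic-regression ROC/AUC used for
cohort-level analyses are routine methods delegated to scipy/scikit-learn
behind a small reporting helper.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as sps


@dataclasses.dataclass
class OverlapMetrics:
    """Per-label segmentation overlap measures, all in [0, 1]."""

    dice: float
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    label: int = 1

    def __post_init__(self):
        for name in ("dice", "accuracy", "sensitivity", "specificity", "precision"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclasses.dataclass
class AgreementReport:
    """Scalar agreement between two paired measurement routes."""

    pearson_r: float
    rmse: float
    bias: float                 # mean(y - x)
    loa_low: float              # bias - 1.96 SD(diff)
    loa_high: float             # bias + 1.96 SD(diff)
    mean_absolute_error: float
    mean_relative_error: float
    icc: float | None = None
    icc_ci: tuple | None = None

    def __post_init__(self):
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")
        if self.icc is not None and self.icc_ci is not None:
            lo, hi = self.icc_ci
            if not lo <= self.icc <= hi:
                raise ValueError("ICC must lie inside its confidence interval")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["icc_ci"] = list(self.icc_ci) if self.icc_ci is not None else None
        return d


def overlap_metrics(a, b, label: int = 1) -> OverlapMetrics:
    """Confusion-table overlap of label ``label`` between two label maps.

    ``a`` is treated as the test segmentation and ``b`` as the reference;
    Dice and accuracy are symmetric, sensitivity(a, b) = precision(b, a).
    Accepts LabelMap objects or plain arrays on a shared grid.
    """
    ad = np.asarray(getattr(a, "data", a))
    bd = np.asarray(getattr(b, "data", b))
    if ad.shape != bd.shape:
        raise ValueError("label maps must share a grid")
    x = ad == label
    y = bd == label
    tp = float(np.sum(x & y))
    fp = float(np.sum(x & ~y))
    fn = float(np.sum(~x & y))
    tn = float(np.sum(~x & ~y))

    def ratio(num, den):
        return num / den if den > 0 else np.nan

    return OverlapMetrics(
        dice=ratio(2 * tp, 2 * tp + fp + fn),
        accuracy=ratio(tp + tn, tp + tn + fp + fn),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        precision=ratio(tp, tp + fp),
        label=label,
    )


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

def icc_oneway(table, alpha: float = 0.05):
    """ICC(1,1): one-way random-effects, single-rater, absolute agreement.

    ``table`` is an (n subjects x k raters) array with no missing cells.
    Returns (icc, (ci_low, ci_high)) with the confidence bounds from the
    F-distribution:

        F = MSB / MSW,  FL = F / F_{1-a/2}(n-1, n(k-1)),
        FU = F * F_{1-a/2}(n(k-1), n-1),
        CI = [(FL - 1)/(FL + k - 1), (FU - 1)/(FU + k - 1)]

    Raises
    ------
    ValueError
        for fewer than 2 subjects or raters, or a fully degenerate table
        (zero between- and within-subject variance).
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an (n >= 2) x (k >= 2) table")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")
    n, k = x.shape
    subject_means = x.mean(axis=1)
    grand = x.mean()
    msb = k * np.sum((subject_means - grand) ** 2) / (n - 1)
    msw = np.sum((x - subject_means[:, None]) ** 2) / (n * (k - 1))
    if msw == 0 and msb == 0:
        raise ValueError("degenerate table: no variance between or within subjects")
    if msw == 0:
        return 1.0, (1.0, 1.0)
    icc = (msb - msw) / (msb + (k - 1) * msw)
    F = msb / msw
    df1, df2 = n - 1, n * (k - 1)
    fl = F / sps.f.ppf(1 - alpha / 2, df1, df2)
    fu = F * sps.f.ppf(1 - alpha / 2, df2, df1)
    ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    return float(icc), (float(ci[0]), float(ci[1]))


def interpret_icc(icc: float) -> str:
    """Agreement band: poor < 0.41 <= moderate <= 0.60 < good <= 0.80 < excellent."""
    if not -1.0 <= icc <= 1.0:
        raise ValueError("ICC must lie in [-1, 1]")
    if icc > 0.80:
        return "excellent"
    if icc >= 0.61:
        return "good"
    if icc >= 0.41:
        return "moderate"
    return "poor"


# ---------------------------------------------------------------------------
# scalar agreement
# ---------------------------------------------------------------------------

def scalar_agreement(x, y, with_icc: bool = True) -> AgreementReport:
    """Agreement between paired scores ``x`` (reference) and ``y`` (test).

    Reports Pearson r, RMSE, Bland-Altman bias (mean of y - x) with 1.96 SD
    limits, mean absolute and relative errors, and optionally ICC(1,1) of
    the two-column table.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    diff = y - x
    r = float(sps.pearsonr(x, y)[0]) if np.std(x) > 0 and np.std(y) > 0 else np.nan
    rmse = float(np.sqrt(np.mean(diff**2)))
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(diff) / np.abs(x)
        rel = rel[np.isfinite(rel)]
    icc = ci = None
    if with_icc:
        try:
            icc, ci = icc_oneway(np.column_stack([x, y]))
        except ValueError:
            pass
    return AgreementReport(
        pearson_r=r,
        rmse=rmse,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        mean_absolute_error=float(np.abs(diff).mean()),
        mean_relative_error=float(rel.mean()) if len(rel) else np.nan,
        icc=icc,
        icc_ci=ci,
    )


def shape_error(auto, manual):
    """(mean absolute error, mean relative error) of paired shape measures."""
    a = np.asarray(auto, dtype=float)
    m = np.asarray(manual, dtype=float)
    if a.shape != m.shape:
        raise ValueError("paired measures required")
    mae = float(np.abs(a - m).mean())
    mre = float((np.abs(a - m) / np.abs(m)).mean())
    return mae, mre


# ---------------------------------------------------------------------------
# delegated routine statistics
# ---------------------------------------------------------------------------

def cohort_report(groups: dict, binary_outcome=None, scores=None, alpha: float = 0.05) -> dict:
    """Routine cohort statistics behind one helper.

    ``groups`` maps group name -> 1D score array; the report contains a
    Shapiro-Wilk normality p-value per group and a one-way ANOVA across
    groups.  If ``binary_outcome``/``scores`` are given, a logistic
    regression of outcome on score is fitted and the ROC AUC reported.
    """
    out = {"alpha": alpha, "shapiro": {}, "anova": None, "auc": None}
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) >= 3:
            w, p = sps.shapiro(vals)
            out["shapiro"][name] = {"W": float(w), "p": float(p), "normal": bool(p > alpha)}
    if len(groups) >= 2:
        f, p = sps.f_oneway(*[np.asarray(v, dtype=float) for v in groups.values()])
        out["anova"] = {"F": float(f), "p": float(p), "significant": bool(p < alpha)}
    if binary_outcome is not None and scores is not None:
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import roc_auc_score

        X = np.asarray(scores, dtype=float).reshape(-1, 1)
        yb = np.asarray(binary_outcome, dtype=int)
        model = LogisticRegression()
        model.fit(X, yb)
        out["auc"] = float(roc_auc_score(yb, model.predict_proba(X)[:, 1]))
        out["logit_coef"] = float(model.coef_[0, 0])
    return out
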