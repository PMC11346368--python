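"""Agreement statistics for paired per-lesion measurements (CCTA vs IVUS).

For each measure: Pearson correlation with OLS slope/intercept (CCTA
regressed on IVUS, IVUS on the abscissa), two-way absolute-agreement
single-measure ICC, Bland-Altman bias and 1.96-SD limits of agreement
(differences taken CCTA - IVUS), and a paired t-test. For low-attenuation
plaque, per-lesion presence/absence by IVUS at 2, 4 and 8 mm^3 thresholds
is compared against the CCTA LAP volume by ROC analysis: AUC, and
sensitivity/specificity/PPV/NPV/accuracy at the Youden-optimal cutoff (a
secondary operating point at CCTA LAP > 0 is reported for audit).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve

LAP_PRESENCE_THRESHOLDS_MM3 = (2.0, 4.0, 8.0)


def pearson_with_fit(x, y) -> tuple[float, float, float, float]:
    """Pearson r with two-sided p, plus OLS slope/intercept of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need paired vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return float(r), float(p), float(fit.slope), float(fit.intercept)


def bland_altman(x, y) -> tuple[float, float, float, float]:
    """Bias and limits of agreement of d = y - x.

    Returns (mean difference, sample SD of differences (n-1), lower limit,
    upper limit) with limits = mean ± 1.96 SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("need paired vectors with n >= 2")
    d = y - x
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, sd, mean - 1.96 * sd, mean + 1.96 * sd


def icc_agreement(x, y) -> float:
    """Two-way random, absolute-agreement, single-measure ICC (ICC(2,1)).

    Mean-squares decomposition of the n x 2 table: with MSR (rows), MSC
    (columns), MSE (error) and k = 2 raters,
    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need paired vectors with n >= 3")
    k = 2
    table = np.column_stack([x, y])
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((table - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0 if msr == mse else 0.0
    return float((msr - mse) / denom)


def paired_t(x, y) -> tuple[float, float]:
    """Paired t-test on d = y - x with n - 1 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("need paired vectors with n >= 2")
    d = y - x
    if d.std(ddof=1) == 0:
        raise ValueError("zero-SD differences: paired t undefined")
    res = stats.ttest_rel(y, x)
    return float(res.statistic), float(res.pvalue)


@dataclass
class OperatingPoint:
    cutoff: float
    sensitivity_pct: float
    specificity_pct: float
    ppv_pct: float
    npv_pct: float
    accuracy_pct: float
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class LapPresenceResult:
    threshold_mm3: float
    auc: float
    n_positive: int
    n_negative: int
    youden: OperatingPoint
    ccta_positive: OperatingPoint  # secondary operating point: CCTA LAP > 0

    def as_dict(self) -> dict:
        return asdict(self)


def _operating_point(labels: np.ndarray, scores: np.ndarray, cutoff: float) -> OperatingPoint:
    pred = scores >= cutoff
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    tn = int(np.sum(~pred & ~labels))
    fn = int(np.sum(~pred & labels))

    def pct(num, den):
        return 100.0 * num / den if den else float("nan")

    return OperatingPoint(
        cutoff=float(cutoff),
        sensitivity_pct=pct(tp, tp + fn),
        specificity_pct=pct(tn, tn + fp),
        ppv_pct=pct(tp, tp + fp),
        npv_pct=pct(tn, tn + fn),
        accuracy_pct=pct(tp + tn, len(labels)),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def lap_presence_analysis(
    ivus_lap, ccta_lap, thresholds=LAP_PRESENCE_THRESHOLDS_MM3
) -> list[LapPresenceResult]:
    """ROC analysis of per-lesion LAP presence.

    The binary reference label is IVUS LAP volume >= threshold; the CCTA LAP
    volume is swept as the score (ties grouped into single ROC steps, AUC by
    trapezoid). The reported operating point maximizes the Youden index
    (sensitivity + specificity - 1); cutoffs are included for audit.
    """
    ivus_lap = np.asarray(ivus_lap, dtype=float)
    scores = np.asarray(ccta_lap, dtype=float)
    if len(ivus_lap) != len(scores):
        raise ValueError("paired vectors required")
    out = []
    for thr in thresholds:
        labels = ivus_lap >= thr
        if labels.all() or not labels.any():
            raise ValueError(f"single-class labels at IVUS threshold {thr} mm^3")
        fpr, tpr, cuts = roc_curve(labels, scores)
        roc_auc = float(_auc(fpr, tpr))
        j = tpr - fpr
        best = int(np.argmax(j))
        cutoff = float(cuts[best]) if np.isfinite(cuts[best]) else float(scores.max())
        out.append(
            LapPresenceResult(
                threshold_mm3=float(thr),
                auc=roc_auc,
                n_positive=int(labels.sum()),
                n_negative=int((~labels).sum()),
                youden=_operating_point(labels, scores, cutoff),
                ccta_positive=_operating_point(labels, scores, np.nextafter(0.0, 1.0)),
            )
        )
    return out


@dataclass
class MeasureAgreement:
    measure: str
    n: int
    pearson_r: float
    pearson_p: float
    slope: float
    intercept: float
    icc: float
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    t_stat: float
    t_p: float


@dataclass
class AgreementReport:
    """All per-measure agreement statistics plus the LAP-presence ROC rows."""

    measures: list = field(default_factory=list)
    lap_presence: list = field(default_factory=list)

    def measures_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(m) for m in self.measures])

    def lap_presence_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.lap_presence:
            for name in ("youden", "ccta_positive"):
                op: OperatingPoint = getattr(r, name)
                rows.append(
                    {
                        "ivus_threshold_mm3": r.threshold_mm3,
                        "operating_point": name,
                        "auc": r.auc,
                        "cutoff_mm3": op.cutoff,
                        "sensitivity_pct": op.sensitivity_pct,
                        "specificity_pct": op.specificity_pct,
                        "ppv_pct": op.ppv_pct,
                        "npv_pct": op.npv_pct,
                        "accuracy_pct": op.accuracy_pct,
                        "n_positive": r.n_positive,
                        "n_negative": r.n_negative,
                    }
                )
        return pd.DataFrame(rows)

    def as_dict(self) -> dict:
        return {
            "measures": [asdict(m) for m in self.measures],
            "lap_presence": [r.as_dict() for r in self.lap_presence],
        }


MEASURES = ("tpv", "cp", "ncp", "lap", "lumen", "vessel")


def compute_agreement_report(
    matched: pd.DataFrame, lap_thresholds=LAP_PRESENCE_THRESHOLDS_MM3
) -> AgreementReport:
    """Full agreement report from a per-lesion matched-volume table.

    Expects columns ``ivus_<m>_mm3`` / ``ccta_<m>_mm3`` for each measure in
    ``MEASURES`` (the IVUS LAP analogue is attenuated-plaque volume). The
    LAP-presence ROC block is skipped for thresholds where only one class is
    present.
    """
    if "excluded" in matched.columns:
        matched = matched[~matched["excluded"].astype(bool)]
    report = AgreementReport()
    for m in MEASURES:
        x = matched[f"ivus_{m}_mm3"].to_numpy(dtype=float)
        y = matched[f"ccta_{m}_mm3"].to_numpy(dtype=float)
        if len(x) < 3 or x.std() == 0 or y.std() == 0:
            continue  # degenerate measure (e.g. no CP anywhere in a tiny cohort)
        r, p, slope, intercept = pearson_with_fit(x, y)
        mean_d, sd_d, lo, hi = bland_altman(x, y)
        try:
            t, tp = paired_t(x, y)
        except ValueError:
            t, tp = float("nan"), float("nan")
        report.measures.append(
            MeasureAgreement(
                measure=m,
                n=len(x),
                pearson_r=r,
                pearson_p=p,
                slope=slope,
                intercept=intercept,
                icc=icc_agreement(x, y),
                mean_diff=mean_d,
                sd_diff=sd_d,
                loa_low=lo,
                loa_high=hi,
                t_stat=t,
                t_p=tp,
            )
        )
    usable = []
    ivus_lap = matched["ivus_lap_mm3"].to_numpy(dtype=float)
    ccta_lap = matched["ccta_lap_mm3"].to_numpy(dtype=float)
    for thr in lap_thresholds:
        labels = ivus_lap >= thr
        if labels.any() and not labels.all():
            usable.append(thr)
    if usable:
        report.lap_presence = lap_presence_analysis(ivus_lap, ccta_lap, usable)
    return report
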