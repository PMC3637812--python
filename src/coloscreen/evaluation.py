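"""Accuracy statistics for indication algorithms.

Confusion-table metrics (sensitivity, specificity, PPV, NPV, each with a 95%
Wald confidence interval, Wilson available by flag) and Cohen's kappa with
its large-sample asymptotic confidence interval.  "Screening" (label 1) is
the positive class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import InputError


@dataclass
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class Metric:
    """One proportion metric as a percentage with its 95% CI (truncated to
    [0, 100]); ``value`` is None when the denominator is zero."""

    value: float | None
    ci_low: float | None
    ci_high: float | None
    numerator: int
    denominator: int


@dataclass
class AccuracyReport:
    sensitivity: Metric
    specificity: Metric
    ppv: Metric
    npv: Metric

    def as_dict(self) -> dict:
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            m: Metric = getattr(self, name)
            out[name] = {
                "value": m.value,
                "ci_low": m.ci_low,
                "ci_high": m.ci_high,
                "numerator": m.numerator,
                "denominator": m.denominator,
            }
        return out


@dataclass
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    observed_agreement: float
    expected_agreement: float
    n: int


def _as_labels(table, name: str) -> pd.Series:
    if isinstance(table, pd.DataFrame):
        if "patient_id" not in table.columns or "label" not in table.columns:
            raise InputError(f"{name} table needs patient_id and label columns")
        s = table.set_index("patient_id")["label"]
    else:
        s = pd.Series(table)
    if s.isna().any():
        raise InputError(f"{name} has missing labels")
    vals = s.to_numpy()
    if not np.all(np.isin(vals, [0, 1])):
        raise InputError(f"{name} labels must be 0/1")
    return s.astype(int)


def _align(pred, ref):
    p = _as_labels(pred, "pred")
    r = _as_labels(ref, "ref")
    if isinstance(p.index, pd.RangeIndex) or isinstance(r.index, pd.RangeIndex):
        if len(p) != len(r):
            raise InputError("label tables have different lengths")
        return p.to_numpy(), r.to_numpy()
    if set(p.index) != set(r.index):
        raise InputError("label tables cover different patient sets")
    r = r.loc[p.index]
    return p.to_numpy(), r.to_numpy()


def confusion(pred, ref) -> ConfusionTable:
    """Cross-tabulate predicted vs reference labels (screening = positive).

    Accepts aligned arrays or (patient_id, label) tables, which are joined
    on patient id.
    """
    p, r = _align(pred, ref)
    return ConfusionTable(
        tp=int(np.sum((p == 1) & (r == 1))),
        fp=int(np.sum((p == 1) & (r == 0))),
        fn=int(np.sum((p == 0) & (r == 1))),
        tn=int(np.sum((p == 0) & (r == 0))),
    )


def _proportion_metric(num: int, den: int, method: str, alpha: float) -> Metric:
    if den == 0:
        return Metric(None, None, None, num, den)
    p = num / den
    z = stats.norm.ppf(1 - alpha / 2)
    if method == "wald":
        half = z * np.sqrt(p * (1 - p) / den)
        lo, hi = p - half, p + half
    elif method == "wilson":
        lo, hi = stats.binomtest(num, den).proportion_ci(1 - alpha, method="wilson")
    else:
        raise InputError(f"unknown CI method {method!r}")
    return Metric(
        value=100.0 * p,
        ci_low=float(np.clip(100.0 * lo, 0.0, 100.0)),
        ci_high=float(np.clip(100.0 * hi, 0.0, 100.0)),
        numerator=num,
        denominator=den,
    )


def accuracy_report(
    ct: ConfusionTable, method: str = "wald", alpha: float = 0.05
) -> AccuracyReport:
    """Sensitivity, specificity, PPV and NPV (percent) with 95% CIs.

    The default Wald interval is p +/- 1.96*sqrt(p(1-p)/denominator); a
    metric with zero denominator is reported as undefined rather than 0.
    """
    return AccuracyReport(
        sensitivity=_proportion_metric(ct.tp, ct.tp + ct.fn, method, alpha),
        specificity=_proportion_metric(ct.tn, ct.tn + ct.fp, method, alpha),
        ppv=_proportion_metric(ct.tp, ct.tp + ct.fp, method, alpha),
        npv=_proportion_metric(ct.tn, ct.tn + ct.fn, method, alpha),
    )


def cohens_kappa(a, b, alpha: float = 0.05) -> KappaResult:
    """Chance-corrected agreement kappa = (Po - Pe) / (1 - Pe) between two
    binary raters, with the large-sample (Fleiss-Cohen-Everitt) CI."""
    x, y = _align(a, b)
    n = len(x)
    if n == 0:
        raise InputError("empty label tables")
    p = np.zeros((2, 2))
    for i in (0, 1):
        for j in (0, 1):
            p[i, j] = np.sum((x == i) & (y == j)) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = p[0, 0] + p[1, 1]
    pe = float(row @ col)
    if pe >= 1.0 - 1e-12:
        raise InputError("expected agreement is 1 (both raters constant); kappa undefined")
    kappa = (po - pe) / (1 - pe)
    # Fleiss, Cohen & Everitt (1969) asymptotic variance
    t1 = sum(
        p[i, i] * ((1 - pe) - (col[i] + row[i]) * (1 - po)) ** 2 for i in (0, 1)
    )
    t2 = (1 - po) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2 for i in (0, 1) for j in (0, 1) if i != j
    )
    t3 = (po * pe - 2 * pe + po) ** 2
    var = (t1 + t2 - t3) / (n * (1 - pe) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(1 - alpha / 2)
    return KappaResult(
        kappa=float(kappa),
        ci_low=float(max(kappa - z * se, -1.0)),
        ci_high=float(min(kappa + z * se, 1.0)),
        observed_agreement=float(po),
        expected_agreement=float(pe),
        n=n,
    )
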