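"""Clinical analysis layer: SYNTAX grouping, vessel inclusion, and the
correlation / ANOVA / chi-square / diagnostic / ROC statistics used to
characterize a PCI cohort.

Group boundaries follow the SYNTAX convention: scores 0-22 are low
risk, 23-32 intermediate, >=33 high.  Vessel inclusion is strict on
both criteria (diameter > 1.5 mm AND stenosis > 50%).  Statistics are
computed from their textbook definitions (scipy supplies only the
reference distributions for p-values); the FFR ischemia cutoff defaults
to the conventional 0.80.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "GROUP_BOUNDS",
    "VesselRecord",
    "DiagnosticTable",
    "syntax_group",
    "vessel_filter",
    "pearson_r",
    "anova_oneway",
    "chi_square",
    "diagnostic_metrics",
    "roc_auc",
    "group_event_rates",
]

#: inclusive score ranges per group; "high" is open-ended
GROUP_BOUNDS = {"low": (0, 22), "medium": (23, 32), "high": (33, None)}

GROUP_ORDER = ("low", "medium", "high")


def syntax_group(score):
    """Risk-group label(s) for SYNTAX score(s): low <=22, medium 23-32, high >=33.

    Fractional scores are rounded half-up before grouping (the scoring
    system is integer-valued).  Accepts a scalar or an array; negative
    scores are rejected.
    """
    arr = np.asarray(score, dtype=float)
    if np.any(arr < 0) or np.any(~np.isfinite(arr)):
        raise ValidationError("SYNTAX scores must be finite and non-negative")
    rounded = np.floor(arr + 0.5)
    labels = np.where(rounded <= 22, "low", np.where(rounded <= 32, "medium", "high"))
    if np.isscalar(score) or arr.ndim == 0:
        return str(labels)
    return labels


@dataclass(frozen=True)
class VesselRecord:
    """A candidate vessel: diameter (mm) and stenosis (% diameter reduction)."""

    diameter: float
    stenosis: float

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValidationError("vessel diameter must be positive")
        if not 0 <= self.stenosis <= 100:
            raise ValidationError("stenosis percentage must lie in [0, 100]")


def vessel_filter(vessels):
    """Vessels included in scoring: diameter > 1.5 mm AND stenosis > 50%.

    Both inequalities are strict; input order is preserved.  Accepts a
    sequence of :class:`VesselRecord` or a DataFrame with ``diameter``
    and ``stenosis`` columns.
    """
    if isinstance(vessels, pd.DataFrame):
        keep = (vessels["diameter"] > 1.5) & (vessels["stenosis"] > 50.0)
        return vessels[keep]
    return [v for v in vessels if v.diameter > 1.5 and v.stenosis > 50.0]


def pearson_r(x, y, confidence: float = 0.95):
    """Pearson correlation with Fisher-z confidence interval and t-test p.

    Returns ``(r, (lo, hi), p)``.  The CI uses z = atanh(r) with
    standard error 1/sqrt(n-3); the two-sided p comes from
    t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 4:
        raise ValidationError("pearson_r needs two equal-length 1-D samples, n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("samples must be finite")
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0 or sy == 0:
        raise ValidationError("correlation undefined: a sample has zero variance")
    r = float(np.sum(xc * yc) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    zcrit = stats.norm.ppf(0.5 + confidence / 2)
    with np.errstate(divide="ignore"):
        z = np.arctanh(r)
    half = zcrit / np.sqrt(n - 3)
    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return r, ci, p


def anova_oneway(*groups):
    """One-way ANOVA: F = between-group MS / within-group MS, with its p.

    Returns ``(F, p)``.  All-identical data across groups makes F 0/0;
    that case returns ``(nan, nan)`` (flagged as degenerate).
    """
    if len(groups) == 1 and not np.isscalar(groups[0][0]):
        try:
            if hasattr(groups[0][0], "__len__"):
                groups = tuple(groups[0])
        except (TypeError, IndexError):
            pass
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValidationError("ANOVA needs >=2 groups with >=2 values each")
    n = sum(g.size for g in gs)
    grand = sum(g.sum() for g in gs) / n
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in gs)
    df_b = len(gs) - 1
    df_w = n - len(gs)
    if ss_within == 0 and ss_between == 0:
        return float("nan"), float("nan")
    if ss_within == 0:
        return float("inf"), 0.0
    F = (ss_between / df_b) / (ss_within / df_w)
    return float(F), float(stats.f.sf(F, df_b, df_w))


def chi_square(table):
    """Pearson chi-square test of independence on a 2-way count table.

    Returns ``(chi2, p)`` with (r-1)(c-1) degrees of freedom and no
    continuity correction.  A zero row or column marginal is rejected.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValidationError("need a 2-way table with >=2 rows and columns")
    if np.any(obs < 0):
        raise ValidationError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValidationError("zero marginal: drop empty rows/columns first")
    expected = np.outer(rows, cols) / obs.sum()
    chi2 = float(np.sum((obs - expected) ** 2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return chi2, float(stats.chi2.sf(chi2, df))


@dataclass
class DiagnosticTable:
    """Confusion counts and the derived diagnostic rates."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def diagnostic_metrics(predicted_ffr, truth, cutoff: float = 0.80) -> DiagnosticTable:
    """Confusion table of the FFR classifier against reference labels.

    A case is called positive (hemodynamically significant) when its
    predicted FFR <= ``cutoff``; ``truth`` holds the reference-standard
    positivity flags.
    """
    ffr = np.asarray(predicted_ffr, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if ffr.size == 0 or ffr.shape != t.shape:
        raise ValidationError("need equal-length non-empty prediction and truth arrays")
    pos = ffr <= cutoff
    return DiagnosticTable(
        tp=int(np.sum(pos & t)),
        fp=int(np.sum(pos & ~t)),
        tn=int(np.sum(~pos & ~t)),
        fn=int(np.sum(~pos & t)),
    )


def roc_auc(scores, labels):
    """ROC curve and AUC by the trapezoidal rule over all unique thresholds.

    Higher scores are taken as more positive; the AUC equals the
    Mann–Whitney concordance probability (ties counted half).  Returns
    ``(points, auc)`` with points an (k, 2) array of (FPR, TPR) pairs.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1 or s.size == 0:
        raise ValidationError("need equal-length 1-D scores and labels")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # keep the last point of each tied-score run
    last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.concatenate([[0.0], tp[last] / n_pos])
    fpr = np.concatenate([[0.0], fp[last] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def group_event_rates(cohort: pd.DataFrame, score_col: str = "syntax_score",
                      event_col: str = "macce"):
    """Per-SYNTAX-group MACCE incidence with overall and pairwise tests.

    Returns a dict with per-group counts/rates, the overall 3x2
    chi-square and the pairwise 2x2 chi-squares.  Pairwise p-values are
    reported uncorrected (the number of comparisons is noted so a
    Bonferroni adjustment, p * n_comparisons, can be applied by the
    caller).  Degenerate tables (a zero marginal, e.g. no events at
    all) are flagged instead of tested.
    """
    groups = syntax_group(cohort[score_col].to_numpy())
    events = cohort[event_col].to_numpy().astype(bool)
    out = {"groups": {}, "overall": None, "pairwise": {},
           "n_comparisons": 3, "correction": "none"}
    counts = {}
    for label in GROUP_ORDER:
        sel = groups == label
        n = int(sel.sum())
        e = int(events[sel].sum())
        counts[label] = (e, n)
        out["groups"][label] = {
            "n": n, "events": e, "rate": e / n if n else float("nan"),
            "empty": n == 0,
        }
    table = np.array([[e, n - e] for e, n in counts.values() if n > 0])
    if len(table) >= 2 and table.sum(axis=0).min() > 0:
        chi2, p = chi_square(table)
        out["overall"] = {"chi2": chi2, "p": p, "degenerate": False}
    else:
        out["overall"] = {"chi2": None, "p": None, "degenerate": True}
    pairs = [("low", "medium"), ("low", "high"), ("medium", "high")]
    for a, b in pairs:
        ea, na = counts[a]
        eb, nb = counts[b]
        t = np.array([[ea, na - ea], [eb, nb - eb]])
        if na == 0 or nb == 0 or t.sum(axis=0).min() == 0:
            out["pairwise"][f"{a}_vs_{b}"] = {"chi2": None, "p": None, "degenerate": True}
        else:
            chi2, p = chi_square(t)
            out["pairwise"][f"{a}_vs_{b}"] = {"chi2": chi2, "p": p, "degenerate": False}
    return out
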