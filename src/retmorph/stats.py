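"""Statistical layer: cutoff classification, contingency metrics with exact
binomial intervals, k-means cutoff derivation, paired group tests, and
interrater reliability.

Subjects are classified *abnormal* when AVR < cutoff, TI > cutoff, or
mean-D < cutoff (arteriolar narrowing and branching rarefaction lower AVR
and mean-D; abnormal twisting raises TI). Disease is the positive class of
every 2x2 table. The "combined" three-index rule is AVR-driven by default:
adding TI and mean-D to the clustering does not change the classification,
so the combined row equals the AVR row (an OR-rule alternative is provided).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, wilcoxon
from statsmodels.stats.proportion import proportion_confint

from .errors import ContractError, DegenerateDataError

__all__ = [
    "SubjectRecord",
    "ConfusionTable",
    "Cutoffs",
    "REFERENCE_CUTOFFS",
    "INDEX_COLUMNS",
    "kmeans_cutoff_1d",
    "derive_cutoffs_kmeans",
    "classify",
    "metric_cis",
    "paired_wilcoxon",
    "icc_two_rater",
    "chi_squared_2x2",
]

INDEX_COLUMNS = ("avr", "ti", "mean_d")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's retinal indices with group and matched-pair labels."""

    subject_id: str
    group: str                      # "disease" | "control"
    pair_id: str | None = None
    avr: float | None = None
    ti: float | None = None
    mean_d: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("disease", "control"):
            raise ContractError(f"group must be disease/control, got {self.group!r}")


@dataclass(frozen=True)
class Cutoffs:
    """Per-index abnormality cutoffs with fixed directions:
    abnormal iff avr < avr_max OR ti > ti_min OR mean_d < mean_d_max."""

    avr_max: float
    ti_min: float
    mean_d_max: float

    def abnormal(self, index: str, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if index == "avr":
            return values < self.avr_max
        if index == "ti":
            return values > self.ti_min
        if index == "mean_d":
            return values < self.mean_d_max
        raise ContractError(f"unknown index {index!r}")


#: Reference abnormality cutoffs for clinical use (AVR < 0.70, TI > 72,
#: mean-D < 1.42), originally derived by k-means on a validation cohort.
REFERENCE_CUTOFFS = Cutoffs(avr_max=0.70, ti_min=72.0, mean_d_max=1.42)


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 contingency table; disease is the positive class.

    Metrics are percentages; a metric with an empty denominator is None
    ("not available"), never 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ContractError("confusion counts must be non-negative")

    @staticmethod
    def _pct(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    @property
    def sensitivity(self) -> float | None:
        return self._pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._pct(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._pct(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._pct(self.tn, self.tn + self.fn)

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "ppv": self.ppv, "npv": self.npv}


def kmeans_cutoff_1d(values: Sequence[float]) -> float:
    """Deterministic, globally optimal 1-D 2-means cutoff.

    For one-dimensional data the optimal 2-means partition is a split of the
    sorted values, so the exact solution is found by scanning all n-1 split
    points for the minimum within-cluster sum of squares (Lloyd iteration
    would only approximate this and can stall in local optima). The cutoff
    returned is the midpoint of the two final cluster means; input order is
    irrelevant.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ContractError(f"k-means cutoff needs >= 4 values, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("all values identical: clusters degenerate")
    x = np.sort(x)
    n = x.size
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    k = np.arange(1, n)  # split: x[:k] | x[k:]
    lo_mean = csum[k - 1] / k
    hi_mean = (csum[-1] - csum[k - 1]) / (n - k)
    wss = (csq[k - 1] - k * lo_mean**2) \
        + (csq[-1] - csq[k - 1] - (n - k) * hi_mean**2)
    best = int(np.argmin(wss))
    return float((lo_mean[best] + hi_mean[best]) / 2.0)


def derive_cutoffs_kmeans(
    avr: Sequence[float], ti: Sequence[float], mean_d: Sequence[float]
) -> Cutoffs:
    """Per-index abnormality cutoffs from pooled 1-D 2-means clustering."""
    return Cutoffs(
        avr_max=kmeans_cutoff_1d(avr),
        ti_min=kmeans_cutoff_1d(ti),
        mean_d_max=kmeans_cutoff_1d(mean_d),
    )


def classify(
    records: pd.DataFrame | Sequence[SubjectRecord],
    cutoffs: Cutoffs,
    index: str = "avr",
    combined_rule: str = "avr",
) -> ConfusionTable:
    """Classify subjects against the cutoffs and tabulate versus diagnosis.

    ``index`` is one of ``avr``, ``ti``, ``mean_d``, or ``combined``. The
    combined rule defaults to the AVR decision (``combined_rule="avr"``);
    ``combined_rule="or"`` flags a subject abnormal on any of the three.
    """
    df = _records_frame(records)
    if index == "combined":
        cols = ["avr"] if combined_rule == "avr" else list(INDEX_COLUMNS)
    else:
        if index not in INDEX_COLUMNS:
            raise ContractError(f"unknown index {index!r}")
        cols = [index]
    missing = df[df[cols].isna().any(axis=1)]
    if len(missing):
        raise ContractError(
            "missing index value(s) for subject(s): "
            + ", ".join(map(str, missing["subject_id"].tolist()))
        )
    abnormal = np.zeros(len(df), dtype=bool)
    for col in cols:
        abnormal |= cutoffs.abnormal(col, df[col].to_numpy())
    disease = (df["group"] == "disease").to_numpy()
    return ConfusionTable(
        tp=int((disease & abnormal).sum()),
        fp=int((~disease & abnormal).sum()),
        fn=int((disease & ~abnormal).sum()),
        tn=int((~disease & ~abnormal).sum()),
    )


def metric_cis(table: ConfusionTable, level: float = 0.95) -> dict:
    """Exact (Clopper-Pearson) binomial CIs for the four table metrics.

    Returned per metric as ``(low, high)`` percentages, or None when the
    metric itself is not available.
    """
    nums = {
        "sensitivity": (table.tp, table.tp + table.fn),
        "specificity": (table.tn, table.tn + table.fp),
        "ppv": (table.tp, table.tp + table.fp),
        "npv": (table.tn, table.tn + table.fn),
    }
    out = {}
    for name, (k, n) in nums.items():
        if n == 0:
            out[name] = None
            continue
        lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
        out[name] = (100.0 * lo, 100.0 * hi)
    return out


def paired_wilcoxon(
    disease: Sequence[float],
    control: Sequence[float],
    exact_max_n: int = 25,
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on matched disease-control pairs.

    Exact-distribution p-value for up to ``exact_max_n`` non-zero pairs,
    normal approximation with continuity correction above. Zero differences
    are dropped. Returns ``(statistic, p_value)``.
    """
    x = np.asarray(disease, dtype=float)
    y = np.asarray(control, dtype=float)
    if x.shape != y.shape:
        raise ContractError("disease and control vectors must be equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 5:
        raise ContractError(f"paired test needs >= 5 complete pairs, got {x.size}")
    diffs = x - y
    nonzero = int((diffs != 0).sum())
    if nonzero == 0:
        raise DegenerateDataError("all paired differences are zero")
    method = "exact" if nonzero <= exact_max_n else "approx"
    res = wilcoxon(x, y, zero_method="wilcox", correction=(method == "approx"),
                   alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def icc_two_rater(rater_a: Sequence[float], rater_b: Sequence[float]) -> float | None:
    """Interrater reliability: ICC(2,1) — two-way random effects, absolute
    agreement, single measures — as a percentage.

    Returns None when between-subject variance is zero (coefficient
    undefined).
    """
    import pingouin as pg  # deferred: pingouin import is slow

    a = np.asarray(rater_a, dtype=float)
    b = np.asarray(rater_b, dtype=float)
    if a.shape != b.shape:
        raise ContractError("rater vectors must be equal length")
    if a.size < 5:
        raise ContractError(f"ICC needs >= 5 subjects, got {a.size}")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return None
    n = a.size
    df = pd.DataFrame({
        "target": np.tile(np.arange(n), 2),
        "rater": np.repeat(["a", "b"], n),
        "rating": np.concatenate([a, b]),
    })
    import warnings as _warnings
    with _warnings.catch_warnings():
        # pingouin divides by a zero residual MS for perfectly agreeing raters
        _warnings.simplefilter("ignore", RuntimeWarning)
        icc = pg.intraclass_corr(df, targets="target", raters="rater",
                                 ratings="rating")
    row = icc[icc["Type"].isin(["ICC2", "ICC(A,1)"])]
    value = float(row["ICC"].iloc[0])
    if np.isnan(value):
        return None
    return 100.0 * value


def chi_squared_2x2(table: np.ndarray) -> tuple[float, float]:
    """Generic 2x2 chi-squared test (Yates-corrected): (statistic, p)."""
    stat, p, _, _ = chi2_contingency(np.asarray(table), correction=True)
    return float(stat), float(p)


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "subject_id" not in df.columns:
            df["subject_id"] = np.arange(len(df))
        return df
    rows = [{"subject_id": r.subject_id, "group": r.group, "pair_id": r.pair_id,
             "avr": r.avr, "ti": r.ti, "mean_d": r.mean_d} for r in records]
    return pd.DataFrame(rows)
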