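"""Per-sample statistical comparison of two quantification methods.

Given replicate means and standard deviations of the same samples measured
by a reference method (UV-vis spectrophotometry) and an alternative method
(image-based quantification), this module computes for each sample:

* the variance-ratio F statistic, with the reference-method variance in the
  numerator (no larger-variance reordering, so F < 1 is possible);
* the paired t statistic, when raw per-replicate differences are supplied —
  printed summary statistics are not enough to reconstruct it;
* the relative error in percent against the reference concentration;
* compliance with a regulatory concentration limit.

Two methods are declared equivalent for a sample when F stays below the
critical F and, if a t value is available, |t| stays below the critical t.
Critical values are computed from the F and t distributions at the chosen
confidence level, not hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REGULATORY_LIMIT",
    "SampleMeasurement",
    "ComparisonRow",
    "variance_ratio_f",
    "critical_f",
    "critical_t",
    "paired_t",
    "relative_error_pct",
    "compliance",
    "compare_table",
]

#: maximum allowable analyte concentration in the product, mg/mL
REGULATORY_LIMIT = 3.0e-1


@dataclass(frozen=True)
class SampleMeasurement:
    """Replicate summary for one sample under one method (mg/mL)."""

    sample_id: str
    mean: float
    sd: float
    n: int = 3

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"{self.sample_id}: sd must be non-negative")
        if self.n < 2:
            raise ValueError(f"{self.sample_id}: need at least two replicates")


@dataclass(frozen=True)
class ComparisonRow:
    """Comparison statistics for one sample."""

    sample_id: str
    ref_mean: float
    alt_mean: float
    f_value: float
    f_crit: float
    relative_error_pct: float
    equivalent: bool
    compliant: bool
    t_value: float | None = None
    t_crit: float | None = None
    t_p: float | None = None


def variance_ratio_f(m1: SampleMeasurement, m2: SampleMeasurement) -> float:
    """Variance ratio ``sd1^2 / sd2^2`` with the reference variance on top.

    Both SDs zero gives 1.0 by convention (identical, degenerate precision);
    a zero denominator with a positive numerator is undefined.
    """
    if m2.sd == 0.0:
        if m1.sd == 0.0:
            return 1.0
        raise ZeroDivisionError(
            f"{m2.sample_id}: zero variance in the denominator method"
        )
    return (m1.sd / m2.sd) ** 2


def critical_f(alpha: float, df1: int, df2: int) -> float:
    """Upper-tail critical value of the F distribution."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be at least 1")
    return float(stats.f.ppf(1.0 - alpha, df1, df2))


def critical_t(alpha: float, df: int) -> float:
    """Two-sided critical value of Student's t (alpha split over both tails)."""
    if df < 1:
        raise ValueError("degrees of freedom must be at least 1")
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def paired_t(diffs) -> tuple[float, float]:
    """Paired t statistic and two-sided p from per-replicate differences.

    ``t = mean(d) / (sd(d) / sqrt(n))`` with n-1 degrees of freedom.  A zero
    SD with a non-zero mean yields an infinite t (p = 0); all-zero
    differences yield t = 0, p = 1.
    """
    diffs = np.asarray(diffs, dtype=float).ravel()
    n = diffs.size
    if n < 2:
        raise ValueError("need at least two paired differences")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        return float(np.sign(mean)) * float("inf"), 0.0
    t = mean / (sd / np.sqrt(n))
    return float(t), float(2.0 * stats.t.sf(abs(t), n - 1))


def relative_error_pct(c_ref: float, c_alt: float) -> float:
    """Relative error of the alternative method, ``|c_ref - c_alt|/c_ref*100``."""
    if c_ref <= 0:
        raise ValueError(f"reference concentration must be positive, got {c_ref}")
    return abs(c_ref - c_alt) / c_ref * 100.0


def compliance(conc: float, limit: float = REGULATORY_LIMIT) -> bool:
    """True when the concentration is strictly below the regulatory limit."""
    if conc < 0:
        raise ValueError(f"concentration must be non-negative, got {conc}")
    return conc < limit


def compare_table(
    ref: Sequence[SampleMeasurement],
    alt: Sequence[SampleMeasurement],
    alpha: float = 0.05,
    limit: float = REGULATORY_LIMIT,
    diffs: Mapping[str, Sequence[float]] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Compare two methods sample-by-sample and summarise across samples.

    *ref* and *alt* must carry the same sample ids in the same order.  Raw
    per-replicate differences, keyed by sample id, enable the paired t test
    for those samples.  Returns the per-sample table and a summary dict with
    the concentration extrema of each method, the largest relative error and
    the overall equivalence/compliance verdicts.
    """
    ref_ids = [m.sample_id for m in ref]
    alt_ids = [m.sample_id for m in alt]
    if ref_ids != alt_ids:
        raise ValueError(f"sample ids differ between methods: {ref_ids} vs {alt_ids}")
    rows = []
    for m_ref, m_alt in zip(ref, alt):
        f_val = variance_ratio_f(m_ref, m_alt)
        f_crit = critical_f(alpha, m_ref.n - 1, m_alt.n - 1)
        re = relative_error_pct(m_ref.mean, m_alt.mean)
        t_val = t_crit = t_p = None
        if diffs is not None and m_ref.sample_id in diffs:
            d = diffs[m_ref.sample_id]
            t_val, t_p = paired_t(d)
            t_crit = critical_t(alpha, len(d) - 1)
        equivalent = f_val < f_crit and (t_val is None or abs(t_val) < t_crit)
        rows.append(
            ComparisonRow(
                sample_id=m_ref.sample_id,
                ref_mean=m_ref.mean,
                alt_mean=m_alt.mean,
                f_value=f_val,
                f_crit=f_crit,
                relative_error_pct=re,
                equivalent=equivalent,
                compliant=compliance(m_ref.mean, limit) and compliance(m_alt.mean, limit),
                t_value=t_val,
                t_crit=t_crit,
                t_p=t_p,
            )
        )
    table = pd.DataFrame([r.__dict__ for r in rows])
    max_idx = int(table["relative_error_pct"].idxmax())
    summary = {
        "ref_min": float(table["ref_mean"].min()),
        "ref_max": float(table["ref_mean"].max()),
        "alt_min": float(table["alt_mean"].min()),
        "alt_max": float(table["alt_mean"].max()),
        "max_relative_error_pct": float(table["relative_error_pct"].max()),
        "max_relative_error_sample": str(table.loc[max_idx, "sample_id"]),
        "all_equivalent": bool(table["equivalent"].all()),
        "all_compliant": bool(table["compliant"].all()),
    }
    return table, summary
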