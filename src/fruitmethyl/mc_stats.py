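"""Bisulfite conversion, binomial methylcytosine calling, weighted levels.

The non-conversion rate is estimated from an unmethylated spike-in control
(lambda-phage style): every methylated read observed on the control is a
conversion failure, so the pooled conversion rate is
``1 - sum(c_count) / sum(total_count)`` over control cytosines — the maximum
likelihood estimate under a common per-read rate.

A cytosine is called a methylcytosine when its methylated read count is
implausibly high under pure non-conversion noise: one-sided upper-tail exact
binomial p = P(X >= c | n = total_count, p0 = 1 - conversion_rate), called at
p < alpha (default 0.05, no multiple-testing correction — alpha is exposed).

The methylation level of any set of cytosines is the weighted methylation
level #C / (#C + #T): total methylated reads over total covering reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .methylome_io import CONTEXTS, NoDataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConversionEstimate:
    """Pooled bisulfite conversion rate from spike-in control cytosines."""

    conversion_rate: float
    n_sites: int
    n_reads: int

    @property
    def non_conversion_rate(self) -> float:
        return 1.0 - self.conversion_rate


@dataclass
class McCallResult:
    """Per-site methylcytosine calls plus the count of uncovered sites skipped."""

    calls: pd.DataFrame  # records + p_value, is_methylcytosine
    n_skipped: int
    alpha: float


def estimate_conversion(control_records: pd.DataFrame) -> ConversionEstimate:
    """Pool all control cytosines into one conversion-rate estimate.

    Raises :class:`NoDataError` when the control carries zero read coverage.
    """
    n_reads = int(control_records["total_count"].sum()) if len(control_records) else 0
    if n_reads == 0:
        raise NoDataError("control has zero total read coverage; cannot estimate conversion")
    n_meth = int(control_records["c_count"].sum())
    rate = 1.0 - n_meth / n_reads
    return ConversionEstimate(
        conversion_rate=rate, n_sites=int(len(control_records)), n_reads=n_reads
    )


def binomial_tail_p(c_count, total_count, p0: float) -> np.ndarray:
    """Exact one-sided upper-tail binomial p-value P(X >= c | n, p0)."""
    c = np.asarray(c_count, dtype=np.int64)
    n = np.asarray(total_count, dtype=np.int64)
    # sf(c-1) = P(X >= c); c = 0 gives exactly 1
    return stats.binom.sf(c - 1, n, p0)


def call_methylcytosines(
    records: pd.DataFrame,
    conversion: ConversionEstimate,
    alpha: float = 0.05,
) -> McCallResult:
    """Call methylcytosines by the exact binomial test against non-conversion.

    Sites with ``total_count == 0`` cannot be tested; they are dropped and
    counted in ``n_skipped``.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    covered = records["total_count"] > 0
    n_skipped = int((~covered).sum())
    if n_skipped:
        logger.info("call_methylcytosines: skipped %d uncovered sites", n_skipped)
    calls = records.loc[covered].copy()
    p0 = conversion.non_conversion_rate
    calls["p_value"] = binomial_tail_p(calls["c_count"], calls["total_count"], p0)
    calls["is_methylcytosine"] = calls["p_value"] < alpha
    return McCallResult(calls=calls, n_skipped=n_skipped, alpha=alpha)


def weighted_level(records: pd.DataFrame) -> float:
    """Weighted methylation level #C/(#C+#T) over a set of cytosines.

    Raises :class:`NoDataError` on an empty or zero-coverage subset — the
    level of no data is undefined, never 0.
    """
    total = int(records["total_count"].sum()) if len(records) else 0
    if total == 0:
        raise NoDataError("no covered cytosines; weighted level undefined")
    return float(records["c_count"].sum()) / total


def mc_proportion(result: McCallResult, context: str) -> float:
    """Fraction of covered cytosines of a context called methylcytosines."""
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    sub = result.calls[result.calls["context"] == context]
    if len(sub) == 0:
        raise NoDataError(f"no covered {context} cytosines")
    return float(sub["is_methylcytosine"].mean())


def context_summary(records: pd.DataFrame, result: McCallResult) -> pd.DataFrame:
    """Per-context weighted level and methylcytosine proportion."""
    rows = []
    for ctx in CONTEXTS:
        sub = records[records["context"] == ctx]
        try:
            level = weighted_level(sub)
        except NoDataError:
            level = np.nan
        try:
            prop = mc_proportion(result, ctx)
        except NoDataError:
            prop = np.nan
        rows.append({"context": ctx, "level": level, "mc_proportion": prop})
    return pd.DataFrame(rows)
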