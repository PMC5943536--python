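"""Control expression ranges, cloglog intervals, and aberrance calls.

Controls define, per event, a reference range mean ± z·SEM across the
qualifying control samples.  A sample qualifies only when it carries more
than 10,000 reads for the gene and expresses at least two minor
transcripts; an event's range uses only controls expressing it with more
than 10 reads, and needs at least two of them.  Carrier proportions get a
complementary log–log confidence interval; an event is called above/below
the control range when its interval is disjoint from the range.  Fold
change is carrier proportion over control mean.  All thresholds are strict
("more than") and surfaced as parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .errors import ConfigError
from .quantify import DETECTION_READS, ExpressionProfile

logger = logging.getLogger(__name__)

WITHIN_RANGE = "within_range"
ABOVE_RANGE = "above_range"
BELOW_RANGE = "below_range"
NOT_EXPRESSED_IN_CONTROLS = "not_expressed_in_controls"


@dataclass(frozen=True)
class RangeCriteria:
    """Inclusion criteria for the control expression ranges.

    Thresholds use strict ">" semantics: an event counts as expressed with
    more than ``min_event_reads`` reads, and a sample qualifies with more
    than ``min_gene_reads`` reads for the gene.
    """

    min_event_reads: int = 10
    min_gene_reads: int = 10_000
    min_minor_transcripts: int = 2
    confidence_level: float = 0.95


@dataclass(frozen=True)
class ControlRange:
    event: str
    n_controls_used: int
    mean_proportion: float
    lower: float
    upper: float
    included: bool
    reason: str = ""


@dataclass(frozen=True)
class ComparisonResult:
    sample_id: str
    event: str
    carrier_proportion: float
    ci_lower: float
    ci_upper: float
    ci_adjusted: bool
    fold_change: float
    flag: str


def cloglog_ci(x, n, level: float = 0.95):
    """Complementary log–log confidence interval for a binomial proportion.

    The interval is built on the scale g(p) = log(−log p) with the
    delta-method standard error sqrt((1−p̂)/(n·p̂·(log p̂)²)) and
    back-transformed, so both endpoints lie strictly inside (0, 1) and
    bracket p̂.  At the boundaries x = 0 or x = n an Anscombe-type
    continuity adjustment (x + 0.5, n + 1) is applied and flagged.

    Accepts scalars or arrays; returns ``(lower, upper, adjusted)``.
    """
    x_arr = np.asarray(x, dtype=float)
    n_arr = np.broadcast_to(np.asarray(n, dtype=float), x_arr.shape).copy()
    if np.any(n_arr <= 0):
        raise ValueError("n must be positive")
    if np.any((x_arr < 0) | (x_arr > n_arr)):
        raise ValueError("x must lie in [0, n]")
    adjusted = (x_arr == 0) | (x_arr == n_arr)
    x_adj = np.where(adjusted, x_arr + 0.5, x_arr)
    n_adj = np.where(adjusted, n_arr + 1.0, n_arr)
    p = x_adj / n_adj
    logp = np.log(p)
    g = np.log(-logp)
    se = np.sqrt((1.0 - p) / (n_adj * p * logp**2))
    z = norm.ppf(1.0 - (1.0 - level) / 2.0)
    # g is decreasing in p: the upper g-limit maps to the lower p-limit
    lower = np.exp(-np.exp(g + z * se))
    upper = np.exp(-np.exp(g - z * se))
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(lower), float(upper), bool(adjusted)
    return lower, upper, adjusted


def _qualifying_controls(
    profiles: Sequence[ExpressionProfile], criteria: RangeCriteria
) -> list[ExpressionProfile]:
    kept = []
    for p in profiles:
        if p.gene_total_reads <= criteria.min_gene_reads:
            logger.info("%s: dropped from ranges (gene reads %d <= %d)",
                        p.sample_id, p.gene_total_reads, criteria.min_gene_reads)
            continue
        minors = p.minor_transcripts(criteria.min_event_reads)
        if len(minors) < criteria.min_minor_transcripts:
            logger.info("%s: dropped from ranges (%d minor transcripts < %d)",
                        p.sample_id, len(minors), criteria.min_minor_transcripts)
            continue
        kept.append(p)
    return kept


def control_ranges(
    profiles: Sequence[ExpressionProfile],
    criteria: RangeCriteria = RangeCriteria(),
) -> list[ControlRange]:
    """Per-event control mean ± z·SEM ranges under the inclusion criteria."""
    if not profiles:
        raise ConfigError("no control profiles supplied")
    kept = _qualifying_controls(profiles, criteria)
    if not kept:
        raise ConfigError(
            "no control sample passes the per-gene read and minor-transcript "
            "criteria"
        )
    z = norm.ppf(1.0 - (1.0 - criteria.confidence_level) / 2.0)
    event_names = sorted({e for p in kept for e in p.counts_by_event})
    ranges = []
    for event in event_names:
        qualifying = [
            p for p in kept
            if p.counts_by_event.get(event, 0) > criteria.min_event_reads
        ]
        n = len(qualifying)
        if n < 2:
            ranges.append(
                ControlRange(event, n, float("nan"), float("nan"), float("nan"),
                             included=False,
                             reason=f"expressed >{criteria.min_event_reads} reads "
                                    f"in only {n} control(s)")
            )
            continue
        props = np.array([p.proportion_by_event[event] for p in qualifying])
        mean = float(props.mean())
        sem = float(props.std(ddof=1) / np.sqrt(n))
        ranges.append(
            ControlRange(event, n, mean, mean - z * sem, mean + z * sem,
                         included=True)
        )
    return ranges


def compare_sample(
    profile: ExpressionProfile,
    ranges: Sequence[ControlRange],
    level: float = 0.95,
) -> list[ComparisonResult]:
    """Compare one sample's event proportions against the control ranges."""
    by_event = {r.event: r for r in ranges}
    results = []
    for r in ranges:
        if not r.included:
            continue
        x = profile.counts_by_event.get(r.event, 0)
        p_hat = profile.proportion_by_event.get(r.event, 0.0)
        lo, hi, adj = cloglog_ci(x, profile.total_reads, level)
        fold = p_hat / r.mean_proportion if r.mean_proportion > 0 else float("nan")
        if lo > r.upper:
            flag = ABOVE_RANGE
        elif hi < r.lower:
            flag = BELOW_RANGE
        else:
            flag = WITHIN_RANGE
        results.append(
            ComparisonResult(profile.sample_id, r.event, p_hat, lo, hi, adj,
                             fold, flag)
        )
    # events expressed in the sample but without a usable control range
    for event, x in sorted(profile.counts_by_event.items()):
        if event in by_event and by_event[event].included:
            continue
        if x <= DETECTION_READS:
            continue
        lo, hi, adj = cloglog_ci(x, profile.total_reads, level)
        results.append(
            ComparisonResult(profile.sample_id, event,
                             profile.proportion_by_event[event], lo, hi, adj,
                             float("nan"), NOT_EXPRESSED_IN_CONTROLS)
        )
    return results


def detection_depth_fit(
    profiles: Sequence[ExpressionProfile],
    threshold: int = DETECTION_READS,
) -> tuple[float, float, float]:
    """OLS of detected-event count on per-gene read depth.

    Returns ``(slope, intercept, r_squared)`` of the regression of the
    number of alternative events with more than ``threshold`` reads on
    ``gene_total_reads``.
    """
    if len(profiles) < 3:
        raise ConfigError("detection-depth fit needs at least 3 profiles")
    y = np.array([len(p.detected_events(threshold)) for p in profiles], float)
    x = np.array([p.gene_total_reads for p in profiles], float)
    if np.ptp(x) == 0:
        raise ConfigError("constant read depth: regression undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return float(model.params[1]), float(model.params[0]), float(model.rsquared)


def presence_matrix(
    profiles: Sequence[ExpressionProfile],
    threshold: int = DETECTION_READS,
) -> pd.DataFrame:
    """Event × sample boolean detection table ordered by time point, replicate."""
    ordered = sorted(
        profiles,
        key=lambda p: (
            p.time_point if p.time_point is not None else -1,
            p.replicate_id or "",
            p.sample_id,
        ),
    )
    events = sorted(
        {e for p in profiles for e in {**p.counts_by_event, **p.excluded_counts}}
    )
    data = {
        p.sample_id: [
            {**p.counts_by_event, **p.excluded_counts}.get(e, 0) > threshold
            for e in events
        ]
        for p in ordered
    }
    return pd.DataFrame(data, index=pd.Index(events, name="event"))


def ranges_to_frame(ranges: Iterable[ControlRange]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in ranges])


def comparisons_to_frame(results: Iterable[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
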