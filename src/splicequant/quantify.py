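"""Reference-junction normalization of splice-event read counts.

The relative abundance of every splicing event in a sample is anchored to
the reference junction (RJ), the canonical junction between exons 2 and 3:

1. full-length = RJ − Σ counts of included events that do not overlap the
   RJ (events overlapping exons 2–3 are not deducted, because their reads
   never contributed to the RJ count in the first place);
2. total = full-length + Σ counts of all included alternative events;
3. proportion(event) = count(event) / total, and likewise for full-length.

Events flagged for questionable probe efficiency and common NAG acceptor
shifts are excluded from the sums: their counts are reported but inert.
The method deliberately does not model co-occurrence of events on one
transcript; concurrent events are double-counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

from .errors import NormalizationError
from .gene_model import (
    CANONICAL,
    FULL_LENGTH,
    RETENTION_INSERTION,
    GeneModel,
    Junction,
    SplicingEvent,
)
from .junction_io import SampleProfile

logger = logging.getLogger(__name__)

#: The only detectability threshold the quantification applies:
#: an event is "expressed"/"detected" when it has strictly more reads.
DETECTION_READS = 10


@dataclass
class EventCounts:
    """Classified event-level read counts for one sample and gene."""

    sample_id: str
    gene_id: str
    rj_count: int
    counts_by_event: dict[str, int]
    events: dict[str, SplicingEvent]
    excluded_events: set[str] = field(default_factory=set)

    def included_items(self) -> list[tuple[str, int]]:
        return [
            (name, n)
            for name, n in self.counts_by_event.items()
            if name not in self.excluded_events
        ]


@dataclass
class ExpressionProfile:
    """Relative expression of full-length and alternative events in a sample."""

    sample_id: str
    gene_id: str
    full_length_count: int
    total_reads: int
    proportion_by_event: dict[str, float]  # includes "full-length"
    counts_by_event: dict[str, int]  # included alternative events
    excluded_counts: dict[str, int]
    excluded_reasons: dict[str, str]
    gene_total_reads: int
    group: str = "control"
    nmd_inhibitor: bool = True
    replicate_id: Optional[str] = None
    time_point: Optional[int] = None

    def detected_events(self, threshold: int = DETECTION_READS) -> list[str]:
        """Alternative events (included or excluded) with count > threshold."""
        allc = {**self.counts_by_event, **self.excluded_counts}
        return [e for e, n in allc.items() if n > threshold]

    def minor_transcripts(self, threshold: int = DETECTION_READS) -> list[str]:
        """Included non-full-length events expressed above the read threshold."""
        return [e for e, n in self.counts_by_event.items() if n > threshold]


def count_events(profile: SampleProfile, gm: GeneModel) -> EventCounts:
    """Classify a sample's junctions and collapse them to event counts.

    Canonical junctions other than the RJ carry no event; retention (▾)
    events, defined by two flanking junctions, are counted as the rounded
    mean of their two junction counts.
    """
    jcounts: dict[Junction, int] = {}
    for j, c in profile.counts_by_junction.items():
        jn = Junction(j.intron_start, j.intron_end, gm.strand)
        jcounts[jn] = jcounts.get(jn, 0) + c
    assembled = gm.assemble_events(jcounts.keys())
    rj_key = gm.reference_junction.key()
    rj_count = 0
    counts: dict[str, int] = {}
    events: dict[str, SplicingEvent] = {}
    excluded: set[str] = set()
    seen_retention: set[str] = set()
    for jn, count in jcounts.items():
        ev = assembled.get(jn)
        if ev is None:
            continue
        if ev.event_class == CANONICAL:
            if jn.key() == rj_key:
                rj_count += count
            continue
        if ev.event_class == RETENTION_INSERTION:
            if ev.name in seen_retention:
                continue
            seen_retention.add(ev.name)
            pair = sorted(ev.defining_junctions)
            count = int(round(
                sum(jcounts.get(p, 0) for p in pair) / len(pair)
            ))
        counts[ev.name] = counts.get(ev.name, 0) + count
        events[ev.name] = ev
        if ev.excluded_nag:
            excluded.add(ev.name)
    return EventCounts(
        sample_id=profile.sample_id,
        gene_id=profile.gene_id,
        rj_count=rj_count,
        counts_by_event=counts,
        events=events,
        excluded_events=excluded,
    )


def apply_exclusions(ec: EventCounts, exclusion_names: Iterable[str]) -> EventCounts:
    """Move probe-efficiency-flagged events to the excluded set.

    NAG events are always excluded; an exclusion list naming an unknown
    event yields a warning, not an error.
    """
    exclusion_names = list(exclusion_names)
    unknown = [n for n in exclusion_names if n not in ec.counts_by_event]
    if unknown:
        logger.warning("%s: exclusion list names unknown events %s",
                       ec.sample_id, unknown)
    excluded = set(ec.excluded_events)
    events = dict(ec.events)
    for name in exclusion_names:
        if name in ec.counts_by_event:
            excluded.add(name)
            events[name] = replace(events[name], excluded_probe_efficiency=True)
    return EventCounts(
        sample_id=ec.sample_id,
        gene_id=ec.gene_id,
        rj_count=ec.rj_count,
        counts_by_event=dict(ec.counts_by_event),
        events=events,
        excluded_events=excluded,
    )


def full_length_count(ec: EventCounts, clamp_fl_zero: bool = False) -> int:
    """Full-length reads: RJ minus included events that retain the RJ."""
    if ec.rj_count == 0:
        raise NormalizationError(
            f"{ec.sample_id}/{ec.gene_id}: reference junction has zero reads; "
            "gene not quantifiable"
        )
    deducted = sum(
        n for name, n in ec.included_items()
        if not ec.events[name].overlaps_reference
    )
    fl = ec.rj_count - deducted
    if fl < 0:
        if clamp_fl_zero:
            logger.warning(
                "%s/%s: full-length deficit %d clamped to 0 "
                "(probe artifact or mis-set overlap flags?)",
                ec.sample_id, ec.gene_id, -fl,
            )
            return 0
        raise NormalizationError(
            f"{ec.sample_id}/{ec.gene_id}: non-overlapping event reads exceed "
            f"the reference junction by {-fl}; "
            "signals a probe artifact or mis-set overlap flags"
        )
    return fl


def relative_proportions(
    ec: EventCounts,
    profile: Optional[SampleProfile] = None,
    clamp_fl_zero: bool = False,
) -> ExpressionProfile:
    """Normalize event counts to relative proportions (sums to 1)."""
    fl = full_length_count(ec, clamp_fl_zero=clamp_fl_zero)
    included = ec.included_items()
    total = fl + sum(n for _, n in included)
    if total == 0:
        raise NormalizationError(
            f"{ec.sample_id}/{ec.gene_id}: zero total reads after normalization"
        )
    proportions = {FULL_LENGTH: fl / total}
    for name, n in included:
        proportions[name] = n / total
    meta = {}
    if profile is not None:
        meta = dict(
            gene_total_reads=profile.gene_total_reads,
            group=profile.group,
            nmd_inhibitor=profile.nmd_inhibitor,
            replicate_id=profile.replicate_id,
            time_point=profile.time_point,
        )
    return ExpressionProfile(
        sample_id=ec.sample_id,
        gene_id=ec.gene_id,
        full_length_count=fl,
        total_reads=total,
        proportion_by_event=proportions,
        counts_by_event=dict(included),
        excluded_counts={
            name: ec.counts_by_event[name] for name in ec.excluded_events
        },
        excluded_reasons={
            name: ("nag" if ec.events[name].excluded_nag else "probe_efficiency")
            for name in ec.excluded_events
        },
        **{"gene_total_reads": total, **meta},
    )


def quantify_sample(
    profile: SampleProfile,
    gm: GeneModel,
    exclusions: Iterable[str] = (),
    clamp_fl_zero: bool = False,
) -> ExpressionProfile:
    """Convenience wrapper: classify, exclude, and normalize one sample."""
    ec = apply_exclusions(count_events(profile, gm), exclusions)
    return relative_proportions(ec, profile=profile, clamp_fl_zero=clamp_fl_zero)


def profiles_to_frame(profiles: Iterable[ExpressionProfile]) -> pd.DataFrame:
    """Long-format table of counts and proportions (reports round to 4 dp)."""
    rows = []
    for p in profiles:
        rows.append(
            dict(sample_id=p.sample_id, gene_id=p.gene_id, event=FULL_LENGTH,
                 count=p.full_length_count,
                 proportion=round(p.proportion_by_event[FULL_LENGTH], 4),
                 included=True, excluded_reason="")
        )
        for name, n in sorted(p.counts_by_event.items()):
            rows.append(
                dict(sample_id=p.sample_id, gene_id=p.gene_id, event=name,
                     count=n, proportion=round(p.proportion_by_event[name], 4),
                     included=True, excluded_reason="")
            )
        for name, n in sorted(p.excluded_counts.items()):
            reason = p.excluded_reasons.get(name, "excluded")
            rows.append(
                dict(sample_id=p.sample_id, gene_id=p.gene_id, event=name,
                     count=n, proportion=float("nan"),
                     included=False, excluded_reason=reason)
            )
    return pd.DataFrame(rows)
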