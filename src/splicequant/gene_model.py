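"""Gene structure, canonical junctions, and splicing-event classification.

A :class:`GeneModel` holds the ordered exons of one transcript and the
canonical junctions between adjacent exons.  Observed splice junctions
(1-based intron coordinates, the SJ.out.tab convention) are classified
against it into the field's event taxonomy: exon skips ("Δ10", "Δ9–10"),
partial exon deletions ("Δ1Aq"), NAG acceptor shifts (+3 nt alternative
acceptors), retained/inserted blocks ("▾20"), or novel junctions.

Coordinate conventions
----------------------
Exons are stored with 1-based inclusive genomic ``start``/``end``.
Junctions are keyed by their 1-based intron interval so that interop with
SJ.out.tab is lossless: ``donor_end = intron_start - 1`` and
``acceptor_start = intron_end + 1`` on the plus strand, mirrored on the
minus strand.  All "transcription order" logic (exon numbering, NAG
displacement direction) follows the strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import AnnotationError

logger = logging.getLogger(__name__)

#: STAR's default cap on intron length; junctions longer than this are not
#: produced by the mapping step this pipeline consumes.
MAX_INTRON_LENGTH = 100_000

#: Acceptor displacement (nt, in transcription direction) that defines a
#: NAG alternative-acceptor event: one NAG codon into the downstream exon.
NAG_SHIFT = 3


@dataclass(frozen=True, order=True)
class Junction:
    """One splice junction, keyed by its 1-based closed intron interval."""

    intron_start: int
    intron_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise ValueError(
                f"intron_start {self.intron_start} > intron_end {self.intron_end}"
            )
        if self.length > MAX_INTRON_LENGTH:
            raise ValueError(
                f"intron length {self.length} exceeds mapping cap {MAX_INTRON_LENGTH}"
            )

    @property
    def length(self) -> int:
        return self.intron_end - self.intron_start + 1

    @property
    def donor_end(self) -> int:
        """Last exonic base of the donor exon (transcription upstream)."""
        return self.intron_start - 1 if self.strand == "+" else self.intron_end + 1

    @property
    def acceptor_start(self) -> int:
        """First exonic base of the acceptor exon (transcription downstream)."""
        return self.intron_end + 1 if self.strand == "+" else self.intron_start - 1

    def key(self) -> tuple[int, int]:
        return (self.intron_start, self.intron_end)


@dataclass(frozen=True)
class Exon:
    label: str
    start: int  # 1-based inclusive genomic
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# Event classes of the taxonomy.
CANONICAL = "canonical"
EXON_SKIP = "exon_skip"
MULTI_EXON_SKIP = "multi_exon_skip"
PARTIAL_EXON_DELETION = "partial_exon_deletion"
RETENTION_INSERTION = "retention_insertion"
NAG_SHIFT_CLASS = "nag_shift"
NOVEL_JUNCTION = "novel_junction"

FULL_LENGTH = "full-length"


@dataclass(frozen=True)
class SplicingEvent:
    """A named alternative splicing event defined by its junction set."""

    name: str
    event_class: str
    defining_junctions: frozenset
    skipped_exons: frozenset = frozenset()
    in_frame: Optional[bool] = None
    overlaps_reference: bool = False
    excluded_probe_efficiency: bool = False
    excluded_nag: bool = False

    @property
    def excluded(self) -> bool:
        return self.excluded_probe_efficiency or self.excluded_nag

    @property
    def is_canonical(self) -> bool:
        return self.event_class == CANONICAL


class GeneModel:
    """Ordered exon structure of one gene; coordinate frame of record."""

    def __init__(
        self,
        gene_id: str,
        chromosome: str,
        strand: str,
        exons: Sequence[Exon],
        rj_exons: Optional[tuple[str, str]] = None,
    ):
        if strand not in "+-":
            raise AnnotationError(f"strand must be '+' or '-', got {strand!r}")
        if len(exons) < 2:
            raise AnnotationError("a gene model needs at least 2 exons")
        genomic = sorted(exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if b.start <= a.end:
                raise AnnotationError(f"exons {a.label} and {b.label} overlap")
        labels = [e.label for e in exons]
        if len(set(labels)) != len(labels):
            raise AnnotationError("exon labels are not unique")
        # transcription order: ascending genomic for +, descending for -
        self.exons: tuple[Exon, ...] = tuple(
            genomic if strand == "+" else genomic[::-1]
        )
        self.gene_id = gene_id
        self.chromosome = chromosome
        self.strand = strand
        self._index = {e.label: i for i, e in enumerate(self.exons)}
        self.canonical_junctions: tuple[Junction, ...] = tuple(
            self._junction_between(i, i + 1) for i in range(len(self.exons) - 1)
        )
        self._canonical_by_key = {
            j.key(): i for i, j in enumerate(self.canonical_junctions)
        }
        if rj_exons is None:
            if "2" in self._index and "3" in self._index:
                rj_exons = ("2", "3")
            else:
                rj_exons = (self.exons[1].label, self.exons[2].label)
        up, down = rj_exons
        if self._index.get(down, -1) != self._index.get(up, -99) + 1:
            raise AnnotationError(
                f"reference-junction exons {rj_exons} are not transcription-adjacent"
            )
        self.rj_exons = rj_exons

    # -- structure ---------------------------------------------------------

    def _junction_between(self, i: int, k: int) -> Junction:
        """Junction joining the canonical boundaries of exons i and k (i < k)."""
        up, down = self.exons[i], self.exons[k]
        if self.strand == "+":
            return Junction(up.end + 1, down.start - 1, "+")
        return Junction(down.end + 1, up.start - 1, "-")

    def exon(self, label: str) -> Exon:
        return self.exons[self._index[label]]

    def exon_index(self, label: str) -> int:
        return self._index[label]

    @property
    def span(self) -> tuple[int, int]:
        starts = [e.start for e in self.exons]
        ends = [e.end for e in self.exons]
        return (min(starts), max(ends))

    @property
    def reference_junction(self) -> Junction:
        """The canonical junction anchoring normalization (exon 2→3 by default)."""
        return self.canonical_junctions[self._index[self.rj_exons[0]]]

    def donor_boundary(self, i: int) -> int:
        """Genomic coordinate of the last base of exon i in transcription order."""
        e = self.exons[i]
        return e.end if self.strand == "+" else e.start

    def acceptor_boundary(self, i: int) -> int:
        """Genomic coordinate of the first base of exon i in transcription order."""
        e = self.exons[i]
        return e.start if self.strand == "+" else e.end

    def _downstream_shift(self, pos: int, nt: int) -> int:
        """Move a coordinate nt bases downstream in transcription direction."""
        return pos + nt if self.strand == "+" else pos - nt

    def contains(self, j: Junction) -> bool:
        lo, hi = self.span
        return lo <= j.intron_start and j.intron_end <= hi

    # -- classification ----------------------------------------------------

    def classify_junction(self, j: Junction) -> Optional[SplicingEvent]:
        """Classify one observed junction against this gene model.

        Returns ``None`` (and logs) for junctions outside the gene span.
        Canonical junctions yield a sentinel event with class ``canonical``.
        """
        if not self.contains(j):
            logger.warning(
                "%s: junction %s-%s outside gene span, skipped",
                self.gene_id, j.intron_start, j.intron_end,
            )
            return None
        jn = Junction(j.intron_start, j.intron_end, self.strand)
        if jn.key() in self._canonical_by_key:
            i = self._canonical_by_key[jn.key()]
            return SplicingEvent(
                name=f"canonical {self.exons[i].label}-{self.exons[i + 1].label}",
                event_class=CANONICAL,
                defining_junctions=frozenset([jn]),
                in_frame=True,
            )

        donor_idx = self._match_boundary(jn.donor_end, self.donor_boundary)
        acceptor_idx = self._match_boundary(jn.acceptor_start, self.acceptor_boundary)

        # NAG: canonical donor, acceptor displaced exactly +3 nt into an exon.
        if donor_idx is not None:
            for k in range(donor_idx + 1, len(self.exons)):
                shifted = self._downstream_shift(self.acceptor_boundary(k), NAG_SHIFT)
                if jn.acceptor_start == shifted:
                    skipped = frozenset(
                        e.label for e in self.exons[donor_idx + 1 : k]
                    )
                    frame_len = NAG_SHIFT + sum(
                        self.exon(l).length for l in skipped
                    )
                    return SplicingEvent(
                        name=f"NAG{self.exons[k].label}",
                        event_class=NAG_SHIFT_CLASS,
                        defining_junctions=frozenset([jn]),
                        skipped_exons=skipped,
                        in_frame=frame_len % 3 == 0,
                        excluded_nag=True,
                    )

        if donor_idx is not None and acceptor_idx is not None:
            if acceptor_idx > donor_idx + 1:
                skipped = self.exons[donor_idx + 1 : acceptor_idx]
                labels = frozenset(e.label for e in skipped)
                return SplicingEvent(
                    name=self._skip_name([e.label for e in skipped]),
                    event_class=EXON_SKIP if len(skipped) == 1 else MULTI_EXON_SKIP,
                    defining_junctions=frozenset([jn]),
                    skipped_exons=labels,
                    in_frame=sum(e.length for e in skipped) % 3 == 0,
                )
            # backwards or adjacent-but-noncanonical: treat as novel
            return self._novel(jn)

        # Partial exon deletion: exactly one side internal to an exon.
        if donor_idx is not None and acceptor_idx is None:
            k = self._exon_containing(jn.acceptor_start)
            if k is not None and k > donor_idx:
                deleted = self._offset_into(k, jn.acceptor_start, side="acceptor")
                skipped = frozenset(e.label for e in self.exons[donor_idx + 1 : k])
                frame_len = deleted + sum(self.exon(l).length for l in skipped)
                return SplicingEvent(
                    name=self._partial_name(k, "p", skipped),
                    event_class=PARTIAL_EXON_DELETION,
                    defining_junctions=frozenset([jn]),
                    skipped_exons=skipped | {self.exons[k].label},
                    in_frame=frame_len % 3 == 0,
                )
        if acceptor_idx is not None and donor_idx is None:
            i = self._exon_containing(jn.donor_end)
            if i is not None and i < acceptor_idx:
                deleted = self._offset_into(i, jn.donor_end, side="donor")
                skipped = frozenset(e.label for e in self.exons[i + 1 : acceptor_idx])
                frame_len = deleted + sum(self.exon(l).length for l in skipped)
                return SplicingEvent(
                    name=self._partial_name(i, "q", skipped),
                    event_class=PARTIAL_EXON_DELETION,
                    defining_junctions=frozenset([jn]),
                    skipped_exons=skipped | {self.exons[i].label},
                    in_frame=frame_len % 3 == 0,
                )

        return self._novel(jn)

    def _novel(self, jn: Junction) -> SplicingEvent:
        return SplicingEvent(
            name=f"j{jn.intron_start}-{jn.intron_end}",
            event_class=NOVEL_JUNCTION,
            defining_junctions=frozenset([jn]),
        )

    def _match_boundary(self, pos: int, boundary) -> Optional[int]:
        for i in range(len(self.exons)):
            if boundary(i) == pos:
                return i
        return None

    def _exon_containing(self, pos: int) -> Optional[int]:
        for i, e in enumerate(self.exons):
            if e.start <= pos <= e.end:
                return i
        return None

    def _offset_into(self, idx: int, pos: int, side: str) -> int:
        """Number of exonic bases removed by an internal donor/acceptor."""
        e = self.exons[idx]
        if side == "acceptor":
            # bases lost from the transcription 5' end of the exon
            return (
                pos - e.start if self.strand == "+" else e.end - pos
            )
        # donor internal: bases lost from the transcription 3' end
        return e.end - pos if self.strand == "+" else pos - e.start

    def _skip_name(self, labels: Sequence[str]) -> str:
        if len(labels) == 1:
            return f"Δ{labels[0]}"
        return f"Δ{labels[0]}–{labels[-1]}"

    def _partial_name(self, idx: int, suffix: str, skipped: frozenset) -> str:
        label = self.exons[idx].label
        if skipped:
            ordered = [e.label for e in self.exons if e.label in skipped]
            first = ordered[0] if suffix == "p" else label
            last = label if suffix == "p" else ordered[-1]
            return f"Δ{first}–{last}{suffix}"
        return f"Δ{label}{suffix}"

    # -- retention pairing -------------------------------------------------

    def assemble_events(
        self, junctions: Iterable[Junction]
    ) -> dict[Junction, SplicingEvent]:
        """Classify a junction set, pairing retention halves into ▾ events.

        A retained/inserted block between transcription-adjacent exons n and
        n+1 is only called when exactly one left half-junction (sharing the
        canonical intron's donor-side boundary) and one right half-junction
        (sharing its acceptor-side boundary) flank a block of at least 1 nt;
        unpaired halves stay ``novel_junction``.
        """
        events: dict[Junction, SplicingEvent] = {}
        novel: list[Junction] = []
        for j in junctions:
            ev = self.classify_junction(j)
            if ev is None:
                continue
            jn = next(iter(ev.defining_junctions))
            if ev.event_class == NOVEL_JUNCTION:
                novel.append(jn)
            events[jn] = ev

        for i, c in enumerate(self.canonical_junctions):
            lefts = [
                j for j in novel
                if j.intron_start == c.intron_start and j.intron_end < c.intron_end
            ]
            rights = [
                j for j in novel
                if j.intron_end == c.intron_end and j.intron_start > c.intron_start
            ]
            if len(lefts) == 1 and len(rights) == 1:
                left, right = lefts[0], rights[0]
                block = right.intron_start - left.intron_end - 1
                if block >= 1:
                    ev = SplicingEvent(
                        name=f"▾{self.exons[i].label}",
                        event_class=RETENTION_INSERTION,
                        defining_junctions=frozenset([left, right]),
                        in_frame=block % 3 == 0,
                    )
                    events[left] = ev
                    events[right] = ev
        return {
            j: replace(ev, overlaps_reference=self.overlaps_reference(ev))
            for j, ev in events.items()
        }

    # -- reference-junction overlap ----------------------------------------

    def overlaps_reference(self, ev: SplicingEvent) -> bool:
        """True iff the event's transcript form lacks the canonical RJ junction.

        Operationalized as: the skipped/deleted footprint touches either RJ
        exon, or a defining junction's intron interval intersects the RJ
        intron (which covers NAG shifts of the RJ acceptor and retained
        blocks inside the RJ intron).
        """
        if ev.event_class == CANONICAL:
            return False
        if ev.skipped_exons & set(self.rj_exons):
            return True
        rj = self.reference_junction
        for j in ev.defining_junctions:
            if j.intron_start <= rj.intron_end and rj.intron_start <= j.intron_end:
                return True
        return False


def name_event(ev: SplicingEvent) -> str:
    """Canonical display name of a classified event (stable, deterministic)."""
    return ev.name


# ---------------------------------------------------------------------------
# annotation input


def build_gene_model(
    exon_table: pd.DataFrame,
    strand: Optional[str] = None,
    rj_exons: Optional[tuple[str, str]] = None,
) -> GeneModel:
    """Build a :class:`GeneModel` from annotation rows.

    ``exon_table`` needs columns ``gene_id, exon_label, chrom, start, end``
    and optionally ``strand``.  All rows must belong to one gene on one
    chromosome and strand.
    """
    required = {"gene_id", "exon_label", "chrom", "start", "end"}
    missing = required - set(exon_table.columns)
    if missing:
        raise AnnotationError(f"exon table missing columns: {sorted(missing)}")
    if exon_table.empty:
        raise AnnotationError("empty exon table")
    genes = exon_table["gene_id"].unique()
    chroms = exon_table["chrom"].unique()
    if len(genes) != 1 or len(chroms) != 1:
        raise AnnotationError("exon table must describe one gene on one chromosome")
    if "strand" in exon_table.columns:
        strands = exon_table["strand"].unique()
        if len(strands) != 1:
            raise AnnotationError("mixed strands in exon table")
        if strand is not None and strand != strands[0]:
            raise AnnotationError("strand argument contradicts annotation")
        strand = strands[0]
    if strand is None:
        raise AnnotationError("strand not given in table or argument")
    exons = [
        Exon(str(r.exon_label), int(r.start), int(r.end))
        for r in exon_table.itertuples()
    ]
    return GeneModel(str(genes[0]), str(chroms[0]), strand, exons, rj_exons=rj_exons)


def read_exon_tsv(path, strand: Optional[str] = None, **kw) -> GeneModel:
    """Read the 5-column exon TSV (gene_id, exon_label, chrom, start, end)."""
    table = pd.read_csv(path, sep="\t", dtype={"exon_label": str})
    return build_gene_model(table, strand=strand, **kw)


def read_gtf(path, gene_id: Optional[str] = None, **kw) -> GeneModel:
    """Read exon features of one transcript from a GTF file.

    The ``exon_number`` attribute is honored as the exon label when present.
    """
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    df = df[df["Feature"] == "exon"]
    if gene_id is not None:
        df = df[df["gene_id"] == gene_id]
    if df.empty:
        raise AnnotationError(f"no exon features found in {path}")
    table = pd.DataFrame(
        {
            "gene_id": df["gene_id"].astype(str),
            "exon_label": (
                df["exon_number"].astype(str)
                if "exon_number" in df.columns
                else [str(i + 1) for i in range(len(df))]
            ),
            "chrom": df["Chromosome"].astype(str),
            # pyranges uses 0-based half-open coordinates
            "start": df["Start"].astype(int) + 1,
            "end": df["End"].astype(int),
            "strand": df["Strand"].astype(str),
        }
    )
    return build_gene_model(table, **kw)
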