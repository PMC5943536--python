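"""Reading STAR SJ.out.tab files and sample manifests; per-sample aggregation.

SJ.out.tab is tab-delimited with 9 columns and 1-based closed intron
coordinates: chromosome, intron start, intron end, strand code (0
undefined, 1 +, 2 -), intron motif code, annotated flag, unique-mapping
read count, multi-mapping read count, maximum spliced-alignment overhang.
Only unique-mapping reads enter quantification downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import ParseError
from .gene_model import GeneModel, Junction

logger = logging.getLogger(__name__)

STRAND_CODES = {0: None, 1: "+", 2: "-"}

MANIFEST_COLUMNS = [
    "sample_id", "group", "nmd_inhibitor", "replicate_id", "time_point", "sj_path",
]


@dataclass(frozen=True)
class JunctionRecord:
    """One SJ.out.tab row."""

    chromosome: str
    intron_start: int
    intron_end: int
    strand_code: int
    motif_code: int
    annotated_flag: int
    unique_reads: int
    multimapped_reads: int
    max_overhang: int

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise ParseError(
                f"intron_start {self.intron_start} > intron_end {self.intron_end}"
            )
        if min(self.unique_reads, self.multimapped_reads, self.max_overhang) < 0:
            raise ParseError("negative count field")

    def to_line(self) -> str:
        return "\t".join(
            str(v)
            for v in (
                self.chromosome, self.intron_start, self.intron_end,
                self.strand_code, self.motif_code, self.annotated_flag,
                self.unique_reads, self.multimapped_reads, self.max_overhang,
            )
        )


def read_sj_tab(path) -> list[JunctionRecord]:
    """Parse an SJ.out.tab file; no filtering is applied at this stage."""
    records: list[JunctionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                records.append(
                    JunctionRecord(
                        chromosome=fields[0],
                        intron_start=int(fields[1]),
                        intron_end=int(fields[2]),
                        strand_code=int(fields[3]),
                        motif_code=int(fields[4]),
                        annotated_flag=int(fields[5]),
                        unique_reads=int(fields[6]),
                        multimapped_reads=int(fields[7]),
                        max_overhang=int(fields[8]),
                    )
                )
            except (ValueError, ParseError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    if not records:
        logger.warning("%s: no junction records found", path)
    return records


def write_sj_tab(records: Iterable[JunctionRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(r.to_line() + "\n")


def read_manifest(path) -> pd.DataFrame:
    """Read the sample manifest TSV and validate its contract.

    Relative ``sj_path`` entries are resolved against the manifest's own
    directory.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "replicate_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: manifest missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"{path}: duplicate sample_ids {dup}")
    bad = set(df["group"]) - {"control", "carrier"}
    if bad:
        raise ParseError(f"{path}: unknown group values {sorted(bad)}")
    df["nmd_inhibitor"] = df["nmd_inhibitor"].astype(bool)
    base = Path(path).parent
    df["sj_path"] = [
        str(p) if Path(p).is_absolute() else str(base / p) for p in df["sj_path"]
    ]
    return df


@dataclass
class SampleProfile:
    """Per-sample junction counts restricted to one gene's span."""

    sample_id: str
    gene_id: str
    counts_by_junction: dict[Junction, int]
    gene_total_reads: int
    group: str = "control"
    nmd_inhibitor: bool = True
    replicate_id: Optional[str] = None
    time_point: Optional[int] = None


def aggregate_profile(
    records: Iterable[JunctionRecord],
    gm: GeneModel,
    sample_id: str = "sample",
    **metadata,
) -> SampleProfile:
    """Aggregate junction records into one per-gene sample profile.

    Keeps records whose intron lies within the gene span, on the gene's
    chromosome, with a compatible strand code (code 0 "undefined" is
    retained).  Counts of duplicate junction keys are summed.
    """
    counts: dict[Junction, int] = {}
    dropped = 0
    lo, hi = gm.span
    for r in records:
        if r.chromosome != gm.chromosome or r.intron_start < lo or r.intron_end > hi:
            dropped += 1
            continue
        strand = STRAND_CODES.get(r.strand_code)
        if strand is not None and strand != gm.strand:
            dropped += 1
            continue
        j = Junction(r.intron_start, r.intron_end, gm.strand)
        counts[j] = counts.get(j, 0) + r.unique_reads
    if dropped:
        logger.info("%s/%s: dropped %d out-of-scope junction records",
                    sample_id, gm.gene_id, dropped)
    return SampleProfile(
        sample_id=sample_id,
        gene_id=gm.gene_id,
        counts_by_junction=counts,
        gene_total_reads=sum(counts.values()),
        **metadata,
    )


def load_profiles(manifest: pd.DataFrame, gm: GeneModel) -> list[SampleProfile]:
    """Read every sample's SJ file named in the manifest and aggregate it."""
    profiles = []
    for row in manifest.itertuples():
        records = read_sj_tab(row.sj_path)
        tp = None if pd.isna(row.time_point) else int(row.time_point)
        profiles.append(
            aggregate_profile(
                records, gm, sample_id=row.sample_id,
                group=row.group, nmd_inhibitor=bool(row.nmd_inhibitor),
                replicate_id=row.replicate_id, time_point=tp,
            )
        )
    return profiles
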