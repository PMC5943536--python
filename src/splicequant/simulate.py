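"""Synthetic targeted-RNA-seq junction-count datasets with known truth.

The generator emulates the statistical structure of targeted junction
counts over one gene: a dominant full-length isoform plus minor
alternative isoforms, each defined by its junction set; wide per-sample
sequencing-depth variation (lognormal); Poisson or negative-binomial
counting noise; suppression of out-of-frame isoforms in samples not
treated with an NMD inhibitor; per-probe efficiency artifacts (an
"overinflated" probe multiplies one junction's counts); and spiked fold
increases for spliceogenic-variant carriers.

Expected count of junction j in sample s:

    mu(s, j) = depth_s * probe_efficiency(j) * sum over isoforms i containing j
               of theta'_i(s)

where theta'(s) is the isoform proportion vector after NMD and variant
adjustment, renormalized to sum to one.  Each sample draws from its own
RNG substream of the master seed, so adding a sample never perturbs the
counts of existing samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigError
from .gene_model import Exon, GeneModel, Junction
from .junction_io import JunctionRecord, SampleProfile

#: exon-length overrides making the default gene's skip events carry the
#: intended reading frame (lengths not divisible by 3 give out-of-frame skips)
_DEFAULT_EXON_LENGTHS = {7: 110, 9: 140, 10: 130, 12: 100, 17: 100, 21: 140}


@dataclass(frozen=True)
class GeneSpec:
    """Parametric toy-gene layout (uniform introns, labelled exons 1..n)."""

    gene_id: str = "GENE1"
    chromosome: str = "chrT"
    strand: str = "+"
    n_exons: int = 24
    exon_length: int = 120
    intron_length: int = 2000
    exon_length_overrides: dict = field(default_factory=lambda: dict(_DEFAULT_EXON_LENGTHS))

    def build(self) -> GeneModel:
        exons = []
        pos = 1000
        for i in range(1, self.n_exons + 1):
            ln = self.exon_length_overrides.get(i, self.exon_length)
            exons.append(Exon(str(i), pos, pos + ln - 1))
            pos += ln + self.intron_length
        if self.strand == "-":
            # mirror so exon 1 sits at the high-coordinate end
            hi = exons[-1].end + 1000
            exons = [Exon(e.label, hi - e.end, hi - e.start) for e in exons]
        return GeneModel(self.gene_id, self.chromosome, self.strand, exons)


@dataclass(frozen=True)
class IsoformDef:
    """One simulated isoform: an event kind plus its defining parameters.

    kind: "full_length" | "skip" (exons: skipped labels) | "nag"
    (exons: [acceptor exon]) | "retention" (exons: [upstream exon],
    block = (offset_nt, length_nt) inside the downstream intron).
    """

    name: str
    proportion: float
    kind: str = "skip"
    exons: tuple = ()
    block: Optional[tuple] = None
    in_frame: Optional[bool] = None

    def junctions(self, gm: GeneModel) -> frozenset:
        canonical = list(gm.canonical_junctions)
        if self.kind == "full_length":
            return frozenset(canonical)
        if self.kind == "skip":
            idx = sorted(gm.exon_index(l) for l in self.exons)
            if idx != list(range(idx[0], idx[-1] + 1)):
                raise ConfigError(f"{self.name}: skipped exons not contiguous")
            lo, hi = idx[0], idx[-1]
            if lo == 0 or hi == len(gm.exons) - 1:
                raise ConfigError(f"{self.name}: cannot skip a terminal exon")
            kept = [
                j for i, j in enumerate(canonical)
                if not (lo - 1 <= i <= hi)
            ]
            skip = gm._junction_between(lo - 1, hi + 1)
            return frozenset(kept + [skip])
        if self.kind == "nag":
            k = gm.exon_index(self.exons[0])
            c = canonical[k - 1]
            if gm.strand == "+":
                shifted = Junction(c.intron_start, c.intron_end + 3, "+")
            else:
                shifted = Junction(c.intron_start - 3, c.intron_end, "-")
            return frozenset([j for j in canonical if j != c] + [shifted])
        if self.kind == "retention":
            i = gm.exon_index(self.exons[0])
            c = canonical[i]
            offset, length = self.block
            start = c.intron_start + offset
            end = start + length - 1
            if not (c.intron_start < start and end < c.intron_end):
                raise ConfigError(f"{self.name}: retained block outside intron")
            left = Junction(c.intron_start, start - 1, gm.strand)
            right = Junction(end + 1, c.intron_end, gm.strand)
            return frozenset([j for j in canonical if j != c] + [left, right])
        raise ConfigError(f"{self.name}: unknown isoform kind {self.kind!r}")

    def frame(self, gm: GeneModel) -> bool:
        if self.in_frame is not None:
            return self.in_frame
        if self.kind == "full_length":
            return True
        if self.kind == "skip":
            return sum(gm.exon(l).length for l in self.exons) % 3 == 0
        if self.kind == "nag":
            return True
        if self.kind == "retention":
            return self.block[1] % 3 == 0
        raise ConfigError(self.kind)


def default_isoform_table() -> tuple[IsoformDef, ...]:
    """The default isoform mixture: dominant full-length plus minors.

    Proportions are chosen so that: in-frame minors stay detectable at any
    realistic depth; out-of-frame minors straddle the >10-read detection
    threshold when NMD suppresses them in untreated samples; three rare
    isoforms are detectable only at high depth, making the number of
    detected events depth-dependent.
    """
    return (
        IsoformDef("full-length", 0.9458, kind="full_length"),
        IsoformDef("Δ5", 0.020, exons=("5",)),
        IsoformDef("Δ9–10", 0.012, exons=("9", "10")),
        IsoformDef("Δ15", 0.008, exons=("15",)),
        IsoformDef("NAG8", 0.004, kind="nag", exons=("8",)),
        IsoformDef("Δ10", 0.004, exons=("10",)),
        IsoformDef("Δ12", 0.002, exons=("12",)),
        IsoformDef("▾20", 0.0015, kind="retention", exons=("20",), block=(200, 74)),
        IsoformDef("Δ21", 0.0012, exons=("21",)),
        IsoformDef("Δ7", 0.001, exons=("7",)),
        IsoformDef("Δ13", 0.00025, exons=("13",)),
        IsoformDef("Δ19", 0.00015, exons=("19",)),
        IsoformDef("Δ22", 0.0001, exons=("22",)),
    )


@dataclass(frozen=True)
class SimulationConfig:
    gene: GeneSpec = field(default_factory=GeneSpec)
    isoforms: tuple = field(default_factory=default_isoform_table)
    depth: float = 5e4
    depth_sigma: float = 0.5
    dispersion: Optional[float] = None  # NB size parameter; None => Poisson
    nmd_factor: float = 0.25
    probe_efficiency: dict = field(default_factory=dict)  # (start, end) -> mult
    variant_effects: dict = field(default_factory=dict)  # event or (sample, event) -> fold
    n_controls: int = 10
    n_carriers: int = 0
    n_time_points: int = 1
    n_replicates: int = 1
    treatments: tuple = (True,)  # nmd_inhibitor statuses emitted per individual
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(i.proportion for i in self.isoforms)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"isoform proportions sum to {total}, not 1")
        if not (0 < self.nmd_factor <= 1):
            raise ConfigError("nmd_factor must be in (0, 1]")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")

    # -- serialization (round-trippable) -----------------------------------

    def to_yaml(self) -> str:
        d = asdict(self)
        d["probe_efficiency"] = {f"{k[0]}-{k[1]}": v
                                 for k, v in self.probe_efficiency.items()}
        d["variant_effects"] = {
            (k if isinstance(k, str) else f"{k[0]}:{k[1]}"): v
            for k, v in self.variant_effects.items()
        }
        return yaml.safe_dump(d, allow_unicode=True, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        d = yaml.safe_load(text)
        d["gene"] = GeneSpec(**{
            **d["gene"],
            "exon_length_overrides": {
                int(k): v for k, v in d["gene"]["exon_length_overrides"].items()
            },
        })
        d["isoforms"] = tuple(
            IsoformDef(**{**i, "exons": tuple(i["exons"]),
                          "block": tuple(i["block"]) if i["block"] else None})
            for i in d["isoforms"]
        )
        d["probe_efficiency"] = {
            tuple(int(x) for x in k.split("-")): v
            for k, v in d.get("probe_efficiency", {}).items()
        }
        d["variant_effects"] = {
            (tuple(k.split(":", 1)) if ":" in k else k): v
            for k, v in d.get("variant_effects", {}).items()
        }
        d["treatments"] = tuple(d["treatments"])
        return cls(**d)


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    group: str
    nmd_inhibitor: bool
    replicate_id: str
    time_point: Optional[int]
    stream_index: int


def sample_table(cfg: SimulationConfig) -> list[SampleSpec]:
    """Deterministic sample layout: controls then carriers, expanded over
    treatments, time points and replicates."""
    samples = []
    idx = 0
    for group, count in (("control", cfg.n_controls), ("carrier", cfg.n_carriers)):
        prefix = "CTRL" if group == "control" else "CARR"
        for i in range(1, count + 1):
            for treated in cfg.treatments:
                for t in range(1, cfg.n_time_points + 1):
                    for r in range(1, cfg.n_replicates + 1):
                        parts = [f"{prefix}{i:02d}"]
                        if len(cfg.treatments) > 1:
                            parts.append("cx" if treated else "nt")
                        if cfg.n_time_points > 1:
                            parts.append(f"T{t}")
                        if cfg.n_replicates > 1:
                            parts.append(f"R{r}")
                        samples.append(
                            SampleSpec(
                                sample_id="_".join(parts),
                                group=group,
                                nmd_inhibitor=bool(treated),
                                replicate_id=f"R{r}",
                                time_point=t if cfg.n_time_points > 1 else None,
                                stream_index=idx,
                            )
                        )
                        idx += 1
    return samples


def effective_proportions(cfg: SimulationConfig, sample: SampleSpec,
                          gm: Optional[GeneModel] = None) -> np.ndarray:
    """Per-isoform proportions after NMD and variant adjustment.

    theta'_i is proportional to theta_i, damped by ``nmd_factor`` for
    out-of-frame isoforms in NMD-inhibitor-untreated samples, and
    multiplied by the configured fold for variant-targeted events in
    carrier samples; the result is renormalized to sum to one.
    """
    gm = gm or cfg.gene.build()
    theta = np.array([i.proportion for i in cfg.isoforms], float)
    for k, iso in enumerate(cfg.isoforms):
        if not sample.nmd_inhibitor and not iso.frame(gm):
            theta[k] *= cfg.nmd_factor
        if sample.group == "carrier":
            fold = cfg.variant_effects.get(iso.name)
            per_sample = cfg.variant_effects.get((sample.sample_id, iso.name))
            if per_sample is not None:
                fold = per_sample
            if fold is not None:
                theta[k] *= fold
    total = theta.sum()
    if total <= 0:
        raise ConfigError("all adjusted isoform weights are zero")
    return theta / total


@dataclass
class SimulatedSample:
    spec: SampleSpec
    depth: float
    records: list
    truth_proportions: dict  # isoform name -> effective proportion
    expected_counts: dict  # Junction -> expected count


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    gene_model: GeneModel
    samples: list


def _draw_counts(rng: np.random.Generator, mu: np.ndarray,
                 dispersion: Optional[float]) -> np.ndarray:
    if dispersion is None or not np.isfinite(dispersion):
        return rng.poisson(mu)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def simulate_counts(cfg: SimulationConfig) -> SimulatedDataset:
    """Draw per-sample junction counts and the matching truth table."""
    gm = cfg.gene.build()
    iso_junctions = []
    canonical = set(j.key() for j in gm.canonical_junctions)
    for iso in cfg.isoforms:
        js = iso.junctions(gm)
        for j in js:
            if not gm.contains(j):
                raise ConfigError(
                    f"{iso.name}: junction {j.key()} outside the gene model"
                )
        iso_junctions.append(js)
    all_junctions = sorted({j for js in iso_junctions for j in js})
    membership = np.array(
        [[j in js for js in iso_junctions] for j in all_junctions], dtype=float
    )
    efficiency = np.array(
        [cfg.probe_efficiency.get(j.key(), 1.0) for j in all_junctions]
    )
    strand_code = 1 if gm.strand == "+" else 2

    samples = []
    for spec in sample_table(cfg):
        rng = np.random.default_rng([cfg.seed, spec.stream_index])
        theta = effective_proportions(cfg, spec, gm)
        depth = (
            cfg.depth * np.exp(cfg.depth_sigma * rng.standard_normal())
            if cfg.depth_sigma > 0 else cfg.depth
        )
        mu = depth * efficiency * (membership @ theta)
        counts = (
            _draw_counts(rng, mu, cfg.dispersion) if cfg.noise
            else np.rint(mu).astype(int)
        )
        records = [
            JunctionRecord(
                chromosome=gm.chromosome,
                intron_start=j.intron_start,
                intron_end=j.intron_end,
                strand_code=strand_code,
                motif_code=1,
                annotated_flag=1 if j.key() in canonical else 0,
                unique_reads=int(c),
                multimapped_reads=0,
                max_overhang=50,
            )
            for j, c in zip(all_junctions, counts)
            if c > 0
        ]
        samples.append(
            SimulatedSample(
                spec=spec,
                depth=float(depth),
                records=records,
                truth_proportions={
                    iso.name: float(t) for iso, t in zip(cfg.isoforms, theta)
                },
                expected_counts={
                    j: float(m) for j, m in zip(all_junctions, mu)
                },
            )
        )
    return SimulatedDataset(config=cfg, gene_model=gm, samples=samples)


def dataset_profiles(ds: SimulatedDataset) -> list[SampleProfile]:
    """In-memory sample profiles, bypassing file round-trips."""
    from .junction_io import aggregate_profile

    return [
        aggregate_profile(
            s.records, ds.gene_model, sample_id=s.spec.sample_id,
            group=s.spec.group, nmd_inhibitor=s.spec.nmd_inhibitor,
            replicate_id=s.spec.replicate_id, time_point=s.spec.time_point,
        )
        for s in ds.samples
    ]


def write_dataset(ds: SimulatedDataset, outdir) -> Path:
    """Write SJ.out.tab files, manifest, truth table, exon table and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    truth_rows = []
    for s in ds.samples:
        sj_path = outdir / f"{s.spec.sample_id}.SJ.out.tab"
        with open(sj_path, "w") as fh:
            for r in s.records:
                fh.write(r.to_line() + "\n")
        # paths relative to the dataset dir keep same-seed runs byte-identical
        manifest_rows.append(
            (s.spec.sample_id, s.spec.group, s.spec.nmd_inhibitor,
             s.spec.replicate_id,
             "" if s.spec.time_point is None else s.spec.time_point,
             sj_path.name)
        )
        for name, t in s.truth_proportions.items():
            truth_rows.append((s.spec.sample_id, name, f"{t:.10g}"))
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("sample_id\tgroup\tnmd_inhibitor\treplicate_id\ttime_point\tsj_path\n")
        for row in manifest_rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("sample_id\tisoform\teffective_proportion\n")
        for row in truth_rows:
            fh.write("\t".join(row) + "\n")
    gm = ds.gene_model
    with open(outdir / "exons.tsv", "w") as fh:
        fh.write("gene_id\texon_label\tchrom\tstart\tend\tstrand\n")
        for e in gm.exons:
            fh.write(f"{gm.gene_id}\t{e.label}\t{gm.chromosome}\t{e.start}\t"
                     f"{e.end}\t{gm.strand}\n")
    with open(outdir / "config.yaml", "w") as fh:
        fh.write(ds.config.to_yaml())
    return outdir


def scenario_presets(seed: int = 0) -> dict[str, SimulationConfig]:
    """Named study-condition presets.

    - ``controls-only``: 10 NMD-inhibitor-treated controls (specificity).
    - ``nmd-contrast``: 5 individuals sequenced treated and untreated with a
      strong NMD factor, at modest depth (detectability contrast).
    - ``spliceogenic-carrier``: 10 controls plus one carrier with an
      8.8-fold spiked exon-skip event at high depth.
    - ``replicate-variability``: one individual over 6 time points with 3
      technical replicates at modest depth (presence/absence structure).
    """
    return {
        "controls-only": SimulationConfig(seed=seed),
        "nmd-contrast": SimulationConfig(
            seed=seed, n_controls=5, treatments=(True, False),
            nmd_factor=0.1, depth=2e4,
        ),
        "spliceogenic-carrier": SimulationConfig(
            seed=seed, n_controls=10, n_carriers=1, depth=1e5,
            variant_effects={"Δ10": 8.8},
        ),
        "replicate-variability": SimulationConfig(
            seed=seed, n_controls=1, n_time_points=6, n_replicates=3,
            depth=2e4,
        ),
    }
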