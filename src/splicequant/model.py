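"""Model/Results facade over the quantification and comparison pipeline.

:class:`SplicingComparison` is built from per-sample junction data plus a
gene model; :meth:`SplicingComparison.fit` normalizes every sample,
derives the control expression ranges under the inclusion criteria, and
compares every carrier sample against them, returning a
:class:`SplicingComparisonResults` that carries the estimates, their
intervals, diagnostics, a text ``summary()`` and a range plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import compare as _compare
from . import quantify as _quantify
from .compare import RangeCriteria
from .errors import ConfigError
from .gene_model import GeneModel
from .junction_io import SampleProfile, load_profiles, read_manifest


class SplicingComparison:
    """Carrier-versus-control splicing comparison for one gene.

    Parameters
    ----------
    profiles
        Per-sample junction-count profiles (``SampleProfile``), carrying
        group and NMD-treatment metadata.
    gene_model
        The gene's exon structure and reference junction.
    exclusions
        Event names excluded from normalization for questionable probe
        efficiency; NAG events are excluded automatically.
    criteria
        Control-range inclusion criteria (strict thresholds).
    clamp_fl_zero
        Clamp a negative full-length count to zero instead of raising.
    """

    def __init__(
        self,
        profiles: Sequence[SampleProfile],
        gene_model: GeneModel,
        exclusions: Iterable[str] = (),
        criteria: RangeCriteria = RangeCriteria(),
        clamp_fl_zero: bool = False,
    ):
        if not profiles:
            raise ConfigError("no sample profiles supplied")
        self.profiles = list(profiles)
        self.gene_model = gene_model
        self.exclusions = tuple(exclusions)
        self.criteria = criteria
        self.clamp_fl_zero = clamp_fl_zero

    @classmethod
    def from_manifest(
        cls,
        manifest_path,
        gene_model: GeneModel,
        **kwargs,
    ) -> "SplicingComparison":
        """Build the model by reading every SJ file named in a manifest TSV."""
        manifest = read_manifest(manifest_path)
        return cls(load_profiles(manifest, gene_model), gene_model, **kwargs)

    def fit(self, level: Optional[float] = None) -> "SplicingComparisonResults":
        """Quantify all samples, build control ranges, compare carriers."""
        level = level if level is not None else self.criteria.confidence_level
        expression = [
            _quantify.quantify_sample(
                p, self.gene_model, exclusions=self.exclusions,
                clamp_fl_zero=self.clamp_fl_zero,
            )
            for p in self.profiles
        ]
        controls = [e for e in expression if e.group == "control"]
        carriers = [e for e in expression if e.group == "carrier"]
        if not controls:
            raise ConfigError("comparison runs need at least one control sample")
        ranges = _compare.control_ranges(controls, self.criteria)
        comparisons = [
            r
            for c in carriers
            for r in _compare.compare_sample(c, ranges, level=level)
        ]
        return SplicingComparisonResults(
            model=self,
            expression=expression,
            control_ranges=ranges,
            comparisons=comparisons,
            level=level,
        )


@dataclass
class SplicingComparisonResults:
    """Fitted comparison: expression profiles, ranges, and aberrance calls."""

    model: SplicingComparison
    expression: list
    control_ranges: list
    comparisons: list
    level: float

    @property
    def expression_frame(self) -> pd.DataFrame:
        return _quantify.profiles_to_frame(self.expression)

    @property
    def ranges_frame(self) -> pd.DataFrame:
        return _compare.ranges_to_frame(self.control_ranges)

    @property
    def comparisons_frame(self) -> pd.DataFrame:
        return _compare.comparisons_to_frame(self.comparisons)

    def aberrant(self) -> pd.DataFrame:
        """Carrier events whose interval falls outside the control range."""
        df = self.comparisons_frame
        if df.empty:
            return df
        return df[df["flag"].isin([_compare.ABOVE_RANGE, _compare.BELOW_RANGE])]

    def presence_matrix(self, threshold: Optional[int] = None) -> pd.DataFrame:
        kw = {} if threshold is None else {"threshold": threshold}
        return _compare.presence_matrix(self.expression, **kw)

    def detection_depth_fit(self) -> tuple[float, float, float]:
        """(slope, intercept, R²) of detected events against gene read depth."""
        return _compare.detection_depth_fit(self.expression)

    def summary(self) -> str:
        gm = self.model.gene_model
        lines = [
            f"Splicing comparison: gene {gm.gene_id} "
            f"({gm.chromosome}, {gm.strand} strand, {len(gm.exons)} exons)",
            f"Reference junction: exons {gm.rj_exons[0]}-{gm.rj_exons[1]}",
            f"Samples: {sum(e.group == 'control' for e in self.expression)} "
            f"controls, {sum(e.group == 'carrier' for e in self.expression)} "
            f"carriers; confidence level {self.level:.2f}",
        ]
        if self.model.exclusions:
            lines.append(
                "Probe-efficiency exclusions: " + ", ".join(self.model.exclusions)
            )
        lines.append("")
        lines.append("Control expression ranges (mean and 95% SEM limits):")
        rf = self.ranges_frame
        lines.append(
            rf.to_string(index=False, float_format=lambda v: f"{v:.4f}")
            if not rf.empty else "  (none)"
        )
        ab = self.aberrant()
        lines.append("")
        if ab.empty:
            lines.append("No aberrant events called.")
        else:
            lines.append("Aberrant events (CI disjoint from control range):")
            for r in ab.itertuples():
                lines.append(
                    f"  {r.sample_id}: {r.event} {r.flag} "
                    f"(proportion {r.carrier_proportion:.4f}, "
                    f"{r.fold_change:.1f}-fold vs control mean)"
                )
        return "\n".join(lines)

    def plot_ranges(self, ax=None):
        """Figure-2-style plot: control ranges with carrier points overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 4))
        rf = self.ranges_frame
        rf = rf[rf["included"]]
        x = range(len(rf))
        ax.errorbar(
            x, rf["mean_proportion"],
            yerr=[rf["mean_proportion"] - rf["lower"],
                  rf["upper"] - rf["mean_proportion"]],
            fmt="o", color="black", capsize=3, label="controls (mean ± 95% SEM)",
        )
        pos = {e: i for i, e in enumerate(rf["event"])}
        cf = self.comparisons_frame
        if not cf.empty:
            for sample_id, sub in cf.groupby("sample_id"):
                sub = sub[sub["event"].isin(pos)]
                ax.scatter(
                    [pos[e] for e in sub["event"]], sub["carrier_proportion"],
                    marker="x", label=sample_id,
                )
        ax.set_xticks(list(x))
        ax.set_xticklabels(rf["event"], rotation=60, ha="right")
        ax.set_yscale("log")
        ax.set_ylabel("relative isoform proportion")
        ax.legend(fontsize="small")
        ax.figure.tight_layout()
        return ax
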