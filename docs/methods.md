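# Methods

## Scope and data model

`splicequant` analyses one gene at a time from per-sample splice-junction
read counts (STAR `SJ.out.tab`: 1-based closed intron coordinates; only
unique-mapping reads, column 7, enter quantification — multi-mapping reads
are ignored). A `GeneModel` holds the ordered exons of one transcript in
transcription order; for minus-strand genes all ordering and naming logic
is strand-aware while junctions stay keyed by their genomic intron
interval, so interop with `SJ.out.tab` arithmetic is lossless
(`donor_end = intron_start − 1`, `acceptor_start = intron_end + 1` on the
plus strand, mirrored on minus). Junctions longer than 100,000 nt are
rejected, matching the intron cap of the mapping step the pipeline
consumes.

## Event taxonomy

Observed junctions are classified against the gene model:

- **canonical** — joins adjacent exons' boundaries; carries no event.
- **exon_skip / multi_exon_skip** — joins canonical boundaries of
  non-adjacent exons i and k; skips exons i+1..k−1; named `Δ10`, `Δ9–10`.
- **nag_shift** — canonical donor with the acceptor displaced exactly
  +3 nt into a downstream exon (one NAG codon); checked before the
  partial-deletion rule, always excluded from normalization, named
  `NAG<exon>`.
- **partial_exon_deletion** — exactly one side internal to an exon; an
  internal acceptor deletes the exon's 5′ part (`Δ<exon>p`), an internal
  donor its 3′ part (`Δ<exon>q`). The p/q suffix convention is this
  package's convention for alternative acceptor/donor use inside an exon.
- **retention_insertion** — a retained/inserted block between adjacent
  exons, called only when exactly one left and one right flanking
  junction bracket a block of ≥1 nt inside the canonical intron; named
  `▾<upstream exon>`. Unpaired halves stay `novel_junction`, because
  short-read junction evidence cannot otherwise distinguish retention
  from noise.
- **novel_junction** — anything else; fallback name
  `j<intron_start>-<intron_end>`.

In-frame status is derived from the deleted/retained length modulo 3
where determinable.

## Reference-junction normalization

The canonical exon 2→3 junction is the reference junction (RJ); its read
count approximates the gene's total transcript output because nearly all
isoforms retain it. Quantification per sample:

1. `FL = RJ − Σ counts of included events that do not overlap the RJ`;
2. `total = FL + Σ counts of all included alternative events`;
3. `p(e) = count(e)/total`, `p(full-length) = FL/total`.

"Overlaps the RJ" means the event's transcript form lacks the canonical
2→3 junction. The operational rule: the skipped/deleted footprint touches
exon 2 or exon 3, or a defining junction's intron interval intersects the
RJ intron (covering NAG shifts of the RJ acceptor and retained blocks
inside the RJ intron). Such events are *not* deducted from the RJ — their
reads never contributed to it — but they do enter the total, so their
proportions share the same denominator.

Two deliberate properties of this scheme:

- **Co-occurrence is not modelled.** Each junction is attributed to its
  own event; two events on one molecule are double-counted. The generator
  therefore simulates one event per isoform by default, and an optional
  co-occurrence path exists only to demonstrate the bias.
- **Excluded events are inert, not removed.** NAG events (which co-occur
  pervasively with other events) and events with questionable probe
  efficiency are excluded from both sums; their reads are consequently
  absorbed into the full-length term. On noise-free data this makes every
  *included* event's proportion exact while full-length absorbs the
  excluded mass — the behaviour the normalization forces, verified by the
  exact-recovery tests.

A negative full-length count (included non-overlapping events exceeding
the RJ) signals a violated assumption — typically a probe artifact or a
mis-set overlap flag — and raises an error; `--clamp-fl-zero` downgrades
it to a warning with `FL := 0`. A zero RJ count makes the gene
unquantifiable. Proportions are carried at full float precision; report
files round to 4 decimals.

Monotonicity note: because `total` is pinned to the RJ count when all
events retain the RJ, adding reads to such an event raises its proportion
at full-length's expense and leaves sibling events unchanged; only
RJ-overlapping events grow the denominator and depress every other
proportion.

## Control ranges and comparison

A control sample qualifies when it has **more than 10,000** reads on the
gene and expresses **at least two** minor transcripts; a minor transcript
is any included non-full-length event with **more than 10** reads — the
single detectability threshold used throughout (also for presence/absence
matrices and detected-event counts). Per event, the range uses only
qualifying controls expressing it with more than 10 reads and needs at
least two of them; it is mean ± z·(sd/√n) at the configured confidence
level (z from the standard normal, 1.96 at 95%; sd with ddof = 1). All
thresholds are strict inequalities and are surfaced as CLI flags.

Carrier comparison per included event: p̂ = x/n with x the event count
and n the sample's normalization total; the complementary log–log
interval is

    g(p) = log(−log p),  se = sqrt((1 − p̂)/(n p̂ (log p̂)²)),
    CI = [exp(−exp(g + z·se)), exp(−exp(g − z·se))]

(g is decreasing, so the upper g-limit maps to the lower p-limit; both
endpoints are strictly inside (0, 1) and bracket p̂). At x = 0 or x = n
the transform is undefined; an Anscombe-type adjustment (x + 0.5, n + 1)
is applied and the interval flagged as adjusted. Fold change is p̂ over
the control mean. Flags: `above_range` iff the CI's lower limit exceeds
the range's upper limit; `below_range` symmetrically; otherwise
`within_range`; events expressed (>10 reads) in the sample but lacking a
usable control range are flagged `not_expressed_in_controls` with an
undefined fold. Calls are descriptive CI-versus-range disjointness; no
formal test and no multiple-testing correction is applied, so with ~10
compared events a null sample still draws a flag in a few percent of
datasets — the measured family-wise rate under the default conditions is
about 3–6%.

`detection_depth_fit` regresses the per-sample count of detected
alternative events (>10 reads, excluded events included — detection is
not normalization) on the per-gene read total by OLS and reports slope,
intercept and R².

## Synthetic data generator

The generator emulates a targeted assay over a parametric toy gene
(default: 24 exons of 120 nt — six exons resized so each skip event's
length-derived frame matches its intended frame — with 2 kb introns).
Isoforms are defined by event kind (full-length, skip, NAG, retention)
and a proportion θ; the default mixture is a dominant full-length
(0.9458) plus 12 minors spanning 2×10⁻² down to 10⁻⁴, including one NAG
isoform (excluded-event path), one retention isoform (junction-pairing
path), five out-of-frame isoforms and three rare depth-limited ones.

Per sample: depth is lognormal around the configured median
(`depth = 5×10⁴`, `sigma = 0.5` by default, emulating the wide per-sample
spread of targeted panels); effective proportions are
θ′ ∝ θ × ν^[out-of-frame, untreated] × fold^[variant-targeted, carrier],
renormalized (ν = `nmd_factor`, default 0.25); the expected count of
junction j is `depth × probe_efficiency(j) × Σ_{isoforms ∋ j} θ′`, and
realized counts are Poisson by default or negative-binomial with size
`dispersion`. Poisson is the default because the comparison's carrier
interval models counting noise only: it is the regime in which the
CI-versus-range call has its nominal few-percent family-wise error, and
the NB path exists to study the method's degradation under overdispersion
rather than to define the reference conditions. `noise=False` emits
rounded expected counts for exactness tests. Each sample uses its own RNG
substream (`default_rng([seed, index])`), so identical seeds are
byte-identical and adding samples never perturbs existing ones. Retention
isoforms are quantified downstream as the rounded mean of their two
flanking junction counts (each flank has the isoform's full expected
depth, so the mean is unbiased and exact in the noise-free path).

Presets (`scenario_presets`): `controls-only` (10 treated controls);
`nmd-contrast` (5 individuals sequenced treated and untreated, ν = 0.1,
depth 2×10⁴ — the out-of-frame minors then straddle the >10-read
threshold, roughly doubling detected events under treatment);
`spliceogenic-carrier` (10 controls + 1 carrier with Δ10 spiked 8.8-fold
at depth 10⁵); `replicate-variability` (6 time points × 3 technical
replicates; the rare isoforms' expected counts of ~5 reads make their
presence intermittent across replicates).

What the generator does **not** emulate: read-level errors, alignment
ambiguity, multi-mapping, co-occurring events on one molecule (except the
demonstration path), probe-sequence effects beyond a per-junction
multiplier, and between-individual biological variability beyond counting
noise. Passing tests therefore validate the arithmetic and the operating
characteristics under the stated generative model, not performance on
real libraries — in particular, true biological overdispersion between
individuals widens the null distribution relative to the carrier CI and
raises the false-flag rate above the Poisson figure quoted above.

## Validation experiments and problem sizes

`splicequant.validation` packages the seeded end-to-end experiments used
by the test suite and `scripts/acceptance.py`: exact recovery on
noise-free counts (depth 2×10⁵, 2 samples); cloglog coverage on 2,000
binomial replicates at n = 1,000; spiked-fold recovery over 100–200
simulated cohorts; null-control specificity over 100 cohorts (ranges from
all qualifying controls, the first control compared against the cohort
range it belongs to); NMD contrast over 100 cohorts; detection-depth R²
on a 30-sample cohort. These sizes keep any single experiment in the
seconds-to-a-minute range while leaving the Monte-Carlo error well inside
the asserted margins.

## Known limitations

- One gene, one transcript model per run; no transcript assembly and no
  sequence-level analysis.
- The RJ anchor assumes events touching exons 2–3 are rare; a gene whose
  dominant alternative events overlap the RJ would need a different
  anchor (`rj_exons` is configurable).
- Fold changes against control means near zero are unstable; events not
  expressed in controls are flagged rather than quantified.
- The cloglog interval ignores overdispersion and within-sample
  dependence between events sharing a denominator.
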