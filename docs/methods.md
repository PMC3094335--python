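# Methods

This note documents the models and procedures implemented in `wormtx`,
the parameters that matter, the numerical conventions, and what the
synthetic-data generators do and do not emulate.

## Gene lineage conversion

**Model.** Gene identity is carried by the stable gene-level WB ID; all
other identifier kinds (CDS/sequence name, public name, transcript
name) are views resolved through a per-release correspondence table.
Annotation changes between releases are a totally ordered event log of
six kinds — merge (≥2 sources, 1 surviving target), split (1 source,
≥2 targets, the retained parent listed among the targets), kill,
create, rename (same WB ID, new names) and resurrect. Converting a list
from release A to release B replays every event with
A < effective_release ≤ B over the resolved genes.

**Conventions.**

* Resolution precedence is WB ID > sequence name > public name >
  transcript name; exact match first, then a logged case-insensitive
  fallback. Transcript names resolve to their parent gene; the reverse
  (gene → transcript output) is refused because lineage is recorded at
  gene level.
* Backward (newer → older) conversion is refused: merges are not
  invertible.
* Merged inputs map to the surviving gene, deduplicated in the output;
  killed inputs are omitted and reported with the release of death;
  split daughters are appended at the end of the output, ordered by
  event then lexicographically. Daughters are tracked through later
  events — a daughter that is itself merged or killed afterwards ends
  up under its final identity or disappears. This tracking is what
  makes conversion compose: A→B followed by B→C equals A→C.
* Every input lands in exactly one report bucket (unresolved, killed,
  merged, split, passthrough), with killed > merged > split >
  passthrough priority when a lineage experienced several fates.
* A split that drops its parent without a formal kill is a curation
  inconsistency; the loader flags it, and a patch file (same schema as
  the event log) may declare the implied kill, which repairs the record.
* `detect_release` scores each release by the fraction of inputs it
  resolves and breaks ties toward the most recent release — users are
  more likely to hold current lists, and the choice is at worst a
  harmless relabeling among releases in which the list is equally valid.

Two independent implementations exist: the indexed single-pass replay
(`convert_list`) and a per-gene linear rescan (`convert_list_naive`).
They are checked against each other and against simulator ground truth
over hundreds of random histories.

## Tiling-array quantification

Per condition: probe signal is PM − MM per replicate (negatives
retained — clipping would bias medians); replicate columns are quantile
normalized (each column's order statistics replaced by the
across-column mean) and combined by the mean (median available via
`TilingConfig.replicate_combine`); combined per-probe values are
smoothed with the Hodges–Lehmann pseudomedian — the median of all
pairwise averages, self-pairs included so singleton windows are
defined — over probes whose centers lie within ±55 bp
(`smoothing_window_bp` = 110); a transcript's value is the median over
probes overlapping its exon union by ≥50 % of the probe length
(overlap summed across exons, strand ignored); finally all probe values
on an array are divided by the slide median. Even-count medians are the
mean of the two central values throughout.

## RNA-seq quantification (dcpm)

For a transcript, dcpm = (sum of per-base coverage scores over exonic
bases that exceed the base-quality threshold and have representation
< 96) divided by (the count of exonic bases with representation < 96),
× 10⁶ / mapped reads. The divisor is read as the eligible-base count
(a per-base average); a double division by both a window size and the
base count would not produce a per-base average. The base-quality
threshold defaults to 0 (all covered bases). Bases absent from the
coverage table count as depth 0, representation 1 — uncovered exonic
sequence dilutes the average, as it should. Zero eligible bases yields
NaN ("nan" in exported tables), distinct from a zero value, and marks
transcripts whose sequence is entirely multi-mapping at the cutoff.

## Differential-regulation callers

All callers take paired (control, infected) values from one platform.
Transcripts expressed in exactly one condition have no usable ratio and
are flagged (`infection_specific` / `lost_on_infection`) rather than
forced into the ratio-based calls; replacing the zero by an arbitrary
small value is deliberately not the default.

**Percentile rule.** Thresholds are the 81.25th percentile of the
strictly positive log₂ ratios (> ε = 10⁻⁵) and the 18.75th of the
strictly negative ones, computed by linear interpolation between
closest ranks (rank = 1 + (n−1)p/100); comparisons are strict, so each
tail holds 18.75 % of its sign class up to boundary ties.

**Envelope caller.** Log₁₀ both axes, rotate 45° clockwise
(u = (x+y)/√2, v = (y−x)/√2 — orthonormal, so distances are
preserved), split the u-range into `n_bins` equal-width bins, and take
each bin's cutoff-percent and (100 − cutoff)-percent percentiles of v
as lower/upper anchors at the bin center (bins with fewer than
`min_bin_count` = 3 points are skipped and logged). A hyperbola
v = a + b/(u − d) is fitted to the upper and, separately, the lower
anchors by least squares, with the pole d constrained below the
smallest anchor center. d is found by a deterministic grid search
(log-spaced offsets; a and b solved linearly at each candidate), which
makes the fit reproducible and exactly shift-equivariant; together with
bin-relative coordinates (u − u_min) this renders the caller exactly
invariant under scaling both conditions by a common factor. If every
candidate pole is rank-deficient the fit falls back, with a log
message, to a fixed pole one span below the anchors. Points strictly
outside a curve are called; the score is v − curve(u).

**Band caller.** On log₁₀ axes, a trend line joins (25th percentile of
x, mean y of points with x in the 20–30th percentile band) and the
analogous 70–80th anchor. Points whose projection along the line falls
within ±`ortho_bin_halfwidth` (default 0.05 of the along-line range) of
an anchor form that anchor's orthogonal bin; the 99th percentile of
their signed perpendicular offsets fixes one point of the threshold
line. Points strictly on the positive side of the line joining the two
tail points are up-calls, scored by perpendicular distance.
Down-regulation runs the identical construction with the axes swapped;
the mirror form (rather than a 1st-percentile line under the same
x-anchored trend) is chosen because it makes swapping the two
conditions exactly swap the up and down call sets. "Above the line" is
read as the positive perpendicular side, which coincides with
above-in-y for any non-vertical threshold line.

**Legacy platform rules.** Oligo arrays: genes with infected/control
ratios > 1.01 or < 0.99 in ≥10 of 14 arrays are eligible; the top and
bottom 18.75 % of eligible genes' median ratios are called. cDNA
arrays: genes above 40 PSL in both experiments contribute the mean fold
change, in exactly one experiment that fold change, otherwise they
leave the base set; log₂ values then go through the percentile rule.

## Cross-platform comparison

Base-set rules per platform: oligo — signal ≥2× background and
unflagged in ≥4 of 6 arrays; cDNA — >40 PSL in either channel of ≥1 of
2 experiments; RNA-seq — non-zero dcpm in ≥1 dataset; tiling — all
transcripts (tiling values are never exactly zero). Every set
operation requires a single common release and raises otherwise,
pointing to the converter. Pairwise overlaps always report percentages
against both set sizes, since a single "overlap %" is ambiguous about
its denominator. Biomarker list 1 is genes up on ≥`min_platforms`
platforms; list 2 is genes whose baseline lies below the lower quartile
of non-zero baselines (quantile configurable; no published cutoff
exists) with induction > 20-fold, infinite fold (zero baseline)
included. Peptide-length classes default to equal-count quintiles of
the genome-wide length distribution (closest-rank-below boundaries,
right-closed classes), with an equal-width option; the short-peptide
comparison (<90 residues, fungal vs bacterial lists) and the
conservation comparison are Pearson chi-squares without Yates
correction by default (flag available).

## Category overrepresentation (EASE)

For a category with K genes in the population (the platform base set,
N genes) and k hits in a list of n, the Fisher p is the upper
hypergeometric tail P(X ≥ k); the EASE p repeats it with the hit cell
reduced by one (k ≤ 1 scores 1.0), a conservative penalization that
suppresses single-gene categories. Categories are intersected with the
population first and skipped below `min_category_size` = 2. BH
q-values across tested categories are advisory. The population is an
explicit parameter — platform base set versus whole genome is a
substantive analysis choice the caller must make. Category databases
carry a release tag; `refresh_categories` converts every gene set
through the lineage converter (merges deduplicated, daughters added,
killed genes dropped and logged, emptied categories flagged for
removal), and refreshing A→B→C equals A→C.

## Synthetic-data generators

All generators take an explicit seed and are deterministic given it.

**Histories** (`simulate_history`): per release transition, Poisson
counts of merges, splits, kills, creations and renames (defaults 2.0
each) over genes not already touched in that transition; kill counts
clamp to the available genes with a warning. Splits retain the parent
among the targets. The truth map records each initial gene's final
fate ("live" with final WB ID, or "dead" with the release of death) —
exactly what a forward conversion must reproduce.

**Paired expression** (`simulate_expression`): true abundances t are
log-normal (ln-mean 1.6, ln-sd 1.5 — median ≈ 5, a dcpm-like scale
spanning ~4 decades). Both conditions are noisy measurements:
control = t·2^e₁, infected = t·fold·2^e₂ with e₁, e₂ independent
N(0, s₀ + s₁/(t+1)), s₀ = 0.1, s₁ = 1.5 — the minimal model in which
each measurement's relative variation grows as expression falls, so
the log-ratio scatter fans out at low expression symmetrically about
the diagonal, the regime the geometric callers are designed for.
Putting the noise on the measurements rather than only on the ratio
matters: with a noiseless control axis, high-noise genes migrate out
of the low-(x+y) region and the rotated envelope degenerates to a flat
threshold. Planted fractions default to 5 % up and 5 % down at 4-fold
(planted transcripts carry the same measurement noise on top of the
fold — an exactly noiseless fold would put a clump of identical ratios
on the strict percentile threshold, a degenerate and unrealistic
configuration); 1 % of transcripts are zero-inflated
(infection-specific: control exactly 0, infected log-normal).

**Probes and coverage** (`simulate_probes_and_coverage`): probes tile
exons at a fixed step (25 bp); PM = expression + noise, MM = 0.3·PM +
noise; coverage depth on every exonic base equals the expression
value, so dcpm should recover expr·10⁶/reads; selected transcripts can
be planted at the representation cutoff to exercise the missing-value
path.

What the generators do **not** emulate: the real *C. elegans* gene
length and expression distributions, count discreteness at very low
coverage, correlated probe effects, batch effects, or biological
replicate variance (the RNA-seq design modelled is single-sample).
Passing tests on these fixtures therefore demonstrate algorithmic
correctness and the intended qualitative behaviour (e.g. where
false positives concentrate), not platform-calibrated error rates on
real data.

## Problem sizes and tolerances

The converter equivalence suite uses 200 random histories, most with
20–200 genes over 3–8 releases and ten with 1,000 genes, 8 releases and
~300 events — large enough to exercise chained merges, daughter
lineages and clamping, while the whole suite stays interactive. Caller
comparisons use 5,000-transcript tables (≈460 up-calls at the 18.75 %
rule) and a 10,000-point null cloud for the band caller's ~1 % tail
(asserted within [0.5 %, 2 %]). Floating-point comparisons use exact
equality only where the arithmetic is exact (worked percentile example,
closed-form dcpm); elsewhere relative tolerances of 1e-8–1e-9 against
term-by-term oracles.

## Known limitations

* Lineage replay trusts the event log; contradictions between log and
  tables are surfaced, not auto-resolved (beyond explicit patches).
* The envelope caller's equal-width bins can leave sparse extreme bins
  skipped; with fewer than three usable anchors the fit raises rather
  than guessing.
* `legacy_cdna_call` iterates genes in Python and is meant for
  array-scale (10³–10⁴ genes) inputs.
* Release detection cannot distinguish releases in which the input list
  is equally resolvable; the most-recent tie-break is a convention, not
  an inference.
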