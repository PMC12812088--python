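# Methods

This note documents the statistical procedures implemented in
`jumpsieve`, the assumptions behind them, the defaults and why, and what
the synthetic benchmark does and does not demonstrate.

## Observation statistics

The unit of filtering is the *observation*: one (ASV, sample) cell with a
positive read count. Three statistics are attached per observation:

* `readprop = reads / (total reads of that ASV over the whole table)`;
* `exprop = 1 / (number of observations of that ASV)`, the share expected
  if the ASV's reads were spread evenly over its observations;
* `norm = (readprop − exprop) / exprop ∈ [−1, (1 − exprop)/exprop]`.

`readprop = 1` identifies single-sample ASVs; `norm` near −1 identifies
observations holding a vanishing share of an ASV's reads, which is how a
small hopped read packet of an abundant ASV looks.

Two readings of the procedure are configurable:

* **Denominator scope.** Statistics are computed once on the raw table,
  blanks included (default). Blank reads belong in the denominator
  because the thresholds are themselves calibrated on blank observations
  of the same table; excluding them would change the very quantities the
  calibration is read from. `recompute_stats_after_filter1=True` instead
  recomputes the statistics after the read-count filter, for users who
  prefer thresholds and decisions on the cleaned table.
* **Filter-1 inclusivity.** `t_reads` is the maximum of *known errors*,
  so the default removes `reads ≤ t_reads` (a count equal to a known
  error magnitude is presumed an error). `filter1_strict=True` removes
  only `reads < t_reads`.

## Threshold derivation

Outlier detection uses Tukey's boxplot rule with the five-number-summary
hinge convention: hinge depth `(⌊(n+1)/2⌋ + 1)/2`, averaging the two
flanking order statistics at fractional depth, upper fence = upper hinge
+ 1.5 × (upper − lower hinge). This matches the hinge convention of the
standard R `boxplot.stats`/`fivenum` routines, so thresholds derived
here are directly comparable with boxplot-based curation scripts. Only
the **high** side is used: the quantities being screened (read counts,
`readprop`, `norm`) are screened for unusually large known errors, and
the derived cutoffs are minima of high-side outlier sets.

* `t_reads`: read counts of observations whose ASV occurs in exactly one
  sample, that sample being a blank (these cannot be tag-jumps, because a
  jump implies a source sample also containing the ASV). High outliers
  are discarded — keeping them would push the cutoff far up and remove
  large numbers of genuine observations — and the maximum of the body is
  the cutoff.
* `t_readprop`, `t_norm`: on blank observations surviving filter 1, the
  minimum of the high outliers of each column. The two thresholds are
  derived independently from the same post-filter-1 blank set. If a
  column has no outliers the data-driven rule is undefined and the
  package refuses to guess, asking for a manual threshold instead.
* Retention in real samples is disjunctive and strict:
  `readprop > t_readprop OR norm > t_norm`. The two criteria cover
  complementary failure modes: `readprop` alone penalises naturally
  widespread ASVs (their shares are small everywhere), which is exactly
  what `norm` corrects for.

At least `min_blank_errors = 5` qualifying blank observations are
required per derivation step (a guard against vacuous calibration sets,
not a scientific constant). Each threshold's provenance — value
multiset, hinges, fence, outlier set — is stored and `replay_provenance`
re-derives the thresholds from it bit-exactly.

Order of operations: statistics → derive `t_reads` → filter 1 on blanks
→ derive (`t_readprop`, `t_norm`) → filter 1 on real samples → filter 2
on real samples → drop blanks.

## OTU clustering

Distances are uncorrected p-distances with pairwise deletion (columns
with a gap or ambiguity in either sequence are skipped); a Jukes–Cantor
switch exists but the 3% barcoding-gap convention is a raw-identity
threshold, so p-distance is the default. Clustering is agglomerative
complete linkage, merging while the smallest complete-linkage distance
is ≤ the cutoff (0.03 default); consequently no OTU contains a pair of
members more than the cutoff apart. Equal-height merges are broken by
the lexicographic order of the candidate clusters' smallest member
labels, which makes the partition invariant to input order — a property
library implementations do not guarantee under ties. Each OTU's
representative is its member with the highest total read count (ties:
lexicographically smallest id); this abundance-based choice is
configurable in spirit (pass any mapping) but is the default because the
most abundant ASV is the best-supported sequence of its cluster. The ASV
tree is collapsed by pruning to representative tips, suppressing
unbranched internal nodes with branch lengths summed, which preserves
patristic distances between surviving tips.

## Diversity

* **Richness** = OTUs with positive count per sample.
* **Faith's PD** = total branch length of the subtree spanning a
  sample's OTUs, *root-inclusive* by default (the path from the spanning
  subtree to the root counts, so a single-OTU sample has positive PD);
  `include_root=False` restricts to the subtree below the MRCA of the
  sample's OTUs.
* **Depth correction**: ordinary least squares of a diversity index on
  sample depth; the residuals are the depth-corrected values (positive =
  more diverse than depth predicts). Scaled residuals (mean 0, sd 1,
  ddof = 1) are reported alongside raw ones. A constant depth vector is
  an error by default; a centering fallback is available.
* **Beta diversity** is computed on presence/absence (`reads > 0`). The
  Sørensen dissimilarity is partitioned into its Simpson (turnover)
  component and the nestedness-resultant remainder, pairwise
  (`β_sor = (b+c)/(2a+b+c)`, `β_sim = min(b,c)/(a+min(b,c))`,
  `β_sne = β_sor − β_sim`) and multi-site (pair sums of `min`/`max`
  shared-absence counts over the pooled-richness core). The identity
  `β_SOR = β_SIM + β_SNE` holds to 1e-12 by construction and is enforced
  in tests against an independent set-arithmetic implementation.
* **Group resampling**: to compare groups of unequal size, `n_sites`
  samples are drawn per group *without replacement* `n_iter` times
  (defaults 20 × 1000) and the multi-site triple recorded per draw.
  Without replacement because drawing 20 of ~30 sites with replacement
  would duplicate sites and distort the multi-site sums. Groups smaller
  than `n_sites` are resampled at their own size with a warning. A
  `mean_pairwise` alternative statistic (average of within-draw pairwise
  triples) is available since the multi-site statistic and the mean of
  pairwise values are both in use in the literature. Per-group draws use
  independent, label-keyed substreams of the user seed, so adding or
  removing a group never changes another group's draws.
* **Venn regions**: per-OTU group membership (present in any sample of
  the group), counted per intersection region, capped at 6 groups;
  region counts sum to pooled richness.

## The synthetic benchmark

`synthetic_data` emulates the situation the filter is built for, with
per-observation ground-truth labels (`genuine` / `tagjump` /
`seqerror`):

1. **Communities**: each of `n_species` species occurs at each site with
   probability `occupancy` (a `nested_sites` switch instead draws
   per-site pool sizes over a fixed species order, making poorer sites
   subsets of richer ones). Per sample, expected reads are proportional
   to the species' global lognormal abundance among species present at
   the site, scaled to `mean_depth`, and realized as independent Poisson
   counts — totals therefore vary around `mean_depth` rather than being
   fixed per sample. Blanks hold zero true reads.
2. **Tag-jumps**: every genuine read independently hops with probability
   `p_jump` to a uniformly chosen other index combination, used or
   blank. Reads are conserved exactly. Real index hopping is
   pair-structured (it depends on which index sequences are shared);
   uniform destinations are the minimal sufficient model because the
   filter under study is destination-agnostic. An observation is
   labelled `tagjump` when it holds no surviving genuine reads of its
   own.
3. **Error ASVs**: `n_error_asvs` novel single-observation ASVs land in
   uniformly chosen combinations with shifted-geometric read counts
   (support ≥ 1, mean `1/error_read_p`) — mostly tiny, with the heavy
   tail that gives the outlier-removal step real work.
4. **Sequences**: species ancestors are mutated copies of a random root
   sequence at pairwise p-distance ≥ `d_between` (disjoint mutation
   blocks guarantee this exactly when they fit in the alignment length;
   otherwise random mutation positions with realized-distance
   verification and bounded retries), and each ASV receives
   `⌊d_within·L/2⌋` private mutations so intra-species distances never
   exceed `d_within`. Error ASVs get independent uniform random
   sequences (~0.75 distance from everything, clustering as
   singletons). The emitted tree mirrors this construction: a root with
   one clade per species (branch length = ancestor divergence) plus
   long-branch error tips.

Per-stage simulation draws come from independent child streams of the
user seed, so changing, say, the error-ASV load never perturbs the
community or the hop pattern.

Default scenario: 4 sites × 6 samples + 4 blanks, 150 species,
`mean_depth = 5×10⁴`, `p_jump = 0.02`, 50 error ASVs, seed 42. The
sample layout, species count, hop rate, error load, depth and seed are
the benchmark's fixed study conditions. The remaining generator values
are package choices: `occupancy = 0.6` (moderate site turnover, typical
of soil-protist surveys), lognormal abundances with log-sd 1.5 (a
realistic skew: a handful of dominant taxa, a long rare tail — the skew
matters because tag-jump load scales with donor abundance), and
`error_read_p = 0.25` (mean ~4 reads per spurious ASV, small relative to
genuine observations but heavy-tailed). The acceptance script uses the
same design scaled to a survey with 8 blank combinations and 150 error
ASVs, sizes at which every blank-derived threshold is well-posed for any
seed.

**What passing the benchmark does and does not show.** The simulator
reproduces the *structure* the filter exploits (known-error blanks,
abundance-dependent hop load, single-sample error ASVs) but not
PCR/abundance biases, chimeras, pair-structured hopping, or taxonomy
assignment error. High sensitivity/specificity here demonstrates that
the implementation performs the intended inference on data matching its
assumptions — not a performance guarantee on any particular real
sequencing run.

## Numerical and degenerate-input choices

* Counts are exact integers; proportions are double precision; removal
  operations never alter the reads of retained observations.
* `tukey_outliers` on an empty multiset, derivation with no blanks, too
  few qualifying blank observations, or empty outlier sets raise typed
  errors (`PreconditionError`, CLI exit code 3) rather than degrading to
  a guess; malformed inputs raise `InputError` (exit code 2).
* Ties in "max of body" / "min of outliers" are multiset extrema, hence
  deterministic.
* Faith's PD sums branch lengths in a fixed tree-traversal order so
  results are bit-reproducible across processes.
* A collapsed OTU tree needs ≥ 2 representatives (a one-tip tree has no
  PD surface); pairs of sequences with zero comparable columns are an
  error, naming the pair.
* Pipeline artifacts are deterministic given config + seed; stage
  wall-clock times are written to a separate `timings.json` so data
  artifacts stay byte-identical across reruns.

## Problem sizes

The test suite and the acceptance script run on simulated surveys of
24–32 samples, 40–150 species and ~1.2 M reads, clustering benchmarks of
60 sequences × 400 bp, and 500–1000 random community matrices; the full
suite completes in well under a minute on one CPU. These sizes exercise
every code path at the scale where exhaustive oracles (brute-force
partition enumeration, set-arithmetic beta sums, hand-computed
five-number summaries) remain checkable.

## Known limitations

* The filter is threshold-based and destination-agnostic: it does not
  model which index pairs exchange reads and cannot rescue a genuine
  observation whose read count happens to fall at or below `t_reads`.
* Blank-derived calibration needs enough blank material: a run with very
  few unused index combinations, or almost no single-sample error ASVs
  landing in them, leaves the thresholds undefined (by design, an error
  rather than a silent default).
* The 3% cutoff is a marker-specific convention; complete linkage with a
  different gap, or a corrected distance, is a parameter change, not a
  code change.
* Depth correction is a single linear term; strongly nonlinear
  depth–richness relationships (e.g. saturation) are better handled by
  rarefaction, which is out of scope here.
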