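# jumpsieve

Blank-informed decontamination and diversity analysis for metabarcoding
count tables.

## The problem

Multiplexed amplicon sequencing assigns every read to a sample through an
index (tag) combination. Two error processes corrupt the resulting
ASV × sample count table:

* **Tag-jumping / index hopping** — reads carry the wrong index
  combination and appear in samples they never came from, creating
  false-positive observations that inflate richness and blur spatial
  diversity patterns.
* **Point sequencing/PCR errors** — spurious low-read ASVs that appear in
  a single sample only.

Fixed, arbitrary read-count cutoffs do not adapt to the error load of a
particular run. `jumpsieve` instead derives the cutoffs from **blank
samples**: index combinations that were never used in the experiment, so
every read assigned to them is a known error. The package is aimed at
anyone curating eDNA/metabarcoding ASV tables (the reference use case is
a soil-protist COI survey) who wants a data-driven, reproducible and
auditable filter, plus the standard downstream community analyses.

## The method

For every observation (an ASV *a* in sample *s* with `reads > 0`):

```
readprop(a, s) = reads(a, s) / Σ_s' reads(a, s')       observed share
exprop(a)      = 1 / (number of observations of a)     even-spread share
norm(a, s)     = (readprop − exprop) / exprop          relative divergence
```

`norm → −1` flags an observation holding far fewer reads than an even
spread predicts — the signature of a small hopped read packet.

**Filter 1 ("sequencing errors").** ASVs found in exactly one sample,
that sample being a blank, cannot be tag-jumps. Their read counts are
split with Tukey's boxplot rule (hinges of the five-number summary,
upper fence = upper hinge + 1.5 × H-spread); after discarding the high
outliers, the maximum remaining count becomes `t_reads`. All
observations with `reads ≤ t_reads` are removed.

**Filter 2 ("tag jump").** On the blank observations surviving filter 1,
the high outliers of the `readprop` and `norm` distributions are located
the same way; the minimum of each outlier set becomes `t_readprop` /
`t_norm`. A real-sample observation is then **retained iff**

```
readprop > t_readprop   OR   norm > t_norm
```

Blank samples are dropped from the output, and every threshold carries
full provenance (value multisets, hinges, fences, outlier sets) so the
derivation can be replayed bit-exactly.

Downstream, surviving ASVs are clustered into OTUs by **complete-linkage
agglomeration at a 3% barcoding gap** (no OTU contains a pair of ASVs
with p-distance > 0.03), the observation table is aggregated to OTU
level, and an ASV tree is collapsed to one representative tip per OTU.
The package then computes OTU richness, Faith's phylogenetic diversity
PD = Σ branch lengths of the subtree spanning a sample's OTUs
(root-inclusive), depth-corrected diversity as residuals of the OLS fit
`diversity ~ sequencing depth`, and the Sørensen-family partition of
beta diversity into turnover and nestedness,

```
β_SOR = β_SIM + β_SNE
```

pairwise and multi-site, with per-group site resampling (default 20
sites × 1000 draws) and Venn-region OTU counts.

A fully labelled simulator (`synthetic_data`) generates site-structured
communities, hops reads between index combinations at a per-read rate
`p_jump` (blanks included), and injects single-sample error ASVs, so any
filter can be scored for sensitivity and specificity against ground
truth.

## Worked example

```python
from jumpsieve import SimParams, simulate_dataset, run_blank_filter, score_filter

params = SimParams(n_blanks=8, n_error_asvs=150, seed=1)
ds = simulate_dataset(params, with_sequences=False)
filtered, thresholds, report = run_blank_filter(ds.table)

print(f"t_reads      = {thresholds.t_reads}")
print(f"t_readprop   = {thresholds.t_readprop:.9f}")
print(f"t_norm       = {thresholds.t_norm:.9f}")
for step in report:
    print(f"{step['step']:<18} {step['n_obs']:>5} obs  {step['n_reads']:>8} reads")
score = score_filter(ds.truth, filtered)
print(f"tag-jump removal    {100 * score.tagjump_sensitivity:.1f}%")
print(f"seq-error removal   {100 * score.error_sensitivity:.1f}%")
print(f"genuine retention   {100 * score.genuine_specificity:.1f}%")
```

prints

```
t_reads      = 9
t_readprop   = 0.001148106
t_norm       = -0.963260620
input               4139 obs   1201034 reads
filter1_blanks      3383 obs   1198435 reads
filter1_nonblanks   2485 obs   1195464 reads
filter2_nonblanks   2352 obs   1193129 reads
drop_blanks         2190 obs   1189433 reads
tag-jump removal    99.9%
seq-error removal   94.0%
genuine retention   98.2%
```

Reading the output: 150 spurious error ASVs landed across the run, and
the blank-only singletons among them calibrated a 9-read cutoff; the
blank `readprop`/`norm` outliers then set the tag-jump thresholds. The
two-stage filter removed 99.9% of the hopped observations and 94% of the
error ASVs while keeping 98% of genuine observations (the few genuine
losses sit at or below the 9-read cutoff, where genuine and artefactual
observations are indistinguishable by construction).

The same pipeline runs from the shell:

```bash
jumpsieve run --seed 42 --out-dir RESULTS/            # simulate → filter → cluster → diversity
jumpsieve filter --table obs.tsv --samples meta.tsv --out-dir OUT/
jumpsieve cluster --alignment asvs.aln.fasta --table OUT/filtered.tsv \
                  --tree asvs.nwk --cutoff 0.03 --out-dir OUT/
jumpsieve diversity --matrix OUT/otu_matrix.tsv --tree OUT/otus.nwk \
                    --samples meta.tsv --out-dir OUT/
```

Every run writes its resolved config, a `report.json` with per-step
observation/read/ASV counts and the threshold provenance, and
deterministic artifacts: identical config + seed ⇒ byte-identical
outputs.

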