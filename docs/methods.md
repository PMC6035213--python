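# Methods

## The statistic and its null

A *guide target site* is an exact match of the guide's protospacer with an
immediately adjacent 3′ PAM on the same strand. Scanning is exhaustive on
both strands, reports every overlapping occurrence, and treats `N` in the
genome as matching nothing. Matching is exact by design: the quantity of
interest is a census of consensus binding sites, not an off-target model,
so mismatch tolerance is deliberately out of scope. Whether the PAM is
required can be toggled (`require_pam`), since a census of bare protospacer
occurrences is sometimes wanted; the default requires it, because a
(d)Cas9 binding site without a PAM is not functional.

Every interval in the package is 0-based half-open, BED-compatible. A
site's position is its protospacer interval on forward genomic
coordinates; *window membership is decided by the protospacer's forward
start position*, a strand-independent rule that removes edge ambiguity for
sites straddling a window boundary.

For a gene with TSS *t* on strand +, the analysis window is
[*t* − 10,000, *t* + 1,000), mirrored for strand −, clipped to the contig;
the defaults (10 kb upstream, 1 kb downstream) are the window in which
Alu-motif site counts are most informative about promoter-proximal
regulation, and both extents are parameters. The per-gene statistic is
sites per kb of effective (post-clipping) window. A gene set is summarised
by the **unweighted mean of per-gene densities**; an aggregate
total-sites / total-kb variant is available (`statistic="aggregate"`)
because the two differ once windows clip, but the per-gene mean is the
default as the natural reading of "mean density per gene, n genes". Genes
whose clipped window falls below 1 kb (`min_effective_kb`) are excluded
from sets and pool alike, with a logged count — a 50 bp residual window
would otherwise contribute absurd densities.

The null is plain subsampling: per-gene densities are computed once for
the whole pool, then each permutation draws |S| genes uniformly without
replacement and takes the mean of the precomputed values. The observed
genes are *not* removed from the pool, matching the plain reading of
"permutations of n genes from a pool"; with pools of thousands of genes
the distinction is negligible. The one-sided upper-tail p-value is
`exceed_count / n_perm` (ties count as exceedances, which makes the
homogeneous-pool case return exactly 1.0). At zero exceedances the
estimate is reported as 0 with an explicit `p < 1/n_perm` flag; the
positively biased but never-zero estimator `(exceed+1)/(n_perm+1)` is
available via `estimator="plus_one"`. All resampling uses
`numpy.random.default_rng(seed)` and the seed is recorded in the result,
so any reported p-value is bit-reproducible.

## Peak overlap

A peak "contains" a site when its interval intersects the protospacer
interval by ≥ 1 bp (standard BED-style overlap); `mode="full"` instead
requires an entire protospacer inside the peak, since the looser rule is a
choice, not a law. Each peak counts at most once. Group comparison is the
classical pooled-variance two-sample two-tailed Student's t-test on the
untransformed per-sample fractions (Welch via `method="welch"`); with
3-vs-5 samples a variance-stabilising transform would change little and
would complicate comparison with directly reported percentages. Zero
pooled variance is handled explicitly: equal means give t = 0, p = 1;
unequal means are flagged as below machine precision rather than dividing
by zero.

## Guide tiling

`enumerate_protospacers` slides a fixed-length window (default 14 nt, the
truncated-gRNA length that still supports dCas9 binding) over both strands
of a query and keeps positions whose 3′ neighbour matches the PAM pattern.
Candidate offsets are forward-coordinate protospacer starts, the same
convention as genomic hits, so candidates re-scanned against the query
recover themselves. PAM-proximal composition — the k bases (default 4)
nearest the PAM, position 1 adjacent to it — is scored against a
disfavoured-base table supplied as configuration. No default table ships:
published disfavoured-nucleotide rules vary by system, so shipping one as
truth would be an invention; an empty table scores every candidate 0 and
ranking degrades to offset order.

## The synthetic-data generator

The generator emulates exactly the features the statistics measure, with
planted truth:

1. **Background genome** — i.i.d. bases with P(G)+P(C) = `gc_content`
   (default 0.41, human-like). If `sanitize` (default), accidental guide
   sites are destroyed by resampling one base inside each occurrence and
   re-scanning until none remain (capped at 100 rounds; local resampling
   rather than whole-genome rejection keeps GC stable and terminates for
   any realistic guide). Sanitization is what makes downstream checks
   *exact*: every site the scanner finds afterwards is a planted one.
2. **Genes and sites** — `pool_size` genes (default 2,000) laid out in
   non-overlapping 11-kb windows (100 bp guard gaps, 1 kb contig margins),
   random strands, across 4 × 6.5 Mb contigs — the smallest round layout
   hosting the pool. Per gene, the site count is drawn
   Poisson(density × 11 kb): `enriched_density` (default 0.409 sites/kb)
   for a randomly designated subset of `enriched_set_size` (default 18)
   genes, `background_density` (default 0.215) otherwise. Poisson placement
   is the simplest generative model consistent with a per-kb density; real
   Alu copies cluster, so this understates real-genome dispersion (see
   Limitations). Sites are written at uniform non-overlapping positions,
   random strand, with the PAM realized concretely (`AGG` for `NGG`, by
   default, for determinism).
3. **Peaks** — per sample, each of `peaks_per_sample` (default 1,000)
   peaks is independently site-bearing with its group's probability
   (defaults 0.008 control / 0.019 treated, 3 and 5 samples); site-bearing
   peaks are centred on a uniformly chosen planted site (guaranteeing
   overlap for any width ≥ protospacer length; default width 500 bp,
   a typical open-chromatin peak), the rest are placed uniformly in
   regions verified free of planted sites. Realized counts go into the
   truth record, so recovered fractions can be checked exactly, not just
   in expectation.

One RNG stream seeded from `config.seed` drives a composite run
(`simulate_dataset`); the same seed reproduces every file byte for byte.

What the generator does **not** emulate: Alu sequence evolution or
clustered repeat placement, chromatin-state structure, read-level noise,
gene-length/GC confounding between set and pool, or peak-width variation.
Passing recovery tests therefore demonstrate that the pipeline measures
what it claims on data matching its assumptions — not that those
assumptions hold in a real genome, where matched or clustered null models
may be needed.

## Problem sizes in the shipped checks

The recovery checks run the full study conditions (2,000-gene pool on
26 Mb, 10⁵ permutations, 1,000 peaks/sample). Multi-seed averages use 50
datasets for density recovery (set-mean standard error ≈ 0.006 sites/kb)
and 20 for peak recovery (group-mean standard error ≈ 0.04 percentage
points). For the 10⁵-permutation significance check, the realized mean of
an 18-gene set planted at 0.409 sites/kb varies seed to seed
(SD ≈ 0.045), and the probability that one dataset reaches p ≤ 5 × 10⁻⁵
is ≈ 0.88 under the generative model; the check therefore requires the
majority of 7 replicate datasets to reach the threshold, which is stable
(≈ 99.6%) without widening the threshold itself. Unit tests use a reduced
layout (60-gene pool on 2 × 400 kb) where every behaviour is scale-free.

## Numerical and degenerate-input choices

* Hit lists are always sorted by (contig, start, strand); consumers
  verify sortedness and fail loudly on contract violation.
* Strand tie-break at one position: `+` sorts before `-`.
* A palindromic protospacer yields two hits (one per strand) at the same
  interval; both count, consistent with an occurrence census.
* Empty scan results, empty gene files and empty peak-overlap numerators
  are valid (0 or empty outputs); empty gene *sets* and empty peak lists
  are argument errors because their statistics are undefined.
* Window extents are floats in kb but realized as integer bp via
  rounding; effective widths below `min_effective_kb` exclude the gene.
* JSON reports embed a run manifest (command, tool version, seed, SHA-256
  input digests). Wall-clock timestamps go to the log stream only, so
  identical inputs and seed produce byte-identical reports.

## Known limitations

* Exact matching only; no mismatch-tolerant or scored site models.
* The scanner is a plain string scan — linear time and fine for tens of
  Mb per guide, but not FM-index scale for thousands of guides.
* The Monte Carlo null resamples genes exchangeably; it does not match on
  GC, gene length or repeat context.
* Single-set testing, as in the upstream analysis it implements; no
  multiple-testing correction across gene sets.
* The CLI `enrich` and `peaks` commands pool hits over all guides in the
  input file; per-guide runs are a matter of supplying one-guide files.
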