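# alusite

Guide-RNA target-site scanning and regulatory enrichment statistics for
Alu-motif analysis.

CRISPR activation (CRISPRa) experiments that target a conserved ~36-bp
Alu-element motif raise a genomic question: are the genes that respond to
the guide RNA the ones with unusually many guide target sites near their
promoters, and does guide-loaded dCas9 binding show up as open chromatin at
those sites? `alusite` implements the computational side of that question
as a reusable, tested pipeline:

* **Site scanning** — exhaustive, strand-aware search of a genome for exact
  protospacer matches with an adjacent 3′ PAM (IUPAC pattern, `NGG` by
  default). Overlapping occurrences all count; `N` matches nothing.
* **Upstream-window density** — for gene *g* with transcription start site
  anchored at 0, count sites whose protospacer start falls in the
  strand-aware window [−10 kb, +1 kb) and divide by the window width:
  *d(g) = n(g) / w(g)* in sites per kb. A gene set *S* is summarised by the
  unweighted mean *D(S) = (1/|S|) Σ d(g)*.
* **Monte Carlo enrichment test** — per-gene densities are precomputed once
  for a pool of protein-coding genes; each of *N* permutations (default
  10⁵) draws |S| genes without replacement and records the mean of their
  densities. The one-sided empirical p-value is
  *p = #{permutation means ≥ D(S)} / N*, flagged `p < 1/N` at zero
  exceedances.
* **Peak overlap** — per sample, the fraction of peaks (e.g. ATAC-seq
  intervals) intersecting ≥ 1 site by ≥ 1 bp; control vs treated groups are
  compared with a pooled-variance two-tailed Student's t-test.
* **Guide tiling** — enumerate candidate protospacers over a motif
  consensus on both strands and score PAM-proximal nucleotide composition
  against a user-supplied disfavoured-base table.
* **Synthetic data** — genomes with guide sites planted at controlled
  per-kb densities inside non-overlapping TSS windows, and peak sets with
  controlled site-bearing fractions, with full ground truth, so every
  statistic above is verifiable at desk scale.

The statistical interfaces follow the model/results convention:
`GuideSiteEnrichment(...).fit()` and `PeakOverlap(...).fit()` return
results objects with estimates, diagnostics and a `summary()` table.

## Worked example

Simulate a dataset at the default study conditions — a 26 Mb sanitized
genome, a 2,000-gene pool planted at 0.215 sites/kb with an 18-gene subset
at 0.409 sites/kb, and 3 control + 5 treated peak samples at site-bearing
fractions 0.008 and 0.019 — then run the full pipeline on the emitted data:

```python
from alusite import GuideSiteEnrichment, PeakOverlap, find_guide_sites
from alusite.simulate import SynthConfig, simulate_dataset

cfg = SynthConfig(seed=7)
ds = simulate_dataset(cfg)
hits = find_guide_sites(ds.genome, cfg.guide)

model = GuideSiteEnrichment(ds.enriched_genes, ds.genes, hits, ds.genome,
                            cfg.window, set_id="day4_up")
print(model.fit(n_perm=100_000, seed=1).summary())
print(PeakOverlap(ds.peaks_by_sample, hits, ds.groups).fit().summary())
```

```
Guide-site upstream-window enrichment (Monte Carlo)
===================================================
Gene set:            day4_up (n = 18)
Pool size:           2000
Window:              -10 kb / +1 kb around TSS
Statistic:           per_gene_mean
Observed mean:       0.4192 sites/kb
Null mean (MC):      0.2162 sites/kb
Permutations:        100000
Exceedances:         0
p-value (upper):     0  [p < 1e-05]
Seed:                1

Peak / guide-site overlap comparison
======================================
Control:  n = 3, mean = 0.77% of peaks with >= 1 site
Treated:  n = 5, mean = 1.90% of peaks with >= 1 site
t (student, two-tailed) = 4.880
p = 0.002765
```

The enriched set's observed mean (0.42 sites/kb) sits far above the
resampling null centred on the pool background (0.216 sites/kb): none of
100,000 random 18-gene draws reached it, so the empirical p is bounded by
1/N = 10⁻⁵. The treated peak samples carry ~1.9% site-bearing peaks
against ~0.8% in controls, and the pooled t-test calls that difference at
p ≈ 0.003.

The same stages are available from the shell:

```bash
alusite simulate --config config.yaml --outdir data/
alusite scan   --genome data/genome.fa --guides data/guides.tsv --out out/sites
alusite enrich --genome data/genome.fa --genes data/genes.tsv \
               --guides data/guides.tsv --set data/enriched_set.txt \
               --n-perm 100000 --seed 1 --out out/enrich.json
alusite peaks  --genome data/genome.fa --guides data/guides.tsv \
               --sample-sheet data/sample_sheet.tsv --out out/peaks.json
alusite design --query <36-nt consensus> --guide-len 14 --out out/candidates.tsv
```

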