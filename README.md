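# medlsm

Analysis toolkit for joint ChIP-seq / RNA-seq studies of transcriptional
co-regulator occupancy at intron-containing ribosomal protein (IC–RP) genes
in budding yeast — specifically, the co-occupancy of the Mediator complex
(Med1/Med15 subunits) and the Lsm RNA-binding complex (via Lsm3) and its
consequences for transcription and splicing across the exponential growth
phase.

The package covers the computational pipeline downstream of read alignment:

- **ChIP signal**: fixed-bin coverage tracks (bedGraph), CPM scaling,
  genome-wide replicate correlation, a self-contained Poisson narrow-peak
  caller with Benjamini–Hochberg FDR control, replicate reconciliation
  (detected in all replicates, >2-fold enrichment in at least one), and
  masking of hyper-ChIPable regions (HCRs).
- **Peak-to-gene curation**: ±500 bp peak-to-gene retrieval, resolution of
  two-gene regions (convergent, parallel, intron-embedded, overlapping
  3′-exons), and rule-based removal (peaks downstream of the CDS, HCR
  overlap, dubious ORFs / ncRNA / ARS / centromere / transposon classes,
  over-broad peaks) with a full audit trail.
- **Occupancy profiles**: landmark-anchored and scaled-gene-body metagene
  matrices, summit-offset estimation against CDS ends and last-intron
  3′-ends, k-means clustering of promoter occupancy, and a
  promoter-to-3′-exon transition index across growth time points.
- **Co-occupancy enrichment**: gene-set intersections and one-sided
  hypergeometric (Fisher exact) class enrichment, computed in log space so
  tails far beyond float underflow remain meaningful.
- **Splicing and expression**: the IC-gene filtering cascade (intron
  ≥ 25 bp, ≥ 75 reads per sample, no HCR association), library-size
  normalization, a length-normalized splice-ratio statistic, and paired
  t-tests between growth time points per occupancy group.
- **Synthetic data**: a generator producing yeast-like annotations, ChIP
  coverage with planted promoter/3′-exon peaks, and paired
  whole-gene/exon-only RNA-seq counts with known per-gene splice ratios —
  every downstream stage is testable against known ground truth.

## The splice-ratio statistic

For an intron-containing gene with total exon length $L_e$ and total intron
length $L_i$, counted once over exons only ($E$) and once over the whole
gene ($G$), the intron-mapped reads are $I = \max(G - E, 0)$ and the splice
ratio is the complement of the length-normalized density ratio

$$
s \;=\; \mathrm{clamp}\!\left(1 - \frac{I / L_i}{E / L_e},\; 0,\; 1\right),
$$

so $s = 1$ when no reads map to introns (fully spliced) and $s = 0$ when
intron read density equals exon read density (unspliced). The statistic is
undefined when $E = 0$.

Class enrichment uses the hypergeometric upper tail: for $k$ category genes
among $n$ sampled from a population of $N$ containing $K$ category genes,
$p = P(X \ge k)$ with $X \sim \mathrm{Hypergeom}(N, K, n)$.

## Worked example

Simulate a 150-gene study (72 co-occupied, 45 unbound IC genes, matching
the study's group sizes), call and curate Lsm3 peaks, estimate the 3′-exon
summit offset, and test the growth-phase splice-ratio drop:

```python
from medlsm import simulate as sim, chip, assign as asg
from medlsm import profiles as prof, splicing as spl

annot, truth = sim.make_genome(
    n_genes=150, frac_ic=1.0, seed=1,
    group_sizes={"co_occupied": 72, "neither": 45,
                 "lsm3_only": 17, "mediator_only": 7})

tracks, control = sim.simulate_chip_coverage(
    annot, truth, time_point=0, n_replicates=3, seed=2, factor="lsm3")
peaks = chip.reconcile_replicates(
    [chip.call_narrow_peaks(t, control) for t in tracks])

assignments = asg.resolve_two_gene_regions(
    asg.genes_near_peaks(peaks, annot), annot)
lsm3_genes, _ = asg.curate_gene_list(assignments, annot)

pooled = prof.pool_rows([
    prof.metagene_matrix(t, annot.subset(lsm3_genes),
                         "last_intron_3prime_end", window=(-500, 1000))
    for t in tracks])
print(f"summit offset: {prof.summit_offset(pooled):.0f} bp")

whole, exon = sim.simulate_rnaseq_counts(annot, truth, seed=3)
retained, _ = spl.filter_ic_genes(annot, whole)
ratios = spl.splice_ratio_by_timepoint(
    spl.splice_table(annot, whole, exon, gene_ids=retained))
groups = {g: truth.table.loc[g, "group"] for g in retained}
res = spl.compare_groups(ratios, groups, t0=0, t1=3)
```

Output:

```
reconciled Lsm3 peaks: 89
curated Lsm3-occupied genes: 89
summit offset from last-intron 3' end: 240 bp
co_occupied: n=72, mean splice ratio 0.917 -> 0.810, paired t p=3.43e-47
neither: n=44, mean splice ratio 0.746 -> 0.744, paired t p=7.81e-01
```

The 89 curated genes are the Lsm3-bound subset (co-occupied + Lsm3-only);
the recovered summit sits within one bin of the planted +250 bp offset; the
co-occupied group shows the planted ~0.1 splice-ratio drop between early
(0 h) and late (6 h) exponential phase, while the unbound group does not.

There is also a CLI mirroring each stage
(`medlsm simulate|callpeaks|reconcile|maskhcr|assign|metagene|offset|cluster|intersect|enrich|filter-ic|normalize|spliceratio|compare|run`);
`medlsm run --seed 3 --outdir out/` executes the whole synthetic-study
pipeline and writes a reproducibility manifest with per-stage record
counts.

## Layout

```
src/medlsm/
  annotation.py   # gene model, landmarks, IC/RP classes, GTF/BED/TSV I/O
  simulate.py     # synthetic genomes, ChIP coverage, RNA-seq counts, fixtures
  chip.py         # coverage tracks, peak caller, reconciliation, HCR mask
  assign.py       # peak-to-gene assignment and curation rules
  profiles.py     # metagene matrices, summit offsets, k-means, transition
  enrichment.py   # set intersections, hypergeometric enrichment
  splicing.py     # count matrices, IC filter, splice ratio, paired tests
  pipeline.py     # end-to-end orchestration with manifest + caching
  cli.py          # click-based command line
docs/methods.md   # model, parameters, and design notes
```
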