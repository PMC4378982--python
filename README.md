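# lightchrom

Analysis toolkit for light-induced transcription and chromatin dynamics in
fungal genomes, modeled on the computational methods used to study the
*Neurospora crassa* light response (the White Collar Complex photoreceptor,
its co-regulators, and light-driven chromatin remodeling). The package
provides tested, reusable implementations of five analyses that are usually
written as one-off scripts, together with synthetic-data generators that
plant known ground truth so every stage can be validated end to end.

## What it computes

**Replicate-free differential expression.** With one library per condition
there is no within-condition variance to estimate, so gene counts are
modeled as negative binomial, `G_i ~ NB(mu_i, sigma_i^2)`, and the variance
is borrowed from the genome-wide mean–variance trend: counts are normalized
with median-of-ratios size factors, genes in the lowest expression quintile
are dropped, and `log sigma^2` is fit against `log mu` by local linear
regression across all samples treated as blind pseudo-replicates (with a
chi-square bias correction so the smoother targets `log sigma^2` rather
than `E[log s^2]`). Two single counts are then compared with a conditional
two-sided exact test over all splits of their sum:

    p = sum_{f(a,b) <= f(k_t, k_c)} f(a,b) / sum_{a+b=k_t+k_c} f(a,b)

with `f(a,b)` the product of the two NB marginals. A gene is called
light-inducible when any light timepoint (30/60/120 min) shows `p < 0.05`
and a ≥ 2-fold increase over dark, and is classified as immediate-early,
early, or late from its induction profile. The same test compares
genotypes (e.g. knock-out vs wild type) at matched timepoints.

**ChIP-seq peak calling.** A 150 bp window sliding by 50 bp counts
fragment 5′ ends; each treatment window is tested against the depth-scaled
control count under a Poisson null, and a binding site is called where at
least 4 consecutive windows reach `p < 1e-5`. Peaks below 1.5-fold of the
genome-wide mean window coverage, or below the 90th percentile of window
coverage, are removed. Peaks are annotated to genes by a three-rule
procedure (promoter window −1000..+500 bp around the TSS, strand-aware;
else nearest gene with the summit on its upstream side; else unannotated),
and dark-vs-light differential binding is classified by position relative
to the 80% prediction interval of a log-scale regression.

**MNase-seq nucleosome mapping.** Paired-end fragments of 100–1000 bp are
nucleosomal; fragments under 100 bp are transcription-factor footprints.
The middle 50 bp of each nucleosomal fragment builds an occupancy track
normalized so the 90th percentile of 150 bp window coverage equals 1, then
smoothed by Gaussian kernel regression. The +1 nucleosome is the coverage
maximum within 200 bp of the TSS; metagene profiles average ±1500 bp
around anchors; per-nucleosome occupancy is the area under the curve over
a 176 bp nucleosome; the repeat length comes from profile autocorrelation
or successive dyad distances; and binding-site occupancy is reported as a
ratio to an NB-distance-randomized TSS-matched background.

**Motif analytics.** IUPAC degenerate-pattern scanning (palindromes such
as GATC reported once), pairwise center-to-center spacing distributions of
motifs in 300 bp summit-centered regions against a random-region
background, and motif positional density around summits.

**Synthetic data.** Generators for random genomes, non-overlapping gene
annotations, NB count tables with planted induction profiles, ChIP
fragments with planted enriched sites, MNase fragments from phased
nucleosome arrays with planted footprints, and planted motifs — every
generator a pure function of its parameters and a seed, with the planted
truth recorded for scoring.

## Worked example

```python
import lightchrom as lc
from lightchrom.synth import CountModel

model = CountModel(frac_induced=0.10)              # 10% of genes light-induced
genes = [f"g{i:04d}" for i in range(2000)]
samples = ["wt_DD", "wt_30", "wt_60", "wt_120"]    # dark + three light timepoints
counts, truth = lc.simulate_counts(model, genes, samples, seed=42)

calls, size_factors, fit = lc.run_de(counts)
tab = calls.table
planted = set(truth.de_genes["gene_id"])
called = set(tab.index[tab["called"]])
kept_planted = set(tab.index) & planted
print(f"genes tested after low-expression filter: {len(tab)}")
print(f"planted induced genes: {len(planted)} ({len(kept_planted)} past filter)")
print(f"called light-inducible: {len(called)}")
print(f"sensitivity: {len(called & kept_planted)/len(kept_planted):.3f}")
print(f"false calls among nulls: {len(called - planted)}")
print("class breakdown:", tab.loc[tab.called, 'class'].value_counts().to_dict())
```

prints

```
genes tested after low-expression filter: 1600
planted induced genes: 200 (194 past filter)
called light-inducible: 211
sensitivity: 0.990
false calls among nulls: 19
class breakdown: {'immediate-early': 122, 'late': 89}
```

194 of the 200 planted genes survive the lower-20% expression filter; the
caller recovers 99% of them, the 19 false calls among 1406 null genes are
within the 5% nominal error rate given the 2-fold gate, and planted "early"
genes (8-fold peak at 30 min) land in the immediate-early class while the
monotone risers land in "late".

The same analyses are available from the shell:

```sh
lightchrom simulate --outdir data --seed 7
lightchrom de      --counts data/counts.tsv --out de.tsv
lightchrom peaks   --treatment data/chip_treatment.tsv --control data/chip_control.tsv \
                   --genome data/genome.fa --genes data/genes.gff3 --out-prefix run
lightchrom nucmap  --fragments data/mnase_fragments.tsv --genome data/genome.fa \
                   --genes data/genes.gff3 --out-prefix nuc
lightchrom motifs  --genome data/genome.fa --summits run_peaks.bed --out-prefix mo
lightchrom diffbind --sites sites.tsv --out db.tsv
```

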