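# panelscreen

Deletion screening and recessive variant prioritization for targeted
capture gene panels, built for the molecular diagnosis of Fanconi anemia
(FA) — a recessive chromosomal-instability syndrome caused by biallelic
mutations in any of 15 genes (FANCA–FANCP). A diagnostic screen must find
*two* hits per gene, and the second hit is often the kind Sanger sequencing
misses: a multi-exon deletion, a mosaic deletion diluted by normal cells,
or a deep intronic variant. `panelscreen` implements the two computations
such a screen needs on top of standard mapping/calling output, plus a
deterministic cohort simulator so every stage is testable without patient
data.

## The method

**Read-depth deletion detection.** Per-base depth over the capture targets
is binned in preset windows (default 100 bp, non-overlapping). A pooled
reference is built per window as the median across the library-size
normalized samples of the run — capture efficiency varies strongly per
bait, but identically across samples, so the ratio cancels it. For each
sample and window,

&nbsp;&nbsp;&nbsp;&nbsp;*M* = log₂((c + p)/(r + p)),&nbsp;&nbsp;
c = sample count, r = reference, p = 0.5 pseudocount,

followed by a mean shift to zero. *M* is aggregated per exon (mean with
25th/75th percentiles), and runs of depressed exons become deletion calls:
*M* ≈ 0 is diploid, *M* ≈ −1 a constitutional heterozygous deletion, and a
heterozygous deletion carried by a fraction *f* of genomes gives
depth ratio 1 − *f*/2, inverted as

&nbsp;&nbsp;&nbsp;&nbsp;*f* = 2·(1 − 2^*M*).

An equimolar pool of a carrier and a normal sample (*f* = 0.5, one allele
lost in a four-copy background) reads *M* = log₂(3/4) ≈ −0.4 to −0.5 and is
still called in mosaic mode.

**Prioritization cascade.** Small variants (with allele fractions from AD
fields) pass a detection threshold of 31% of covering reads (12% when
screening for mosaicism), then a funnel: panel genes → protein-affecting
classes (nonsynonymous/splice/truncating, "NS/SS") → absent or ≤ 2% in
dbSNP and the in-house database → disease genes → pathogenic clue
(truncating classes outright; missense with a quorum of damaging
SIFT/PolyPhen-2/Align-GVGD verdicts, consumed as input). Survivors combine
with deletion calls under recessive inheritance: homozygous clue, compound
het pair, het clue over a het deletion, or homozygous deletion ⇒ biallelic;
a single hit escalates the gene's novel intronic/UTR variants for manual
review — the route by which deep intronic second alleles (c.893+920-style)
are found. Variants inside declared pseudogene-homologous regions with
suspiciously low allele fractions are flagged and bypass the detection
threshold, since co-mapping pseudogene reads dilute true variants toward
0.5/copies.

The annotator is transcript-aware: effect classes, HGVS c. positions with
intronic offsets (`c.893+920`), and protein changes for coding SNVs.

## Worked example

Simulate an 11-library capture run in which sample S11 carries a
heterozygous stopgain in *FANCI* plus a heterozygous deletion of the
gene's last exon (exon 38), then run both arms of the screen:

```python
import panelscreen as ps
from panelscreen.prioritization import af_filter, recessive_prioritize, run_cascade
from panelscreen.variant_annotation import annotate

spec = ps.CohortSpec(
    seed=11, n_samples=11,
    planted_variants=[ps.PlantedVariant("S11", "FANCI", "stopgain", "het")],
    planted_deletions=[ps.PlantedDeletion("S11", "FANCI", 38, 38, "het_del")],
)
cohort = ps.simulate_cohort(spec)
cfg = cohort.panel.config()

cnv = ps.run_cnv_pipeline(cohort.panel.targets, cohort.panel.models,
                          [s.depth for s in cohort.samples.values()])
print("deletion calls for S11:", cnv["S11"].calls)

sample = cohort.samples["S11"]
ann = annotate(sample.variants, cohort.panel.models, cohort.frequencies,
               cohort.predictors, cohort.panel.cds_sequences)
funnel = run_cascade(af_filter(ann, cfg), cfg)
print("funnel:", [funnel.counts[s] for s in funnel.counts])
findings = recessive_prioritize(funnel.final, cnv["S11"].calls, ann, cfg)
```

prints

```
deletion calls for S11: [DeletionCall(gene='FANCI', first_exon=38, last_exon=38,
    mean_M=-1.0336..., zygosity_class='het', mosaic_fraction=1.0)]
funnel: [2498, 2336, 220, 7, 1, 1]
```

The single-exon deletion is found at *M* ≈ −1 (one allele lost), the
funnel reduces ~2,500 called variants to one pathogenic clue, and the
finding for *FANCI* is `biallelic` with phase `point+deletion` — the
stopgain on one allele, the exon-38 deletion on the other.

The same pipeline is scriptable from the shell:

```
panelscreen simulate --spec cohort.yaml --out fixtures/
panelscreen cnv --targets fixtures/targets.bed --genes fixtures/genes.refflat \
    --depth fixtures/S01.depth.tsv ... --mosaic --out cnv/
panelscreen prioritize --vcf fixtures/S11.vcf --genes fixtures/genes.refflat \
    --cds fixtures/cds.fasta --freq fixtures/frequencies.tsv \
    --predictors fixtures/predictors.tsv --cnv-calls cnv/S11.depth.calls.tsv --out out/
```

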