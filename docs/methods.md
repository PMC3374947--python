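# Methods

## Depth model and deletion detection

The detector assumes that per-target capture efficiency is a property of
the bait design, not of the sample: the expected depth at base *b* of
target *t* in sample *s* is `mean_depth_s × e_t × cn/2`, with `cn` the
local copy number. Because `e_t` is shared across the run, the per-window
ratio of a sample to a reference pooled from the same run cancels the bait
bias; this cancellation — not any explicit bias correction — is what makes
exon-scale copy-number visible in capture data.

Pipeline stages and the numerical choices in each:

* **Windows** tile each capture target from its start (default size 100 bp,
  step 100 bp, i.e. non-overlapping; minimum size 20). Non-overlapping
  windows keep counts independent and make depth conservation exactly
  testable; overlap is available with `step < size`. Windows never span two
  targets, and the last window of a target is truncated.
* **Library-size normalization** scales every sample's window counts so
  its total equals the cohort median total.
* **Pooled reference** = per-window *median* across the normalized
  samples. A mean or sum would be biased by the very deletion being looked
  for; the median tolerates one aberrant sample in a cohort of ≥ 3. An
  `exclude_self` flag drops the test sample from its own reference (needed
  for 2-sample runs).
* **log2 ratio** uses a pseudocount of 0.5 on both numerator and
  denominator and clamps M to ±5. Zero-coverage windows are otherwise
  undefined; the clamp keeps homozygous deletions (M ≲ −5 raw)
  distinguishable without infinities. In the self-reference limit the
  pseudocount cancels exactly and M ≡ 0.
* **Mean-shift normalization** subtracts the track mean (enforced to
  1e-9). With a small deleted fraction of the panel this shifts deleted
  windows up by roughly (deleted windows / all windows) × |M|, ~0.01–0.02
  in the default panel — visible in the mosaic numbers below.
* **Exon aggregation**: a window belongs to an exon iff they overlap by
  ≥ 1 bp; per exon the mean and the 25th/75th percentiles of window M are
  reported, quantiles by linear interpolation between order statistics
  (pinned so summaries are bit-stable). Exons with no windows are reported
  with `n_windows = 0` and absent summaries.
* **Calling**: an exon is flagged when `mean_M ≤ het_M` (default −0.65, the
  midpoint between 0 and −1 biased toward specificity) **and**
  `q75_M ≤ q75_guard` (default −0.2, requiring the bulk of the exon's
  windows to be depressed, not just the mean). Mosaic mode lowers the flag
  threshold to `mosaic_M` (default −0.2) to keep sensitivity for diluted
  deletions at the cost of specificity — it is an explicit screening mode,
  not the default. Maximal runs of consecutive flagged exons merge into one
  call; single-exon calls are permitted. A run is classed `hom` when its
  mean M ≤ −3.0, `mosaic` when mosaic mode is on and the mean is above
  −0.8, else `het`. Gain calling (mean M ≥ +0.4) exists but is off by
  default.
* **Mosaic fraction**: a heterozygous deletion carried by a fraction *f*
  of genomes dilutes depth as `ratio = 1 − f/2`, inverted as
  `f = 2·(1 − 2^M)`, clamped to [0, 1] and defined only for non-positive M.
  *f* = 1 is a constitutional het deletion; *f* = 0.5 the equimolar
  two-sample pool, i.e. one allele lost in a four-copy background with an
  analytic ratio of log₂(3/4) ≈ −0.415. The measured value in simulation is
  ≈ −0.40 (pseudocount and mean-shift each contribute ~+0.01); the pipeline
  reports whatever it measures.

Chromosome X is treated as diploid; hemizygous male X (the FANCB case) is
a documented limitation — expected copy number per sample sex is a natural
extension but not modeled. Breakpoint-level detection from split reads,
GC correction and HMM/CBS segmentation are out of scope: at exon scale
with a pooled same-run reference, thresholding on per-exon summaries is
sufficient and much easier to audit.

## Annotation

HGVS c. positions follow the standard conventions: coding bases from the A
of the start codon, UTR bases as c.−k/c.*k, intronic bases as offsets from
the nearest exon edge with the smaller offset winning and "+" (offset from
the preceding exon) on ties. The canonical splice region is the 2 intronic
bases on each side of a junction (GT donor / AG acceptor). Alleles are
reduced to minimal representation (shared suffix then prefix trimmed)
before classification. Coding SNVs are classified codon-locally against
the transcript CDS, with the ref allele checked against it (a mismatch is
an input inconsistency and raises); the test suite holds this classifier to
100% agreement with a brute-force oracle that rebuilds and translates the
whole CDS. Indels fully inside the CDS are frameshift/in-frame by length
mod 3; indels elsewhere classify by position. Predictor verdicts
(SIFT/PolyPhen-2/Align-GVGD style) are consumed as input, never computed —
a Grantham-distance surrogate (damaging iff distance > 100) exists solely
to decorate simulated cohorts.

Pseudogene handling is a deliberate formalization: regions with
`copy_factor` highly similar genomic copies are declared (BED with the
factor in column 5), and a variant inside one is flagged when its allele
fraction is in `[af_floor, flag_af_below)` = [0.05, 0.35). The expected
heterozygous AF under full co-mapping is 0.5/copy_factor. Flagged variants
bypass the allele-fraction filter downstream.

## Cascade and recessive model

Defaults: detection at ≥ 31% of covering reads, 12% in mosaic mode;
population-frequency exclusion above 2% (absence from a database counts as
novel and passes); missense clue quorum 2 of 3 damaging verdicts
(configurable down to 1, the reading in which any in-silico evidence
counts); homozygosity at AF ≥ 0.7 (midpoint between the het 0.5 and hom
1.0 clouds at ~100× depth). The "NS/SS" funnel stage keeps nonsynonymous,
stopgain, frameshift, in-frame indel and canonical-splice classes, since
truncating variants evidently survive that stage of the funnel. Compound
heterozygotes are reported "phase unknown" — segregation testing is
outside the pipeline. A single hit in a disease gene (one het clue
variant, or one non-homozygous deletion call — the latter an extension of
the enumerated cases, chosen so a lone het deletion is not silently
dropped under a recessive model) yields `one_allele` plus an escalation
list of that gene's intronic/UTR variants absent from both frequency
databases, rather than auto-promoting them: deep intronic pathogenicity
needs functional follow-up. Clues are counted per variant, not per allele.

## The simulator

`simdata` emulates a multiplexed capture run: 15 disease genes with
realistic exon counts (including a 43-exon and a 38-exon gene) plus two
non-disease panel genes, exons 80–250 bp, introns 0.5–2 kb, targets =
exons ± 50 bp, per-target efficiency lognormal(0, 0.3) shared across
samples, per-base Poisson depth at mean 100×, 11 samples, and ~2,500
background variants per sample (~62% within gene spans) with population
frequencies (88% common, 7% rare-known, 5% novel). Planted pathogenic
variants are realized with class-appropriate alleles found by searching
the actual CDS (e.g. a single substitution producing a stop), and their
keys are reserved out of every sample's background draw — a novel
pathogenic allele cannot simultaneously be a database variant. Allele
depths are Binomial(depth, AF); planted het variants therefore
occasionally dip below the 31% detection threshold, which is the real
behaviour of that threshold and is why the recovery checks are stated at
the ≥ 95%-of-seeds level. Everything derives deterministically from the
spec seed (the capture design optionally from its own `panel_seed`, since
a lab's design is fixed across runs); identical inputs give byte-identical
outputs.

What the simulator does *not* model — and hence what passing tests do not
show about real data: read-level artifacts (mappability, GC, strand bias,
duplicates), overdispersed depth noise, pseudogene sequence homology
(pseudogene regions are declared, not sequence-derived), population
structure in the frequency tables, and exonic/intronic differences in
background variant density (positions are uniform within gene spans, so
the simulated funnel's NS/SS stage retains proportionally more variants
than a real cohort's).

## Problem sizes

The quantitative checks run at the simulator's default conditions: the
full panel at 100× depth, 11-sample cohorts for the deletion criteria (50
seeds each), 5 replicates of the equimolar-mixture design for the mosaic
ratio, 20 replicates in the acceptance script, 3-sample cohorts with full
background variant load for end-to-end truth recovery (50 seeds), and
1,000 random SNVs/variant sets for the annotator-oracle and funnel
property checks.
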