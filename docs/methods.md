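# Methods

## Data model and conventions

All genomic coordinates are 0-based half-open; the `cgmap` dialect (1-based)
is converted on read and write. A site is identified by (chromosome,
position, strand); CpGs on opposite strands are kept as distinct sites,
matching per-cytosine read counting — a dinucleotide merge is left to the
caller because published per-site counts do not state whether strands were
collapsed. Context (CG/CHG/CHH) is trusted from the input file. The
methylation level of a site is #C/(#C+#T), the fraction of
bisulfite-unconverted reads, interpreted as the average methylation of the
cell population at that cytosine. Only sites covered by at least four reads
enter any analysis (boundary inclusive), and each pairwise test uses only
sites observed in every sample of both groups.

## Statistical model

**Per-site test.** The per-cytosine test is the classical equal-variance
pooled two-sample *t* (df = n₁+n₂−2). With two replicates per group, df = 2
and single-site p-values are weak by design; inference rests on the fragment
z-score plus the simulation-based FDR, not on per-site significance. The
pooled (rather than Welch) form was chosen because it exactly reproduces the
published companion statistic computed from group mean ± SEM summaries
(t = 13.6 on the levator-ani muscle areas); Welch is available via
`equal_var=False`. Degenerate case: pooled SD = 0 yields t = 0, p = 1 when
the means agree, and a signed infinite t with p = 0 otherwise — such sites
are almost always removed by the 10% delta filter downstream.

**Fragments.** With a genome FASTA, fragments are internal MspI pieces
(C^CGG) with length in [100, 300] bp — matching an RRBS library's
size-selected fragment span. Without a genome, assayed sites are grouped
greedily left-to-right (gap ≤ 100 bp, span ≤ 300 bp), which exactly recovers
the generating fragment layout on synthetic cohorts. Both yield the same
fragment table and downstream behaviour.

**DMR calling.** Fragment z = unweighted mean of member site t-scores, and
fragment delta = unweighted mean of member site deltas (consistent
weighting). The three filters are |delta| ≥ 0.10 (inclusive), ≥ 3 member
cytosines observed in all relevant samples, and |z| ≥ threshold. The
threshold is applied to the magnitude with direction recorded separately, so
hyper- and hypomethylation are called symmetrically. "Extreme" DMRs
additionally require length > 50 bp, |delta| ≥ 0.25 and |z| ≥ 3.5.

**FDR calibration.** The null model holds the methylation landscape and the
study's exact coverage fixed: per site, Pm is the mean level over all real
samples in the comparison, and each simulated sample draws
c ~ Binomial(n, Pm) at its real coverage n. The entire calling procedure is
re-run on the simulated cohort, and FDR(th) = n_sim(th)/n_real(th), with
FDR = 1 when n_real = 0 but n_sim > 0 and FDR = 0 when both vanish.
The default grid is |z| ∈ {1.00, 1.25, …, 5.00} and one simulated cohort per
comparison (`n_sim_reps` raises this; ≥ 5 gives visibly stabler curves).
The selected threshold is the most lenient grid point with FDR strictly
below the target (default 10%); if none qualifies the caller raises rather
than silently falling back. Note that at 58× coverage the binomial-null
fragment delta has a standard error near 0.03, so the ≥ 10% delta filter
alone suppresses essentially all null fragments and estimated FDRs of
exactly 0 at lenient thresholds are the expected behaviour, not a bug.

**Gene association and set logic.** A DMR supports a gene when its interval
overlaps the gene body or lies within 5 kb (inclusive, minimal base-to-base
distance) of the TSS. Genes are counted once however many fragments support
them. Cross-region "shared" genes require supporting DMR intervals that
overlap and agree in delta sign; cross-age "stable" genes intersect at the
gene level only, because stable differential methylation may shift between
nearby fragments with age. Feature enrichment uses 2×2 Fisher tests of
DMR-CpG membership against the background of **all assayed common CpGs** —
RRBS coverage is CpG-island biased, so the assayed background is the only
universe in which enrichment/depletion claims are meaningful. Overlap
enrichment between gene sets is the upper-tail hypergeometric test with
fold = (k/|A|)/(|B|/N); the gene universe N is not derivable from within a
single analysis and must be supplied (the natural default being the count of
genes reachable by the association rule from any assayed CpG).

**Masculinization.** Dimorphic sites are selected per age
(|mean_XX − mean_XY| ≥ 0.15 and p ≤ 0.05, both inclusive); the score
rescales the treated-group mean so XY ↦ 0, XX ↦ 100. Scores are clipped to
[0, 100] for the bounded histogram and the ≤ 50 masculinized count; the raw
value is kept in the output table for inspection. Selection is recomputed at
each age independently, as implied by age-specific site totals. The
dimorphic-site FDR can be estimated with the same binomial null machinery
but is reported as metadata, never used as an additional filter.

## Synthetic cohorts

The generator emulates the study conditions: 3 groups × 2 ages × 2 regions ×
2 replicates; CpGs in 5-site clusters 40 bp apart, clusters 1 kb apart,
across four autosomes and chrX (15% of fragments); baseline levels from a
bimodal beta mixture (modes 0.05 and 0.85, concentration 60, equal weight —
island-like and body-like compartments); coverage ~ NegativeBinomial(mean
58, dispersion 10); counts ~ Binomial(coverage, true mean). Implanted
effects, drawn independently per region with all true means clipped to
[0.02, 0.98]:

| block | default | emulates |
|---|---|---|
| autosomal sex fragments | 3% of autosomal fragments, Δ = 0.30, 92% XY-hyper | male-biased autosomal hypermethylation |
| chrX sex fragments | 15% of chrX fragments, Δ = 0.30, 85% XX-hyper | X-inactivation-driven female hypermethylation |
| testosterone PN4 | 0.2% of fragments, Δ = 0.30, 96% XX+T-hyper | scarce early effects |
| testosterone PN60 | 4% of fragments, Δ = 0.30, 96% XX+T-hyper | ~20-fold late emergence |
| masculinization | f = 0.7 of dimorphic sites: XX+T mean := XY mean at PN60 | adult methylome masculinization |
| non-CpG age shift | +0.02 at PN60 (CHG/CHH, baseline 0.02) | age-increasing non-CpG methylation |

PN60 testosterone fragments are drawn off the sex fragments by default
(`t_sex_overlap = 0`): overlap between called testosterone-affected and
sex-affected gene sets then *emerges* from the masculinization mechanism
(masculinized dimorphic sites differ between XX and XX+T) instead of being
implanted twice — implanting both inflates the masculinized-site count at
feminine sites and biases the recovered fraction upward. Masculinization
labels are drawn per site (Bernoulli(f)), making the recovered fraction
exactly binomial. All draws flow from the master seed through named SHA-256
substreams (`_rng.child_seed`), so a cohort is byte-reproducible and every
comparison's null simulation is independently reproducible.

What the generator does **not** model: sequencing error and incomplete
bisulfite conversion (levels are exact binomial draws around the true mean),
replicate-level biological overdispersion (replicates share a true mean, so
the binomial null is exactly correct by construction — on real tissue the
null can be optimistic if replicates vary biologically), linked methylation
along a fragment beyond the shared effect, and realistic genomic spacing.
Passing recovery tests therefore demonstrates correctness of the machinery
under the stated sampling model, not performance on real libraries.

## Problem sizes and numerical choices

Tests and the acceptance script use 50,000-CpG cohorts (10,000 fragments)
for calibration/recovery runs and 3,000–5,000-CpG cohorts for pipeline-level
checks; these sizes give binomial tolerances tight enough to detect
miscalibration while keeping a full run in seconds. Threshold grids must be
strictly increasing; ties in hierarchical clustering fall back to scipy's
deterministic ordering; correlation against a zero-variance vector is
reported as NaN rather than 0; duplicate sites, negative counts and
malformed rows are hard errors with line numbers.

## Known limitations

* The per-site test at df = 2 is not trustworthy in isolation; do not
  interpret single-site p-values.
* A single simulated cohort (the default) makes the FDR curve itself noisy
  at strict thresholds where counts are small.
* `bedgraph_counts` cannot encode strand or non-CpG context.
* GFF3 parsing covers plain `gene`/`exon` records with `ID`/`Parent`
  attributes — adequate for toy and standard annotations, not the full
  specification.
* The expression side of any methylation–expression intersection must be
  produced externally; only the gene-level join is provided.
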