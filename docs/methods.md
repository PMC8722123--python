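# Methods

This note documents the models and numerical choices behind `acetylseq`:
what each stage computes, the parameters that matter, what the synthetic
epigenome emulates (and does not), and the known limitations.

## Coordinate conventions

All internal coordinates are 0-based half-open (BED convention). GFF3
(1-based inclusive) and CX-report positions (1-based) are converted at
the I/O boundary. One representative transcript is kept per gene: the
longest mRNA by span, ties broken by file order. The TSS is the first
transcribed base (`start` on `+`, `end − 1` on `−`); the promoter is the
1-kb window strictly upstream of the TSS, strand-aware and clipped at
chromosome ends.

## Peak calling

The caller is a windowed Poisson enrichment test, deliberately simple
and fully specified rather than a re-implementation of a production
ChIP-seq caller. For each sliding window (200 bp, step 50 bp — sized for
200–400-bp fragment libraries) the IP signal `k = round(Σ IP coverage)`
is tested against a rate `λ = max(input window signal × L_IP/L_input,
pseudocount)`, where `L` are library sizes (total signal). The one-sided
upper-tail p-value `P(Poisson(λ) ≥ k)` is corrected across all windows by
Benjamini–Hochberg; windows with q < 0.05 **and** fold `k/λ ≥ 2` are
merged within 100 bp into peaks, scored by the max −log10 p of member
windows (capped at 1000). Rounding `k` is needed because coverage tracks
can carry non-integer per-base values (e.g. 10-bp-binned bedGraphs); at
realistic depths the rounding is negligible relative to λ.

Replicate consensus retains peaks with ≥ 1 bp overlap in the other
replicate and reports the union of the reciprocally overlapping
coordinates (conservative for downstream overlap statistics); the output
is disjoint.

Limitations: no local-λ background (large-scale copy-number or
accessibility gradients inflate calls), no duplicate filtering, no
fragment-size estimation. The FDR < 0.05 retention rule is the
analysis contract; the other knobs live in `PeakCallParams`.

## Peak annotation

Every base is labelled with a fixed priority — gene-body subfeatures
beat promoters; among subfeatures 5′ UTR > exon (UTRs excluded) >
intron > 3′ UTR; the first-listed gene wins equal-priority collisions —
and a peak takes the single category with maximal base overlap (ties in
the same order). This single-assignment rule makes category percentages
sum to 100. The expected composition for the per-category Fisher tests
is the per-base category fraction of the whole genome under the same
rules, scaled to the observed peak count; the test therefore compares
peak placement against uniform base placement, not against a
gene-structure-preserving null.

## Profiles

Metagene matrices use 20 equal-length gene-body bins (remainder bases to
the TES-proximal bin) plus 1-kb flanks in fixed 50-bp bins; minus-strand
genes are computed directly in transcription orientation, so
`Σ (bin mean × bin width)` reproduces the exact per-base body signal
(conservation tolerance 1e-9) and strand-mirrored genes give identical
rows. Bins with no measurable base are NaN and excluded from column
means. Two gap policies exist: `zero` (IP coverage; gaps are true zero
signal) and `ignore` (methylation level tracks; gaps are unmeasured
cytosines and must not dilute bin means).

A gene is `tss_marked` when a peak overlaps the 250-bp window centred on
the TSS (`[tss − 125, tss + 125)`), `nontss_marked` when only the body or
promoter is hit, else `unmarked`. Chromosome-scale profiles report the
fraction of each 100-kb bin covered by merged peaks (the final partial
bin normalised by its true length); peak-coverage fraction was chosen
over read coverage as the bin statistic because it is robust to depth.

## Methylation

Interval methylation is the weighted level Σ n_meth / Σ n_total over
qualifying sites of one context (CG/CHG/CHH), with a ≥ 5× per-site
coverage floor for gene-level statistics; "no qualifying site" is
`None`, distinct from a measured 0. Opposite-strand calls at one
position are pooled. Gene-body mCG classes: heavy ≥ 0.1, moderate
[0.01, 0.1), light < 0.01 — the only three-way partition of [0, 1]
consistent with the class boundaries, resolving the boundary ambiguity
at 0.01 in favour of moderate.

DMR calling tests each shared ≥ 5×-covered cytosine with a two-sided
Fisher exact test on the two samples' (methylated, unmethylated) counts
(vectorised hypergeometric implementation, identical to scipy's
definition to < 1e-10). Candidate sites need p < 0.05 and a same-sign
level difference ≥ 0.1; runs of candidates within 300 bp join into
regions; regions are kept with ≥ 4 sites, span ≥ 100 bp, and a
region-wide weighted-level difference ≥ 0.1. The 300-bp join gap is this
package's choice (regional callers behave similarly; no rule is imposed
by the thresholds themselves). The per-site exact test replaces
smoothed beta-binomial dispersion modelling: it is exact at each site
but does not borrow strength across sites, so single-site power is lower
at shallow depth and no biological-replicate variance is modelled.

## Differential acetylation

Signal is summed per merged peak region per sample and scaled to the
mean library size. `log2FC = log2((mut + 0.5)/(wt + 0.5))` on scaled
group means; significance comes from a two-sided binomial test of the
pooled raw mutant count against `n = mut + wt` with the library-size
ratio as the null proportion, BH-corrected across regions. A region is
a DAR iff |log2FC| > 1 and q < 0.05. The pooled binomial test treats
replicates as exchangeable pools (no overdispersion), so its p-values
are anti-conservative on noisy real replicates — the fold-change gate
carries most of the specificity. Swapping group labels negates every
log2FC and preserves q exactly.

DAGs are genes whose body or 1-kb promoter overlaps a DAR; uDAGs are
DAGs whose body **and** 1-kb upstream region overlap no DMR of any
context. DAR-vs-DMR overlap is compared against length-matched random
regions (chromosome chosen ∝ length, start uniform, overlaps with the
template not excluded — the simplest null) with a Fisher test on the
2×2 overlap table. Methylation fold changes over regions use
`log2((level_b + 0.01)/(level_a + 0.01))`; the 0.01 pseudocount keeps
near-zero euchromatic levels from exploding the ratio.

## Integration statistics

All gene-level joins live in one table (FPKM, acetylation label, mCG
class, per-mark booleans). "Marked by" a histone mark means ≥ 1 bp
overlap with the gene body (promoter inclusion is opt-in). Expression
comparisons use the two-sided Mann–Whitney U test: exact null by full
enumeration of group assignments (ties counted half) whenever the
smaller group has ≤ 8 members and C(N, n_small) ≤ 50,000 — full
enumeration is intractable beyond that, so larger designs use the
tie-corrected normal approximation with continuity correction; two
identical constant groups return p = 1. Quartile groups rank by FPKM
descending (ties by gene id), extra genes to the top groups. Expected
colocalization percentages come from one seeded length-matched
randomisation of the query peaks (randomising the query rather than the
references keeps every reference set fixed); BH-adjusted p-values are
reported alongside raw per-row p.

## Synthetic epigenome

The generator emulates the structure the pipeline is built to detect, in
a 5-Mb toy genome (2 × 2.5 Mb) with 500 non-overlapping genes confined
to euchromatic arms around one central pericentromeric heterochromatin
block per chromosome (20% of its length):

- **Expression**: FPKM = 0 with probability 0.2, else log-normal
  (μ = 1, σ = 1.5 natural-log) — a heavy-tailed mix of silent and
  expressed genes.
- **Acetylation truth**: peak presence is Bernoulli with logistic
  probability in the centred expression rank (slope 6), so the marked
  fraction rises from ~5% to ~95% across the expression range. Given a
  peak, TSS-proximal placement (centre ~150 bp downstream of the TSS
  ± 100 bp, truncated at 4σ) is itself logistic in expression rank
  (intercept 1, slope 3); the remainder are gene-body peaks well clear
  of the TSS window, so the TSS/non-TSS expression ordering is planted.
  Peak widths are uniform 300–500 bp at 8-fold enrichment.
- **Coverage**: per-10-bp-bin Poisson counts around a background depth
  of 30× (matching ~30× sequencing), with the enrichment footprint
  smoothed by a 300-bp box kernel (the centre of the 200–400-bp fragment
  range); the input and the second replicate are independent draws.
- **Methylation**: cytosine sites every ~20 bp; per-site latent levels
  are beta-distributed — hyper-methylated heterochromatin (CG/CHG/CHH
  means ≈ 0.8/0.6/0.33), low euchromatic background (≈ 0.02), and
  gene-body mCG around a per-gene latent mean drawn from Beta(0.5, 3.5)
  so genes populate all three heavy/moderate/light classes; counts are
  binomial at Poisson(30×) depth.
- **Companion marks**: histone marks, DHS and TF sites are sampled
  conditional on the acetylation truth (active marks ~0.65–0.75 given a
  peaked gene vs ~0.25–0.30 otherwise; repressive marks inverted).
- **Mutants**: `met1` resamples CG levels from Beta(0.5, 50) (genome-wide
  CG erasure, CHG/CHH untouched); `rdd` adds +0.4 to all contexts in 20
  planted 2-kb hyper-regions. Both modes attenuate a configurable 30% of
  peaks to background to plant true DARs. Every planted element is in
  the ground-truth manifest.

The same config + seed reproduces every emitted file byte-for-byte
(seeds are spawned per component from one `SeedSequence`).

What the simulator does **not** model — and what passing tests therefore
do not demonstrate about real data: sequence composition and
mappability, PCR duplicates, copy-number or accessibility gradients in
the input, biological-replicate variance beyond resampling noise,
bisulfite conversion failure, isoform diversity, and overlapping genes.
Recovery rates on synthetic data are upper bounds on real-data
performance.

## Scaling of the test battery

The default test battery runs the full pipeline at the 5-Mb / 500-gene
study scale once, planted-peak recovery at 5 Mb / 50 peaks over 10
seeds, DMR recovery on five 0.6-Mb methylation simulations, DAR recovery
over ten 0.8-Mb simulations, and a 20-seed null calibration at 1 Mb /
300 genes; the whole suite completes in well under a minute on one CPU
while exercising every stage at the configured depths and effect sizes.
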