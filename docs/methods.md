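# Methods

This note documents the models, conventions and numerical choices behind
`lncnet`, in the spirit of the methods documentation of statistical
genomics packages.

## Coordinate and data conventions

GTF input/output is 1-based inclusive; in memory all intervals are 0-based
half-open. The distance between two disjoint intervals is the gap length in
bp (0 when they touch). Expression matrices are feature × sample tables of
non-negative reals tagged as `counts` or `fpkm`; sample metadata (tissue,
stage ∈ {IV, V, VI}, replicate) lives in a separate design table.

## lncRNA identification and classification

Novel-transcript candidates must have ≥ 2 exons and ≥ 200 bp of exonic
sequence. Coding potential is a three-verdict consensus: a transcript is a
lncRNA candidate only when *all three* sources (two ab initio predictors
plus a protein-database search — external tools whose boolean verdicts are
inputs) call it noncoding. A built-in ORF heuristic (coding iff the longest
forward-strand ATG→stop ORF spans ≥ 100 codons) is provided as a simple
stand-in verdict source for pipelines without external predictions.

The five positional categories are names in common use; their geometry here
is an explicit convention, applied in priority order so each lncRNA gets
exactly one label:

| priority | category | rule (defaults) |
|---|---|---|
| 1 | antisense | ≥ 1 bp exonic overlap with a gene, opposite strand |
| 2 | sense_overlapping | exonic overlap, same strand |
| 3 | intronic | wholly inside one intron of a gene (either strand), no exonic overlap |
| 4 | bidirectional | non-overlapping, TSS within 1 kb of a gene TSS, divergent orientation |
| 5 | intergenic | > 5 kb from every gene |
| 6 | other | everything remaining (e.g. 0–5 kb from a gene, convergent orientation) |

Both distances are configurable (`ClassifyParams`). Category percentages
are rounded half-up to one decimal, matching the usual reporting style.

## Differential expression

Counts are normalized as FPKM[i, j] = counts[i, j]·10⁹ / (libsize[j]·len[i]).
The per-feature test is pluggable; the default is Welch's *t* on
log₂(FPKM+1), a deliberately simple substitute for a negative-binomial
count test — an NB test can be registered under the same contract
(`register_de_test`). With identical groups the default test returns *p* = 1.
Multiplicity is controlled by Benjamini–Hochberg step-up. Calls are strict
threshold rules: `up` iff log₂FC > 1 and *q* < 0.05 (mRNA/lncRNA) or
*p* < 0.05 (miRNA); symmetric for `down`. Fold change uses pseudocount 1 on
mean FPKM and is oriented later-stage over earlier-stage (the label
`IV_vs_V` means V relative to IV).

Null calibration of the default test on simulated NB counts (n = 3 vs 3,
2,500 null features) gives empirical type-I error ≈ 0.03–0.04 at α = 0.05 —
slightly conservative, as expected for Welch at small n.

Headline DE totals are reported in two forms: the *sum* of per-comparison
counts (the convention used for combined totals, which double-counts
features DE in both comparisons) and the deduplicated *union*, with the
pairwise intersection sizes; |A∪B| = |A|+|B|−|A∩B| is asserted in tests.

## Target assignment and ceRNA inference

Antisense edges require ≥ 1 bp of opposite-strand exonic overlap (evidence:
overlap bp). Cis edges require a non-overlapping gene with span gap strictly
< 10 kb (evidence: gap bp); overlapping pairs belong to the antisense/sense
logic, never cis. Trans edges require |Pearson r| ≥ 0.9 (inclusive) across
all samples of the tissue under analysis; the sign is recorded. By default
the pipeline pairs only DE lncRNAs with DE mRNAs (`de_only_targets: false`
lifts this).

ceRNA triplets join the SCC-filtered (feature, miRNA) pair lists:
a pair survives only if the miRNA targets the feature per the input target
table *and* Spearman ρ < −0.7 (strict; mid-ranks for ties). For each
(mRNA, lncRNA) couple sharing ≥ 1 retained miRNA, the couple is kept iff
Pearson r > 0.9 (strict) and the shared-sponge hypergeometric upper tail
P(X ≥ k) < 0.05, with universe M = the number of expressed miRNAs
(configurable; the alternative of all miRNAs in the target table is a
caller choice), and K, n the *retained*-pair miRNA counts of the two
features. Sponge p-values are not multiplicity-corrected by default
(the filter is on raw *p*); a BH option exists. A triplet stores the most
negative SCC per side when several miRNAs are shared. The hypergeometric
engine is shared with ORA and is validated against brute-force enumeration
of all draws for M ≤ 12.

Note the minimum-universe consequence: a single shared miRNA (k = K = n = 1)
has p = 1/M, so triplets are only detectable at α = 0.05 when M > 20. The
synthetic study's default of 30 miRNAs respects this.

## Enrichment

ORA uses the upper-tail hypergeometric on the DE-list/gene-set overlap
within a configurable universe (default: expressed genes), reporting raw
*p* (the conventional filter is *p* < 0.05). GSEA ranks genes by
signal-to-noise (μ_A−μ_B)/(σ_A+σ_B) with each σ floored at
max(0.2·|μ|, 0.2) (the floor convention of the reference desktop
implementation), computes the weighted-KS enrichment score (hits advance by
|score|/Σ|score|, misses retreat by 1/(N−set size); ES is the signed
extremum), and normalizes against phenotype relabelings: NES = ES / mean
|null ES| of matching sign, nominal *p* by the add-one convention
(so 999 same-sign nulls give a floor of 1/1000), and FDR *q* by the
standard signed tail-area method on sign-normalized null and observed NES.
Phenotype (not gene-set) permutation is used because the design has
replicate structure; with few replicates the relabeling space is tiny, so
all distinct relabelings are enumerated exhaustively whenever their number
does not exceed the requested permutation count (e.g. all C(12,6)−1 = 923
relabelings of a pooled 6 vs 6 design). Significance requires |NES| > 1,
*p* < 0.05 and *q* < 0.25, all strict. The signed-extremum ES statistic is
mean-zero for uniformly random sets only on long ranked lists; the
invariant test uses N = 1,000 genes, where |mean ES| < 0.05 holds.

## Synthetic data

The generator emulates the study design: 2 tissues × 3 ovarian stages × 3
replicates, negative-binomial counts (mean/dispersion parameterization;
defaults: mean 100, dispersion 0.05) with per-sample library-size factors
drawn uniformly within ±20 %. A fifth of the features (default) carry a
planted |log₂FC| = 2 step change from the later stage of their assigned
comparison onward, alternating up/down, identical in both tissues. The
default category mix renormalizes the empirical proportions of the four
categories observed in the motivating system (intergenic 0.563,
bidirectional 0.103, antisense 0.222, sense-overlapping 0.112; no intronic
by default, though intronic placement is supported).

Geometry: genes (3 exons, 5 kb) sit on one synthetic chromosome at 30 kb
spacing; each lncRNA occupies its own host locus and is constructed to
satisfy exactly one category rule. Antisense lncRNAs yield planted
antisense pairs; bidirectional lncRNAs (gap 200 bp) and half of the
intergenic lncRNAs (placed at 6 kb, inside the 5–10 kb band) yield planted
cis pairs; the remaining intergenic lncRNAs sit at 12 kb, outside the cis
window.

ceRNA triplets are driven by a shared latent profile z per triplet: the
mRNA and lncRNA add 1.5·(c·z + √(1−c²)·ε) on the log₂ scale and the miRNA
adds the negated latent term, where c = `corr_strength`; at c = 1 the
planted SCCs are exactly −1 and the PCC exactly +1. When `nb_dispersion`
is 0 the matrices contain the expected counts themselves (no sampling
step), which is what makes the noiseless-limit recovery assertions exact.
All randomness derives from the config seed, so identical configs give
byte-identical fixture files.

What the generator does *not* emulate: per-feature baseline heterogeneity,
tissue effects, length-dependent count bias, batch structure, correlated
nulls, or sequence content. Passing recovery tests therefore demonstrate
correctness of the inference logic under the stated noise model, not
performance on real libraries.

## Recovery analyses and problem sizes

Planted-truth recovery (tests and `scripts/acceptance.py`) uses the default
study size: 120 genes, 60 lncRNAs, 30 miRNAs, 8 triplets. DE
sensitivity/FDR is measured over ≥ 10–20 replicate simulations, pooling
the two tissues per stage (6 vs 6), since the planted effect is
tissue-shared; sensitivity ≥ 0.9 at empirical FDR ≤ 0.1 is the acceptance
bar, and the observed values are ~1.0 and < 0.01. The per-tissue runs of
the worked example (3 vs 3) are shown unpooled and are expectedly less
sensitive. GSEA recovery uses the pooled stage-V vs stage-VI columns with
exhaustive relabeling.

## Known limitations

* The default Welch-on-log-FPKM test underperforms count-based tests at
  n = 3; it is a contract placeholder, not a recommendation.
* Antisense pairing is coordinate-overlap only; no RNA–RNA duplex
  energetics.
* The ceRNA model uses marginal correlations, not partial/sensitivity
  correlation, and inherits the universe-size sensitivity noted above.
* The GSEA FDR follows the tail-area normalization and can be coarse when
  few gene sets are tested.
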