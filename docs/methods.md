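# Methods

This note documents the models and procedures implemented in
`cernaforge`, the defaults and why they were chosen, what the synthetic
study generator does and does not emulate, and the design decisions made
where the analysis convention was genuinely open.

## Study design assumed

Two muscle groups (a glycolytic analogue, "PMM", as group 1 and an
oxidative analogue, "SART", as group 2), each with `n_per_group` = 4
replicate libraries, quantified per RNA class: mRNA, lncRNA, circRNA
(back-splice junction counts), miRNA. Fold changes are oriented group 2
over group 1, i.e. positive log₂FC means higher in the oxidative
analogue.

## Normalization

FPKM is computed exactly as `c·10⁹/(L·T)` with `L` the spliced
(exon-sum) transcript length and `T` the per-sample total of the class's
count table. The identity `Σ_f FPKM_fs·L_f·T_s/10⁹ = T_s` holds to
floating-point precision and is asserted in the tests. circRNA
abundances are junction counts with no meaningful transcript-length
normalization, and mature miRNAs are essentially constant-length, so
both classes use counts per million instead. Samples with zero total
counts are a hard error naming the sample.

## Differential expression

The test is a conditional exact two-group negative-binomial test:

1. Counts are scaled to the mean effective library size
   (`c′ = c·T̄/T_s`) and rounded. Library sizes default to column totals
   and can be supplied explicitly.
2. A single common dispersion φ is estimated by method of moments,
   pooling over features and groups: φ̂ = max(0, Σ(v−m)/Σm²) with
   unbiased within-group variances v and group means m. The pooled ratio
   form keeps the estimator stable at n = 4; tests confirm it recovers a
   known φ within a few percent on 1 000 features.
3. Under the null, the sum of n i.i.d. NB(μ, φ) counts is NB(nμ, φ/n).
   Conditional on the feature's total s, the group-1 sum has probability
   ∝ NB(a; n₁/φ, ·)·NB(s−a; n₂/φ, ·); at φ = 0 this reduces exactly to
   Binomial(s, n₁/(n₁+n₂)). The two-sided p-value sums the conditional
   probabilities of all splits no more likely than the observed one
   (minimum-likelihood rule, with a 1+1e−12 relative tie tolerance
   against floating-point ordering artifacts). p ∈ (0, 1] always.
4. log₂FC = log₂((mean₂+0.5)/(mean₁+0.5)) on scaled counts. The 0.5
   pseudocount keeps all-zero groups finite.

Significance is raw p < 0.05 (strict) **and** |log₂FC| ≥ 1 (inclusive).
No multiple-testing correction is applied by default, matching the
raw-p filtering convention of the study design this pipeline targets; a
Benjamini–Hochberg option (`adjust="BH"`) exists and is off by default.
A full edgeR-style TMM/tagwise-dispersion treatment is deliberately out
of scope; the exact conditional test with a common dispersion is
self-contained, auditable against a binomial oracle, and holds its
nominal type-I error within the tested band (empirically ≈ 0.05–0.065 at
φ = 0.1, 4 vs 4 — slightly anti-conservative because a single common
dispersion understates per-feature variability, which the planted-FDR
check bounds in practice).

Sample correlations (the replicate-consistency heatmap) are computed on
log₂(FPKM+1); the transform is a convention choice, exposed as an
argument. Constant sample vectors give missing correlations with a
warning rather than an error.

"Expressed in a group" for the presence (Venn) partition means raw
count ≥ 1 in at least one sample of the group; the partition
group1-specific / group2-specific / shared / unexpressed is exhaustive
and disjoint.

## Candidate filters

lncRNA candidates are accepted when spliced length ≥ 200 bp, exon
count ≥ 2, and **both** coding-potential predictors label the transcript
noncoding (labels are an input table; the predictors themselves run
externally). Rejections are attributed to the first failing rule in the
fixed order length → exons → coding so tallies are deterministic.
circRNAs are retained when their junction count is ≥ 1 in at least two
samples, groups ignored; ≥ 1 is the read floor chosen where the
convention gives none.

## Cis-target windowing

The gap between two features is the number of bases strictly between
their 1-based inclusive spans, `max(0, max(start) − min(end) − 1)`, zero
on overlap. A (lncRNA, gene) pair is emitted when the gap is
≤ `cis_window` (default 10 000 bp, **inclusive** — the written
conventions "10 kb" and "< 10 kb" conflict, so the inclusive reading is
used and the window is a flag; the generator's placements avoid the
9 500–15 000 bp band so either convention labels planted pairs
identically). Strand does not affect eligibility and only annotates the
lncRNA as upstream/downstream/overlapping relative to the gene's strand.
Distances are between transcript spans, not promoters or TSSs, which the
source convention leaves unstated. The implementation queries an
interval tree of window-padded gene spans; tests hold it to exact
agreement with a brute-force all-pairs oracle.

## Enrichment and the sponge test

Both use the upper-tail hypergeometric probability computed as a
log-space sum of log-gamma terms (`logsumexp`), exact to well over 10
significant digits for the background sizes involved and verified
against exhaustive draw enumeration (N ≤ 12) and one-sided Fisher exact
tests to 1e−10. Term enrichment uses, as background, all genes expressed
in either group; genes without term annotations stay in N (droppable by
flag). Raw p < 0.05 defines significance, BH optional. The sponge test
for a (regulator, mRNA) pair counts shared targeting miRNAs within the
miRNA universe; the universe defaults to the DE-miRNA set, which is the
deliberately conservative choice — a universe of all annotated miRNAs
would only shrink the tail probabilities.

## miRNA target edges

Canonical seed matching on the target sense strand: 7mer-m8 = exact
reverse complement of miRNA positions 2–8 (the default and only site
type enabled out of the box, keeping false positives low on short
sequences), 6mer = positions 2–7, 7mer-A1 and 8mer add the A opposite
position 1. U/T are interchangeable on input. Non-overlapping sites are
claimed strongest-type-first, left to right. Imported edge tables are
deduplicated on (miRNA, target); when merged with predictions the
strongest evidence wins under imported < 6mer < 7mer-A1 < 7mer-m8 <
8mer. No thermodynamic or conservation scoring is attempted.

## ceRNA triads

Correlations are computed across the pooled 8 samples on log₂(expr+1):
Spearman with average ranks on ties for miRNA–target pairs (kept when
SCC < −0.7, strictly, and the pair is a target edge), Pearson for
regulator–mRNA pairs (kept when PCC > 0.9, strictly). Pooling the groups
is the substantive choice here: with 4 replicates per group,
within-group correlation is hopeless, and it is the group contrast
itself that carries the co-expression signal; the scope is exposed as
`corr_scope`. A triad row is emitted per miRNA anti-correlated with both
members of a co-expressed pair whose sponge p < 0.05. circRNA regulators
go through identical rules (flag `circ_triads`, on by default). Each
triad carries a descriptive `direction_consistent` flag (regulator and
mRNA moving together, opposite to the miRNA) rather than filtering on
it.

## Synthetic study generator

The generator produces what the pipeline consumes — GTF annotation,
four count TSVs, miRNA/target FASTA, coding labels, a target-edge table,
a GO-like term map — plus a JSON truth ledger of every planted signal.

* **Layout.** Features are placed on 5 synthetic chromosomes with
  ≥ 20 kb between layout entities, so a lncRNA can be within 10 kb only
  of the gene it was planted beside. `cis_fraction` (default 0.15,
  roughly the fraction of DE lncRNAs with a close neighbour in studies
  of this design) of lncRNAs get a gap uniform in [0, 9 500] bp on a
  random side of a distinct gene; all others are ≥ 15 000 bp from every
  gene. circRNAs are 1–3 consecutive exons of a random host gene.
  Optional decoy lncRNAs violate exactly one filter rule each.
* **Counts.** Gamma–Poisson with log-normal baselines
  (`exp(N(5, 1))`, medians ≈ 150 counts; circRNAs shifted −2 on the log
  scale because junction reads are scarce), dispersion φ = 0.1 (a
  typical bulk RNA-seq replicate value), per-sample library-size factors
  drawn uniformly from 0.8–1.2×10⁶. 10 % of features per class are DE
  with the group-2 mean multiplied by 2^±2.
* **Triads.** Members of the 30 planted triads share a per-triad latent
  factor z_s = (±1 by group) + N(0, 0.25²), entering the regulator and
  mRNA log-means with +, the miRNA with −, scaled by
  `triad_corr_strength · latent_scale` (0.9 · 2.2 by default). Aligning
  the factor with the group contrast makes triad members both strongly
  DE and strongly co-ranked across the pooled samples — the behaviour of
  fiber-type program genes, which differ by orders of magnitude between
  red and white muscle. The amplitude was set from the gate arithmetic:
  at n = 8 samples a strict PCC > 0.9 demands a latent correlation
  around 0.97+, i.e. a latent variance ≈ 30× the NB log-scale noise
  (≈ 0.11 at these means), giving amplitude ≈ 2. Each triad also gets
  two decoy miRNAs targeting both members (edges only, no correlation
  structure), because a single shared miRNA cannot reach p < 0.05 under
  the hypergeometric tail for any realistic universe size — with k = 3
  shared of ~45 the test is decisively significant.
* **Sequences.** miRNAs are random 22-nt RNA; each planted target edge
  embeds one exact 7mer-m8 site at a recorded position in a 500-nt
  random target, and unintended copies of a planted miRNA's seed in its
  own target are scrubbed by point mutation, so seed scanning recovers
  exactly the planted sites plus only cross-pair chance matches.

What the generator does **not** emulate: read-level artifacts (GC and
length bias, mapping ambiguity), isoform structure beyond exon counts,
batch effects, tagwise dispersion, correlated DE beyond the triads, and
any real GO/KEGG structure (terms are flat random sets with one term
planted in DE genes). Passing the planted-recovery checks therefore
demonstrates internal statistical correctness of the pipeline under its
own model, not performance on real libraries.

## Numerical and determinism choices

Child RNG streams are derived from the single seed by fixed offsets
(annotation, counts, sequences), so stages regenerate independently.
All outputs are sorted with stable tiebreaks (p then term id; regulator,
mRNA, miRNA for triads; lncRNA, gap, gene for cis pairs). No timestamps
enter output files; re-runs are byte-identical and tests assert it.
Degenerate inputs (zero-total samples, constant expression vectors,
empty miRNA universes, empty DE sets) are either named errors, warnings
with skips, or graceful stage skips as documented per function.

## Problem sizes used in the checks

The shipped verification runs use the default conditions: 2 000 mRNAs /
400 lncRNAs / 300 circRNAs / 150 miRNAs at 4 vs 4 for recovery metrics;
2 000 null features for the type-I rate; group sums to 30 for the
binomial-oracle grid; 200 random tables for the Fisher comparison; 50
random annotations (≤ 200 features) for the cis oracle; 10 label
permutations for the false-triad null. These sizes give stable
statistics while keeping a full run in tens of seconds.

## Known limitations

The common-dispersion exact test is mildly anti-conservative relative
to tagwise-dispersion methods when variability differs across features.
The raw-p DE filter makes no FDR guarantee (the BH option does). The
sponge test inherits the usual independence assumption between the two
target sets. Triad discovery at n = 8 pooled samples fundamentally
relies on the group contrast; within-group ceRNA dynamics are not
detectable at this design size and the permutation check confirms the
pipeline does not invent them.
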