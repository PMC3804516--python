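# Methods

This note documents the models and procedures `alemut` implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Cohort model and presence rule

A cohort is one wild-type ancestor, N ≥ 2 population samples with a
strict stage ordering, and M ≥ 1 single-colony isolates from the final
population. Population samples are deep sequencing of a mixed
population, so each variant observation carries an allele frequency;
wild-type and isolate samples are clonal and their observations are
treated as fixed.

A single **presence threshold** (default 0.02) governs everything
downstream: a population observation below it is recorded as a
*detection* but does not establish the mutation in that population. The
same rule feeds the reference-artifact screen, the pan-genome partition
and the longitudinal profile, so one parameter cannot drift between
stages. The 2% default reflects the detection floor of population
resequencing at ~50× coverage: isolate-private mutations are routinely
detected in the final population below that level without being
established in it.

## Screening

Screening is two ordered steps, counted in distinct variants:

1. **Reference-artifact removal.** A variant present (per the presence
   rule) in *every* sample including the wild type is a discrepancy
   between the actual ancestor and the published reference, not an
   evolved mutation; the whole variant is removed. Running this first
   means the artifact count is independent of caller confidence flags.
2. **Confidence-flag filtering.** Only `hc` calls survive; `fp`, `ise`
   and `sv` calls are dropped and tallied per flag. Flags are
   caller-provided inputs; the package never recomputes them from read
   evidence. Flags must agree across a variant's observations.

Both steps are idempotent, and artifact-removal-then-flag-filtering
equals flag filtering restricted to non-artifact variants; both
properties are tested against brute-force set arithmetic.

## Effect classification

SNPs inside a CDS are classified by extracting the affected codon on the
coding strand (reverse-strand genes are reverse-complemented), mutating
it, and translating both codons with NCBI translation table 11:
`SYN` (same residue), `STOP` (mutant codon is a stop), otherwise
`NONSYN`. Any insertion or deletion is a single `INDEL` class regardless
of frame; frameshift status (length mod 3) is kept as metadata only.
Variants overlapping two CDS annotations are reported once per gene.

Positions outside every CDS are `NONCODING`. An intergenic mutation is
assigned to the gene whose translation start lies downstream *on that
gene's strand* within the **upstream window** (default 500 bp, nearest
start wins). The default window covers typical promoter-proximal hits
(tens to a few hundred bp) while leaving gene-desert mutations
unassigned; it is exposed as configuration.

## Pan-genome partition, longitudinal profile, hotspots

Partition classes are determined purely by the number of isolates
carrying a variant: all → **core**, 2..M−1 → **shared**, 1 → **unique**,
0 → **discarded** (population-only lineages that lost the competition
before plating). The four classes are disjoint and exhaustive by
construction; this is property-tested on randomized cohorts.

The longitudinal profile counts mutations present per population sample
in stage order; deltas start from the wild type (zero mutations).
Summary statistics use the population standard deviation. Because two
samples can carry equal counts while holding different mutations, the
profile also reports symmetric-difference sizes between consecutive
sample mutation sets.

A **hotspot** is a maximal group of ≥ 2 mutations located within one
gene, one operon, or one pathway, with at least one member gene carrying
a core mutation (a gene is a core gene if *any* of its mutations is
core). Grouping precedence keeps the report non-redundant: operon groups
absorb the single-gene clusters they contain; pathway groups merge only
genes not already merged by an operon; remaining genes with ≥ 2
mutations of their own form same-gene hotspots. A gene belonging to two
pathways may anchor two hotspots, so pathway hotspots can overlap; the
caller is verified against an independent exhaustive enumeration on all
random instances with ≤ 20 genes.

Mapping for hotspot purposes uses the CDS locus tag, or the
upstream-assigned gene for non-coding mutations; unmapped mutations are
skipped.

## Function-change scoring

For a profile (PSSM) covering protein positions `[start, end]`, a
substitution at position *p* scores
`Δ = pssm[p − start + 1, alt] − pssm[p − start + 1, ref]`; the verdict is
`potential_gain` (Δ > 0), `potential_loss` (Δ < 0) or `neutral`.
Only the sign and the ordering of Δ are guaranteed: absolute magnitudes
depend on the scaling of whatever toolkit produced the profile and are
not comparable across sources. Mapping protein position → profile column
assumes ungapped correspondence with an explicit `protein_start`;
alignment-based mapping is out of scope. Stop codons are not scored
(they are handled as STOP effects upstream).

`build_profile_from_msa` provides self-contained profiles:
match columns are those with ≤ 50% gaps, and residue scores are
pseudocounted log-odds against a uniform background,
`log2(((count + c) / (N + 20c)) / (1/20))` with pseudocount c = 1 and N
the non-gap count. Under this construction, substituting the column
consensus with any other residue scores ≤ 0.

Conservation calls classify one alignment column by the fraction of
non-gap residues matching the reference residue: 1.0 → `very_conserved`,
below 0.5 → `non_conserved` (a threshold of our own; this
classification is inherently coarse), otherwise `intermediate`.

## Expression linkage

Normalization is upper-quartile scaling: each sample is divided by the
75th percentile of its nonzero counts and multiplied by the geometric
mean of all factors, then log2(x + 1) (pseudocount chosen because zero
counts exist). Note the geometric-mean rescale is shared by every
column, so scaling one raw sample by c changes all columns by the common
factor c^(1/m): the per-sample scaling step is exactly equivariant, the
global rescale is cosmetic. Gene-length normalization is assumed done
upstream; counts are treated as gene-level.

Differential expression runs a per-gene one-way ANOVA across condition
groups on the normalized values, Benjamini–Hochberg FDR control at 5%
across genes, and per-contrast log2 differences versus the baseline
condition. A gene×contrast call is significant only if it passes *all*
of: BH rejection, |log2 difference| > 1, and −log10 p > 1.714
(p < 0.0193). The 1.714 cut is applied to the raw ANOVA p-value with BH
run separately — the two rules' interaction is not standardized, so both
must hold; under a global null the combined rule fires on well under 7%
of genes (tested over simulated null matrices). With single-replicate
conditions the ANOVA is not well-posed and the code falls back to
contrast-only log2 differences with no p-values.

Candidate-gene selection is the union of four rules (mutated; downstream
of or in an operon with a mutated gene; paralog copy of a mutated gene;
regulatory target of a mutated gene), with the selection reasons kept
per gene. "Downstream" is implemented as the next same-strand gene.
Significant genes are ordered by average-linkage hierarchical clustering
(Euclidean distance) of their log2 contrast profiles; scipy's
deterministic tie-breaking makes the leaf order reproducible.

## Growth kinetics

μ_net is the least-squares slope of ln(OD600) versus time from lag end
to the time of maximum OD. Lag end is the first sampling time from which
OD stays above (1 + ε) × OD(0) through the OD peak, with ε = 0.2 and
OD(0) estimated as the median of the first three readings — the
sustained-crossing and median-baseline guards protect the rule against
single noisy readings and reduce to plain first-crossing on clean
monotone curves. Non-positive (blank-referenced) OD readings are
excluded from log fits; ≥ 3 usable points are required.

Yields are least-squares slopes of product concentration against
substrate utilized over the exponential window (window endpoints are
configuration; the whole aligned series is used by default).

ANCOVA compares two (x, y) series by pooled regression with a 0/1
treatment indicator z. The default `main_effect` form `y ~ x + z` tests
the treatment *offset* — this is the conventional reporting form for
these fermentation comparisons even though slope questions are often the
scientific target — and the `interaction` form `y ~ x + z + x·z`, which
tests the slope difference directly, is available and flagged in the
result's `model_form`. Significance is p < 0.05 on the tested term.

## Synthetic-data generator

The generator's defaults *are* the study conditions the pipeline was
designed around: 224 raw variants in a 14-sample cohort (1 wild type,
6 populations, 7 isolates) = 73 high-confidence mutations (22 core,
4 shared, 23 unique, 24 discarded) + 20 wild-type-shared artifacts +
131 flagged calls (120 fp, 6 ise, 5 sv); per-sample mutation-count gains
(8, 4, 0, 4, 5, 9) — mean 5, population SD 2.9, maximum 9, with one
zero-gain pair whose mutation sets nonetheless differ; 8 of 73 mutations
non-coding; 4 isolate mutations detected sub-threshold (< 2%) in the
final population; unique mutations distributed (2, 4, 4, 2, 4, 5, 2)
across isolates and shared memberships {three mutations in isolates
1+4, one in isolates 1–6}, which puts the mean isolate burden at
exactly 27.

The lineage model is a single dominant lineage (core mutations arise per
epoch and fix) with transient side-lineages (discarded mutations carry a
birth–death epoch window and segregate at frequencies drawn uniform on
(0.05, 0.5)); core population frequencies are drawn uniform on
(0.5, 1.0). This is deliberately *not* a Wright–Fisher simulation: it is
the minimal structure that realizes all four partition classes, the
planted count trajectory and the sub-threshold rule exactly, which is
what the downstream logic consumes. Consequences: no clonal
interference, no frequency autocorrelation between samples, no mutation
rate model — recovery tests demonstrate the pipeline's bookkeeping is
correct, not that it would be robust to caller noise or coverage
artifacts in real data (flags here are planted, not derived from reads).

The synthetic genome is a gene grid (defaults: 300-codon CDS, 250 bp
intergenic gaps, a 4 kb gene desert for unassignable non-coding
variants, a fraction of reverse-strand genes) with planted hotspot
structure: a two-gene operon with core mutations, a twice-mutated core
gene, and a two-gene pathway pairing a core with a discarded mutation.
Coding mutations are constructed by enumerating single-base
substitutions of real codons until the requested effect class is
realized, so the effect annotator is exercised against sequence-level
truth rather than labels.

RNA-seq counts are gamma-Poisson (negative binomial) with lognormal
baseline means (median 200, log-sd 0.6) and dispersion 0.05; DE genes
get ±log2-fold-change shifts (random sign) in every non-baseline
condition. Growth curves are lag / exponential / plateau with the
exponential section snapped to the sampling grid (so noise-free fits
recover μ exactly), a slow post-peak decline (0.05/h) so the OD maximum
marks the end of exponential growth as in real batch fermentations,
Gaussian OD noise, and product/substrate series consistent with planted
yields. Power and recovery checks run at study-plausible sizes: 3
conditions × 3 replicates and 60 genes for DE (power ≥ 90% at log2
FC = 2), 30 curves at OD noise 0.01 for μ (recovery within 5%), 1000
small regressions for ANCOVA calibration — sizes chosen as the smallest
that make the statistical claims stable.

## Numerical choices and degenerate inputs

- Coordinates are 1-based inclusive everywhere; VCF indel records
  (anchor-base convention) are converted to the table convention
  (`-` on the empty side, position at the first affected base).
- Multi-allelic sites are distinct variant ids.
- A variant table's SNP reference alleles are checked against the
  reference sequence; a mismatch is a data-integrity error.
- ANOVA p-values that come back NaN (zero variance everywhere) are set
  to 1; p-values are floored at the smallest positive float before
  −log10.
- Single-gene clusters inside a qualifying operon group are reported at
  operon basis (the widest level used).
- One isolate: `shared` is structurally empty and every isolate variant
  is core. Zero isolates: the partition is refused.
- Cluster dendrograms are emitted as Newick text with merge heights as
  branch lengths.

## Known limitations

- PSSM magnitudes are not comparable to any external toolkit's scores;
  only signs and orderings are meaningful.
- The upstream-assignment rule knows nothing about operon internal
  structure: a mutation upstream of gene 2 of an operon is assigned to
  gene 2, not to the operon's promoter.
- The ANCOVA main-effect default tests offsets, not slopes; use the
  interaction form for slope comparisons.
- The generator plants caller flags; it does not simulate reads, so
  flag-accuracy questions are out of scope.
- Real RNA-seq library composition effects (upper-quartile scaling's
  known weakness under extreme asymmetric DE) are not simulated.
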