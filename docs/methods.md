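# Methods

This note records the models, the numerical choices, and the honest limits
of what the test suite demonstrates.

## Data model

Genotypes are alternate-allele dosages in {0, 1, 2} with an explicit missing
code, over sites keyed by `(chrom, pos)` — marker names are carried but never
used as identity, since panel site lists often lack them. Positions are
1-based as in VCF; internal indices 0-based. Multi-allelic records are
rejected by default (a flag drops them silently); indels and sex-chromosome
special handling are out of scope. The minor allele at a site is whichever
of REF/ALT is rarer in the observed data, so the minor-allele-count filter
(default: remove sites with fewer than 4 minor-allele copies; a count of
exactly 4 survives) does not depend on how the alleles were labelled.
Missing genotypes are preserved through masking and filtering; each
downstream stage declares its own missing-data policy.

## Window phasing (EM)

Within non-overlapping windows of 4 SNPs (tiling each chromosome; a
chromosome's leftover sites form a final shorter window rather than being
dropped, so distances use every locus), haplotype frequencies are estimated
by the standard haplotype-frequency EM. Initialisation is uniform over the
observed-compatible haplotypes, which makes a run deterministic; random
restarts exist but are off by default. Convergence is declared when the
largest frequency change drops below 1e-8 (or 200 iterations); the
log-likelihood is recorded per iteration and asserted non-decreasing in
tests. An individual with missing sites in a window contributes marginally
over all compatible completions instead of being discarded. Phasing pools
all animals jointly: small breeds have too few animals to phase within
breed. Quasi-genotype output defaults to posterior-expected counts
("expected" mode); a "hard" mode emits the most probable diplotype's integer
counts. Whether windows should tile or slide was genuinely open; tiling was
chosen for simplicity and so each window is one well-defined pseudo-marker.

## Distances

Euclidean distances are computed on raw dosages (or on concatenated
quasi-genotype count vectors) with no per-locus standardisation — the
distance is meant to capture both relatedness and allele frequency, and
standardising would remove the latter. An optional centering flag exists for
exploration only. With missing data the squared sum runs over
pairwise-complete loci and is rescaled by `n_total/n_shared` before the
square root, keeping pairs with different missingness comparable; a pair
with no shared loci is an error, not a silent NaN. Flagging uses the sample
(n−1) SD, and the boundary is inclusive (a value exactly at mean + k·SD is
flagged). Minimum distance is the default flagging statistic — an animal's
nearest relative in the reference is what drives its imputability; the mean
mixes in phylogenetic position of the whole breed. One observed wrinkle is
worth recording: the 2-SD rule on skewed distance distributions can flag
nobody at small n, so the threshold is configurable (`k_sd`).

## IBS clustering

The DST similarity uses shared-allele counts per locus (for biallelic
dosages, `shared = 2 − |g_a − g_b|`; for quasi-genotype windows,
`shared = Σ_h min(count_a, count_b)`), making genotype- and haplotype-based
clustering literally the same code on different features. Merging is plain
agglomerative clustering (average linkage by default) on `1 − DST` via
scipy's linkage/fcluster; the significance-based merge restrictions of the
original IBS-grouping software are deliberately not reproduced — the
constraints honoured exactly are the ones that define the design: a fixed
cluster count, reduced from a start value (default 6) until the smallest
cluster reaches the minimum size. Equal-height merges follow scipy's
deterministic merge order, so repeated runs agree. The 150-animal floor of
the full-scale study corresponds to ~13% of its population; the pipeline's
desk-scale default uses 40 of 200 (20%) in the same spirit.

## The imputation engine (a stand-in, and its honest limits)

The engine exists so the design experiments are runnable end to end; it is
**not** a reimplementation of any production imputer, and an adapter point
is kept throughout: any externally imputed genotype matrix can be handed to
evaluation, augmentation and modelling.

*Library construction* phases the reference with EM windows of 12 sites
advancing 6 at a time; overlapping halves are used to orient each new
window's diplotype against the strands already laid down. Orientation
information only travels through heterozygous overlap sites, so animals
whose haplotypes are unique in the sample — founders without relatives —
cannot be oriented and acquire switch errors. Measured on the default
synthetic population, the library's switch rate is ≈ 0.36 per heterozygous
interval, and this, not the matcher, is the accuracy bottleneck: with the
true haplotypes in the library the engine reaches ≈ 0.98 concordance from
the mock-50K panel, with the window-phased library ≈ 0.76. Rare-site
concordance stays high (> 0.93) either way because rare sites are mostly
homozygous. An iterative refinement (re-phasing each animal against the
others' haplotypes) was prototyped and rejected: it bought ~0.03 concordance
for minutes of runtime.

*Matching* restricts candidates to the `top_m` (default 50) haplotypes
individually most compatible with the target, then scores all candidate
pairs by exact-match count at observed loci. If the best pair explains every
observed locus in a region the whole region takes that pair; otherwise the
region halves and matching recurses, down to 4 observed loci — long matches
are preferred and windows shrink only where needed. Ties break to the
lexicographically smallest pair (the library is stored sorted), making
output deterministic. Observed genotypes are preserved verbatim in the
output (the selected phase is re-aligned to them); a region with no observed
loci takes the surrounding region's pair, and a fully unobserved target the
modal haplotype twice, so output is complete. Two-step imputation is two
calls with nested panels.

## Evaluation

Concordance is the per-animal mean of exact-genotype-match indicators; a
heterozygote called where the truth is homozygous scores 0 — no partial
credit. The rare subset uses MAF strictly below the threshold (default
0.05), computed from a designated frequency source; the pipeline uses the
full population's sequence calls, mirroring a frame where the gold standard
defines frequency (whether reference-only or all-animal frequencies were
meant is unknowable, so the source is an argument). Allelic R² follows the
per-animal convention (squared Pearson correlation of imputed on true dosage
across sites); it is undefined for constant vectors and recorded as missing
with a warning, never raised. Validation groups are dealt round-robin within
breed after a seeded shuffle, then breed subgroups are scrambled across
final groups — within-breed sizes differ by at most 1 for every seed.

## Accuracy model

Categoricals are reference-level coded; a term's p-value is a partial F-test
comparing the model with and without the whole term (a categorical leaves as
a block). Backward selection interprets the 0.01 stopping rule
round-over-round: the candidate removal is rejected when the CV R² of the
current model minus that of the reduced model exceeds `drop_tol`, and the
kept model is refit on all animals. CV folds are simple random splits
(within-breed stratification is available); fold fits use a pseudoinverse
solve so a level absent from a training fold degrades instead of failing.
Because "squared correlation" drives selection but plain correlations are
the natural headline, both `cv_r` and `cv_r2` are reported. The
externally-computed-cluster hook (`extra_clusters` in `build_features`)
keeps the full candidate set constructible when a model-based ancestry
clustering is available; none is bundled, since that arm is out of scope.

## Synthetic populations

Balding–Nichols was chosen as the simplest divergence model with a tunable
FST: ancestral frequencies from Beta(0.5, 0.5) (U-shaped, as empirical site
frequency spectra are), breed frequencies from
Beta(p(1−F)/F, (1−p)(1−F)/F). Defaults — 3 breeds × 60 animals + 20
crossbreds, F = 0.15, one chromosome of 20,000 sites, mock panels at 25% and
5% of sequence sites, Poisson(1) crossovers per gamete, two pedigree
generations, 0.1% per-allele miscall rate — are the package's desk-scale
study conditions; the panel fractions keep the low:mid:sequence density
ordering of real 50K/777K/sequence data at sizes a laptop handles. Miscalls
are applied to the truth copies used as "sequence calls" so the
minor-allele-count filter has realistic work to do.

What the generator does *not* emulate: chromosome-scale LD from deep
coalescent history (founder haplotypes are frequency-independent draws, so
LD exists only through pedigree IBD), realistic genetic maps, genotyping
error correlated with MAF, and 27-breed heterogeneity. Consequently, passing
tests demonstrate the *relative* claims — clustering recovers structure,
matched references beat mismatched ones, augmentation does not hurt and
usually helps flagged animals, accuracy is predictable from distances — but
absolute accuracy levels here say nothing about absolute accuracy on real
cattle sequence.

## Problem sizes used by the test suite and acceptance script

The acceptance script and the end-to-end test run the default 200-animal /
20,000-site configuration (about 2 minutes on one CPU); unit and property
tests use populations of 12–60 animals and 400–2,000 sites, and the model
recovery study uses n = 500 animals × 100 replicates. These sizes were
chosen as the smallest at which the tested contrasts are comfortably clear
of sampling noise.

## Known limitations

- The bundled phaser/imputer is a stand-in; its founder switch errors bound
  absolute concordance (see above). Substituting an external imputer's
  output files is the intended path for real studies.
- A single augmentation round is implemented; the fully iterative
  impute-one-add-one cascade is future work.
- The flagging threshold's "2 SD" convention is kept as default even though
  min-distance flagging at 1 SD can be the more useful screen in practice;
  both are a parameter away.
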