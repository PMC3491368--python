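# Methods

## Propionylation/trypsin chemistry

The chemistry model follows the standard two-round derivatization used in
bottom-up histone PTM work: propionic anhydride first reacts with free and
monomethyl lysine ε-amines at the protein level (blocking tryptic cleavage
at K), the protein is digested (cleavage strictly C-terminal to R; the
no-cleavage-before-proline refinement is deliberately omitted because none
of the histone tail peptides of interest has an R-P junction), and a
second round propionylates the newly exposed peptide N-termini. Hence
every tryptic peptide carries an N-terminal propionyl, and each lysine
carries exactly one of: propionyl (was unmodified), me1+propionyl, me2,
me3, or acetyl. The label channel (d0/d5) changes only the propionyl mass
(+56.02621 vs +61.05759 Da; Δ = 5 × (²H − ¹H) = 5.03138 Da).

Residue and modification monoisotopic constants live in one table in
`ptm_chemistry` and are validated in the test suite against an independent
composition-based calculation (pyteomics). Isobaric grouping uses single-
linkage clustering on sorted neutral mass at 10 ppm (Orbitrap-class
precursor accuracy); fragment matching uses 20 ppm. Both are arguments,
not constants, because the instrument tolerances behind any given dataset
vary.

## Superposition deconvolution

Co-eluting isobaric positional isomers produce one chromatographic peak
and mixed MS/MS spectra. We fit the observed fragment intensities o as a
non-negative superposition A·x of the members' theoretical templates
(min ‖A·x − o‖, x ≥ 0 by NNLS), normalize x to proportions, and flag a
member "indeterminate" when none of its site-determining ions (fragment
m/z unique to it within the group) is observed. A full integer-programming
formulation of the same superposition model would add the ability to
impose combinatorial side constraints; NNLS solves the identical least-
squares core, is convex, and is checked in the tests against an exhaustive
simplex grid search at 0.001 resolution.

Templates are uniform over b/y ions. This has one structural consequence:
fragment m/z depend only on the running count of acetyl groups N-terminal
of each cleavage site, so the six diacetyl isomers of H4 K5/K8/K12/K16
span a rank-5 template space — one mixing direction (moving abundance
between {K8ac+K16ac, K5ac+K12ac} and {K8ac+K12ac, K5ac+K16ac}) is
invisible to any fragment-intensity method using shared per-ion response.
The degree-of-acetylation summary and every group total are invariant to
this flat direction; per-isomer claims within the full diacetyl sextet are
not identifiable and are reported as the NNLS solution. The synthetic
truth vectors plant diacetyl abundance on an identifiable three-isomer
support ({K12ac,K16ac}, {K8ac,K16ac}, {K5ac,K8ac}).

Precursor areas are trapezoidal XIC integrals over ±0.5 min around the
apex (apex = maximum of a 3-point moving average, ties to the earliest
scan). When several matching MS/MS scans fall inside the peak window their
proportions are combined weighted by scan total intensity. Zero-
denominator d0/d5 ratios are returned as flagged sentinels (NaN/inf),
never silently dropped.

## Differential statistics

Fold change per modified form is log2(ChIP %/Input %) of replicate means;
a symmetric pseudocount (default 0.01 percentage points) applies only when
a term is zero, and is flagged. Significance is the classical equal-
variance two-tailed Student's t over replicates (Welch and log-space
options exist behind flags); multiple testing is controlled by
Benjamini–Hochberg within each ChIP-vs-input comparison (the family
matching how per-comparison supplementary tables are organized), with the
step-up implemented directly and verified against statsmodels. Whether the
t-test should run on raw or log percentages is not determined by the study
design; raw is the default.

## ChIP-seq signal model

Coordinates are 0-based half-open throughout; SAM records are converted on
read, keeping reads with MAPQ ≥ 20 as the operational definition of
"uniquely aligned". The tag position is the strand-specific 5' end
(leftmost base for +, rightmost for −). Deduplication keeps at most one
tag per (position, strand). Tags are shifted 75 bp toward the fragment
midpoint — half the nucleosomal DNA length — with clamping (not dropping)
at chromosome edges. Window counting, normalization to 5 × 10⁶ reads, and
control subtraction with max(0, ·) clipping follow; the whole chain is
tested for exact equality against a brute-force per-tag scan. Browser
tracks: 200-bp tiles of shifted ChIP tags (depth-normalized) and 20-bp
tiles of RNA read centers (raw counts), zero tiles omitted.

## Island calling

Enriched domains are called on a fixed non-overlapping 200-bp grid,
independent of the 1-Mb/100-kb sliding windows used only for chromosome-
scale display. A window is *eligible* when its tag count is improbable
under the genome-wide Poisson background (upper-tail p ≤ p0 = 0.2);
eligible windows separated by at most 3 ineligible windows (600 bp, the
histone-scale gap used by clustering-based island callers) are merged, and
an island's score is the sum of its eligible windows' −log10 p. The score
threshold is calibrated by Monte-Carlo simulation of background-only
genomes (50 replicates, fixed internal seed, so the threshold is a pure
function of the configuration) to yield a configured expected number of
null islands per genome (E-value, default 100). λ comes from the control
library scaled to sample depth when a control exists, else from the
sample's genome-wide mean. Thresholds are cached keyed on λ rounded to two
significant digits, because the calibrated threshold varies slowly with λ.
Island significance against the control is a fold ((s+1)/(c+1)) plus a
Poisson upper tail of the sample count at the control expectation.

## Gene annotation and stratification

A promoter is the 2-kb interval strictly upstream of the TSS (excluding
the TSS base), strand-aware and clamped at chromosome ends. Islands are
assigned a single category with priority promoter > gene body >
intergenic; a gene is bound when any island overlaps its promoter by ≥1 bp
(half-open semantics, so touching intervals do not overlap). Promoter
ranking uses the Poisson upper-tail p-value of the promoter tag count at
the scaled control expectation plus a pseudocount of 1 (the exact ranking
model behind such lists is a declared choice here), ties broken by fold
then gene id. Pattern groups are keyed by the exact 5-protein bound/
unbound vector, ordered by size descending (ties: more-bound patterns
first), with the all-unbound group forced last. RPKM uses exonic length
when exons are provided, else the TSS–TES span; genes with RPKM ≥ 1 are
"expressed"; the ranked list splits 30/40/30 into high/medium/silent with
floor-rounded class sizes and gene-id tie-breaks. Metagene profiles use
20 × 100-bp windows per flank and a 40-bin length-rescaled body; the
per-window signal is the depth-normalized density difference
max(0, sample − control) per 100 bp; minus-strand genes are flipped;
classes are averaged unweighted. Genes shorter than one body bin are
excluded with a warning.

## Synthetic data: what it emulates and what it does not

`simulate_spectra` plants a known relative-abundance vector: each isobaric
group elutes as one shared Gaussian peak (width 20 s) sampled by MS1 scans
every 2 s, with three MS2 scans straddling the apex mixing member
templates proportionally. Noise is multiplicative log-normal with σ = 0.05
(≈ SNR 20). It does **not** emulate isotope envelopes, chimeric precursor
windows, retention-time drift, or chemistry-dependent fragment response —
so recovery tests demonstrate the correctness of the quantification
algebra under the stated noise model, not robustness to real Orbitrap
artifacts.

`simulate_chip_reads` draws fragment midpoints from an inhomogeneous
Poisson process (background 0.5 tags/kb/strand by default; planted islands
multiply the local rate) and emits strand-split 5' tags ±75 bp from the
midpoints, so the pipeline's shift step exactly re-centers them. It does
not model mappability, GC bias, or PCR duplication beyond what the
per-position dedup rule removes.

`make_study_fixture` builds a 10-Mb, 200-gene, 5-protein miniature of the
study design: three activator-like readers enriched 8-fold over promoters
and bodies of high-expression genes and 3-fold over medium genes; two
repressor-like readers enriched 8-fold on silent gene bodies plus a few
intergenic blocks; expression truth in three well-separated tertiles
(RPKM ≈ 30/3/0.02); RNA-seq counts Poisson at 5 M reads. The fixture's
ChIP background is 2 tags/kb/strand — pooled-replicate depth, chosen a
priori so that 40-bin class-mean profiles over ~60 genes per class
separate at every bin by a comfortable margin (≥3 standard errors) — and
the planted knockdown table gives exactly 75 % of activator-bound genes a
≥2-fold reduction and 8 % a ≥2-fold increase, with quotas applied within
each expression class so that any binding-ranked subset carries the same
fractions.

## Problem sizes and numerical choices

Recovery runs use 20 seeded replicates; null calibration checks use 100
background genomes of 50,000 windows; the deconvolution oracle uses 100
random 2–3-member groups against a 0.001-step simplex grid (solved via the
Gram matrix, so the 3-member grid of ~5 × 10⁵ points is cheap). The whole
simulation scale is a miniature: a 10-Mb single-chromosome genome stands
in for 3 Gb, so absolute island counts and p-values are not comparable to
full-genome runs — only the recovery and calibration properties are.

Known limitations: no paired-end support; no de novo identification (the
candidate proteoform set comes from the catalog); the modification
alphabet is me1/me2/me3/ac/propionyl; monoisotopic masses only; the
diacetyl identifiability gap described above.
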