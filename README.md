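# readerscope

Proteogenomics of histone-code **reader** proteins. The bromodomain
proteins Brd2/Brd3/Brd4 recognize acetyl-lysine and the chromodomain
proteins HP1α/HP1β recognize methyl-lysine on nucleosomal histones;
immunoprecipitating the nucleosomes bound by each reader and analyzing
(a) their histone H3/H4 tails by quantitative mass spectrometry and
(b) their genomic DNA by deep sequencing connects combinatorial histone
PTM states to genomic locations and transcriptional outcomes.
`readerscope` implements both analysis arms as a reusable, tested Python
library with a thin CLI, plus a synthetic-data module that generates
spectra and sequencing tags with known ground truth so every stage has a
parameter-recovery test without any external downloads.

## What it computes

**ChIP-qMS arm.** Histones are propionylated (d0 or d5 channel),
trypsinized (cleavage after R only, since propionylated K is blocked), and
analyzed by LC-MS/MS. For each tail peptide (e.g. H4 4–17,
`GKGGKGLGKGGAKR`, carrying K5/K8/K12/K16):

- `ptm_chemistry` enumerates proteoforms, computes monoisotopic masses and
  b/y fragment ladders, and partitions forms into **isobaric groups**
  (e.g. the six diacetyl positional isomers, identical in mass).
- `ms_quantification` integrates each group's extracted ion chromatogram
  and resolves co-eluting isobaric isomers by the **superposition model**:
  the mixed MS/MS spectrum is fit as min ‖A·x − o‖, x ≥ 0, where the
  columns of A are the members' theoretical fragment templates; mixing
  proportions split the shared precursor area. Relative abundances are
  normalized to 100 % per peptide family, and the H4 **degree of
  acetylation** (un/mono/di/tri/tetra) is summarized.
- `differential_ptm` forms log2(ChIP %/Input %) fold changes over
  replicates with two-tailed unpaired Student's *t*-tests and
  Benjamini–Hochberg FDR control per ChIP comparison.

**ChIP-seq arm.** Aligned single-end tags (SAM or BED6) are reduced to at
most one tag per position per strand, shifted 75 bp toward the nucleosome
midpoint, counted in windows, normalized to 5 million reads, and
control-subtracted with clipping at zero (`chipseq_signal`).
`island_calling` aggregates Poisson-improbable 200-bp windows (allowing
small gaps) into enriched domains whose score threshold is calibrated to a
genome-wide E-value. `genome_annotation` then classifies islands against
gene models (promoter = 2 kb upstream of the TSS > gene body >
intergenic), ranks promoters by Poisson binding p-value, groups genes by
their 5-protein combinatorial binding pattern, stratifies genes into
high/medium/silent RPKM tertiles (30/40/30), computes expression-
stratified metagene profiles, and intersects top-bound promoters with
knockdown expression fold changes.

## Worked example

```python
import readerscope.ms_quantification as mq
import readerscope.synthetic_data as sd

vec = sd._h4_truth_vector("input")        # genomic-chromatin-like truth
pl, truth, groups = sd.simulate_spectra(
    sd.h4_spectra_scenario(vec, seed=1, noise_sigma=0.05))  # SNR ~ 20
table = mq.quantify(pl, groups)            # XIC -> NNLS -> abundances
print(mq.degree_of_acetylation(table).round(2))
```

prints

```
un       50.14
mono     34.77
di       10.06
tri       4.53
tetra     0.50
Name: pct, dtype: float64
```

i.e. the planted degree-of-acetylation vector (50/35/10/4.5/0.5 %) is
recovered within fractions of a percentage point despite 5 % multiplicative
intensity noise and the six co-eluting diacetyl isomers sharing a single
precursor. Feeding such tables for a reader ChIP and an input sample to
`differential_ptm.build_heatmap_matrix` yields the log2 fold-change matrix
with q-values; for instance a tetraacetyl-H4 abundance of 6.8 % in a ChIP
against 0.5 % in whole-genome chromatin is a 13.6-fold enrichment.

The same end-to-end flow for the sequencing arm:

```bash
readerscope simulate --kind chip --seed 1 --out fix/
printf 'chr1\t10000000\n' > fix/chrom.sizes
readerscope islands --chip fix/tags.bed --chrom-sizes fix/chrom.sizes \
    --evalue 1 --out fix/islands.bed
```

calls back the five planted 10-kb, 8-fold enriched domains.

## Layout

```
src/readerscope/
  ptm_chemistry.py      propionylation/trypsin model, proteoforms, fragments
  ms_quantification.py  peak lists, XICs, superposition deconvolution
  differential_ptm.py   fold changes, t-tests, Benjamini-Hochberg
  chipseq_signal.py     tag dedup/shift/window/normalize/subtract, bedGraph
  island_calling.py     Poisson eligible-window aggregation, E-value calibration
  genome_annotation.py  promoters, binding patterns, RPKM classes, metagenes
  synthetic_data.py     ground-truthed spectra/genome/study generators
  cli.py                readerscope quantify|signal|islands|annotate|...
```

See `docs/methods.md` for the underlying models, parameter defaults and
known limitations.
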