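# Methods

## Scope and design

`gvreprog` reimplements the computational analyses of a GV-oocyte
nuclear-transfer study as one tested pipeline with two arms: sequencing
(cross-species nascent-transcriptome classification) and imaging
(chromatin density, nucleus segmentation, HP1α occupancy). Standard steps
ride on established libraries (pyfaidx, Biopython, pandas, scipy,
scikit-image, tifffile); the analyses that define the pipeline — the
unique-k-mer species assigner, the response/resistance classification
rules, Huang thresholding, the iterative restricted Otsu and the
recursive watershed — are implemented here and verified against
independent brute-force oracles in the test suite.

## Sequencing arm

### Hybrid reference and read assignment

The two genomes are concatenated, species A first, species B's
chromosome names prefixed (`chr1` → `xla_chr1`); prefix collisions are
errors. GTF input is 1-based inclusive; all internal intervals are
0-based half-open, converted once at the boundary.

A full spliced aligner is out of scope; species attribution — the
analytic content of the hybrid-reference trick — is done by a canonical
k-mer classifier (default k = 25). A read whose k-mers all occur in
exactly one genome is assigned to that species; any k-mer occurring in
both genomes makes the read ambiguous; reads with no (or incomplete)
k-mer support are unassigned. The four labels are exhaustive, so
`species_A + species_B + ambiguous + unassigned = total` holds per
sample. A species-assigned read receives a gene id only when every k-mer
lies within exactly one common gene's exons, mirroring htseq-count union
semantics (multi-gene overlap → dropped from counting). Counting is
unstranded. A loader for externally produced count tables
(`CountMatrix.from_tsv`) covers real data quantified by conventional
aligners. The distinguishability of transcripts between species is
operationalized as k-mer uniqueness; this is a stated stand-in, not a
reconstruction of any particular published filter.

### Quantification and classification

TPM is the canonical length-normalized composition
(`TPM_g = 1e6·(c_g/L_g)/Σ_j(c_j/L_j)`); every column sums to 10⁶ and an
all-zero sample is an error. All thresholding uses replicate-mean TPM
(arithmetic mean; median available) and a single pseudocount (default 1).

Classes are assigned with precedence activated → enhanced → repressed →
unchanged, which makes them mutually exclusive and exhaustive:

| class | rule (defaults) |
|---|---|
| activated | donor < 1 TPM and NT ≥ 1 TPM |
| enhanced | donor ≥ 1 TPM and (NT+1)/(donor+1) ≥ 2 |
| repressed | (donor+1)/(NT+1) ≥ 2 |
| unchanged | otherwise |

The activation/enhancement boundary (donor "expressed" cut = 1 TPM) and
the fold-change cuts of 2 are config-exposed (`ClassificationConfig`)
because published summaries of such experiments print category
percentages without stating the cuts; the inducibility threshold
(TPM ≥ 1) and the resistance fold change (≥ 4) are the conventional
values in this literature.

Resistance in focal cell type X requires (a) inducibility in at least one
other cell type, (b) NT level ≥ `fc_resist`-fold (default 4) below the
mean over the other cell types' NT means (`mode="pairwise"` compares to
each other cell type separately and is strictly more permissive), and
(c) the gene not being repressed in X — genes the oocyte itself
downregulates would otherwise masquerade as resistant. The focal-cell-type
reading of the exclusion rule is the minimal one.

Correlations are Pearson r on log₂(TPM+1) replicate means; heatmap
ordering uses average-linkage agglomerative clustering on the
(1 − Pearson r) distance. Genes with zero variance have undefined
correlation distance and are appended after the clustered genes in input
order. Top-expressed lists sort by mean TPM descending with ties broken
lexicographically by gene id, making the top-n list deterministic.

## Imaging arm

### Huang threshold

For each candidate level t the image splits into low (≤ t) and high
(> t) classes with means μ₀, μ₁; each gray level's fuzzy membership to
its class is u = 1/(1+|g−μ|/C) with C the occupied gray-level range, and
t minimizes the histogram-weighted Shannon entropy
−u·ln u −(1−u)·ln(1−u). Ties resolve to the lowest level; a constant
image is an error. Foreground is `image > t`.

### Iterative restricted multi-level Otsu

The first threshold is the Otsu split (maximum between-class variance,
ties → lowest) of the full histogram; each subsequent threshold is the
Otsu split of the histogram restricted — inclusively — to values ≥ the
previous threshold. Three chained thresholds yield background / loose /
middle / dense: the background cut is iteration 1, since the stated
restriction rule chains naturally from the first threshold. The
restriction means each threshold needs two occupied levels above the
previous cut, so n thresholds require ≥ n+1 distinct levels; a collapsed
restricted histogram is an error. Note that with equally weighted modes
Otsu splits the *widest* gap first, so a background-free three-spike
histogram is partitioned by two chained thresholds only when the first
inter-mode gap dominates.

### Recursive watershed

Connected components of the binary mask within the size gate
[`min_area`, `max_area`] are emitted at depth 0. An oversized component
is split by marker-based watershed on its Euclidean distance transform,
markers being the h-maxima of the map at the current tolerance; the
starting tolerance defaults to half the component's maximum distance
value (a deliberately conservative first split) and decays by 0.7 per
recursion level down to a floor of 1 px or `max_depth` = 8. Fragments
inside the gate are emitted with their extraction depth; oversized
remnants at the floor are reported as *unresolved*, and sub-`min_area`
fragments are discarded but tallied, so
`emitted + unresolved + discarded = foreground` always holds. There are
no randomized steps; identical input gives identical segments.

The default gate (600–1550 px) is derived from the simulator's nucleus
prior (semi-axes 18–22 px, eccentricity ≤ 0.53 → single-nucleus areas
≈ 865–1520 px): `max_area` sits just above the largest single nucleus so
every touching pair is split, and `min_area` ≈ 0.7 × the smallest
nucleus rejects watershed slivers without discarding real nuclei. At
another magnification both values must be rescaled (they are
config-exposed, with a CLI `--pixel-size` for unit conversion).

### Quantification

Per-cell chromatin area is the count of non-background density-class
pixels inside a segment, times the pixel area. Group comparisons report
means ± SD, fold change of means and an equal-variance two-sample
Student's t-test; two degenerate zero-variance groups return p = 1 when
the means agree (no-difference sentinel) and p = 0 otherwise. HP1α
positivity defaults to an Otsu cut on HP1α intensities within chromatin
pixels (a fixed cutoff is available, since published analyses do not
state which was used); occupancy per density class is positive∩class /
class area, with zero-area classes flagged NaN rather than 0. Analysis
is 2-D per-slice: the quantity of interest is area, and per-slice
processing keeps the watershed and the density histogram well-posed.

## Synthetic data

### Expression generator

Each gene draws a response pattern from configured proportions (defaults
0.16 / 0.10 / 0.14 / 0.60 for activated / enhanced / repressed /
unchanged — the regime where ~26% of genes go up and ~40% change
overall). Donor levels: activated genes are silent (U(0, 0.5) TPM);
enhanced/repressed genes draw a shared base (2^U(1,5), 2^U(3,8)) times a
per-cell-type effect (log₂ sd 0.5); unchanged genes are 30% silent,
otherwise log-normal around `donor_mean_log2` with the same cell-type
effect. Induced genes share one target level across cell types
(activation 2^U(3,8) × calibration; enhancement/repression fold changes
2^U(2,4)), modelling the oocyte driving different donors to one induced
state. Because nascent (BrUTP) capture sequences only post-transfer
transcription, NT levels are the induced targets themselves, with no
carried-over donor RNA.

TPM is compositional, so the expressed-regime levels are calibrated by a
single factor so that each condition column totals ≈ 10⁶ while
sub-threshold draws stay in absolute TPM units; the exact per-condition
renormalization is then recorded in the truth (`*_tpm` columns), and
truth classes are assigned by applying the construction thresholds to
those expected TPM values — exactly what a noise-free analysis converges
to. The generative `*_level` columns preserve construction identities
(a resistant gene's NT level equals its donor level exactly).

Per cell type, a configured fraction of inducible genes (defaults
ESC 0.04 / MEF 0.03 / MYO 0.10, reproducing the adult ≫ embryonic
resistance asymmetry) is forced resistant, drawn disjointly across cell
types; in the focal cell type their NT level stays at the donor level.
Counts are negative-binomial around TPM-implied expected counts
(variance μ + φμ², default φ = 0.05, library 2×10⁶, 3 replicates per
condition, each replicate tagged with a recipient-female id whose effect
is zero — oocyte source does not alter outcomes in this design).
`exact_counts=True` emits the expected counts themselves: the zero-noise
limit in which classification recovery is exactly 100%. 48 h samples
re-draw from the 24 h means (reprogramming is complete by 24 h).

What the generator does **not** emulate: batch/female effects, read-level
error or coverage bias, isoform structure, correlated gene programs, or
partial induction. Passing recovery tests therefore shows the estimators
are correct under the stated noise model, not that real data meet it.

### Image generator

Nuclei are ellipses (semi-axes 18–22 px, minor/major ≥ 0.85) placed
fully inside a 512×512 frame; clusters place partners at 1.5× the mean
radius, i.e. below the sum of semi-axes, producing genuinely overlapping
pairs for the watershed. A nucleus mask is the first A pixels in
elliptical-radius order, so areas are exact integers and the paired
"post-NT" set (areas × `dispersal_factor`, HP1α occupancy ×
`hp1_reduction`) changes each nucleus's area by exactly the configured
factor — which is why the noise-free fold-change recovery is exact.
Density classes are radial (dense core 0.2, middle 0.3, loose rim 0.5 of
the area) with DNA intensities 80/140/200 over background 0 and additive
Gaussian noise (sd 4); HP1α positivity is Bernoulli per chromatin pixel
with class probabilities 0.2/0.5/0.8, and the HP1α channel renders
positives at 200 vs 30. Not emulated: PSF blur, autofluorescence,
clearing artifacts, 3-D structure, intensity gradients.

### Fixture genomes

Two independent random 20 kb single-chromosome genomes (a shared segment
can be copied from A into B to create deliberate ambiguity), eight
two-exon genes each, and 500 error-free 50 nt single-end reads sampled
within single exons, names encoding the true species and gene. Both
chromosomes are named `chr1` so the prefixing logic is always exercised.
All outputs are byte-deterministic under a fixed seed.

## Pipeline

A flat YAML config drives stages `expression`, `hybrid`, `imaging`; the
run manifest records versions, seeds, the full config and a SHA-256
checksum of every output file, and reruns under identical config+seed
are byte-identical (verified in tests, including TIFF outputs). The
imaging stage analyzes the clustered single-timepoint set for
segmentation/density/occupancy and a cluster-free 0 h/24 h pair — both
groups with identical, gate-widened watershed parameters — for the
area-change comparison, since a gate tuned to single nuclei would
otherwise misreport dispersed (2×-area) nuclei.

## Problem sizes and numerical choices

Tests and the acceptance script use 5000 genes × 3 cell types ×
27 samples for expression recovery (seeds spanning ten replicates),
512×512 images with 20 nuclei including three touching pairs for
segmentation, and ≥100 random 8-bit histograms for the brute-force
oracle comparisons — sizes chosen so the whole suite runs in about a
minute on one core while keeping binomial/NB sampling error well below
the tested tolerances. Thresholding ties always resolve to the lowest
candidate; all RNG flows through `numpy.random.default_rng(seed)`.

## Known limitations

* The k-mer assigner has no mismatch tolerance: a single SNP or splice
  junction unassigns a real read; it is a species/gene attribution
  surrogate, not an aligner.
* Response classes are threshold rules on replicate means, not a
  dispersion-modelling DE test; near-threshold genes flip under noise,
  which is the dominant term in the ~1% classification error at default
  dispersion.
* Resistance sensitivity is bounded below 1 for enhanced genes whose
  donor level approaches the induced target within the ×4 criterion.
* The watershed size gate assumes a narrow nucleus-size distribution;
  strongly varying nucleus sizes would require per-image gating.
* 2-D area is a proxy; volumetric dispersion is not measured.
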