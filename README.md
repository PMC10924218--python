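# gvreprog

Desk-scale analysis toolkit for nuclear-transfer (NT) reprogramming
experiments in which somatic cell nuclei (mouse ESC, MEF, MYO, or human
lines) are transplanted into the germinal vesicle (GV) of *Xenopus*
meiotic oocytes. It covers both measurement arms of such a study:

* **sequencing arm** — nascent (BrUTP-labelled) transcripts are sequenced
  against a *hybrid* two-species reference (mouse + *Xenopus*, the second
  species' chromosomes renamed `xla_chr…`); reads are attributed to a
  species and gene, quantified as TPM, and each gene is classified by its
  response to the oocyte (activation / enhancement / repression /
  unchanged); *reprogramming-resistant* genes — induced in other donor
  cell types but not in the focal one — are identified per cell type;
* **imaging arm** — two-channel confocal images (DNA stain + HP1α
  immunofluorescence) are binarized with Huang's fuzzy threshold,
  touching nuclei are separated by a recursive distance-map watershed,
  chromatin is partitioned into loose / middle / dense density classes by
  an iterative restricted-histogram multi-level Otsu, and HP1α occupancy
  and chromatin-area changes are quantified per class and per cell.

Because raw reads and confocal stacks from such experiments are rarely
shareable, the package ships first-class synthetic-data generators with
exact recorded ground truth, so every stage is testable end to end.

## Core definitions

With `c_g` the read count of gene `g`, `L_g` its summed exon length:

```
TPM_g = 1e6 · (c_g / L_g) / Σ_j (c_j / L_j)          (per sample)
```

On replicate-mean TPM (`d` donor, `n` NT, pseudocount `pc = 1`):

* **inducible**: `n ≥ 1` (nascent transcription reaches 1 TPM after NT)
* **activated**: `d < 1` and `n ≥ 1`
* **enhanced**:  `d ≥ 1` and `(n+pc)/(d+pc) ≥ 2`
* **repressed**: `(d+pc)/(n+pc) ≥ 2`
* **resistant in X**: inducible in ≥1 other cell type, NT level ≥4-fold
  lower in X than the mean over the other cell types, and not repressed
  in X (genes the oocyte itself downregulates are excluded)

Imaging: Huang's threshold minimizes the fuzzy entropy
`Σ_g h(g)·H(u_t(g))` with membership `u_t(g) = 1/(1+|g−μ_class|/C)`; the
density thresholds are chained Otsu splits, each computed on the
histogram restricted to values ≥ the previous threshold; watershed
markers are h-maxima of the Euclidean distance transform with a tolerance
that decays across recursion levels to split merged nuclei.

## Worked example

```python
from gvreprog import (ExprSimConfig, simulate_expression, compute_tpm,
                      ClassificationConfig, classify_response, find_resistant,
                      ImgSimConfig, simulate_images, huang_threshold,
                      recursive_watershed, iterative_otsu, hp1a_occupancy,
                      WatershedParams)
from gvreprog.expression import response_summary

cm, truth = simulate_expression(ExprSimConfig(seed=1))   # 5000 genes, 3 cell types
expr = compute_tpm(cm)
cfg = ClassificationConfig()
responses = {ct: classify_response(expr, cfg, ct) for ct in ("ESC", "MEF", "MYO")}
print(response_summary(responses["MEF"]).round(2))
print({ct: len(s) for ct, s in find_resistant(expr, responses, cfg).items()})

images, truths = simulate_images(ImgSimConfig(seed=7))   # 20 nuclei incl. clusters
dna, hp1 = images[0]
seg = recursive_watershed(dna > huang_threshold(dna), WatershedParams())
part = iterative_otsu(dna)
occ = hp1a_occupancy(part.class_map, hp1)
print(f"nuclei: {len(seg.segments)}  thresholds: {part.thresholds}")
print({k: round(v, 3) for k, v in occ.occupancy.items()})
```

prints

```
class
activated    15.44
enhanced      9.24
repressed    13.86
unchanged    61.46
Name: percent, dtype: float64
{'ESC': 48, 'MEF': 36, 'MYO': 123}
nuclei: 20  thresholds: (21, 96, 156)
{1: 0.197, 2: 0.494, 3: 0.802}
```

Reading the output: about 39% of MEF genes change transcription after
transfer (15% switched on from silence, 9% further enhanced, 14%
repressed); the myotube-derived nuclei retain far more resistant genes
(123) than the embryonic ESC (48) and MEF (36) donors; the watershed
recovers all 20 simulated nuclei including the touching pairs; and HP1α
occupancy rises with chromatin density (≈0.2 / 0.5 / 0.8 in the loose /
middle / dense classes), recovering the simulated ground truth.

## Command line

`gvreprog` exposes thin subcommands over the library: `build-ref`,
`assign`, `count` (hybrid-reference arm), `classify` (sequencing arm),
`segment`, `density`, `occupancy`, `compare-areas` (imaging arm),
`simulate`, and `run <config.yaml>` for a full reproducible pipeline run
that writes a manifest with SHA-256 checksums of every output.

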