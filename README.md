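# chemocoex

Chemokine co-expression clustering and chemokine:GAG binding analysis.

Chemokines direct leukocyte recruitment, and multiple ligands that recruit
the same cell type are often produced together — e.g. CXCL9, CXCL10 and
CXCL11, which all signal through CXCR3. `chemocoex` is a toolkit for asking
how chemokine-pathway genes co-vary across large compendia of
differential-expression experiments, and for quantifying how differently
those chemokines bind extracellular-matrix glycosaminoglycans (GAGs). It is
aimed at immunologists and computational biologists who want a reproducible,
fully tested version of this analysis that runs end-to-end on simulated data
with known ground truth, and equally on real Expression-Atlas-style tables.

## What it computes

**Co-expression pipeline.** A categorised 136-gene panel (44 chemokine
ligands, 23 receptors, 17 GAG-synthesis genes, 24 matrix metalloproteinases,
28 proteoglycan-synthesis genes; user-replaceable TSV) is assembled from a
corpus of per-assay log2 fold-change measurements into a gene × assay matrix
(tumour-flagged projects excluded, optional species/tissue/disease scope).
Missingness is removed by a sequential four-step filtration — drop genes
present in <70% of assays, then assays containing <90% of surviving genes,
then genes present in <80% of surviving assays, then any assay still
incomplete — yielding a complete matrix on which the package computes:

* the gene–gene Pearson correlation matrix (with complete-linkage
  dendrogram ordering for heatmaps),
* PCA gene coordinates (genes as observations, assay variables centered),
* CLARA k-medoids clusters on Euclidean distance between z-scored gene
  profiles (for standardized rows, d² = 2(n−1)(1−r), so clusters agree with
  the correlation view), with the cluster count k chosen by maximum mean
  silhouette width,
* receptor–ligand relatedness summaries: mean pairwise r among a family's
  ligands versus mean r between ligands and their receptor.

**Synthetic atlas generator.** A seeded simulator produces
Expression-Atlas-like corpora with planted co-expression blocks (per assay,
genes in block *b* get `effect_sd·(√ρ·z_b + √(1−ρ)·ε)`, so within-block
correlation is exactly ρ), bimodal platform-style gene missingness, and
tumour-flagged projects — giving every pipeline stage a ground truth.

**Binding analytics.** Steady-state affinity estimation for equilibrium
bio-layer interferometry: blank-sensor subtraction, one-site Langmuir
isotherm `Req = Rmax·C/(KD+C)` fitted by nonlinear least squares for the
dissociation constant KD (nM) and maximal response Rmax, with standard
errors and a low-saturation warning; plus the relative-to-wild-type MFI
normalisation and percent-of-control inhibition used for cell-surface
binding readouts.

## Worked example

```python
import chemocoex as cc

panel = cc.default_panel()                                  # 136 genes, 5 categories
lr = cc.subset(panel, {"chemokine_ligand", "chemokine_receptor"})

corpus = cc.generate_corpus(cc.default_corpus_config(panel, seed=1))
matrix = cc.assemble_matrix(corpus, lr)                     # 67 genes x 308 assays
filtered, stats = cc.four_step_filter(matrix)
print(cc.retention_summary(stats))

corr = cc.pearson_matrix(filtered)
k, table = cc.select_k(cc.standardize_genes(filtered), range(2, 7), seed=1)
print("selected k =", k)

fam = cc.FamilyDefinition(name="CXCR3", receptors=("CXCR3",),
                          ligands=("CXCL9", "CXCL10", "CXCL11"))
s = cc.family_relatedness(corr, fam)
print(f"ligand-ligand r = {s.mean_ligand_ligand:.3f}, "
      f"ligand-receptor r = {s.mean_ligand_receptor:.3f}")
```

prints

```
gene_presence_70: genes 67->60 (-7), assays 308->308 (-0)
assay_coverage_90: genes 60->60 (-0), assays 308->308 (-0)
gene_presence_80: genes 60->60 (-0), assays 308->308 (-0)
complete_case: genes 60->60 (-0), assays 308->268 (-40)
retained genes 89.6%, assays 87.0%
selected k = 3
ligand-ligand r = 0.718, ligand-receptor r = -0.053
```

Filtration keeps ~90% of genes and ~87% of assays; silhouette-maximising
CLARA recovers the three planted co-expression blocks; and the CXCR3
ligands track each other (r ≈ 0.72) far more tightly than they track their
receptor (r ≈ −0.05) — ligands are produced together at inflamed sites,
while the receptor rides on the recruited cells.

Affinity fitting works the same way:

```python
from chemocoex.binding import twofold_dilutions
curve = cc.simulate_binding_curve(24.0, 1.0, twofold_dilutions(2000, 8),
                                  noise_sd=0.02, seed=42)
fit = cc.fit_kd(curve)
print(f"KD = {fit.kd:.1f} nM (se {fit.kd_se:.1f}), Rmax = {fit.rmax:.3f}")
# KD = 23.2 nM (se 1.4), Rmax = 1.013
```

A `chemocoex` CLI wraps the same stages (`simulate`, `filter`, `correlate`,
`pca`, `cluster`, `relatedness`, `fitkd`, `run`); every command takes
`--seed`, `--out-dir` and `--log-level`, and `run` executes the whole
pipeline from a JSON/YAML config, writing TSV artifacts plus a manifest.

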