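# Methods

## The gene panel

The analysis is restricted to a categorised focus set of 136 genes in five
functional groups: chemokine ligands (44), chemokine receptors (23),
GAG-synthesis enzymes (17), matrix metalloproteinases (24) and
proteoglycan-synthesis genes (28). The shipped default is assembled from
standard human nomenclature — all CXCL/CCL/XCL/CX3CL ligand genes
(including PF4/PF4V1/PPBP), the CXCR/CCR/XCR1/CX3CR1 receptors plus the
atypical receptors ACKR1–4 and CCRL2, the heparan-sulfate biosynthesis
chain (EXT/EXTL, NDST1–4, GLCE, HS2ST1, HS6ST1–3, HS3ST enzymes), the human
MMP family, and the chondroitin/heparan proteoglycan assembly genes and
core proteoglycans — sized to the five category counts above. The panel is
a plain TSV (`symbol  category  mouse_symbol`) and every downstream
computation is panel-agnostic; mouse symbols are static annotations, no
ortholog inference is performed. Symbols are stored as given and matched
case-insensitively (human CXCL9 vs mouse Cxcl9).

## Synthetic corpus model

Each corpus is a set of projects (with species, tissue, disease and a
tumour flag) containing a uniform random number of assays; each assay
reports log2 fold-changes for a subset of panel genes.

**Planted correlation.** Genes are partitioned into disjoint blocks (genes
in no block are background). Per assay, each block *b* draws an independent
latent factor z_b ~ N(0,1) and gene *g* in block *b* takes

    x_g = effect_sd · (√ρ · z_b + √(1−ρ) · ε_g),   ε_g ~ N(0,1),

background genes take `effect_sd · ε_g`. Consequences, used as test
oracles: every within-block pair has population correlation exactly ρ,
cross-block pairs are independent, and every gene's marginal variance is
`effect_sd²`. The latent-factor construction was preferred to sampling from
an explicit covariance because it scales linearly in genes × assays and
makes the planted correlation exact by construction.

**Missingness.** Each gene draws a presence probability p_g once per
corpus; each (gene, assay) cell is then omitted independently with
probability 1−p_g. Real atlas missingness is platform-driven and strongly
bimodal: a gene is either part of essentially every platform's annotation
or absent from a sizeable fraction of experiments. The default therefore
draws p_g from a U-shaped Beta(0.15, 0.015) — in the Bernoulli limit ~9% of
genes land near p=0 (off-platform) and the rest near p=1 — rather than a
unimodal Beta. This choice is load-bearing: under a unimodal presence
distribution (e.g. mean 0.89 with sd 0.08) essentially no assay is ever
complete (P ≈ ∏p_g ≈ 0 over ~60 genes), and the complete-case step of the
filtration below would empty the matrix; the bimodal model instead
reproduces the retention actually observed on atlas-scale data (~90% of
genes, ~85% of assays kept). Focal genes that every real platform reports
(the CXCR3 family in the default configuration) are pinned to p=1 via
`always_present`.

**Default configuration.** 60 projects of 3–8 assays
(~330 assays) over the 67-gene ligand+receptor subpanel; three blocks
mirroring the cluster structure seen in real pooled data: a 3-gene
CXCL9/CXCL10/CXCL11 block, a 10-gene neutrophil-recruitment block
(CXCL1/2/3/5/6/8, PPBP, CXCR1/2, CCL20), and the remaining 54 genes as one
large diverse block; ρ = 0.7; effect_sd = 1; 10% tumour-flagged projects;
seed 1. CXCR3 sits in the large block, away from its ligands, reflecting
the receptor/ligand decoupling the relatedness analysis is designed to
detect. The corpus is deliberately small enough that the whole pipeline
runs in seconds while leaving the planted structure comfortably
recoverable.

**What the generator does not emulate.** Platform/batch effects, p-values
or FDR columns, inter-project heterogeneity in effect size, species
differences beyond a label, and any real biological covariance beyond the
block model. Passing tests therefore demonstrate correctness of the
machinery (filtration, correlation, clustering, selection) under a known
truth — not that three clusters is the right description of any real
tissue.

## Four-step filtration

Applied strictly sequentially, each step on the survivors of the previous:

1. remove genes present in <70% of assays;
2. remove assays containing <90% of surviving genes;
3. remove genes present in <80% of surviving assays;
4. remove every assay that still has a missing value.

"Present" means a non-missing measurement; zero is a value. Removal is
strict-less-than, evaluated on exact rationals: thresholds arrive as floats
and the binary double 0.9 is slightly *above* 9/10, so a naive float
comparison would wrongly discard an assay with exactly 90% coverage;
`Fraction(t).limit_denominator(10⁶)` recovers the intended rational. There
is no iteration to convergence and no imputation. The implementation is
verified against an independent brute-force restatement on thousands of
random presence patterns. Note that the step-wise interaction means raising
the step-1 threshold is not *guaranteed* to shrink the final gene set
(changing step-2 assay survival can rescue a gene at step 3), though it
does on random matrices.

## Correlation, PCA, clustering

Pearson correlation is computed across assays on the complete matrix;
zero-variance genes are dropped with a warning (correlation undefined,
never imputed). PCA treats genes as observations and assays as centered
(not scaled — log2FC shares units) variables; each loading's
largest-magnitude entry is made positive so orientations are deterministic.

Clustering runs on Euclidean distance between per-gene z-scored profiles
(sample-sd convention). For standardized rows d² = 2(n−1)(1−r), so the
cluster geometry is an affine function of the correlation structure shown
in the heatmaps — this is the package's answer to the open choice of
clustering feature space, picked for consistency between the two views.

PAM follows the canonical definition: greedy BUILD (add the medoid
minimising total dissimilarity, k times) then best-improvement SWAP
(repeatedly apply the single medoid/non-medoid exchange with the largest
cost decrease until none improves), all ties broken toward the lowest item
index. PAM is a local search: on a few percent of small random instances
the swap-local optimum it returns is not the global optimum (the reference
R implementation returns the identical solution on such instances). CLARA
runs PAM on `n_samples` seeded random subsamples of `sample_size` genes
(classical defaults 5 and min(n, 40+2k)), assigns every gene to the nearest
medoid, scores by total dissimilarity over all genes, and keeps the best
solution; with `sample_size ≥ n` it reduces exactly to PAM.

The cluster count is chosen by maximising mean silhouette width
(s(i) = (b−a)/max(a,b), singletons scored 0) over a k range, smallest k on
ties. Heatmap display order comes from complete-linkage agglomeration on
distance 1−r.

## Receptor–ligand relatedness

For a family (receptor set + cognate ligand set) the summary extracts all
ligand–ligand and ligand–receptor pairwise r values from the correlation
matrix and reports the two means and their difference. The statistic is
deliberately descriptive — no test is attached — because the scientific
claim it supports is an ordering (which families' receptors track their
ligands), directly checkable against simulated ground truth. Families with
a single ligand are allowed (the shipped set includes CXCR5→CXCL13,
CXCR6→CXCL16, CCR6→CCL20); their ligand–ligand mean is NaN with zero pairs.
The shipped CCR7 family uses CCL19 and CCL21.

## Steady-state affinity estimation

Equilibrium BLI signals are modelled by the one-site Langmuir isotherm
Req(C) = Rmax·C/(KD+C) — the standard steady-state model underlying
instrument-software affinity estimates; no kinetic (kon/koff) or Hill-type
fitting is attempted. Blank-sensor signals attached to a curve are
subtracted first (negatives allowed and logged). The fit is unweighted
nonlinear least squares over all points, replicates stacked rather than
averaged; initialisation KD₀ = concentration nearest half-maximal signal,
Rmax₀ = 1.1·max signal; positivity enforced by bounds; tolerance 1e−10 on
relative parameter change, ≤500 iterations. Standard errors come from the
Gauss–Newton covariance RSS/(n−2)·(JᵀJ)⁻¹. A fit whose top concentration
reaches less than half-saturation (max C < KD) is flagged: in that linear
regime only the ratio Rmax/KD is well determined and the KD standard error
is correspondingly wide. Monotone-decreasing signal profiles are rejected
as not being saturation curves. Concentrations are nM throughout.

Parameter recovery is exercised at the three measured chemokine:GAG
affinities (KD = 24, 253, 520 nM against heparin dp8): noiseless curves
are recovered to 1e−6 relative, and with 2%-of-Rmax Gaussian noise on
eight two-fold dilutions from 2000 nM the median fitted KD over 200
replicates stays within a few percent of truth.

Percent inhibition of a chemokine-alone control is 100·(1 − with/control),
reported raw (enhancement gives negative values) alongside a [0,100]-clipped
convenience field; MFI normalisation divides by the wild-type reference.

## Determinism and numerics

All randomness flows from a single integer seed through named substreams
("generator", "clara", "fits") derived via CRC-keyed `SeedSequence` spawn
keys, so re-seeding one stage never perturbs another; identical seeds give
bit-identical corpora, subsample draws and noise. Numeric TSV output uses
6 significant digits, `.` decimal separator, LF endings.

## Known limitations

* The default panel's gene identities are a nomenclature-based
  reconstruction sized to the published category counts; swap in your own
  TSV for a curated set.
* CLARA/PAM results are local optima; the silhouette criterion can prefer
  merging small tight blocks when ρ is low or blocks are tiny.
* The generator's block model gives every within-block pair the same ρ;
  real co-expression is graded.
* The atlas_wide reader covers the common bulk-download layout
  (`Gene Name` + `<assay>.log2foldchange` columns) and is best-effort for
  other exports.
* No batch correction, imputation, or cross-species pooling: human and
  mouse corpora are analysed separately.
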