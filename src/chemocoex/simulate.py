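"""Synthetic Expression-Atlas-like corpora with planted co-expression structure.

Real inputs to the pipeline are collections of differential-expression
contrasts ("assays") grouped into projects, each reporting log2 fold-changes
for a subset of the gene panel. This module simulates such corpora with a
known ground truth so every downstream stage — filtration, correlation,
clustering, relatedness — is verifiable without any download.

The statistical model is a single-factor-per-block latent construction.
Gene blocks are disjoint groups of panel genes; for each assay and each
block ``b`` an independent latent factor ``z_b ~ N(0,1)`` is drawn, and each
gene ``g`` in block ``b`` takes the value

    effect_sd * (sqrt(rho) * z_b + sqrt(1 - rho) * eps_g),   eps_g ~ N(0,1)

so every within-block gene pair has population Pearson correlation exactly
``rho``, cross-block pairs are independent, and the marginal variance is
``effect_sd**2`` for every gene. Genes in no block ("background") are pure
noise. Missingness is gene-driven: each gene draws a presence probability
``p_g ~ Beta(a, b)`` once per corpus and every (gene, assay) measurement is
independently omitted with probability ``1 - p_g``, mimicking panel genes
that individual platforms do not report. A fraction of projects is flagged
as tumour-derived so the tumour-exclusion step has something to exclude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from chemocoex._util import substream
from chemocoex.panel import GenePanel, subset


class GeneratorError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Shape and statistical parameters of a synthetic corpus.

    Parameters
    ----------
    genes
        Panel gene symbols simulated in the corpus (rows of the eventual matrix).
    n_projects, assays_per_project
        Corpus shape: number of projects and the inclusive (low, high) range
        of assays drawn uniformly per project.
    blocks
        Mapping block-name -> gene symbols; disjoint; genes in no block are
        uncorrelated background.
    rho
        Within-block Pearson correlation, in [0, 1).
    effect_sd
        Marginal standard deviation of every gene's log2 fold-change.
    presence_beta
        (a, b) shape of the per-gene presence-probability Beta draw, or None
        for complete data (every p_g = 1). Atlas-style missingness is
        platform-driven and bimodal — a gene is either annotated on nearly
        every platform or absent from many — so the default is a U-shaped
        Beta with spikes at 0 and 1 rather than a unimodal one.
    tumour_fraction
        Fraction of projects flagged as tumour-derived.
    always_present
        Genes exempt from missingness (presence probability pinned to 1) —
        the universally annotated core genes every platform reports.
    """

    genes: tuple[str, ...]
    n_projects: int = 60
    assays_per_project: tuple[int, int] = (3, 8)
    species: str = "Homo sapiens"
    tissues: tuple[str, ...] = ("blood", "lung", "brain", "spleen", "lymph node")
    tissue_weights: tuple[float, ...] | None = None
    diseases: tuple[str, ...] = (
        "normal",
        "Crohn's disease",
        "ulcerative colitis",
        "psoriasis",
        "rheumatoid arthritis",
        "Alzheimer's disease",
    )
    disease_weights: tuple[float, ...] | None = None
    blocks: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    rho: float = 0.7
    effect_sd: float = 1.0
    presence_beta: tuple[float, float] | None = (0.15, 0.015)
    tumour_fraction: float = 0.1
    always_present: tuple[str, ...] = ()
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.genes:
            raise GeneratorError("config lists no genes to simulate")
        if not 0.0 <= self.rho < 1.0:
            raise GeneratorError(f"rho must lie in [0, 1), got {self.rho}")
        if not 0.0 <= self.tumour_fraction <= 1.0:
            raise GeneratorError(f"tumour_fraction must lie in [0, 1], got {self.tumour_fraction}")
        if self.n_projects < 1:
            raise GeneratorError("n_projects must be positive")
        lo, hi = self.assays_per_project
        if lo < 1 or hi < lo:
            raise GeneratorError(f"bad assays_per_project range {self.assays_per_project}")
        if self.presence_beta is not None:
            a, b = self.presence_beta
            if a <= 0 or b <= 0:
                raise GeneratorError("presence_beta shape parameters must be positive")
        gene_set = {g.upper() for g in self.genes}
        for g in self.always_present:
            if g.upper() not in gene_set:
                raise GeneratorError(f"always_present gene {g!r} not in config genes")
        seen: set[str] = set()
        for name, members in self.blocks.items():
            for g in members:
                key = g.upper()
                if key not in gene_set:
                    raise GeneratorError(f"block {name!r} references gene {g!r} not in config genes")
                if key in seen:
                    raise GeneratorError(f"gene {g!r} appears in more than one block")
                seen.add(key)


@dataclass(frozen=True)
class AssayRecord:
    """One differential-expression contrast with its project metadata."""

    assay_id: str
    project_id: str
    species: str
    tissue: str
    disease: str
    is_tumour: bool
    measurements: dict[str, float]  # gene symbol -> log2FC; absent = missing


@dataclass(frozen=True)
class Corpus:
    """A collection of assay records, optionally carrying generator provenance."""

    assays: tuple[AssayRecord, ...]
    provenance: dict | None = None

    def __post_init__(self) -> None:
        if not self.assays:
            raise GeneratorError("corpus has no assays")
        ids = [a.assay_id for a in self.assays]
        if len(set(ids)) != len(ids):
            raise GeneratorError("duplicate assay ids in corpus")

    def __len__(self) -> int:
        return len(self.assays)


def block_labels(config: GeneratorConfig) -> dict[str, str]:
    """Ground-truth block membership: gene symbol -> block name ('background' if none)."""
    out = {g: "background" for g in config.genes}
    upper_to_symbol = {g.upper(): g for g in config.genes}
    for name, members in config.blocks.items():
        for g in members:
            out[upper_to_symbol[g.upper()]] = name
    return out


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Draw a synthetic corpus. Identical config (incl. seed) gives a bit-identical corpus."""
    rng = substream(config.seed, "generator")
    genes = list(config.genes)
    n_genes = len(genes)

    # project-level metadata
    n_assays_per_project = rng.integers(
        config.assays_per_project[0], config.assays_per_project[1] + 1, size=config.n_projects
    )
    tissues = rng.choice(
        np.asarray(config.tissues, dtype=object),
        size=config.n_projects,
        p=_norm_weights(config.tissue_weights, len(config.tissues)),
    )
    diseases = rng.choice(
        np.asarray(config.diseases, dtype=object),
        size=config.n_projects,
        p=_norm_weights(config.disease_weights, len(config.diseases)),
    )
    n_tumour = int(round(config.tumour_fraction * config.n_projects))
    tumour_projects = set(rng.choice(config.n_projects, size=n_tumour, replace=False).tolist())

    n_assays = int(n_assays_per_project.sum())

    # latent-factor values: one factor per block per assay
    block_names = list(config.blocks.keys())
    membership = block_labels(config)
    values = np.empty((n_genes, n_assays))
    eps = rng.standard_normal((n_genes, n_assays))
    z = rng.standard_normal((len(block_names), n_assays))
    sq_rho, sq_comp = np.sqrt(config.rho), np.sqrt(1.0 - config.rho)
    block_index = {name: i for i, name in enumerate(block_names)}
    for gi, g in enumerate(genes):
        b = membership[g]
        if b == "background":
            values[gi] = config.effect_sd * eps[gi]
        else:
            values[gi] = config.effect_sd * (sq_rho * z[block_index[b]] + sq_comp * eps[gi])

    # gene-driven missingness
    if config.presence_beta is None:
        present = np.ones((n_genes, n_assays), dtype=bool)
    else:
        a, b = config.presence_beta
        p_g = rng.beta(a, b, size=n_genes)
        pinned = {g.upper() for g in config.always_present}
        for gi, g in enumerate(genes):
            if g.upper() in pinned:
                p_g[gi] = 1.0
        present = rng.random((n_genes, n_assays)) < p_g[:, None]

    records: list[AssayRecord] = []
    col = 0
    for pi in range(config.n_projects):
        project_id = f"P{pi + 1:04d}"
        for ai in range(int(n_assays_per_project[pi])):
            mask = present[:, col]
            measurements = {genes[gi]: float(values[gi, col]) for gi in np.flatnonzero(mask)}
            records.append(
                AssayRecord(
                    assay_id=f"{project_id}.a{ai + 1}",
                    project_id=project_id,
                    species=config.species,
                    tissue=str(tissues[pi]),
                    disease=str(diseases[pi]),
                    is_tumour=pi in tumour_projects,
                    measurements=measurements,
                )
            )
            col += 1

    prov = asdict(config)
    prov["blocks"] = {k: list(v) for k, v in config.blocks.items()}
    return Corpus(assays=tuple(records), provenance=prov)


def corpus_summary(corpus: Corpus) -> dict:
    """Counts table: projects, assays, tumour projects, missing rate, tallies.

    The missing rate is relative to the gene universe of the corpus: the union
    of all measured symbols for a generated corpus, or the provenance gene
    list when available.
    """
    projects = {a.project_id for a in corpus.assays}
    tumour_projects = {a.project_id for a in corpus.assays if a.is_tumour}
    if corpus.provenance and "genes" in corpus.provenance:
        universe = list(corpus.provenance["genes"])
    else:
        universe = sorted({g for a in corpus.assays for g in a.measurements})
    total_cells = len(corpus.assays) * len(universe)
    present = sum(len(a.measurements) for a in corpus.assays)
    by_species: dict[str, int] = {}
    by_tissue: dict[str, int] = {}
    for a in corpus.assays:
        by_species[a.species] = by_species.get(a.species, 0) + 1
        by_tissue[a.tissue] = by_tissue.get(a.tissue, 0) + 1
    return {
        "projects": len(projects),
        "assays": len(corpus.assays),
        "tumour_projects": len(tumour_projects),
        "genes": len(universe),
        "missing_rate": 1.0 - present / total_cells if total_cells else 0.0,
        "assays_by_species": by_species,
        "assays_by_tissue": by_tissue,
    }


#: Block structure of the default ("default") corpus over the
#: ligand+receptor subpanel: a small CXCR3-axis ligand block, a
#: neutrophil-recruitment block, and everything else in one large diverse
#: block. CXCR3 itself sits in the large block, transcriptionally apart from
#: its ligands.
DEFAULT_BLOCK_CXCR3_AXIS: tuple[str, ...] = ("CXCL9", "CXCL10", "CXCL11")
DEFAULT_BLOCK_NEUTROPHIL: tuple[str, ...] = (
    "CXCL1",
    "CXCL2",
    "CXCL3",
    "CXCL5",
    "CXCL6",
    "CXCL8",
    "PPBP",
    "CXCR1",
    "CXCR2",
    "CCL20",
)


def default_corpus_config(panel: GenePanel, seed: int = 1) -> GeneratorConfig:
    """The default study conditions: 60 projects of 3-8 assays over the
    ligand+receptor subpanel, three planted blocks at rho=0.7, bimodal gene
    presence ~ Beta(0.15, 0.015) (~9% of genes off-platform, ~9% of cells
    missing overall; the four-step filtration then retains about 90% of
    genes and 85% of assays, matching large-scale atlas behaviour), and 10%
    tumour-flagged projects. The focal CXCR3-family genes are pinned as
    always-present core annotations — every real platform reports them."""
    sub = subset(panel, {"chemokine_ligand", "chemokine_receptor"})
    genes = sub.symbols
    small = set(DEFAULT_BLOCK_CXCR3_AXIS) | set(DEFAULT_BLOCK_NEUTROPHIL)
    core = tuple(g for g in genes if g not in small)
    return GeneratorConfig(
        genes=genes,
        n_projects=60,
        assays_per_project=(3, 8),
        blocks={
            "cxcr3_axis": DEFAULT_BLOCK_CXCR3_AXIS,
            "neutrophil": DEFAULT_BLOCK_NEUTROPHIL,
            "core": core,
        },
        rho=0.7,
        effect_sd=1.0,
        presence_beta=(0.15, 0.015),
        tumour_fraction=0.1,
        always_present=("CXCL9", "CXCL10", "CXCL11", "CXCR3"),
        seed=seed,
    )


def _norm_weights(weights: Sequence[float] | None, n: int) -> np.ndarray | None:
    if weights is None:
        return None
    w = np.asarray(weights, dtype=float)
    if len(w) != n or (w < 0).any() or w.sum() <= 0:
        raise GeneratorError("label weights must be non-negative, matching the pool length")
    return w / w.sum()
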