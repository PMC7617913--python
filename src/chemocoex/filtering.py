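"""Matrix assembly and the sequential four-step missingness filtration.

Differential-expression corpora are sparse in the panel genes: microarray
platforms and species annotations each miss some symbols. The cleaning
strategy trades a small number of genes and assays for a complete matrix,
in four strictly sequential steps, each computed on the survivors of the
previous one:

1. drop genes present in fewer than 70% of assays,
2. drop assays containing fewer than 90% of the surviving genes,
3. drop genes present in fewer than 80% of the surviving assays,
4. drop any assay that still has a missing value.

"Present" means a non-missing measurement (zero is a present value).
Thresholds are compared as exact rationals — a gene present in exactly 70%
of assays is kept — and removal is strict-less-than. The output matrix has
no missing entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from chemocoex.panel import GenePanel
from chemocoex.simulate import Corpus

logger = logging.getLogger(__name__)


class ScopeError(ValueError):
    """Raised when metadata filters select no assays."""


class FiltrationError(ValueError):
    """Raised when filtration eliminates every gene or every assay."""

    def __init__(self, message: str, stats: "RetentionStats | None" = None):
        super().__init__(message)
        self.stats = stats


@dataclass
class ExpressionMatrix:
    """Gene x assay log2 fold-change grid with explicit missingness.

    ``values`` is a pandas DataFrame (rows = panel genes in panel order,
    columns = assay ids, NaN = missing); ``assay_meta`` carries per-assay
    project/species/tissue/disease metadata indexed by assay id.
    """

    values: pd.DataFrame
    assay_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers in matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate assay identifiers in matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def assays(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def subset(self, genes=None, assays=None) -> "ExpressionMatrix":
        v = self.values
        if genes is not None:
            v = v.loc[list(genes)]
        if assays is not None:
            v = v[list(assays)]
        return ExpressionMatrix(values=v, assay_meta=self.assay_meta.loc[v.columns])


@dataclass(frozen=True)
class FilterStep:
    name: str
    genes_before: int
    genes_after: int
    assays_before: int
    assays_after: int


@dataclass(frozen=True)
class RetentionStats:
    """Per-step survivor counts and final retention fractions."""

    steps: tuple[FilterStep, ...]
    gene_retention: float
    assay_retention: float


def assemble_matrix(
    corpus: Corpus,
    panel: GenePanel,
    species: str | None = None,
    tissue: str | None = None,
    disease: str | None = None,
    exclude_tumour: bool = True,
) -> ExpressionMatrix:
    """Concatenate the in-scope assays of a corpus into one gene x assay frame.

    Rows are the panel genes in panel order; columns are the assays passing
    the metadata filters (tumour-flagged projects excluded by default). Gene
    symbols are matched case-insensitively between panel and measurements.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    selected = []
    for a in corpus.assays:
        if exclude_tumour and a.is_tumour:
            continue
        if species is not None and a.species.lower() != species.lower():
            continue
        if tissue is not None and a.tissue.lower() != tissue.lower():
            continue
        if disease is not None and a.disease.lower() != disease.lower():
            continue
        selected.append(a)
    if not selected:
        filters = {
            "species": species,
            "tissue": tissue,
            "disease": disease,
            "exclude_tumour": exclude_tumour,
        }
        active = {k: v for k, v in filters.items() if v is not None}
        raise ScopeError(f"no assays match scope filters {active}")

    panel_by_upper = {e.symbol.upper(): e.symbol for e in panel.entries}
    grid = np.full((len(panel), len(selected)), np.nan)
    gene_pos = {sym: i for i, sym in enumerate(panel.symbols)}
    for j, a in enumerate(selected):
        for g, v in a.measurements.items():
            sym = panel_by_upper.get(g.upper())
            if sym is not None:
                grid[gene_pos[sym], j] = v
    values = pd.DataFrame(grid, index=list(panel.symbols), columns=[a.assay_id for a in selected])
    meta = pd.DataFrame(
        {
            "project_id": [a.project_id for a in selected],
            "species": [a.species for a in selected],
            "tissue": [a.tissue for a in selected],
            "disease": [a.disease for a in selected],
            "is_tumour": [a.is_tumour for a in selected],
        },
        index=values.columns,
    )
    return ExpressionMatrix(values=values, assay_meta=meta)


def _keep_fraction(present: np.ndarray, total: int, threshold: float) -> np.ndarray:
    """Boolean keep-mask: kept when present/total >= threshold, as exact rationals.

    Thresholds arrive as floats (0.70, 0.90, 0.80); the binary float 0.9 is
    slightly above 9/10, so a naive float comparison would wrongly drop an
    assay at exactly 90% coverage. limit_denominator recovers the intended
    rational.
    """
    thr = Fraction(threshold).limit_denominator(10**6)
    return np.array([Fraction(int(p), total) >= thr for p in present])


def four_step_filter(
    matrix: ExpressionMatrix,
    t_gene1: float = 0.70,
    t_assay: float = 0.90,
    t_gene2: float = 0.80,
) -> tuple[ExpressionMatrix, RetentionStats]:
    """Apply the gene(70%) -> assay(90%) -> gene(80%) -> complete-case filtration.

    Returns the complete (zero-missing) matrix and per-step retention stats.
    Raises FiltrationError (carrying the stats) if any step eliminates every
    row or every column.
    """
    for t, label in ((t_gene1, "t_gene1"), (t_assay, "t_assay"), (t_gene2, "t_gene2")):
        if not 0.0 < t <= 1.0:
            raise ValueError(f"{label} must lie in (0, 1], got {t}")
    v = matrix.values
    if v.empty:
        raise ValueError("empty matrix")
    steps: list[FilterStep] = []
    g0, a0 = v.shape

    def record(name: str, before: pd.DataFrame, after: pd.DataFrame) -> None:
        steps.append(
            FilterStep(
                name=name,
                genes_before=before.shape[0],
                genes_after=after.shape[0],
                assays_before=before.shape[1],
                assays_after=after.shape[1],
            )
        )

    def check(after: pd.DataFrame, step: str) -> None:
        if after.shape[0] == 0 or after.shape[1] == 0:
            stats = _stats(steps, g0, a0)
            raise FiltrationError(f"filtration step {step!r} eliminated all rows or columns", stats)

    # step 1: genes present in < t_gene1 of assays
    present = v.notna().to_numpy()
    keep_g = _keep_fraction(present.sum(axis=1), v.shape[1], t_gene1)
    v1 = v.loc[keep_g]
    record("gene_presence_70", v, v1)
    check(v1, "gene_presence_70")

    # step 2: assays containing < t_assay of surviving genes
    keep_a = _keep_fraction(v1.notna().to_numpy().sum(axis=0), v1.shape[0], t_assay)
    v2 = v1.loc[:, keep_a]
    record("assay_coverage_90", v1, v2)
    check(v2, "assay_coverage_90")

    # step 3: genes present in < t_gene2 of surviving assays
    keep_g2 = _keep_fraction(v2.notna().to_numpy().sum(axis=1), v2.shape[1], t_gene2)
    v3 = v2.loc[keep_g2]
    record("gene_presence_80", v2, v3)
    check(v3, "gene_presence_80")

    # step 4: assays with any remaining missing value
    keep_a2 = ~v3.isna().any(axis=0).to_numpy()
    v4 = v3.loc[:, keep_a2]
    record("complete_case", v3, v4)
    check(v4, "complete_case")

    stats = _stats(steps, g0, a0)
    logger.info(
        "four-step filtration: %d->%d genes, %d->%d assays",
        g0,
        v4.shape[0],
        a0,
        v4.shape[1],
    )
    out = ExpressionMatrix(values=v4, assay_meta=matrix.assay_meta.loc[v4.columns])
    assert out.n_missing == 0
    return out, stats


def _stats(steps: list[FilterStep], g0: int, a0: int) -> RetentionStats:
    gf = steps[-1].genes_after if steps else g0
    af = steps[-1].assays_after if steps else a0
    return RetentionStats(
        steps=tuple(steps),
        gene_retention=gf / g0 if g0 else 0.0,
        assay_retention=af / a0 if a0 else 0.0,
    )


def retention_summary(stats: RetentionStats) -> str:
    """Human-readable per-step trace with final percentages."""
    lines = []
    for s in stats.steps:
        lines.append(
            f"{s.name}: genes {s.genes_before}->{s.genes_after} "
            f"(-{s.genes_before - s.genes_after}), "
            f"assays {s.assays_before}->{s.assays_after} "
            f"(-{s.assays_before - s.assays_after})"
        )
    final = f"retained genes {100 * stats.gene_retention:.1f}%, assays {100 * stats.assay_retention:.1f}%"
    if stats.gene_retention == 0.0 or stats.assay_retention == 0.0:
        final += "  [WARNING: empty result]"
    lines.append(final)
    return "\n".join(lines)
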