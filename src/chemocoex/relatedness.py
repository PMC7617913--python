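"""Receptor-ligand transcriptional relatedness summaries.

A chemokine "family" is one or more receptors together with the ligands that
signal through them (e.g. CXCR3 with CXCL9/CXCL10/CXCL11). The relatedness
summary extracts, from a gene-gene correlation matrix, the pairwise Pearson
r among the ligands and between each ligand and each receptor, and reports
the two means and their difference. A positive difference means the ligands
track each other more tightly than they track their receptor — the pattern
expected when ligands are co-produced at inflamed sites while the receptor
is carried by the recruited cells.

The statistic is deliberately descriptive (mean pairwise r, no test); it is
the simplest summary that supports ordering families by ligand-receptor
coupling and is directly checkable against simulated ground truth.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from itertools import combinations, product
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FamilyError(ValueError):
    pass


@dataclass(frozen=True)
class FamilyDefinition:
    """A named receptor set plus the ligand set signalling through it."""

    name: str
    receptors: tuple[str, ...]
    ligands: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.receptors:
            raise FamilyError(f"family {self.name!r} has no receptor")
        if not self.ligands:
            raise FamilyError(f"family {self.name!r} has no ligands")
        rec = {r.upper() for r in self.receptors}
        lig = {l.upper() for l in self.ligands}
        if rec & lig:
            raise FamilyError(f"family {self.name!r}: receptor(s) {sorted(rec & lig)} listed as ligand")
        if len(rec) != len(self.receptors) or len(lig) != len(self.ligands):
            raise FamilyError(f"family {self.name!r}: duplicate symbols")


@dataclass(frozen=True)
class RelatednessSummary:
    """Pairwise r values and their means for one family in one scope."""

    family: str
    ligand_ligand: dict[tuple[str, str], float]
    ligand_receptor: dict[tuple[str, str], float]
    mean_ligand_ligand: float  # NaN when the family has a single ligand
    mean_ligand_receptor: float
    difference: float
    scope: dict


def _resolve(corr: pd.DataFrame, symbols: tuple[str, ...], family: str) -> list[str]:
    by_upper = {str(g).upper(): g for g in corr.index}
    missing = [s for s in symbols if s.upper() not in by_upper]
    if missing:
        raise FamilyError(f"family {family!r}: genes absent from correlation matrix: {missing}")
    return [by_upper[s.upper()] for s in symbols]


def family_relatedness(
    corr: pd.DataFrame, family: FamilyDefinition, scope: dict | None = None
) -> RelatednessSummary:
    """Extract ligand-ligand and ligand-receptor correlations for one family.

    All family genes must be present in the matrix (case-insensitive). The
    ligand-ligand mean is NaN for single-ligand families (no pairs).
    """
    ligands = _resolve(corr, family.ligands, family.name)
    receptors = _resolve(corr, family.receptors, family.name)
    ll = {(a, b): float(corr.loc[a, b]) for a, b in combinations(ligands, 2)}
    lr = {(l, r): float(corr.loc[l, r]) for l, r in product(ligands, receptors)}
    mean_ll = float(np.mean(list(ll.values()))) if ll else float("nan")
    mean_lr = float(np.mean(list(lr.values())))
    return RelatednessSummary(
        family=family.name,
        ligand_ligand=ll,
        ligand_receptor=lr,
        mean_ligand_ligand=mean_ll,
        mean_ligand_receptor=mean_lr,
        difference=mean_ll - mean_lr,
        scope=scope or {},
    )


def compare_families(
    corr: pd.DataFrame, families: list[FamilyDefinition], scope: dict | None = None
) -> list[RelatednessSummary]:
    """Summaries for every family resolvable in the matrix, sorted by difference.

    Families with genes absent from the matrix are skipped with a warning;
    an error is raised only when no family can be evaluated.
    """
    out: list[RelatednessSummary] = []
    for fam in families:
        try:
            out.append(family_relatedness(corr, fam, scope=scope))
        except FamilyError as exc:
            logger.warning("skipping family %s: %s", fam.name, exc)
    if not out:
        raise FamilyError("no family could be evaluated against this correlation matrix")
    return sorted(out, key=lambda s: (np.isnan(s.difference), -s.difference))


def load_families(source: str | Path) -> list[FamilyDefinition]:
    """Read family definitions from TSV `family<TAB>receptor<TAB>ligands` (comma-separated lists)."""
    path = Path(source)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t")[:3] != ["family", "receptor", "ligands"]:
        raise FamilyError(f"bad family file header in {path}")
    fams = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) < 3:
            raise FamilyError(f"{path}:{lineno}: expected 3 tab-separated fields")
        fams.append(
            FamilyDefinition(
                name=fields[0].strip(),
                receptors=tuple(s.strip() for s in fields[1].split(",") if s.strip()),
                ligands=tuple(s.strip() for s in fields[2].split(",") if s.strip()),
            )
        )
    if not fams:
        raise FamilyError(f"family file {path} defines no families")
    return fams


def default_families() -> list[FamilyDefinition]:
    """The shipped family set: CXCR3, CXCR1/2, CXCR5, CXCR6, CCR1, CCR4, CCR6,
    CCR7, CCR8 and CCR10 with their cognate ligands."""
    ref = importlib.resources.files("chemocoex.data").joinpath("default_families.tsv")
    with importlib.resources.as_file(ref) as path:
        return load_families(path)
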