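"""The categorised chemokine-biology gene panel.

The analysis is restricted to a 136-gene focus set covering five functional
groups: chemokine ligands (44), chemokine receptors (23), glycosaminoglycan
(GAG) synthesis enzymes (17), matrix metalloproteinases (24), and
proteoglycan synthesis genes (28). The shipped default panel is assembled
from standard human nomenclature (CXCL/CCL/XCL/CX3CL ligands,
CXCR/CCR/XCR/CX3CR1/atypical ACKR receptors, HS/CS biosynthesis and MMP
genes) and is a plain TSV the user can replace; all downstream code is
panel-agnostic.

Gene symbols are stored as given but matched case-insensitively against
corpus measurements, since human (CXCL9) and mouse (Cxcl9) conventions
differ only by case.
"""

from __future__ import annotations

import importlib.resources
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

#: The five functional categories, in panel display order.
CATEGORIES: tuple[str, ...] = (
    "chemokine_ligand",
    "chemokine_receptor",
    "gag_synthesis",
    "mmp",
    "proteoglycan_synthesis",
)


class PanelError(ValueError):
    """Raised for malformed panel documents or invalid panel operations."""


@dataclass(frozen=True)
class GeneEntry:
    """One panel gene: human symbol, functional category, optional mouse ortholog."""

    symbol: str
    category: str
    mouse_symbol: str | None = None

    def __post_init__(self) -> None:
        if not self.symbol:
            raise PanelError("gene entry has an empty symbol")
        if self.category not in CATEGORIES:
            raise PanelError(
                f"unknown category {self.category!r} for gene {self.symbol!r}; "
                f"expected one of {', '.join(CATEGORIES)}"
            )


@dataclass(frozen=True)
class GenePanel:
    """An ordered collection of unique gene entries."""

    entries: tuple[GeneEntry, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.entries:
            raise PanelError("panel is empty: a panel document must define at least one gene")
        seen: set[str] = set()
        for e in self.entries:
            key = e.symbol.upper()
            if key in seen:
                raise PanelError(f"duplicate gene symbol in panel: {e.symbol!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(e.symbol for e in self.entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in {e.symbol.upper() for e in self.entries}


def load_panel(source: str | Path) -> GenePanel:
    """Read and validate a panel document.

    The document is a UTF-8 TSV with header ``symbol<TAB>category<TAB>mouse_symbol``
    (the third column may be empty or absent per row). Duplicate symbols and
    unknown category labels are rejected with errors naming the offender.
    """
    path = Path(source)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise PanelError(f"empty panel document: {path}")
    header = lines[0].rstrip("\n").split("\t")
    if header[:2] != ["symbol", "category"]:
        raise PanelError(
            f"bad panel header {lines[0]!r}: expected 'symbol\\tcategory[\\tmouse_symbol]'"
        )
    entries: list[GeneEntry] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 2:
            raise PanelError(f"{path}:{lineno}: expected at least 2 tab-separated fields")
        symbol = fields[0].strip()
        category = fields[1].strip()
        mouse = fields[2].strip() if len(fields) > 2 and fields[2].strip() else None
        entries.append(GeneEntry(symbol=symbol, category=category, mouse_symbol=mouse))
    if not entries:
        raise PanelError(f"panel document {path} defines no genes")
    return GenePanel(entries=tuple(entries))


def write_panel(panel: GenePanel, path: str | Path) -> None:
    """Write a panel back to its TSV document form (round-trips with load_panel)."""
    out = ["symbol\tcategory\tmouse_symbol"]
    for e in panel.entries:
        out.append(f"{e.symbol}\t{e.category}\t{e.mouse_symbol or ''}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def default_panel() -> GenePanel:
    """The shipped 136-gene default panel (44/23/17/24/28 per category)."""
    ref = importlib.resources.files("chemocoex.data").joinpath("default_panel.tsv")
    with importlib.resources.as_file(ref) as path:
        return load_panel(path)


def category_counts(panel: GenePanel) -> dict[str, int]:
    """Number of panel genes per category; counts always sum to len(panel)."""
    counts = Counter(e.category for e in panel.entries)
    return {c: counts.get(c, 0) for c in CATEGORIES}


def subset(panel: GenePanel, categories: Iterable[str]) -> GenePanel:
    """Restrict a panel to the given categories (e.g. ligands+receptors)."""
    cats = set(categories)
    if not cats:
        raise PanelError("subset requires a nonempty category set")
    unknown = cats - set(CATEGORIES)
    if unknown:
        raise PanelError(f"unknown categories: {sorted(unknown)}")
    kept = tuple(e for e in panel.entries if e.category in cats)
    if not kept:
        raise PanelError(f"no panel genes in categories {sorted(cats)}")
    return GenePanel(entries=kept)
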