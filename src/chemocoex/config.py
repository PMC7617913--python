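"""Pipeline configuration: paths, scope, thresholds, clustering, seed."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs, loadable from JSON or YAML.

    ``corpus_path`` may be None, in which case the run simulates the default
    synthetic corpus from ``seed``. ``k`` fixes the cluster count; when None,
    ``k_range`` is scanned and the silhouette-maximizing k used.
    """

    out_dir: str = "chemocoex_out"
    panel_path: str | None = None  # None -> shipped default panel
    corpus_path: str | None = None  # None -> simulate
    corpus_dialect: str = "long_tsv"
    corpus_metadata: str | None = None
    families_path: str | None = None  # None -> shipped defaults
    panel_categories: tuple[str, ...] = ("chemokine_ligand", "chemokine_receptor")
    species: str | None = None
    tissue: str | None = None
    disease: str | None = None
    exclude_tumour: bool = True
    t_gene1: float = 0.70
    t_assay: float = 0.90
    t_gene2: float = 0.80
    k: int | None = None
    k_range: tuple[int, int] = (2, 6)
    n_samples: int = 5
    sample_size: int | None = None
    pca_components: int = 2
    seed: int = 1
    log_level: str = "INFO"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("t_gene1", "t_assay", "t_gene2"):
            t = getattr(self, name)
            if not 0.0 < t <= 1.0:
                raise ConfigError(f"{name} must lie in (0, 1], got {t}")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ConfigError(f"seed must be a non-negative integer, got {self.seed}")
        lo, hi = self.k_range
        if lo < 2 or hi < lo:
            raise ConfigError(f"bad k_range {self.k_range}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not define a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in data:
            data["k_range"] = tuple(data["k_range"])
        if "panel_categories" in data:
            data["panel_categories"] = tuple(data["panel_categories"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        d["panel_categories"] = list(self.panel_categories)
        return d
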