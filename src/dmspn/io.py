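"""Readers for the tabular inputs and the run configuration."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .enrichment import DiseaseGeneSet

log = logging.getLogger(__name__)


def read_gad_table(path) -> list[DiseaseGeneSet]:
    """Read a gene-disease association TSV into per-disease gene sets.

    Expected columns: disease_id, disease_class, gene_id (one association
    per row; duplicate rows collapse).  Lines starting with '#' are
    comments.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("disease_id", "disease_class", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = df.drop_duplicates()
    out: list[DiseaseGeneSet] = []
    for (did, cls), grp in df.groupby(["disease_id", "disease_class"], sort=True):
        genes = frozenset(grp["gene_id"])
        log.debug("disease %s: %d genes", did, len(genes))
        out.append(DiseaseGeneSet(disease_id=str(did), disease_class=str(cls), genes=genes))
    return out


def read_gene_list(path) -> frozenset[str]:
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return frozenset(out)


def read_expression_matrix(path) -> pd.DataFrame:
    """Genes x tissues TSV with a header row; first column is the gene ID."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


@dataclass
class RunConfig:
    """One run's inputs, parameters and output directory (YAML-serializable)."""

    kgml_dir: str = ""
    annotations: str = ""
    gad_table: str = ""
    disease_gene_list: str = ""
    essential_gene_list: str = ""
    housekeeping_gene_list: str = ""
    tissue_specific_gene_list: str = ""
    expression_matrix: str = ""
    currency_blacklist: str = ""
    out_dir: str = "dmspn_out"
    k: int = 3
    min_enzymes: int = 1
    alpha: float = 0.01
    null_replicates: int = 200
    seed: int = 0
    projection_min_shared: int = 1
    bd_bh_mode: str = "analytic"
    n_bins: int = 10
    coexpression_method: str = "pearson"
    pathway_classes: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.null_replicates < 1:
            raise ValueError("null_replicates must be >= 1")
        if self.bd_bh_mode not in ("analytic", "permutation"):
            raise ValueError(f"unknown bd_bh_mode {self.bd_bh_mode!r}")
        if self.coexpression_method not in ("pearson", "spearman"):
            raise ValueError(f"unknown coexpression_method {self.coexpression_method!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
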