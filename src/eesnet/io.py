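"""File formats: expression tables, sample sheets, panel exports, run config.

TSV is canonical; CSV is accepted on read (sniffed from the extension).
Gene identity is by string id — column order is never semantic.  All JSON
artifacts carry a ``format_version`` field and readers reject unknown major
versions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from eesnet.influence_network import NetworkConfig
from eesnet.stats_compare import WILDTYPE, ExpressionDataset

FORMAT_VERSION = "1.0"
FLOAT_FMT = "%.10g"


class ReconciliationError(ValueError):
    """Sample sheet and expression table disagree on sample names."""


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return df


def read_expression_table(table_path, sheet_path) -> ExpressionDataset:
    """Load a genes x samples table plus a sample sheet into a dataset.

    The sheet needs columns ``sample``, ``condition`` and optionally
    ``knocked_out_genes`` (semicolon-separated gene ids).
    """
    table = _read_table(table_path)
    if table.index.duplicated().any():
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups[:10]}")
    bad = table.columns[~table.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
    if len(bad):
        raise ValueError(f"non-numeric expression columns: {list(bad)}")

    sep = "," if str(sheet_path).endswith(".csv") else "\t"
    sheet = pd.read_csv(sheet_path, sep=sep, dtype=str).fillna("")
    required = {"sample", "condition"}
    if not required <= set(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")

    table_samples = set(map(str, table.columns))
    sheet_samples = set(sheet["sample"])
    if table_samples != sheet_samples:
        raise ReconciliationError(
            f"samples only in table: {sorted(table_samples - sheet_samples)}; "
            f"only in sheet: {sorted(sheet_samples - table_samples)}"
        )

    gene_ids = list(table.index)
    conditions: dict[str, pd.DataFrame] = {}
    annotation: dict[str, set] = {}
    for cond, grp in sheet.groupby("condition", sort=False):
        conditions[cond] = table[list(grp["sample"])]
        genes: set = set()
        if "knocked_out_genes" in grp.columns:
            for cell in grp["knocked_out_genes"]:
                genes |= {g for g in str(cell).split(";") if g}
        annotation[cond] = genes
    if WILDTYPE not in conditions:
        raise ValueError(f"sample sheet defines no {WILDTYPE!r} condition")
    return ExpressionDataset(
        gene_ids=gene_ids, conditions=conditions, knockout_annotation=annotation
    )


def write_expression_table(data: ExpressionDataset, table_path, sheet_path) -> None:
    """Inverse of :func:`read_expression_table` (round-trip identity)."""
    mats, rows = [], []
    for cond, mat in data.conditions.items():
        renamed = mat.copy()
        renamed.columns = [f"{cond}_r{i+1}" for i in range(mat.shape[1])]
        mats.append(renamed)
        kos = ";".join(sorted(data.knockout_annotation.get(cond, set())))
        rows += [
            {"sample": c, "condition": cond, "knocked_out_genes": kos}
            for c in renamed.columns
        ]
    table = pd.concat(mats, axis=1)
    table.index.name = "gene"
    table.to_csv(table_path, sep="\t", float_format=FLOAT_FMT)
    pd.DataFrame(rows).to_csv(sheet_path, sep="\t", index=False)


def write_panel_tsv(panel, gene_ids, expr_path, viability_path) -> None:
    """Export a knockout panel as a genes x mutants TSV plus a viability
    sidecar TSV (label, viable, residual, iterations)."""
    expr = pd.DataFrame(
        {st.mutant.label or f"mutant{i}": st.x for i, st in enumerate(panel)},
        index=pd.Index(gene_ids, name="gene"),
    )
    expr.to_csv(expr_path, sep="\t", float_format=FLOAT_FMT)
    meta = pd.DataFrame(
        {
            "label": [st.mutant.label for st in panel],
            "clamped_genes": [
                ";".join(str(g) for g in sorted(st.mutant.clamps)) for st in panel
            ],
            "viable": [st.viable for st in panel],
            "residual": [st.residual for st in panel],
            "iterations": [st.iterations for st in panel],
        }
    )
    meta.to_csv(viability_path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_target_vector(path, gene_ids) -> np.ndarray:
    """One-column TSV (gene, value) -> vector aligned to gene_ids."""
    df = _read_table(path)
    missing = [g for g in gene_ids if g not in df.index]
    if missing:
        raise ValueError(f"target vector missing genes: {missing[:10]}")
    return df.iloc[:, 0].reindex(gene_ids).to_numpy(dtype=float)


@dataclass
class RunConfig:
    """YAML-backed run configuration; echoed into every output artifact."""

    seed: int = 0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    internal_genes: list[str] | str = "auto-candidates"
    tolerances: dict = field(
        default_factory=lambda: {
            "fit_condition_cap": 1e8,
            "viability_residual": 1e-8,
            "solver_max_iter": 500,
        }
    )
    output_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name, v in self.tolerances.items():
            if not v > 0:
                raise ValueError(f"tolerance {name!r} must be strictly positive")

    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "seed": self.seed,
            "network": self.network.to_dict(),
            "internal_genes": self.internal_genes,
            "tolerances": self.tolerances,
            "output_dir": str(self.output_dir),
            "log_level": self.log_level,
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.pop("format_version", None)
        if "network" in raw:
            raw["network"] = NetworkConfig.from_dict(raw["network"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def write_json(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
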