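"""Plain-text readers/writers for panels, OTU tables, kernels and configs.

Genotypes are exchanged as PLINK-.raw-style whitespace tables (FID IID PAT
MAT SEX PHENOTYPE then one additive-dosage column per SNP, NA = missing) or
as plain TSV; OTU counts as TSV with a JSON sidecar carrying the stage
label; kernels as TSV with animal-id row/column headers plus a JSON sidecar
of construction metadata; simulation configs as YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import GenotypePanel, OtuCountTable, RelationshipKernel
from .simulate import SimulationConfig

RAW_LEAD_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def write_genotype_raw(
    panel: GenotypePanel, path, design: pd.DataFrame | None = None
) -> None:
    """PLINK-.raw-style whitespace table; sex taken from the design table
    when given (M=1, F=2), otherwise 0."""
    dos = panel.dosages
    out = pd.DataFrame(index=dos.index)
    out["FID"] = (
        design["sire"].reindex(dos.index) if design is not None else "0"
    )
    out["IID"] = dos.index
    out["PAT"] = 0
    out["MAT"] = 0
    if design is not None:
        out["SEX"] = design["sex"].reindex(dos.index).map({"M": 1, "F": 2}).fillna(0)
    else:
        out["SEX"] = 0
    out["PHENOTYPE"] = -9
    body = dos.copy()
    full = pd.concat([out, body], axis=1)
    full.to_csv(path, sep=" ", index=False, na_rep="NA")


def read_genotype_raw(path) -> GenotypePanel:
    df = pd.read_csv(path, sep=r"\s+", na_values="NA")
    dos = df.drop(columns=RAW_LEAD_COLS).set_index(df["IID"].astype(str))
    dos.index.name = "animal"
    return GenotypePanel(dos.astype(float))


def write_genotype_tsv(panel: GenotypePanel, path) -> None:
    panel.dosages.to_csv(path, sep="\t", na_rep="NA")


def read_genotype_tsv(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    df.index = df.index.astype(str)
    return GenotypePanel(df.astype(float))


def _sidecar(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_otu_table(table: OtuCountTable, path) -> None:
    table.counts.to_csv(path, sep="\t")
    _sidecar(path).write_text(json.dumps({"stage": table.stage}))


def read_otu_table(path) -> OtuCountTable:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    return OtuCountTable(counts, stage=meta.get("stage", "Wean"))


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index_label="animal")


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="animal")
    df.index = df.index.astype(str)
    return df


def write_kernel(kernel: RelationshipKernel, path) -> None:
    kernel.to_frame().to_csv(path, sep="\t")
    meta = {"kind": kernel.kind}
    meta.update(
        {k: v for k, v in kernel.meta.items() if isinstance(v, (str, int, float, type(None)))}
    )
    _sidecar(path).write_text(json.dumps(meta))


def read_kernel(path) -> RelationshipKernel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    kind = meta.pop("kind", "G")
    return RelationshipKernel(df.index.to_numpy(), df.to_numpy(), kind=kind, meta=meta)


def save_config(config: SimulationConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["maf_range"] = list(d["maf_range"])
    d["stage_labels"] = list(d["stage_labels"])
    d["var_fractions"] = dict(d["var_fractions"])
    d["fixed_effect_sizes"] = dict(d["fixed_effect_sizes"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    if "maf_range" in d:
        d["maf_range"] = tuple(d["maf_range"])
    if "stage_labels" in d:
        d["stage_labels"] = tuple(d["stage_labels"])
    return SimulationConfig(**d)
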