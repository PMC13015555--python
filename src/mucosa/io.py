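"""Readers and writers for the pipeline's tabular interchange formats."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from gseapy.parser import read_gmt as _gseapy_read_gmt

from .signatures import MarkerGeneSet

__all__ = [
    "read_serology_csv",
    "read_standards_csv",
    "read_plate_csv",
    "read_expression_tsv",
    "read_cell_table",
    "read_gmt",
    "write_gmt",
    "write_thresholds_json",
]

SEROLOGY_COLUMNS = ("subject_id", "group", "isotype", "antigen", "od", "dilution")


def _require(df: pd.DataFrame, columns, what: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")
    return df


def read_serology_csv(path) -> pd.DataFrame:
    return _require(pd.read_csv(path), SEROLOGY_COLUMNS, "serology table")


def read_standards_csv(path) -> pd.DataFrame:
    return _require(pd.read_csv(path), ("concentration", "od"), "standards table")


def read_plate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "adherent" not in df.columns and "od620" not in df.columns:
        raise ValueError("plate table needs an 'adherent' or 'od620' column")
    return _require(df, ("plate_id", "well_id", "condition", "sample_id"),
                    "plate table")


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes x samples matrix; first column is the gene identifier."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_cell_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    return _require(df, ("cell_id", "sample_id", "genotype", "x", "y", "cluster"),
                    "cell table")


def read_gmt(path) -> list[MarkerGeneSet]:
    sets = _gseapy_read_gmt(str(path))
    return [MarkerGeneSet(name, tuple(genes)) for name, genes in sets.items()]


def write_gmt(gene_sets, path) -> None:
    """Write {name: genes} or MarkerGeneSet iterables as GMT."""
    with open(path, "w") as fh:
        if isinstance(gene_sets, dict):
            items = [(name, genes) for name, genes in gene_sets.items()]
        else:
            items = [(gs.subset_name, gs.genes) for gs in gene_sets]
        for name, genes in items:
            fh.write("\t".join([name, name, *genes]) + "\n")


def write_thresholds_json(results: dict, path) -> None:
    """Per-(isotype, antigen) threshold/AUC summary as JSON."""
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
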