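"""Tab-delimited table and GMT readers/writers.

All tables are plain tab-delimited text with one header row. Writers accept
a metadata mapping rendered as ``# key=value`` comment lines above the
header; readers skip such lines. Floats are serialized at 12 significant
digits so that rerunning a pipeline with the same configuration reproduces
byte-identical files.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import pandas as pd

FLOAT_FMT = "%.12g"


def write_table(
    df: pd.DataFrame,
    path: str | os.PathLike,
    metadata: Mapping[str, object] | None = None,
    index: bool = False,
) -> None:
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", float_format=FLOAT_FMT, index=index)


def read_table(path: str | os.PathLike, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_expression(expr: pd.DataFrame, path, metadata=None) -> None:
    """Probe x sample matrix; first column holds probe ids."""
    out = expr.copy()
    out.index.name = "probe_id"
    write_table(out, path, metadata, index=True)


def read_expression(path) -> pd.DataFrame:
    return read_table(path, index_col="probe_id")


def read_annotation(path) -> pd.DataFrame:
    """Two-column probe_id / gene_symbol table; empty symbol = unnamed."""
    annot = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    annot["gene_symbol"] = annot["gene_symbol"].replace("", pd.NA)
    return annot


def write_gene_list(genes: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gmt(path) -> dict[str, dict[str, object]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, dict[str, object]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = {
                "description": fields[1],
                "genes": [g for g in fields[2:] if g],
            }
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
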