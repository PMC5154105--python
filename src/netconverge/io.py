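"""Readers and writers for the plain-text formats the pipeline exchanges.

All tabular formats are TSV; gene sets use the GMT convention
(set name, description, then one gene per column); ranked gene scores use the
two-column RNK convention.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample expression matrix (genes as rows, header = sample IDs)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_partition(path: str | Path) -> dict[str, str]:
    """Read a two-column gene/module TSV into a gene -> module mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("partition file needs two columns: gene, module")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_partition(assignment: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"gene": list(assignment.keys()), "module": list(assignment.values())}
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name, *genes]) + "\n")


def read_rnk(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
    return df.set_index("gene")["score"].astype(float)


def write_rnk(scores: pd.Series, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", header=False)


def read_edges(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column undirected edge list."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    return [tuple(r) for r in df.iloc[:, :2].itertuples(index=False)]


def write_edges(edges: Sequence[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(edges, columns=["gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False, header=False
    )


def write_sif(
    edges: Sequence[tuple[str, str]], path: str | Path, interaction: str = "pp"
) -> None:
    """Write an edge list in SIF format (node, interaction type, node)."""
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{interaction}\t{b}\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
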