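"""Readers and writers for the plain-text formats the pipeline exchanges.

Every stage communicates through TSV / GMT / Newick / JSON files so that
each stage can be run, inspected and tested independently. All writers use
a fixed float format so repeated runs with the same seed are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

FLOAT_FMT = "%.6g"


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix (first column = feature id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_labels(path: str | Path) -> pd.Series:
    """Read a sample -> arm ('case'/'control') sidecar table."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("arm").to_frame().rename_axis("sample").to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name, description, members."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            desc = (descriptions or {}).get(name, "na")
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read an undirected interactome from a 2-column TSV edge list."""
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline()  # skip header row
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                g.add_edge(parts[0], parts[1])
    del header
    return g


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


def read_pair_map(path: str | Path) -> dict[str, list[str]]:
    """Read a 2-column TSV map; repeated keys accumulate (multi-mapping)."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                out.setdefault(parts[0], []).append(parts[1])
    return out


def write_pair_map(pairs: list[tuple[str, str]], path: str | Path,
                   header: tuple[str, str] = ("key", "value")) -> None:
    with open(path, "w") as fh:
        fh.write(f"{header[0]}\t{header[1]}\n")
        for k, v in pairs:
            fh.write(f"{k}\t{v}\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
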