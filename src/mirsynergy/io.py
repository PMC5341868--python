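"""Readers and writers for every on-disk format the pipeline touches.

Tab-separated tables are the canonical tabular dialect throughout
(matching the distribution format of miRTarBase- and TransmiR-style
annotation tables), gene sets use GMT, networks are exported as GraphML
or a sorted edge list, and run configuration is YAML.  Readers validate
strictly and reject malformed input rather than repairing it; every
writer/reader pair round-trips losslessly on valid data.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .simulate import ExpressionMatrix, TISSUE_CLASSES

__all__ = [
    "ParseError",
    "read_expression",
    "write_expression",
    "read_metadata",
    "read_gmt",
    "write_gmt",
    "read_target_map",
    "write_target_map",
    "read_tf_map",
    "write_tf_map",
    "write_network",
    "read_network_graphml",
    "write_yaml_config",
    "read_yaml_config",
]

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; the message carries file coordinates."""


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata table: columns sample_id, tissue_class, pair_id."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "tissue_class", "pair_id"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ParseError(f"{path}: metadata missing columns {missing}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    bad = set(meta["tissue_class"]) - set(TISSUE_CLASSES)
    if bad:
        raise ParseError(f"{path}: unknown tissue classes {sorted(bad)}")
    return meta.set_index("sample_id")


def read_expression(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated miRNA x sample matrix with aligned metadata.

    The first column holds miRNA ids and the header row sample ids, each
    of which must appear in the metadata table.  Duplicated miRNA ids,
    samples without metadata, non-numeric cells (reported with row and
    column coordinates) and header-only files are all rejected.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ParseError(f"{path}: expression matrix has no data rows/columns")
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate miRNA id {dup!r}")
    try:
        # astype goes through the correctly-rounded float parser, so a
        # write/read cycle is bit-exact
        values = raw.astype(float)
    except (TypeError, ValueError):
        coerced = raw.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere((coerced.isna() & ~raw.isna()).to_numpy())
        if len(bad) == 0:
            raise
        i, j = bad[0]
        raise ParseError(
            f"{path}: non-numeric value {raw.iat[i, j]!r} at "
            f"row {raw.index[i]!r}, column {raw.columns[j]!r}"
        ) from None
    meta = read_metadata(metadata_path)
    unknown = [s for s in values.columns if s not in meta.index]
    if unknown:
        raise ParseError(f"{path}: samples missing from metadata: {unknown}")
    meta = meta.loc[list(values.columns)]
    values.index.name = "mirna"
    return ExpressionMatrix(values=values, samples=meta)


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     metadata_path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="mirna")
    expr.samples.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: ``pathway<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a line are collapsed with a logged warning;
    duplicate pathway ids and lines with fewer than three fields are
    rejected.
    """
    db: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        if name in db:
            raise ParseError(f"{path}:{lineno}: duplicate pathway id {name!r}")
        if len(set(genes)) < len(genes):
            log.warning("%s:%d: duplicate genes within %s collapsed", path, lineno, name)
        if not genes:
            raise ParseError(f"{path}:{lineno}: pathway {name!r} has no genes")
        db[name] = set(genes)
    if not db:
        raise ParseError(f"{path}: no gene sets found")
    return db


def write_gmt(pathway_db: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name in sorted(pathway_db):
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *sorted(pathway_db[name])]))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_two_column_map(path: str | Path, key_col: str, val_col: str) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (key_col, val_col):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if df.isna().any().any():
        raise ParseError(f"{path}: empty fields are not allowed")
    out: dict[str, set[str]] = {}
    for key, val in zip(df[key_col], df[val_col]):
        out.setdefault(key, set()).add(val)
    if not out:
        raise ParseError(f"{path}: table is empty")
    return out


def _write_two_column_map(mapping: dict[str, set[str]], path: str | Path,
                          key_col: str, val_col: str) -> None:
    rows = [(k, v) for k in sorted(mapping) for v in sorted(mapping[k])]
    pd.DataFrame(rows, columns=[key_col, val_col]).to_csv(path, sep="\t", index=False)


def read_target_map(path: str | Path) -> dict[str, set[str]]:
    """miRTarBase-style table: columns ``mirna``, ``target_gene``."""
    return _read_two_column_map(path, "mirna", "target_gene")


def write_target_map(target_map: dict[str, set[str]], path: str | Path) -> None:
    _write_two_column_map(target_map, path, "mirna", "target_gene")


def read_tf_map(path: str | Path) -> dict[str, set[str]]:
    """TransmiR-style table: columns ``tf``, ``mirna``."""
    return _read_two_column_map(path, "tf", "mirna")


def write_tf_map(tf_map: dict[str, set[str]], path: str | Path) -> None:
    _write_two_column_map(tf_map, path, "tf", "mirna")


def write_network(network: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Export a synergy network.

    ``graphml`` carries the ``hub_score`` node attribute and ``weight`` /
    ``evidence`` (semicolon-joined) edge attributes.  ``edgelist`` is a
    tab-separated ``mirna_a  mirna_b  weight`` table with
    lexicographically ordered endpoints and sorted rows, for
    reproducible diffs.
    """
    if format == "graphml":
        out = nx.Graph()
        out.graph.update(network.graph)
        for node, data in network.nodes(data=True):
            out.add_node(node, hub_score=float(data.get("hub_score", 0.0)))
        for u, v, data in network.edges(data=True):
            evidence = ";".join(str(e) for e in data.get("evidence", []))
            out.add_edge(u, v, weight=float(data["weight"]), evidence=evidence)
        nx.write_graphml(out, str(path))
    elif format == "edgelist":
        rows = sorted(tuple(sorted((u, v))) + (data["weight"],)
                      for u, v, data in network.edges(data=True))
        lines = [f"{u}\t{v}\t{w!r}" for u, v, w in rows]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_graphml(path: str | Path) -> nx.Graph:
    """Read back a GraphML export, splitting the evidence attribute."""
    g = nx.read_graphml(str(path))
    out = nx.Graph()
    out.graph.update({k: v for k, v in g.graph.items()})
    for node, data in g.nodes(data=True):
        out.add_node(node, hub_score=float(data.get("hub_score", 0.0)))
    for u, v, data in g.edges(data=True):
        evidence = [e for e in str(data.get("evidence", "")).split(";") if e]
        out.add_edge(u, v, weight=float(data["weight"]), evidence=evidence)
    return out


def write_yaml_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_yaml_config(path: str | Path) -> dict:
    loaded = yaml.safe_load(Path(path).read_text())
    if loaded is None:
        return {}
    if not isinstance(loaded, dict):
        raise ParseError(f"{path}: expected a YAML mapping")
    return loaded
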