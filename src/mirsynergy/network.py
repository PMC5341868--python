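"""miRNA-miRNA functional synergy networks and hub scoring.

Three complementary notions of synergy between two miRNAs are built as
weighted undirected graphs: co-regulation of enriched pathways
(the primary network), shared upstream transcription factors, and
within-class expression correlation.  Node importance ("node size") is
operationalised as the weighted degree, exposed as the ``hub_score``
node attribute and ranked by :func:`hub_ranking`.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Mapping, Sequence, Set

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ExpressionMatrix

__all__ = [
    "pathway_synergy_network",
    "target_synergy_network",
    "tf_synergy_network",
    "correlation_network",
    "hub_ranking",
]

log = logging.getLogger(__name__)


def _finalize(g: nx.Graph, kind: str) -> nx.Graph:
    """Attach hub scores (weighted degree) and validate invariants."""
    for u, v, data in g.edges(data=True):
        if u == v:
            raise ValueError(f"self-loop on {u}")
        if data["weight"] <= 0:
            raise ValueError(f"non-positive weight on edge ({u}, {v})")
    for node in g.nodes:
        g.nodes[node]["hub_score"] = float(g.degree(node, weight="weight"))
    g.graph["kind"] = kind
    return g


def _shared_evidence_network(
    sets: Mapping[str, Set[str]], kind: str, nodes: Sequence[str] | None = None
) -> nx.Graph:
    g = nx.Graph()
    names = sorted(sets) if nodes is None else list(nodes)
    g.add_nodes_from(names)
    for i, m1 in enumerate(names):
        for m2 in names[i + 1:]:
            shared = sets.get(m1, set()) & sets.get(m2, set())
            if shared:
                g.add_edge(m1, m2, weight=float(len(shared)),
                           evidence=sorted(shared))
    return _finalize(g, kind)


def pathway_synergy_network(enrichment: pd.DataFrame) -> nx.Graph:
    """Synergy network from co-regulated *enriched* pathways.

    Two miRNAs are joined iff they share at least one enriched pathway;
    the edge weight counts the shared enriched pathways and the edge
    ``evidence`` lists their ids.  miRNAs with no shared pathway remain
    as isolated nodes with hub score 0.
    """
    if enrichment["mirna"].nunique() < 2:
        raise ValueError("need enrichment results for at least 2 miRNAs")
    enriched = enrichment[enrichment["enriched"]]
    sets = {m: set(sub["pathway"]) for m, sub in enriched.groupby("mirna")}
    nodes = sorted(enrichment["mirna"].unique())
    return _shared_evidence_network(sets, "pathway_synergy", nodes=nodes)


def target_synergy_network(target_map: Mapping[str, Set[str]]) -> nx.Graph:
    """Alternative synergy reading: edges weighted by raw shared target genes."""
    if len(target_map) < 2:
        raise ValueError("need target sets for at least 2 miRNAs")
    return _shared_evidence_network(dict(target_map), "target_synergy")


def tf_synergy_network(
    tf_map: Mapping[str, Set[str]], mirnas: Sequence[str]
) -> nx.Graph:
    """Synergy network from shared upstream transcription factors.

    Two listed miRNAs are joined iff at least one TF regulates both;
    weight counts the shared TFs, evidence lists their symbols.
    """
    if not tf_map:
        raise ValueError("tf_map must not be empty")
    listed = set(mirnas)
    regulators: dict[str, set[str]] = {m: set() for m in mirnas}
    for tf, targets in tf_map.items():
        for m in set(targets) & listed:
            regulators[m].add(tf)
    return _shared_evidence_network(regulators, "tf_synergy", nodes=list(mirnas))


def correlation_network(
    expr: ExpressionMatrix,
    tissue_class: str,
    method: str = "pearson",
    min_abs_r: float = 0.7,
) -> nx.Graph:
    """Co-expression network within one tissue class.

    An edge joins two miRNAs when the absolute correlation of their
    expression across the class's samples reaches ``min_abs_r``; the
    weight is ``|r|`` and the signed coefficient is kept as the edge
    ``evidence``.  Zero-variance miRNAs are excluded with a warning.
    ``method`` is ``pearson`` or ``spearman``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if not 0 < min_abs_r <= 1:
        raise ValueError("min_abs_r must lie in (0, 1]")
    cols = expr.class_samples(tissue_class)
    if len(cols) < 3:
        raise ValueError(f"need >= 3 samples in class {tissue_class!r}, got {len(cols)}")
    mat = expr.values[cols].to_numpy(dtype=float)
    variable = mat.std(axis=1) > 0
    if not variable.all():
        dropped = [m for m, ok in zip(expr.mirnas, variable) if not ok]
        log.warning("excluding %d zero-variance miRNAs: %s...", len(dropped), dropped[:5])
    names = [m for m, ok in zip(expr.mirnas, variable) if ok]
    mat = mat[variable]
    if method == "spearman":
        mat = np.apply_along_axis(stats.rankdata, 1, mat)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(mat)

    g = nx.Graph()
    g.add_nodes_from(names)
    hit = np.argwhere(np.triu(np.abs(r) >= min_abs_r, k=1))
    for i, j in hit:
        g.add_edge(names[i], names[j], weight=float(abs(r[i, j])),
                   evidence=[float(r[i, j])])
    return _finalize(g, f"correlation_{method}")


def hub_ranking(network: nx.Graph) -> list[tuple[str, float]]:
    """Nodes by descending hub score (weighted degree), ties lexicographic."""
    scores = [(m, float(network.degree(m, weight="weight"))) for m in network.nodes]
    scores.sort(key=lambda item: (-item[1], item[0]))
    return scores
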