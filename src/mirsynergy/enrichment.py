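"""Per-miRNA target-set pathway enrichment and redundancy grouping.

The statistics follow the ClueGO-style recipe: a right-sided
hypergeometric test of each miRNA's target genes against every pathway
gene set, a Bonferroni step-down (Holm) correction applied within each
miRNA's family of pathway tests, retention of pathways with corrected
p <= 0.05, and grouping of redundant pathways whose gene memberships
agree at a Cohen kappa of at least 0.3.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence, Set
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "hypergeom_right_pvalue",
    "holm_adjust",
    "kappa_score",
    "enrich_mirna_targets",
    "group_terms",
    "TermGroup",
]

log = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["mirna", "pathway", "k", "K", "n", "N", "p_raw", "p_adj", "enriched"]


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(np.asarray(n) - np.asarray(k) + 1)


def hypergeom_right_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Right tail P(X >= k) of a hypergeometric(N, K, n) variable.

    ``N`` genes in the universe, ``K`` of them in the pathway, ``n``
    drawn (the miRNA's targets), ``k`` observed in the overlap.  The tail
    is summed in log space (log-gamma terms with a max-shift), which is
    exact to well over 10 significant digits for any practical sizes.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if not float(v).is_integer() or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if K > N or n > N or k > min(K, n):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    shift = log_terms.max()
    return float(min(1.0, np.exp(shift) * np.exp(log_terms - shift).sum()))


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni step-down (Holm) adjusted p-values, in input order.

    Sort ascending; the i-th smallest raw p is multiplied by (m - i + 1),
    a running maximum enforces monotonicity, and values are capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    m = p.size
    stepped = p[order] * (m - np.arange(m))
    adjusted = np.minimum(1.0, np.maximum.accumulate(stepped))
    out = np.empty(m)
    out[order] = adjusted
    return out


def kappa_score(set_a: Set[str], set_b: Set[str], universe: Set[str]) -> float:
    """Cohen's kappa between two gene sets as binary membership vectors.

    Chance-corrected agreement over the ``universe``:
    ``kappa = (p_o - p_e) / (1 - p_e)`` with observed agreement
    ``p_o = (|A&B| + |~A&~B|) / N`` and ``p_e`` the product of marginals.
    Identical indicators (including two empty sets) score 1 by convention.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    a, b = set(set_a), set(set_b)
    if not a <= set(universe) or not b <= set(universe):
        raise ValueError("sets must be subsets of the universe")
    n = len(universe)
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = n - n11 - n10 - n01
    p_o = (n11 + n00) / n
    p_e = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def enrich_mirna_targets(
    target_map: Mapping[str, Set[str]],
    pathway_db: Mapping[str, Set[str]],
    universe: Set[str] | None = None,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric pathway enrichment of each miRNA's target set.

    Target sets are intersected with the gene universe (default: the
    union of all pathway genes) before testing; the Holm correction is
    applied within each miRNA's family of pathway tests, and rows with
    corrected p <= ``p_threshold`` are flagged enriched.  miRNAs whose
    intersected target set is empty are skipped with a logged warning.

    Returns a data frame with columns ``mirna, pathway, k, K, n, N,
    p_raw, p_adj, enriched``.
    """
    if not pathway_db:
        raise ValueError("pathway_db must not be empty")
    if universe is None:
        universe = set().union(*pathway_db.values())
    universe = set(universe)
    N = len(universe)
    pathways = sorted(pathway_db)
    sizes = {p: len(pathway_db[p] & universe) for p in pathways}

    records: list[dict] = []
    for mirna in sorted(target_map):
        targets = set(target_map[mirna]) & universe
        if not targets:
            log.warning("miRNA %s has no targets in the universe; skipped", mirna)
            continue
        n = len(targets)
        raw = []
        for p in pathways:
            k = len(targets & pathway_db[p])
            raw.append(hypergeom_right_pvalue(k, sizes[p], n, N))
            records.append(
                {"mirna": mirna, "pathway": p, "k": k, "K": sizes[p], "n": n, "N": N,
                 "p_raw": raw[-1]}
            )
        adj = holm_adjust(raw)
        for rec, p_adj in zip(records[-len(pathways):], adj):
            rec["p_adj"] = float(p_adj)
            rec["enriched"] = bool(p_adj <= p_threshold)
    return pd.DataFrame.from_records(records, columns=ENRICHMENT_COLUMNS)


@dataclass(frozen=True)
class TermGroup:
    """A cluster of mutually redundant enriched pathways."""

    members: tuple[str, ...]
    representative: str
    kappas: dict[tuple[str, str], float]


def group_terms(
    enriched: pd.DataFrame,
    pathway_db: Mapping[str, Set[str]],
    universe: Set[str] | None = None,
    kappa_threshold: float = 0.3,
) -> list[TermGroup]:
    """Group one miRNA's enriched pathways by gene-membership agreement.

    Pathway pairs with Cohen kappa >= ``kappa_threshold`` are linked and
    groups are the connected components of the resulting graph
    (single linkage).  Each group's representative is its lowest-``p_adj``
    member, ties broken by lexicographic pathway id.  ``enriched`` must
    hold enrichment rows for a single miRNA with at least one
    ``enriched`` row.
    """
    if enriched.empty or not enriched["enriched"].any():
        raise ValueError("need at least one enriched row to group")
    if enriched["mirna"].nunique() > 1:
        raise ValueError("group_terms expects rows for a single miRNA")
    if universe is None:
        universe = set().union(*pathway_db.values())
    rows = enriched[enriched["enriched"]]
    terms = sorted(rows["pathway"])
    p_adj = dict(zip(rows["pathway"], rows["p_adj"]))

    g = nx.Graph()
    g.add_nodes_from(terms)
    kappas: dict[tuple[str, str], float] = {}
    for i, t1 in enumerate(terms):
        for t2 in terms[i + 1:]:
            kap = kappa_score(pathway_db[t1] & universe, pathway_db[t2] & universe, universe)
            kappas[(t1, t2)] = kap
            if kap >= kappa_threshold:
                g.add_edge(t1, t2)

    groups = []
    for comp in nx.connected_components(g):
        members = tuple(sorted(comp))
        rep = min(members, key=lambda t: (p_adj[t], t))
        pair_kappas = {
            pair: kap for pair, kap in kappas.items()
            if pair[0] in comp and pair[1] in comp
        }
        groups.append(TermGroup(members=members, representative=rep, kappas=pair_kappas))
    groups.sort(key=lambda grp: grp.members)
    return groups
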