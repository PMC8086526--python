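"""Hypergeometric gene-set enrichment with BH-FDR and a Jaccard clustering tree.

Each term in a GMT collection is tested against a query gene list by the
one-sided upper-tail hypergeometric distribution over a user-supplied gene
universe; p-values are corrected with the Benjamini–Hochberg step-up
procedure.  Enriched terms are then clustered by the Jaccard distance
``1 - |A∩B| / |A∪B|`` between their query-restricted member genes
(average linkage), and the tree is serialized as newick.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "term_test",
    "bh_fdr",
    "enrich_collection",
    "jaccard_tree",
]


def read_gmt(path) -> Dict[str, Tuple[str, Set[str]]]:
    """Read a GMT file: one term per line — name, description, member genes."""
    out: Dict[str, Tuple[str, Set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, desc, members = parts[0], parts[1], set(filter(None, parts[2:]))
            if not members:
                continue
            out[name] = (desc, members)
    return out


@dataclass
class TermEnrichment:
    """One gene-set test: overlap k of query n against set K in universe N."""

    term: str
    description: str
    k: int
    K: int
    n: int
    N: int
    p: float
    members: Tuple[str, ...]  # query ∩ term, sorted
    q: float = float("nan")


def term_test(query: Set[str], term: Set[str], universe: Set[str],
              name: str = "", description: str = "") -> TermEnrichment:
    """Upper-tail hypergeometric test of a query against one gene set.

    Query and term members outside the universe are dropped (logged).
    p = P(overlap >= k) when drawing |query| genes from the universe.
    """
    if not universe:
        raise ValueError("empty gene universe")
    q_in = query & universe
    if len(q_in) < len(query):
        log.info("term %s: dropped %d query genes outside universe",
                 name or "?", len(query) - len(q_in))
    t_in = term & universe
    if len(t_in) < len(term):
        log.debug("term %s: dropped %d set members outside universe",
                  name or "?", len(term) - len(t_in))
    k = len(q_in & t_in)
    K, n, N = len(t_in), len(q_in), len(universe)
    p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, N, K, n))
    return TermEnrichment(term=name, description=description, k=k, K=K, n=n, N=N,
                          p=min(p, 1.0), members=tuple(sorted(q_in & t_in)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_collection(
    query: Set[str],
    collection: Mapping[str, Tuple[str, Set[str]]],
    universe: Set[str],
) -> pd.DataFrame:
    """Test every term of a GMT collection; returns a q-annotated table.

    Sorted by (p, term name) for deterministic output.
    """
    results = [term_test(query, members, universe, name=name, description=desc)
               for name, (desc, members) in sorted(collection.items())]
    if not results:
        return pd.DataFrame(columns=["term", "description", "k", "K", "n", "N",
                                     "p", "q", "members"])
    qvals = bh_fdr([r.p for r in results])
    rows = []
    for r, qv in zip(results, qvals):
        r.q = float(qv)
        rows.append({"term": r.term, "description": r.description,
                     "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                     "p": r.p, "q": r.q, "members": ",".join(r.members)})
    df = pd.DataFrame(rows).sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    return df


def jaccard_distance_matrix(member_sets: Mapping[str, Iterable[str]]) -> tuple[list, np.ndarray]:
    """Symmetric Jaccard distance matrix over term member sets (sorted names)."""
    names = sorted(member_sets)
    sets = [set(member_sets[n]) for n in names]
    m = len(names)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            union = len(sets[i] | sets[j])
            inter = len(sets[i] & sets[j])
            d = 1.0 - inter / union if union else 0.0
            D[i, j] = D[j, i] = d
    return names, D


def jaccard_tree(member_sets: Mapping[str, Iterable[str]],
                 method: str = "average") -> str:
    """Average-linkage tree over terms by Jaccard distance, as a newick string.

    Term names are sorted before clustering so ties break deterministically.
    Requires >= 2 terms; returns ``""`` (logged) otherwise.
    """
    if len(member_sets) < 2:
        log.info("fewer than 2 enriched terms; no tree built")
        return ""
    from skbio.tree import TreeNode

    names, D = jaccard_distance_matrix(member_sets)
    Z = linkage(squareform(D, checks=False), method=method)
    tree = TreeNode.from_linkage_matrix(Z, names)
    return str(tree).strip()
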