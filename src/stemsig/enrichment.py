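"""Over-representation tests and the enrichment-map overlap network.

Enrichment of a gene list in a gene set is the one-sided Fisher exact
(hypergeometric upper-tail) probability P(X >= overlap) for the 2x2 table of
list membership x set membership over a stated gene universe. Enriched sets
become network nodes; pairs of sets whose memberships overlap more than
chance (same test, default P < 1e-10) become edges. No multiple-testing
correction is applied on the map-construction path (raw thresholds); a
Benjamini-Hochberg column is emitted for convenience.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import ExpressionMatrix, GeneSetCollection

__all__ = ["fisher_enrichment", "overlap_network", "default_universe", "write_network"]


def _upper_tail_p(overlap: int, universe: int, set_size: int, list_size: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set_size, list_size)."""
    return float(hypergeom.sf(overlap - 1, universe, set_size, list_size))


def default_universe(
    matrix: ExpressionMatrix, collection: GeneSetCollection
) -> list[str]:
    """Measured genes intersected with the union of collection genes."""
    union = set()
    for s in collection:
        union.update(s.genes)
    return [g for g in matrix.gene_ids if g in union]


def fisher_enrichment(
    gene_list: Sequence[str],
    collection: GeneSetCollection,
    universe: Sequence[str],
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """One-sided enrichment of ``gene_list`` in each set of ``collection``.

    Sets are intersected with the universe before testing. Returns rows with
    p < ``p_threshold`` sorted ascending by p; columns: set_name, set_size,
    list_size, overlap, universe_size, p_value, bh_fdr.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    offenders = sorted(set(gene_list) - universe_set)
    if offenders:
        raise ValueError(f"gene(s) in list absent from universe: {offenders[:10]}")
    glist = set(gene_list)
    N, n = len(universe_set), len(glist)
    rows = []
    for s in collection:
        members = set(s.genes) & universe_set
        if not members:
            continue
        k = len(glist & members)
        rows.append(
            {
                "set_name": s.name,
                "set_size": len(members),
                "list_size": n,
                "overlap": k,
                "universe_size": N,
                "p_value": _upper_tail_p(k, N, len(members), n),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["set_name", "set_size", "list_size", "overlap", "universe_size", "p_value"],
    )
    if len(df):
        # BH over all tested sets, attached before threshold filtering
        p = df["p_value"].to_numpy()
        m = len(p)
        order = np.argsort(p, kind="stable")
        stepped = p[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(stepped[::-1])[::-1]
        bh = np.empty(m)
        bh[order] = np.clip(stepped, 0.0, 1.0)
        df["bh_fdr"] = bh
    else:
        df["bh_fdr"] = []
    df = df[df["p_value"] < p_threshold]
    return df.sort_values(["p_value", "set_name"]).reset_index(drop=True)


def overlap_network(
    enriched: pd.DataFrame,
    collection: GeneSetCollection,
    universe: Sequence[str],
    edge_p_threshold: float = 1e-10,
) -> nx.Graph:
    """Build the enrichment map: enriched sets as nodes, significant
    pairwise membership overlap as undirected edges.

    Node attributes: ``set_size``, ``overlap`` (with the query list),
    ``enrichment_p``. Edge attributes: ``overlap``, ``p_value``.
    """
    if enriched is None or len(enriched) == 0:
        raise ValueError("need at least one enriched set")
    universe_set = set(universe)
    N = len(universe_set)
    members = {
        row.set_name: set(collection[row.set_name].genes) & universe_set
        for row in enriched.itertuples()
    }
    G = nx.Graph()
    for row in enriched.itertuples():
        G.add_node(
            row.set_name,
            set_size=int(row.set_size),
            overlap=int(row.overlap),
            enrichment_p=float(row.p_value),
        )
    names = list(members)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            k = len(members[a] & members[b])
            p = _upper_tail_p(k, N, len(members[a]), len(members[b]))
            if p < edge_p_threshold:
                G.add_edge(a, b, overlap=k, p_value=p)
    return G


def write_network(G: nx.Graph, prefix: str | Path) -> None:
    """Export as SIF plus node/edge attribute TSVs (graph-viewer friendly)."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".sif"), "w") as fh:
        connected = set()
        for a, b in G.edges:
            fh.write(f"{a}\tpp\t{b}\n")
            connected.update((a, b))
        for n in G.nodes:
            if n not in connected:
                fh.write(f"{n}\n")
    nodes = pd.DataFrame(
        [{"set_name": n, **G.nodes[n]} for n in G.nodes]
    )
    nodes.to_csv(prefix.parent / (prefix.name + "_nodes.tsv"), sep="\t", index=False)
    edges = pd.DataFrame(
        [{"set_a": a, "set_b": b, **G.edges[a, b]} for a, b in G.edges]
    )
    edges.to_csv(prefix.parent / (prefix.name + "_edges.tsv"), sep="\t", index=False)
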