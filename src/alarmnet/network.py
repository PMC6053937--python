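"""Directed interspecific communication network from response probabilities.

An edge caller -> receiver means the receiver responds to the caller's alarm
calls with probability at or above a cut-off (0.72 in the source analysis).
Node size in the published figure — the count of species whose calls a
species responds to above threshold — is stored as the ``in_degree_callers``
node attribute.  Probabilities can be raw per-pair response proportions or
model-adjusted values; both are accepted as a caller x receiver matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

DEFAULT_THRESHOLD = 0.72

__all__ = ["response_probability_matrix", "build_network", "asymmetry_index",
           "write_graphml", "read_graphml", "write_edge_list"]


def response_probability_matrix(playbacks: pd.DataFrame,
                                include_conspecific: bool = True) -> pd.DataFrame:
    """Empirical per-(caller, receiver) response proportions.

    Control trials are excluded.  Pairs with no trials are NaN — flagged
    missing, never imputed as zero.
    """
    dat = playbacks[playbacks["call_kind"] != "control"]
    if not include_conspecific:
        dat = dat[dat["call_kind"] != "conspecific"]
    if len(dat) == 0:
        raise ValueError("response_probability_matrix: no alarm-playback trials")
    P = dat.pivot_table(index="caller_species", columns="receiver_species",
                        values="responded", aggfunc="mean")
    P.index.name = "caller"
    P.columns.name = "receiver"
    return P


def build_network(P: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD,
                  include_conspecific: bool = False) -> nx.DiGraph:
    """Thresholded directed graph: edge caller -> receiver iff P >= threshold.

    The comparison is inclusive (a pair exactly at the cut-off is kept).
    Self-loops (conspecific edges) are excluded unless requested.  Every
    species appearing as caller or receiver is a node; ``in_degree_callers``
    counts the above-threshold in-edges of each node.
    """
    vals = P.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("build_network: probabilities must lie in [0, 1]")
    if not 0 <= threshold <= 1:
        raise ValueError("build_network: threshold must lie in [0, 1]")
    G = nx.DiGraph(threshold=float(threshold))
    G.add_nodes_from(map(str, P.index))
    G.add_nodes_from(map(str, P.columns))
    for caller in P.index:
        for receiver in P.columns:
            if caller == receiver and not include_conspecific:
                continue
            w = P.loc[caller, receiver]
            if pd.notna(w) and w >= threshold:
                G.add_edge(str(caller), str(receiver), weight=float(w))
    for node in G.nodes:
        G.nodes[node]["in_degree_callers"] = G.in_degree(node)
    return G


def asymmetry_index(P: pd.DataFrame) -> pd.DataFrame:
    """Directionality of each species pair: |P(a->b) - P(b->a)|.

    Returned long-format over unordered pairs present in both directions;
    pairs missing a direction are NaN.
    """
    rows = []
    common = [s for s in P.index if s in P.columns]
    for i, a in enumerate(common):
        for b in common[i + 1:]:
            ab, ba = P.loc[a, b], P.loc[b, a]
            rows.append({
                "species_a": a, "species_b": b,
                "asymmetry": (abs(ab - ba)
                              if pd.notna(ab) and pd.notna(ba) else np.nan),
            })
    return pd.DataFrame(rows)


def write_graphml(G: nx.DiGraph, path) -> None:
    nx.write_graphml(G, path)


def read_graphml(path) -> nx.DiGraph:
    return nx.read_graphml(path)


def write_edge_list(G: nx.DiGraph, path) -> None:
    rows = [{"caller": u, "receiver": v, "weight": d["weight"]}
            for u, v, d in G.edges(data=True)]
    pd.DataFrame(rows, columns=["caller", "receiver", "weight"]).to_csv(
        path, index=False)
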