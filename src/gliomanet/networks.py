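"""From sparse precision supports to reported network artifacts.

Turns the exact zero patterns of the fused-graphical-lasso consensus
matrices into per-class edge lists, presence-pattern categories (shared vs
class-exclusive edges), hub features ranked by within-class degree, and
connected components (subnetworks).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .fgl import PrecisionSet

__all__ = [
    "NetworkSet",
    "HubReport",
    "extract_edges",
    "classify_edges",
    "hub_genes",
    "connected_components",
    "selected_features",
    "EmptyNetworkError",
]


class EmptyNetworkError(ValueError):
    """No edge survives at the chosen penalty; selection is empty."""


@dataclass
class NetworkSet:
    """Per-class edge weights keyed by canonical (i < j) feature-name pairs.

    ``edges[d]`` maps (feature_a, feature_b) -> z value for class d;
    ``pattern_of`` maps each edge in the union to the tuple of class indices
    in which it is present.
    """

    edges: list[dict[tuple[str, str], float]]
    feature_names: list[str]
    class_names: list[str]

    @property
    def D(self) -> int:
        return len(self.edges)

    @property
    def union_edges(self) -> list[tuple[str, str]]:
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            seen.update(e)
        return sorted(seen)

    @property
    def pattern_of(self) -> dict[tuple[str, str], tuple[int, ...]]:
        return {
            pair: tuple(d for d in range(self.D) if pair in self.edges[d])
            for pair in self.union_edges
        }

    def union_nodes(self) -> list[str]:
        """Features incident to >= 1 edge in any class, in input order."""
        incident = {f for pair in self.union_edges for f in pair}
        return [f for f in self.feature_names if f in incident]

    def to_graph(self, scope: int | str = "union") -> nx.Graph:
        g = nx.Graph()
        if scope == "union":
            for (a, b), pat in self.pattern_of.items():
                g.add_edge(a, b, pattern=pat)
        else:
            for (a, b), w in self.edges[int(scope)].items():
                g.add_edge(a, b, weight=w)
        return g

    def to_edge_table(self) -> pd.DataFrame:
        """Edge table: one row per union edge, per-class z columns, pattern."""
        rows = []
        for pair in self.union_edges:
            row: dict = {"feature_a": pair[0], "feature_b": pair[1]}
            pat = []
            for d, name in enumerate(self.class_names):
                w = self.edges[d].get(pair, 0.0)
                row[f"z_{name}"] = w
                if pair in self.edges[d]:
                    pat.append(name)
            row["pattern"] = "+".join(pat)
            rows.append(row)
        cols = ["feature_a", "feature_b",
                *[f"z_{n}" for n in self.class_names], "pattern"]
        return pd.DataFrame(rows, columns=cols)


@dataclass
class HubReport:
    """Top-degree features per class, ties at the cutoff included."""

    hubs: list[list[tuple[str, int]]]
    class_names: list[str]
    k: int
    tie_flags: list[bool]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, lst, tie in zip(self.class_names, self.hubs, self.tie_flags):
            for feat, deg in lst:
                rows.append({"class": name, "feature": feat,
                             "degree": deg, "tied_cutoff": tie})
        return pd.DataFrame(rows, columns=["class", "feature", "degree",
                                           "tied_cutoff"])


def extract_edges(precisions: PrecisionSet, tol: float = 0.0) -> NetworkSet:
    """Edge (i, j) is present in class d iff |z^(d)_ij| > tol (i < j)."""
    names = precisions.feature_names or [
        f"f{j}" for j in range(precisions.p)
    ]
    class_names = precisions.class_names or [
        f"class{d + 1}" for d in range(precisions.D)
    ]
    edges: list[dict[tuple[str, str], float]] = []
    for z in precisions.Z:
        present = np.abs(z) > tol
        if not np.array_equal(present, present.T):
            raise ValueError("asymmetric zero pattern in consensus matrix")
        d_edges: dict[tuple[str, str], float] = {}
        ii, jj = np.where(np.triu(present, k=1))
        for i, j in zip(ii, jj):
            d_edges[(names[i], names[j])] = float(z[i, j])
        edges.append(d_edges)
    return NetworkSet(edges=edges, feature_names=list(names),
                      class_names=list(class_names))


def classify_edges(net: NetworkSet) -> dict[tuple[int, ...], int]:
    """Count union edges by presence pattern (tuple of class indices).

    For D=2 the patterns are shared (0, 1) and the two exclusives; for D=3,
    the 7 non-empty patterns. Counts partition the edge union.
    """
    counts: dict[tuple[int, ...], int] = {}
    for pat in net.pattern_of.values():
        counts[pat] = counts.get(pat, 0) + 1
    return counts


def hub_genes(net: NetworkSet, k: int = 5) -> HubReport:
    """Per class, the k features with the highest degree, plus cutoff ties.

    Features are ranked by within-class degree descending, name ascending.
    Every feature tied with the k-th degree is included and the tie flag set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    hubs = []
    tie_flags = []
    for d_edges in net.edges:
        deg: dict[str, int] = {}
        for a, b in d_edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        ranked = sorted(deg.items(), key=lambda t: (-t[1], t[0]))
        if len(ranked) <= k:
            hubs.append(ranked)
            tie_flags.append(False)
            continue
        cutoff = ranked[k - 1][1]
        kept = [t for t in ranked if t[1] >= cutoff]
        hubs.append(kept)
        tie_flags.append(len(kept) > k)
    return HubReport(hubs=hubs, class_names=list(net.class_names), k=k,
                     tie_flags=tie_flags)


def connected_components(net: NetworkSet, scope: str | int = "union") -> list[set[str]]:
    """Connected components of the chosen graph, largest first.

    ``scope`` is "union" for the all-classes graph or a class index.
    """
    g = net.to_graph(scope)
    comps = [set(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), sorted(c)))


def selected_features(net: NetworkSet) -> list[str]:
    """Union node list in input feature order — the clustering-stage input."""
    nodes = net.union_nodes()
    if not nodes:
        raise EmptyNetworkError(
            "no feature is incident to any edge; decrease lambda1"
        )
    return nodes
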