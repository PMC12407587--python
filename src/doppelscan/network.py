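"""Microbial co-occurrence networks and random-removal ("attack") simulation.

Features whose across-sample correlation exceeds a threshold (0.7 by
default) are connected; the resulting graph is then degraded by removing
nodes uniformly at random, one at a time, while tracking the average
shortest-path length of the largest connected component and the average
clustering coefficient. Near-duplicate samples inflate feature-feature
correlations, so networks built before and after doppelganger removal
degrade differently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import AbundanceTable, SampleLabels, SamplePair, as_relative
from .detection import remove_doppelgangers

__all__ = [
    "CooccurrenceNetwork",
    "AttackTrace",
    "build_network",
    "average_path_length",
    "average_clustering",
    "attack_simulation",
    "compare_conditions",
]

DEFAULT_THRESHOLD = 0.7


@dataclass(frozen=True)
class CooccurrenceNetwork:
    """Undirected feature graph; edge weights are the correlations."""

    graph: nx.Graph
    threshold: float
    method: str
    use_absolute: bool

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "weight": d["weight"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight"])


@dataclass(frozen=True)
class AttackTrace:
    """Across-replicate mean topology after each random node removal.

    Step k (1-based) has ``n_nodes - k`` nodes remaining. Average path length
    is NaN once the largest component has fewer than 2 nodes.
    """

    n_nodes: int
    n_replicates: int
    n_remaining: np.ndarray
    path_length: np.ndarray  # per-step mean over replicates (NaN-aware)
    clustering: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_remaining": self.n_remaining,
                "avg_path_length": self.path_length,
                "avg_clustering": self.clustering,
            }
        )

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_replicates": self.n_replicates,
            "n_remaining": self.n_remaining.tolist(),
            "avg_path_length": self.path_length.tolist(),
            "avg_clustering": self.clustering.tolist(),
        }


def build_network(
    table: AbundanceTable,
    threshold: float = DEFAULT_THRESHOLD,
    method: str = "pearson",
    use_absolute: bool = False,
) -> CooccurrenceNetwork:
    """Connect features whose across-sample correlation exceeds ``threshold``.

    Correlations are computed between feature vectors on relative abundances;
    the edge rule is strict (``> threshold``), on the signed correlation by
    default or on ``|r|`` when ``use_absolute``. Constant features have
    undefined correlation and are excluded with a warning; isolated nodes are
    retained.
    """
    if table.n_features < 3:
        raise ValueError("need at least 3 features")
    rel = as_relative(table)
    X = rel.values.T  # features x samples
    constant = np.flatnonzero(X.std(axis=1) == 0)
    keep = np.setdiff1d(np.arange(X.shape[0]), constant)
    if constant.size:
        names = [rel.feature_ids[i] for i in constant[:10]]
        warnings.warn(
            f"excluding {constant.size} constant features from network: {names}",
            stacklevel=2,
        )
    ids = [rel.feature_ids[i] for i in keep]
    if method == "pearson":
        corr = np.corrcoef(X[keep])
    elif method == "spearman":
        from scipy import stats

        corr = np.corrcoef(stats.rankdata(X[keep], axis=1))
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    g = nx.Graph()
    g.add_nodes_from(ids)
    vals = np.abs(corr) if use_absolute else corr
    ii, jj = np.nonzero(np.triu(vals > threshold, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(ids[i], ids[j], weight=float(corr[i, j]))
    return CooccurrenceNetwork(g, float(threshold), method, use_absolute)


def _graph_of(network) -> nx.Graph:
    return network.graph if isinstance(network, CooccurrenceNetwork) else network


def average_path_length(network) -> float:
    """Mean unweighted shortest-path length over the largest component.

    NaN when the largest connected component has fewer than 2 nodes.
    """
    g = _graph_of(network)
    if g.number_of_nodes() == 0:
        return float("nan")
    # ties on component size broken by smallest node label, for determinism
    giant = max(nx.connected_components(g), key=lambda c: (len(c), min(c)))
    if len(giant) < 2:
        return float("nan")
    return float(nx.average_shortest_path_length(g.subgraph(giant)))


def average_clustering(network) -> float:
    """Mean local clustering coefficient (degree-<2 nodes contribute 0)."""
    g = _graph_of(network)
    if g.number_of_nodes() == 0:
        return float("nan")
    return float(nx.average_clustering(g, count_zeros=True))


def attack_simulation(
    network, n_replicates: int = 100, seed: int = 0
) -> AttackTrace:
    """Random node-removal attack, replicated over removal orders.

    Each replicate removes all nodes in an independent uniformly random
    order, recording topology after every removal; the trace reports
    per-step means across replicates (NaN-aware for path length).
    """
    g0 = _graph_of(network)
    n = g0.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes to attack")
    if n_replicates < 1:
        raise ValueError("n_replicates must be positive")
    rng = np.random.default_rng(seed)
    nodes = sorted(g0.nodes)
    apl = np.empty((n_replicates, n))
    clus = np.empty((n_replicates, n))
    for r in range(n_replicates):
        order = rng.permutation(n)
        g = g0.copy()
        for step, k in enumerate(order):
            g.remove_node(nodes[k])
            apl[r, step] = average_path_length(g)
            clus[r, step] = average_clustering(g) if g.number_of_nodes() else np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN steps
        return AttackTrace(
            n_nodes=n,
            n_replicates=n_replicates,
            n_remaining=np.arange(n - 1, -1, -1),
            path_length=np.nanmean(apl, axis=0),
            clustering=np.nanmean(clus, axis=0),
        )


def compare_conditions(
    table: AbundanceTable,
    labels: SampleLabels,
    pairs: list[SamplePair],
    threshold: float = DEFAULT_THRESHOLD,
    n_replicates: int = 100,
    seed: int = 0,
    policy: str = "greedy_degree",
) -> dict[str, AttackTrace]:
    """Attack traces for raw, doppelganger-removed, and random-removed data.

    The random condition removes the same number of samples per class as the
    doppelganger removal did, chosen uniformly, so the comparison isolates
    *which* samples were removed rather than how many.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 991]).generate_state(1)[0])
    cleaned, removed = remove_doppelgangers(table, pairs, policy=policy)
    # class-stratified random removal matching the doppelganger removal counts
    per_class = {
        cls: sum(1 for s in removed if labels[s] == cls) for cls in labels.classes
    }
    rand_removed: list[str] = []
    for cls, k in per_class.items():
        members = [s for s in table.sample_ids if labels[s] == cls]
        rand_removed.extend(rng.choice(members, size=k, replace=False))
    randomized = table.drop_samples(rand_removed)

    out: dict[str, AttackTrace] = {}
    conditions = (("raw", table), ("doppel_removed", cleaned), ("random_removed", randomized))
    for cond_idx, (name, t) in enumerate(conditions):
        if t.n_samples < 3:
            raise ValueError(f"condition {name!r} leaves fewer than 3 samples")
        net = build_network(t, threshold=threshold)
        if net.n_nodes < 2:
            raise ValueError(f"condition {name!r} yields a network with < 2 nodes")
        sub_seed = int(
            np.random.SeedSequence([seed, cond_idx]).generate_state(1)[0] % (2**31)
        )
        out[name] = attack_simulation(net, n_replicates=n_replicates, seed=sub_seed)
    return out
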