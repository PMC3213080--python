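"""PPI connectivity of hit genes: induced mean degree and permutation test.

Hit proteins that work in shared recovery pathways interact with each other
more than random proteins do.  The statistic is the mean degree of the
subgraph induced by the hit genes present in the network; the null is the
same statistic over uniformly drawn node sets of equal size, and the
empirical p-value uses the add-one (phantom permutation) convention so it
can never be exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConnectivityResult:
    observed_mean_degree: float
    null_mean: float
    null_sd: float
    p_empirical: float
    n_perm: int
    seed: int
    n_hits_in_network: int
    n_hits_missing: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def read_edgelist(path) -> nx.Graph:
    """Undirected network from a two-column TSV; duplicate edges collapse,
    self-loops are dropped with a warning."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated gene columns")
    g = nx.Graph()
    for a, b in df.iloc[:, :2].itertuples(index=False):
        if pd.isna(a) or pd.isna(b):
            raise ValueError(f"{path}: malformed row ({a!r}, {b!r})")
        if a == b:
            logger.warning("dropping self-loop on %s", a)
            g.add_node(a)
            continue
        g.add_edge(a, b)
    return g


def mean_induced_degree(
    network: nx.Graph, genes: Iterable[str], *, mode: str = "induced"
) -> float:
    """Mean number of interaction partners a hit has among the hits.

    ``mode='global'`` instead averages the hits' degrees in the full
    network.  Genes absent from the network are dropped.
    """
    present = [g for g in genes if g in network]
    if not present:
        raise ValueError("no query genes present in the network")
    if mode == "induced":
        sub = network.subgraph(present)
        return sum(d for _, d in sub.degree()) / len(present)
    if mode == "global":
        return sum(network.degree(g) for g in present) / len(present)
    raise ValueError(f"unknown mode {mode!r}")


def degree_permutation_test(
    network: nx.Graph,
    genes: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    *,
    mode: str = "induced",
) -> ConnectivityResult:
    """Permutation test of hit connectivity against same-size random node
    sets drawn uniformly without replacement from the network's nodes.

    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes = list(genes)
    present = [g for g in genes if g in network]
    n_missing = len(genes) - len(present)
    observed = mean_induced_degree(network, present, mode=mode)

    nodes = sorted(network.nodes())
    k = len(present)
    if k > len(nodes):
        raise ValueError("more hits in network than network nodes")
    rng = np.random.default_rng(seed)
    # adjacency-matrix form of the same statistic, for fast resampling
    adj = nx.to_numpy_array(network, nodelist=nodes, dtype=float)
    degrees = adj.sum(axis=1)
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(len(nodes), size=k, replace=False)
        if mode == "induced":
            null[i] = adj[np.ix_(idx, idx)].sum() / k
        else:
            null[i] = degrees[idx].mean()
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return ConnectivityResult(
        observed_mean_degree=float(observed),
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        p_empirical=float(p),
        n_perm=n_perm,
        seed=seed,
        n_hits_in_network=k,
        n_hits_missing=n_missing,
    )
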