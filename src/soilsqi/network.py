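"""Correlation-threshold co-occurrence networks for top-abundance OTUs.

Edges are pairwise Pearson correlations on relative abundances passing a
joint threshold (|r| > 0.9 and p < 0.05 by default, both strict); the
topology panel reports link counts by sign, average degree, density,
seeded-Louvain modularity, mean local clustering and mean shortest-path
length over connected pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities, modularity
from scipy import stats

from .simulate import CommunityMatrix


def select_top_otus(communities: dict[str, CommunityMatrix] | CommunityMatrix,
                    top_n: int = 100, samples: list | None = None,
                    mode: str = "per-domain") -> pd.DataFrame:
    """Rank OTUs by mean relative abundance and keep the most abundant.

    ``mode`` "per-domain" (default) keeps ``top_n`` per domain and
    concatenates over shared samples; "combined" ranks the pooled table and
    keeps ``top_n`` overall.  Boundary ties break lexically by otu_id.
    Returns a samples x OTUs relative-abundance table.
    """
    if isinstance(communities, CommunityMatrix):
        communities = {communities.domain: communities}
    rels = {}
    sample_sets = []
    for domain, cm in communities.items():
        rel = cm.relative_abundance()
        if samples is not None:
            missing = set(samples) - set(rel.index)
            if missing:
                raise ValueError(f"samples absent from {domain}: {sorted(missing)}")
            rel = rel.loc[list(samples)]
        rels[domain] = rel
        sample_sets.append(tuple(rel.index))
    if len(set(sample_sets)) > 1:
        raise ValueError("sample sets differ between domains")

    def _top(rel: pd.DataFrame, n: int) -> pd.DataFrame:
        if n >= rel.shape[1]:
            if n > rel.shape[1]:
                warnings.warn(
                    f"top_n={n} exceeds available OTUs ({rel.shape[1]}): keeping all",
                    stacklevel=3,
                )
            return rel
        ranking = sorted(rel.columns, key=lambda o: (-rel[o].mean(), o))
        return rel[ranking[:n]]

    if mode == "per-domain":
        parts = [_top(rels[d], top_n) for d in rels]
        return pd.concat(parts, axis=1)
    if mode == "combined":
        pooled = pd.concat(list(rels.values()), axis=1)
        return _top(pooled, top_n)
    raise ValueError("mode must be 'per-domain' or 'combined'")


@dataclass
class OccurrenceNetwork:
    """Thresholded signed correlation graph over OTUs."""

    edges: pd.DataFrame                  # source, target, r, p, sign
    nodes: pd.DataFrame                  # otu_id index: mean_abundance (+ taxonomy)
    params: dict = field(default_factory=dict)

    @property
    def node_count(self) -> int:
        return len(self.nodes)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes.index)
        for _, e in self.edges.iterrows():
            g.add_edge(e["source"], e["target"], r=e["r"], p=e["p"],
                       sign=e["sign"])
        return g

    def to_edge_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph(), path)


def pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed p for Pearson r via t = r sqrt(n-2)/sqrt(1-r^2)."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def correlation_edges(matrix: pd.DataFrame, r_threshold: float = 0.9,
                      p_threshold: float = 0.05,
                      taxonomy: pd.DataFrame | None = None,
                      fdr: bool = False) -> OccurrenceNetwork:
    """Build the network from a samples x OTUs abundance table.

    Both thresholds are strict (|r| > r_threshold AND p < p_threshold).
    Constant abundance rows are excluded from pairing with a warning.
    Optional Benjamini-Hochberg correction of the p matrix before
    thresholding (off by default).
    """
    n = matrix.shape[0]
    if n < 3:
        raise ValueError("correlation p-value undefined: need >= 3 samples")
    x = matrix.to_numpy(float)
    sds = x.std(axis=0)
    constant = sds == 0
    if constant.any():
        warnings.warn(
            f"excluded constant OTUs: {list(matrix.columns[constant])[:5]}...",
            stacklevel=2,
        )
    keep = ~constant
    cols = matrix.columns[keep]
    xk = x[:, keep]
    corr = np.corrcoef(xk, rowvar=False)
    iu = np.triu_indices(len(cols), k=1)
    r = corr[iu]
    p = pearson_p(r, n)
    if fdr:
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        p = np.empty_like(p)
        p[order] = np.clip(adj, 0.0, 1.0)
    mask = (np.abs(r) > r_threshold) & (p < p_threshold)
    edges = pd.DataFrame(
        {
            "source": cols.values[iu[0][mask]],
            "target": cols.values[iu[1][mask]],
            "r": r[mask],
            "p": p[mask],
        }
    )
    edges["sign"] = np.where(edges["r"] > 0, "positive", "negative")
    nodes = pd.DataFrame({"mean_abundance": matrix.mean(axis=0)})
    nodes.index.name = "otu_id"
    if taxonomy is not None:
        nodes = nodes.join(taxonomy, how="left")
    return OccurrenceNetwork(
        edges=edges, nodes=nodes,
        params={"r_threshold": r_threshold, "p_threshold": p_threshold,
                "n_samples": n, "fdr": fdr},
    )


@dataclass
class NetworkSummary:
    node_count: int
    total_links: int
    positive_links: int
    negative_links: int
    average_degree: float
    density: float
    modularity: float
    average_clustering: float
    average_path_length: float
    flags: list = field(default_factory=list)

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "Node count": self.node_count,
                "Total linear links": self.total_links,
                "Positive links": self.positive_links,
                "Negative links": self.negative_links,
                "Average degree": self.average_degree,
                "Density": self.density,
                "Modularity": self.modularity,
                "Average clustering coefficient": self.average_clustering,
                "Average path length": self.average_path_length,
            }
        )


def summarize_network(net: OccurrenceNetwork, seed: int = 0) -> NetworkSummary:
    """Topology metric panel on the unweighted, unsigned graph.

    Modularity is the Louvain partition modularity with a fixed seed;
    clustering is the mean local coefficient (0 for degree < 2); path length
    averages shortest paths over all connected ordered pairs.
    """
    g = net.graph()
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need >= 2 nodes")
    m = g.number_of_edges()
    pos = int((net.edges["sign"] == "positive").sum())
    neg = int((net.edges["sign"] == "negative").sum())
    flags = []
    if m == 0:
        flags.append("edgeless graph: modularity/path length undefined, reported 0")
        return NetworkSummary(n, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, flags)
    communities = louvain_communities(g, seed=int(seed))
    q = modularity(g, communities)
    clustering = float(np.mean(list(nx.clustering(g).values())))
    # mean over connected ordered pairs (excluding self)
    total = 0.0
    pairs = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) < 2:
            continue
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            for target, dist in lengths.items():
                if dist > 0:
                    total += dist
                    pairs += 1
    apl = total / pairs if pairs else 0.0
    if pairs == 0:
        flags.append("no connected pairs: average path length reported 0")
    return NetworkSummary(
        node_count=n, total_links=m, positive_links=pos, negative_links=neg,
        average_degree=2.0 * m / n, density=2.0 * m / (n * (n - 1)),
        modularity=float(q), average_clustering=clustering,
        average_path_length=float(apl), flags=flags,
    )


def per_treatment_networks(
    communities: dict[str, CommunityMatrix], chem: pd.DataFrame,
    top_n: int = 100, r_threshold: float = 0.9, p_threshold: float = 0.05,
    mode: str = "per-domain", seed: int = 0, pooled: bool = False,
) -> dict[str, tuple[OccurrenceNetwork, NetworkSummary]]:
    """One network per treatment (or one pooled network across samples).

    With 3 replicates the joint threshold |r| > 0.9, p < 0.05 requires
    |r| >= 0.997 (df = 1); such networks are emitted with a loud caveat
    rather than refused.
    """
    chem = chem.set_index("sample_id") if "sample_id" in chem.columns else chem
    taxonomy = pd.concat(
        [cm.taxonomy for cm in communities.values()]
    )
    out = {}
    groups = (
        {"pooled": list(chem.index)} if pooled
        else {t: list(chem.index[chem["treatment"] == t])
              for t in dict.fromkeys(chem["treatment"])}
    )
    for label, samples in groups.items():
        if len(samples) < 3:
            raise ValueError(
                f"treatment {label}: need >= 3 samples for correlation p-values"
            )
        matrix = select_top_otus(communities, top_n=top_n, samples=samples,
                                 mode=mode)
        net = correlation_edges(matrix, r_threshold=r_threshold,
                                p_threshold=p_threshold, taxonomy=taxonomy)
        summary = summarize_network(net, seed=seed)
        df = len(samples) - 2
        r_needed = _r_for_p(p_threshold, len(samples))
        if max(r_threshold, r_needed) > 0.99:
            summary.flags.append(
                f"caveat: with n={len(samples)} (df={df}) the joint threshold "
                f"requires |r| >= {max(r_threshold, r_needed):.4f}; edge counts "
                "are unstable at this sample size"
            )
        out[label] = (net, summary)
    return out


def _r_for_p(p: float, n: int) -> float:
    """Smallest |r| giving a two-tailed p below the threshold at n samples."""
    t = stats.t.isf(p / 2.0, df=n - 2)
    return float(t / np.sqrt(n - 2 + t ** 2))


def summary_table(
    results: dict[str, tuple[OccurrenceNetwork, NetworkSummary]]
) -> pd.DataFrame:
    """Topology panel with treatments as columns (comparison-table layout)."""
    return pd.DataFrame({label: s.to_series() for label, (_, s) in results.items()})


def planted_block_recovery(net: OccurrenceNetwork,
                           communities: dict[str, CommunityMatrix]) -> dict:
    """Sensitivity/false-edge audit of a network against generator truth.

    Sensitivity = recovered fraction of planted within-block pairs (both
    members present in the network); the false-edge rate is the fraction of
    non-planted candidate pairs that received an edge.
    """
    truth = {}
    for cm in communities.values():
        for pb in cm.planted_blocks:
            truth.update(pb.pair_signs())
    nodes = set(net.nodes.index)
    truth = {pair: s for pair, s in truth.items()
             if pair[0] in nodes and pair[1] in nodes}
    found = {tuple(sorted((e["source"], e["target"]))):
             (1 if e["sign"] == "positive" else -1)
             for _, e in net.edges.iterrows()}
    hits = sum(1 for pair in truth if pair in found)
    sign_hits = sum(1 for pair, s in truth.items()
                    if pair in found and found[pair] == s)
    n_nodes = len(nodes)
    candidates = n_nodes * (n_nodes - 1) // 2
    false_edges = sum(1 for pair in found if pair not in truth)
    non_planted = candidates - len(truth)
    return {
        "planted_pairs": len(truth),
        "sensitivity": hits / len(truth) if truth else np.nan,
        "sign_accuracy": sign_hits / hits if hits else np.nan,
        "false_edge_rate": false_edges / non_planted if non_planted else np.nan,
        "edges": len(found),
    }
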