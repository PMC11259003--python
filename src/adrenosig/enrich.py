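"""Metabolite-set enrichment.

Two engines:

* hypergeometric over-representation analysis (ORA) over annotated pathway
  sets, with an optional topology "impact" score based on relative
  betweenness centrality of the hit compounds within the pathway graph;
* chemical-similarity cluster enrichment: metabolites are grouped into
  non-overlapping clusters by Tanimoto similarity of binary substructure
  fingerprints, and each cluster is tested with a one-sided
  Kolmogorov-Smirnov test of its members' raw association p-values against
  Uniform(0, 1), with BH-FDR across clusters and counts of significantly
  increased / decreased members (raw p < 0.05 combined with the fold-change
  direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .assoc import bh_fdr

DEFAULT_SIMILARITY_THRESHOLD = 0.7
DEFAULT_MIN_CLUSTER_SIZE = 3


@dataclass
class PathwayDB:
    """Pathway membership plus an optional compound graph."""

    members: dict[str, set[str]]
    graph: nx.Graph | None = None

    def __post_init__(self) -> None:
        for name, ids in self.members.items():
            if not ids:
                raise ValueError(f"pathway {name!r} has no members")
            if self.graph is not None and not set(ids) <= set(self.graph.nodes):
                raise ValueError(f"pathway {name!r} has members outside the graph")

    @classmethod
    def from_tsv(cls, path, graph_path=None) -> "PathwayDB":
        df = pd.read_csv(path, sep="\t")
        if not {"pathway", "member"} <= set(df.columns):
            raise ValueError("pathway TSV needs 'pathway' and 'member' columns")
        members: dict[str, set[str]] = {}
        for pw, sub in df.groupby("pathway"):
            members[str(pw)] = set(sub["member"].astype(str))
        graph = None
        if graph_path is not None:
            edges = pd.read_csv(graph_path, sep="\t")
            graph = nx.Graph()
            graph.add_nodes_from(str(m) for ids in members.values() for m in ids)
            graph.add_edges_from(zip(edges.iloc[:, 0].astype(str), edges.iloc[:, 1].astype(str)))
        return cls(members=members, graph=graph)

    @classmethod
    def from_annotations(cls, metabolite_meta: pd.DataFrame, column: str = "sub_pathway") -> "PathwayDB":
        """Build pathway sets from a per-metabolite annotation column."""
        members = {
            str(pw): set(sub.index.astype(str))
            for pw, sub in metabolite_meta.groupby(column)
        }
        return cls(members=members)


def hypergeometric_ora(
    hits: set[str], universe: set[str], db: PathwayDB
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation p per pathway, BH-adjusted."""
    hits = set(hits)
    universe = set(universe)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    M, N = len(universe), len(hits)
    rows = []
    for name, ids in sorted(db.members.items()):
        members = ids & universe
        n = len(members)
        if n == 0:
            continue
        k = len(members & hits)
        # P(X >= k) for X ~ Hypergeom(M, n, N)
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, M, n, N))
        rows.append((name, n, k, p))
    table = pd.DataFrame(rows, columns=["pathway", "size", "overlap", "p"]).set_index("pathway")
    table["q_fdr"] = bh_fdr(table["p"].to_numpy()) if len(table) else []
    return table


def pathway_impact(hits: set[str], db: PathwayDB) -> pd.Series:
    """Relative-betweenness topology impact per pathway.

    impact = sum of betweenness centrality over hit members / sum over all
    members, computed on the pathway's induced subgraph. Pathways whose
    members all have zero centrality get impact 1 if every member is a hit,
    else 0. Missing graph -> all NaN.
    """
    out = {}
    for name, ids in sorted(db.members.items()):
        if db.graph is None:
            out[name] = np.nan
            continue
        sub = db.graph.subgraph(ids)
        bc = nx.betweenness_centrality(sub, normalized=False)
        total = sum(bc.values())
        if total == 0:
            out[name] = 1.0 if ids <= set(hits) else 0.0
        else:
            out[name] = sum(bc[m] for m in ids if m in hits) / total
    return pd.Series(out, name="impact")


def parse_fingerprint(fp: str) -> np.ndarray:
    """'0110...' bitstring -> boolean array."""
    return np.frombuffer(fp.encode(), dtype=np.uint8) == ord("1")


def tanimoto(a: np.ndarray | str, b: np.ndarray | str) -> float:
    """Tanimoto similarity |a AND b| / |a OR b|; 0 when both are empty."""
    if isinstance(a, str):
        a = parse_fingerprint(a)
    if isinstance(b, str):
        b = parse_fingerprint(b)
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def cluster_by_similarity(
    fingerprints: pd.Series | dict[str, str],
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> pd.Series:
    """Non-overlapping chemical clusters: connected components of the graph
    with an edge wherever Tanimoto similarity >= threshold.

    Cluster labels are deterministic: components are numbered by their
    smallest member id, so the labeling is invariant to input order.
    """
    fps = pd.Series(fingerprints)
    ids = sorted(fps.index.astype(str))
    mats = np.array([parse_fingerprint(fps[i]) if isinstance(fps[i], str) else np.asarray(fps[i], bool) for i in ids])
    inter = (mats[:, None, :] & mats[None, :, :]).sum(axis=2)
    union = (mats[:, None, :] | mats[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    g = nx.Graph()
    g.add_nodes_from(ids)
    n = len(ids)
    ii, jj = np.triu_indices(n, k=1)
    keep = sim[ii, jj] >= threshold
    g.add_edges_from((ids[a], ids[b]) for a, b in zip(ii[keep], jj[keep]))
    comps = sorted(nx.connected_components(g), key=lambda c: min(c))
    labels = {m: ci for ci, comp in enumerate(comps) for m in comp}
    return pd.Series(labels, name="cluster").sort_index()


def ks_cluster_test(
    cluster_labels: pd.Series,
    raw_p: pd.Series,
    fold_change: pd.Series,
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    sig_p: float = 0.05,
    cluster_names: pd.Series | None = None,
) -> pd.DataFrame:
    """Chemical-cluster enrichment via a one-sided KS test toward small p.

    For each cluster of at least `min_size` members, the members' raw
    association p-values are tested against Uniform(0,1) with the one-sided
    alternative that they are stochastically smaller; BH-FDR is applied
    across the tested clusters. Members with raw p < `sig_p` are counted as
    increased (fold change > 1) or decreased (fold change < 1), and the key
    compound is the member with the smallest raw p.
    """
    labels = pd.Series(cluster_labels)
    raw_p = pd.Series(raw_p)
    fold_change = pd.Series(fold_change)
    missing = labels.index.difference(raw_p.index)
    if len(missing):
        raise ValueError(f"missing raw p for members: {list(missing)[:5]}")
    rows = []
    skipped = []
    for cl, members in labels.groupby(labels):
        ids = list(members.index)
        if len(ids) < min_size:
            skipped.append((cl, len(ids)))
            continue
        pvals = raw_p[ids].to_numpy(dtype=float)
        fc = fold_change[ids].to_numpy(dtype=float)
        # alternative="greater": empirical CDF above the uniform CDF,
        # i.e. member p-values stochastically smaller than U(0,1)
        ks = stats.kstest(pvals, "uniform", alternative="greater")
        sig = pvals < sig_p
        key = ids[int(np.argmin(pvals))]
        name = cluster_names[key] if cluster_names is not None else str(cl)
        rows.append(
            (cl, name, len(ids), float(ks.statistic), float(ks.pvalue),
             int((sig & (fc > 1)).sum()), int((sig & (fc < 1)).sum()), key)
        )
    table = pd.DataFrame(
        rows,
        columns=["cluster", "name", "size", "ks_statistic", "p", "n_up", "n_down", "key_compound"],
    ).set_index("cluster")
    table["q_fdr"] = bh_fdr(table["p"].to_numpy()) if len(table) else []
    table.attrs["skipped_clusters"] = skipped
    return table.sort_values("p")
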