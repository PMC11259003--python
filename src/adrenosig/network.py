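"""Pearson correlation network of significant metabolites.

Built on the log-transformed measurements: an edge joins metabolites i, j
whenever |Pearson r| >= threshold (default 0.8, which at n = 200 samples
corresponds to a correlation p-value below 2.22e-16). Connected components
define clusters and node degrees identify hubs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_THRESHOLD = 0.8


@dataclass
class MetaboliteGraph:
    """Thresholded correlation graph plus node-level summaries."""

    graph: nx.Graph
    edges: pd.DataFrame  # columns: source, target, r (i < j, unique)
    components: pd.Series  # component label per node
    degrees: pd.Series

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def write(self, outdir: str | Path, prefix: str = "network") -> dict[str, Path]:
        """Export as GraphML plus a 3-column weighted edge-list TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "graphml": outdir / f"{prefix}.graphml",
            "edges": outdir / f"{prefix}_edges.tsv",
            "nodes": outdir / f"{prefix}_nodes.tsv",
        }
        nx.write_graphml(self.graph, paths["graphml"])
        self.edges.to_csv(paths["edges"], sep="\t", index=False)
        pd.DataFrame({"component": self.components, "degree": self.degrees}).to_csv(
            paths["nodes"], sep="\t", index_label="metabolite_id"
        )
        return paths


def build_network(
    logX: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    annotations: pd.DataFrame | None = None,
) -> MetaboliteGraph:
    """Threshold the all-pairs Pearson correlation matrix of `logX` columns.

    Zero-variance columns are excluded with a warning. Edges keep the signed
    correlation; the threshold applies to |r|.
    """
    if logX.shape[1] < 2 or logX.shape[0] < 3:
        raise ValueError("need at least 2 metabolites and 3 samples")
    sd = logX.std(axis=0, ddof=0)
    if (sd == 0).any():
        dropped = list(logX.columns[sd == 0])
        warnings.warn(f"excluding {len(dropped)} zero-variance metabolite(s): {dropped[:5]}")
        logX = logX.loc[:, sd > 0]
    ids = list(logX.columns.astype(str))
    r = np.corrcoef(logX.to_numpy(dtype=float), rowvar=False)

    g = nx.Graph()
    g.add_nodes_from(ids)
    if annotations is not None:
        for mid in ids:
            if mid in annotations.index:
                for col, val in annotations.loc[mid].items():
                    if isinstance(val, np.generic):
                        val = val.item()
                    if isinstance(val, (str, int, float, bool)) and pd.notna(val):
                        g.nodes[mid][str(col)] = val
    ii, jj = np.triu_indices(len(ids), k=1)
    keep = np.abs(r[ii, jj]) >= threshold
    rows = []
    for a, b in zip(ii[keep], jj[keep]):
        g.add_edge(ids[a], ids[b], r=float(r[a, b]))
        rows.append((ids[a], ids[b], float(r[a, b])))
    edges = pd.DataFrame(rows, columns=["source", "target", "r"])

    comps = sorted(nx.connected_components(g), key=lambda c: min(c))
    components = pd.Series(
        {m: ci for ci, comp in enumerate(comps) for m in comp}, name="component"
    ).sort_index()
    degrees = pd.Series(dict(g.degree()), name="degree").sort_index()
    return MetaboliteGraph(graph=g, edges=edges, components=components, degrees=degrees)


def correlation_p(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation via the t-transform.

    t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom. |r| = 1 is
    reported as 0.0 (the p-value underflows any float tail).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return float(2 * stats.t.sf(abs(t), n - 2))


def hubs(
    graph: MetaboliteGraph | nx.Graph,
    top_k: int | None = None,
    min_degree: int | None = None,
) -> pd.DataFrame:
    """Nodes ranked by degree, ties broken lexicographically by id."""
    g = graph.graph if isinstance(graph, MetaboliteGraph) else graph
    deg = sorted(g.degree(), key=lambda kv: (-kv[1], str(kv[0])))
    table = pd.DataFrame(deg, columns=["metabolite_id", "degree"]).set_index("metabolite_id")
    if min_degree is not None:
        table = table[table["degree"] >= min_degree]
    if top_k is not None:
        table = table.head(top_k)
    return table
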