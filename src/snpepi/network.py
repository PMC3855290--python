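"""Epistasis networks: construction, subnets, importance, export.

Nodes are SNPs; an undirected edge joins two SNPs whose pairwise epistatic
effect is significant.  Connected components ("subnets") are scored by an
entropy-motivated importance

    w = sum_i  c_i * (-log10 p_i)        over the subnet's edges,

where p_i is the edge's P-value and c_i its contribution rate expressed as
a proportion (1.25% -> 0.0125).  Each edge's surprisal -log10 p_i is
weighted by the share of phenotypic variation the effect explains, so
subnets with more edges, smaller P-values and larger contributions score
higher.
"""

from __future__ import annotations

import math
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import chrom_sort_key

#: Fig-style node color classes by best incident P-value (upper bounds)
P_COLOR_CLASSES = (
    (1e-13, "red"),
    (1e-12, "blue"),
    (1e-11, "green"),
    (1e-10, "white"),
)

TREE_LABEL = "Tree graph"
LOOP_LABEL = "Loop graph"


def p_color_class(p: float) -> str:
    for bound, color in P_COLOR_CLASSES:
        if p < bound:
            return color
    return "none"


REQUIRED_PAIR_COLUMNS = ("snp1", "snp2", "effect", "P", "c")


def build_network(pairs: pd.DataFrame) -> nx.Graph:
    """Build the SNP-SNP graph from a significant-pair table.

    Expects columns ``snp1, snp2, effect, P, c`` (``c`` in percent) and,
    optionally, ``chrom1``/``chrom2``.  Parallel records for one unordered
    pair collapse to a single edge keeping the most significant record;
    self-loops are rejected.  Node attributes carry the chromosome and the
    color class of the best (smallest) incident P-value; edge attributes
    carry effect type, P, contribution (as a proportion) and the edge color
    by effect type (AA red, AD purple).
    """
    missing = set(REQUIRED_PAIR_COLUMNS) - set(pairs.columns)
    if missing:
        raise ValueError(f"pair table missing columns: {sorted(missing)}")
    G = nx.Graph()
    for rownum, row in enumerate(pairs.itertuples(index=False), start=1):
        s1, s2 = str(row.snp1), str(row.snp2)
        if s1 == s2:
            raise ValueError(f"row {rownum}: self-interaction {s1}")
        try:
            p = float(row.P)
            c = float(row.c)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {rownum}: unparseable P or c") from exc
        if not 0 < p <= 1:
            raise ValueError(f"row {rownum}: P={p} outside (0, 1]")
        if c < 0:
            raise ValueError(f"row {rownum}: negative contribution")
        chrom1 = str(getattr(row, "chrom1", "?"))
        chrom2 = str(getattr(row, "chrom2", "?"))
        for node, chrom in ((s1, chrom1), (s2, chrom2)):
            if node not in G:
                G.add_node(node, chrom=chrom, best_p=p)
            else:
                G.nodes[node]["best_p"] = min(G.nodes[node]["best_p"], p)
        if G.has_edge(s1, s2):
            if p >= G.edges[s1, s2]["P"]:
                continue
        G.add_edge(s1, s2, effect=str(row.effect), P=p, c=c / 100.0,
                   c_percent=c)
    for node in G.nodes:
        G.nodes[node]["color"] = p_color_class(G.nodes[node]["best_p"])
    return G


def classify_topology(subnet: nx.Graph) -> str:
    """"Tree graph" iff edges = nodes - 1, else "Loop graph"."""
    if subnet.number_of_nodes() and not nx.is_connected(subnet):
        raise ValueError("topology is defined for connected subnets only")
    n, e = subnet.number_of_nodes(), subnet.number_of_edges()
    return TREE_LABEL if e == n - 1 else LOOP_LABEL


def importance(subnet: nx.Graph) -> float:
    """Entropy-weighted subnet importance w = Σ c_i · (−log10 p_i)."""
    w = 0.0
    for _, _, attrs in subnet.edges(data=True):
        p = attrs["P"]
        if p <= 0:
            raise ValueError(f"edge P-value {p} must be positive")
        w += attrs["c"] * (-math.log10(p))
    return w


def extract_subnets(network: nx.Graph, min_nodes: int = 3) -> list[nx.Graph]:
    """Connected components with >= ``min_nodes`` nodes.

    Ordered deterministically: descending node count, then the
    lexicographically smallest member SNP id.
    """
    comps = [network.subgraph(c).copy()
             for c in nx.connected_components(network)]
    comps = [c for c in comps if c.number_of_nodes() >= min_nodes]
    comps.sort(key=lambda c: (-c.number_of_nodes(), min(c.nodes)))
    return comps


def subnet_summary(subnets: list[nx.Graph]) -> pd.DataFrame:
    """Per-subnet table: importance, node/edge counts, greatest degree,
    topology label and chromosomes spanned (sorted, comma-joined)."""
    rows = []
    for k, sn in enumerate(subnets):
        chroms = sorted({d.get("chrom", "?") for _, d in sn.nodes(data=True)},
                        key=chrom_sort_key)
        rows.append({
            "subnet": f"S{k+1}",
            "importance": importance(sn),
            "n_nodes": sn.number_of_nodes(),
            "n_edges": sn.number_of_edges(),
            "greatest_degree": max(dict(sn.degree).values()),
            "structure": classify_topology(sn),
            "chromosomes": ", ".join(chroms),
        })
    return pd.DataFrame(rows, columns=["subnet", "importance", "n_nodes",
                                       "n_edges", "greatest_degree",
                                       "structure", "chromosomes"])


EFFECT_EDGE_COLORS = {"AA": "red", "AD": "purple", "DA": "orange",
                      "DD": "brown"}


def export_network(network: nx.Graph, outdir, prefix: str = "epinet"
                   ) -> dict[str, Path]:
    """Write viewer-ready files: SIF edges plus node/edge attribute tables.

    The SIF relationship label is the effect type.  Node attributes carry
    chromosome and P-value color class; edge attributes carry effect type,
    P, contribution (%) and the effect-type color.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sif": outdir / f"{prefix}.sif",
        "nodes": outdir / f"{prefix}.nodes.tsv",
        "edges": outdir / f"{prefix}.edges.tsv",
    }
    try:
        edges = sorted(network.edges(data=True), key=lambda e: tuple(sorted(e[:2])))
        with open(paths["sif"], "w") as fh:
            for u, v, attrs in edges:
                a, b = sorted((u, v))
                fh.write(f"{a}\t{attrs['effect']}\t{b}\n")
        node_rows = [
            {"snp": n, "chrom": d.get("chrom", "?"),
             "best_P": d.get("best_p", float("nan")),
             "color": d.get("color", "none")}
            for n, d in sorted(network.nodes(data=True))
        ]
        pd.DataFrame(node_rows, columns=["snp", "chrom", "best_P", "color"]) \
            .to_csv(paths["nodes"], sep="\t", index=False)
        edge_rows = [
            {"snp1": min(u, v), "snp2": max(u, v), "effect": d["effect"],
             "P": d["P"], "c_percent": d["c_percent"],
             "color": EFFECT_EDGE_COLORS.get(d["effect"], "gray")}
            for u, v, d in edges
        ]
        pd.DataFrame(edge_rows, columns=["snp1", "snp2", "effect", "P",
                                         "c_percent", "color"]) \
            .to_csv(paths["edges"], sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"network export failed at {exc.filename}: {exc}") from exc
    return paths
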