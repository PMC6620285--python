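"""Downstream statistics: gene-set enrichment, network topology, qPCR copy number.

Enrichment is the exact hypergeometric upper tail against user-supplied
GMT collections (universe defaults to the array design), BH-adjusted
across terms.  Network analysis filters a weighted edge list by
confidence, reports hubs (degree >= 10) and unweighted edge
betweenness, and can expand a seed list by a capped first neighbour
shell.  qPCR copy number uses the 2^-ddCt statistic with gain >= 1.4,
loss <= 0.6, diploid in [0.8, 1.2] and an explicit indeterminate class
for the gaps the cut-offs leave open.
"""

from __future__ import annotations

import warnings

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "parse_gmt",
    "hypergeom_enrich",
    "build_network",
    "network_hubs",
    "expand_seed_network",
    "ddct_classify",
]

DEGREE_THRESHOLD = 10
MIN_CONFIDENCE = 0.8
MAX_ADDED_NEIGHBORS = 100
DDCT_GAIN = 1.4
DDCT_LOSS = 0.6
DDCT_DIPLOID = (0.8, 1.2)


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------

def parse_gmt(path) -> dict[str, tuple[str, frozenset]]:
    """GMT file: one line per term — name, description, member genes."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = (parts[1], frozenset(g for g in parts[2:] if g))
    return sets


def hypergeom_enrich(
    query: set,
    gene_sets: dict,
    universe: set,
    strict: bool = True,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query against gene sets.

    ``p = P[X >= k]`` for ``X ~ Hypergeom(N, K, n)`` with N the universe
    size, K the (universe-intersected) set size, n the query size and k
    the overlap.  BH-adjusted across terms, sorted by p.  ``gene_sets``
    maps term -> member set, or term -> (description, member set) as
    returned by :func:`parse_gmt`.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        if strict:
            raise ValueError(f"query genes outside universe: {sorted(outside)[:5]} ...")
        query &= universe
    N, n = len(universe), len(query)
    rows = []
    for term, members in gene_sets.items():
        desc = ""
        if isinstance(members, tuple) and len(members) == 2:
            desc, members = members
        members = set(members) & universe
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {"term": term, "description": desc, "k": k, "K": K, "n": n, "N": N,
             "p": min(max(p, 0.0), 1.0)}
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["fdr"] = []
        return out
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Network topology
# ---------------------------------------------------------------------------

def build_network(edges: pd.DataFrame, min_confidence: float = MIN_CONFIDENCE) -> nx.Graph:
    """Simple graph from an edge list, filtered by interaction confidence.

    Edges below ``min_confidence`` (when a confidence column exists) are
    dropped; self-loops are dropped with a warning; duplicate edges
    collapse (a simple graph keeps one).
    """
    g = nx.Graph()
    has_conf = "confidence" in edges.columns
    n_self = 0
    for rec in edges.itertuples(index=False):
        a, b = rec.node1, rec.node2
        if has_conf:
            c = float(rec.confidence)
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"confidence {c} outside [0, 1]")
            if c < min_confidence:
                continue
        else:
            c = 1.0
        if a == b:
            n_self += 1
            continue
        g.add_edge(a, b, confidence=c)
    if n_self:
        warnings.warn(f"dropped {n_self} self-loop(s)", stacklevel=2)
    return g


def network_hubs(
    edges: pd.DataFrame,
    degree_threshold: int = DEGREE_THRESHOLD,
    min_confidence: float = MIN_CONFIDENCE,
) -> tuple[pd.DataFrame, pd.DataFrame, nx.Graph]:
    """Hub table and edge-betweenness metrics on the confidence-filtered graph.

    Hubs are nodes with degree >= ``degree_threshold`` (inclusive);
    betweenness is computed over all unweighted shortest paths.
    Returns ``(nodes, edge_metrics, graph)``.
    """
    g = build_network(edges, min_confidence)
    deg = dict(g.degree())
    nodes = pd.DataFrame(
        {"node": list(deg), "degree": list(deg.values())}
    ).sort_values(["degree", "node"], ascending=[False, True], kind="mergesort")
    nodes["is_hub"] = nodes["degree"] >= degree_threshold
    eb = nx.edge_betweenness_centrality(g, normalized=True)
    edge_metrics = pd.DataFrame(
        [{"node1": a, "node2": b, "betweenness": v} for (a, b), v in eb.items()]
    )
    if not edge_metrics.empty:
        edge_metrics = edge_metrics.sort_values(
            "betweenness", ascending=False, kind="mergesort"
        ).reset_index(drop=True)
    return nodes.reset_index(drop=True), edge_metrics, g


def expand_seed_network(
    edges: pd.DataFrame,
    seeds: set,
    min_confidence: float = MIN_CONFIDENCE,
    max_added_neighbors: int = MAX_ADDED_NEIGHBORS,
) -> nx.Graph:
    """Induced subgraph on seeds plus a capped first shell of neighbours.

    Neighbours are ranked by number of seed connections, then degree,
    then name; at most ``max_added_neighbors`` are added.
    """
    g = build_network(edges, min_confidence)
    seeds = {s for s in seeds if s in g}
    shell = {}
    for s in seeds:
        for nb in g.neighbors(s):
            if nb not in seeds:
                shell[nb] = shell.get(nb, 0) + 1
    ranked = sorted(shell, key=lambda v: (-shell[v], -g.degree(v), v))
    keep = seeds | set(ranked[:max_added_neighbors])
    return g.subgraph(keep).copy()


# ---------------------------------------------------------------------------
# qPCR 2^-ddCt copy-number classification
# ---------------------------------------------------------------------------

def _classify_ratio(ratio: float) -> str:
    if ratio >= DDCT_GAIN:
        return "gain"
    if ratio <= DDCT_LOSS:
        return "loss"
    if DDCT_DIPLOID[0] <= ratio <= DDCT_DIPLOID[1]:
        return "diploid"
    return "indeterminate"


def ddct_classify(
    ct_table: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """Relative copy number per sample and target gene by 2^-ddCt.

    ``ct_table`` is long-format with columns sample, gene, ct; replicate
    Cts are arithmetic-mean-averaged before dCt.  dCt = Ct(target) -
    Ct(reference) per sample; ddCt subtracts the calibrator sample's
    dCt; ratio = 2^-ddCt.  Classes: gain (>= 1.4), loss (<= 0.6),
    diploid ([0.8, 1.2]) and indeterminate for the uncovered gaps.
    """
    required = {"sample", "gene", "ct"}
    if not required <= set(ct_table.columns):
        raise ValueError(f"ct table needs columns {sorted(required)}")
    mean_ct = ct_table.groupby(["sample", "gene"])["ct"].mean()

    samples = sorted(ct_table["sample"].unique())
    targets = sorted(set(ct_table["gene"].unique()) - {reference_gene})
    if calibrator_sample not in samples:
        raise ValueError(f"calibrator sample {calibrator_sample!r} absent from table")

    def _dct(sample: str, target: str) -> float:
        if (sample, reference_gene) not in mean_ct.index:
            raise ValueError(f"missing reference-gene Ct for sample {sample!r}")
        if (sample, target) not in mean_ct.index:
            raise ValueError(f"missing Ct for {target!r} in sample {sample!r}")
        return float(mean_ct[(sample, target)] - mean_ct[(sample, reference_gene)])

    rows = []
    for target in targets:
        dct_cal = _dct(calibrator_sample, target)
        for sample in samples:
            dct = _dct(sample, target)
            ddct = dct - dct_cal
            ratio = float(2.0 ** (-ddct))
            rows.append(
                {
                    "sample": sample,
                    "target": target,
                    "reference": reference_gene,
                    "dct": dct,
                    "ddct": ddct,
                    "ratio": ratio,
                    "cn_class": _classify_ratio(ratio),
                }
            )
    return pd.DataFrame(rows)
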