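"""Clonal networks: unique sequences joined by single-nucleotide edges.

Each vertex is a unique V(D)J nucleotide sequence; its size is the
number of reads supporting it after barcode correction. An edge joins
two vertices iff they have equal length and Hamming distance exactly 1
(single-nucleotide, non-indel difference). Clones are the connected
components. Networks are per sample.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .isotypes import CLASS7

logger = logging.getLogger(__name__)


@dataclass
class ClonalNetwork:
    graph: nx.Graph               # nodes are vertex indices into `vertices`
    vertices: pd.DataFrame        # sequence, duplicate_count, isotypes, ...

    @property
    def n_clusters(self) -> int:
        return int(self.vertices["clone_id"].max()) + 1 if len(self.vertices) else 0

    def cluster_members(self, clone_id: int) -> pd.DataFrame:
        return self.vertices[self.vertices["clone_id"] == clone_id]


def _hamming1_edges(seqs: list[str]) -> list[tuple[int, int]]:
    """All index pairs at equal length and Hamming distance exactly 1.

    Length-bucketed; small buckets use vectorized row-vs-rest
    comparison, large buckets a position-masked key join. The contract
    is the brute-force all-pairs definition either way.
    """
    buckets = defaultdict(list)
    for i, s in enumerate(seqs):
        buckets[len(s)].append(i)
    edges = []
    for length, idx in buckets.items():
        if len(idx) < 2:
            continue
        if len(idx) <= 3000:
            mat = np.frombuffer("".join(seqs[i] for i in idx).encode(),
                                dtype=np.uint8).reshape(len(idx), length)
            for a in range(len(idx) - 1):
                d = (mat[a + 1:] != mat[a]).sum(axis=1)
                for b in np.nonzero(d == 1)[0]:
                    edges.append((idx[a], idx[a + 1 + b]))
        else:
            masked = defaultdict(list)
            for i in idx:
                s = seqs[i]
                for p in range(length):
                    masked[(p, s[:p], s[p + 1:])].append(i)
            seen = set()
            for group in masked.values():
                for a in range(len(group) - 1):
                    for b in range(a + 1, len(group)):
                        pair = (group[a], group[b])
                        if pair not in seen:
                            seen.add(pair)
                            edges.append(pair)
    return edges


def build_network(annotated: pd.DataFrame) -> ClonalNetwork:
    """Deduplicate annotated records to unique sequences (summing read
    support, unioning isotypes) and build the Hamming-1 network.

    Cluster ids are assigned deterministically: components ordered by
    total read support (descending), ties by smallest vertex index.
    """
    agg = annotated.groupby("sequence", sort=True).agg(
        duplicate_count=("duplicate_count", "sum"),
        n_mut_total=("n_mut_total", "first"),
        v_call=("v_call", "first"),
        j_call=("j_call", "first"),
        junction_aa=("junction_aa", "first"),
        v_seq_length=("v_seq_length", "first"),
    ).reset_index()
    iso_sets = annotated.groupby("sequence", sort=True)["c_call"].agg(
        lambda s: frozenset(s))
    agg["isotypes"] = iso_sets.values

    seqs = agg["sequence"].tolist()
    g = nx.Graph()
    g.add_nodes_from(range(len(seqs)))
    g.add_edges_from(_hamming1_edges(seqs))

    components = [sorted(c) for c in nx.connected_components(g)]
    reads = agg["duplicate_count"].to_numpy()
    components.sort(key=lambda c: (-int(reads[c].sum()), c[0]))
    clone_id = np.empty(len(seqs), dtype=int)
    for cid, comp in enumerate(components):
        clone_id[comp] = cid
    agg["clone_id"] = clone_id
    return ClonalNetwork(graph=g, vertices=agg)


def largest_cluster(net: ClonalNetwork, by: str = "reads") -> int:
    """Cluster with the most reads (default) or the most vertices; ties
    resolve to the smallest cluster id, with a warning."""
    if len(net.vertices) == 0:
        raise ValueError("empty network")
    if by == "reads":
        totals = net.vertices.groupby("clone_id")["duplicate_count"].sum()
    elif by == "vertices":
        totals = net.vertices.groupby("clone_id").size()
    else:
        raise ValueError(f"unknown criterion {by!r}")
    best = totals.max()
    winners = sorted(totals[totals == best].index)
    if len(winners) > 1:
        logger.warning("largest_cluster tie between %s; choosing %d",
                       winners, winners[0])
    return int(winners[0])


def clone_summaries(net: ClonalNetwork) -> pd.DataFrame:
    """Per-clone size, read fraction, isotype grouping and mean SHM.

    ``n_isotype_classes`` counts grouped classes (IgM, IgD, IgG1/2,
    IgG3, IgG4, IgA1/2, IgE); the raw subclass set is retained in
    ``isotype_set``. ``has_igmd`` marks clones whose class set touches
    {IgM, IgD} (the Fig-2-style IgM+IgD+ vs IgM-IgD- split).
    """
    total_reads = int(net.vertices["duplicate_count"].sum())
    rows = []
    for cid, grp in net.vertices.groupby("clone_id"):
        iso_set = frozenset().union(*grp["isotypes"])
        classes = frozenset(CLASS7[i] for i in iso_set)
        rows.append({
            "cluster_id": int(cid),
            "n_vertices": len(grp),
            "clone_reads": int(grp["duplicate_count"].sum()),
            "clone_size_fraction": grp["duplicate_count"].sum() / total_reads,
            "isotype_set": iso_set,
            "isotype_classes": classes,
            "n_isotype_classes": len(classes),
            "has_igmd": bool(classes & {"IgM", "IgD"}),
            "mean_mut_from_germline": float(grp["n_mut_total"].mean()),
        })
    return pd.DataFrame(rows).sort_values("cluster_id").reset_index(drop=True)


def mutations_from_dominant(net: ClonalNetwork, cluster_id: int) -> pd.DataFrame:
    """V-region nucleotide distance of every cluster member from the
    cluster's dominant (most-read) sequence."""
    members = net.cluster_members(cluster_id)
    if members.empty:
        raise ValueError(f"no such cluster {cluster_id}")
    dom = members.loc[members["duplicate_count"].idxmax()]
    dom_seq = dom["sequence"]
    rows = []
    for _, rec in members.iterrows():
        ln = int(min(rec["v_seq_length"], dom["v_seq_length"],
                     len(rec["sequence"]), len(dom_seq)))
        dist = sum(a != b for a, b in zip(rec["sequence"][:ln], dom_seq[:ln]))
        rows.append({"sequence": rec["sequence"],
                     "isotypes": rec["isotypes"],
                     "duplicate_count": int(rec["duplicate_count"]),
                     "distance_from_dominant": dist,
                     "is_dominant": rec["sequence"] == dom_seq})
    return pd.DataFrame(rows)
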