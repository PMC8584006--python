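"""Kinase-regulatory network assembly.

Nodes are kinases with significantly activated/inhibited activity and
phosphosites with significantly changed phosphorylation; directed edges
kinase -> site carry the kinase-substrate prediction score.  The result is
a bipartite networkx DiGraph ready for SIF/GraphML export (Cytoscape).
"""

from __future__ import annotations

import logging
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .activity import STATE_INDETERMINATE, KinaseActivity
from .kinase_substrate import KSRelation
from .model import ComparisonResult, STATUS_NS

logger = logging.getLogger("phosflow")


def build_network(
    activities: Sequence[KinaseActivity],
    comparison_result: ComparisonResult,
    relations: Sequence[KSRelation],
    p_threshold: float = 0.05,
    require_significance: bool = True,
) -> nx.DiGraph:
    """Assemble the kinase -> site regulatory network for one comparison.

    Kinases are kept when their state is not indeterminate (|NES| >= 1) and,
    with ``require_significance``, their permutation p is below
    ``p_threshold``.  Sites are kept when their differential status is not
    ns.  Edges are the predicted relations whose endpoints both survive;
    nodes without a surviving edge are dropped (an empty network is valid).
    """
    keep_kinases = {
        a.kinase_id: a
        for a in activities
        if a.state != STATE_INDETERMINATE
        and (not require_significance
             or (np.isfinite(a.p_perm) and a.p_perm < p_threshold))
    }
    table = comparison_result.table
    keep_sites = {
        sid: (table.at[sid, "status"], float(table.at[sid, "log2fc"]))
        for sid in table.index[table["status"] != STATUS_NS]
    }
    g = nx.DiGraph(comparison=comparison_result.name)
    for rel in relations:
        if rel.kinase_id not in keep_kinases or rel.site_id not in keep_sites:
            continue
        act = keep_kinases[rel.kinase_id]
        status, log2fc = keep_sites[rel.site_id]
        g.add_node(rel.kinase_id, type="kinase", state=act.state,
                   nes=float(act.nes))
        g.add_node(rel.site_id, type="site", status=status, log2fc=log2fc)
        g.add_edge(rel.kinase_id, rel.site_id, score=float(rel.score),
                   relation="regulates")
    logger.info(
        "network %s: %d nodes, %d edges (%d kinases passed, %d sites significant)",
        comparison_result.name, g.number_of_nodes(), g.number_of_edges(),
        len(keep_kinases), len(keep_sites),
    )
    return g


def degree_summary(network: nx.DiGraph, top_k: int = 10) -> pd.DataFrame:
    """Kinases ranked by out-degree and sites by in-degree (ties broken by
    id; stable)."""
    rows = []
    kinases = [n for n, d in network.nodes(data=True) if d.get("type") == "kinase"]
    sites = [n for n, d in network.nodes(data=True) if d.get("type") == "site"]
    for n in sorted(kinases, key=lambda n: (-network.out_degree(n), n))[:top_k]:
        rows.append({"node": n, "type": "kinase", "degree": network.out_degree(n)})
    for n in sorted(sites, key=lambda n: (-network.in_degree(n), n))[:top_k]:
        rows.append({"node": n, "type": "site", "degree": network.in_degree(n)})
    return pd.DataFrame(rows, columns=["node", "type", "degree"])
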