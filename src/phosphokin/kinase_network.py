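"""Weighted kinase-site regulatory network assembly.

Combines classified kinase activities, predicted kinase-substrate edges
and differential site calls into a bipartite directed graph: kinase nodes
(NES, direction) point at site nodes (log2 ratio, status) with the
peptide-similarity score as edge weight. Only kinases with a significant
direction and sites with a significant status enter; isolated nodes are
dropped.
"""

from __future__ import annotations

import logging
from typing import Sequence

import networkx as nx
import pandas as pd

from phosphokin.differential import DOWN, UNCHANGED, UP
from phosphokin.gsea_engine import NOT_SIGNIFICANT, KinaseActivity
from phosphokin.ksr_predict import KSREdge

logger = logging.getLogger(__name__)


def build_network(
    activities: Sequence[KinaseActivity],
    ksr_edges: Sequence[KSREdge],
    calls: pd.DataFrame,
) -> nx.DiGraph:
    """Assemble the regulatory network (kinase -> site, weight = KSR score).

    Kinases classified not-significant and unchanged sites are excluded
    with all their edges; edges referencing a kinase absent from
    ``activities`` or a site absent from ``calls`` raise with the list of
    offenders. Isolated nodes are dropped, so the result's edge set is a
    subset of ``ksr_edges``.
    """
    activity_by_name = {a.kinase_name: a for a in activities}
    call_by_key = {
        f"{row.protein_id}_{row.position}": row for row in calls.itertuples(index=False)
    }

    unknown_kinases = sorted({e.kinase_name for e in ksr_edges} - set(activity_by_name))
    unknown_sites = sorted({e.site_key for e in ksr_edges if e.site_key not in call_by_key})
    if unknown_kinases or unknown_sites:
        raise ValueError(
            f"edges reference unknown kinases {unknown_kinases} / unknown sites {unknown_sites}"
        )

    graph = nx.DiGraph()
    for edge in ksr_edges:
        activity = activity_by_name[edge.kinase_name]
        if activity.direction == NOT_SIGNIFICANT:
            continue
        call = call_by_key[edge.site_key]
        if call.status == UNCHANGED:
            continue
        kinase_node = edge.kinase_name
        site_node = edge.site_key
        graph.add_node(
            kinase_node,
            kind="kinase",
            nes=activity.nes,
            direction=activity.direction,
            bipartite=0,
        )
        graph.add_node(
            site_node,
            kind="site",
            protein_id=call.protein_id,
            position=int(call.position),
            residue=call.residue,
            log2_ratio=float(call.log2_ratio),
            status=call.status,
            bipartite=1,
        )
        graph.add_edge(kinase_node, site_node, weight=edge.score)
    # isolated nodes cannot occur: nodes are only added alongside an edge
    return graph


def correlate_kinase_site(
    network: nx.DiGraph,
    target_site: str,
) -> list[tuple[str, bool]]:
    """Kinases adjacent to ``target_site`` with a direction-concordance flag.

    A kinase is concordant when its activity direction sign matches the
    site's regulation sign (positive kinase -> up site, negative -> down):
    the structural reading of a kinase "positively correlated" with a
    site's phosphorylation level in a pooled one-ratio design.
    """
    if target_site not in network:
        logger.warning("site %r not present in the network", target_site)
        return []
    status = network.nodes[target_site]["status"]
    out = []
    for kinase in network.predecessors(target_site):
        direction = network.nodes[kinase]["direction"]
        concordant = (direction == "positive" and status == UP) or (
            direction == "negative" and status == DOWN
        )
        out.append((kinase, concordant))
    out.sort()
    return out


def network_to_frame(network: nx.DiGraph) -> pd.DataFrame:
    """Flat TSV-ready edge list with node attributes."""
    rows = []
    for kinase, site, data in network.edges(data=True):
        site_attrs = network.nodes[site]
        rows.append(
            {
                "kinase": kinase,
                "protein_id": site_attrs["protein_id"],
                "position": site_attrs["position"],
                "residue": site_attrs["residue"],
                "score": data["weight"],
                "kinase_nes": network.nodes[kinase]["nes"],
                "site_log2_ratio": site_attrs["log2_ratio"],
                "site_status": site_attrs["status"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "kinase",
            "protein_id",
            "position",
            "residue",
            "score",
            "kinase_nes",
            "site_log2_ratio",
            "site_status",
        ],
    )


def write_graphml(network: nx.DiGraph, path) -> None:
    nx.write_graphml(network, path)
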