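"""Feature→pathway mapping and construction of the merged metabolic graph.

Features are mapped to the lowest pathway level: a feature matches a
pathway node when its identifier appears among the node's members (the
node id itself also counts as a member, so 1:1 annotations need not be
spelled out twice). Identifier namespaces are the user's responsibility —
no cross-database reconciliation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ValidationError
from .model import (
    FeatureKind,
    MetabolicGraph,
    NodeKind,
    OmicsDataset,
    Pathway,
    PathwayDatabase,
    PathwayNode,
)

# which feature kinds may annotate to which node kinds
_KIND_COMPAT: dict[NodeKind, set[FeatureKind]] = {
    NodeKind.GENE: {FeatureKind.GENE, FeatureKind.REGULATOR, FeatureKind.REGION},
    NodeKind.COMPOUND: {FeatureKind.COMPOUND},
}


def node_member_ids(node: PathwayNode) -> set[str]:
    return set(node.members) | {node.id}


def pathway_feature_ids(pathway: Pathway, dataset: OmicsDataset) -> set[str]:
    """Measured features of ``dataset`` mapping to ≥1 node of ``pathway``."""
    hits: set[str] = set()
    for node in pathway.nodes:
        if dataset.feature_kind not in _KIND_COMPAT[node.kind]:
            continue
        hits |= node_member_ids(node) & dataset.ids
    return hits


@dataclass
class LayerMappingReport:
    layer: str
    mapped: int
    unmapped: int
    mapped_ids: set[str] = field(default_factory=set)


@dataclass
class MappingReport:
    per_layer: dict[str, LayerMappingReport] = field(default_factory=dict)


def map_features(
    db: PathwayDatabase,
    datasets: Sequence[OmicsDataset],
    databases: Sequence[str] | None = None,
) -> MappingReport:
    """Match every dataset's features against pathway node members.

    Returns, per layer, the features mapping to at least one pathway and
    the count left unmapped. Unmapped features are reported, never fatal.
    """
    report = MappingReport()
    pathways = db.select(databases)
    for ds in datasets:
        mapped: set[str] = set()
        for pw in pathways:
            mapped |= pathway_feature_ids(pw, ds)
        report.per_layer[ds.name] = LayerMappingReport(
            layer=ds.name,
            mapped=len(mapped),
            unmapped=ds.n_features - len(mapped),
            mapped_ids=mapped,
        )
    return report


def build_metabolic_graph(
    db: PathwayDatabase,
    datasets: Sequence[OmicsDataset] = (),
    databases: Sequence[str] | None = None,
) -> MetabolicGraph:
    """Union of pathway node/edge sets, merged on node id, undirected.

    Measured/significant status is attached from the datasets: a node is
    measured when any of its member features is measured in a compatible
    layer, and significant when any such feature is flagged significant.
    Conflicting node kinds for one id raise :class:`ValidationError`.
    """
    pathways = db.select(databases)
    if not pathways:
        raise ValidationError("pathway database selection is empty")
    graph = MetabolicGraph()
    for pw in pathways:
        for node in pw.nodes:
            graph.add_node(node.id, node.kind, node_member_ids(node))
        for a, b in pw.edges:
            graph.add_edge(a, b)

    for node_id, data in graph.g.nodes(data=True):
        members: set[str] = data["members"]
        for ds in datasets:
            if ds.feature_kind not in _KIND_COMPAT[data["kind"]]:
                continue
            matched = members & ds.ids
            if matched:
                data["measured"] = True
                if matched & ds.significant_ids:
                    data["significant"] = True
    return graph
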