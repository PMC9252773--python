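"""Domain types: omics layers, pathways, and the merged metabolic graph.

An :class:`OmicsDataset` is one omics layer — a feature-by-condition value
matrix plus the set of features the user's upstream statistics flagged as
significant (differentially expressed genes/metabolites, "DEG"/"DEM").
Pathways are node/edge sets whose nodes (gene or compound entities) carry
``members``: the feature identifiers that annotate to the node. The
:class:`MetabolicGraph` is the undirected union of pathway connectivity
across databases and is the substrate of the neighborhood tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError


class FeatureKind(str, Enum):
    GENE = "gene"
    COMPOUND = "compound"
    REGULATOR = "regulator"
    REGION = "region"


class NodeKind(str, Enum):
    GENE = "gene"
    COMPOUND = "compound"


@dataclass
class Feature:
    """One measured feature: identifier, layer, profile over conditions.

    ``profile`` holds one value per condition in the layer's condition
    order; missing measurements are NaN, never zero.
    """

    id: str
    omic: str
    profile: np.ndarray
    is_significant: bool = False

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)


@dataclass
class OmicsDataset:
    """A single omics layer with a shared condition ordering."""

    name: str
    conditions: list[str]
    features: dict[str, Feature] = field(default_factory=dict)
    feature_kind: FeatureKind = FeatureKind.GENE

    def __post_init__(self) -> None:
        for f in self.features.values():
            if len(f.profile) != len(self.conditions):
                raise ValidationError(
                    f"feature {f.id!r} in layer {self.name!r} has "
                    f"{len(f.profile)} values for {len(self.conditions)} conditions"
                )

    # -- accessors -------------------------------------------------------
    @property
    def ids(self) -> set[str]:
        return set(self.features)

    @property
    def significant_ids(self) -> set[str]:
        return {fid for fid, f in self.features.items() if f.is_significant}

    @property
    def n_features(self) -> int:
        return len(self.features)

    def __contains__(self, fid: str) -> bool:
        return fid in self.features

    def __getitem__(self, fid: str) -> Feature:
        return self.features[fid]

    def add_feature(self, feature: Feature) -> None:
        if feature.id in self.features:
            raise ValidationError(
                f"duplicate feature id {feature.id!r} in layer {self.name!r}"
            )
        if len(feature.profile) != len(self.conditions):
            raise ValidationError(
                f"feature {feature.id!r} profile length {len(feature.profile)} "
                f"!= {len(self.conditions)} conditions"
            )
        self.features[feature.id] = feature

    def set_significant(self, ids: Iterable[str]) -> None:
        """Flag the given features as significant; unknown ids are ignored
        (the relevant-features list may cover unmeasured features)."""
        wanted = set(ids)
        for fid, f in self.features.items():
            f.is_significant = fid in wanted

    def to_frame(self) -> pd.DataFrame:
        """Feature-by-condition matrix as a DataFrame (NaN = missing)."""
        data = {fid: f.profile for fid, f in self.features.items()}
        return pd.DataFrame.from_dict(data, orient="index", columns=self.conditions)


@dataclass
class PathwayNode:
    """A pathway map entity (gene/enzyme or compound).

    ``members`` lists the feature identifiers annotating to the node (a
    gene family or complex may aggregate several); it may be empty for a
    node never measured by any layer.
    """

    id: str
    kind: NodeKind
    members: list[str] = field(default_factory=list)


@dataclass
class Pathway:
    id: str
    name: str
    source_db: str = "custom"
    category: str = ""
    nodes: list[PathwayNode] = field(default_factory=list)
    edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(ids) != len(set(ids)):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ValidationError(
                f"pathway {self.id!r}: duplicate node ids {sorted(dupes)}"
            )
        known = set(ids)
        for a, b in self.edges:
            if a not in known or b not in known:
                raise ValidationError(
                    f"pathway {self.id!r}: edge ({a!r}, {b!r}) references unknown node"
                )

    def node_by_id(self, node_id: str) -> PathwayNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def nodes_of_kind(self, kind: NodeKind) -> list[PathwayNode]:
        return [n for n in self.nodes if n.kind == kind]


@dataclass
class PathwayDatabase:
    pathways: list[Pathway] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for p in self.pathways:
            key = (p.source_db, p.id)
            if key in seen:
                raise ValidationError(f"duplicate pathway {key} in database")
            seen.add(key)

    @property
    def db_names(self) -> set[str]:
        return {p.source_db for p in self.pathways}

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def select(self, databases: Sequence[str] | None = None) -> list[Pathway]:
        if databases is None:
            return list(self.pathways)
        wanted = set(databases)
        return [p for p in self.pathways if p.source_db in wanted]


class MetabolicGraph:
    """Undirected, unweighted heterogeneous gene–compound graph.

    Node attributes: ``kind`` (:class:`NodeKind`), ``measured`` and
    ``significant`` booleans derived from matching features, and
    ``members`` (union of member ids across the pathways merged in).
    Reaction directionality is deliberately discarded: neighborhoods are
    counted over shortest paths regardless of direction.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.g = graph if graph is not None else nx.Graph()

    def add_node(
        self,
        node_id: str,
        kind: NodeKind,
        members: Iterable[str] = (),
    ) -> None:
        if node_id in self.g:
            existing = self.g.nodes[node_id]["kind"]
            if existing != kind:
                raise ValidationError(
                    f"node {node_id!r} declared both {existing.value} and {kind.value}"
                )
            self.g.nodes[node_id]["members"].update(members)
        else:
            self.g.add_node(
                node_id,
                kind=kind,
                members=set(members),
                measured=False,
                significant=False,
            )

    def add_edge(self, a: str, b: str) -> None:
        if a == b:  # self-loops carry no neighborhood information
            return
        self.g.add_edge(a, b)

    # -- queries ---------------------------------------------------------
    def kind(self, node_id: str) -> NodeKind:
        return self.g.nodes[node_id]["kind"]

    def is_compound(self, node_id: str) -> bool:
        return node_id in self.g and self.g.nodes[node_id]["kind"] == NodeKind.COMPOUND

    def compound_ids(self) -> list[str]:
        return [n for n, d in self.g.nodes(data=True) if d["kind"] == NodeKind.COMPOUND]

    def gene_ids(self) -> list[str]:
        return [n for n, d in self.g.nodes(data=True) if d["kind"] == NodeKind.GENE]

    def is_measured(self, node_id: str) -> bool:
        return bool(self.g.nodes[node_id]["measured"])

    def is_significant(self, node_id: str) -> bool:
        return bool(self.g.nodes[node_id]["significant"])

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()
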