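"""Flat-file readers and writers.

Dialects:

* omics matrix — TSV, UTF-8, header row = condition labels, column 1 =
  feature ID, ``NA`` (or empty) = missing, ``#`` lines ignored;
* relevant-feature list — one ID per line, ``#`` comments ignored;
* pathway JSON — ``{"database": str, "pathways": [{"id", "name",
  "category", "nodes": [{"id", "kind", "members"}], "edges": [[a, b],
  ...]}]}``;
* KGML — the KEGG pathway XML subset of entry/relation/reaction elements
  (graphics and coordinates are ignored);
* class map / regulator map — two-column TSVs.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable

from lxml import etree

from .errors import ParseError, ValidationError
from .model import (
    Feature,
    FeatureKind,
    NodeKind,
    OmicsDataset,
    Pathway,
    PathwayDatabase,
    PathwayNode,
)

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "na", "null", "NULL"}


def _parse_value(token: str, path: str, lineno: int) -> float:
    if token in _MISSING_TOKENS:
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: cannot parse value {token!r} as a number"
        ) from None


def read_omics_matrix(
    path: str | Path,
    layer_name: str,
    feature_kind: FeatureKind = FeatureKind.GENE,
) -> OmicsDataset:
    """Read one omics layer from a TSV matrix.

    Rows are features, columns are conditions/time points. Missing values
    stay missing (NaN); rows whose field count disagrees with the header
    raise :class:`ParseError` naming the line, and duplicate feature IDs
    raise :class:`ValidationError`.
    """
    path = Path(path)
    conditions: list[str] | None = None
    dataset: OmicsDataset | None = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if conditions is None:
                if len(parts) < 2:
                    raise ParseError(
                        f"{path}:{lineno}: header must contain at least one condition"
                    )
                conditions = parts[1:]
                dataset = OmicsDataset(
                    name=layer_name, conditions=conditions, feature_kind=feature_kind
                )
                continue
            if len(parts) != len(conditions) + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {len(conditions) + 1} fields "
                    f"(ID + {len(conditions)} conditions), found {len(parts)}"
                )
            fid = parts[0].strip()
            if not fid:
                raise ParseError(f"{path}:{lineno}: empty feature ID")
            values = [_parse_value(tok.strip(), str(path), lineno) for tok in parts[1:]]
            assert dataset is not None
            dataset.add_feature(Feature(id=fid, omic=layer_name, profile=values))
    if dataset is None:
        raise ParseError(f"{path}: no header row found")
    return dataset


def read_feature_list(path: str | Path) -> set[str]:
    """Read a relevant-feature list: one ID per line, de-duplicated."""
    out: set[str] = set()
    with Path(path).open("r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            out.add(line)
    return out


def read_two_column_tsv(path: str | Path, what: str = "pair") -> list[tuple[str, str]]:
    """Read a two-column TSV into a de-duplicated, order-preserving pair list."""
    path = Path(path)
    pairs: dict[tuple[str, str], None] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ParseError(
                    f"{path}:{lineno}: expected two tab-separated {what} fields"
                )
            pairs[(parts[0], parts[1])] = None
    return list(pairs)


def read_class_map(path: str | Path) -> dict[str, set[str]]:
    """Read metabolite→class assignments; returns class → member-id sets."""
    classes: dict[str, set[str]] = {}
    for metabolite, cls in read_two_column_tsv(path, what="metabolite/class"):
        classes.setdefault(cls, set()).add(metabolite)
    return classes


# ---------------------------------------------------------------------------
# pathway JSON
# ---------------------------------------------------------------------------

def read_pathway_json(path: str | Path) -> PathwayDatabase:
    with Path(path).open("r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "pathways" not in doc:
        raise ValidationError(f"{path}: pathway JSON must contain a 'pathways' list")
    database = str(doc.get("database", "custom"))
    pathways: list[Pathway] = []
    for entry in doc["pathways"]:
        pid = entry.get("id")
        try:
            nodes = [
                PathwayNode(
                    id=str(n["id"]),
                    kind=NodeKind(n["kind"]),
                    members=[str(m) for m in n.get("members", [])],
                )
                for n in entry.get("nodes", [])
            ]
            edges = [(str(a), str(b)) for a, b in entry.get("edges", [])]
            pathways.append(
                Pathway(
                    id=str(pid),
                    name=str(entry.get("name", pid)),
                    source_db=str(entry.get("database", database)),
                    category=str(entry.get("category", "")),
                    nodes=nodes,
                    edges=edges,
                )
            )
        except (KeyError, TypeError, ValueError, ValidationError) as exc:
            raise ValidationError(f"pathway {pid!r}: {exc}") from exc
    return PathwayDatabase(pathways=pathways)


def write_pathway_json(db: PathwayDatabase, path: str | Path) -> None:
    doc = {
        "database": sorted(db.db_names)[0] if len(db.db_names) == 1 else "mixed",
        "pathways": [
            {
                "id": p.id,
                "name": p.name,
                "database": p.source_db,
                "category": p.category,
                "nodes": [
                    {"id": n.id, "kind": n.kind.value, "members": list(n.members)}
                    for n in p.nodes
                ],
                "edges": [[a, b] for a, b in p.edges],
            }
            for p in db.pathways
        ],
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# KGML
# ---------------------------------------------------------------------------

_GENE_ENTRY_TYPES = {"gene", "ortholog"}


def read_kgml(path: str | Path) -> Pathway:
    """Read a KEGG pathway XML file (KGML) into a :class:`Pathway`.

    Entries of type ``gene``/``ortholog`` become gene nodes and ``compound``
    entries become compound nodes; ``map`` and other entry types are
    dropped. Each reaction contributes edges between its substrate/product
    compounds and the gene entries catalyzing it; every relation contributes
    an edge between its two entries when both survive the type filter.
    Node identity is the first token of the entry ``name``; all tokens
    become node members. Graphics/coordinates are ignored.
    """
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ParseError(f"{path}: cannot parse KGML: {exc}") from exc
    root = tree.getroot()

    nodes: dict[str, PathwayNode] = {}
    entry_to_node: dict[str, str] = {}  # KGML entry id -> node id
    reaction_to_genes: dict[str, list[str]] = {}  # reaction name -> gene node ids

    for entry in root.iter("entry"):
        etype = entry.get("type", "")
        name = (entry.get("name") or "").strip()
        eid = entry.get("id") or ""
        if etype in _GENE_ENTRY_TYPES:
            kind = NodeKind.GENE
        elif etype == "compound":
            kind = NodeKind.COMPOUND
        else:
            continue
        members = name.split() if name else [eid]
        node_id = members[0]
        if node_id in nodes:
            if nodes[node_id].kind != kind:
                raise ValidationError(
                    f"{path}: entry {eid} redeclares node {node_id!r} "
                    f"as {kind.value}"
                )
            for m in members:
                if m not in nodes[node_id].members:
                    nodes[node_id].members.append(m)
        else:
            nodes[node_id] = PathwayNode(id=node_id, kind=kind, members=members)
        entry_to_node[eid] = node_id
        if kind == NodeKind.GENE:
            for rname in (entry.get("reaction") or "").split():
                reaction_to_genes.setdefault(rname, []).append(node_id)

    edges: set[tuple[str, str]] = set()

    def _add_edge(a: str, b: str) -> None:
        if a != b:
            edges.add((a, b) if a <= b else (b, a))

    for relation in root.iter("relation"):
        a = entry_to_node.get(relation.get("entry1") or "")
        b = entry_to_node.get(relation.get("entry2") or "")
        if a is not None and b is not None:
            _add_edge(a, b)

    for reaction in root.iter("reaction"):
        rname = (reaction.get("name") or "").strip()
        genes = list(reaction_to_genes.get(rname, []))
        # newer KGML also carries the catalyzing entry id on the reaction
        rid = reaction.get("id") or ""
        if rid in entry_to_node and entry_to_node[rid] not in genes:
            node = nodes[entry_to_node[rid]]
            if node.kind == NodeKind.GENE:
                genes.append(node.id)
        partners = []
        for tag in ("substrate", "product"):
            for el in reaction.iter(tag):
                node_id = entry_to_node.get(el.get("id") or "")
                if node_id is None and el.get("name"):
                    # fall back to matching the compound by name token
                    tok = el.get("name").split()[0]
                    node_id = tok if tok in nodes else None
                if node_id is not None:
                    partners.append(node_id)
        for g in genes:
            for c in partners:
                _add_edge(g, c)

    pid = root.get("name") or Path(path).stem
    title = root.get("title") or pid
    return Pathway(
        id=pid,
        name=title,
        source_db="KEGG",
        category="",
        nodes=list(nodes.values()),
        edges=sorted(edges),
    )
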