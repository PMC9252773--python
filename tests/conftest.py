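import numpy as np
import pytest

from omicpaths.model import (
    Feature,
    FeatureKind,
    NodeKind,
    OmicsDataset,
    Pathway,
    PathwayDatabase,
    PathwayNode,
)


def make_dataset(
    name: str,
    profiles: dict[str, list[float]],
    significant: set[str] = frozenset(),
    kind: FeatureKind = FeatureKind.GENE,
    conditions: list[str] | None = None,
) -> OmicsDataset:
    n_cond = len(next(iter(profiles.values()))) if profiles else 2
    conditions = conditions or [f"t{i}" for i in range(n_cond)]
    ds = OmicsDataset(name=name, conditions=conditions, feature_kind=kind)
    for fid, prof in profiles.items():
        ds.add_feature(
            Feature(id=fid, omic=name, profile=prof, is_significant=fid in significant)
        )
    return ds


@pytest.fixture
def chain_db() -> PathwayDatabase:
    """A(cpd)-g1-B(cpd)-g2 chain in one pathway."""
    pw = Pathway(
        id="chain",
        name="chain pathway",
        source_db="custom",
        nodes=[
            PathwayNode("A", NodeKind.COMPOUND, ["A"]),
            PathwayNode("g1", NodeKind.GENE, ["g1"]),
            PathwayNode("B", NodeKind.COMPOUND, ["B"]),
            PathwayNode("g2", NodeKind.GENE, ["g2"]),
        ],
        edges=[("A", "g1"), ("g1", "B"), ("B", "g2")],
    )
    return PathwayDatabase(pathways=[pw])


@pytest.fixture
def chain_datasets() -> tuple[OmicsDataset, OmicsDataset]:
    expr = make_dataset(
        "transcriptomics",
        {"g1": [1.0, 2.0], "g2": [2.0, 1.0]},
        significant={"g1"},
    )
    mets = make_dataset(
        "metabolomics",
        {"A": [0.5, 0.6], "B": [0.1, 0.2]},
        significant={"A", "B"},
        kind=FeatureKind.COMPOUND,
    )
    return expr, mets
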