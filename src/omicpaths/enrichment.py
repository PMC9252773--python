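"""Multi-omics pathway enrichment.

Each omics layer contributes a one-sided hypergeometric over-representation
P-value per pathway (significant vs measured features mapped to the
pathway, against the layer's background). Layer P-values are merged with
Fisher's combined probability test (−2 Σ ln pᵢ ~ χ²(2m)), so the degrees
of freedom vary with the number of layers actually represented in the
pathway; a layer with no mapped measured feature contributes nothing
rather than an imputed P = 1. Benjamini–Hochberg correction is applied
across pathways within each source database, because pathway definitions
overlap heavily between databases.

The background for a layer defaults to its features mapped to ≥1 pathway
of the selected databases ("annotated"); ``background="measured"`` uses
every measured feature instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .errors import ConfigurationError
from .graph import map_features, pathway_feature_ids
from .model import OmicsDataset, PathwayDatabase
from .stats import (
    ContingencyCounts,
    adjust_bh,
    combine_pvalues_fisher,
    fisher_exact_enrichment,
)

BACKGROUND_MODES = ("annotated", "measured")


@dataclass
class EnrichmentRecord:
    pathway_id: str
    name: str
    source_db: str
    category: str
    layer_pvalues: dict[str, float] = field(default_factory=dict)
    layer_counts: dict[str, ContingencyCounts] = field(default_factory=dict)
    combined_p: float = 1.0
    adjusted_p: float = 1.0


def run_pathway_enrichment(
    db: PathwayDatabase,
    datasets: Sequence[OmicsDataset],
    background: str = "annotated",
    databases: Sequence[str] | None = None,
) -> list[EnrichmentRecord]:
    """Per-pathway, per-layer enrichment with Fisher-combined P-values.

    Returns records sorted by BH-adjusted combined P ascending, ties broken
    by pathway id. Emits a warning and returns an empty list when no
    pathway has any mapped measured feature.
    """
    if background not in BACKGROUND_MODES:
        raise ConfigurationError(
            f"background must be one of {BACKGROUND_MODES}, got {background!r}"
        )
    pathways = db.select(databases)
    if not pathways:
        raise ConfigurationError("pathway database selection is empty")

    mapping = map_features(db, datasets, databases)
    backgrounds: dict[str, tuple[set[str], set[str]]] = {}
    for ds in datasets:
        if background == "annotated":
            universe = mapping.per_layer[ds.name].mapped_ids
        else:
            universe = ds.ids
        backgrounds[ds.name] = (universe, universe & ds.significant_ids)

    records: list[EnrichmentRecord] = []
    for pw in pathways:
        rec = EnrichmentRecord(
            pathway_id=pw.id, name=pw.name, source_db=pw.source_db, category=pw.category
        )
        for ds in datasets:
            universe, sig_universe = backgrounds[ds.name]
            in_pathway = pathway_feature_ids(pw, ds) & universe
            if not in_pathway:
                continue  # layer absent from this pathway: no P-value
            counts = ContingencyCounts(
                k=len(in_pathway & sig_universe),
                n=len(in_pathway),
                K=len(sig_universe),
                N=len(universe),
            )
            rec.layer_counts[ds.name] = counts
            rec.layer_pvalues[ds.name] = fisher_exact_enrichment(counts)
        if rec.layer_pvalues:
            rec.combined_p = combine_pvalues_fisher(list(rec.layer_pvalues.values()))
            records.append(rec)

    if not records:
        warnings.warn(
            "no pathway has any mapped measured feature; nothing to test",
            RuntimeWarning,
            stacklevel=2,
        )
        return []

    # BH within each source database
    for db_name in {r.source_db for r in records}:
        group = [r for r in records if r.source_db == db_name]
        adjusted = adjust_bh([r.combined_p for r in group])
        for rec, adj in zip(group, adjusted):
            rec.adjusted_p = float(adj)

    records.sort(key=lambda r: (r.adjusted_p, r.combined_p, r.pathway_id))
    return records


def enrichment_frame(
    records: Sequence[EnrichmentRecord], layers: Sequence[str]
) -> pd.DataFrame:
    """Tabulate records: one row per pathway, per-layer P and k/n/K/N columns."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "pathway_id": r.pathway_id,
            "name": r.name,
            "database": r.source_db,
            "category": r.category,
        }
        for layer in layers:
            row[f"p_{layer}"] = r.layer_pvalues.get(layer)
            c = r.layer_counts.get(layer)
            row[f"k_{layer}"] = c.k if c else None
            row[f"n_{layer}"] = c.n if c else None
            row[f"K_{layer}"] = c.K if c else None
            row[f"N_{layer}"] = c.N if c else None
        row["combined_p"] = r.combined_p
        row["adjusted_p"] = r.adjusted_p
        rows.append(row)
    return pd.DataFrame(rows)
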