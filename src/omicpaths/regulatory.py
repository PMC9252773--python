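"""Trans-regulatory omics: target mapping, correlation filtering, enrichment.

Trans-acting regulators (miRNAs, transcription factors, RNA-binding
proteins, splicing factors) are linked to their target genes/proteins by
a user-supplied mapping. Pairs are filtered by the signed correlation of
regulator and target profiles across shared conditions — positive,
negative, or two-sided — keeping only relationships consistent with the
expected regulatory sign (e.g. miRNA–target pairs are expected to
anti-correlate). Retained pairs feed a pathway-level enrichment score in
two modes: counting regulators mapping to each pathway, or counting
regulated genes present in the pathway; both are realized as one-sided
hypergeometric tests over the corresponding universe, BH-corrected across
pathways.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, ValidationError
from .graph import node_member_ids
from .io import read_two_column_tsv
from .model import NodeKind, OmicsDataset, PathwayDatabase
from .stats import ContingencyCounts, adjust_bh, fisher_exact_enrichment

METHODS = ("pearson", "spearman")
FILTER_MODES = ("positive", "negative", "both")
ENRICH_MODES = ("regulators", "targets")
MIN_COMPLETE_PAIRS = 3


def read_regulator_mapping(path: str | Path) -> list[tuple[str, str]]:
    """Read the user-supplied regulator→target mapping (two-column TSV)."""
    return read_two_column_tsv(path, what="regulator/target")


@dataclass
class RegulatorTargetPair:
    regulator: str
    target: str
    correlation: float | None
    retained: bool
    reason: str = ""


def _pairwise_correlation(
    x: np.ndarray, y: np.ndarray, method: str
) -> tuple[float | None, str]:
    """Correlation over pairwise-complete observations, or a refusal reason."""
    mask = ~(np.isnan(x) | np.isnan(y))
    if int(mask.sum()) < MIN_COMPLETE_PAIRS:
        return None, "fewer than 3 complete condition pairs"
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
        return None, "zero variance"
    if method == "pearson":
        r = sps.pearsonr(xs, ys).statistic
    else:
        r = sps.spearmanr(xs, ys).statistic
    if math.isnan(r):
        return None, "undefined correlation"
    return float(r), ""


def correlation_filter(
    regulator_ds: OmicsDataset,
    target_ds: OmicsDataset,
    pairs: Iterable[tuple[str, str]],
    method: str = "pearson",
    mode: str = "both",
    threshold: float = 0.7,
) -> list[RegulatorTargetPair]:
    """Retain regulator–target pairs whose profile correlation passes the filter.

    Correlations are computed across the conditions shared (by label)
    between the two layers, pairwise-complete over missing values. A pair
    is retained iff r ≥ t (positive mode), r ≤ −t (negative mode), or
    |r| ≥ t (both). Pairs with an unmeasured member, fewer than 3
    complete pairs, or zero variance are kept in the output, unretained,
    with the reason recorded.
    """
    if method not in METHODS:
        raise ConfigurationError(f"method must be one of {METHODS}, got {method!r}")
    if mode not in FILTER_MODES:
        raise ConfigurationError(f"mode must be one of {FILTER_MODES}, got {mode!r}")
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError(f"threshold must be in [0, 1], got {threshold}")

    shared = [c for c in regulator_ds.conditions if c in set(target_ds.conditions)]
    if not shared:
        raise ConfigurationError(
            "regulator and target layers share no condition labels"
        )
    r_idx = [regulator_ds.conditions.index(c) for c in shared]
    t_idx = [target_ds.conditions.index(c) for c in shared]

    out: list[RegulatorTargetPair] = []
    for reg, tgt in pairs:
        if reg not in regulator_ds:
            out.append(RegulatorTargetPair(reg, tgt, None, False, "regulator unmeasured"))
            continue
        if tgt not in target_ds:
            out.append(RegulatorTargetPair(reg, tgt, None, False, "target unmeasured"))
            continue
        x = regulator_ds[reg].profile[r_idx]
        y = target_ds[tgt].profile[t_idx]
        r, reason = _pairwise_correlation(x, y, method)
        if r is None:
            out.append(RegulatorTargetPair(reg, tgt, None, False, reason))
            continue
        if mode == "positive":
            keep = r >= threshold
        elif mode == "negative":
            keep = r <= -threshold
        else:
            keep = abs(r) >= threshold
        out.append(
            RegulatorTargetPair(
                reg, tgt, r, keep, "" if keep else "correlation below threshold"
            )
        )
    return out


@dataclass
class RegulatoryEnrichmentRecord:
    pathway_id: str
    name: str
    source_db: str
    mode: str
    counts: ContingencyCounts
    p: float
    adjusted_p: float = 1.0


def _gene_node_members(db: PathwayDatabase, databases=None) -> dict[str, set[str]]:
    """pathway id -> ids matchable through the pathway's gene nodes."""
    out: dict[str, set[str]] = {}
    for pw in db.select(databases):
        ids: set[str] = set()
        for node in pw.nodes_of_kind(NodeKind.GENE):
            ids |= node_member_ids(node)
        out[pw.id] = ids
    return out


def regulatory_pathway_enrichment(
    db: PathwayDatabase,
    retained_pairs: Sequence[RegulatorTargetPair],
    significant_regulators: Iterable[str] | None = None,
    mode: str = "regulators",
    databases: Sequence[str] | None = None,
) -> list[RegulatoryEnrichmentRecord]:
    """Pathway enrichment of the retained regulatory relationships.

    mode="regulators": universe = regulators with ≥1 retained target
    mapping to any pathway; significant = membership in
    ``significant_regulators``; a pathway's draw is the regulators with
    ≥1 retained target inside it. mode="targets": the same construction
    over target features, where a target counts as significant when at
    least one of its retained regulators is significant. Targets reach
    pathways through gene nodes only.
    """
    if mode not in ENRICH_MODES:
        raise ConfigurationError(f"mode must be one of {ENRICH_MODES}, got {mode!r}")
    kept = [p for p in retained_pairs if p.retained]
    if not kept:
        raise ConfigurationError("no retained regulator–target pairs")
    sig_regs = set(significant_regulators or ())
    if mode == "regulators" and not sig_regs:
        raise ConfigurationError(
            "mode='regulators' requires a non-empty significant regulator list"
        )

    pw_members = _gene_node_members(db, databases)
    target_pathways: dict[str, set[str]] = {}
    for pair in kept:
        hits = {pid for pid, members in pw_members.items() if pair.target in members}
        if hits:
            target_pathways.setdefault(pair.target, set()).update(hits)

    if mode == "regulators":
        entity_pathways: dict[str, set[str]] = {}
        for pair in kept:
            if pair.target in target_pathways:
                entity_pathways.setdefault(pair.regulator, set()).update(
                    target_pathways[pair.target]
                )
        significant_entities = set(entity_pathways) & sig_regs
    else:
        entity_pathways = dict(target_pathways)
        regulated_by_sig = {p.target for p in kept if p.regulator in sig_regs}
        significant_entities = set(entity_pathways) & regulated_by_sig

    if not entity_pathways:
        raise ConfigurationError(
            "no retained pair maps to any pathway through gene nodes"
        )

    N = len(entity_pathways)
    K = len(significant_entities)
    records: list[RegulatoryEnrichmentRecord] = []
    for pw in db.select(databases):
        in_pw = {e for e, pws in entity_pathways.items() if pw.id in pws}
        if not in_pw:
            continue
        counts = ContingencyCounts(
            k=len(in_pw & significant_entities), n=len(in_pw), K=K, N=N
        )
        records.append(
            RegulatoryEnrichmentRecord(
                pathway_id=pw.id,
                name=pw.name,
                source_db=pw.source_db,
                mode=mode,
                counts=counts,
                p=fisher_exact_enrichment(counts),
            )
        )
    adjusted = adjust_bh([r.p for r in records])
    for rec, adj in zip(records, adjusted):
        rec.adjusted_p = float(adj)
    records.sort(key=lambda r: (r.adjusted_p, r.p, r.pathway_id))
    return records


def pairs_frame(pairs: Sequence[RegulatorTargetPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "regulator": p.regulator,
                "target": p.target,
                "r": p.correlation,
                "retained": p.retained,
                "reason": p.reason,
            }
            for p in pairs
        ],
        columns=["regulator", "target", "r", "retained", "reason"],
    )


def regulatory_frame(records: Sequence[RegulatoryEnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "name": r.name,
                "database": r.source_db,
                "mode": r.mode,
                "k": r.counts.k,
                "n": r.counts.n,
                "K": r.counts.K,
                "N": r.counts.N,
                "p": r.p,
                "adjusted_p": r.adjusted_p,
            }
            for r in records
        ]
    )
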