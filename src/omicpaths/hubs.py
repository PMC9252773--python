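"""Metabolite hub analysis.

For each differentially expressed metabolite (DEM), ask whether the genes
in its proximal network are unexpectedly rich in differentially expressed
genes (DEGs). The step-s neighborhood of a compound is every gene node
within shortest-path distance s over the undirected heterogeneous graph
(s = 1: directly connected; s = 2..4: up to s − 1 intermediate nodes of
any kind). Two complementary tests are run:

* exact binomial — with p₀ the global DEG proportion, the upper tail
  P(X ≥ deg_count), X ~ Binomial(n_measured, p₀); only measured genes
  enter n because DEG status is undefined for unmeasured neighbors;
* network percentile — the midrank percentile of the metabolite's
  neighborhood DEG proportion within the distribution of that proportion
  over every compound node in the graph (compounds with no measured
  neighbor are excluded from the distribution).

Binomial P-values are BH-corrected across the tested metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import ConfigurationError, UndefinedTestError, ValidationError
from .model import MetabolicGraph, NodeKind, OmicsDataset
from .stats import adjust_bh, binomial_tail, midrank_percentile

MAX_STEP = 4
SCOPES = ("significant", "all")


@dataclass(frozen=True)
class Neighborhood:
    metabolite: str
    step: int
    genes: frozenset[str]
    measured_genes: frozenset[str]
    deg_count: int

    @property
    def proportion(self) -> float | None:
        if not self.measured_genes:
            return None
        return self.deg_count / len(self.measured_genes)


@dataclass
class HubResult:
    metabolite: str
    step: int
    n_genes: int
    n_measured: int
    deg_count: int
    proportion: float | None
    p0: float
    binomial_p: float | None
    adjusted_p: float | None
    percentile: float | None
    reason: str = ""


def _check_step(step: int) -> None:
    if not 1 <= step <= MAX_STEP:
        raise ValidationError(f"step must be in 1..{MAX_STEP}, got {step}")


def gene_neighborhood(
    graph: MetabolicGraph, metabolite: str, step: int
) -> Neighborhood:
    """Gene nodes within shortest-path distance ≤ step of a compound node."""
    _check_step(step)
    if metabolite not in graph.g:
        raise ValidationError(f"node {metabolite!r} not in graph")
    if not graph.is_compound(metabolite):
        raise ValidationError(f"node {metabolite!r} is not a compound")
    dists = nx.single_source_shortest_path_length(graph.g, metabolite, cutoff=step)
    genes = frozenset(
        n for n, d in dists.items() if d >= 1 and graph.kind(n) == NodeKind.GENE
    )
    measured = frozenset(n for n in genes if graph.is_measured(n))
    deg = sum(1 for n in measured if graph.is_significant(n))
    return Neighborhood(
        metabolite=metabolite,
        step=step,
        genes=genes,
        measured_genes=measured,
        deg_count=deg,
    )


def hub_binomial_test(deg_count: int, n_measured: int, p0: float) -> float:
    """Upper-tail exact binomial P for a neighborhood's DEG count."""
    if n_measured == 0:
        raise UndefinedTestError("no measured genes in neighborhood")
    return binomial_tail(deg_count, n_measured, p0)


def _compound_proportions(
    graph: MetabolicGraph, deg_set: set[str], step: int
) -> dict[str, float]:
    """Neighborhood DEG proportion for every compound with measured neighbors."""
    props: dict[str, float] = {}
    for cpd in graph.compound_ids():
        nb = gene_neighborhood(graph, cpd, step)
        if nb.measured_genes:
            hits = len(nb.measured_genes & deg_set)
            props[cpd] = hits / len(nb.measured_genes)
    return props


def network_percentile(
    graph: MetabolicGraph,
    deg_set: Iterable[str],
    metabolite: str,
    step: int,
) -> float:
    """Midrank percentile of a metabolite's DEG proportion in the network."""
    _check_step(step)
    deg = set(deg_set)
    props = _compound_proportions(graph, deg, step)
    if metabolite not in props:
        raise UndefinedTestError(
            f"metabolite {metabolite!r} has no measured neighboring gene at step {step}"
        )
    return midrank_percentile(props[metabolite], list(props.values()))


def run_hub_analysis(
    graph: MetabolicGraph,
    expression_dataset: OmicsDataset,
    metabolite_dataset: OmicsDataset,
    step: int,
    scope: str = "significant",
) -> list[HubResult]:
    """Binomial + percentile hub tests over the metabolites in scope.

    p₀ is the global DEG proportion of the expression layer. Scope
    defaults to significant metabolites (DEMs) only; ``scope="all"``
    tests every measured metabolite present in the graph. Metabolites
    with no measured neighboring gene are returned flagged, with no
    P-value, and excluded from the BH correction.
    """
    _check_step(step)
    if scope not in SCOPES:
        raise ConfigurationError(f"scope must be one of {SCOPES}, got {scope!r}")
    n_genes_measured = expression_dataset.n_features
    if n_genes_measured == 0:
        raise ConfigurationError("expression layer has no measured genes")
    n_deg = len(expression_dataset.significant_ids)
    p0 = n_deg / n_genes_measured
    if not 0.0 < p0 < 1.0:
        raise ConfigurationError(
            f"global DEG proportion p0 = {p0} leaves the binomial test undefined; "
            "the expression layer must contain both significant and "
            "non-significant genes"
        )

    if scope == "significant":
        wanted = metabolite_dataset.significant_ids
    else:
        wanted = metabolite_dataset.ids
    targets = sorted(m for m in wanted if graph.is_compound(m))

    deg_nodes = {g for g in graph.gene_ids() if graph.is_significant(g)}
    props = _compound_proportions(graph, deg_nodes, step)
    ref = list(props.values())

    results: list[HubResult] = []
    for met in targets:
        nb = gene_neighborhood(graph, met, step)
        if not nb.measured_genes:
            results.append(
                HubResult(
                    metabolite=met,
                    step=step,
                    n_genes=len(nb.genes),
                    n_measured=0,
                    deg_count=0,
                    proportion=None,
                    p0=p0,
                    binomial_p=None,
                    adjusted_p=None,
                    percentile=None,
                    reason="no measured neighboring genes",
                )
            )
            continue
        p = hub_binomial_test(nb.deg_count, len(nb.measured_genes), p0)
        pct = midrank_percentile(props[met], ref)
        results.append(
            HubResult(
                metabolite=met,
                step=step,
                n_genes=len(nb.genes),
                n_measured=len(nb.measured_genes),
                deg_count=nb.deg_count,
                proportion=nb.proportion,
                p0=p0,
                binomial_p=p,
                adjusted_p=None,
                percentile=pct,
            )
        )

    tested = [r for r in results if r.binomial_p is not None]
    if tested:
        adjusted = adjust_bh([r.binomial_p for r in tested])
        for r, adj in zip(tested, adjusted):
            r.adjusted_p = float(adj)

    results.sort(
        key=lambda r: (
            r.adjusted_p if r.adjusted_p is not None else 2.0,
            r.binomial_p if r.binomial_p is not None else 2.0,
            -(r.percentile if r.percentile is not None else -1.0),
            r.metabolite,
        )
    )
    return results


def hub_results_frame(results: Sequence[HubResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metabolite_id": r.metabolite,
                "step": r.step,
                "n_genes": r.n_genes,
                "n_measured": r.n_measured,
                "deg_count": r.deg_count,
                "proportion": r.proportion,
                "p0": r.p0,
                "binomial_p": r.binomial_p,
                "adjusted_p": r.adjusted_p,
                "percentile": r.percentile,
                "note": r.reason,
            }
            for r in results
        ]
    )


def neighbor_pairs_frame(
    graph: MetabolicGraph, results: Sequence[HubResult]
) -> pd.DataFrame:
    """Companion metabolite→neighbor-gene pair table for navigation."""
    rows = []
    for r in results:
        nb = gene_neighborhood(graph, r.metabolite, r.step)
        for gene in sorted(nb.genes):
            rows.append(
                {
                    "metabolite_id": r.metabolite,
                    "gene_id": gene,
                    "measured": gene in nb.measured_genes,
                    "significant": gene in nb.measured_genes
                    and graph.is_significant(gene),
                }
            )
    return pd.DataFrame(rows, columns=["metabolite_id", "gene_id", "measured", "significant"])
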