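"""Seeded synthetic multi-omics fixture generator with planted signal.

Generates a pathway database, gene-expression / metabolite / regulator
matrices, relevant-feature lists, a regulator→target map and a metabolite
class map — everything the analysis modules consume — with exact
bookkeeping (``truth``) of what was planted where, so recovery can be
verified without external downloads.

Topology: each pathway is a gene–compound bipartite chain with random
chord edges; compounds are drawn with some probability from the pool of
compounds already created, so pathways merge on shared compounds and the
union graph acquires realistic hub structure without degree-sequence
fitting. Background significance is i.i.d. Bernoulli at the configured
rates; planted effects locally raise those rates (hub, class, pathway),
inject two anti-correlated profile patterns into one dense node
(metagene), or concentrate the targets of significant regulators into
one pathway with near-perfect profile correlation (regulatory).

One pseudo-random stream per concern, derived from the master seed, so
adding outputs never perturbs existing ones; the same spec always yields
byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import write_pathway_json
from .model import (
    Feature,
    FeatureKind,
    NodeKind,
    OmicsDataset,
    Pathway,
    PathwayDatabase,
    PathwayNode,
)

PLANT_KINDS = ("hub", "class", "pathway", "metagene", "regulatory")

# fixed stream order; append-only so existing outputs never shift
_STREAMS = (
    "topology",
    "plants",
    "significance",
    "expression",
    "metabolites",
    "regulators",
    "classes",
)


@dataclass
class PlantedEffect:
    kind: str
    location: str | None = None  # node/pathway/class id; None = auto-pick
    strength: float = 0.6
    size: int | None = None  # hub: min measured step-1 genes; metagene: members

    def __post_init__(self) -> None:
        if self.kind not in PLANT_KINDS:
            raise ValidationError(f"unknown planted effect kind {self.kind!r}")


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_pathways: int = 20
    genes_per_pathway: tuple[int, int] = (6, 12)
    compounds_per_pathway: tuple[int, int] = (4, 8)
    n_conditions: int = 6
    deg_rate: float = 0.1  # background DEG proportion p0
    dem_rate: float = 0.3  # background DEM proportion
    n_regulators: int = 10
    targets_per_regulator: int = 6
    regulator_sig_rate: float = 0.4
    n_classes: int = 5
    chord_probability: float = 0.04
    compound_share_rate: float = 0.25
    n_unmapped_genes: int = 15
    effect_amplitude: float = 2.0
    noise_sd: float = 1.0
    planted: list[PlantedEffect] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rate in (self.deg_rate, self.dem_rate, self.regulator_sig_rate):
            if not 0.0 < rate < 1.0:
                raise ValidationError(f"rates must lie in (0, 1), got {rate}")
        if self.n_pathways < 1 or self.n_conditions < 1:
            raise ValidationError("need at least one pathway and one condition")


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    db: PathwayDatabase
    expression: OmicsDataset
    metabolites: OmicsDataset
    regulators: OmicsDataset
    regulator_map: list[tuple[str, str]]
    class_map: dict[str, set[str]]
    truth: dict

    @property
    def datasets(self) -> list[OmicsDataset]:
        return [self.expression, self.metabolites, self.regulators]


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _plant(spec: FixtureSpec, kind: str) -> PlantedEffect | None:
    hits = [p for p in spec.planted if p.kind == kind]
    if len(hits) > 1:
        raise ValidationError(f"at most one {kind!r} effect may be planted")
    return hits[0] if hits else None


def _trend(n: int) -> np.ndarray:
    t = np.linspace(-1.0, 1.0, n)
    return (t - t.mean()) / (t.std() if t.std() > 0 else 1.0)


def _bump(n: int) -> np.ndarray:
    u = np.sin(np.linspace(0.0, np.pi, n))
    sd = u.std()
    return (u - u.mean()) / (sd if sd > 0 else 1.0)


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Build the whole fixture in memory; see :func:`simulate` to write it."""
    rng = _rngs(spec.seed)
    truth: dict = {"planted": {}, "seed": spec.seed}

    # ------------------------------------------------------------------ topology
    top = rng["topology"]
    pathways: list[Pathway] = []
    gene_counter = 0
    cpd_counter = 0
    compound_pool: list[str] = []
    pathway_genes: dict[str, list[str]] = {}
    pathway_compounds: dict[str, list[str]] = {}

    for i in range(spec.n_pathways):
        pid = f"pw{i + 1:03d}"
        n_g = int(top.integers(spec.genes_per_pathway[0], spec.genes_per_pathway[1] + 1))
        n_c = int(
            top.integers(spec.compounds_per_pathway[0], spec.compounds_per_pathway[1] + 1)
        )
        genes = []
        for _ in range(n_g):
            gene_counter += 1
            genes.append(f"g{gene_counter:04d}")
        compounds: list[str] = []
        for _ in range(n_c):
            reused = None
            if compound_pool and top.random() < spec.compound_share_rate:
                cand = compound_pool[int(top.integers(len(compound_pool)))]
                if cand not in compounds:
                    reused = cand
            if reused is None:
                cpd_counter += 1
                reused = f"c{cpd_counter:03d}"
                compound_pool.append(reused)
            compounds.append(reused)

        edges: set[tuple[str, str]] = set()

        def add_edge(a: str, b: str) -> None:
            if a != b:
                edges.add((a, b) if a <= b else (b, a))

        # bipartite chain g1-c1-g2-c2-..., leftovers attached randomly
        chain = min(len(genes), len(compounds))
        for j in range(chain):
            add_edge(genes[j], compounds[j])
            if j + 1 < len(genes):
                add_edge(genes[j + 1], compounds[j])
        for g in genes[chain:]:
            add_edge(g, compounds[int(top.integers(len(compounds)))])
        for c in compounds[chain:]:
            add_edge(genes[int(top.integers(len(genes)))], c)
        for g in genes:  # random chords
            for c in compounds:
                if top.random() < spec.chord_probability:
                    add_edge(g, c)

        nodes = [PathwayNode(id=g, kind=NodeKind.GENE, members=[g]) for g in genes]
        nodes += [PathwayNode(id=c, kind=NodeKind.COMPOUND, members=[c]) for c in compounds]
        pathways.append(
            Pathway(
                id=pid,
                name=f"synthetic pathway {i + 1}",
                source_db="synthetic",
                category=f"category {(i % 4) + 1}",
                nodes=nodes,
                edges=sorted(edges),
            )
        )
        pathway_genes[pid] = genes
        pathway_compounds[pid] = compounds

    all_genes: list[str] = [g for pid in pathway_genes for g in pathway_genes[pid]]
    all_compounds: list[str] = []
    for pid in pathway_compounds:
        for c in pathway_compounds[pid]:
            if c not in all_compounds:
                all_compounds.append(c)
    unmapped_genes = [f"gx{i + 1:03d}" for i in range(spec.n_unmapped_genes)]

    # ------------------------------------------------------------------ plants
    pl = rng["plants"]
    C = spec.n_conditions

    metagene_members: dict[str, int] = {}  # feature id -> +1/-1 pattern sign
    mg_effect = _plant(spec, "metagene")
    if mg_effect is not None:
        pid = mg_effect.location or pathways[0].id
        pw = next(p for p in pathways if p.id == pid)
        size = mg_effect.size or 6
        node_id = f"{pid}_complex"
        members = [f"mg{j + 1:02d}" for j in range(size)]
        pw.nodes.append(PathwayNode(id=node_id, kind=NodeKind.GENE, members=members))
        anchor = pathway_compounds[pid][0]
        pw.edges.append((node_id, anchor) if node_id <= anchor else (anchor, node_id))
        for j, m in enumerate(members):
            metagene_members[m] = 1 if j < (size + 1) // 2 else -1
        truth["planted"]["metagene"] = {
            "pathway": pid,
            "node": node_id,
            "members_positive": [m for m, s in metagene_members.items() if s > 0],
            "members_negative": [m for m, s in metagene_members.items() if s < 0],
            "pattern": _bump(C).tolist(),
            "noise_sd": 1.0 - mg_effect.strength if mg_effect.strength < 1 else 0.05,
        }

    # per-gene DEG rates, overridden by pathway then hub plants
    deg_rate: dict[str, float] = {
        g: spec.deg_rate for g in all_genes + unmapped_genes + list(metagene_members)
    }

    pw_effect = _plant(spec, "pathway")
    if pw_effect is not None:
        # auto-pick: the pathway with the most genes (mirrors the hub
        # plant's max-degree pick) so the perturbation is well populated
        pid = pw_effect.location or max(
            pathway_genes, key=lambda p: (len(pathway_genes[p]), p)
        )
        if pid not in pathway_genes:
            raise ValidationError(f"planted pathway {pid!r} does not exist")
        for g in pathway_genes[pid]:
            deg_rate[g] = pw_effect.strength
        truth["planted"]["pathway"] = {
            "pathway": pid,
            "strength": pw_effect.strength,
            "genes": list(pathway_genes[pid]),
        }

    hub_effect = _plant(spec, "hub")
    hub_compound: str | None = None
    if hub_effect is not None:
        # degree over gene partners in the merged graph
        partners: dict[str, set[str]] = {c: set() for c in all_compounds}
        for pw in pathways:
            kinds = {n.id: n.kind for n in pw.nodes}
            for a, b in pw.edges:
                if kinds[a] == NodeKind.COMPOUND and kinds[b] == NodeKind.GENE:
                    partners[a].add(b)
                elif kinds[b] == NodeKind.COMPOUND and kinds[a] == NodeKind.GENE:
                    partners[b].add(a)
        if hub_effect.location is not None:
            hub_compound = hub_effect.location
            if hub_compound not in partners:
                raise ValidationError(f"planted hub {hub_compound!r} does not exist")
        else:
            hub_compound = max(partners, key=lambda c: (len(partners[c]), c))
        want = hub_effect.size or 15
        home = next(p for p in pathways if hub_compound in pathway_compounds[p.id])
        candidates = [g for g in all_genes if g not in partners[hub_compound]]
        while len(partners[hub_compound]) < want and candidates:
            g = candidates.pop(int(pl.integers(len(candidates))))
            partners[hub_compound].add(g)
            if g not in pathway_genes[home.id]:
                home.nodes.append(PathwayNode(id=g, kind=NodeKind.GENE, members=[g]))
                pathway_genes[home.id].append(g)
            edge = (g, hub_compound) if g <= hub_compound else (hub_compound, g)
            if edge not in home.edges:
                home.edges.append(edge)
        step1 = sorted(partners[hub_compound])
        for g in step1:
            deg_rate[g] = hub_effect.strength
        truth["planted"]["hub"] = {
            "compound": hub_compound,
            "strength": hub_effect.strength,
            "step1_genes": step1,
        }

    # ------------------------------------------------------------------ classes
    cls_rng = rng["classes"]
    shuffled = list(all_compounds)
    cls_rng.shuffle(shuffled)
    class_map: dict[str, set[str]] = {
        f"class{j + 1:02d}": set() for j in range(spec.n_classes)
    }
    names = sorted(class_map)
    for idx, cpd in enumerate(shuffled):
        class_map[names[idx % spec.n_classes]].add(cpd)

    dem_rate: dict[str, float] = {c: spec.dem_rate for c in all_compounds}
    cls_effect = _plant(spec, "class")
    if cls_effect is not None:
        cname = cls_effect.location or names[0]
        if cname not in class_map:
            raise ValidationError(f"planted class {cname!r} does not exist")
        for cpd in class_map[cname]:
            dem_rate[cpd] = cls_effect.strength
        truth["planted"]["class"] = {
            "class": cname,
            "strength": cls_effect.strength,
            "members": sorted(class_map[cname]),
        }

    # ------------------------------------------------------------------ significance
    sig = rng["significance"]
    gene_ids = all_genes + list(metagene_members) + unmapped_genes
    deg = {g for g in gene_ids if sig.random() < deg_rate[g]}
    dem = {c for c in all_compounds if sig.random() < dem_rate[c]}
    if hub_compound is not None:
        dem.add(hub_compound)  # the hub question is asked of a DEM

    # ------------------------------------------------------------------ regulators
    reg_rng = rng["regulators"]
    reg_ids = [f"r{j + 1:02d}" for j in range(spec.n_regulators)]
    sig_regs = {r for r in reg_ids if reg_rng.random() < spec.regulator_sig_rate}
    reg_effect = _plant(spec, "regulatory")
    if reg_effect is not None and not sig_regs:
        sig_regs = {reg_ids[0]}
    reg_profiles = {r: reg_rng.normal(0.0, 1.0, C) for r in reg_ids}

    regulator_map: list[tuple[str, str]] = []
    forced_targets: dict[str, str] = {}  # target gene -> regulator to mimic
    if reg_effect is not None:
        pid = reg_effect.location or pathways[len(pathways) // 2].id
        if pid not in pathway_genes:
            raise ValidationError(f"planted regulatory pathway {pid!r} does not exist")
        pool = list(pathway_genes[pid])
        for r in reg_ids:
            if r in sig_regs:
                take = min(spec.targets_per_regulator, len(pool))
                targets = [
                    pool[i] for i in reg_rng.choice(len(pool), take, replace=False)
                ]
                for t in targets:
                    forced_targets.setdefault(t, r)
            else:
                targets = [
                    all_genes[i]
                    for i in reg_rng.choice(
                        len(all_genes), spec.targets_per_regulator, replace=False
                    )
                ]
            regulator_map.extend((r, t) for t in targets)
        truth["planted"]["regulatory"] = {
            "pathway": pid,
            "significant_regulators": sorted(sig_regs),
            "targets": sorted(forced_targets),
        }
    else:
        for r in reg_ids:
            targets = [
                all_genes[i]
                for i in reg_rng.choice(
                    len(all_genes), spec.targets_per_regulator, replace=False
                )
            ]
            regulator_map.extend((r, t) for t in targets)

    # ------------------------------------------------------------------ matrices
    conditions = [f"t{j}" for j in range(C)]
    trend = _trend(C)
    bump = _bump(C)

    expr_rng = rng["expression"]
    expression = OmicsDataset(
        name="transcriptomics", conditions=conditions, feature_kind=FeatureKind.GENE
    )
    mg_noise = (
        truth["planted"]["metagene"]["noise_sd"] if "metagene" in truth["planted"] else 0.05
    )
    for g in gene_ids:
        if g in metagene_members:
            profile = metagene_members[g] * bump + expr_rng.normal(0.0, mg_noise, C)
        elif g in forced_targets:
            profile = reg_profiles[forced_targets[g]] + expr_rng.normal(0.0, 0.1, C)
        elif g in deg:
            sign = 1.0 if expr_rng.random() < 0.5 else -1.0
            profile = sign * spec.effect_amplitude * trend + expr_rng.normal(
                0.0, 0.5 * spec.noise_sd, C
            )
        else:
            profile = expr_rng.normal(0.0, spec.noise_sd, C)
        expression.add_feature(
            Feature(id=g, omic=expression.name, profile=profile, is_significant=g in deg)
        )

    met_rng = rng["metabolites"]
    metabolites = OmicsDataset(
        name="metabolomics", conditions=conditions, feature_kind=FeatureKind.COMPOUND
    )
    for c in all_compounds:
        if c in dem:
            sign = 1.0 if met_rng.random() < 0.5 else -1.0
            profile = sign * spec.effect_amplitude * trend + met_rng.normal(
                0.0, 0.5 * spec.noise_sd, C
            )
        else:
            profile = met_rng.normal(0.0, spec.noise_sd, C)
        metabolites.add_feature(
            Feature(id=c, omic=metabolites.name, profile=profile, is_significant=c in dem)
        )

    regulators = OmicsDataset(
        name="regulators", conditions=conditions, feature_kind=FeatureKind.REGULATOR
    )
    for r in reg_ids:
        regulators.add_feature(
            Feature(
                id=r,
                omic=regulators.name,
                profile=reg_profiles[r],
                is_significant=r in sig_regs,
            )
        )

    db = PathwayDatabase(pathways=pathways)

    # ------------------------------------------------------------------ bookkeeping
    node_kind: dict[str, NodeKind] = {}
    edge_set: set[tuple[str, str]] = set()
    for pw in pathways:
        for n in pw.nodes:
            node_kind[n.id] = n.kind
        for a, b in pw.edges:
            if a != b:
                edge_set.add((a, b) if a <= b else (b, a))
    truth["graph"] = {
        "n_nodes": len(node_kind),
        "n_gene_nodes": sum(1 for k in node_kind.values() if k == NodeKind.GENE),
        "n_compound_nodes": sum(
            1 for k in node_kind.values() if k == NodeKind.COMPOUND
        ),
        "n_edges": len(edge_set),
    }
    truth["expression"] = {
        "n_measured": expression.n_features,
        "n_significant": len(deg),
        "p0": len(deg) / expression.n_features,
    }
    truth["metabolites"] = {
        "n_measured": metabolites.n_features,
        "n_significant": len(dem),
        "rate": len(dem) / metabolites.n_features,
    }
    if hub_compound is not None:
        step1 = truth["planted"]["hub"]["step1_genes"]
        realized = sum(1 for g in step1 if g in deg)
        truth["planted"]["hub"].update(
            {
                "n_measured": len(step1),
                "deg_count": realized,
                "realized_fraction": realized / len(step1) if step1 else None,
            }
        )
    if "pathway" in truth["planted"]:
        genes = truth["planted"]["pathway"]["genes"]
        truth["planted"]["pathway"].update(
            {
                "n_genes": len(genes),
                "deg_count": sum(1 for g in genes if g in deg),
            }
        )
    if "class" in truth["planted"]:
        members = truth["planted"]["class"]["members"]
        truth["planted"]["class"].update(
            {
                "n_measured": len(members),
                "dem_count": sum(1 for c in members if c in dem),
            }
        )

    return FixtureBundle(
        spec=spec,
        db=db,
        expression=expression,
        metabolites=metabolites,
        regulators=regulators,
        regulator_map=regulator_map,
        class_map=class_map,
        truth=truth,
    )


def _write_matrix(ds: OmicsDataset, path: Path) -> None:
    ds.to_frame().to_csv(
        path, sep="\t", na_rep="NA", float_format="%.6f", index_label="feature_id"
    )


def _write_list(ids: Sequence[str], path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        for fid in sorted(ids):
            fh.write(fid + "\n")


def write_fixture(bundle: FixtureBundle, outdir: str | Path) -> dict:
    """Write every fixture file; returns the truth record (also saved)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_matrix(bundle.expression, outdir / "transcriptomics.tsv")
    _write_matrix(bundle.metabolites, outdir / "metabolomics.tsv")
    _write_matrix(bundle.regulators, outdir / "regulators.tsv")
    _write_list(bundle.expression.significant_ids, outdir / "transcriptomics_significant.txt")
    _write_list(bundle.metabolites.significant_ids, outdir / "metabolomics_significant.txt")
    _write_list(bundle.regulators.significant_ids, outdir / "regulators_significant.txt")
    write_pathway_json(bundle.db, outdir / "pathways.json")
    with (outdir / "regulator_map.tsv").open("w", encoding="utf-8") as fh:
        for reg, tgt in bundle.regulator_map:
            fh.write(f"{reg}\t{tgt}\n")
    with (outdir / "class_map.tsv").open("w", encoding="utf-8") as fh:
        for cls in sorted(bundle.class_map):
            for cpd in sorted(bundle.class_map[cls]):
                fh.write(f"{cpd}\t{cls}\n")
    with (outdir / "truth.json").open("w", encoding="utf-8") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return bundle.truth


def simulate(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Generate a fixture and write it to ``outdir``; returns the truth."""
    return write_fixture(generate(spec), outdir)
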