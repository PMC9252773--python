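import math

import numpy as np
import pytest

from omicpaths.errors import ConfigurationError
from omicpaths.model import FeatureKind, NodeKind, Pathway, PathwayDatabase, PathwayNode
from omicpaths.regulatory import (
    correlation_filter,
    read_regulator_mapping,
    regulatory_pathway_enrichment,
)
from omicpaths.simulate import FixtureSpec, PlantedEffect, generate
from tests.conftest import make_dataset


def _regs(profiles, significant=frozenset()):
    return make_dataset(
        "regulators", profiles, significant=significant, kind=FeatureKind.REGULATOR
    )


def _targets(profiles, significant=frozenset()):
    return make_dataset("transcriptomics", profiles, significant=significant)


def brute_force_pearson(x, y):
    """Independent recomputation from the definition (mean/cov/sd)."""
    pairs = [(a, b) for a, b in zip(x, y) if not (math.isnan(a) or math.isnan(b))]
    n = len(pairs)
    mx = sum(a for a, _ in pairs) / n
    my = sum(b for _, b in pairs) / n
    cov = sum((a - mx) * (b - my) for a, b in pairs)
    sx = math.sqrt(sum((a - mx) ** 2 for a, _ in pairs))
    sy = math.sqrt(sum((b - my) ** 2 for _, b in pairs))
    return cov / (sx * sy)


class TestMappingReader:
    def test_dedup_and_self_pairs(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("r1\tg1\nr1\tg1\nr2\tg2\nr2\tr2\n")
        pairs = read_regulator_mapping(p)
        assert pairs == [("r1", "g1"), ("r2", "g2"), ("r2", "r2")]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("")
        assert read_regulator_mapping(p) == []


class TestCorrelationFilter:
    def test_perfect_positive_collinearity(self):
        regs = _regs({"r1": [1.0, 2.0, 3.0]})
        tgts = _targets({"g1": [2.0, 4.0, 6.0]})
        out = correlation_filter(regs, tgts, [("r1", "g1")], mode="positive", threshold=0.9)
        assert out[0].retained and out[0].correlation == pytest.approx(1.0)

    def test_positive_pair_fails_negative_mode(self):
        regs = _regs({"r1": [1.0, 2.0, 3.0]})
        tgts = _targets({"g1": [2.0, 4.0, 6.0]})
        out = correlation_filter(regs, tgts, [("r1", "g1")], mode="negative", threshold=0.5)
        assert not out[0].retained

    def test_constant_target_flagged_zero_variance(self):
        regs = _regs({"r1": [1.0, 2.0, 3.0]})
        tgts = _targets({"g1": [5.0, 5.0, 5.0]})
        out = correlation_filter(regs, tgts, [("r1", "g1")])
        assert not out[0].retained
        assert out[0].correlation is None
        assert out[0].reason == "zero variance"

    def test_unmeasured_members_and_short_overlap_flagged(self):
        regs = _regs({"r1": [1.0, 2.0, float("nan")]})
        tgts = _targets({"g1": [1.0, 2.0, 3.0]})
        out = correlation_filter(
            regs, tgts, [("rX", "g1"), ("r1", "gX"), ("r1", "g1")]
        )
        reasons = {(p.regulator, p.target): p.reason for p in out}
        assert reasons[("rX", "g1")] == "regulator unmeasured"
        assert reasons[("r1", "gX")] == "target unmeasured"
        assert reasons[("r1", "g1")] == "fewer than 3 complete condition pairs"

    def test_no_shared_conditions_fatal(self):
        regs = _regs({"r1": [1.0, 2.0]})
        tgts = make_dataset(
            "transcriptomics", {"g1": [1.0, 2.0]}, conditions=["u0", "u1"]
        )
        with pytest.raises(ConfigurationError):
            correlation_filter(regs, tgts, [("r1", "g1")])

    def test_matches_brute_force_on_exhaustive_small_instances(self):
        rng = np.random.default_rng(99)
        profiles = {}
        for i in range(8):
            prof = rng.integers(-3, 4, 5).astype(float)
            if np.ptp(prof) == 0:
                prof[0] += 1.0
            profiles[f"f{i}"] = list(prof)
        regs = _regs({k: v for k, v in profiles.items() if k < "f4"})
        tgts = _targets({k: v for k, v in profiles.items() if k >= "f4"})
        pairs = [(r, t) for r in regs.ids for t in tgts.ids]
        for mode in ("positive", "negative", "both"):
            for t in (0.0, 0.3, 0.8):
                out = correlation_filter(regs, tgts, pairs, mode=mode, threshold=t)
                for p in out:
                    r = brute_force_pearson(
                        profiles[p.regulator], profiles[p.target]
                    )
                    assert p.correlation == pytest.approx(r, abs=1e-12)
                    expected = {
                        "positive": r >= t,
                        "negative": r <= -t,
                        "both": abs(r) >= t,
                    }[mode]
                    assert p.retained == expected

    def test_negating_regulators_swaps_positive_and_negative(self):
        rng = np.random.default_rng(4)
        reg_profiles = {f"r{i}": list(rng.normal(size=6)) for i in range(5)}
        tgt_profiles = {f"g{i}": list(rng.normal(size=6)) for i in range(5)}
        regs = _regs(reg_profiles)
        neg_regs = _regs({k: [-v for v in prof] for k, prof in reg_profiles.items()})
        tgts = _targets(tgt_profiles)
        pairs = [(r, t) for r in reg_profiles for t in tgt_profiles]
        pos = correlation_filter(regs, tgts, pairs, mode="positive", threshold=0.4)
        neg = correlation_filter(neg_regs, tgts, pairs, mode="negative", threshold=0.4)
        assert {(p.regulator, p.target) for p in pos if p.retained} == {
            (p.regulator, p.target) for p in neg if p.retained
        }


class TestRegulatoryEnrichment:
    def _db(self):
        p1 = Pathway(
            id="p1",
            name="p1",
            source_db="custom",
            nodes=[PathwayNode(g, NodeKind.GENE, [g]) for g in ("g1", "g2")],
        )
        p2 = Pathway(
            id="p2",
            name="p2",
            source_db="custom",
            nodes=[PathwayNode("g3", NodeKind.GENE, ["g3"])],
        )
        return PathwayDatabase(pathways=[p1, p2])

    def _retained(self, pairs):
        from omicpaths.regulatory import RegulatorTargetPair

        return [RegulatorTargetPair(r, t, 1.0, True) for r, t in pairs]

    def test_pathway_covering_all_targets_is_unenriched(self):
        db = PathwayDatabase(
            pathways=[
                Pathway(
                    id="p1",
                    name="p1",
                    source_db="custom",
                    nodes=[PathwayNode(g, NodeKind.GENE, [g]) for g in ("g1", "g2")],
                )
            ]
        )
        pairs = self._retained([("r1", "g1"), ("r2", "g2")])
        for mode in ("regulators", "targets"):
            recs = regulatory_pathway_enrichment(db, pairs, {"r1"}, mode=mode)
            assert recs[0].p == 1.0  # n = N: the draw is the whole universe

    def test_regulator_with_many_targets_counted_once(self):
        db = self._db()
        pairs = self._retained([("r1", "g1"), ("r1", "g2"), ("r2", "g3")])
        recs = regulatory_pathway_enrichment(db, pairs, {"r1"}, mode="regulators")
        p1 = next(r for r in recs if r.pathway_id == "p1")
        assert p1.counts.n == 1 and p1.counts.k == 1
        assert p1.counts.N == 2  # r1 and r2

    def test_empty_significant_set_fatal_in_regulator_mode(self):
        db = self._db()
        pairs = self._retained([("r1", "g1")])
        with pytest.raises(ConfigurationError):
            regulatory_pathway_enrichment(db, pairs, set(), mode="regulators")

    def test_planted_regulatory_pathway_is_top_ranked(self):
        bundle = generate(
            FixtureSpec(seed=31, planted=[PlantedEffect("regulatory", strength=0.9)])
        )
        filtered = correlation_filter(
            bundle.regulators,
            bundle.expression,
            bundle.regulator_map,
            mode="both",
            threshold=0.9,
        )
        recs = regulatory_pathway_enrichment(
            bundle.db,
            filtered,
            bundle.regulators.significant_ids,
            mode="regulators",
        )
        assert recs[0].pathway_id == bundle.truth["planted"]["regulatory"]["pathway"]
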