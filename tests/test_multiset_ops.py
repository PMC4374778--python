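import numpy as np
import pytest

from cnvquartet import (
    CallSet,
    CNVCall,
    QuartetCalls,
    Status,
    combined_inherited_rate,
    inherited_rate,
    match_components,
    pairwise_setop,
    venn_counts,
)

from conftest import TINY_GENOME, call
from oracles import brute_components, random_calls


def by_source(**kwargs):
    return {
        name: CallSet.from_iter(calls, sample_id="s", source=name)
        for name, calls in kwargs.items()
    }


class TestMatchComponents:
    def test_identical_callsets_all_components_shared(self):
        calls = [call("1", 0, 1000), call("2", 0, 2000, Status.LOSS)]
        comps = match_components(by_source(a=calls, b=calls), 0.7)
        assert len(comps) == 2
        assert all(c.sources == frozenset({"a", "b"}) for c in comps)

    def test_disjoint_callsets_single_source_components(self):
        comps = match_components(
            by_source(a=[call("1", 0, 1000)], b=[call("1", 50_000, 51_000)]), 0.7
        )
        assert sorted(c.sources for c in comps) == [frozenset({"a"}), frozenset({"b"})]

    def test_non_transitive_chain_forms_one_component(self):
        # a≈b and b≈c at 0.7 while a and c do not match directly
        a = call("1", 0, 1000)
        b = call("1", 250, 1250)
        c = call("1", 500, 1500)
        assert not (min(*_ro(a, c)) >= 0.7)
        comps = match_components(by_source(x=[a], y=[b], z=[c]), 0.7)
        assert len(comps) == 1
        assert comps[0].sources == frozenset({"x", "y", "z"})
        assert (comps[0].start, comps[0].end) == (0, 1500)

    def test_partition_and_oracle_agreement(self, rng):
        for _ in range(5):
            sources = {
                name: random_calls(
                    rng, 25, TINY_GENOME, [Status.GAIN, Status.LOSS], CNVCall
                )
                for name in ("t1", "t2", "t3")
            }
            comps = match_components(by_source(**sources), 0.5)
            total = sum(len(c.member_calls) for c in comps)
            assert total == 75  # partition: every call in exactly one component
            flat = [(s, c) for s, calls in sources.items() for c in calls]
            index_of = {id(c): i for i, (_, c) in enumerate(flat)}
            oracle = sorted(sorted(comp) for comp in brute_components(flat, 0.5))
            got = sorted(
                sorted(index_of[id(m)] for m in comp.member_calls) for comp in comps
            )
            assert oracle == got

    def test_invariant_under_source_relabeling(self, rng):
        calls_a = random_calls(rng, 20, TINY_GENOME, [Status.GAIN], CNVCall)
        calls_b = random_calls(rng, 20, TINY_GENOME, [Status.GAIN], CNVCall)
        c1 = match_components(by_source(first=calls_a, second=calls_b), 0.6)
        c2 = match_components(by_source(second=calls_b, first=calls_a), 0.6)
        key = lambda comps: sorted((c.chrom, c.start, c.end, len(c.member_calls)) for c in comps)
        assert key(c1) == key(c2)


def _ro(a, b):
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    return ov / a.size(), ov / b.size()


class TestVennCounts:
    def test_single_tool_single_sample(self):
        calls = {"tool": {"s": CallSet.from_iter(
            [call("1", i * 10_000, i * 10_000 + 1000, sample_id="s") for i in range(5)],
            sample_id="s", source="tool")}}
        table = venn_counts(calls, threshold=0.7)
        assert table.cells == {frozenset({"tool"}): 5.0}

    def test_noise_free_loss_ratio_zero_everywhere(self, noise_free_study):
        study = noise_free_study
        table = venn_counts(study.calls, study.pedigree, threshold=0.7, filtered=True)
        assert table.loss_ratio  # populated
        assert all(v == pytest.approx(0.0) for v in table.loss_ratio.values())
        # noise-free: both (identical) callers agree on every region
        assert set(table.cells) == {frozenset({"exact_a", "exact_b"})}

    def test_filter_without_pedigree_rejected(self, noise_free_study):
        with pytest.raises(ValueError, match="pedigree"):
            venn_counts(noise_free_study.calls, None, filtered=True)

    def test_fp_only_contamination_drives_orphan_cell_loss(self, noise_free_study):
        """A caller whose extra calls are pure FPs loses them all under the
        Mendelian filter: its orphan cell's loss ratio approaches 1."""
        from cnvquartet.simulator import CallerProfile, SimulationConfig, simulate_study, zero_noise_profile

        cfg = SimulationConfig(
            n_families=3, n_cnvs_per_parent=20, population_cnv_pool_size=0,
            profiles=(zero_noise_profile("clean"),
                      CallerProfile("fp_heavy", fp_rate=25)),
            seed=77,
        )
        study = simulate_study(cfg)
        table = venn_counts(study.calls, study.pedigree, threshold=0.7, filtered=True)
        orphan = frozenset({"fp_heavy"})
        assert table.cells[orphan] > 5  # FP orphans are plentiful
        assert table.loss_ratio[orphan] > 0.95
        both = frozenset({"clean", "fp_heavy"})
        assert table.loss_ratio[both] == pytest.approx(0.0)


class TestPairwiseSetop:
    def test_identical_inputs_union_equals_intersection(self):
        calls = [call("1", 0, 1000, sample_id="s"), call("2", 0, 500, Status.LOSS, sample_id="s")]
        a = {"s": CallSet.from_iter(calls, sample_id="s", source="A")}
        b = {"s": CallSet.from_iter(calls, sample_id="s", source="B")}
        union = pairwise_setop(a, b, "union", 0.7)["s"]
        inter = pairwise_setop(a, b, "intersection", 0.7)["s"]
        assert [c.key for c in union] == [c.key for c in inter]
        assert len(union) == 2

    def test_disjoint_inputs(self):
        a = {"s": CallSet.from_iter([call("1", 0, 1000)], sample_id="s", source="A")}
        b = {"s": CallSet.from_iter([call("1", 50_000, 51_000)], sample_id="s", source="B")}
        assert len(pairwise_setop(a, b, "intersection", 0.7)["s"]) == 0
        assert len(pairwise_setop(a, b, "union", 0.7)["s"]) == 2

    def test_unknown_op_rejected(self):
        a = {"s": CallSet.from_iter([], sample_id="s")}
        with pytest.raises(ValueError, match="op"):
            pairwise_setop(a, a, "xor", 0.7)

    def test_counting_bounds_on_random_fixtures(self, rng):
        for _ in range(5):
            ca = random_calls(rng, 30, TINY_GENOME, [Status.GAIN, Status.LOSS], CNVCall)
            cb = random_calls(rng, 30, TINY_GENOME, [Status.GAIN, Status.LOSS], CNVCall)
            a = {"s": CallSet.from_iter(ca, sample_id="s", source="A")}
            b = {"s": CallSet.from_iter(cb, sample_id="s", source="B")}
            comps = match_components({"A": a["s"], "B": b["s"]}, 0.6)
            n_union = len(pairwise_setop(a, b, "union", 0.6)["s"])
            n_inter = len(pairwise_setop(a, b, "intersection", 0.6)["s"])
            n_both = sum(1 for c in comps if len(c.sources) == 2)
            assert n_union == len(comps)
            assert n_inter == n_both <= n_union


class TestCombinedInheritedRate:
    def test_noise_free_union_and_intersection_rates_are_one(self, noise_free_study):
        study = noise_free_study
        a = study.calls["exact_a"]
        b = study.calls["exact_b"]
        for op in ("union", "intersection"):
            rates, mean_count = combined_inherited_rate(a, b, op, study.pedigree, 0.7)
            assert all(r.rate == 1.0 for r in rates.values())
            assert mean_count > 0

    def test_self_union_reproduces_own_inherited_rate(self, noisy_study):
        # holds on normalized call sets: after gap-merging no two same-status
        # calls within one set can RO-match, so self-union adds no components
        from cnvquartet import merge_adjacent

        study = noisy_study
        per_sample = {
            sid: merge_adjacent(cs) for sid, cs in study.calls["tight"].items()
        }
        rates, _ = combined_inherited_rate(per_sample, per_sample, "union", study.pedigree, 0.7)
        for fam in study.pedigree:
            q = QuartetCalls(
                fam, per_sample[fam.twin1], per_sample[fam.twin2],
                per_sample[fam.parent1], per_sample[fam.parent2],
            )
            assert rates[fam.family_id].rate == pytest.approx(inherited_rate(q, 0.7).rate)

    def test_fp_contamination_makes_intersection_beat_union(self):
        from cnvquartet.simulator import CallerProfile, SimulationConfig, simulate_study, zero_noise_profile

        cfg = SimulationConfig(
            n_families=3, n_cnvs_per_parent=20, population_cnv_pool_size=0,
            profiles=(zero_noise_profile("clean"), CallerProfile("fp", fp_rate=20)),
            seed=5,
        )
        study = simulate_study(cfg)
        a, b = study.calls["clean"], study.calls["fp"]
        union_rates, _ = combined_inherited_rate(a, b, "union", study.pedigree, 0.7)
        inter_rates, _ = combined_inherited_rate(a, b, "intersection", study.pedigree, 0.7)
        mean = lambda rs: np.mean([r.rate for r in rs.values()])
        assert mean(inter_rates) > mean(union_rates)
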