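"""Consensus clustering, s-of-k support, representative selection, joint merge."""

import numpy as np
import pytest

from svensemble import (
    CallSet,
    cluster_tool_calls,
    consensus_sample,
    joint_merge,
    representative,
)
from svensemble.core import ValidationError, breakpoint_distance
from svensemble.ensemble import ToolCluster, ensemble_sample
from conftest import make_call


def one_tool_cs(calls, caller):
    samples = sorted({c.sample_id for c in calls}) or ["S0"]
    return CallSet([c.with_(caller_id=caller) for c in calls], samples, caller)


class TestClusterToolCalls:
    def test_type_agnostic_dup_ins_cluster(self):
        dup = make_call("1", 10_000, 10_300, "DUP", caller="Manta")
        ins = make_call("1", 10_005, None, "INS", svlen=290, caller="Delly")
        clusters = cluster_tool_calls(
            [one_tool_cs([dup], "Manta"), one_tool_cs([ins], "Delly")],
            max_dist=1000, type_aware=False,
        )
        assert len(clusters) == 1
        assert clusters[0].tools_supporting == {"Manta", "Delly"}

    def test_type_aware_splits_dup_and_ins(self):
        dup = make_call("1", 10_000, 10_300, "DUP", caller="Manta")
        ins = make_call("1", 10_005, None, "INS", svlen=290, caller="Delly")
        clusters = cluster_tool_calls(
            [one_tool_cs([dup], "Manta"), one_tool_cs([ins], "Delly")],
            max_dist=1000, type_aware=True,
        )
        assert len(clusters) == 2

    def test_mixed_samples_rejected(self):
        a = make_call(sample="S0")
        b = make_call(sample="S1")
        with pytest.raises(ValidationError):
            cluster_tool_calls([one_tool_cs([a], "t1"), one_tool_cs([b], "t2")])

    def test_one_call_per_tool_per_cluster(self):
        near = make_call("1", 10_000, 10_300, "DEL", caller="t1")
        alt = make_call("1", 10_050, 10_350, "DEL", caller="t1")
        other = make_call("1", 10_010, 10_310, "DEL", caller="t2")
        clusters = cluster_tool_calls(
            [one_tool_cs([near, alt], "t1"), one_tool_cs([other], "t2")],
            max_dist=1000,
        )
        assert sorted(len(c.member_calls) for c in clusters) == [1, 2]
        for cl in clusters:
            tools = [c.caller_id for c in cl.member_calls]
            assert len(tools) == len(set(tools))

    def test_matches_brute_force_single_linkage_oracle(self):
        # centres far apart, at most one call per tool near each centre:
        # greedy clustering must equal the connected components of the
        # distance-threshold graph.
        rng = np.random.default_rng(7)
        max_dist = 1000
        tools = ["t1", "t2", "t3", "t4"]
        calls_by_tool = {t: [] for t in tools}
        all_calls = []
        for centre in range(25):
            start = 10_000 + centre * 20_000
            length = int(rng.integers(100, 5_000))
            for t in tools:
                if rng.random() < 0.7:
                    ds, de = rng.integers(-300, 300, 2)
                    c = make_call("1", start + int(ds),
                                  start + length + int(de), "DEL", caller=t)
                    calls_by_tool[t].append(c)
                    all_calls.append(c)

        # O(n^2) single-linkage components
        n = len(all_calls)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if breakpoint_distance(all_calls[i], all_calls[j]) <= max_dist:
                    parent[find(i)] = find(j)
        expected = {}
        for i, c in enumerate(all_calls):
            expected.setdefault(find(i), set()).add(c)

        clusters = cluster_tool_calls(
            [one_tool_cs(calls_by_tool[t], t) for t in tools],
            max_dist=max_dist,
        )
        got = {frozenset(cl.member_calls) for cl in clusters}
        assert got == {frozenset(v) for v in expected.values()}

    def test_conservation_every_call_in_exactly_one_cluster(self):
        rng = np.random.default_rng(11)
        callsets = []
        total = 0
        for t in ("t1", "t2", "t3"):
            calls = []
            for _ in range(60):
                s = int(rng.integers(0, 2_000_000))
                calls.append(make_call("1", s, s + int(rng.integers(50, 3000)),
                                       "DEL", caller=t))
            callsets.append(one_tool_cs(calls, t))
            total += len(calls)
        clusters = cluster_tool_calls(callsets, max_dist=1000)
        assert sum(len(c.member_calls) for c in clusters) == total


class TestRepresentative:
    def test_medoid_coordinates(self):
        members = [
            make_call("1", 10_000, 10_300, "DUP", caller="t1"),
            make_call("1", 10_010, 10_298, "DUP", caller="t2"),
            make_call("1", 10_002, 10_300, "DUP", caller="t3"),
        ]
        interval, svtype, svlen, _ = representative(ToolCluster(members))
        assert (interval.start, interval.end) == (10_002, 10_300)
        assert svtype == "DUP"

    def test_singleton_is_itself(self):
        c = make_call("1", 5_000, 5_500, "INV")
        interval, svtype, svlen, _ = representative(ToolCluster([c]))
        assert interval == c.interval and svtype == "INV" and svlen == 500

    def test_type_tie_broken_by_precedence(self):
        members = [
            make_call("1", 10_000, 10_300, "DEL", caller="t1"),
            make_call("1", 10_000, 10_300, "CNV", caller="t2"),
        ]
        _, svtype, _, _ = representative(ToolCluster(members))
        assert svtype == "DEL"


class TestConsensusSample:
    panel = ("Delly", "GRIDSS", "Manta", "smoove")

    def cluster(self, tools):
        return ToolCluster([
            make_call("1", 10_000, 10_300, "DUP", caller=t) for t in tools
        ])

    def test_three_tool_cluster_emitted_at_s3(self):
        cs = consensus_sample([self.cluster(["Manta", "Delly", "smoove"])],
                              s=3, tool_panel=self.panel)
        assert len(cs) == 1
        assert cs.calls[0].tools == ("Delly", "Manta", "smoove")

    def test_two_tool_cluster_needs_s2(self):
        cl = [self.cluster(["Manta", "Delly"])]
        assert len(consensus_sample(cl, s=3, tool_panel=self.panel)) == 0
        assert len(consensus_sample(cl, s=2, tool_panel=self.panel)) == 1

    def test_s_above_k_rejected(self):
        with pytest.raises(ValidationError):
            consensus_sample([], s=5, tool_panel=self.panel)

    def test_support_sweep_strictly_nested(self):
        rng = np.random.default_rng(5)
        clusters = []
        for centre in range(40):
            n_tools = int(rng.integers(1, 5))
            tools = list(rng.choice(self.panel, size=n_tools, replace=False))
            start = 10_000 + centre * 50_000
            clusters.append(ToolCluster([
                make_call("1", start, start + 400, "DEL", caller=t)
                for t in tools
            ]))
        emitted = {
            s: {(c.start, c.end) for c in
                consensus_sample(clusters, s=s, tool_panel=self.panel)}
            for s in (2, 3, 4)
        }
        assert emitted[4] <= emitted[3] <= emitted[2]


class TestJointMerge:
    def test_same_variant_in_two_samples_merges(self):
        a = make_call("1", 10_000, 10_300, "DUP", sample="A",
                      caller="consensus", tools=("Manta", "Delly"))
        b = make_call("1", 10_010, 10_298, "DUP", sample="B",
                      caller="consensus", tools=("Manta", "smoove"))
        pop = joint_merge([
            CallSet([a], ["A"], "consensus"),
            CallSet([b], ["B"], "consensus"),
        ])
        assert len(pop) == 1
        v = pop.variants[0]
        carriers = [s for s, g in v.genotypes.items()
                    if not g.missing and g.alt_alleles > 0]
        assert sorted(carriers) == ["A", "B"]
        assert v.supp_vec == (True, True, True)  # Delly, Manta, smoove

    def test_disjoint_calls_stay_separate(self):
        a = make_call("1", 10_000, 10_300, "DEL", sample="A")
        b = make_call("1", 500_000, 500_300, "DEL", sample="B")
        pop = joint_merge([
            CallSet([a], ["A"], "consensus"),
            CallSet([b], ["B"], "consensus"),
        ])
        assert len(pop) == 2
        for v in pop.variants:
            carriers = [s for s, g in v.genotypes.items() if not g.missing]
            assert len(carriers) == 1

    def test_duplicate_sample_ids_rejected(self):
        a = make_call(sample="A")
        with pytest.raises(ValidationError):
            joint_merge([CallSet([a], ["A"], "x"),
                         CallSet([a], ["A"], "y")])

    def test_permutation_invariant_over_sample_order(self):
        rng = np.random.default_rng(13)
        callsets = []
        for sid in ("A", "B", "C", "D"):
            calls = []
            for centre in range(20):
                if rng.random() < 0.6:
                    start = 10_000 + centre * 30_000 + int(rng.integers(-200, 200))
                    calls.append(make_call("1", start, start + 500, "DEL",
                                           sample=sid, caller="consensus"))
            callsets.append(CallSet(calls, [sid], "consensus"))

        pop1 = joint_merge(list(callsets))
        pop2 = joint_merge(list(reversed(callsets)))
        assert pop1.sample_ids == pop2.sample_ids
        key = lambda v: (v.chrom, v.start, v.end, v.svtype)
        assert [key(v) for v in pop1.variants] == [key(v) for v in pop2.variants]
        for v1, v2 in zip(pop1.variants, pop2.variants):
            assert {s: g.dosage for s, g in v1.genotypes.items()} == \
                   {s: g.dosage for s, g in v2.genotypes.items()}

    def test_ids_are_deterministic_and_unique(self):
        a = make_call("1", 10_000, 10_300, "DEL", sample="A")
        b = make_call("2", 10_000, 10_300, "DEL", sample="A")
        pop = joint_merge([CallSet([a, b], ["A"], "consensus")])
        ids = [v.id for v in pop.variants]
        assert len(set(ids)) == 2
        assert all(":" in i for i in ids)


class TestEnsembleSample:
    def test_min_size_filter_applied(self):
        small = make_call("1", 1_000, 1_040, "DEL", caller="t1")  # 40 bp
        big = [make_call("1", 10_000, 10_500, "DEL", caller=t)
               for t in ("t1", "t2", "t3")]
        cs = ensemble_sample(
            [one_tool_cs([small, big[0]], "t1"),
             one_tool_cs([big[1]], "t2"),
             one_tool_cs([big[2]], "t3")],
            s=1,
        )
        assert all(c.start != 1_000 for c in cs)
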