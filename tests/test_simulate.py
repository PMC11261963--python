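"""Synthetic-data generator: determinism, error models, recovery scoring."""

import math

import numpy as np
import pytest

from svensemble import (
    CallerProfile,
    carrier_recall,
    emulate_depth_caller,
    emulate_sv_caller,
    evaluate_recovery,
    run_end_to_end,
    simulate_truth,
)
from svensemble.core import ValidationError, sv_length
from svensemble.ensemble import ensemble_sample
from svensemble.simulate import GenomeSpec, _subset_sample


class TestSimulateTruth:
    def test_deterministic_for_fixed_seed(self):
        a = simulate_truth(n_samples=20, n_loci=200, seed=42)
        b = simulate_truth(n_samples=20, n_loci=200, seed=42)
        assert a.loci == b.loci
        assert np.array_equal(a.genotypes, b.genotypes)

    def test_different_seeds_differ(self):
        a = simulate_truth(n_samples=5, n_loci=50, seed=1)
        b = simulate_truth(n_samples=5, n_loci=50, seed=2)
        assert a.loci != b.loci

    def test_fixed_af_dosage_expectation(self):
        truth = simulate_truth(
            n_samples=1000, n_loci=30, seed=3,
            af_dist=lambda rng, size: np.full(size, 0.5),
        )
        mean_dosage = truth.genotypes.mean(axis=0)
        se = math.sqrt(0.5 / 1000)  # Var[Bin(2,.5)]/n = 0.5/n
        assert np.all(np.abs(mean_dosage - 1.0) < 3 * se + 1e-12)

    def test_type_mix_respected(self):
        truth = simulate_truth(n_samples=2, n_loci=50, seed=4,
                               type_mix={"DEL": 1.0})
        assert all(l.svtype == "DEL" for l in truth.loci)

    def test_loci_do_not_overlap(self):
        truth = simulate_truth(n_samples=2, n_loci=300, seed=5)
        by_chrom = {}
        for l in truth.loci:
            by_chrom.setdefault(l.extent.chrom, []).append(l.extent)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start

    def test_two_subpopulations_are_separable_in_genotype_space(self):
        from svensemble import genotype_matrix

        truth = simulate_truth(n_samples=40, n_loci=150, seed=27,
                               n_subpops=2)
        assert set(truth.subpop_of_sample) == {0, 1}
        tools = [emulate_sv_caller(truth, CallerProfile.identity(f"t{i}"),
                                   seed=i) for i in range(4)]
        pop = run_end_to_end(truth, tools, s=3, uncalled_as_ref=True)
        m = genotype_matrix(pop).to_numpy()
        centred = m - m.mean(axis=0)
        # first principal component separates the two subpopulations
        u, s_vals, _ = np.linalg.svd(centred, full_matrices=False)
        pc1 = u[:, 0] * s_vals[0]
        g0 = pc1[np.array(truth.subpop_of_sample) == 0]
        g1 = pc1[np.array(truth.subpop_of_sample) == 1]
        gap = abs(g0.mean() - g1.mean())
        assert gap > 2 * (g0.std() + g1.std()) / 2

    def test_too_small_genome_raises(self):
        tiny = GenomeSpec(chrom_lengths=(("1", 30_000),))
        with pytest.raises(ValidationError):
            simulate_truth(n_samples=2, n_loci=500, seed=6, genome=tiny)


class TestEmulateSvCaller:
    def test_identity_profile_reproduces_carriers(self):
        truth = simulate_truth(n_samples=10, n_loci=80, seed=7)
        cs = emulate_sv_caller(truth, CallerProfile.identity("perfect"))
        expected = int((truth.genotypes > 0).sum())
        assert len(cs) == expected
        for c in cs:
            locus = next(l for l in truth.loci
                         if l.interval.chrom == c.chrom
                         and l.interval.start == c.start)
            assert c.svtype == locus.svtype
            assert sv_length(c) == locus.svlen

    def test_zero_sensitivity_empty(self):
        truth = simulate_truth(n_samples=5, n_loci=40, seed=8)
        cs = emulate_sv_caller(truth,
                               CallerProfile(name="blind", sensitivity=0.0))
        assert len(cs) == 0

    def test_jitter_matches_half_normal_expectation(self):
        truth = simulate_truth(
            n_samples=20, n_loci=100, seed=9,
            af_dist=lambda rng, size: np.full(size, 0.6),
            length_dist=lambda rng, size: np.full(size, 5_000.0),
            type_mix={"DEL": 1.0},
        )
        sd = 20.0
        cs = emulate_sv_caller(truth, CallerProfile(name="t", jitter_sd=sd))
        shifts = []
        loci = {(l.interval.chrom, round(l.af, 6)): l for l in truth.loci}
        by_pos = sorted(truth.loci, key=lambda l: (l.interval.chrom,
                                                   l.interval.start))
        for c in cs:
            locus = min(
                (l for l in by_pos if l.interval.chrom == c.chrom),
                key=lambda l: abs(l.interval.start - c.start),
            )
            shifts.append(abs(c.start - locus.interval.start))
            shifts.append(abs(c.end - locus.interval.end))
        shifts = np.array(shifts, dtype=float)
        expected = sd * math.sqrt(2 / math.pi)
        se = sd * math.sqrt(1 - 2 / math.pi) / math.sqrt(len(shifts))
        # rounding to integer bp adds sub-bp slack
        assert abs(shifts.mean() - expected) < 3 * se + 0.5
        assert len(shifts) > 1000

    def test_type_confusion_rates(self):
        truth = simulate_truth(
            n_samples=30, n_loci=60, seed=10,
            af_dist=lambda rng, size: np.full(size, 0.7),
            type_mix={"DUP": 1.0},
        )
        profile = CallerProfile(
            name="c", type_confusion={"DUP": {"DUP": 0.7, "INS": 0.3}}
        )
        cs = emulate_sv_caller(truth, profile)
        frac_ins = sum(1 for c in cs if c.svtype == "INS") / len(cs)
        se = math.sqrt(0.3 * 0.7 / len(cs))
        assert abs(frac_ins - 0.3) < 4 * se

    def test_false_positives_at_poisson_rate_avoid_truth(self):
        truth = simulate_truth(n_samples=10, n_loci=30, seed=12)
        profile = CallerProfile(name="fp", sensitivity=0.0, fp_rate=0.5)
        cs = emulate_sv_caller(truth, profile)
        lam = 0.5 * truth.genome.total_bp / 1e6 * 10  # per-sample x samples
        assert abs(len(cs) - lam) < 4 * math.sqrt(lam)
        for c in cs:
            for l in truth.loci:
                if l.interval.chrom == c.chrom:
                    assert c.interval.overlap_bp(l.extent) == 0

    def test_confusion_row_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            CallerProfile(name="bad",
                          type_confusion={"DUP": {"DUP": 0.5, "INS": 0.3}})


class TestEmulateDepthCaller:
    def test_outward_window_snapping(self):
        truth = simulate_truth(
            n_samples=2, n_loci=10, seed=13,
            af_dist=lambda rng, size: np.full(size, 0.9),
            length_dist=lambda rng, size: np.full(size, 12_345.0),
            type_mix={"DEL": 1.0},
        )
        calls = emulate_depth_caller(truth)
        assert calls
        for dc in calls:
            assert dc.interval.start % 1000 == 0
            assert dc.interval.end % 1000 == 0
            locus = next(l for l in truth.loci
                         if l.interval.chrom == dc.interval.chrom
                         and dc.interval.start <= l.interval.start)
            assert dc.interval.start <= locus.interval.start
            assert dc.interval.end >= locus.interval.end

    def test_ins_and_inv_are_depth_invisible(self):
        truth = simulate_truth(
            n_samples=5, n_loci=20, seed=14,
            type_mix={"INS": 0.5, "INV": 0.5},
            length_dist=lambda rng, size: np.full(size, 20_000.0),
        )
        assert emulate_depth_caller(truth) == []


class TestEndToEndRecovery:
    def test_identity_profiles_reproduce_truth_exactly(self):
        truth = simulate_truth(n_samples=12, n_loci=150, seed=15)
        tools = [emulate_sv_caller(truth, CallerProfile.identity(f"t{i}"),
                                   seed=i) for i in range(4)]
        pop = run_end_to_end(truth, tools, s=3, uncalled_as_ref=True)
        carried = truth.carried_loci
        assert len(pop) == len(carried)
        by_pos = {(v.chrom, v.start): v for v in pop.variants}
        for li in carried:
            locus = truth.loci[li]
            v = by_pos[(locus.interval.chrom, locus.interval.start)]
            assert v.svtype == locus.svtype
            assert v.svlen == locus.svlen
            for si, sid in enumerate(truth.sample_ids):
                assert v.genotypes[sid].dosage == int(truth.genotypes[si, li])
        metrics = evaluate_recovery(truth, pop)
        assert metrics["recall"] == 1.0
        assert metrics["precision"] == 1.0
        assert metrics["af_mean_abs_error"] == 0.0

    def test_caps_in_pipeline_remove_long_planted_calls(self):
        from svensemble import LengthCaps

        truth = simulate_truth(
            n_samples=6, n_loci=40, seed=28,
            length_dist=lambda rng, size: rng.uniform(500, 9_000, size),
            type_mix={"INS": 1.0},
        )
        tools = [emulate_sv_caller(truth, CallerProfile.identity(f"t{i}"),
                                   seed=i) for i in range(4)]
        pop = run_end_to_end(truth, tools, s=3, caps=LengthCaps())
        assert all(v.svlen <= 1_000 for v in pop.variants)
        pop_nocaps = run_end_to_end(truth, tools, s=3)
        assert len(pop_nocaps) > len(pop)

    def test_support_monotonicity_on_noisy_run(self):
        truth = simulate_truth(n_samples=8, n_loci=100, seed=16)
        tools = [
            emulate_sv_caller(
                truth, CallerProfile(name=f"t{i}", sensitivity=0.8), seed=i)
            for i in range(4)
        ]
        recalls = {}
        for s in (2, 3, 4):
            pop = run_end_to_end(truth, tools, s=s)
            recalls[s] = evaluate_recovery(truth, pop)["recall"]
        assert recalls[4] <= recalls[3] <= recalls[2]

    def test_carrier_recall_matches_binomial_closed_form_small(self):
        truth = simulate_truth(n_samples=10, n_loci=150, seed=17)
        p_tool = 0.95
        tools = [
            emulate_sv_caller(
                truth, CallerProfile(name=f"t{i}", sensitivity=p_tool), seed=i)
            for i in range(4)
        ]
        per_sample = {}
        for sid in truth.sample_ids:
            per_sample[sid] = ensemble_sample(
                [_subset_sample(cs, sid) for cs in tools], s=3)
        observed = carrier_recall(truth, per_sample)
        from scipy.stats import binom

        expected = binom.sf(2, 4, p_tool)  # P(X >= 3)
        n_pairs = int((truth.genotypes > 0).sum())
        se = math.sqrt(expected * (1 - expected) / n_pairs)
        assert abs(observed - expected) < 4 * se
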