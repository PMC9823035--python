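"""Call-set merging and SV/TR filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pecknet import simulate as sim
from pecknet.variants import (
    MISSING,
    BiallelicVariant,
    CallerRecord,
    MergedVariant,
    MultiallelicVariant,
    RecordValidationError,
    TandemRepeatCall,
    filter_merged,
    filter_tr,
    merge_callsets,
    split_multiallelic,
)


def rec(caller, chrom, start, end, sv_type="DEL", strands=("+", "-"), qual=1500.0, gts=None):
    return CallerRecord(
        caller_id=caller,
        chrom=chrom,
        start=start,
        end=end,
        sv_type=sv_type,
        strands=strands,
        qual=qual,
        genotypes=gts,
    )


def oracle_cluster_count(records, max_dist, type_aware=True, strand_aware=True):
    """Independent clustering oracle: sequential assignment to the first
    compatible cluster seed, written with explicit per-record loops."""
    ordered = sorted(
        records,
        key=lambda r: (r.chrom, r.start, r.end, r.sv_type, r.strands, r.caller_id),
    )
    seeds = []
    assignment = []
    for r in ordered:
        chosen = None
        for k, s in enumerate(seeds):
            if type_aware and r.sv_type != s.sv_type:
                continue
            if strand_aware and r.strands != s.strands:
                continue
            if r.chrom != s.chrom or r.chrom2 != s.chrom2:
                continue
            if abs(r.start - s.start) <= max_dist and abs(r.end - s.end) <= max_dist:
                chosen = k
                break
        if chosen is None:
            seeds.append(r)
            chosen = len(seeds) - 1
        assignment.append(chosen)
    return seeds, assignment


class TestMergeCallsets:
    def test_chained_breakpoints_cluster_through_seed(self):
        """Three DELs within 1000 bp of the first record's breakpoints form
        one cluster with support 3."""
        sets = [
            [rec("a", "chr1", 1000, 1500)],
            [rec("b", "chr1", 1200, 1700)],
            [rec("c", "chr1", 1900, 2400)],
        ]
        merged = merge_callsets(sets, min_callers=2)
        assert len(merged) == 1
        assert merged[0].supporting_callers == {"a", "b", "c"}
        # representative from the highest-priority (lexicographic) caller
        assert (merged[0].start, merged[0].end) == (1000, 1500)

    def test_type_awareness_separates_identical_coordinates(self):
        sets = [
            [rec("a", "chr1", 1000, 2000, "DEL")],
            [rec("b", "chr1", 1000, 2000, "INV")],
        ]
        assert merge_callsets(sets, min_callers=2) == []
        merged = merge_callsets(sets, min_callers=1)
        assert {m.sv_type for m in merged} == {"DEL", "INV"}

    def test_strand_awareness(self):
        sets = [
            [rec("a", "chr1", 1000, 2000, strands=("+", "+"))],
            [rec("b", "chr1", 1000, 2000, strands=("-", "-"))],
        ]
        assert merge_callsets(sets, min_callers=2) == []
        assert len(merge_callsets(sets, min_callers=2, strand_aware=False)) == 1

    def test_min_size_drops_short_deletion(self):
        sets = [
            [rec("a", "chr1", 1000, 1024)],
            [rec("b", "chr1", 1000, 1024)],
            [rec("c", "chr1", 1000, 1024)],
        ]
        assert merge_callsets(sets) == []  # 25 bp < 30 bp
        assert len(merge_callsets(sets, min_size=25)) == 1

    def test_translocations_exempt_from_min_size(self):
        sets = [
            [rec("a", "chr1", 1000, 1000, "TRA")],
            [rec("b", "chr1", 1000, 1000, "TRA")],
        ]
        assert len(merge_callsets(sets)) == 1

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        sets = []
        for caller in ("smoove", "delly", "manta"):
            calls = []
            for i in range(30):
                start = int(rng.integers(1_000, 500_000))
                calls.append(
                    rec(
                        caller,
                        f"chr{rng.integers(1, 3)}",
                        start,
                        start + int(rng.integers(30, 4000)),
                        sv_type=str(rng.choice(["DEL", "INV", "DUP"])),
                        qual=float(rng.integers(500, 3000)),
                    )
                )
            sets.append(calls)
        a = merge_callsets(sets)
        b = merge_callsets(sets[::-1])
        key = lambda v: (v.chrom, v.start, v.end, v.sv_type)
        assert [key(v) for v in a] == [key(v) for v in b]
        assert [v.supporting_callers for v in a] == [v.supporting_callers for v in b]

    def test_each_record_joins_one_cluster(self):
        # two seeds 1500 apart; a middle record can only join the first
        sets = [
            [rec("a", "chr1", 1000, 2000), rec("a", "chr1", 2500, 3500)],
            [rec("b", "chr1", 1800, 2800)],
        ]
        merged = merge_callsets(sets, min_callers=1)
        assert sum(len(m.members) for m in merged) == 3

    def test_unknown_type_rejected_at_construction(self):
        with pytest.raises(RecordValidationError):
            rec("a", "chr1", 1, 2, sv_type="WEIRD")

    def test_merge_matches_clustering_oracle_on_noisy_simulation(self):
        cfg = sim.SimConfig(seed=5, n_samples=40, n_expr_samples=30, n_sv_truth=120)
        gt = sim.simulate_genotypes(cfg)
        truth = sim.draw_truth(cfg, gt)
        callsets = sim.simulate_caller_outputs(
            truth, n_callers=3, jitter_sd=200.0, fn_rate_per_caller=0.1, fp_rate=0.05, seed=9
        )
        flat = [r for cs in callsets for r in cs]
        for min_callers in (1, 2, 3):
            merged = merge_callsets(callsets, min_callers=min_callers)
            seeds, assignment = oracle_cluster_count(flat, max_dist=1000)
            ordered = sorted(
                flat, key=lambda r: (r.chrom, r.start, r.end, r.sv_type, r.strands, r.caller_id)
            )
            members_per_cluster = {}
            for r, k in zip(ordered, assignment):
                members_per_cluster.setdefault(k, []).append(r)
            expected = 0
            for members in members_per_cluster.values():
                callers = {r.caller_id for r in members}
                if len(callers) < min_callers:
                    continue
                # representative: lexicographically first caller, then position
                rep = min(members, key=lambda r: (r.caller_id, r.start))
                if rep.sv_type == "TRA" or rep.end - rep.start + 1 >= 30:
                    expected += 1
            assert len(merged) == expected

    def test_exact_recovery_without_noise(self):
        cfg = sim.SimConfig(seed=6, n_samples=30, n_expr_samples=20, n_sv_truth=100)
        gt = sim.simulate_genotypes(cfg)
        truth = sim.draw_truth(cfg, gt)
        callsets = sim.simulate_caller_outputs(
            truth, 3, jitter_sd=0.0, fn_rate_per_caller=0.0, fp_rate=0.0, seed=2,
            caller_missing_rate=0.0,
        )
        merged = merge_callsets(callsets)
        assert len(merged) == len(truth.sv_records)

    def test_dropout_caller_does_not_break_two_caller_support(self):
        cfg = sim.SimConfig(seed=7, n_samples=30, n_expr_samples=20, n_sv_truth=50)
        gt = sim.simulate_genotypes(cfg)
        truth = sim.draw_truth(cfg, gt)
        callsets = sim.simulate_caller_outputs(
            truth, 3, jitter_sd=0.0, fn_rate_per_caller=[0.0, 0.0, 1.0], fp_rate=0.0, seed=2,
            caller_missing_rate=0.0,
        )
        assert callsets[2] == []
        merged = merge_callsets(callsets, min_callers=2)
        assert len(merged) == len(truth.sv_records)


class TestFilterMerged:
    def mk(self, qual, gts):
        return MergedVariant(
            chrom="chr1", start=1000, end=2000, sv_type="DEL", strands=("+", "-"),
            supporting_callers=frozenset({"a", "b"}), qual=qual,
            genotypes=np.array(gts, dtype=np.int8),
        )

    def test_qual_boundary(self):
        below = self.mk(999.9, [0, 1, 2])
        at = self.mk(1000.0, [0, 1, 2])
        assert filter_merged([below, at]) == [at]

    def test_callrate_boundary(self):
        at = self.mk(1500, [0, 1, 2, 2, MISSING])  # call rate exactly 0.8
        below = self.mk(1500, [0, 1, MISSING, 2, MISSING])
        assert filter_merged([at, below]) == [at]

    def test_enumerated_toy_set(self):
        good = [self.mk(1200, [0, 1, 2, 1, 0]) for _ in range(5)]
        bad_qual = [self.mk(900, [0, 1, 2, 1, 0]) for _ in range(3)]
        bad_cr = [self.mk(1200, [0, MISSING, MISSING, 1, 0]) for _ in range(2)]
        out = filter_merged(good + bad_qual + bad_cr)
        assert out == good

    @given(
        quals=st.lists(st.floats(0, 3000, allow_nan=False), min_size=1, max_size=20),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_idempotent(self, quals, seed):
        rng = np.random.default_rng(seed)
        records = [
            self.mk(q, rng.choice([0, 1, 2, MISSING], size=8, p=[0.3, 0.3, 0.2, 0.2]))
            for q in quals
        ]
        once = filter_merged(records)
        assert filter_merged(once) == once


class TestFilterTr:
    def mk(self, gts, dp, q):
        return TandemRepeatCall(
            chrom="chr1", pos=100, motif="ACG",
            genotypes=np.array(gts), dp=np.array(dp), q=np.array(q),
        )

    def test_all_low_depth_removes_variant(self):
        call = self.mk([1, 2, 1], [9, 9, 9], [0.9, 0.9, 0.9])
        assert filter_tr([call]) == []

    def test_depth_threshold_inclusive(self):
        call = self.mk([1, 2], [10, 10], [0.9, 0.9])
        assert len(filter_tr([call])) == 1

    def test_quality_threshold_strict(self):
        """Q exactly 0.8 is masked ('higher than 0.8')."""
        call = self.mk([1, 2, 1, 2, 0], [20] * 5, [0.8, 0.9, 0.9, 0.9, 0.9])
        out = filter_tr([call], min_callrate=0.8)
        assert len(out) == 1
        assert out[0].genotypes[0] == -1
        assert out[0].call_rate == 0.8

    def test_callrate_arithmetic(self):
        gts = [1] * 10
        dp = [20] * 8 + [5, 5]  # 8 of 10 pass -> call rate 0.8 retained
        call = self.mk(gts, dp, [0.9] * 10)
        out = filter_tr([call])
        assert len(out) == 1
        assert out[0].call_rate == pytest.approx(0.8)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        calls = [
            self.mk(
                rng.integers(0, 5, 12),
                rng.integers(0, 40, 12),
                rng.random(12),
            )
            for _ in range(10)
        ]
        once = filter_tr(calls)
        twice = filter_tr(once)
        assert len(once) == len(twice)
        for a, b in zip(once, twice):
            assert np.array_equal(a.genotypes, b.genotypes)


class TestSplitMultiallelic:
    def test_triallelic_tr_splits_in_two(self):
        var = MultiallelicVariant(
            "tr1", "chr1", 500, ("CN5", "CN7"),
            np.array([[0, 1], [1, 2], [2, 2], [0, 0]]),
        )
        out = split_multiallelic([var])
        assert len(out) == 2
        assert [v.variant_id for v in out] == ["tr1_1", "tr1_2"]

    def test_heterozygous_for_two_alts(self):
        var = MultiallelicVariant("tr1", "chr1", 500, ("CN5", "CN7"), np.array([[1, 2]]))
        a, b = split_multiallelic([var])
        assert a.dosages[0] == 1 and b.dosages[0] == 1

    def test_biallelic_passthrough(self):
        var = MultiallelicVariant("del1", "chr1", 500, ("DEL",), np.array([[0, 1], [1, 1]]))
        (out,) = split_multiallelic([var])
        assert out.variant_id == "del1"
        assert np.array_equal(out.dosages, [1, 2])

    @given(seed=st.integers(0, 500), k=st.integers(1, 4))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_dosage_conservation(self, seed, k):
        """Summed alt dosages over split records equal the per-sample count
        of non-reference alleles."""
        rng = np.random.default_rng(seed)
        gts = rng.integers(0, k + 1, size=(15, 2))
        var = MultiallelicVariant("v", "chr2", 10, tuple(f"A{i}" for i in range(k)), gts)
        out = split_multiallelic([var])
        total = sum(v.dosages for v in out)
        assert np.array_equal(total, (gts >= 1).sum(axis=1))
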