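import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvmap.cnv_map import (
    assign_genotypes,
    build_cnvrs,
    build_map,
    classify_cnvr,
    compare_reference,
    dissect_cnvsegs,
    qc_filter_calls,
    qc_filter_samples,
    resolve_call_conflicts,
)
from conftest import make_calls


def brute_force_components(intervals):
    """O(n^2) union-find over pairwise positive overlap; returns a label list."""
    n = len(intervals)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei = intervals[i]
            cj, sj, ej = intervals[j]
            if ci == cj and si < ej and sj < ei:
                parent[find(i)] = find(j)
    return [find(i) for i in range(n)]


class TestQcFilterCalls:
    def test_boundary_values(self):
        calls = make_calls(
            [
                ("s1", "A", "chr1", 0, 999, 1, "RARE", 10, np.nan, 5),
                ("s1", "A", "chr1", 5000, 6000, 1, "RARE", 5.0, np.nan, 3),
            ]
        )
        out = qc_filter_calls(calls)
        assert list(out["start"]) == [5000]  # 999 bp removed; exact thresholds kept

    def test_absent_metadata_passes(self):
        calls = make_calls([("s1", "A", "chr1", 0, 2000, 1, "RARE")])
        assert len(qc_filter_calls(calls)) == 1

    def test_each_violation_removes_exactly_its_call(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(6):  # six clean calls
            rows.append(("s", "A", "chr1", i * 10_000, i * 10_000 + 5000, 1, "RARE", 20, np.nan, 8))
        rows.append(("s", "A", "chr2", 0, 500, 1, "RARE", 20, np.nan, 8))  # short
        rows.append(("s", "A", "chr2", 10_000, 15_000, 1, "RARE", 20, np.nan, 2))  # probes
        rows.append(("s", "A", "chr2", 30_000, 35_000, 1, "RARE", 2, np.nan, 8))  # lod
        rows.append(("s", "A", "chr2", 50_000, 50_900, 1, "RARE", 20, np.nan, 8))  # short
        calls = make_calls(rows)
        out = qc_filter_calls(calls)
        # independent re-check of every rule
        keep = [
            (e - s >= 1000) and (not (p == p) or p >= 3) and (not (l == l) or l >= 5)
            for s, e, p, l in zip(calls["start"], calls["end"], calls["n_probes"], calls["lod"])
        ]
        assert len(out) == sum(keep) == 6

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            qc_filter_calls(make_calls([]), min_len=0)


class TestQcFilterSamples:
    def _samples(self, ids):
        return pd.DataFrame({"sample_id": ids, "population": "A"})

    def test_identical_counts_exclude_nobody(self):
        rows = [(f"s{i}", "A", "chr1", j * 10_000, j * 10_000 + 2000, 1, "RARE")
                for i in range(10) for j in range(5)]
        retained, excluded = qc_filter_samples(
            make_calls(rows), self._samples([f"s{i}" for i in range(10)])
        )
        assert excluded == []

    def test_gross_outlier_excluded(self):
        # one outlier among n samples can reach at most ~sqrt(n) sd, so the
        # cohort must be large enough for a 5 sd exceedance to be possible
        rows = [(f"s{i}", "A", "chr1", j * 10_000, j * 10_000 + 2000, 1, "RARE")
                for i in range(60) for j in range(10)]
        rows += [("bad", "A", "chr2", j * 10_000, j * 10_000 + 2000, 1, "RARE")
                 for j in range(500)]
        ids = [f"s{i}" for i in range(60)] + ["bad"]
        retained, excluded = qc_filter_samples(make_calls(rows), self._samples(ids))
        # oracle: direct mean/sd computation over all 61 samples
        counts = np.array([10.0] * 60 + [500.0])
        assert 500 > counts.mean() + 5 * counts.std(ddof=1)
        assert excluded == ["bad"]

    def test_duplication_outlier_excluded_despite_normal_deletions(self):
        rows = [(f"s{i}", "A", "chr1", j * 10_000, j * 10_000 + 2000, 1, "RARE")
                for i in range(60) for j in range(10)]
        rows += [(f"s{i}", "A", "chr3", 0, 2000, 3, "RARE") for i in range(60)]
        rows += [("dup", "A", "chr1", j * 10_000, j * 10_000 + 2000, 1, "RARE")
                 for j in range(10)]
        rows += [("dup", "A", "chr2", j * 10_000, j * 10_000 + 2000, 3, "RARE")
                 for j in range(200)]
        ids = [f"s{i}" for i in range(60)] + ["dup"]
        _, excluded = qc_filter_samples(make_calls(rows), self._samples(ids))
        assert excluded == ["dup"]

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            qc_filter_samples(
                make_calls([("s1", "A", "chr1", 0, 2000, 1, "RARE")]),
                self._samples(["s1"]),
            )


class TestResolveConflicts:
    def test_uncertain_cnp_call_becomes_missing(self):
        calls = make_calls([("s1", "A", "chr1", 0, 5000, 1, "CNP", 10, 0.2, 5)])
        out, missing = resolve_call_conflicts(calls)
        assert len(out) == 0
        assert len(missing) == 1 and missing.loc[0, "sample_id"] == "s1"

    def test_higher_lod_wins_state_conflict(self):
        calls = make_calls(
            [
                ("s1", "A", "chr1", 0, 5000, 1, "RARE", 8, np.nan, 5),
                ("s1", "A", "chr1", 1000, 6000, 3, "CNP", 12, 0.01, 5),
            ]
        )
        out, _ = resolve_call_conflicts(calls)
        assert list(out["copy_state"]) == [3]

    def test_same_state_overlap_kept(self):
        calls = make_calls(
            [
                ("s1", "A", "chr1", 0, 5000, 1, "RARE", 8, np.nan, 5),
                ("s1", "A", "chr1", 1000, 6000, 1, "CNP", 12, 0.01, 5),
            ]
        )
        out, _ = resolve_call_conflicts(calls)
        assert len(out) == 2

    def test_equal_lod_keeps_cnp(self):
        calls = make_calls(
            [
                ("s1", "A", "chr1", 0, 5000, 1, "RARE", 8, np.nan, 5),
                ("s1", "A", "chr1", 1000, 6000, 3, "CNP", 8, 0.01, 5),
            ]
        )
        out, _ = resolve_call_conflicts(calls)
        assert list(out["source"]) == ["CNP"]

    def test_different_samples_never_conflict(self):
        calls = make_calls(
            [
                ("s1", "A", "chr1", 0, 5000, 1, "RARE", 8, np.nan, 5),
                ("s2", "A", "chr1", 1000, 6000, 3, "CNP", 12, 0.01, 5),
            ]
        )
        out, _ = resolve_call_conflicts(calls)
        assert len(out) == 2


class TestBuildCnvrs:
    def test_disjoint_calls_make_two_regions(self):
        calls = make_calls(
            [
                ("s1", "A", "chr1", 0, 100, 1, "RARE"),
                ("s2", "A", "chr1", 200, 300, 1, "RARE"),
            ]
        )
        assert len(build_cnvrs(calls)) == 2

    def test_transitive_chaining(self):
        calls = make_calls(
            [
                ("s1", "A", "chr1", 0, 100, 1, "RARE"),
                ("s2", "A", "chr1", 90, 150, 1, "RARE"),
                ("s3", "A", "chr1", 140, 400, 1, "RARE"),
            ]
        )
        cnvrs = build_cnvrs(calls)
        assert len(cnvrs) == 1
        assert (cnvrs[0].start, cnvrs[0].end) == (0, 400)

    def test_abutting_calls_do_not_merge(self):
        calls = make_calls(
            [
                ("s1", "A", "chr1", 0, 100, 1, "RARE"),
                ("s2", "A", "chr1", 100, 200, 1, "RARE"),
            ]
        )
        assert len(build_cnvrs(calls)) == 2

    def test_matches_brute_force_components_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = rng.integers(2, 60)
            starts = rng.integers(0, 2000, size=n)
            lengths = rng.integers(1, 300, size=n)
            chroms = rng.choice(["chr1", "chr2"], size=n)
            calls = make_calls(
                [
                    (f"s{i % 7}", "A", chroms[i], int(starts[i]),
                     int(starts[i] + lengths[i]), 1, "RARE")
                    for i in range(n)
                ]
            )
            cnvrs = build_cnvrs(calls)
            labels = brute_force_components(
                list(zip(calls["chrom"], calls["start"], calls["end"]))
            )
            assert len(cnvrs) == len(set(labels))
            # every call lies inside exactly one CNVR
            total_members = sum(len(r.members) for r in cnvrs)
            assert total_members == n
            for r in cnvrs:
                assert r.start == r.members["start"].min()
                assert r.end == r.members["end"].max()


class TestDissect:
    def test_two_member_example(self):
        calls = make_calls(
            [
                ("s1", "A", "chr1", 100, 200, 1, "RARE"),
                ("s2", "A", "chr1", 150, 300, 1, "RARE"),
            ]
        )
        (cnvr,) = build_cnvrs(calls)
        segs = [(s.start, s.end) for s in dissect_cnvsegs(cnvr)]
        assert segs == [(100, 150), (150, 200), (200, 300)]

    def test_single_member_is_one_segment(self):
        calls = make_calls([("s1", "A", "chr1", 100, 200, 1, "RARE")])
        (cnvr,) = build_cnvrs(calls)
        segs = dissect_cnvsegs(cnvr)
        assert len(segs) == 1 and (segs[0].start, segs[0].end) == (100, 200)

    def test_segments_tile_and_match_breakpoint_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(2, 15)
            start0 = 1000
            rows, cursor = [], start0
            # overlapping chain with random breakpoints
            for i in range(n):
                s = cursor - rng.integers(0, 50)
                e = s + rng.integers(60, 400)
                rows.append((f"s{i}", "A", "chr1", int(s), int(e), 1, "RARE"))
                cursor = e
            cnvrs = build_cnvrs(make_calls(rows))
            for r in cnvrs:
                segs = dissect_cnvsegs(r)
                bounds = sorted({x for row in r.members.itertuples() for x in (row.start, row.end)})
                assert len(segs) == len(bounds) - 1
                assert segs[0].start == r.start and segs[-1].end == r.end
                assert sum(s.end - s.start for s in segs) == r.end - r.start
                for a, b in zip(segs[:-1], segs[1:]):
                    assert a.end == b.start


class TestAssignGenotypes:
    SAMPLES = pd.DataFrame({"sample_id": ["s1", "s2", "s3"], "population": "A"})

    def test_no_call_is_copy_neutral(self):
        calls = make_calls([("s1", "A", "chr1", 0, 5000, 1, "RARE")])
        cnvrs = build_cnvrs(calls)
        g = assign_genotypes(calls, cnvrs, self.SAMPLES)
        assert g.iloc[1, 0] == 2 and g.iloc[0, 0] == 1

    def test_longest_call_wins(self):
        calls = make_calls(
            [
                ("s1", "A", "chr1", 0, 60_000, 1, "RARE"),
                ("s1", "A", "chr1", 10_000, 20_000, 3, "RARE", 99, np.nan, 5),
                ("s2", "A", "chr1", 0, 60_000, 1, "RARE"),
            ]
        )
        cnvrs = build_cnvrs(calls)
        g = assign_genotypes(calls, cnvrs, self.SAMPLES)
        assert g.loc["s1"].iloc[0] == 1

    def test_equal_length_tie_prefers_lower_state(self):
        calls = make_calls(
            [
                ("s1", "A", "chr1", 0, 10_000, 3, "RARE"),
                ("s1", "A", "chr1", 5_000, 15_000, 1, "RARE"),
            ]
        )
        cnvrs = build_cnvrs(calls)
        g = assign_genotypes(calls, cnvrs, self.SAMPLES)
        # exhaustive oracle over the two candidates: equal length -> state 1
        assert g.loc["s1"].iloc[0] == 1

    def test_missing_marker_propagates(self):
        calls = make_calls(
            [
                ("s1", "A", "chr1", 0, 5000, 1, "CNP", 10, 0.5, 5),
                ("s2", "A", "chr1", 100, 4000, 1, "CNP", 10, 0.01, 5),
            ]
        )
        resolved, missing = resolve_call_conflicts(calls)
        cnvrs = build_cnvrs(resolved)
        g = assign_genotypes(resolved, cnvrs, self.SAMPLES, missing)
        assert np.isnan(g.loc["s1"].iloc[0])
        assert g.loc["s2"].iloc[0] == 1
        assert g.loc["s3"].iloc[0] == 2

    def test_segment_genotypes_consistent_with_cnvr(self, clean_cohort):
        calls, samples, truth = clean_cohort
        cnvrs, genotypes, segs, seg_genotypes = build_map(
            calls, samples, with_segments=True
        )
        # for non-complex CNVRs the longest-segment state equals the CNVR state
        for r in cnvrs:
            if r.complex:
                continue
            own = [s for s in segs if s.parent is r]
            longest = max(own, key=lambda s: s.end - s.start)
            pd.testing.assert_series_equal(
                seg_genotypes[longest.locus_id],
                genotypes[r.locus_id],
                check_names=False,
            )


class TestClassify:
    def test_pure_deletion_non_singleton(self):
        calls = make_calls(
            [(f"s{i}", "A", "chr1", 0, 5000, 1, "RARE") for i in range(3)]
        )
        (cnvr,) = build_cnvrs(calls)
        assert cnvr.cnv_class == "deletion"
        assert not cnvr.singleton and not cnvr.complex

    def test_complex_flag(self):
        calls = make_calls(
            [
                ("s1", "A", "chr1", 0, 5000, 1, "RARE"),
                ("s1", "A", "chr1", 4000, 9000, 3, "RARE"),
            ]
        )
        (cnvr,) = build_cnvrs(calls)
        assert cnvr.complex and cnvr.cnv_class == "multiallelic" and cnvr.singleton

    def test_event_frequency_direct_count(self):
        n, carriers = 155, 16
        calls = make_calls(
            [(f"s{i}", "A", "chr1", 0, 5000, 1, "RARE") for i in range(carriers)]
        )
        samples = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(n)], "population": "A"}
        )
        (cnvr,) = build_cnvrs(calls)
        g = assign_genotypes(calls, [cnvr], samples)
        classify_cnvr(cnvr, g[cnvr.locus_id])
        assert cnvr.event_frequency == pytest.approx(16 / 155)


class TestCompareReference:
    def _cnvrs(self, triples):
        calls = make_calls(
            [(f"s{i}", "A", c, s, e, 1, "RARE") for i, (c, s, e) in enumerate(triples)]
        )
        return build_cnvrs(calls)

    def test_disjoint_reference_all_novel(self):
        cnvrs = self._cnvrs([("chr1", 0, 100), ("chr2", 0, 100)])
        ref = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [600], "name": ["x"]})
        assert compare_reference(cnvrs, ref) == 2

    def test_self_reference_none_novel(self):
        cnvrs = self._cnvrs([("chr1", 0, 100), ("chr2", 0, 100)])
        ref = pd.DataFrame(
            {"chrom": [r.chrom for r in cnvrs], "start": [r.start for r in cnvrs],
             "end": [r.end for r in cnvrs], "name": "."}
        )
        assert compare_reference(cnvrs, ref) == 0

    def test_random_case_matches_all_pairs_scan(self):
        rng = np.random.default_rng(9)
        cnvrs = self._cnvrs(
            [("chr1", int(s), int(s + l)) for s, l in
             zip(rng.integers(0, 5000, 25), rng.integers(1, 400, 25))]
        )
        ref = pd.DataFrame(
            {"chrom": "chr1", "start": rng.integers(0, 5000, 10),
             "end": 0, "name": "."}
        )
        ref["end"] = ref["start"] + rng.integers(1, 400, 10)
        novel = compare_reference(cnvrs, ref)
        brute = sum(
            not any(
                r.start < e and s < r.end
                for s, e in zip(ref["start"], ref["end"])
            )
            for r in cnvrs
        )
        assert novel == brute


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 1000), st.integers(1, 200)),
        min_size=1,
        max_size=40,
    )
)
def test_union_consistency_property(intervals):
    """Every call lies in exactly one CNVR and unions match brute force."""
    calls = make_calls(
        [
            (f"s{i % 5}", "A", "chr1", s, s + l, 1, "RARE")
            for i, (s, l) in enumerate(intervals)
        ]
    )
    cnvrs = build_cnvrs(calls)
    labels = brute_force_components(
        [("chr1", s, s + l) for s, l in intervals]
    )
    assert len(cnvrs) == len(set(labels))
    assert sum(len(r.members) for r in cnvrs) == len(intervals)
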