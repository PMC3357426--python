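"""Tiling rules, run collection, depth weighting and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metacaz.io_formats import Contig, HitRecord, ValidationError
from metacaz.tiling_profile import (
    FamilyProfile,
    TileAssignment,
    TilingParams,
    best_hit_per_tile,
    bin_profiles,
    collect_runs,
    family_totals,
    normalize_per_million,
    rank_families,
    tile_contig,
)


def _hit(qid, fam, evalue, bitscore=100.0, qstart=0, qend=100, subject="p1"):
    return HitRecord(query_id=qid, subject_id=subject, family=fam,
                     evalue=evalue, bitscore=bitscore, qstart=qstart, qend=qend)


class TestTileContig:
    def test_length_900_gives_5_tiles(self):
        assert tile_contig(("c", 900)) == [
            ("c", 0, 300), ("c", 150, 450), ("c", 300, 600),
            ("c", 450, 750), ("c", 600, 900)]

    def test_length_1000_gives_6_tiles_with_250nt_tail(self):
        tiles = tile_contig(("c", 1000))
        assert len(tiles) == 6
        assert tiles[-1] == ("c", 750, 1000)    # 250 >= 150 tail kept

    def test_short_tail_suppressed(self):
        # 1049: start 750 -> [750,1049) length 299 >= 150 kept, stop
        assert tile_contig(("c", 1049))[-1] == ("c", 750, 1049)
        # 920: [600,900)? no - [600,920) reaches end at length 320>300?
        tiles = tile_contig(("c", 920))
        assert tiles[-1] == ("c", 750, 920)     # 170 >= 150

    def test_contig_shorter_than_min_tail_yields_one_tile(self):
        assert tile_contig(("c", 100)) == [("c", 0, 100)]

    @given(st.integers(min_value=300, max_value=5000))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_coverage_one_to_two_tiles_per_nucleotide(self, length):
        cover = np.zeros(length, dtype=int)
        for _, s, e in tile_contig(("c", length)):
            cover[s:e] += 1
        assert cover.min() >= 1
        assert cover.max() <= 2

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            TilingParams(tile_len=100, step=200)


class TestBestHitPerTile:
    def test_minimum_evalue_wins(self):
        hits = [_hit("c:0-300", "GH13", 1e-30), _hit("c:0-300", "GH3", 1e-12)]
        assert best_hit_per_tile(hits)["c:0-300"].family == "GH13"

    def test_bitscore_breaks_evalue_tie(self):
        hits = [_hit("c:0-300", "GH3", 1e-20, bitscore=90),
                _hit("c:0-300", "GT2", 1e-20, bitscore=80)]
        assert best_hit_per_tile(hits)["c:0-300"].family == "GH3"

    def test_family_then_subject_break_full_tie(self):
        hits = [_hit("c:0-300", "GT2", 1e-20), _hit("c:0-300", "GH13", 1e-20)]
        assert best_hit_per_tile(hits)["c:0-300"].family == "GH13"
        hits = [_hit("c:0-300", "GH13", 1e-20, subject="p2"),
                _hit("c:0-300", "GH13", 1e-20, subject="p1")]
        assert best_hit_per_tile(hits)["c:0-300"].contig_id == "c"
        assert best_hit_per_tile(hits)["c:0-300"].start == 0

    def test_span_lifted_to_contig_coordinates(self):
        a = best_hit_per_tile([_hit("c:150-450", "GH13", 1e-20,
                                    qstart=10, qend=40)])["c:150-450"]
        assert (a.start, a.end) == (160, 190)

    def test_tile_mode_attributes_whole_tile(self):
        a = best_hit_per_tile([_hit("c:150-450", "GH13", 1e-20,
                                    qstart=10, qend=40)],
                              run_length="tile")["c:150-450"]
        assert (a.start, a.end) == (150, 450)


class TestCollectRuns:
    def test_overlapping_same_family_spans_union(self):
        asg = [
            TileAssignment("c", 0, 300, "GH13", 1e-20, 100, 10, 290),
            TileAssignment("c", 150, 450, "GH13", 1e-20, 100, 160, 440),
        ]
        (run,) = collect_runs(asg, {"c": 1000})
        assert (run.start, run.end, run.covered_nt) == (10, 440, 430)

    def test_adjacent_different_families_stay_separate(self):
        asg = [
            TileAssignment("c", 0, 300, "GH13", 1e-20, 100, 10, 140),
            TileAssignment("c", 150, 450, "GH3", 1e-20, 100, 150, 300),
        ]
        runs = collect_runs(asg, {"c": 1000})
        assert sorted((r.family, r.covered_nt) for r in runs) == [
            ("GH13", 130), ("GH3", 150)]

    def test_span_outside_contig_rejected(self):
        asg = [TileAssignment("c", 0, 300, "GH13", 1e-20, 100, 10, 400)]
        with pytest.raises(ValidationError):
            collect_runs(asg, {"c": 350})

    def test_covered_nt_matches_per_nucleotide_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            n_spans = int(rng.integers(1, 12))
            fams = ["GH13", "GH3", "GT2"]
            asg = []
            marks = {f: np.zeros(2000, dtype=bool) for f in fams}
            for _ in range(n_spans):
                a = int(rng.integers(0, 1900))
                b = a + int(rng.integers(1, 100))
                f = fams[rng.integers(3)]
                asg.append(TileAssignment("c", 0, 300, f, 1e-20, 100, a, b))
                marks[f][a:b] = True
            runs = collect_runs(asg, {"c": 2000})
            got = {}
            for r in runs:
                got[r.family] = got.get(r.family, 0) + r.covered_nt
            want = {f: int(m.sum()) for f, m in marks.items() if m.sum()}
            assert got == want
            # runs per family are disjoint maximal intervals
            by_fam = {}
            for r in runs:
                by_fam.setdefault(r.family, []).append((r.start, r.end))
            for spans in by_fam.values():
                spans.sort()
                for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
                    assert e0 < s1


class TestTotalsAndNormalization:
    def test_run_times_depth(self):
        asg = [TileAssignment("c", 0, 300, "f", 1e-20, 100, 0, 300)]
        runs = collect_runs(asg, {"c": 1000}, {"c": 2.0})
        assert family_totals(runs) == {"f": 600.0}

    def test_no_runs_empty_map(self):
        assert family_totals([]) == {}

    def test_missing_depth_table_means_unweighted(self):
        asg = [TileAssignment("c", 0, 300, "f", 1e-20, 100, 0, 250)]
        runs = collect_runs(asg, {"c": 1000})
        assert family_totals(runs) == {"f": 250.0}

    def test_per_million_arithmetic(self):
        contigs = [Contig("c", "A" * 1000, 2.0)]
        prof = normalize_per_million({"GH5": 600.0}, contigs)
        assert prof.per_million == {"GH5": 300000.0}
        assert prof.total_weighted_bases == 2000.0

    def test_contig_duplication_leaves_per_million_unchanged(self):
        contigs = [Contig("a", "A" * 1000, 2.0), Contig("b", "C" * 500, 3.0)]
        doubled = contigs + [Contig("a2", "A" * 1000, 2.0),
                             Contig("b2", "C" * 500, 3.0)]
        p1 = normalize_per_million({"f": 700.0}, contigs)
        p2 = normalize_per_million({"f": 1400.0}, doubled)
        assert p1.per_million == pytest.approx(p2.per_million, rel=1e-12)

    def test_empty_contigs_rejected(self):
        with pytest.raises(ValidationError):
            normalize_per_million({"f": 1.0}, [])


class TestBinProfiles:
    def _runs_contigs(self):
        contigs = [Contig("c1", "A" * 1500, 2.0), Contig("c2", "C" * 1200, 1.0),
                   Contig("c3", "G" * 800, 5.0)]   # c3 below the 1 kb cut
        asg = [
            TileAssignment("c1", 0, 300, "GH13", 1e-20, 100, 0, 300),
            TileAssignment("c2", 0, 300, "GH3", 1e-20, 100, 0, 200),
            TileAssignment("c3", 0, 300, "GH13", 1e-20, 100, 0, 100),
        ]
        lengths = {c.id: len(c) for c in contigs}
        depths = {c.id: c.depth for c in contigs}
        runs = collect_runs(asg, lengths, depths)
        return runs, contigs, depths

    def test_single_bin_equals_whole_metagenome_restricted(self):
        runs, contigs, depths = self._runs_contigs()
        profs = bin_profiles(runs, contigs, {"c1": "binA", "c2": "binA"}, depths)
        whole = normalize_per_million(
            family_totals([r for r in runs if r.contig_id != "c3"], depths),
            [c for c in contigs if len(c) >= 1000], depths)
        assert profs["binA"].per_million == pytest.approx(whole.per_million)

    def test_short_contigs_excluded_entirely(self):
        runs, contigs, depths = self._runs_contigs()
        profs = bin_profiles(runs, contigs, {"c1": "binA", "c3": "binA"}, depths)
        assert "GH13" in profs["binA"].per_million
        # c3's GH13 contribution (100 nt x depth 5) must not appear
        assert profs["binA"].weighted_nt["GH13"] == 600.0

    def test_unassigned_contigs_fall_into_no_match(self):
        runs, contigs, depths = self._runs_contigs()
        profs = bin_profiles(runs, contigs, {"c1": "binA"}, depths)
        assert set(profs) == {"binA", "no match"}
        assert profs["no match"].weighted_nt == {"GH3": 200.0}

    def test_partition_additivity_of_weighted_nt(self):
        runs, contigs, depths = self._runs_contigs()
        profs = bin_profiles(runs, contigs, {"c1": "binA", "c2": "binB"}, depths)
        summed = {}
        for p in profs.values():
            for f, w in p.weighted_nt.items():
                summed[f] = summed.get(f, 0.0) + w
        whole = family_totals([r for r in runs if r.contig_id != "c3"], depths)
        assert summed == pytest.approx(whole)

    def test_metagenome_wide_denominator_flag(self):
        runs, contigs, depths = self._runs_contigs()
        profs = bin_profiles(runs, contigs, {"c1": "binA", "c2": "binB"},
                             depths, per_bin_denominator=False)
        assert profs["binA"].total_weighted_bases == \
               profs["binB"].total_weighted_bases == 1500 * 2.0 + 1200 * 1.0


class TestRankFamilies:
    def test_tie_broken_lexicographically(self):
        top = rank_families({"a": 5.0, "b": 3.0, "c": 3.0}, top_n=2)
        assert [t[0] for t in top] == ["a", "b"]

    def test_shares_sum_to_one_when_all_kept(self):
        top = rank_families({"a": 5.0, "b": 3.0, "c": 2.0}, top_n=10)
        assert sum(t[2] for t in top) == pytest.approx(1.0)

    def test_top_n_must_be_positive(self):
        with pytest.raises(ValidationError):
            rank_families({"a": 1.0}, top_n=0)

    def test_share_uses_grand_total_not_topn_total(self):
        top = rank_families({"a": 60.0, "b": 30.0, "c": 10.0}, top_n=1)
        assert top[0][2] == pytest.approx(0.6)
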