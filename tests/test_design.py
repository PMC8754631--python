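"""Candidate construction: concatemers, interleaving, markers, mutagenesis."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from atcen.composition import AnnotatedSequence, at_fraction, find_at_runs
from atcen.design import (
    DesignSpec,
    MarkerSet,
    build_interleaved,
    concatemerize,
    disrupt_runs,
    introduce_markers,
    reduce_at_preserving_runs,
    select_at_windows,
)
from atcen.simulate import gen_sequence

dna = st.text(alphabet="ACGT", min_size=1, max_size=120)


def seq(s: str) -> AnnotatedSequence:
    return AnnotatedSequence(id="t", residues=s)


class TestConcatemerize:
    def test_heptamer_and_pentamer_of_889bp_unit(self):
        unit = gen_sequence(889, 0.70, seed=11)
        hepta = concatemerize(unit, 7)
        penta = concatemerize(unit, 5)
        assert len(hepta) == 6223
        assert len(penta) == 4445
        assert round(len(hepta) / 1000, 1) == 6.2
        assert round(len(penta) / 1000, 1) == 4.4

    def test_identity_for_single_copy(self, random_sequence):
        out = concatemerize(random_sequence, 1)
        assert out.residues == random_sequence.residues

    def test_rejects_zero_copies(self, random_sequence):
        with pytest.raises(ValueError):
            concatemerize(random_sequence, 0)

    @given(dna, st.integers(min_value=1, max_value=6))
    def test_length_and_composition_invariants(self, residues, n):
        unit = seq(residues)
        out = concatemerize(unit, n)
        assert len(out) == n * len(unit)
        assert at_fraction(out) == pytest.approx(at_fraction(unit))
        assert len([f for f in out.features if f[2] == "unit"]) == n


class TestBuildInterleaved:
    def _pools(self, seed0):
        pool_a = [gen_sequence(20, 0.94, seed=seed0 + i).residues for i in range(30)]
        pool_b = [gen_sequence(20, 0.55, seed=seed0 + 100 + i).residues
                  for i in range(30)]
        return pool_a, pool_b

    def test_overall_at_near_weighted_mean(self):
        pool_a, pool_b = self._pools(1)
        spec = DesignSpec(unit_length=20, segment_a_at=0.94, segment_b_at=0.55,
                          total_length=5900, seed=42)
        out = build_interleaved(spec, pool_a, pool_b)
        assert len(out) == 5900
        # per the design the overall A+T equals the mean of the emitted
        # segments, which centres on (0.94 + 0.55) / 2 = 0.745
        assert at_fraction(out) == pytest.approx(0.745, abs=0.015)

    def test_overall_at_equals_recount_of_emitted_segments(self):
        pool_a, pool_b = self._pools(2)
        spec = DesignSpec(20, 0.94, 0.55, 1000, seed=3)
        out = build_interleaved(spec, pool_a, pool_b)
        per_segment = [at_fraction(seq(out.residues[s:e]))
                       for s, e, _ in out.features]
        assert at_fraction(out) == pytest.approx(np.mean(per_segment))

    def test_single_segment_total_returns_a_pool_segment(self):
        pool_a, pool_b = self._pools(4)
        spec = DesignSpec(20, 0.94, 0.55, 20, seed=0)
        out = build_interleaved(spec, pool_a, pool_b)
        assert out.residues in pool_a

    def test_truncates_to_whole_segments(self):
        pool_a, pool_b = self._pools(5)
        spec = DesignSpec(20, 0.94, 0.55, 59, seed=0)
        assert len(build_interleaved(spec, pool_a, pool_b)) == 40

    def test_empty_pool_rejected(self):
        spec = DesignSpec(20, 0.94, 0.55, 100, seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            build_interleaved(spec, [], ["A" * 20])

    def test_wrong_segment_length_rejected(self):
        spec = DesignSpec(20, 0.94, 0.55, 100, seed=0)
        with pytest.raises(ValueError, match="unit_length"):
            build_interleaved(spec, ["A" * 19], ["T" * 20])

    def test_seed_reproducibility(self):
        pool_a, pool_b = self._pools(6)
        spec = DesignSpec(20, 0.94, 0.55, 2000, seed=9)
        assert build_interleaved(spec, pool_a, pool_b).residues == \
            build_interleaved(spec, pool_a, pool_b).residues


class TestIntroduceMarkers:
    def test_default_marking_of_9460bp_central_core(self):
        core = gen_sequence(9460, 0.70, seed=21)
        marked, markers = introduce_markers(core, seed=22)
        assert len(markers.deletions) == 9  # one per full 1 kb block
        assert len(marked) == 9424
        assert all(d.length == 4 for d in markers.deletions)

    def test_zero_length_deletion_is_identity(self, random_sequence):
        marked, markers = introduce_markers(random_sequence, del_len=0)
        assert marked.residues == random_sequence.residues
        assert markers.deletions == []

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_reconstructs_original(self, seed):
        original = gen_sequence(5000, 0.72, seed=seed)
        marked, markers = introduce_markers(original, seed=seed)
        assert markers.revert(marked).residues == original.residues

    def test_deleted_length_accounting(self):
        original = gen_sequence(7300, 0.7, seed=30)
        marked, markers = introduce_markers(original, seed=31)
        assert sum(d.length for d in markers.deletions) == \
            len(original) - len(marked)

    def test_excessive_jitter_rejected(self):
        original = gen_sequence(5000, 0.7, seed=32)
        with pytest.raises(ValueError, match="jitter"):
            introduce_markers(original, jitter=600, seed=0)

    def test_markers_tsv_round_trip(self, tmp_path):
        original = gen_sequence(3000, 0.7, seed=33)
        _, markers = introduce_markers(original, seed=34)
        path = tmp_path / "markers.tsv"
        markers.to_tsv(path)
        assert MarkerSet.from_tsv(path) == markers

    def test_bed_export_uses_unmodified_coordinates(self, tmp_path):
        original = gen_sequence(3000, 0.7, seed=35)
        _, markers = introduce_markers(original, seed=36)
        path = tmp_path / "markers.bed"
        markers.to_bed(path, chrom="cc")
        for line, d in zip(path.read_text().splitlines(), markers.deletions):
            chrom, s, e, _ = line.split("\t")
            assert (int(s), int(e)) == (d.position, d.position + d.length)

    def test_overlapping_deletions_rejected(self):
        from atcen.design import Deletion
        with pytest.raises(ValueError, match="overlap"):
            MarkerSet([Deletion(10, 4, "AAAA"), Deletion(12, 4, "AAAA")])


class TestDisruptRuns:
    def test_aaaa_forced_single_substitution(self):
        out = disrupt_runs(seq("AAAA"), max_run=2, seed=0)
        assert out.residues[0:2] == "AA"
        assert out.residues[2] in "GC"
        assert out.residues[3] == "A"

    def test_sequence_without_runs_unchanged(self):
        assert disrupt_runs(seq("ACGTACGT"), seed=0).residues == "ACGTACGT"

    def test_postcondition_and_minimal_substitutions(self):
        s = gen_sequence(4000, 0.70, run_intensity=4.0, seed=40)
        out = disrupt_runs(s, max_run=2, seed=41)
        assert find_at_runs(out, 3) == []
        assert len(out) == len(s)
        expected_subs = sum(r.length // 3 for r in find_at_runs(s, 3))
        observed_subs = sum(a != b for a, b in zip(s.residues, out.residues))
        assert observed_subs == expected_subs
        assert at_fraction(s) - at_fraction(out) == \
            pytest.approx(observed_subs / len(s))

    @given(dna, st.integers(min_value=1, max_value=4))
    def test_never_increases_at(self, residues, max_run):
        s = seq(residues)
        out = disrupt_runs(s, max_run=max_run, seed=1)
        assert at_fraction(out) <= at_fraction(s)
        assert all(r.length <= max_run for r in find_at_runs(out, 1))

    def test_seed_reproducibility(self):
        s = gen_sequence(1000, 0.8, seed=42)
        assert disrupt_runs(s, seed=7).residues == disrupt_runs(s, seed=7).residues


class TestReduceAtPreservingRuns:
    def test_identity_at_current_composition(self, random_sequence):
        out = reduce_at_preserving_runs(random_sequence,
                                        at_fraction(random_sequence), seed=0)
        assert out.residues == random_sequence.residues

    def test_aaaatgtg_to_half(self):
        s = seq("AAAATGTG")  # one preserved run [0,4), A+T 0.75
        out = reduce_at_preserving_runs(s, 0.5, seed=0)
        assert out.residues[0:4] == "AAAA"
        assert at_fraction(out) == 0.5
        # only the two A/T residues outside the run may change
        changed = [i for i, (a, b) in enumerate(zip(s.residues, out.residues))
                   if a != b]
        assert set(changed) <= {4, 6}
        assert all(out.residues[i] in "GC" for i in changed)

    @pytest.mark.parametrize("seed", range(4))
    def test_runs_preserved_exactly(self, seed):
        s = gen_sequence(3000, 0.75, run_intensity=4.0, seed=seed)
        runs = find_at_runs(s, 3)
        floor = sum(r.length for r in runs) / len(s)
        target = max(floor, at_fraction(s) - 0.06)
        out = reduce_at_preserving_runs(s, target, seed=seed)
        assert find_at_runs(out, 3) == runs
        for r in runs:
            assert out.residues[r.start:r.end] == s.residues[r.start:r.end]
        assert abs(at_fraction(out) - target) <= 1.0 / len(s)

    def test_unachievable_target_reports_minimum(self):
        s = seq("AAAAAAGG")  # run contributes 6/8 = 0.75 minimum
        with pytest.raises(ValueError, match="0.75"):
            reduce_at_preserving_runs(s, 0.5, seed=0)

    def test_target_above_current_rejected(self):
        with pytest.raises(ValueError, match="exceeds current"):
            reduce_at_preserving_runs(seq("ACGTACGT"), 0.9, seed=0)


class TestSelectAtWindows:
    def test_uniform_low_at_genome_is_empty(self):
        genome = gen_sequence(20000, 0.60, seed=50)
        assert select_at_windows(genome, 2000, 0.75) == []

    def test_planted_island_ranked_first(self):
        bg = gen_sequence(30000, 0.60, seed=51)
        island = gen_sequence(2000, 0.78, seed=52)
        residues = bg.residues[:10000] + island.residues + bg.residues[12000:]
        genome = AnnotatedSequence(id="g", residues=residues)
        hits = select_at_windows(genome, 2000, 0.70)
        assert hits[0][0] == 10000
        assert hits[0][2] == pytest.approx(0.78, abs=0.01)

    def test_ranking_matches_brute_force(self, random_sequence):
        window, min_at = 100, 0.5
        hits = select_at_windows(random_sequence, window, min_at)
        brute = []
        for s_ in range(0, len(random_sequence) - window + 1, window):
            sub = random_sequence.residues[s_:s_ + window]
            at = (sub.count("A") + sub.count("T")) / window
            if at >= min_at:
                brute.append((s_, s_ + window, at))
        brute.sort(key=lambda t: (-t[2], t[0]))
        assert [(h[0], h[1]) for h in hits] == [(b[0], b[1]) for b in brute]
        assert np.allclose([h[2] for h in hits], [b[2] for b in brute])
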