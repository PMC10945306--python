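"""The iterative CMBS caller: planted-peak behavior, equivalence with a
full-rescan reference implementation, exclusion rules, invariants."""

import numpy as np
import pytest
from conftest import make_cmbs, naive_call_cmbs, random_smoothed_tracks

from mcmchec.core_io import GenomeAssembly
from mcmchec.coverage import FULL_LENGTH, MIDPOINT, CoverageTrack, make_coverage
from mcmchec.peakcall import (
    PeakCallConfig,
    apply_exclusions,
    call_cmbs,
    rank_abundance_curve,
)


def tracks_from_arrays(full_vals: dict, mid_vals: dict):
    asm = GenomeAssembly(tuple(full_vals), {c: len(v) for c, v in full_vals.items()})
    full = CoverageTrack(asm, {c: np.asarray(v, float) for c, v in full_vals.items()},
                         mode=FULL_LENGTH, smoothed_window=10)
    mid = CoverageTrack(asm, {c: np.asarray(v, float) for c, v in mid_vals.items()},
                        mode=MIDPOINT, smoothed_window=10)
    return full, mid


def bump(n, center, width, height):
    v = np.zeros(n)
    lo, hi = max(center - width, 0), min(center + width, n)
    v[lo:hi] = height * np.hanning(hi - lo)
    return v


class TestCallCmbs:
    def test_single_isolated_peak(self):
        full = bump(5000, 2500, 40, 10)
        full, mid = tracks_from_arrays({"c": full}, {"c": full.copy()})
        (peak,) = call_cmbs(full, mid)
        assert peak.rank == 1
        assert abs(peak.midpoint - 2500) <= 2

    def test_two_distant_peaks_taller_first(self):
        v = bump(5000, 1000, 40, 5) + bump(5000, 2200, 40, 9)
        full, mid = tracks_from_arrays({"c": v}, {"c": v.copy()})
        peaks = call_cmbs(full, mid)
        assert len(peaks) == 2
        assert abs(peaks[0].midpoint - 2200) <= 2  # taller one first
        assert abs(peaks[1].midpoint - 1000) <= 2

    def test_close_second_peak_suppressed_by_zeroing(self):
        v = bump(5000, 1000, 40, 9) + bump(5000, 1300, 40, 5)
        full, mid = tracks_from_arrays({"c": v}, {"c": v.copy()})
        peaks = call_cmbs(full, mid)
        assert len(peaks) == 1  # 300 bp < 500 bp zeroing radius

    def test_refinement_moves_midpoint_to_sharp_track(self):
        full = bump(5000, 2500, 60, 10)
        mid = np.zeros(5000)
        mid[2530] = 3.0  # sharp midpoint-track peak 30 bp away
        full, mid = tracks_from_arrays({"c": full}, {"c": mid})
        (peak,) = call_cmbs(full, mid)
        assert peak.midpoint == 2530
        assert peak.midpoint_signal == 3.0

    def test_unsmoothed_tracks_rejected(self, tiny_assembly):
        z = {c: np.zeros(tiny_assembly.length(c)) for c in tiny_assembly.chrom_names}
        full = CoverageTrack(tiny_assembly, z, mode=FULL_LENGTH)
        mid = CoverageTrack(tiny_assembly, dict(z), mode=MIDPOINT)
        with pytest.raises(ValueError, match="smoothed"):
            call_cmbs(full, mid)

    def test_all_zero_tracks_give_empty_list(self):
        full, mid = tracks_from_arrays({"c": np.zeros(2000)}, {"c": np.zeros(2000)})
        assert call_cmbs(full, mid) == []

    def test_input_tracks_not_mutated(self):
        v = bump(3000, 1500, 40, 8)
        full, mid = tracks_from_arrays({"c": v}, {"c": v.copy()})
        before = full.values["c"].copy()
        call_cmbs(full, mid)
        np.testing.assert_array_equal(full.values["c"], before)

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(11)
        full, mid = random_smoothed_tracks(rng, {"a": 8000, "b": 5000})
        assert call_cmbs(full, mid) == call_cmbs(full, mid)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_full_rescan_reference(self, seed):
        rng = np.random.default_rng(seed)
        lengths = {"a": int(rng.integers(2000, 30_000)),
                   "b": int(rng.integers(1000, 20_000))}
        full, mid = random_smoothed_tracks(rng, lengths)
        config = PeakCallConfig(max_peaks=10_000)
        assert call_cmbs(full, mid, config) == naive_call_cmbs(full, mid, config)


class TestInvariants:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_separation_and_monotone_abundance(self, seed):
        rng = np.random.default_rng(seed)
        full, mid = random_smoothed_tracks(rng, {"a": 30_000, "b": 15_000})
        peaks = call_cmbs(full, mid)
        assert [p.rank for p in peaks] == list(range(1, len(peaks) + 1))
        abund = [p.abundance for p in peaks]
        assert all(x >= y for x, y in zip(abund, abund[1:]))
        by_chrom = {}
        for p in peaks:
            by_chrom.setdefault(p.chrom, []).append(p.midpoint)
        for mids in by_chrom.values():
            mids.sort()
            assert all(b - a > 440 for a, b in zip(mids, mids[1:]))

    def test_separation_on_synthetic_pipeline_output(self, sim):
        by_chrom = {}
        for p in sim.cmbs:
            by_chrom.setdefault(p.chrom, []).append(p.midpoint)
        for mids in by_chrom.values():
            mids.sort()
            assert all(b - a > 440 for a, b in zip(mids, mids[1:]))


class TestExclusions:
    def _config(self, rdna=(), ty=()):
        return PeakCallConfig(
            exclusion_intervals={"rdna": list(rdna), "ty": list(ty)}
        )

    def test_rdna_keeps_only_best_ranked_peak(self):
        peaks = [
            make_cmbs("c", 1000, 1, 10),
            make_cmbs("c", 2000, 2, 8),
            make_cmbs("c", 3000, 3, 5),
            make_cmbs("c", 9000, 4, 2),
        ]
        out = apply_exclusions(peaks, self._config(rdna=[("c", 500, 3500)]))
        assert [(p.midpoint, p.rank) for p in out] == [(1000, 1), (9000, 2)]

    @pytest.mark.parametrize("midpoint, kept", [(399, True), (401, False)])
    def test_ty_margin_boundary_is_inclusive_100(self, midpoint, kept):
        # distance to interval [500, 600) is measured to the nearest
        # contained base: 101 bp away survives, 99 bp away is removed
        peaks = [make_cmbs("c", midpoint, 1, 5)]
        out = apply_exclusions(peaks, self._config(ty=[("c", 500, 600)]))
        assert bool(out) == kept

    def test_ty_distance_exactly_100_removed(self):
        peaks = [make_cmbs("c", 400, 1, 5), make_cmbs("c", 700, 2, 4)]
        out = apply_exclusions(peaks, self._config(ty=[("c", 500, 601)]))
        assert out == []  # 400 is 100 bp from base 500; 700 is 100 from 600

    def test_ranks_renumbered_consecutively(self):
        peaks = [make_cmbs("c", 1000, 1, 9), make_cmbs("c", 5000, 2, 5),
                 make_cmbs("c", 9000, 3, 2)]
        out = apply_exclusions(peaks, self._config(ty=[("c", 4990, 5010)]))
        assert [(p.midpoint, p.rank) for p in out] == [(1000, 1), (9000, 2)]


class TestRankAbundance:
    def test_monotone_table(self):
        peaks = [make_cmbs("c", i * 1000, i, a) for i, a in
                 enumerate([100.0, 10.0, 1.0], start=1)]
        df = rank_abundance_curve(peaks)
        assert df["abundance"].is_monotonic_decreasing
        assert df.shape == (3, 2)

    def test_single_peak(self):
        df = rank_abundance_curve([make_cmbs("c", 10, 1, 7.0)])
        assert df.shape == (1, 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_abundance_curve([])

    def test_synthetic_curve_spans_three_decades(self, sim):
        df = rank_abundance_curve(sim.cmbs)
        top = df.abundance.iloc[0]
        matched = sim.matched[sim.matched.category == "origin"]
        recovered = matched[~matched.recovered_rank.isna()]
        lowest = df.abundance[df["rank"].isin(recovered.recovered_rank)].min()
        assert top / lowest >= 1000
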