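"""PWM scoring semantics, genome scanning against a per-window oracle,
strand symmetry, and the ACS-centric site analyses."""

import numpy as np
import pandas as pd
import pytest
from conftest import make_cmbs

from mcmchec.core_io import AcsRecord, GenomeAssembly, SignalTrack
from mcmchec.motif import (
    HALF_WIN,
    PWM_WIDTH,
    composite_pwm_profile,
    conditional_flank_test,
    cumulative_mcm_around_acs,
    downstream_orientation,
    load_pwm,
    revcomp,
    scan_genome,
    score_17mer,
)

MAX_SCORE = 12.742


@pytest.fixture(scope="module")
def pwm():
    return load_pwm()


def seq_assembly(**seqs):
    return GenomeAssembly(
        tuple(seqs), {c: len(s) for c, s in seqs.items()}, dict(seqs)
    )


class TestScore17mer:
    def test_consensus_reaches_printed_maximum(self, pwm):
        assert round(score_17mer("TTTTTTTATGTTTAGTT", pwm), 3) == MAX_SCORE
        assert round(pwm.max_score, 3) == MAX_SCORE

    def test_all_c_seventeen_mer(self, pwm):
        # hand-summed C column of the probability matrix
        assert round(score_17mer("C" * 17, pwm), 3) == 0.730

    def test_n_makes_score_undefined(self, pwm):
        assert np.isnan(score_17mer("TTTTTTTATGTTTAGTN", pwm))

    def test_wrong_length_rejected(self, pwm):
        with pytest.raises(ValueError, match="17"):
            score_17mer("ACGT", pwm)

    def test_scoring_is_position_wise(self, pwm):
        """Shuffling a 17-mer changes the score: the sum reads each
        position against its own matrix row."""
        rng = np.random.default_rng(0)
        changed = 0
        for _ in range(20):
            s = "".join(rng.choice(list("ACGT"), PWM_WIDTH))
            t = "".join(rng.permutation(list(s)))
            if s != t and score_17mer(s, pwm) != score_17mer(t, pwm):
                changed += 1
        assert changed >= 15


class TestScanGenome:
    def test_planted_consensus_found_once_on_watson(self, pwm):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("AC"), 300))  # consensus cannot occur
        seq = seq[:100] + pwm.consensus + seq[117:]
        w, c = scan_genome(seq_assembly(chr1=seq), pwm)
        hits = np.flatnonzero(np.round(w.values["chr1"], 3) == MAX_SCORE)
        assert hits.tolist() == [100 + HALF_WIN]  # scores index window centers

    def test_planted_revcomp_consensus_hits_crick(self, pwm):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("AC"), 300))
        seq = seq[:100] + revcomp(pwm.consensus) + seq[117:]
        w, c = scan_genome(seq_assembly(chr1=seq), pwm)
        hits = np.flatnonzero(np.round(c.values["chr1"], 3) == MAX_SCORE)
        assert hits.tolist() == [100 + HALF_WIN]

    def test_matches_per_window_oracle(self, pwm):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGTN"), 1000, p=[0.3, 0.2, 0.2, 0.29, 0.01]))
        w, c = scan_genome(seq_assembly(chr1=seq), pwm)
        for start in range(0, len(seq) - PWM_WIDTH + 1, 7):
            window = seq[start : start + PWM_WIDTH]
            center = start + HALF_WIN
            expect_w = score_17mer(window, pwm)
            expect_c = score_17mer(revcomp(window), pwm)
            np.testing.assert_equal(
                np.isnan(w.values["chr1"][center]), np.isnan(expect_w)
            )
            if not np.isnan(expect_w):
                assert w.values["chr1"][center] == pytest.approx(expect_w)
                assert c.values["chr1"][center] == pytest.approx(expect_c)

    def test_strand_antisymmetry(self, pwm):
        """The Crick track equals the Watson track of the reverse-
        complemented genome, index-reversed."""
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 500))
        w, c = scan_genome(seq_assembly(chr1=seq), pwm)
        w_rc, _ = scan_genome(seq_assembly(chr1=revcomp(seq)), pwm)
        np.testing.assert_allclose(
            c.values["chr1"], w_rc.values["chr1"][::-1], equal_nan=True
        )

    def test_edges_are_undefined(self, pwm):
        seq = "ACGT" * 20
        w, _ = scan_genome(seq_assembly(chr1=seq), pwm)
        assert np.isnan(w.values["chr1"][:HALF_WIN]).all()
        assert np.isnan(w.values["chr1"][-HALF_WIN:]).all()


class TestCompositeProfile:
    def _tracks(self, n=2000):
        asm = GenomeAssembly(("c",), {"c": n})
        w = SignalTrack(asm, {"c": np.arange(n, dtype=float) % 7})
        c = SignalTrack(asm, {"c": np.arange(n, dtype=float) % 5})
        return asm, w, c

    def test_identical_windows_reproduce_the_window(self):
        _, w, c = self._tracks()
        sites = [make_cmbs("c", m, i + 1) for i, m in enumerate([700, 707, 714])]
        prof = composite_pwm_profile(sites, w, c, half_width=3)
        # all windows congruent mod 7 -> watson profile equals the window
        np.testing.assert_allclose(
            prof["watson"], w.values["c"][697:704]
        )

    def test_empty_subset_rejected(self):
        _, w, c = self._tracks()
        with pytest.raises(ValueError):
            composite_pwm_profile([], w, c, 10)

    def test_synthetic_origin_flanks_peak_at_planted_offsets(self, sim):
        """ACS motifs planted 35 bp from the Mcm midpoint must surface as
        composite maxima at -35 (Watson) and +35 (Crick)."""
        pwm = load_pwm()
        w, c = scan_genome(sim.assembly, pwm)
        top = [x for x in sim.cmbs if x.rank <= 100]
        prof = composite_pwm_profile(top, w, c, half_width=120)
        w_off = prof["offset"][prof["watson"].idxmax()]
        c_off = prof["offset"][prof["crick"].idxmax()]
        assert abs(w_off - (-35)) <= 5
        assert abs(c_off - 35) <= 5


class TestConditionalFlank:
    def test_threshold_above_maximum_gives_empty_error(self, sim):
        pwm = load_pwm()
        w, c = scan_genome(sim.assembly, pwm)
        with pytest.raises(ValueError, match="0 of"):
            conditional_flank_test(sim.cmbs[:50], w, c, threshold=12.8)

    def test_threshold_zero_selects_everything(self, sim):
        pwm = load_pwm()
        w, c = scan_genome(sim.assembly, pwm)
        res = conditional_flank_test(sim.cmbs[:50], w, c, threshold=0.0)
        assert res["n_selected"] == 50
        pd.testing.assert_frame_equal(res["selected_crick"], res["all_crick"])

    def test_double_acs_origins_keep_crick_enrichment(self, sim):
        """Sites selected for a strong Watson-flank ACS still show a Crick
        composite peak comparable to the full set's."""
        pwm = load_pwm()
        w, c = scan_genome(sim.assembly, pwm)
        top = [x for x in sim.cmbs if x.rank <= 120]
        res = conditional_flank_test(top, w, c, threshold=10.8, half_width=120)
        assert res["n_selected"] >= 5
        sel_peak = res["selected_crick"]["crick"].max()
        all_peak = res["all_crick"]["crick"].max()
        assert sel_peak >= all_peak * 0.8


class TestDownstreamOrientation:
    def test_plus_strand_larger_coordinate_is_downstream(self):
        cmbs = [make_cmbs("c", 1035, 1)]
        n, d, f = downstream_orientation(cmbs, [AcsRecord("c", 1000, "+")])
        assert (n, d, f) == (1, 1, 1.0)

    def test_minus_strand_larger_coordinate_is_upstream(self):
        cmbs = [make_cmbs("c", 1035, 1)]
        n, d, f = downstream_orientation(cmbs, [AcsRecord("c", 1000, "-")])
        assert (n, d, f) == (1, 0, 0.0)

    def test_distance_gate(self):
        cmbs = [make_cmbs("c", 1200, 1)]
        n, d, f = downstream_orientation(cmbs, [AcsRecord("c", 1000, "+")], 100)
        assert n == 0 and np.isnan(f)

    def test_translation_invariance(self, sim):
        acs = sim.truth.acs_sites
        base = downstream_orientation(sim.cmbs, acs)
        shift = 13
        moved_cmbs = [make_cmbs(c.chrom, c.midpoint + shift, c.rank, c.abundance)
                      for c in sim.cmbs]
        moved_acs = [AcsRecord(a.chrom, a.midpoint + shift, a.strand) for a in acs]
        assert downstream_orientation(moved_cmbs, moved_acs) == base

    def test_recovers_configured_downstream_probability(self, sim):
        _, _, frac = downstream_orientation(sim.cmbs, sim.truth.acs_sites, 100)
        assert abs(frac - sim.config.downstream_prob) <= 0.05


class TestCumulativeProfile:
    def _track(self, values):
        asm = GenomeAssembly(("c",), {"c": len(values)})
        return SignalTrack(asm, {"c": np.asarray(values, float)})

    def test_single_window_scaled_to_norm_total(self):
        v = np.zeros(200)
        v[90:110] = 2.0
        prof = cumulative_mcm_around_acs(
            [AcsRecord("c", 100, "+")], self._track(v), half_width=20
        )
        assert prof["cumulative"].sum() == pytest.approx(100.0)

    def test_two_identical_windows_add(self):
        v = np.zeros(400)
        v[90:110] = 1.0
        v[290:310] = 1.0
        prof = cumulative_mcm_around_acs(
            [AcsRecord("c", 100, "+"), AcsRecord("c", 300, "+")],
            self._track(v), half_width=20,
        )
        assert prof["cumulative"].sum() == pytest.approx(200.0)

    def test_minus_strand_window_is_reversed(self):
        v = np.zeros(200)
        v[110:120] = 1.0  # right of the site
        plus = cumulative_mcm_around_acs(
            [AcsRecord("c", 100, "+")], self._track(v), half_width=30
        )
        minus = cumulative_mcm_around_acs(
            [AcsRecord("c", 100, "-")], self._track(v), half_width=30
        )
        np.testing.assert_allclose(
            plus["cumulative"].to_numpy(), minus["cumulative"].to_numpy()[::-1]
        )

    def test_synthetic_mcm_mass_is_downstream_of_acs(self, sim):
        from mcmchec.pipeline import mcm_tracks

        _, mid = mcm_tracks(sim.fragments, sim.assembly)
        prof = cumulative_mcm_around_acs(sim.truth.acs_sites, mid, half_width=300)
        down = prof.loc[prof.offset > 0, "cumulative"].sum()
        up = prof.loc[prof.offset < 0, "cumulative"].sum()
        assert down > up
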