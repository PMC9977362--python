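"""Phase extraction at the tempo frequencies and circular statistics."""

import itertools

import numpy as np
import pytest

from betalat.phase_analysis import (
    FAST_FREQ,
    SLOW_FREQ,
    circ_dist,
    circ_kappa,
    circ_mean,
    circ_r,
    fft_phase_at,
    harrison_kanji_test,
    label_attention,
    rayleigh_test,
    resultant_diff_perm_test,
)

TIMES = np.round(np.arange(0.0, 2.2001, 0.05), 9)


class TestFFTPhase:
    # a 2.2-s rectangular window carries ~0.058 rad of irreducible leakage
    # from the negative-frequency component of a pure tone at 1.25 Hz
    TOL = 0.06

    def test_cosine_has_zero_phase(self):
        x = np.cos(2 * np.pi * SLOW_FREQ * TIMES)
        assert abs(fft_phase_at(x, SLOW_FREQ)) < self.TOL

    def test_sine_is_in_quadrature(self):
        x = np.sin(2 * np.pi * SLOW_FREQ * TIMES)
        assert abs(fft_phase_at(x, SLOW_FREQ) + np.pi / 2) < self.TOL

    def test_known_phase_recovered_at_both_tempos(self):
        for f in (SLOW_FREQ, FAST_FREQ):
            for phi in (-2.5, -1.0, 0.3, 2.0):
                x = np.cos(2 * np.pi * f * TIMES + phi)
                got = fft_phase_at(x, f)
                assert abs(circ_dist(got, phi)) < self.TOL

    def test_matches_direct_projection_oracle(self):
        # oracle: single-frequency projection of the demeaned series onto a
        # complex exponential at the target frequency
        rng = np.random.default_rng(0)
        for f in (SLOW_FREQ, FAST_FREQ):
            x = rng.standard_normal(len(TIMES))
            xd = x - x.mean()
            proj = np.sum(xd * np.exp(-2j * np.pi * f * TIMES))
            assert abs(circ_dist(fft_phase_at(x, f), np.angle(proj))) < 0.02

    def test_grid_resolution_at_most_001_hz(self):
        assert 1.0 / 120.0 <= 0.01

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            fft_phase_at(np.zeros(45), target_freq=11.0, dt=0.05)


class TestLabels:
    @pytest.mark.parametrize(
        "freq,cond,expected",
        [
            (SLOW_FREQ, "attend_slow", "attended"),
            (SLOW_FREQ, "attend_fast", "unattended"),
            (FAST_FREQ, "attend_slow", "unattended"),
            (FAST_FREQ, "attend_fast", "attended"),
        ],
    )
    def test_label_map(self, freq, cond, expected):
        assert label_attention(freq, cond) == expected

    def test_bijection_per_condition(self):
        for cond in ("attend_slow", "attend_fast"):
            labels = {label_attention(f, cond) for f in (SLOW_FREQ, FAST_FREQ)}
            assert labels == {"attended", "unattended"}


class TestRayleigh:
    def test_identical_angles_full_resultant(self):
        res = rayleigh_test(np.full(10, 1.2))
        assert circ_r(np.full(10, 1.2)) == pytest.approx(1.0)
        assert res.p < 1e-6

    def test_uniform_grid_has_zero_resultant(self):
        n = 12
        angles = 2 * np.pi * np.arange(n) / n
        assert circ_r(angles) == pytest.approx(0.0, abs=1e-12)
        res = rayleigh_test(angles)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            rayleigh_test([0.1, 0.2])

    def test_matches_pingouin_reference(self):
        from pingouin import circ_rayleigh

        rng = np.random.default_rng(3)
        for n in (8, 26):
            angles = rng.vonmises(0.5, 1.0, size=n)
            res = rayleigh_test(angles)
            z_ref, p_ref = circ_rayleigh(angles)
            assert res.statistic == pytest.approx(z_ref, rel=1e-9)
            assert res.p == pytest.approx(p_ref, rel=1e-6)

    def test_null_rejection_rate_calibrated(self):
        # uniform-null rejection at alpha=.05 close to nominal (n=26)
        rng = np.random.default_rng(4)
        rejections = sum(
            rayleigh_test(rng.uniform(-np.pi, np.pi, 26)).p < 0.05
            for _ in range(400)
        )
        assert 8 <= rejections <= 34  # binomial(400, .05) central range


class TestCircDescriptives:
    def test_rotation_invariance_of_resultant(self):
        rng = np.random.default_rng(5)
        angles = rng.vonmises(1.0, 2.0, 30)
        for rot in (0.5, -2.0):
            assert circ_r(angles + rot) == pytest.approx(circ_r(angles))
        perm = rng.permutation(angles)
        assert circ_r(perm) == pytest.approx(circ_r(angles))

    def test_kappa_monotone_in_resultant(self):
        rs = np.linspace(0.05, 0.95, 15)
        ks = [circ_kappa(r) for r in rs]
        assert np.all(np.diff(ks) > 0)


class TestHarrisonKanji:
    def paper_like_phases(self, rng, n=26, kappa=3.0):
        att = rng.vonmises(np.pi, kappa, size=2 * n)
        unatt = rng.vonmises(0.0, kappa, size=2 * n)
        angles = np.concatenate([att, unatt])
        attention = np.array(["attended"] * 2 * n + ["unattended"] * 2 * n)
        frequency = np.array((["1.25"] * n + ["1.66"] * n) * 2)
        return angles, attention, frequency

    def test_attention_main_effect_detected(self):
        angles, att, freq = self.paper_like_phases(np.random.default_rng(0))
        res = harrison_kanji_test(angles, att, freq,
                                  factor_names=("attention", "frequency"))
        assert res["attention"].p < 0.001
        assert res["frequency"].p > 0.05
        assert res["interaction"].p > 0.05

    def test_statistic_kind_follows_kappa_rule(self):
        rng = np.random.default_rng(1)
        diffuse, att, freq = self.paper_like_phases(rng, kappa=0.5)
        res = harrison_kanji_test(diffuse, att, freq)
        assert all(r.kind == "chi2" for r in res.values())
        # main-effect chi2 has 2(p-1) df, interaction (p-1)(q-1)
        assert res["A"].df == (2,) and res["interaction"].df == (1,)

        concentrated = rng.vonmises(0.0, 20.0, size=40)
        res2 = harrison_kanji_test(
            concentrated, np.repeat(["a", "b"], 20), np.tile(["x", "y"], 20)
        )
        assert all(r.kind == "F" for r in res2.values())

    def test_rotation_invariance(self):
        angles, att, freq = self.paper_like_phases(np.random.default_rng(2))
        base = harrison_kanji_test(angles, att, freq)
        rotated = harrison_kanji_test(
            np.angle(np.exp(1j * (angles + 1.1))), att, freq
        )
        for key in base:
            assert base[key].statistic == pytest.approx(
                rotated[key].statistic, rel=1e-9
            )

    def test_null_false_positive_rate(self):
        # all angles from one von Mises: main effects non-significant in
        # >=90% of runs; the published low-kappa interaction statistic is
        # referred to (p-1)(q-1) df (the field convention) and is known to
        # be anticonservative, so it gets a looser empirical bar
        rng = np.random.default_rng(6)
        ok = {"A": 0, "B": 0, "interaction": 0}
        n_runs = 30
        for _ in range(n_runs):
            angles = rng.vonmises(0.3, 1.0, size=48)
            att = np.repeat(["attended", "unattended"], 24)
            freq = np.tile(np.repeat(["1.25", "1.66"], 12), 2)
            res = harrison_kanji_test(angles, att, freq)
            for key, r in res.items():
                ok[key] += r.p >= 0.05
        assert ok["A"] >= 0.85 * n_runs
        assert ok["B"] >= 0.85 * n_runs
        assert ok["interaction"] >= 0.70 * n_runs

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            harrison_kanji_test(
                np.zeros(4), ["a", "a", "a", "b"], ["x", "y", "x", "x"]
            )


class TestResultantDiffPerm:
    def test_identical_sets_not_significant(self):
        angles = np.random.default_rng(0).uniform(-np.pi, np.pi, 12)
        res = resultant_diff_perm_test(angles, angles.copy(),
                                       n_permutations=500)
        assert res.statistic == pytest.approx(0.0)
        assert res.p >= 0.5

    def test_matches_exhaustive_enumeration(self):
        # 6 pairs: enumerate all 2^6 label swaps exactly
        rng = np.random.default_rng(1)
        a = rng.vonmises(0.0, 4.0, 6)
        b = rng.uniform(-np.pi, np.pi, 6)
        observed = circ_r(a) - circ_r(b)
        count = 0
        for swaps in itertools.product([False, True], repeat=6):
            s = np.array(swaps)
            pa = np.where(s, b, a)
            pb = np.where(s, a, b)
            if circ_r(pa) - circ_r(pb) >= observed - 1e-12:
                count += 1
        p_exact = count / 64
        res = resultant_diff_perm_test(a, b, n_permutations=10_000,
                                       rng=np.random.default_rng(2))
        tol = 3 * np.sqrt(p_exact * (1 - p_exact) / 10_000) + 1 / 64
        assert abs(res.p - p_exact) <= tol

    def test_power_against_concentrated_alternative(self):
        # f1 von Mises kappa=4 vs f2 uniform, n=26: significant in >=80%
        rng = np.random.default_rng(3)
        sig = sum(
            resultant_diff_perm_test(
                rng.vonmises(0.0, 4.0, 26),
                rng.uniform(-np.pi, np.pi, 26),
                n_permutations=500,
                rng=rng,
            ).p
            < 0.05
            for _ in range(20)
        )
        assert sig >= 16

    def test_few_pairs_warns(self):
        with pytest.warns(RuntimeWarning, match="coarse"):
            resultant_diff_perm_test(np.zeros(3), np.ones(3),
                                     n_permutations=50)
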