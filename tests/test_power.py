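"""Introgression tests, coarse/fine scans and MF80 extraction."""

import math

import numpy as np
import pandas as pd
import pytest

from dsense.power import (MF80_INSENSITIVE, basic_f_bracket, coarse_scan,
                          compute_mf80, fine_scan_mf80, introgression_test,
                          mf80_from_outcomes, n_introgressed_loci)
from dsense.scenario import BASIC_F_LIST
from dsense.synthetic import logistic_bernoulli
from tests.conftest import mid_scenario


class TestIntrogressionTest:
    def test_f_zero_equals_pure_noflow(self, mid_table, rng):
        res = introgression_test(mid_table, 0.0, "H3_to_H2", rng,
                                 block_size_loci=50)
        s = mid_table["abba_n0"].sum() - mid_table["baba_n0"].sum()
        tot = mid_table["abba_n0"].sum() + mid_table["baba_n0"].sum()
        assert res.n_introgressed == 0
        assert res.d.value == pytest.approx(s / tot)

    def test_locus_counting_rule(self):
        assert n_introgressed_loci(0.5, 50_000) == 25_000
        assert n_introgressed_loci(0.003, 2000) == 6
        # ties round to even
        assert n_introgressed_loci(0.0015, 1000) == 2
        assert n_introgressed_loci(0.0025, 1000) == 2

    def test_f_above_half_rejected(self, mid_table, rng):
        with pytest.raises(ValueError):
            introgression_test(mid_table, 0.9, "H3_to_H2", rng)

    def test_z_grows_with_f(self, mid_table, rng):
        zs = [introgression_test(mid_table, f, "H3_to_H2", rng,
                                 block_size_loci=50).d.z
              for f in (0.0, 0.1, 0.3, 0.5)]
        assert zs[-1] > zs[1] > zs[0]
        assert zs[-1] > 3

    def test_direction_none_has_no_fg(self, mid_table, rng):
        res = introgression_test(mid_table, 0.0, "H2_to_H3", rng)
        assert res.fg is None
        assert res.fhom is not None

    def test_deterministic_with_seeded_rng(self, mid_table):
        a = introgression_test(mid_table, 0.2, "H3_to_H2",
                               np.random.default_rng(1))
        b = introgression_test(mid_table, 0.2, "H3_to_H2",
                               np.random.default_rng(1))
        assert a.d == b.d and a.fg == b.fg and a.fhom == b.fhom

    def test_diploid_modes_run(self, rng):
        from dsense.pipeline import simulate_pattern_table
        scn = mid_scenario(n_loci=300, locus_length=500, ploidy=2)
        table = simulate_pattern_table(scn, seed=8)
        for mode in ("same_loci", "random_loci"):
            res = introgression_test(table, 0.3, "H3_to_H2", rng,
                                     block_size_loci=50, diploid_mode=mode)
            assert res.fg is None and res.fhom is None
            assert np.isfinite(res.d.value)
        with pytest.raises(ValueError):
            introgression_test(table, 0.3, "H3_to_H2", rng,
                               diploid_mode="psychic")


class TestBracketRules:
    @pytest.mark.parametrize("f0,fmin,fmax", [
        (0.001, 0.001, 0.002),
        (0.002, 0.001, 0.003),
        (0.03, 0.015, 0.04),
        (0.5, 0.3, 0.5),
    ])
    def test_printed_rules(self, f0, fmin, fmax):
        assert basic_f_bracket(f0) == (fmin, fmax)


class TestMf80Fit:
    def test_recovers_known_logistic_curve(self, rng):
        beta0, beta1 = -5.0, 50.0
        truth = (math.log(4) - beta0) / beta1  # 0.12777
        f_grid = np.arange(0.08, 0.18, 0.001)
        out = logistic_bernoulli(beta0, beta1, f_grid, 500, rng)
        mf80, b0, b1 = mf80_from_outcomes(out["f"], out["n_significant"],
                                          out["n_reps"])
        assert mf80 == pytest.approx(truth, abs=0.01)

    def test_saturated_reports_floor(self):
        f = [0.01, 0.02, 0.03]
        mf80, *_ = mf80_from_outcomes(f, [500, 500, 500], 500)
        assert mf80 == 0.01

    def test_all_negative_reports_insensitive(self):
        mf80, *_ = mf80_from_outcomes([0.3, 0.4, 0.5], [0, 0, 0], 500)
        assert mf80 == MF80_INSENSITIVE

    def test_crossing_beyond_half_is_insensitive(self, rng):
        # gentle curve crossing 80% far above f=0.5
        out = logistic_bernoulli(-3.0, 4.0, np.arange(0.3, 0.5, 0.001),
                                 400, rng)
        mf80, *_ = mf80_from_outcomes(out["f"], out["n_significant"],
                                      out["n_reps"])
        assert mf80 == MF80_INSENSITIVE

    def test_step_function_recovers_step(self, rng):
        out = logistic_bernoulli(-4000.0, 20000.0,
                                 np.arange(0.15, 0.25, 0.001), 200, rng)
        mf80, *_ = mf80_from_outcomes(out["f"], out["n_significant"],
                                      out["n_reps"])
        assert mf80 == pytest.approx(0.2, abs=0.003)


class TestScans:
    @pytest.fixture(scope="class")
    def strong_table(self):
        """Small-population dataset where gene flow is easy to detect."""
        from dsense.pipeline import simulate_pattern_table
        scn = mid_scenario(Ne=0.002, n_loci=2000, locus_length=1000)
        return simulate_pattern_table(scn, seed=301)

    def test_coarse_scan_brackets_f0(self, strong_table):
        rng = np.random.default_rng(17)
        cs = coarse_scan(strong_table, "H3_to_H2", rng, block_size_loci=50)
        assert cs.f0 is not None
        assert cs.f_min <= cs.f0 <= cs.f_max
        assert cs.f0 in BASIC_F_LIST
        assert all(len(v) == 3 for v in cs.outcomes.values())

    def test_full_mf80_pipeline(self, strong_table):
        rng = np.random.default_rng(23)
        res = compute_mf80(strong_table, "H3_to_H2", rng, coarse_reps=3,
                           fine_reps=60, block_size_loci=50)
        assert 0.0 < res.mf80 <= MF80_INSENSITIVE
        assert res.mf80 < 0.1  # easy dataset: small fraction detectable
        assert res.fine_table is not None
        assert (res.fine_table["n_reps"] == 60).all()

    def test_fine_scan_bad_bracket(self, strong_table, rng):
        with pytest.raises(ValueError):
            fine_scan_mf80(strong_table, "H3_to_H2", 0.2, 0.1, rng)

    def test_mf80_bit_deterministic(self, strong_table):
        vals = [compute_mf80(strong_table, "H3_to_H2",
                             np.random.default_rng(42), coarse_reps=2,
                             fine_reps=12, block_size_loci=50).mf80
                for _ in range(2)]
        assert vals[0] == vals[1]

    def test_run_scheme_grid_reduced(self):
        """Grid driver: per-dataset MF80 rows for both directions plus a
        correlation report over the demographic predictors."""
        from dsense.power import run_scheme_grid
        scns = [mid_scenario(Ne=ne, n_loci=400, locus_length=500)
                for ne in (0.002, 0.02)]
        df, corr = run_scheme_grid(scns, master_seed=13, coarse_reps=2,
                                   fine_reps=8, block_size_loci=40)
        assert len(df) == 4  # 2 scenarios x 2 directions
        assert {"mf80", "rel_pop_size", "direction", "null_z"} <= set(df)
        assert (df["mf80"] > 0).all()
        # only predictors that vary across the grid are reported
        assert "rel_pop_size" in set(corr["predictor"])
        assert "tgf_over_t3" not in set(corr["predictor"])

    def test_mean_z_nondecreasing_in_f(self, mid_table):
        """Expected jackknife Z grows with the gene-flow fraction."""
        from dsense.power import d_significance_scan
        rng = np.random.default_rng(2)
        fs = [0.0, 0.05, 0.1, 0.2, 0.3, 0.5]
        scan = d_significance_scan(mid_table, "H3_to_H2", fs, 6, rng,
                                   block_size_loci=50)
        means = scan.groupby("f")["z"].mean()
        # allow sampling noise: each step up may dip by at most 0.5
        diffs = np.diff(means.to_numpy())
        assert (diffs > -0.5).all()
        assert means.iloc[-1] > means.iloc[0]
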