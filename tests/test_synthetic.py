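"""Synthetic dataset generator, generating map and packaged fixtures."""

import numpy as np
import pytest

from mesomelt.duplex import DEOXY, RIBO, canonical_steps
from mesomelt.parameters import parse_compact
from mesomelt.regression import fit_regression, mean_abs_deviation
from mesomelt.synthetic import (
    DEFAULT_B_TRUE,
    DR_HS_MORSE,
    DR_HS_STACKING,
    DR_LS_MORSE,
    DR_LS_STACKING,
    EXPERIMENT_GRID,
    SyntheticSpec,
    cosolute_shifted_parameters,
    dr_parameter_set,
    example_parameters,
    generate_duplexes,
    noiseless_tm,
    simulate_melting_table,
)


class TestGenerateDuplexes:
    def test_counts_lengths_validity(self):
        spec = SyntheticSpec(kind="DD", n_sequences=36, lengths=(8, 10, 12, 16), seed=1)
        dups = generate_duplexes(spec)
        assert len(dups) == 36
        lengths = [d.n_bp for d in dups]
        for n in (8, 10, 12, 16):
            assert lengths.count(n) == 9  # round-robin allocation
        assert all(d.kind == "DD" for d in dups)

    def test_deterministic_under_seed(self):
        spec = SyntheticSpec(kind="DR", n_sequences=10, lengths=(8, 12), seed=7)
        a = generate_duplexes(spec)
        b = generate_duplexes(spec)
        assert [d.render() for d in a] == [d.render() for d in b]

    def test_composition_sweeps_requested_range(self):
        spec = SyntheticSpec(kind="DD", n_sequences=20, lengths=(10, 12),
                             cg_range=(0.4, 0.6), seed=2)
        fracs = [d.cg_fraction() for d in generate_duplexes(spec)]
        assert all(0.4 - 0.05 <= f <= 0.6 + 0.05 for f in fracs)
        spec_wide = SyntheticSpec(kind="DD", n_sequences=24, lengths=(8, 12),
                                  cg_range=(0.0, 1.0), seed=2)
        fracs = [d.cg_fraction() for d in generate_duplexes(spec_wide)]
        assert min(fracs) <= 0.15 and max(fracs) >= 0.85  # spans the range

    def test_all_pyrimidine_deoxy_strand_for_hybrids(self):
        spec = SyntheticSpec(kind="DR", n_sequences=6, lengths=(8, 10),
                             cg_range=(0.0, 1.0), dpy_range=(1.0, 1.0), seed=3)
        for d in generate_duplexes(spec):
            assert d.strand1.chemistry == DEOXY
            assert d.strand2.chemistry == RIBO
            assert set(d.strand1.bases) <= {"C", "T"}

    def test_infeasible_constraint_raises(self):
        # no integer pyrimidine count of an 8-mer lies in (0.40, 0.45)
        spec = SyntheticSpec(kind="DD", n_sequences=4, lengths=(8, 8, 8, 10),
                             dpy_range=(0.40, 0.45), seed=0)
        with pytest.raises(ValueError, match="infeasible"):
            generate_duplexes(spec)


class TestSimulate:
    def test_zero_noise_is_exactly_invertible(self, dd_params):
        spec = SyntheticSpec(kind="DD", n_sequences=16, lengths=(8, 12), sigma=0.0,
                             seed=5)
        dups = generate_duplexes(spec)
        records, taus = simulate_melting_table(
            dups, dd_params, DEFAULT_B_TRUE, 0.0, np.random.default_rng(5),
            grid=EXPERIMENT_GRID)
        lengths = [r.N for r in records]
        tms = [r.Tm_exp for r in records]
        model = fit_regression(lengths, taus, tms)
        np.testing.assert_allclose(model.b, DEFAULT_B_TRUE, atol=1e-7)
        pred = [model.predict(t, n) for t, n in zip(taus, lengths)]
        assert mean_abs_deviation(pred, tms).mean_abs_dev <= 1e-8

    def test_noise_has_requested_scale(self, dd_params):
        spec = SyntheticSpec(kind="DD", n_sequences=40, sigma=0.7, seed=6)
        dups = generate_duplexes(spec)
        records, taus = simulate_melting_table(
            dups, dd_params, DEFAULT_B_TRUE, 0.7, np.random.default_rng(6),
            grid=EXPERIMENT_GRID)
        clean = np.array([noiseless_tm(t, r.N, DEFAULT_B_TRUE)
                          for t, r in zip(taus, records)])
        noise = np.array([r.Tm_exp for r in records]) - clean
        assert noise.std(ddof=1) == pytest.approx(0.7, abs=0.3)

    def test_ct_follows_dataset_convention(self, dd_params):
        spec = SyntheticSpec(kind="DD", n_sequences=8, lengths=(8, 10), sigma=0.0,
                             seed=8)
        dups = generate_duplexes(spec)
        records, _ = simulate_melting_table(
            dups, dd_params, DEFAULT_B_TRUE, 0.0, np.random.default_rng(8),
            grid=EXPERIMENT_GRID)
        for rec in records:
            expected = 200.0 if rec.duplex.self_complementary else 100.0
            assert rec.Ct == expected

    def test_cg_rich_simulates_hotter_than_at_rich(self, dd_params):
        from mesomelt.duplex import parse_duplex

        cg = parse_duplex("d(CGCGCGCGCGCG)")
        at = parse_duplex("d(ATATATATATAT)")
        records, _ = simulate_melting_table(
            [cg, at], dd_params, DEFAULT_B_TRUE, 0.0, np.random.default_rng(0),
            grid=EXPERIMENT_GRID)
        assert records[0].Tm_exp > records[1].Tm_exp

    def test_simulated_range_is_experimentally_plausible(self, dd_params):
        spec = SyntheticSpec(kind="DD", n_sequences=40, sigma=0.0, seed=12)
        dups = generate_duplexes(spec)
        records, _ = simulate_melting_table(
            dups, dd_params, DEFAULT_B_TRUE, 0.0, np.random.default_rng(12),
            grid=EXPERIMENT_GRID)
        tms = [r.Tm_exp for r in records]
        assert 5.0 < min(tms) < 45.0
        assert 55.0 < max(tms) < 95.0


class TestFixtureTables:
    def test_morse_fixture_values(self):
        assert parse_compact(DR_LS_MORSE["dArU"]) == pytest.approx((22.0, 2.0))
        assert parse_compact(DR_LS_MORSE["dTrA"]) == pytest.approx((41.1, 0.6))
        assert parse_compact(DR_HS_MORSE["dCrG"]) == pytest.approx((74.0, 1.0))
        assert parse_compact(DR_HS_MORSE["dGrC"]) == pytest.approx((63.0, 1.0))

    def test_stacking_fixtures_complete_and_positive(self):
        assert set(DR_LS_STACKING) == set(canonical_steps("DR"))
        assert set(DR_HS_STACKING) == set(canonical_steps("DR"))
        for table in (DR_LS_STACKING, DR_HS_STACKING):
            for text in table.values():
                v, s = parse_compact(text)
                assert v > 0 and s > 0

    def test_low_salt_widens_au_ta_gap(self):
        # the low-salt set separates the two AT-like hybrid pairs more
        # than high salt: 41.1 - 22 ≈ 19 vs 40 - 28 = 12 meV
        ls = dr_parameter_set("LS")
        hs = dr_parameter_set("HS")
        gap_ls = ls.morse["dTrA"].D - ls.morse["dArU"].D
        gap_hs = hs.morse["dTrA"].D - hs.morse["dArU"].D
        assert gap_ls > gap_hs

    def test_example_parameter_sets_complete(self):
        for kind in ("DD", "DR", "RR"):
            p = example_parameters(kind)
            assert p.kind == kind
            q = cosolute_shifted_parameters(kind)
            for pair in p.morse:
                assert q.morse[pair].D < p.morse[pair].D
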