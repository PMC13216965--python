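"""Transfer-integral correctness: oracles, symmetries, monotonicity, grids."""

import math

import numpy as np
import pytest

from mesomelt.duplex import Duplex, Strand, parse_duplex
from mesomelt.fastpath import BatchedTauSolver
from mesomelt.parameters import MorsePotential, ParameterSet
from mesomelt.transfer import (
    KB_EV,
    QuadratureGrid,
    TransferIntegrator,
    morse_energy,
    stacking_energy,
)


class TestPotentials:
    def test_morse_equilibrium_and_plateau(self):
        assert morse_energy(0.0, 30.0, 0.03) == 0.0
        assert morse_energy(50.0, 30.0, 0.03) == pytest.approx(0.030, rel=1e-6)

    def test_morse_at_one_width(self):
        # D (e^{-1} - 1)^2 at y = lambda
        expected = 30e-3 * (math.exp(-1) - 1) ** 2
        assert morse_energy(0.03, 30.0, 0.03) == pytest.approx(expected, rel=1e-12)
        assert expected * 1e3 == pytest.approx(11.99, abs=0.01)

    def test_stacking_closed_forms(self):
        assert stacking_energy(0.0, 0.0, 2.0, 0.01) == 0.0
        assert stacking_energy(1.0, 1.0, 2.0, 0.0) == 0.0
        assert stacking_energy(1.0, -1.0, 2.0, 0.0) == pytest.approx(4.0)

    def test_stacking_positive_with_twist(self):
        assert stacking_energy(1.0, 1.0, 2.0, 0.01) > 0.0


def brute_force_log_z_and_y1(duplex, params, T, grid):
    """Direct tensor quadrature of the full multidimensional integral.

    Independent of the chain-product path: builds the integrand over the
    full N-dimensional product grid and sums.
    """
    y = grid.nodes
    w = grid.weights
    beta = 1.0 / (KB_EV * T)
    n = duplex.n_bp
    pots = [params.morse[p] for p in duplex.pairs]
    ks = [params.stacking[s] for s in duplex.steps]
    shape = [1] * n
    log_weight = np.zeros([len(y)] * n)
    for i in range(n):
        sh = shape.copy()
        sh[i] = len(y)
        e = morse_energy(y, pots[i].D, pots[i].lam)
        log_weight = log_weight - beta * e.reshape(sh) + np.log(w).reshape(sh)
    for i in range(1, n):
        sh_a, sh_b = shape.copy(), shape.copy()
        sh_a[i - 1] = len(y)
        sh_b[i] = len(y)
        wmat = stacking_energy(
            y.reshape(sh_b), y.reshape(sh_a), ks[i - 1], params.theta
        )
        log_weight = log_weight - beta * wmat
    m = log_weight.max()
    weight = np.exp(log_weight - m)
    z = weight.sum()
    sh = shape.copy()
    sh[0] = len(y)
    y1 = (weight * y.reshape(sh)).sum() / z
    return math.log(z) + m, y1


@pytest.fixture(scope="module")
def oracle_grid():
    return QuadratureGrid(y_min=-0.2, y_max=20.0, n_points=160)


@pytest.fixture(scope="module")
def dd_2bp(dd_params):
    return parse_duplex("d(GA)"), dd_params


class TestBruteForceOracle:
    @pytest.mark.parametrize("T", [250.0, 320.0, 400.0])
    def test_two_bp_log_z(self, dd_2bp, oracle_grid, T):
        duplex, params = dd_2bp
        ref_logz, ref_y1 = brute_force_log_z_and_y1(duplex, params, T, oracle_grid)
        ti = TransferIntegrator(params, oracle_grid)
        assert ti.log_partition(duplex, T) == pytest.approx(ref_logz, rel=1e-6)
        prof = ti.opening_profile(duplex, T)
        assert prof.values[0] == pytest.approx(ref_y1, rel=1e-6)

    def test_three_bp_log_z_and_profile(self, dd_params, oracle_grid):
        duplex = parse_duplex("d(GAT)")
        ref_logz, ref_y1 = brute_force_log_z_and_y1(duplex, dd_params, 320.0, oracle_grid)
        ti = TransferIntegrator(dd_params, oracle_grid)
        assert ti.log_partition(duplex, 320.0) == pytest.approx(ref_logz, rel=1e-6)
        assert ti.opening_profile(duplex, 320.0).values[0] == pytest.approx(ref_y1, rel=1e-6)


class TestSymmetries:
    def test_traversal_direction_invariance(self, dd_params, default_grid):
        d = parse_duplex("d(GATTACAG)")
        ti = TransferIntegrator(dd_params, default_grid)
        logz = ti.log_partition(d, 300.0)
        logz_swapped = ti.log_partition(d.swapped(), 300.0)
        assert logz_swapped == pytest.approx(logz, rel=1e-10)

    def test_tau_strand_swap_invariance(self, dd_params, small_grid):
        d = parse_duplex("d(GATTACAGCA)")
        ti = TransferIntegrator(dd_params, small_grid)
        t1 = ti.tau(d)
        ti2 = TransferIntegrator(dd_params, small_grid)
        t2 = ti2.tau(d.swapped())
        assert t1.converged and t2.converged
        assert t2.tau == pytest.approx(t1.tau, abs=1e-8)

    def test_palindromic_profile_mirror_symmetry(self, dd_params, default_grid):
        d = parse_duplex("d(CGCAAATTTGCG)")
        assert d.self_complementary
        ti = TransferIntegrator(dd_params, default_grid)
        prof = ti.opening_profile(d, 300.0).values
        np.testing.assert_allclose(prof, prof[::-1], atol=1e-8)


class TestEndFraying:
    def test_terminals_fray_relative_to_adjacent_stem(self, dd_params, default_grid):
        # below the transition the terminal pairs, having a single
        # stacking neighbour, open more than the interior positions of
        # the same CG stem (the weak AT core is a separate, larger bubble)
        d = parse_duplex("d(CGCAAATTTGCG)")
        ti = TransferIntegrator(dd_params, default_grid)
        t_star = ti.tau(d).T_star
        prof = ti.opening_profile(d, t_star - 30.0).values
        assert prof[0] > prof[1]
        assert prof[0] > prof[2]
        assert prof[-1] > prof[-2]


@pytest.fixture(scope="module")
def duplex10():
    return parse_duplex("d(GCATTAGCCA)")


class TestTauMonotonicity:

    def test_uniform_morse_scaling_raises_tau(self, dd_params, small_grid, duplex10):
        base = TransferIntegrator(dd_params, small_grid).tau(duplex10)
        up = TransferIntegrator(dd_params.scaled(morse_factor=1.1), small_grid).tau(duplex10)
        assert up.tau > base.tau

    def test_uniform_stacking_scaling_raises_tau(self, dd_params, small_grid, duplex10):
        base = TransferIntegrator(dd_params, small_grid).tau(duplex10)
        up = TransferIntegrator(dd_params.scaled(stacking_factor=1.1), small_grid).tau(duplex10)
        assert up.tau > base.tau

    def test_single_parameter_bumps_do_not_decrease_tau(self, dd_params, small_grid, duplex10):
        base = TransferIntegrator(dd_params, small_grid).tau(duplex10).tau
        # bump one Morse depth and one stacking constant present in the duplex
        p1 = dd_params.copy()
        p1.morse["dAdT"] = MorsePotential(dd_params.morse["dAdT"].D * 1.15)
        assert TransferIntegrator(p1, small_grid).tau(duplex10).tau > base
        p2 = dd_params.copy()
        step = duplex10.steps[3]
        p2.stacking[step] = dd_params.stacking[step] * 1.2
        assert TransferIntegrator(p2, small_grid).tau(duplex10).tau >= base

    def test_cg_rich_melts_above_at_rich(self, dd_params, small_grid):
        cg = parse_duplex("d(CGCGCGCGCGCG)")
        at = parse_duplex("d(ATATATATATAT)")
        ti = TransferIntegrator(dd_params, small_grid)
        assert ti.tau(cg).tau > ti.tau(at).tau


class TestGridStability:
    def test_doubling_points_changes_tau_below_tenth_percent(self, dd_params):
        d = parse_duplex("d(CGCAAATTTGCG)")
        t400 = TransferIntegrator(dd_params, QuadratureGrid(n_points=400)).tau(d)
        t800 = TransferIntegrator(dd_params, QuadratureGrid(n_points=800)).tau(d)
        assert abs(t800.tau - t400.tau) / t400.tau < 1e-3

    def test_extending_y_max_at_fixed_density(self, dd_params):
        # +50% integration range with the node density held fixed: the
        # finite upper bound is a regularizer, not a physical scale
        d = parse_duplex("d(CGCAAATTTGCG)")
        t20 = TransferIntegrator(dd_params, QuadratureGrid(y_max=20.0, n_points=400)).tau(d)
        t30 = TransferIntegrator(dd_params, QuadratureGrid(y_max=30.0, n_points=600)).tau(d)
        assert abs(t30.tau - t20.tau) / t20.tau < 1e-3


class TestTwistRegularizer:
    def test_zero_twist_remains_finite_on_finite_grid(self, dd_params, default_grid):
        d = parse_duplex("d(GCGC)")
        p0 = ParameterSet("DD", dict(dd_params.morse), dict(dd_params.stacking), theta=0.0)
        logz = TransferIntegrator(p0, default_grid).log_partition(d, 300.0)
        assert math.isfinite(logz)

    def test_small_twist_shift_is_absorbed_by_the_regression(self, dd_params, small_grid):
        # Doubling θ confines the open state and shifts τ by a few
        # percent, but the shift is almost common-mode across sequences,
        # so the length regression absorbs it: fitted temperatures move
        # by well under a degree.
        from mesomelt.regression import fit_regression
        from mesomelt.synthetic import (
            DEFAULT_B_TRUE,
            SyntheticSpec,
            generate_duplexes,
            noiseless_tm,
        )

        spec = SyntheticSpec(kind="DD", n_sequences=18, lengths=(8, 10, 12), seed=9)
        duplexes = generate_duplexes(spec, np.random.default_rng(9))
        lengths = np.array([d.n_bp for d in duplexes])
        taus = {}
        for theta in (0.01, 0.02):
            p = ParameterSet("DD", dict(dd_params.morse), dict(dd_params.stacking),
                             theta=theta)
            solver = BatchedTauSolver(duplexes, grid=small_grid)
            taus[theta], _ = solver.solve(p)
        rel = np.abs(taus[0.02] - taus[0.01]) / taus[0.01]
        assert rel.max() < 0.10
        tm = np.array([noiseless_tm(t, n, DEFAULT_B_TRUE)
                       for t, n in zip(taus[0.01], lengths)])
        refit = fit_regression(lengths, taus[0.02], tm)
        pred = np.array([refit.predict(t, n) for t, n in zip(taus[0.02], lengths)])
        assert np.abs(pred - tm).max() < 1.0


class TestBatchedAgainstScalar:
    def test_batched_solver_matches_scalar_integrator(self, dd_params, small_grid):
        duplexes = [
            parse_duplex(s)
            for s in ("d(GATTACAG)", "d(CGCGATAT)", "d(GCATTAGCCA)", "d(CGCAAATTTGCG)")
        ]
        solver = BatchedTauSolver(duplexes, grid=small_grid)
        taus, _ = solver.solve(dd_params)
        for i, d in enumerate(duplexes):
            ref = TransferIntegrator(dd_params, small_grid).tau(d)
            assert taus[i] == pytest.approx(ref.tau, abs=2e-6)

    def test_batched_mean_openings_match(self, dd_params, small_grid):
        duplexes = [parse_duplex("d(GATTACAG)"), parse_duplex("d(CGCGATAT)")]
        solver = BatchedTauSolver(duplexes, grid=small_grid)
        T = np.array([300.0, 320.0])
        batched = solver.mean_openings(dd_params, T)
        for i, d in enumerate(duplexes):
            ti = TransferIntegrator(dd_params, small_grid)
            assert batched[i] == pytest.approx(ti.mean_opening(d, T[i]), rel=1e-10)

    def test_no_crossing_reported_unconverged(self, small_grid):
        # pathologically strong bonds: no melting inside the scan window
        morse = {"dAdT": MorsePotential(500.0), "dCdG": MorsePotential(900.0)}
        from mesomelt.duplex import canonical_steps

        stacking = {s: 25.0 for s in canonical_steps("DD")}
        p = ParameterSet("DD", morse, stacking)
        d = parse_duplex("d(CGCGCGCG)")
        res = TransferIntegrator(p, small_grid).tau(d)
        assert not res.converged
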