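"""Merit function, simplex contracts, multistart averaging and perturbations."""

import numpy as np
import pytest

from mesomelt.optimize import (
    MeltingObjective,
    OptimizationConfig,
    Stage,
    TauConvergenceError,
    chi_square,
    minimize_once,
    multistart_round,
    perturb_temperatures,
    run_protocol,
)
from mesomelt.synthetic import EXPERIMENT_GRID


@pytest.fixture()
def exact_config():
    """Float64 everywhere so simulated and refitted τ agree bit for bit."""
    return OptimizationConfig(grid=EXPERIMENT_GRID, solver_dtype="float64")


class TestChiSquare:
    def test_self_consistency_on_noiseless_data(self, small_dataset, dd_params,
                                                exact_config):
        records, _, _ = small_dataset
        value = chi_square(dd_params, records, config=exact_config)
        assert value <= 1e-10

    def test_chi_square_is_sum_of_squared_residuals(self, small_dataset, dd_params,
                                                    exact_config):
        records, _, _ = small_dataset
        obj = MeltingObjective(records, {"PEG": dd_params}, config=exact_config)
        x = obj.reference_vector() * 1.07
        chi2, mad, _, _, pred = obj.fit_report(x)
        tm = np.array([r.Tm_exp for r in records])
        assert chi2 == pytest.approx(float(((tm - pred) ** 2).sum()), rel=1e-12)
        # Jensen: <ΔT>² ≤ χ²/n on the same residuals
        assert mad**2 <= chi2 / len(records) + 1e-15

    def test_nonconvergent_record_is_named(self, small_dataset, dd_params,
                                           exact_config):
        records, _, _ = small_dataset
        obj = MeltingObjective(records, {"PEG": dd_params}, config=exact_config)
        huge = obj.reference_vector() * 40.0  # melts far above the scan window
        with pytest.raises(TauConvergenceError, match="syn"):
            obj.chi_square(huge)


class TestMinimizeOnce:
    def test_already_at_minimum_stays(self, small_dataset, dd_params, fast_config):
        records, _, _ = small_dataset
        obj = MeltingObjective(records, {"PEG": dd_params}, config=fast_config)
        x0 = obj.reference_vector()
        start_chi2 = obj.chi_square(x0)
        res = minimize_once(obj, x0, fast_config)
        assert res.chi2 <= start_chi2 + 1e-12
        assert res.mean_abs_dev < 0.05

    def test_anisotropic_offset_recovers_on_noiseless_data(self, small_dataset,
                                                           dd_params):
        # a uniform scaling of all D and k is absorbed by the regression,
        # so the informative displaced start is anisotropic
        records, _, _ = small_dataset
        cfg = OptimizationConfig(grid=EXPERIMENT_GRID, tau_tol=1e-3,
                                 simplex_maxfev=700, simplex_maxiter=700)
        obj = MeltingObjective(records, {"PEG": dd_params}, config=cfg)
        truth = obj.reference_vector()
        # alternate ±25/20% so the offset is orthogonal to the soft
        # common-scale directions and the starting merit is large
        x0 = truth * np.where(np.arange(truth.size) % 2 == 0, 1.25, 0.8)
        start_chi2 = obj.chi_square(x0)
        res = minimize_once(obj, x0, cfg)
        assert res.chi2 <= start_chi2 * 1e-4

    def test_frozen_parameters_do_not_move(self, small_dataset, dd_params,
                                           fast_config):
        records, _, _ = small_dataset
        frozen = {("PEG", "morse", "dCdG")} | {
            ("PEG", "stack", s) for s in dd_params.stacking
        }
        obj = MeltingObjective(records, {"PEG": dd_params}, frozen=frozen,
                               config=fast_config)
        assert obj.free_names == [("PEG", "morse", "dAdT")]
        x = obj.reference_vector() * 1.1
        sets = obj.param_sets_at(x)
        assert sets["PEG"].morse["dCdG"].D == dd_params.morse["dCdG"].D
        assert sets["PEG"].stacking == dd_params.stacking
        assert sets["PEG"].morse["dAdT"].D == pytest.approx(
            dd_params.morse["dAdT"].D * 1.1)

    def test_positivity_penalty(self, small_dataset, dd_params, fast_config):
        records, _, _ = small_dataset
        obj = MeltingObjective(records, {"PEG": dd_params}, config=fast_config)
        z = np.ones(12)
        z[3] = -0.1
        assert obj.penalized(z, obj.reference_vector()) >= 1e12


class TestPerturbTemperatures:
    def test_zero_sigma_is_identity(self, small_dataset):
        records, _, _ = small_dataset
        out = perturb_temperatures(records, 0.0, np.random.default_rng(0))
        assert [r.Tm_exp for r in out] == [r.Tm_exp for r in records]

    @pytest.mark.parametrize("sigma", [0.4, 0.7])
    def test_sample_sd_is_exact(self, small_dataset, sigma):
        records, _, _ = small_dataset
        out = perturb_temperatures(records, sigma, np.random.default_rng(1))
        offsets = np.array([a.Tm_exp - b.Tm_exp for a, b in zip(out, records)])
        assert offsets.std(ddof=1) == pytest.approx(sigma, abs=1e-9)
        assert offsets.mean() == pytest.approx(0.0, abs=1e-12)

    def test_originals_untouched(self, small_dataset):
        records, _, _ = small_dataset
        before = [r.Tm_exp for r in records]
        perturb_temperatures(records, 0.7, np.random.default_rng(2))
        assert [r.Tm_exp for r in records] == before


class TestMultistart:
    def test_single_start_mean_equals_run_sd_zero(self, small_dataset, dd_params,
                                                  fast_config):
        from dataclasses import replace

        records, _, _ = small_dataset
        cfg = replace(fast_config, n_starts=1)
        obj = MeltingObjective(records, {"PEG": dd_params}, config=cfg)
        result = multistart_round(obj, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(result.mean, result.starts[0].x)
        assert np.all(result.sd == 0.0)

    def test_fixed_seed_reproduces_bitwise(self, small_dataset, dd_params,
                                           fast_config):
        records, _, _ = small_dataset

        def run():
            obj = MeltingObjective(records, {"PEG": dd_params}, config=fast_config)
            return multistart_round(obj, fast_config,
                                    np.random.default_rng(fast_config.seed))

        a, b = run(), run()
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.sd, b.sd)
        assert a.best_chi2 == b.best_chi2

    def test_acceptance_rule_excludes_poor_starts(self, small_dataset, dd_params,
                                                  fast_config):
        records, _, _ = small_dataset
        obj = MeltingObjective(records, {"PEG": dd_params}, config=fast_config)
        result = multistart_round(obj, fast_config, np.random.default_rng(3))
        best = min(s.mean_abs_dev for s in result.starts)
        for s in result.starts:
            assert s.accepted == (s.mean_abs_dev <= fast_config.accept_factor * best)


class TestProtocol:
    def test_unknown_dataset_rejected(self, small_dataset, dd_params, fast_config):
        records, _, _ = small_dataset
        stages = [Stage("fit", ["nope"], vary=["PEG"])]
        with pytest.raises(KeyError, match="unknown datasets"):
            run_protocol(stages, {"PEG": records}, {"PEG": dd_params}, fast_config)

    def test_zero_extra_rounds_equals_joint_result(self, small_dataset, dd_params,
                                                   fast_config):
        # a plan holding only the joint stage returns exactly that stage
        records, _, _ = small_dataset
        nc = [r for r in records[:6]]
        for r in nc:
            r = r  # records already tagged PEG; retag copies below
        from dataclasses import replace as drep

        nc = [drep(r, condition="NC") for r in records[:6]]
        peg = records[6:]
        datasets = {"NC": nc, "PEG": peg}
        params = {"NC": dd_params, "PEG": dd_params}
        stages = [Stage("joint", ["NC", "PEG"], vary=["PEG"], n_rounds=1)]
        out = run_protocol(stages, datasets, params, fast_config,
                           np.random.default_rng(0))
        assert set(out) == {"joint"}
        assert out["joint"].mean.shape == (12,)
        # NC parameters were never exposed to the optimizer
        assert all(cond == "PEG" for cond, _, _ in out["joint"].free_names)
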