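"""Model/Results interface for fitting mesoscopic parameters to melting data.

:class:`MeltingModel` is constructed from melting records (or a
DataFrame in the melting-table dialect) together with seed parameter
sets; ``fit()`` runs the multi-start downhill-simplex protocol and
returns a :class:`MeltingFitResults` carrying the averaged parameters,
their standard deviations, fit diagnostics, the fitted τ→Tm regression
and a printable summary table.  Simulation of synthetic datasets and
base-pair opening profiles hang off the model and results objects.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .duplex import Duplex
from .optimize import (
    MeltingObjective,
    OptimizationConfig,
    OptimizationResult,
    Stage,
    minimize_once,
    run_protocol,
    run_rounds,
)
from .parameters import ParameterSet, format_compact, generic_seed
from .regression import MeltingRecord, RegressionModel, mean_abs_deviation
from .transfer import OpeningProfile, QuadratureGrid, TransferIntegrator

__all__ = ["MeltingModel", "MeltingFitResults"]


class MeltingModel:
    """Mesoscopic melting model bound to a set of melting records.

    Parameters
    ----------
    records
        Melting records; each carries a condition tag ("PEG", "NC", ...).
    param_sets
        Seed parameter set, or a mapping of condition tag to seed set.
        A single set is used for every condition present.  Defaults to
        the generic weak/strong seed for the records' duplex kind.
    vary
        Conditions whose parameters are optimized (default: all).
    config
        Protocol settings (:class:`OptimizationConfig`).
    """

    def __init__(
        self,
        records: list[MeltingRecord],
        param_sets: ParameterSet | dict[str, ParameterSet] | None = None,
        vary: list[str] | None = None,
        config: OptimizationConfig | None = None,
    ):
        if not records:
            raise ValueError("records must be nonempty")
        self.records = list(records)
        conditions = sorted({r.condition for r in self.records})
        kinds = {r.duplex.kind for r in self.records}
        if len(kinds) != 1:
            raise ValueError(f"records mix duplex kinds {sorted(kinds)}")
        self.kind = kinds.pop()
        if param_sets is None:
            param_sets = generic_seed(self.kind)
        if isinstance(param_sets, ParameterSet):
            param_sets = {c: param_sets.copy() for c in conditions}
        self.param_sets = param_sets
        self.vary = vary
        self.config = config or OptimizationConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, condition: str | None = None,
                       **kwargs) -> "MeltingModel":
        """Build from a DataFrame in the melting-table TSV dialect."""
        import io as _io

        from .io import read_melting_table

        buf = _io.StringIO()
        df.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        records = read_melting_table(buf, condition=condition)
        return cls(records, **kwargs)

    def objective(self) -> MeltingObjective:
        return MeltingObjective(self.records, self.param_sets, vary=self.vary,
                                config=self.config)

    # -- fitting ------------------------------------------------------------

    def fit(self, seed: int | None = None, n_starts: int | None = None,
            n_rounds: int | None = None) -> "MeltingFitResults":
        """Run the multi-start protocol; returns the results object."""
        cfg = self.config
        if seed is not None or n_starts is not None or n_rounds is not None:
            cfg = replace(
                cfg,
                seed=cfg.seed if seed is None else seed,
                n_starts=cfg.n_starts if n_starts is None else n_starts,
                n_rounds=cfg.n_rounds if n_rounds is None else n_rounds,
            )
        objective = MeltingObjective(self.records, self.param_sets, vary=self.vary,
                                     config=cfg)
        rng = np.random.default_rng(cfg.seed)
        rounds = run_rounds(objective, cfg, rng)
        return MeltingFitResults(self, objective, rounds)

    def fit_once(self, start: np.ndarray | None = None) -> "MeltingFitResults":
        """A single simplex minimization from the seed (no multistart)."""
        objective = self.objective()
        x0 = objective.reference_vector() if start is None else np.asarray(start)
        summary = minimize_once(objective, x0, self.config)
        result = OptimizationResult(
            free_names=list(objective.free_names),
            mean=summary.x,
            sd=np.zeros_like(summary.x),
            best_chi2=summary.chi2,
            chi2_at_mean=summary.chi2,
            mean_abs_dev=summary.mean_abs_dev,
            starts=[summary],
        )
        objective.set_reference(summary.x)
        return MeltingFitResults(self, objective, [result])

    def fit_protocol(self, stages: list[Stage],
                     datasets: dict[str, list[MeltingRecord]],
                     seed: int | None = None) -> dict[str, OptimizationResult]:
        """Run a staged plan (joint/frozen rounds, uncertainty rounds)."""
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        rng = np.random.default_rng(cfg.seed)
        return run_protocol(stages, datasets, self.param_sets, cfg, rng)

    # -- model-level quantities ---------------------------------------------

    def tau(self, params: ParameterSet | dict[str, ParameterSet] | None = None
            ) -> np.ndarray:
        """Melting index of every record under the given (or seed) parameters."""
        objective = self.objective()
        if params is None:
            sets = objective.param_sets
        elif isinstance(params, ParameterSet):
            sets = {c: params for c in objective.param_sets}
        else:
            sets = params
        return objective.taus(sets)


class MeltingFitResults:
    """Fitted parameters, uncertainties and diagnostics.

    Attributes
    ----------
    params : dict[str, ParameterSet]
        Round-averaged parameter sets per condition.
    bse : dict[tuple, float]
        Standard deviation of each free parameter over the accepted
        starts of the final round, keyed by (condition, group, label).
    chi2, mean_abs_dev : float
        Merit and ⟨ΔT⟩ at the averaged parameters.
    regression : RegressionModel
        The τ→Tm regression refitted at the averaged parameters.
    """

    def __init__(self, model: MeltingModel, objective: MeltingObjective,
                 rounds: list[OptimizationResult]):
        self.model = model
        self.rounds = rounds
        final = rounds[-1]
        self.result = final
        self.free_names = final.free_names
        self.params = objective.param_sets_at(final.mean)
        self.bse = final.sds_by_name()
        chi2, mad, regression, taus, predicted = objective.fit_report(final.mean)
        self.chi2 = chi2
        self.mean_abs_dev = mad
        self.regression: RegressionModel = regression
        self.taus = taus
        self.predicted = predicted
        self.observed = np.array([r.Tm_exp for r in objective.records])
        self.residuals = self.observed - predicted
        self.n_rounds_run = len(rounds)

    @property
    def converged(self) -> bool:
        """Round means moved less than the threshold before the round cap."""
        return self.n_rounds_run < self.model.config.n_rounds or \
            self.n_rounds_run == 1

    def params_for(self, condition: str) -> ParameterSet:
        return self.params[condition]

    def fit_table(self) -> pd.DataFrame:
        """Per-sequence τ, predicted Tm and residual."""
        recs = self.model.records
        return pd.DataFrame({
            "id": [r.record_id or r.duplex.render() for r in recs],
            "condition": [r.condition for r in recs],
            "N": [r.N for r in recs],
            "tau": self.taus,
            "Tm_exp": self.observed,
            "Tm_pred": self.predicted,
            "residual": self.residuals,
        })

    def parameter_table(self) -> pd.DataFrame:
        rows = []
        for (cond, group, label), value, sd in zip(
            self.free_names, self.result.mean, self.result.sd
        ):
            unit = "meV" if group == "morse" else "eV/nm^2"
            rows.append({
                "condition": cond,
                "type": "Morse D" if group == "morse" else "stacking k",
                "label": label,
                "value": value,
                "sd": sd,
                "compact": format_compact(value, sd),
                "unit": unit,
            })
        return pd.DataFrame(rows)

    def opening_profile(self, duplex: Duplex, T_calc: float,
                        condition: str | None = None,
                        grid: QuadratureGrid | None = None) -> OpeningProfile:
        """⟨y_i⟩ profile at a model temperature with the fitted parameters."""
        cond = condition or next(iter(self.params))
        integ = TransferIntegrator(self.params[cond], grid or QuadratureGrid())
        return integ.opening_profile(duplex, T_calc)

    def predict(self, duplex: Duplex, condition: str | None = None,
                grid: QuadratureGrid | None = None) -> float:
        """Predicted melting temperature (°C) for a new duplex."""
        cond = condition or next(iter(self.params))
        cfg = self.model.config
        integ = TransferIntegrator(self.params[cond], grid or cfg.grid or QuadratureGrid())
        res = integ.tau(duplex, threshold=cfg.tau_threshold, T_ref=cfg.T_ref,
                        window=cfg.scan_window)
        if not res.converged:
            raise RuntimeError(f"melting index did not converge for {duplex.render()}")
        return self.regression.predict(res.tau, duplex.n_bp)

    def summary(self) -> str:
        """Printable summary in the style of statistical model results."""
        lines = []
        hdr = f"Mesoscopic melting fit ({self.model.kind})"
        lines.append(hdr)
        lines.append("=" * len(hdr))
        lines.append(f"records: {len(self.model.records)}   "
                     f"free parameters: {len(self.free_names)}   "
                     f"rounds: {self.n_rounds_run}")
        lines.append(f"chi^2 = {self.chi2:.4g} °C²    "
                     f"<ΔT> = {self.mean_abs_dev:.3f} °C    "
                     f"accepted starts (final round): {self.result.n_accepted}"
                     f"/{len(self.result.starts)}")
        b = self.regression.b
        lines.append("regression: T' = (b00 + b10·√N) + (b01 + b11·√N)·τ")
        lines.append(f"  b00={b[0]:.4g}  b10={b[1]:.4g}  b01={b[2]:.4g}  b11={b[3]:.4g}")
        lines.append("")
        lines.append(f"{'condition':<10} {'type':<10} {'label':<12} "
                     f"{'value (compact SD)':<20} unit")
        lines.append("-" * 62)
        for (cond, group, label), value, sd in zip(
            self.free_names, self.result.mean, self.result.sd
        ):
            unit = "meV" if group == "morse" else "eV/nm^2"
            kind = "Morse D" if group == "morse" else "stack k"
            lines.append(f"{cond:<10} {kind:<10} {label:<12} "
                         f"{format_compact(value, sd):<20} {unit}")
        return "\n".join(lines)

    def plot_fit(self, ax=None):  # pragma: no cover - optional artifact
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.observed, self.predicted, s=18)
        lim = [min(self.observed.min(), self.predicted.min()) - 2,
               max(self.observed.max(), self.predicted.max()) + 2]
        ax.plot(lim, lim, "k--", lw=0.8)
        ax.set_xlabel("experimental Tm (°C)")
        ax.set_ylabel("predicted Tm (°C)")
        return ax
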