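"""Multi-start downhill-simplex optimization of Morse and stacking parameters.

The merit function is the sum of squared deviations between experimental
and predicted melting temperatures,

    χ²(P) = Σ_s [T_s - T'_s(P)]²,

where T'_s is obtained by computing the melting index τ_s(P) for every
record and refitting the two-level length regression at every merit
evaluation.  Because the regression absorbs any affine rescaling of τ,
χ² has an exactly flat direction under a common scaling of all D and k;
the multi-start protocol (random starts in ±20% around a seed, averaged
over the accepted runs, re-seeded round after round until the averages
move by less than 0.1%) keeps the reported parameters anchored to the
seed scale, which is how the published parameter sets are defined.

Optimization is carried out in seed-normalized coordinates (each free
parameter divided by its current round seed) so the simplex sees
commensurate scales for Morse depths (meV) and stacking constants
(eV/nm²).  Non-positive proposals receive a rejection penalty, keeping
the parameters physical without reparameterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .parameters import ParameterSet
from .regression import (
    MeltingRecord,
    RegressionError,
    fit_regression,
    mean_abs_deviation,
)
from .fastpath import BatchedTauSolver, SolverState
from .transfer import (
    DEFAULT_BISECT_TOL_K,
    DEFAULT_SCAN_WINDOW,
    DEFAULT_T_REF,
    DEFAULT_THRESHOLD_NM,
    QuadratureGrid,
)

__all__ = [
    "OptimizationConfig",
    "OptimizationResult",
    "StartSummary",
    "Stage",
    "MeltingObjective",
    "TauConvergenceError",
    "chi_square",
    "minimize_once",
    "multistart_round",
    "run_rounds",
    "perturb_temperatures",
    "run_protocol",
]

PENALTY = 1e12


class TauConvergenceError(RuntimeError):
    """The melting index of a record did not converge."""


@dataclass
class OptimizationConfig:
    """Settings for the multi-start simplex protocol.

    ``sample_width`` is the half-width of the uniform sampling interval
    around the seed (0.20 reproduces the ±20% convention; 0 starts every
    minimization exactly at the seed, which the uncertainty rounds use so
    the spread reflects temperature noise alone).  ``perturb_sigma`` is
    the experimental temperature uncertainty (°C) applied independently
    per start.  ``convergence_threshold`` is the relative change of the
    round-averaged parameters below which the rounds driver stops.
    """

    n_starts: int = 100
    n_rounds: int = 2
    sample_width: float = 0.20
    convergence_threshold: float = 0.001
    accept_factor: float = 1.2
    perturb_sigma: float = 0.0
    seed: int | None = None
    grid: QuadratureGrid | None = None
    tau_threshold: float = DEFAULT_THRESHOLD_NM
    T_ref: float = DEFAULT_T_REF
    scan_window: tuple[float, float] = DEFAULT_SCAN_WINDOW
    tau_tol: float = DEFAULT_BISECT_TOL_K
    simplex_xatol: float = 1e-4
    simplex_fatol: float = 1e-6
    simplex_maxiter: int = 5000
    simplex_maxfev: int | None = None
    solver_dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if not (0.0 <= self.sample_width < 1.0):
            raise ValueError("sample_width must be in [0, 1)")
        if not self.convergence_threshold > 0:
            raise ValueError("convergence_threshold must be positive")


class MeltingObjective:
    """χ² merit function over the free parameters of one or more conditions.

    ``param_sets`` maps condition tags (e.g. "PEG", "NC") to complete
    parameter sets; records carry the tag of the condition they were
    measured in.  Only the parameters of the conditions in ``vary`` are
    exposed to the optimizer (minus any in ``frozen``); the others stay
    fixed, which implements the joint stage where reference parameters
    are held constant.  One regression is fitted over all records at
    every evaluation.
    """

    def __init__(
        self,
        records: list[MeltingRecord],
        param_sets: dict[str, ParameterSet],
        vary: list[str] | None = None,
        frozen: set[tuple[str, str, str]] | None = None,
        config: OptimizationConfig | None = None,
    ):
        if not records:
            raise ValueError("records must be nonempty")
        self.records = list(records)
        self.param_sets = {c: p.copy() for c, p in param_sets.items()}
        for rec in self.records:
            if rec.condition not in self.param_sets:
                raise KeyError(f"no parameter set for condition {rec.condition!r}")
        self.vary = list(vary) if vary is not None else sorted(self.param_sets)
        frozen = frozen or set()
        self.config = config or OptimizationConfig()
        self.grid = self.config.grid or QuadratureGrid()
        # free parameter names: (condition, group, label)
        self.free_names: list[tuple[str, str, str]] = []
        for cond in self.vary:
            for group, label in self.param_sets[cond].free_names():
                if (cond, group, label) not in frozen:
                    self.free_names.append((cond, group, label))
        if not self.free_names:
            raise ValueError("no free parameters to optimize")
        self._tm = np.array([r.Tm_exp for r in self.records])
        self._lengths = np.array([r.N for r in self.records])
        # batched τ solvers with warm-started crossing temperatures, one
        # per condition present in the records
        cfg = self.config
        self._solvers: dict[str, tuple[np.ndarray, BatchedTauSolver]] = {}
        self._states: dict[str, SolverState] = {}
        for cond in sorted({r.condition for r in self.records}):
            idx = np.array([i for i, r in enumerate(self.records) if r.condition == cond])
            solver = BatchedTauSolver(
                [self.records[i].duplex for i in idx],
                grid=self.grid,
                threshold=cfg.tau_threshold,
                T_ref=cfg.T_ref,
                window=cfg.scan_window,
                tol=cfg.tau_tol,
                dtype=np.dtype(cfg.solver_dtype),
            )
            self._solvers[cond] = (idx, solver)
            self._states[cond] = SolverState()
        self.n_evaluations = 0

    # -- vector packing ---------------------------------------------------

    def reference_vector(self) -> np.ndarray:
        """Current parameter values of the free parameters (original units)."""
        out = []
        for cond, group, label in self.free_names:
            ps = self.param_sets[cond]
            out.append(ps.morse[label].D if group == "morse" else ps.stacking[label])
        return np.array(out)

    def param_sets_at(self, x: np.ndarray) -> dict[str, ParameterSet]:
        """Parameter sets with the free parameters replaced by ``x``."""
        sets = {c: p.copy() for c, p in self.param_sets.items()}
        for (cond, group, label), v in zip(self.free_names, x):
            ps = sets[cond]
            if group == "morse":
                ps.morse[label] = replace(ps.morse[label], D=float(v))
            else:
                ps.stacking[label] = float(v)
        return sets

    def set_reference(self, x: np.ndarray) -> None:
        """Adopt ``x`` as the new stored parameter values (round re-seeding)."""
        self.param_sets = self.param_sets_at(x)

    # -- merit evaluation -------------------------------------------------

    def taus(self, sets: dict[str, ParameterSet]) -> np.ndarray:
        out = np.empty(len(self.records))
        for cond, (idx, solver) in self._solvers.items():
            taus, self._states[cond] = solver.solve(sets[cond], self._states[cond])
            bad = np.flatnonzero(~np.isfinite(taus))
            if bad.size:
                rec = self.records[idx[bad[0]]]
                raise TauConvergenceError(
                    f"melting index did not converge for record "
                    f"{rec.record_id or rec.duplex.render()} (condition {rec.condition})"
                )
            out[idx] = taus
        return out

    def chi_square(self, x: np.ndarray, tm_override: np.ndarray | None = None) -> float:
        """χ² (°C²) at free-parameter values ``x`` (original units)."""
        self.n_evaluations += 1
        sets = self.param_sets_at(x)
        taus = self.taus(sets)
        tm = self._tm if tm_override is None else tm_override
        model = fit_regression(self._lengths, taus, tm)
        pred = np.array([model.predict(t, n) for t, n in zip(taus, self._lengths)])
        return float(np.sum((tm - pred) ** 2))

    def fit_report(self, x: np.ndarray, tm_override: np.ndarray | None = None):
        """(χ², ⟨ΔT⟩, regression model, τ, predictions) at ``x``."""
        sets = self.param_sets_at(x)
        taus = self.taus(sets)
        tm = self._tm if tm_override is None else tm_override
        model = fit_regression(self._lengths, taus, tm)
        pred = np.array([model.predict(t, n) for t, n in zip(taus, self._lengths)])
        quality = mean_abs_deviation(pred, tm)
        chi2 = float(np.sum(quality.residuals**2))
        return chi2, quality.mean_abs_dev, model, taus, pred

    def penalized(self, z: np.ndarray, scale: np.ndarray,
                  tm_override: np.ndarray | None = None) -> float:
        """Merit in seed-normalized coordinates with positivity penalty."""
        if np.any(z <= 0.0):
            return PENALTY * (1.0 + float(np.sum(np.maximum(0.0, -z))))
        try:
            return self.chi_square(z * scale, tm_override=tm_override)
        except (TauConvergenceError, RegressionError):
            return PENALTY
        except FloatingPointError:
            return PENALTY


def chi_square(params: ParameterSet | dict[str, ParameterSet],
               records: list[MeltingRecord],
               config: OptimizationConfig | None = None) -> float:
    """One-shot χ² of a parameter set against a record list.

    τ is computed for every record and the length regression refitted;
    a non-convergent record raises :class:`TauConvergenceError` naming it.
    """
    if isinstance(params, ParameterSet):
        params = {rec.condition: params for rec in records}
    obj = MeltingObjective(records, params, config=config)
    return obj.chi_square(obj.reference_vector())


@dataclass
class StartSummary:
    """Outcome of a single minimization start."""

    x: np.ndarray
    chi2: float
    mean_abs_dev: float
    accepted: bool = False
    n_evaluations: int = 0
    flagged: bool = False  # iteration cap reached


@dataclass
class OptimizationResult:
    """Mean ± SD over the accepted starts of a round (original units)."""

    free_names: list[tuple[str, str, str]]
    mean: np.ndarray
    sd: np.ndarray
    best_chi2: float
    chi2_at_mean: float
    mean_abs_dev: float
    starts: list[StartSummary] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return sum(1 for s in self.starts if s.accepted)

    def sds_by_name(self) -> dict[tuple[str, str, str], float]:
        return dict(zip(self.free_names, self.sd))

    def param_sets(self, objective: MeltingObjective) -> dict[str, ParameterSet]:
        return objective.param_sets_at(self.mean)


def minimize_once(objective: MeltingObjective, x0: np.ndarray,
                  config: OptimizationConfig | None = None,
                  tm_override: np.ndarray | None = None) -> StartSummary:
    """One downhill-simplex minimization from ``x0`` (original units).

    The simplex runs in x0-normalized coordinates; the returned merit
    never exceeds the starting merit (the best vertex is monotone).
    """
    cfg = config or objective.config
    scale = np.asarray(x0, dtype=float)
    if np.any(scale <= 0):
        raise ValueError("starting parameters must be positive")
    z0 = np.ones_like(scale)
    n0 = objective.n_evaluations
    res = minimize(
        objective.penalized,
        z0,
        args=(scale, tm_override),
        method="Nelder-Mead",
        options={
            "xatol": cfg.simplex_xatol,
            "fatol": cfg.simplex_fatol,
            "maxiter": cfg.simplex_maxiter,
            "maxfev": cfg.simplex_maxfev or cfg.simplex_maxiter,
            "adaptive": True,
        },
    )
    x_opt = res.x * scale
    chi2, mad, *_ = objective.fit_report(x_opt, tm_override=tm_override)
    return StartSummary(
        x=x_opt,
        chi2=chi2,
        mean_abs_dev=mad,
        n_evaluations=objective.n_evaluations - n0,
        flagged=not res.success,
    )


def perturb_temperatures(records: list[MeltingRecord], sigma: float,
                         rng: np.random.Generator) -> list[MeltingRecord]:
    """Records with Gaussian offsets added to the experimental temperatures.

    The offsets are centred and rescaled so their sample standard
    deviation equals ``sigma`` exactly (the stated experimental
    uncertainty), not merely in expectation.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0.0 or not records:
        return [replace(r) for r in records]
    offsets = _exact_sd_offsets(len(records), sigma, rng)
    return [replace(r, Tm_exp=r.Tm_exp + d) for r, d in zip(records, offsets)]


def _exact_sd_offsets(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    z = rng.normal(size=n)
    if n < 2:
        return sigma * z
    z = z - z.mean()
    sd = z.std(ddof=1)
    if sd == 0.0:  # pragma: no cover - probability zero
        z = np.linspace(-1, 1, n)
        z = z - z.mean()
        sd = z.std(ddof=1)
    return z * (sigma / sd)


def multistart_round(objective: MeltingObjective,
                     config: OptimizationConfig | None = None,
                     rng: np.random.Generator | None = None) -> OptimizationResult:
    """One optimization round: ``n_starts`` minimizations around the seed.

    Initial points are drawn per parameter from
    Uniform[(1-w)·seed, (1+w)·seed]; a start enters the round average
    when its final ⟨ΔT⟩ is within ``accept_factor`` of the round best
    (this excludes stuck local minima while averaging the solution
    basin).  With ``perturb_sigma`` > 0 every start minimizes against
    its own perturbed copy of the experimental temperatures.
    """
    cfg = config or objective.config
    rng = rng or np.random.default_rng(cfg.seed)
    seed_x = objective.reference_vector()
    starts: list[StartSummary] = []
    for _ in range(cfg.n_starts):
        tm_override = None
        if cfg.perturb_sigma > 0.0:
            offsets = _exact_sd_offsets(len(objective.records), cfg.perturb_sigma, rng)
            tm_override = objective._tm + offsets
        if cfg.sample_width > 0.0:
            factors = rng.uniform(1.0 - cfg.sample_width, 1.0 + cfg.sample_width,
                                  size=seed_x.shape)
        else:
            factors = np.ones_like(seed_x)
        starts.append(minimize_once(objective, seed_x * factors, cfg,
                                    tm_override=tm_override))
    finite = [s for s in starts if math.isfinite(s.mean_abs_dev)]
    if not finite:
        raise RuntimeError("all starts failed")
    best_mad = min(s.mean_abs_dev for s in finite)
    for s in finite:
        s.accepted = s.mean_abs_dev <= cfg.accept_factor * best_mad
    accepted = np.array([s.x for s in finite if s.accepted])
    mean = accepted.mean(axis=0)
    sd = accepted.std(axis=0)
    chi2_at_mean, mad_at_mean, *_ = objective.fit_report(mean)
    return OptimizationResult(
        free_names=list(objective.free_names),
        mean=mean,
        sd=sd,
        best_chi2=min(s.chi2 for s in finite),
        chi2_at_mean=chi2_at_mean,
        mean_abs_dev=mad_at_mean,
        starts=starts,
    )


def run_rounds(objective: MeltingObjective,
               config: OptimizationConfig | None = None,
               rng: np.random.Generator | None = None
               ) -> list[OptimizationResult]:
    """Repeat multistart rounds, re-seeding with each round's mean.

    Stops after ``n_rounds`` or earlier once every averaged parameter
    changes by less than ``convergence_threshold`` relative to the
    previous round.
    """
    cfg = config or objective.config
    rng = rng or np.random.default_rng(cfg.seed)
    results: list[OptimizationResult] = []
    prev_mean = objective.reference_vector()
    for _ in range(cfg.n_rounds):
        result = multistart_round(objective, cfg, rng)
        results.append(result)
        objective.set_reference(result.mean)
        rel = np.abs(result.mean - prev_mean) / np.abs(prev_mean)
        prev_mean = result.mean
        if np.all(rel < cfg.convergence_threshold):
            break
    return results


@dataclass
class Stage:
    """One stage of an optimization protocol.

    ``datasets`` names the record sets joined for the merit function;
    ``vary`` the conditions whose parameters move (all others frozen);
    ``perturb_sigma`` > 0 makes it an uncertainty-estimation stage.
    ``sample_width`` of 0 starts every minimization at the stage seed
    so that the reported SD isolates the effect of temperature noise.
    """

    name: str
    datasets: list[str]
    vary: list[str]
    n_rounds: int = 1
    n_starts: int | None = None
    perturb_sigma: float = 0.0
    sample_width: float | None = None
    frozen: set[tuple[str, str, str]] | None = None


def run_protocol(stages: list[Stage],
                 datasets: dict[str, list[MeltingRecord]],
                 param_sets: dict[str, ParameterSet],
                 config: OptimizationConfig | None = None,
                 rng: np.random.Generator | None = None
                 ) -> dict[str, OptimizationResult]:
    """Execute a staged optimization plan.

    Parameter sets are carried from stage to stage: each stage re-seeds
    from the previous stage's round mean for the conditions it varies.
    Returns the final round result of every stage, keyed by stage name.
    """
    cfg = config or OptimizationConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    current = {c: p.copy() for c, p in param_sets.items()}
    out: dict[str, OptimizationResult] = {}
    for stage in stages:
        unknown = [d for d in stage.datasets if d not in datasets]
        if unknown:
            raise KeyError(f"stage {stage.name!r} references unknown datasets {unknown}")
        records = [r for d in stage.datasets for r in datasets[d]]
        stage_cfg = replace(
            cfg,
            n_rounds=stage.n_rounds,
            n_starts=stage.n_starts or cfg.n_starts,
            perturb_sigma=stage.perturb_sigma,
            sample_width=cfg.sample_width if stage.sample_width is None else stage.sample_width,
        )
        objective = MeltingObjective(records, current, vary=stage.vary,
                                     frozen=stage.frozen, config=stage_cfg)
        rounds = run_rounds(objective, stage_cfg, rng)
        result = rounds[-1]
        out[stage.name] = result
        updated = objective.param_sets_at(result.mean)
        for cond in stage.vary:
            current[cond] = updated[cond]
    return out


def peg_stage_plan(n_starts: int | None = None, peg_rounds: int = 2,
                   uncertainty_sigma: float = 0.7) -> list[Stage]:
    """The cosolute optimization scheme.

    Round 1 fits the cosolute parameters against the joined cosolute +
    no-cosolute temperatures with the reference (NC) parameters held
    fixed, anchoring both conditions to one shared regression; the next
    rounds drop the NC records; the final round repeats the fit on
    temperature-perturbed data to estimate parameter uncertainties.
    """
    return [
        Stage("joint", ["NC", "PEG"], vary=["PEG"], n_rounds=1, n_starts=n_starts),
        Stage("peg_only", ["PEG"], vary=["PEG"], n_rounds=peg_rounds, n_starts=n_starts),
        Stage("uncertainty", ["PEG"], vary=["PEG"], n_rounds=1, n_starts=n_starts,
              perturb_sigma=uncertainty_sigma, sample_width=0.0),
    ]


def dr_ls_stage_plan(n_starts: int = 500, uncertainty_sigma: float = 0.4) -> list[Stage]:
    """Two-round single-condition scheme used for the hybrid low-salt set."""
    return [
        Stage("fit", ["LS"], vary=["LS"], n_rounds=1, n_starts=n_starts),
        Stage("uncertainty", ["LS"], vary=["LS"], n_rounds=1, n_starts=n_starts,
              perturb_sigma=uncertainty_sigma, sample_width=0.0),
    ]
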