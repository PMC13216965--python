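"""Batched transfer-integral evaluation across a whole record set.

The optimizer evaluates the melting index of every record at every merit
call.  Doing that one duplex at a time is dominated by Python and small-
array overhead, so this module evaluates the strand-averaged opening of
all duplexes of equal length simultaneously: the stacking kernels of a
group are built with one vectorized exponential per bond position and
the chain products advance with one batched matrix-vector contraction
per site.  The crossing temperatures T* are tracked per record between
merit evaluations and re-located with a vectorized secant iteration
(with full-window bisection as fallback), which needs only 2-4 sweeps
when the parameters move a little, as they do between simplex steps.

Numerically this is the same quadrature, kernel and chain product as
:class:`mesomelt.transfer.TransferIntegrator`; only the batching and the
root-finding bookkeeping differ, and the test suite checks the two paths
against each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .duplex import Duplex, canonical_pairs, canonical_steps
from .parameters import ParameterSet
from .transfer import (
    DEFAULT_BISECT_TOL_K,
    DEFAULT_SCAN_WINDOW,
    DEFAULT_T_REF,
    DEFAULT_THRESHOLD_NM,
    KB_EV,
    QuadratureGrid,
)

__all__ = ["BatchedTauSolver", "SolverState"]

# above this many stored kernel bytes per length group, kernels are
# recomputed in the backward pass instead of kept from the forward pass
_KERNEL_STORE_LIMIT = 3e8

# Boltzmann exponents are clamped at this value before exponentiation:
# exp(-200) ≈ 1e-87 is utterly negligible against the per-step kernel
# maximum (≈1) yet stays far from the subnormal range, whose hardware
# assists would dominate the runtime of the kernel builds
_EXP_CLAMP = {np.dtype(np.float64): -200.0, np.dtype(np.float32): -80.0}


def _bexp(arg: np.ndarray) -> np.ndarray:
    """exp with the argument clamped to avoid subnormal outputs."""
    return np.exp(np.maximum(arg, _EXP_CLAMP[arg.dtype], out=arg))


@dataclass
class SolverState:
    """Warm-start bookkeeping carried between merit evaluations."""

    t_star: np.ndarray | None = None
    slope: np.ndarray | None = None


@dataclass
class _LengthGroup:
    indices: np.ndarray        # positions in the full record list
    site_pair_idx: np.ndarray  # (R, N) -> row of the Morse table
    bond_step_idx: np.ndarray  # (R, N-1) -> entry of the stacking vector
    n_bp: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_bp = self.site_pair_idx.shape[1]


class BatchedTauSolver:
    """Vectorized τ computation for a fixed list of duplexes.

    The duplex list, grid and τ construction constants are fixed at
    construction; parameter sets vary call to call.  All duplexes must
    be of the same kind (one Morse/stacking table).
    """

    def __init__(
        self,
        duplexes: list[Duplex],
        grid: QuadratureGrid | None = None,
        threshold: float = DEFAULT_THRESHOLD_NM,
        T_ref: float = DEFAULT_T_REF,
        window: tuple[float, float] = DEFAULT_SCAN_WINDOW,
        tol: float = DEFAULT_BISECT_TOL_K,
        dtype=np.float64,
    ):
        if not duplexes:
            raise ValueError("duplexes must be nonempty")
        kinds = {d.kind for d in duplexes}
        if len(kinds) != 1:
            raise ValueError(f"all duplexes must share one kind, got {sorted(kinds)}")
        self.kind = kinds.pop()
        self.duplexes = list(duplexes)
        self.grid = grid or QuadratureGrid()
        self.threshold = threshold
        self.T_ref = T_ref
        self.window = window
        self.tol = tol
        # float32 kernels halve the cost of the exponentials at ~1e-6
        # relative precision on the mean opening, ample against the
        # crossing tolerance; the reference path stays float64
        self.dtype = np.dtype(dtype)
        self.pair_classes = canonical_pairs(self.kind)
        self.step_classes = canonical_steps(self.kind)
        pair_row = {p: i for i, p in enumerate(self.pair_classes)}
        step_row = {s: i for i, s in enumerate(self.step_classes)}

        by_len: dict[int, list[int]] = {}
        for i, d in enumerate(duplexes):
            by_len.setdefault(d.n_bp, []).append(i)
        self.groups: list[_LengthGroup] = []
        for n_bp in sorted(by_len):
            idx = by_len[n_bp]
            sp = np.array([[pair_row[p] for p in duplexes[i].pairs] for i in idx])
            bs = np.array([[step_row[s] for s in duplexes[i].steps] for i in idx])
            self.groups.append(_LengthGroup(np.array(idx), sp, bs))

        self._Q_cache: dict[float, np.ndarray] = {}

    # -- parameter staging -------------------------------------------------

    def _stage(self, params: ParameterSet):
        if params.kind != self.kind:
            raise ValueError(f"parameter set is for {params.kind}, solver for {self.kind}")
        y = self.grid.nodes
        theta = params.theta
        Q = self._Q_cache.get(theta)
        if Q is None:
            Q = 0.5 * (y[:, None] ** 2 + y[None, :] ** 2) - math.cos(theta) * np.outer(y, y)
            Q = Q.astype(self.dtype)
            self._Q_cache[theta] = Q
        # Morse energies in eV, one row per pair class
        E = np.stack([
            1e-3 * params.morse[p].D * np.square(np.expm1(-y / params.morse[p].lam))
            for p in self.pair_classes
        ])
        k = np.array([params.stacking[s] for s in self.step_classes])
        return Q, E.astype(self.dtype), k

    # -- batched mean opening ----------------------------------------------

    def mean_openings(self, params: ParameterSet, T: np.ndarray,
                      active: np.ndarray | None = None) -> np.ndarray:
        """Strand-averaged ⟨y⟩ of every duplex, each at its own temperature.

        ``T`` has one entry per duplex; entries for duplexes not in
        ``active`` (a boolean mask) are skipped and returned as NaN.
        """
        Q, E, k_vec = self._stage(params)
        y = self.grid.nodes
        w = self.grid.weights
        out = np.full(len(self.duplexes), np.nan)
        for grp in self.groups:
            sel = np.arange(len(grp.indices))
            if active is not None:
                sel = sel[active[grp.indices]]
            if sel.size == 0:
                continue
            idx = grp.indices[sel]
            beta = (1.0 / (KB_EV * T[idx])).astype(self.dtype)  # (R,)
            n_bp = grp.n_bp
            # site Boltzmann factors (R, N, n)
            site = _bexp(-E[grp.site_pair_idx[sel]] * beta[:, None, None])
            # bond kernels (R, N-1, n, n), possibly recomputed in the R pass
            c = (k_vec[grp.bond_step_idx[sel]] * beta[:, None]).astype(self.dtype)  # (R, N-1)
            store = c.size * Q.size * self.dtype.itemsize <= _KERNEL_STORE_LIMIT
            with np.errstate(under="ignore"):
                kernels = _bexp(-c[:, :, None, None] * Q) if store else None

                wd = w.astype(self.dtype)
                yd = y.astype(self.dtype)
                left = np.empty((len(idx), n_bp, y.size), dtype=self.dtype)
                v = site[:, 0, :] * wd
                v /= v.max(axis=1, keepdims=True)
                left[:, 0, :] = v
                for i in range(1, n_bp):
                    K = kernels[:, i - 1] if store else _bexp(-c[:, i - 1, None, None] * Q)
                    v = (site[:, i, :] * wd) * np.matmul(K, v[:, :, None])[:, :, 0]
                    v /= v.max(axis=1, keepdims=True)
                    left[:, i, :] = v

                total = np.zeros(len(idx))
                r = np.ones((len(idx), y.size), dtype=self.dtype)
                for i in range(n_bp - 1, -1, -1):
                    num = ((left[:, i, :] * yd) * r).sum(axis=1, dtype=np.float64)
                    den = (left[:, i, :] * r).sum(axis=1, dtype=np.float64)
                    total += num / den
                    if i > 0:
                        K = kernels[:, i - 1] if store else _bexp(-c[:, i - 1, None, None] * Q)
                        r = np.matmul(K, (site[:, i, :] * wd * r)[:, :, None])[:, :, 0]
                        r /= r.max(axis=1, keepdims=True)
            if not np.all(np.isfinite(total)):
                raise FloatingPointError("non-finite chain product; grid or T out of range")
            out[idx] = total / n_bp
        return out

    # -- vectorized crossing-temperature location ---------------------------

    def solve(self, params: ParameterSet, state: SolverState | None = None
              ) -> tuple[np.ndarray, SolverState]:
        """τ for every duplex plus the updated warm-start state.

        Records whose opening threshold is not crossed inside the scan
        window come back as NaN (the caller decides whether that is an
        error).
        """
        n = len(self.duplexes)
        state = state or SolverState()
        lo, hi = self.window
        t_star = np.full(n, np.nan)
        slope_out = np.full(n, np.nan)

        warm = np.zeros(n, dtype=bool)
        if state.t_star is not None:
            warm = (
                np.isfinite(state.t_star)
                & np.isfinite(state.slope)
                & (state.slope > 0)
                & (state.t_star > lo)
                & (state.t_star < hi)
            )
        need_bisect = ~warm

        if warm.any():
            T = np.where(warm, state.t_star, 0.5 * (lo + hi))
            slope = np.where(warm, state.slope, np.nan)
            f_prev = np.full(n, np.nan)
            t_prev = np.full(n, np.nan)
            active = warm.copy()
            for _ in range(10):
                if not active.any():
                    break
                f = self.mean_openings(params, T, active=active) - self.threshold
                upd = active & np.isfinite(f_prev)
                with np.errstate(invalid="ignore", divide="ignore"):
                    new_slope = (f - f_prev) / (T - t_prev)
                    good = upd & np.isfinite(new_slope) & (new_slope > 0)
                    slope[good] = new_slope[good]
                    step = np.where(active, -f / slope, 0.0)
                step = np.clip(step, -50.0, 50.0)
                t_prev, f_prev = T.copy(), f.copy()
                T = T + step
                escaped = active & ((T < lo) | (T > hi) | ~np.isfinite(T))
                need_bisect |= escaped
                # a small step alone is not convergence: with an
                # overestimated slope the step shrinks while f stays
                # large, so require the residual itself to be tiny
                small_step = np.abs(step) <= self.tol
                small_f = np.abs(f) <= 1e-4 * self.threshold
                done = active & small_step & small_f & ~escaped
                stuck = active & small_step & ~small_f & ~escaped
                need_bisect |= stuck
                t_star[done] = T[done]
                slope_out[done] = slope[done]
                active &= ~done & ~escaped & ~stuck
            need_bisect |= active  # secant did not settle

        if need_bisect.any():
            tb, sb, ok = self._bisect(params, need_bisect)
            t_star[need_bisect] = np.where(ok[need_bisect], tb[need_bisect], np.nan)
            slope_out[need_bisect] = np.where(ok[need_bisect], sb[need_bisect], np.nan)

        taus = t_star / self.T_ref
        return taus, SolverState(t_star=t_star, slope=slope_out)

    def _bisect(self, params: ParameterSet, mask: np.ndarray):
        n = len(self.duplexes)
        lo, hi = self.window
        a = np.full(n, lo)
        b = np.full(n, hi)
        f_lo = self.mean_openings(params, a, active=mask) - self.threshold
        f_hi = self.mean_openings(params, b, active=mask) - self.threshold
        ok = mask & (f_lo < 0.0) & (f_hi >= 0.0)
        active = ok.copy()
        n_iter = int(math.ceil(math.log2((hi - lo) / self.tol)))
        for _ in range(n_iter):
            if not active.any():
                break
            mid = 0.5 * (a + b)
            fm = self.mean_openings(params, mid, active=active) - self.threshold
            low = active & (fm < 0.0)
            high = active & ~low
            a[low] = mid[low]
            b[high] = mid[high]
            active &= (b - a) > self.tol
        t_star = 0.5 * (a + b)
        # finite-difference slope for future warm starts
        dt = max(10.0 * self.tol, 1e-3)
        f_p = self.mean_openings(params, t_star + dt, active=ok)
        f_m = self.mean_openings(params, t_star - dt, active=ok)
        slope = (f_p - f_m) / (2.0 * dt)
        return t_star, slope, ok
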