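"""Transfer-integral evaluation of the mesoscopic duplex Hamiltonian.

Each base pair carries one displacement coordinate ``y`` (nm).  The
Hamiltonian is a chain of on-site Morse potentials V_i(y_i) coupled by
twisted-harmonic stacking terms W_i(y_i, y_{i-1}); the classical
configurational partition function

    Z = ∫ dy_1 … dy_N  exp[-β (Σ_i V_i(y_i) + Σ_{i≥2} W_i(y_i, y_{i-1}))]

is evaluated exactly (up to quadrature) by iterated kernel-vector
products over a fixed Gauss-Legendre grid.  From the same chain
products we obtain the per-site ensemble averages ⟨y_i⟩ (the opening
profile) and, by locating the model temperature T* at which the
strand-averaged opening crosses a threshold, the adimensional melting
index τ = T*/T_ref that is regressed onto experimental melting
temperatures.

The finite upper integration bound is the conventional regularizer of
the Morse plateau (the integrand is bounded but not integrable on an
infinite domain); the small twist θ removes the translational
degeneracy of the stacking kernel along y = y_prev.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .duplex import Duplex
from .parameters import ParameterSet

__all__ = [
    "KB_EV",
    "QuadratureGrid",
    "TauResult",
    "OpeningProfile",
    "TransferIntegrator",
    "morse_energy",
    "stacking_energy",
    "partition_function",
    "opening_profile",
    "tau_index",
]

#: Boltzmann constant in eV/K; energies are handled internally in eV.
KB_EV = 8.617333e-5

#: default τ construction constants: reference temperature (K), opening
#: threshold (nm), scan window (K) and bisection tolerance (K)
DEFAULT_T_REF = 300.0
DEFAULT_THRESHOLD_NM = 0.1
DEFAULT_SCAN_WINDOW = (100.0, 500.0)
DEFAULT_BISECT_TOL_K = 1e-4


def morse_energy(y, D_meV: float, lam_nm: float) -> np.ndarray | float:
    """Morse hydrogen-bond energy D(e^{-y/λ}-1)² in eV (D given in meV)."""
    return 1e-3 * D_meV * np.square(np.expm1(-np.asarray(y, dtype=float) / lam_nm))


def stacking_energy(y, y_prev, k: float, theta: float) -> np.ndarray | float:
    """Twisted-harmonic stacking energy (k/2)(y² - 2 y y' cosθ + y'²) in eV."""
    y = np.asarray(y, dtype=float)
    y_prev = np.asarray(y_prev, dtype=float)
    return 0.5 * k * (y * y - 2.0 * y * y_prev * math.cos(theta) + y_prev * y_prev)


class QuadratureGrid:
    """Gauss-Legendre discretization of the displacement variable y (nm)."""

    def __init__(self, y_min: float = -0.2, y_max: float = 20.0, n_points: int = 400):
        if not (y_min < 0.0 < y_max):
            raise ValueError("grid must straddle the equilibrium displacement y=0")
        if n_points < 50:
            raise ValueError("n_points must be at least 50")
        self.y_min = float(y_min)
        self.y_max = float(y_max)
        self.n_points = int(n_points)
        x, w = np.polynomial.legendre.leggauss(self.n_points)
        half = 0.5 * (self.y_max - self.y_min)
        self.nodes = self.y_min + half * (x + 1.0)
        self.weights = half * w

    def __repr__(self) -> str:  # pragma: no cover
        return f"QuadratureGrid(y_min={self.y_min}, y_max={self.y_max}, n_points={self.n_points})"


@dataclass(frozen=True)
class TauResult:
    """Melting index τ = T*/T_ref and the crossing temperature T* (K)."""

    tau: float
    T_star: float
    converged: bool


@dataclass
class OpeningProfile:
    """Average base-pair displacements ⟨y_i⟩ (nm) at model temperature T_calc (K)."""

    T_calc: float
    values: np.ndarray
    duplex: Duplex | None = None

    def __len__(self) -> int:
        return len(self.values)

    def plot(self, ax=None, **kwargs):  # pragma: no cover - optional artifact
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(1, len(self.values) + 1)
        ax.plot(x, self.values, marker="o", **kwargs)
        ax.set_xlabel("base pair position i")
        ax.set_ylabel(r"$\langle y_i \rangle$ (nm)")
        ax.set_title(f"T = {self.T_calc:g} K")
        return ax


class TransferIntegrator:
    """Evaluates log Z, opening profiles and τ for one parameter set.

    The stacking kernel exp(-β W) factorizes as exp(-c Q) with the
    geometry matrix Q = (y² + y'²)/2 - y y' cosθ precomputed once and
    c = k/(k_B T) a scalar per NN step, so a temperature evaluation
    costs one vectorized exponential per distinct stacking constant
    plus 2(N-1) kernel-vector products.
    """

    def __init__(self, params: ParameterSet, grid: QuadratureGrid | None = None,
                 tstar_cache: dict | None = None):
        self.params = params
        self.grid = grid or QuadratureGrid()
        y = self.grid.nodes
        self._Q = 0.5 * (y[:, None] ** 2 + y[None, :] ** 2) - math.cos(params.theta) * np.outer(y, y)
        # Morse energy arrays (eV) per canonical pair class
        self._site_energy = {
            pair: morse_energy(y, pot.D, pot.lam) for pair, pot in params.morse.items()
        }
        # duplex key -> (T*, d<y>/dT slope); may be shared across integrators
        # built for successive nearby parameter sets (optimizer warm starts)
        self._tstar_cache: dict[str, tuple[float, float]] = (
            tstar_cache if tstar_cache is not None else {}
        )

    # -- per-temperature building blocks ---------------------------------

    def _site_factors(self, duplex: Duplex, T: float) -> list[np.ndarray]:
        beta = 1.0 / (KB_EV * T)
        factors = {}
        for pair in set(duplex.pairs):
            factors[pair] = np.exp(np.maximum(-beta * self._site_energy[pair], -200.0))
        return [factors[p] for p in duplex.pairs]

    def _kernels(self, duplex: Duplex, T: float) -> list[np.ndarray]:
        beta = 1.0 / (KB_EV * T)
        ks = [self.params.stacking[s] for s in duplex.steps]
        unique = sorted(set(ks))
        c = np.array(unique) * beta
        with np.errstate(under="ignore"):
            arg = -c[:, None, None] * self._Q[None, :, :]
            mats = np.exp(np.maximum(arg, -200.0, out=arg))
        lookup = {k: mats[i] for i, k in enumerate(unique)}
        return [lookup[k] for k in ks]

    def _chain(self, duplex: Duplex, T: float):
        """Left-to-right chain products L_i (normalized) and Σ log-scales.

        L_i(j) = w_j m_i(j) Σ_{j'} K_i(j,j') L_{i-1}(j'); each stored
        vector is normalized by its max with the log factor accumulated.
        """
        w = self.grid.weights
        site = self._site_factors(duplex, T)
        kernels = self._kernels(duplex, T)
        vecs = []
        log_scale = 0.0
        v = site[0] * w
        s = v.max()
        if not (s > 0 and np.isfinite(s)):
            raise FloatingPointError("non-finite chain product; grid or T out of range")
        v = v / s
        log_scale += math.log(s)
        vecs.append(v)
        for i in range(1, duplex.n_bp):
            v = (site[i] * w) * (kernels[i - 1] @ v)
            s = v.max()
            if not (s > 0 and np.isfinite(s)):
                raise FloatingPointError("non-finite chain product; grid or T out of range")
            v = v / s
            log_scale += math.log(s)
            vecs.append(v)
        return vecs, log_scale, site, kernels

    # -- public quantities ------------------------------------------------

    def log_partition(self, duplex: Duplex, T: float) -> float:
        """log Z of the duplex at model temperature T (K)."""
        vecs, log_scale, _, _ = self._chain(duplex, T)
        return math.log(vecs[-1].sum()) + log_scale

    def opening_values(self, duplex: Duplex, T: float) -> np.ndarray:
        """⟨y_i⟩ for every base pair, in nm."""
        y = self.grid.nodes
        w = self.grid.weights
        left, _, site, kernels = self._chain(duplex, T)
        n = duplex.n_bp
        out = np.empty(n)
        # right-to-left companion products; kernels are symmetric matrices
        r = np.ones_like(y)
        for i in range(n - 1, -1, -1):
            num = float(np.dot(y * left[i], r))
            den = float(np.dot(left[i], r))
            out[i] = num / den
            if i > 0:
                r = kernels[i - 1] @ (site[i] * w * r)
                s = r.max()
                if not (s > 0 and np.isfinite(s)):
                    raise FloatingPointError("non-finite chain product; grid or T out of range")
                r = r / s
        return out

    def opening_profile(self, duplex: Duplex, T: float) -> OpeningProfile:
        return OpeningProfile(T_calc=float(T), values=self.opening_values(duplex, T), duplex=duplex)

    def mean_opening(self, duplex: Duplex, T: float) -> float:
        """Strand-averaged displacement, the τ crossing statistic."""
        return float(self.opening_values(duplex, T).mean())

    def tau(
        self,
        duplex: Duplex,
        threshold: float = DEFAULT_THRESHOLD_NM,
        T_ref: float = DEFAULT_T_REF,
        window: tuple[float, float] = DEFAULT_SCAN_WINDOW,
        tol: float = DEFAULT_BISECT_TOL_K,
    ) -> TauResult:
        """Adimensional melting index τ = T*/T_ref.

        T* is the model temperature at which the strand-averaged ⟨y⟩
        crosses ``threshold`` (nm), located by bisection inside
        ``window``; warm-started from the previous call for the same
        duplex, which makes repeated evaluations during optimization
        cheap.
        """
        if threshold <= 0:
            raise ValueError("threshold must be positive")
        f = lambda T: self.mean_opening(duplex, T) - threshold  # noqa: E731
        lo, hi = window
        key = duplex.render()
        cached = self._tstar_cache.get(key)

        result = None
        if cached is not None:
            result = _secant_root(f, cached, lo, hi, tol)
        if result is None:
            result = _bisect_root(f, lo, hi, tol)
        if result is None:
            return TauResult(tau=math.nan, T_star=math.nan, converged=False)
        t_star, slope = result
        self._tstar_cache[key] = (t_star, slope)
        return TauResult(tau=t_star / T_ref, T_star=t_star, converged=True)


_SECANT_F_SCALE = DEFAULT_THRESHOLD_NM


def _secant_root(f, cached, lo, hi, tol):
    """Secant iteration warm-started at a previously located crossing.

    ``cached`` is (T*, d⟨y⟩/dT) from an earlier call for the same duplex;
    when the parameters have moved only slightly (the common case inside
    the optimizer) this converges in 2-4 evaluations.  Returns
    (root, slope) or None to signal fallback to bracketing bisection.
    """
    t0, slope = cached
    if not (lo < t0 < hi) or not (slope > 0 and math.isfinite(slope)):
        return None
    f0 = f(t0)
    for _ in range(10):
        step = -f0 / slope
        if not math.isfinite(step):
            return None
        step = max(-50.0, min(50.0, step))
        t1 = t0 + step
        if not (lo <= t1 <= hi):
            return None
        if abs(step) <= tol:
            if abs(f0) <= 1e-4 * _SECANT_F_SCALE:
                return t1, slope
            return None  # slope was off; fall back to bisection
        f1 = f(t1)
        new_slope = (f1 - f0) / (t1 - t0)
        if new_slope > 0 and math.isfinite(new_slope):
            slope = new_slope
        t0, f0 = t1, f1
    return None


def _bisect_root(f, lo, hi, tol):
    """Bracketing bisection on the full scan window.

    Returns (root, finite-difference slope) or None when the opening
    threshold is not crossed inside the window (pathological parameters).
    """
    f_lo, f_hi = f(lo), f(hi)
    if f_lo >= 0.0 or f_hi < 0.0:
        return None
    a, b, f_a = lo, hi, f_lo
    for _ in range(200):
        if b - a <= tol:
            break
        mid = 0.5 * (a + b)
        fm = f(mid)
        if fm < 0.0:
            a, f_a = mid, fm
        else:
            b = mid
    t_star = 0.5 * (a + b)
    dt = max(10.0 * tol, 1e-3)
    slope = (f(t_star + dt) - f(t_star - dt)) / (2.0 * dt)
    if not (slope > 0 and math.isfinite(slope)):
        slope = math.nan
    return t_star, slope


# ---------------------------------------------------------------------------
# functional wrappers (one-shot convenience API)
# ---------------------------------------------------------------------------

def partition_function(duplex: Duplex, params: ParameterSet, T: float,
                       grid: QuadratureGrid | None = None) -> float:
    """log Z of ``duplex`` at model temperature T (K)."""
    return TransferIntegrator(params, grid).log_partition(duplex, T)


def opening_profile(duplex: Duplex, params: ParameterSet, T_calc: float,
                    grid: QuadratureGrid | None = None) -> OpeningProfile:
    """Average base-pair displacement profile ⟨y_i⟩ at T_calc (K)."""
    return TransferIntegrator(params, grid).opening_profile(duplex, T_calc)


def tau_index(duplex: Duplex, params: ParameterSet,
              grid: QuadratureGrid | None = None,
              threshold: float = DEFAULT_THRESHOLD_NM,
              **kwargs) -> TauResult:
    """Melting index τ for a single duplex (see :meth:`TransferIntegrator.tau`)."""
    return TransferIntegrator(params, grid).tau(duplex, threshold=threshold, **kwargs)
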