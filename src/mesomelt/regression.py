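"""Length-grouped linear mapping between melting indices and temperatures.

Experimental melting temperatures T_s and the model's melting index
τ_s(P) are linearly related within groups of sequences of equal length
N,

    T'_s(P) = a_0(N) + a_1(N) τ_s(P),

and the group coefficients themselves vary linearly with sqrt(N),

    a_k(N) = b_{0,k} + b_{1,k} sqrt(N),   k = 0, 1.

Both levels are ordinary (unweighted) least squares.  Predictions always
use the second-level b coefficients, so duplexes of any length — and
record sets measured under different conditions but scored against the
same regression — are mapped consistently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .duplex import Duplex

__all__ = [
    "MeltingRecord",
    "RegressionModel",
    "FitQuality",
    "RegressionError",
    "fit_regression",
    "predict_tm",
    "mean_abs_deviation",
    "pearson_correlation",
]


class RegressionError(ValueError):
    """Non-identifiable or degenerate regression input."""


@dataclass
class MeltingRecord:
    """One duplex with its experimental melting temperature.

    Tm_exp in °C; Ct is the total strand concentration in µM (200 for
    self-complementary, 100 for non-self-complementary in the datasets
    this package emulates).  ``condition`` tags the solvent condition
    (e.g. "PEG" or "NC") so joint fits can look up per-condition
    parameter sets.
    """

    duplex: Duplex
    Tm_exp: float
    Ct: float | None = None
    condition: str = "PEG"
    record_id: str | None = None

    def __post_init__(self) -> None:
        self.Tm_exp = float(self.Tm_exp)
        if self.Ct is not None:
            self.Ct = float(self.Ct)
        if not math.isfinite(self.Tm_exp):
            raise ValueError("Tm_exp must be finite")
        if self.Ct is not None and not self.Ct > 0:
            raise ValueError("Ct must be positive when present")

    @property
    def N(self) -> int:
        return self.duplex.n_bp


@dataclass
class RegressionModel:
    """Fitted two-level regression.

    ``b`` holds (b_{0,0}, b_{1,0}, b_{0,1}, b_{1,1}); ``group_coeffs``
    maps each trained length N to its first-level (a_0, a_1);
    ``pooled`` records singleton lengths that were folded into their
    nearest length group.
    """

    b00: float
    b10: float
    b01: float
    b11: float
    group_coeffs: dict[int, tuple[float, float]] = field(default_factory=dict)
    pooled: dict[int, int] = field(default_factory=dict)

    @property
    def b(self) -> tuple[float, float, float, float]:
        return (self.b00, self.b10, self.b01, self.b11)

    def a(self, N: int) -> tuple[float, float]:
        """Second-level coefficients a_0(N), a_1(N) at length N."""
        rn = math.sqrt(N)
        return (self.b00 + self.b10 * rn, self.b01 + self.b11 * rn)

    def predict(self, tau: float, N: int) -> float:
        a0, a1 = self.a(N)
        return a0 + a1 * tau


def predict_tm(tau: float, N: int, model: RegressionModel) -> float:
    """Predicted melting temperature T' (°C) from τ at duplex length N."""
    return model.predict(tau, N)


def fit_regression(lengths, taus, tms) -> RegressionModel:
    """Fit the two-level regression of melting temperature on τ.

    ``lengths``, ``taus`` and ``tms`` are equal-length sequences giving,
    per duplex, its length N (bp), melting index τ and experimental Tm
    (°C).  Lengths represented by a single sequence are pooled with the
    nearest multi-sequence length group (first level is unidentifiable
    on one point); a group in which all τ are equal has no identifiable
    slope and raises :class:`RegressionError`.
    """
    lengths = np.asarray(lengths, dtype=int)
    taus = np.asarray(taus, dtype=float)
    tms = np.asarray(tms, dtype=float)
    if not (len(lengths) == len(taus) == len(tms)):
        raise ValueError("lengths, taus and tms must have equal length")
    if len(lengths) == 0:
        raise RegressionError("empty input")

    counts = {int(n): int((lengths == n).sum()) for n in np.unique(lengths)}
    anchors = sorted(n for n, c in counts.items() if c >= 2)
    if len(anchors) < 2:
        raise RegressionError(
            "need at least 2 lengths with >= 2 sequences each "
            f"(got group sizes {counts})"
        )
    pooled: dict[int, int] = {}
    group_of = {}
    for n in counts:
        if counts[n] >= 2:
            group_of[n] = n
        else:
            target = min(anchors, key=lambda a: (abs(a - n), a))
            group_of[n] = target
            pooled[n] = target

    group_labels = np.array([group_of[int(n)] for n in lengths])
    group_coeffs: dict[int, tuple[float, float]] = {}
    for n in anchors:
        sel = group_labels == n
        t = taus[sel]
        y = tms[sel]
        if np.ptp(t) == 0.0:
            raise RegressionError(f"length group N={n}: all τ equal, slope not identifiable")
        a1, a0 = np.polyfit(t, y, 1)
        group_coeffs[n] = (float(a0), float(a1))

    rn = np.sqrt(np.array(anchors, dtype=float))
    a0s = np.array([group_coeffs[n][0] for n in anchors])
    a1s = np.array([group_coeffs[n][1] for n in anchors])
    X = np.column_stack([np.ones_like(rn), rn])
    (b00, b10), *_ = np.linalg.lstsq(X, a0s, rcond=None)
    (b01, b11), *_ = np.linalg.lstsq(X, a1s, rcond=None)
    return RegressionModel(
        float(b00), float(b10), float(b01), float(b11),
        group_coeffs=group_coeffs, pooled=pooled,
    )


@dataclass
class FitQuality:
    """Mean absolute deviation ⟨ΔT⟩ (°C) and per-sequence residuals."""

    mean_abs_dev: float
    residuals: np.ndarray


def mean_abs_deviation(predicted, experimental) -> FitQuality:
    """⟨ΔT⟩ = mean |T_s - T'_s| between predictions and experiment (°C)."""
    predicted = np.asarray(predicted, dtype=float)
    experimental = np.asarray(experimental, dtype=float)
    if predicted.shape != experimental.shape:
        raise ValueError("predicted and experimental must have equal length")
    if predicted.size == 0:
        raise ValueError("empty input")
    residuals = experimental - predicted
    return FitQuality(float(np.abs(residuals).mean()), residuals)


def pearson_correlation(x, y) -> float:
    """Product-moment correlation between two parameter vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero variance input")
    return float(np.corrcoef(x, y)[0, 1])
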