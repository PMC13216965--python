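"""Model parameter sets: Morse hydrogen-bond potentials and NN stacking constants.

Units follow the conventions of the mesoscopic melting literature:
Morse depths ``D`` in meV, Morse widths ``lambda`` in nm, stacking
elastic constants ``k`` in eV/nm^2, twist angle ``theta`` in rad.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

from .duplex import DuplexError, canonical_pairs, canonical_steps

__all__ = [
    "MorsePotential",
    "ParameterSet",
    "format_compact",
    "parse_compact",
    "read_parameter_file",
    "write_parameter_file",
    "generic_seed",
]

DEFAULT_LAMBDA_NM = 0.030
DEFAULT_THETA_RAD = 0.01


@dataclass(frozen=True)
class MorsePotential:
    """On-site hydrogen-bond potential D*(exp(-y/lam)-1)^2.

    D is the well depth in meV (the hydrogen-bond strength of the pair);
    lam the width in nm.
    """

    D: float
    lam: float = DEFAULT_LAMBDA_NM

    def __post_init__(self) -> None:
        if not (self.D > 0 and self.lam > 0):
            raise ValueError(f"Morse parameters must be positive, got {self}")


@dataclass
class ParameterSet:
    """Complete Morse + stacking parameter set for one duplex kind.

    ``morse`` maps each canonical base-pair class to its potential,
    ``stacking`` maps each canonical NN step class to its elastic
    constant k (eV/nm^2).  The twist ``theta`` is a global constant that
    regularizes the transfer-integral kernel.
    """

    kind: str
    morse: dict[str, MorsePotential]
    stacking: dict[str, float]
    theta: float = DEFAULT_THETA_RAD

    def __post_init__(self) -> None:
        pairs = canonical_pairs(self.kind)
        steps = canonical_steps(self.kind)
        missing_m = set(pairs) - set(self.morse)
        missing_s = set(steps) - set(self.stacking)
        if missing_m or missing_s:
            raise DuplexError(
                f"incomplete parameter set for {self.kind}: "
                f"missing morse {sorted(missing_m)}, stacking {sorted(missing_s)}"
            )
        extra_m = set(self.morse) - set(pairs)
        extra_s = set(self.stacking) - set(steps)
        if extra_m or extra_s:
            raise DuplexError(
                f"unknown labels for {self.kind}: {sorted(extra_m | extra_s)}"
            )
        for k in self.stacking.values():
            if not k > 0:
                raise ValueError("stacking constants must be positive")

    # ---- flat-vector view of the free (optimized) parameters ----------

    def free_names(self) -> list[tuple[str, str]]:
        """Ordered (group, label) names of the optimized parameters.

        Morse depths first (lambda stays fixed), then stacking
        constants, each alphabetically.
        """
        return [("morse", p) for p in canonical_pairs(self.kind)] + [
            ("stack", s) for s in canonical_steps(self.kind)
        ]

    def to_vector(self) -> list[float]:
        out = []
        for group, label in self.free_names():
            out.append(self.morse[label].D if group == "morse" else self.stacking[label])
        return out

    def with_vector(self, values) -> "ParameterSet":
        names = self.free_names()
        if len(values) != len(names):
            raise ValueError(f"expected {len(names)} values, got {len(values)}")
        morse = dict(self.morse)
        stacking = dict(self.stacking)
        for (group, label), v in zip(names, values):
            if group == "morse":
                morse[label] = replace(morse[label], D=float(v))
            else:
                stacking[label] = float(v)
        return ParameterSet(self.kind, morse, stacking, self.theta)

    def scaled(self, morse_factor: float = 1.0, stacking_factor: float = 1.0) -> "ParameterSet":
        morse = {p: replace(m, D=m.D * morse_factor) for p, m in self.morse.items()}
        stacking = {s: k * stacking_factor for s, k in self.stacking.items()}
        return ParameterSet(self.kind, morse, stacking, self.theta)

    def copy(self) -> "ParameterSet":
        return ParameterSet(self.kind, dict(self.morse), dict(self.stacking), self.theta)


def generic_seed(kind: str, theta: float = DEFAULT_THETA_RAD) -> ParameterSet:
    """Generic seed parameters for an optimization run.

    For hybrids these are the published generic hybrid seeds
    (D = 30 meV for A·U / T·A pairs, 80 meV for C·G / G·C pairs, and a
    uniform k = 2.5 eV/nm^2); for DD and RR the same weak/strong scheme
    is applied to the AT(U)-like and CG-like pair classes.
    """
    morse = {}
    for p in canonical_pairs(kind):
        depth = 80.0 if ("C" in p or "G" in p) else 30.0
        morse[p] = MorsePotential(D=depth)
    stacking = {s: 2.5 for s in canonical_steps(kind)}
    return ParameterSet(kind, morse, stacking, theta)


# ---------------------------------------------------------------------------
# compact uncertainty notation, e.g. 22(2) = 22 +/- 2, 41.1(6) = 41.1 +/- 0.6
# ---------------------------------------------------------------------------

_COMPACT_RE = re.compile(r"^\s*(-?\d+(?:\.(\d+))?)\((\d+)\)\s*$")


def parse_compact(text: str) -> tuple[float, float]:
    """Parse compact uncertainty notation into (value, sd)."""
    m = _COMPACT_RE.match(text)
    if not m:
        return float(text), 0.0
    value_s, decimals, sd_digits = m.group(1), m.group(2), m.group(3)
    n_dec = len(decimals) if decimals else 0
    return float(value_s), int(sd_digits) * 10.0 ** (-n_dec)


def format_compact(value: float, sd: float) -> str:
    """Render value +/- sd in compact uncertainty notation.

    The uncertainty is rounded to one or two significant digits (two when
    its leading digit is 1, the usual convention) and the value to the
    matching decimal place.
    """
    if sd <= 0 or not math.isfinite(sd):
        return f"{value:g}"
    exp = math.floor(math.log10(sd))
    lead = sd / 10**exp
    sig = 2 if round(lead) == 1 and round(sd / 10 ** (exp - 1)) < 20 else 1
    dec = -(exp - (sig - 1))
    sd_scaled = int(round(sd * 10**dec))
    if dec <= 0:
        # uncertainty >= 1: print integer value with parenthesised integer sd
        return f"{value:.0f}({sd_scaled * 10 ** (-dec):.0f})"
    return f"{value:.{dec}f}({sd_scaled})"


# ---------------------------------------------------------------------------
# parameter files: one record per line, round-trippable plain text
# ---------------------------------------------------------------------------

_KV_RE = re.compile(r"(\w+)=([^\s]+)")


def read_parameter_file(path) -> tuple[ParameterSet, dict]:
    """Read a parameter file.

    Format, one record per line::

        kind DR
        theta 0.01
        morse dArU D=22 lambda=0.03
        stack dArU-dCrG k=8.0
        config T_ref=300 threshold=0.1 y_min=-0.2 y_max=20 n_points=400

    Returns the :class:`ParameterSet` and a dict with any ``config``
    entries (empty when absent).  Lines starting with ``#`` are comments.
    """
    kind = None
    theta = DEFAULT_THETA_RAD
    morse: dict[str, MorsePotential] = {}
    stacking: dict[str, float] = {}
    config: dict[str, float] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split(None, 1)
            tag = tokens[0]
            rest = tokens[1] if len(tokens) > 1 else ""
            kv = {m.group(1): m.group(2) for m in _KV_RE.finditer(rest)}
            if tag == "kind":
                kind = rest.strip()
            elif tag == "theta":
                theta = float(rest.strip())
            elif tag == "morse":
                label = rest.split()[0]
                lam = float(kv.get("lambda", DEFAULT_LAMBDA_NM))
                morse[label] = MorsePotential(D=float(kv["D"]), lam=lam)
            elif tag == "stack":
                label = rest.split()[0]
                stacking[label] = float(kv["k"])
            elif tag == "config":
                config.update({key: float(v) for key, v in kv.items()})
            else:
                raise DuplexError(f"{path}:{lineno}: unknown record {tag!r}")
    if kind is None:
        raise DuplexError(f"{path}: missing 'kind' record")
    return ParameterSet(kind, morse, stacking, theta), config


def write_parameter_file(path, params: ParameterSet, config: dict | None = None,
                         sds: dict | None = None) -> None:
    """Write a parameter file (inverse of :func:`read_parameter_file`).

    ``sds`` optionally maps (group, label) to a standard deviation,
    rendered as a trailing comment in compact uncertainty notation.
    """
    lines = [f"kind {params.kind}", f"theta {params.theta!r}"]
    for p in canonical_pairs(params.kind):
        m = params.morse[p]
        line = f"morse {p} D={m.D!r} lambda={m.lam!r}"
        if sds and ("morse", p) in sds:
            line += f"  # {format_compact(m.D, sds[('morse', p)])} meV"
        lines.append(line)
    for s in canonical_steps(params.kind):
        line = f"stack {s} k={params.stacking[s]!r}"
        if sds and ("stack", s) in sds:
            line += f"  # {format_compact(params.stacking[s], sds[('stack', s)])} eV/nm^2"
        lines.append(line)
    if config:
        kv = " ".join(f"{k}={v!r}" for k, v in sorted(config.items()))
        lines.append(f"config {kv}")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
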