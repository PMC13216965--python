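"""Duplex representation for DNA/DNA, DNA/RNA and RNA/RNA oligomers.

Base pairs and nearest-neighbour (NN) stacking steps are named by the
chemistry-explicit convention ``dAdT`` (a DNA A paired with a DNA T),
``dArU`` (a DNA A paired with an RNA U), ``rCrG`` and so on.  A stacking
step is the dimer ``pair1-pair2`` read 5'->3' along the first strand.

For DD and RR duplexes the antiparallel dyad symmetry makes a step and
its strand-swapped reading equivalent (``dTdA-dGdC`` is the same stack
as ``dCdG-dAdT``); the canonical representative is the alphabetically
smaller rendering.  Hybrid DR duplexes have two chemically distinct
strands, so no merging applies and all 16 steps are distinct.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

__all__ = [
    "Strand",
    "Duplex",
    "parse_duplex",
    "canonicalize_pair",
    "canonicalize_step",
    "canonical_pairs",
    "canonical_steps",
    "free_parameter_count",
    "DuplexError",
]

DEOXY = "deoxy"
RIBO = "ribo"

_ALPHABET = {DEOXY: "ACGT", RIBO: "ACGU"}
_PREFIX = {DEOXY: "d", RIBO: "r"}
_CHEM_FROM_PREFIX = {"d": DEOXY, "r": RIBO}

# Watson-Crick complement within each chemistry.
_COMPLEMENT = {
    DEOXY: {"A": "T", "T": "A", "C": "G", "G": "C"},
    RIBO: {"A": "U", "U": "A", "C": "G", "G": "C"},
}

# Watson-Crick partners across chemistries: base1 on strand1 pairs base2
# on strand2 iff base2 is the complement of base1 in strand2's chemistry.


class DuplexError(ValueError):
    """Invalid sequence text or inconsistent duplex geometry."""


@dataclass(frozen=True)
class Strand:
    """A single nucleic-acid strand, bases stored 5'->3'."""

    chemistry: str
    bases: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.chemistry not in (DEOXY, RIBO):
            raise DuplexError(f"unknown chemistry {self.chemistry!r}")
        if len(self.bases) < 2:
            raise DuplexError("strand must have at least 2 bases")
        alphabet = _ALPHABET[self.chemistry]
        for b in self.bases:
            if b not in alphabet:
                raise DuplexError(
                    f"base {b!r} not allowed in a {self.chemistry} strand"
                )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def prefix(self) -> str:
        return _PREFIX[self.chemistry]

    @property
    def sequence(self) -> str:
        return "".join(self.bases)

    def reverse_complement(self) -> "Strand":
        comp = _COMPLEMENT[self.chemistry]
        return Strand(self.chemistry, tuple(comp[b] for b in reversed(self.bases)))

    def complement_strand(self, chemistry: str | None = None) -> "Strand":
        """Perfect Watson-Crick partner (5'->3'), optionally in the other chemistry."""
        chem = chemistry or self.chemistry
        out = []
        for b in reversed(self.bases):
            if b == "C":
                out.append("G")
            elif b == "G":
                out.append("C")
            elif b in ("T", "U"):
                out.append("A")
            else:  # A: partner is T or U depending on the partner chemistry
                out.append("U" if chem == RIBO else "T")
        return Strand(chem, tuple(out))

    def render(self) -> str:
        return f"{self.prefix}({self.sequence})"


def _pair_label(chem1: str, base1: str, chem2: str, base2: str) -> str:
    return f"{_PREFIX[chem1]}{base1}{_PREFIX[chem2]}{base2}"


_PAIR_RE = re.compile(r"^([dr])([ACGTU])([dr])([ACGTU])$")


def _parse_pair_label(label: str) -> tuple[str, str, str, str]:
    m = _PAIR_RE.match(label)
    if not m:
        raise DuplexError(f"unknown pair label {label!r}")
    p1, b1, p2, b2 = m.groups()
    chem1, chem2 = _CHEM_FROM_PREFIX[p1], _CHEM_FROM_PREFIX[p2]
    if b1 not in _ALPHABET[chem1] or b2 not in _ALPHABET[chem2]:
        raise DuplexError(f"pair label {label!r} mixes T/U with the wrong chemistry")
    if not _is_wc(chem1, b1, chem2, b2):
        raise DuplexError(f"pair label {label!r} is not Watson-Crick")
    return chem1, b1, chem2, b2


def _is_wc(chem1: str, b1: str, chem2: str, b2: str) -> bool:
    """Is b1 (on a chem1 strand) Watson-Crick paired with b2 (on a chem2 strand)?"""
    wc = {("A", "T"), ("T", "A"), ("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
    if (b1, b2) not in wc:
        return False
    return b1 in _ALPHABET[chem1] and b2 in _ALPHABET[chem2]


def _swap_pair(label: str) -> str:
    """Read a pair from the opposite strand: dAdT -> dTdA, dArU -> rUdA."""
    chem1, b1, chem2, b2 = _parse_pair_label(label)
    return _pair_label(chem2, b2, chem1, b1)


def canonicalize_pair(label: str) -> str:
    """Canonical hydrogen-bond class of a base pair.

    DD and RR pairs merge with their strand-swapped reading (alphabetical
    tie-break), giving 2 classes each; hybrid pairs are kept distinct
    deoxy-first, giving 4 classes.
    """
    chem1, _, chem2, _ = _parse_pair_label(label)
    if chem1 != chem2:
        if chem1 == RIBO:  # store deoxy-first
            return _swap_pair(label)
        return label
    return min(label, _swap_pair(label))


_STEP_SEP_RE = re.compile(r"[-–—]")


def canonicalize_step(raw: str) -> str:
    """Canonical NN stacking-step label.

    For DD/RR the step and its dyad-symmetric reading (swap strands,
    reverse order) are the same physical stack; the alphabetically
    smaller rendering is returned.  Hybrid (DR) steps are returned
    unchanged apart from deoxy-first normalisation of each pair.
    """
    parts = [p for p in _STEP_SEP_RE.split(raw.strip()) if p]
    if len(parts) != 2:
        raise DuplexError(f"step label {raw!r} must name two base pairs")
    p1, p2 = parts
    c11, _, c12, _ = _parse_pair_label(p1)
    c21, _, c22, _ = _parse_pair_label(p2)
    kinds = {(c11, c12), (c21, c22)}
    if len(kinds) != 1:
        raise DuplexError(f"step label {raw!r} mixes duplex kinds")
    (chem1, chem2) = kinds.pop()
    if chem1 != chem2:
        # hybrid: normalise each pair deoxy-first; strands are distinct so
        # the dyad merging does not apply
        if chem1 == RIBO:
            p1, p2 = _swap_pair(p2), _swap_pair(p1)
        return f"{p1}-{p2}"
    alt = f"{_swap_pair(p2)}-{_swap_pair(p1)}"
    return min(f"{p1}-{p2}", alt)


def canonical_pairs(kind: str) -> tuple[str, ...]:
    """All canonical base-pair classes of a duplex kind (2/4/2 for DD/DR/RR)."""
    if kind == "DD":
        return ("dAdT", "dCdG")
    if kind == "RR":
        return ("rArU", "rCrG")
    if kind == "DR":
        return ("dArU", "dCrG", "dGrC", "dTrA")
    raise DuplexError(f"unknown duplex kind {kind!r}")


def canonical_steps(kind: str) -> tuple[str, ...]:
    """All canonical NN step classes (10 for DD, 10 for RR, 16 for DR)."""
    if kind == "DR":
        pairs = canonical_pairs("DR")
        return tuple(sorted(f"{a}-{b}" for a, b in itertools.product(pairs, pairs)))
    if kind == "DD":
        raw_pairs = ("dAdT", "dTdA", "dCdG", "dGdC")
    elif kind == "RR":
        raw_pairs = ("rArU", "rUrA", "rCrG", "rGrC")
    else:
        raise DuplexError(f"unknown duplex kind {kind!r}")
    labels = {canonicalize_step(f"{a}-{b}") for a, b in itertools.product(raw_pairs, raw_pairs)}
    return tuple(sorted(labels))


def free_parameter_count(kind: str) -> int:
    """Number of optimized parameters: Morse depths + stacking constants."""
    return len(canonical_pairs(kind)) + len(canonical_steps(kind))


@dataclass(frozen=True)
class Duplex:
    """A fully complementary, gap-free duplex.

    ``strand1`` and ``strand2`` are both stored 5'->3'; position ``i`` of
    strand1 pairs with position ``L-1-i`` of strand2.  For hybrids the
    deoxy strand is always strand1; ``display_swapped`` records that the
    user wrote the RNA strand first (RD labelling).
    """

    strand1: Strand
    strand2: Strand
    display_swapped: bool = False
    kind: str = field(init=False)
    pairs: tuple[str, ...] = field(init=False)
    steps: tuple[str, ...] = field(init=False)
    self_complementary: bool = field(init=False)

    def __post_init__(self) -> None:
        s1, s2 = self.strand1, self.strand2
        if len(s1) != len(s2):
            raise DuplexError(
                f"strand lengths differ: {len(s1)} vs {len(s2)}"
            )
        if s1.chemistry == RIBO and s2.chemistry == DEOXY:
            raise DuplexError("hybrid duplexes must store the deoxy strand first")
        kind = {"deoxydeoxy": "DD", "deoxyribo": "DR", "riboribo": "RR"}[
            s1.chemistry + s2.chemistry
        ]
        n = len(s1)
        raw_pairs = []
        for i in range(n):
            b1 = s1.bases[i]
            b2 = s2.bases[n - 1 - i]
            if not _is_wc(s1.chemistry, b1, s2.chemistry, b2):
                raise DuplexError(
                    f"aligned pair {b1}·{b2} at position {i + 1} is not Watson-Crick"
                )
            raw_pairs.append(_pair_label(s1.chemistry, b1, s2.chemistry, b2))
        steps = tuple(
            canonicalize_step(f"{raw_pairs[i]}-{raw_pairs[i + 1]}")
            for i in range(n - 1)
        )
        selfc = kind != "DR" and s1.bases == s1.reverse_complement().bases
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "pairs", tuple(canonicalize_pair(p) for p in raw_pairs))
        object.__setattr__(self, "steps", steps)
        object.__setattr__(self, "self_complementary", selfc)

    def __len__(self) -> int:
        return len(self.strand1)

    @property
    def n_bp(self) -> int:
        return len(self.strand1)

    def raw_pairs(self) -> tuple[str, ...]:
        """Position-oriented pair labels (strand1 base first), uncanonicalized."""
        s1, s2 = self.strand1, self.strand2
        n = len(s1)
        return tuple(
            _pair_label(s1.chemistry, s1.bases[i], s2.chemistry, s2.bases[n - 1 - i])
            for i in range(n)
        )

    def swapped(self) -> "Duplex":
        """The same duplex read with the strand roles exchanged."""
        if self.kind == "DR":
            return self  # deoxy-first storage is fixed for hybrids
        return Duplex(self.strand2, self.strand1, display_swapped=not self.display_swapped)

    def render(self) -> str:
        """Text form ``d(...)/d(...)`` with strand2 written 3'->5' (aligned)."""
        s2_aligned = "".join(reversed(self.strand2.bases))
        return f"{self.strand1.render()}/{self.strand2.prefix}({s2_aligned})"

    def cg_fraction(self) -> float:
        return sum(1 for p in self.pairs if "C" in p or "G" in p) / len(self.pairs)


_STRAND_RE = re.compile(r"^([dr])?\(?([ACGTUacgtu\s\-]+)\)?$")


def _parse_strand_text(text: str, default_chemistry: str | None) -> Strand:
    text = text.strip()
    # strip 5'/3' decorations
    text = re.sub(r"5[′']\s*-?", "", text)
    text = re.sub(r"-?\s*3[′']", "", text)
    m = _STRAND_RE.match(text.strip())
    if not m:
        raise DuplexError(f"cannot parse strand text {text!r}")
    prefix, seq = m.groups()
    seq = re.sub(r"[\s\-]", "", seq).upper()
    if prefix is None:
        if default_chemistry is None:
            chem = RIBO if "U" in seq else DEOXY
        else:
            chem = default_chemistry
    else:
        chem = _CHEM_FROM_PREFIX[prefix]
    return Strand(chem, tuple(seq))


def parse_duplex(text: str, chemistry: str | None = None) -> Duplex:
    """Parse duplex notation into a validated :class:`Duplex`.

    Accepts a single strand, e.g. ``d(CGCAAATTTGCG)`` (the perfect
    Watson-Crick complement of the same chemistry is inferred), or the
    two-strand form ``d(TCCGAATTATCT)/r(AGGCUUAAUAGA)`` in which the
    second strand is written 3'->5' so the two sequences align position
    by position, following the usual duplex-dimer notation.

    Parsing is case-insensitive; whitespace, hyphens and 5'/3' labels in
    the sequence text are ignored.  An RNA-first hybrid (RD) input is
    stored deoxy-strand-first with ``display_swapped=True``.
    """
    parts = text.split("/")
    if len(parts) == 1:
        s1 = _parse_strand_text(parts[0], chemistry)
        s2 = s1.complement_strand()
        return Duplex(s1, s2)
    if len(parts) != 2:
        raise DuplexError(f"expected at most two strands in {text!r}")
    s1 = _parse_strand_text(parts[0], chemistry)
    s2_aligned = _parse_strand_text(parts[1], chemistry)
    # the second strand is written 3'->5'; store 5'->3'
    s2 = Strand(s2_aligned.chemistry, tuple(reversed(s2_aligned.bases)))
    if s1.chemistry == RIBO and s2.chemistry == DEOXY:
        return Duplex(s2, s1, display_swapped=True)
    return Duplex(s1, s2)
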