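"""No-cosolute reference melting temperatures from nearest-neighbour tables.

The two-state NN model predicts the melting temperature of a duplex from
tabulated per-step enthalpies ΔH° (kcal/mol) and entropies ΔS°
(cal/(mol·K)):

    Tm = ΔH°_tot / (ΔS°_tot + R ln(Ct/x)) - 273.15,

with R = 1.9872 cal/(mol·K), Ct the total strand concentration (M) and
symmetry factor x = 1 for self-complementary duplexes, 4 otherwise.
ΔH°_tot and ΔS°_tot sum the NN step terms, the initiation terms and the
self-complementarity symmetry correction.  These reference temperatures
give the no-cosolute condition against which cosolute-perturbed
parameters are anchored.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources

from .duplex import Duplex, DuplexError
from .regression import MeltingRecord

__all__ = [
    "R_CAL",
    "NNThermoTable",
    "nn_tm",
    "generate_nc_set",
    "load_packaged_nn_table",
    "default_ct",
]

#: gas constant in cal/(mol K)
R_CAL = 1.9872

#: total strand concentrations (µM) of the emulated datasets
CT_SELF_COMPLEMENTARY_UM = 200.0
CT_NON_SELF_COMPLEMENTARY_UM = 100.0


def default_ct(duplex: Duplex) -> float:
    """Dataset convention: 200 µM self-complementary, 100 µM otherwise."""
    return CT_SELF_COMPLEMENTARY_UM if duplex.self_complementary else CT_NON_SELF_COMPLEMENTARY_UM


@dataclass
class NNThermoTable:
    """Nearest-neighbour ΔH°/ΔS° table for one duplex kind.

    ``steps`` maps canonical NN step labels to (ΔH° kcal/mol, ΔS°
    cal/(mol·K)); ``init`` holds initiation terms — the reserved label
    ``init`` is applied once per duplex, ``init:<pair>`` once per
    terminal end whose pair class matches; ``sym`` is the
    self-complementarity correction.  ``provenance`` is required and is
    carried into the table file header.
    """

    kind: str
    steps: dict[str, tuple[float, float]]
    init: dict[str, tuple[float, float]] = field(default_factory=dict)
    sym: tuple[float, float] = (0.0, 0.0)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("NN table requires a provenance label")

    def totals(self, duplex: Duplex) -> tuple[float, float]:
        """ΔH°_tot (kcal/mol) and ΔS°_tot (cal/(mol·K)) for ``duplex``."""
        if duplex.kind != self.kind:
            raise DuplexError(
                f"table for {self.kind} cannot score a {duplex.kind} duplex "
                f"{duplex.render()}"
            )
        dh = ds = 0.0
        missing = [s for s in duplex.steps if s not in self.steps]
        if missing:
            raise DuplexError(
                f"table {self.provenance!r} missing NN entries {sorted(set(missing))} "
                f"for duplex {duplex.render()}"
            )
        for s in duplex.steps:
            h, sv = self.steps[s]
            dh += h
            ds += sv
        if "init" in self.init:
            h, sv = self.init["init"]
            dh += h
            ds += sv
        for terminal in (duplex.pairs[0], duplex.pairs[-1]):
            key = f"init:{terminal}"
            if key in self.init:
                h, sv = self.init[key]
                dh += h
                ds += sv
        if duplex.self_complementary:
            dh += self.sym[0]
            ds += self.sym[1]
        return dh, ds


def nn_tm(duplex: Duplex, table: NNThermoTable, Ct: float) -> float:
    """Two-state NN melting temperature (°C) at total strand concentration Ct (µM)."""
    if not Ct > 0:
        raise ValueError("Ct must be positive")
    dh, ds = table.totals(duplex)
    x = 1.0 if duplex.self_complementary else 4.0
    ct_molar = Ct * 1e-6
    denom = ds + R_CAL * math.log(ct_molar / x)
    tm_k = dh * 1000.0 / denom
    return tm_k - 273.15


def generate_nc_set(duplexes: list[Duplex], table: NNThermoTable,
                    ct_rule=default_ct, condition: str = "NC") -> list[MeltingRecord]:
    """One no-cosolute reference record per duplex.

    All coverage errors are gathered and reported together, naming the
    offending duplexes.
    """
    errors = []
    records = []
    for d in duplexes:
        try:
            ct = ct_rule(d)
            records.append(
                MeltingRecord(duplex=d, Tm_exp=nn_tm(d, table, ct), Ct=ct,
                              condition=condition)
            )
        except DuplexError as exc:
            errors.append(str(exc))
    if errors:
        raise DuplexError("; ".join(errors))
    return records


# ---------------------------------------------------------------------------
# TSV table I/O
# ---------------------------------------------------------------------------

def read_nn_table(path_or_file, kind: str | None = None) -> NNThermoTable:
    """Read an NN table from TSV with columns nn_label, dH_kcal_mol, dS_cal_molK.

    Header comment lines ``# provenance: ...`` and ``# kind: ...`` set the
    metadata; reserved labels ``init``, ``init:<pair>`` and ``sym`` fill
    the non-step terms.
    """
    if hasattr(path_or_file, "read"):
        lines = path_or_file.read().splitlines()
    else:
        with open(path_or_file, "rt", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    provenance = ""
    steps: dict[str, tuple[float, float]] = {}
    init: dict[str, tuple[float, float]] = {}
    sym = (0.0, 0.0)
    rows = []
    for line in lines:
        if line.startswith("#"):
            meta = line[1:].strip()
            if meta.lower().startswith("provenance:"):
                provenance = meta.split(":", 1)[1].strip()
            elif meta.lower().startswith("kind:"):
                kind = kind or meta.split(":", 1)[1].strip()
            continue
        if line.strip():
            rows.append(line)
    reader = csv.DictReader(rows, delimiter="\t")
    for row in reader:
        label = row["nn_label"].strip()
        entry = (float(row["dH_kcal_mol"]), float(row["dS_cal_molK"]))
        if label == "sym":
            sym = entry
        elif label == "init" or label.startswith("init:"):
            init[label] = entry
        else:
            steps[label] = entry
    if kind is None:
        raise ValueError("duplex kind not given and not present in the file header")
    return NNThermoTable(kind=kind, steps=steps, init=init, sym=sym,
                         provenance=provenance or "unspecified")


def write_nn_table(path, table: NNThermoTable) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# provenance: {table.provenance}\n")
        fh.write(f"# kind: {table.kind}\n")
        fh.write("nn_label\tdH_kcal_mol\tdS_cal_molK\n")
        for label in sorted(table.steps):
            h, s = table.steps[label]
            fh.write(f"{label}\t{h!r}\t{s!r}\n")
        for label in sorted(table.init):
            h, s = table.init[label]
            fh.write(f"{label}\t{h!r}\t{s!r}\n")
        if table.sym != (0.0, 0.0):
            fh.write(f"sym\t{table.sym[0]!r}\t{table.sym[1]!r}\n")


_PACKAGED = {
    "DD": "nn_dd_santalucia1998.tsv",
    "DR": "nn_dr_synthetic.tsv",
    "RR": "nn_rr_synthetic.tsv",
}


def load_packaged_nn_table(kind: str) -> NNThermoTable:
    """Load the NN table shipped with the package for a duplex kind.

    The DD table transcribes the unified oligonucleotide NN set
    (SantaLucia 1998).  The DR and RR tables are synthetic stand-ins
    with realistic magnitudes (see their provenance headers): the
    published hybrid and RNA tables should be supplied by the user for
    quantitative work.
    """
    try:
        name = _PACKAGED[kind]
    except KeyError:
        raise DuplexError(f"no packaged NN table for kind {kind!r}") from None
    ref = resources.files("mesomelt.data").joinpath(name)
    with ref.open("rt", encoding="utf-8") as fh:
        return read_nn_table(fh, kind=kind)
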