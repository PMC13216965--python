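"""Tabular I/O, run configuration and provenance manifests.

Melting tables are plain TSV with the columns

    id  strand1  strand2  chemistry1  chemistry2  Tm_experimental  Ct  condition

of which only ``id`` and ``strand1`` are required: a missing strand2 is
inferred as the perfect Watson-Crick complement, chemistries default to
deoxy (or to the letters present: a U implies ribo), and Tm/Ct may be
empty for prediction-only inputs.  strand2 is written 3'->5' so the two
sequences align position by position, the same convention as the
duplex-notation parser.  Temperatures in files are °C.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .duplex import DEOXY, RIBO, Duplex, DuplexError, Strand
from .regression import MeltingRecord

__all__ = [
    "read_melting_table",
    "write_melting_table",
    "read_fasta_strands",
    "RunManifest",
]

_CHEM_ALIASES = {
    "d": DEOXY, "dna": DEOXY, "deoxy": DEOXY,
    "r": RIBO, "rna": RIBO, "ribo": RIBO,
}


def _chemistry_of(value, seq: str) -> str:
    if value is not None and not pd.isna(value) and str(value).strip():
        key = str(value).strip().lower()
        if key not in _CHEM_ALIASES:
            raise DuplexError(f"unknown chemistry {value!r}")
        return _CHEM_ALIASES[key]
    return RIBO if "U" in seq.upper() else DEOXY


def read_melting_table(path, strict: bool = True, condition: str | None = None,
                       log=None) -> list[MeltingRecord]:
    """Read melting records from TSV.

    In strict mode any malformed row raises an error naming the row; in
    permissive mode malformed rows are skipped and reported through
    ``log`` (a callable, default print).
    """
    log = log or (lambda msg: print(msg))
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "strand1" not in df.columns or "id" not in df.columns:
        raise DuplexError(f"{path}: melting table needs 'id' and 'strand1' columns")
    records = []
    for row_no, row in df.iterrows():
        try:
            records.append(_record_from_row(row, condition))
        except (DuplexError, ValueError) as exc:
            msg = f"{path}: row {row_no + 2} ({row.get('id', '?')}): {exc}"
            if strict:
                raise DuplexError(msg) from exc
            log(f"skipping {msg}")
    return records


def _record_from_row(row, condition: str | None) -> MeltingRecord:
    seq1 = str(row["strand1"]).strip()
    chem1 = _chemistry_of(row.get("chemistry1"), seq1)
    s1 = Strand(chem1, tuple(seq1.upper().replace(" ", "")))
    seq2 = row.get("strand2")
    if seq2 is None or pd.isna(seq2) or not str(seq2).strip():
        chem2 = _chemistry_of(row.get("chemistry2"), "") if _has(row, "chemistry2") else chem1
        s2 = s1.complement_strand(chem2)
    else:
        seq2 = str(seq2).strip().upper()
        chem2 = _chemistry_of(row.get("chemistry2"), seq2)
        # table stores strand2 aligned 3'->5'
        s2 = Strand(chem2, tuple(reversed(seq2)))
    if s1.chemistry == RIBO and s2.chemistry == DEOXY:
        duplex = Duplex(s2, s1, display_swapped=True)
    else:
        duplex = Duplex(s1, s2)
    tm = _float_or_none(row.get("Tm_experimental"))
    ct = _float_or_none(row.get("Ct"))
    cond = condition
    if cond is None:
        raw = row.get("condition")
        cond = str(raw).strip() if raw is not None and not pd.isna(raw) else "PEG"
    if tm is None:
        raise ValueError("missing Tm_experimental")
    return MeltingRecord(duplex=duplex, Tm_exp=tm, Ct=ct, condition=cond,
                         record_id=str(row["id"]))


def _has(row, key) -> bool:
    return key in row.index if hasattr(row, "index") else key in row


def _float_or_none(value):
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if not text or text.lower() in ("na", "n/a", "nan", "none"):
        if text and text.lower() != "nan":
            raise ValueError(f"non-numeric value {value!r}")
        return None
    return float(text)


def write_melting_table(path, records: list[MeltingRecord]) -> None:
    rows = []
    for i, rec in enumerate(records):
        d = rec.duplex
        rows.append({
            "id": rec.record_id or f"seq{i:03d}",
            "strand1": d.strand1.sequence,
            "strand2": "".join(reversed(d.strand2.bases)),
            "chemistry1": d.strand1.chemistry,
            "chemistry2": d.strand2.chemistry,
            "Tm_experimental": repr(float(rec.Tm_exp)),
            "Ct": "" if rec.Ct is None else repr(float(rec.Ct)),
            "condition": rec.condition,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta_strands(path) -> list[tuple[str, Strand]]:
    """Single strands from FASTA; chemistry from a ``chemistry=`` header tag.

    Example header: ``>seq1 chemistry=ribo``.  Without a tag the
    chemistry is inferred from the letters (U implies ribo).
    """
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        chem = None
        for token in rec.description.split():
            if token.lower().startswith("chemistry="):
                chem = _CHEM_ALIASES[token.split("=", 1)[1].lower()]
        seq = str(rec.seq).upper()
        if chem is None:
            chem = RIBO if "U" in seq else DEOXY
        out.append((rec.id, Strand(chem, tuple(seq))))
    return out


@dataclass
class RunManifest:
    """Provenance record of a pipeline run.

    Written as JSON before the process exits, on success or failure, so
    a run directory is always self-describing: resolved configuration,
    input digests, RNG seed, software version, stage timings and the
    produced files.
    """

    command: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    timings: dict = field(default_factory=dict)
    status: str = "running"
    version: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        self._t0 = time.monotonic()

    def add_input(self, path) -> None:
        p = Path(path)
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        self.inputs[str(p)] = digest

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def time_stage(self, name: str) -> None:
        self.timings[name] = round(time.monotonic() - self._t0, 3)

    def write(self, path, status: str | None = None) -> None:
        if status:
            self.status = status
        payload = {
            "command": self.command,
            "seed": self.seed,
            "config": self.config,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "timings": self.timings,
            "status": self.status,
            "version": self.version,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n",
                              encoding="utf-8")
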