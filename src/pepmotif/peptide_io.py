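"""Reading and writing the tool's external formats.

Formats handled here:

* peptide tables — whitespace-separated ``PEPTIDE [value]`` lines,
  ``#`` comments ignored; either every data line carries a numeric value
  (training / validation data) or none does (prediction-only input);
* FASTA protein files (via Bio.SeqIO);
* trained-model files — a versioned JSON container holding every network's
  weights, the encoding configuration and the rescaling parameters, so that
  a model trained once can be reloaded for prediction with bit-identical
  results;
* PSSM text — one row per motif position, one column per amino acid in
  alphabetical order, 4 decimals.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Union

import numpy as np
from Bio import SeqIO

from .alphabet import AA_ORDER, validate_peptide

MODEL_FORMAT = "pepmotif-ensemble"
MODEL_VERSION = 1


class FormatError(ValueError):
    """Raised when an input file does not follow the expected format."""


@dataclass
class QuantPeptideDataset:
    """Peptide sequences with (optional) quantitative measurements."""

    peptides: list[str]
    targets: Optional[list[float]] = None
    source_labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.peptides = [validate_peptide(p) for p in self.peptides]
        if self.targets is not None:
            self.targets = [float(t) for t in self.targets]
            if len(self.targets) != len(self.peptides):
                raise ValueError(
                    f"{len(self.peptides)} peptides but "
                    f"{len(self.targets)} target values"
                )

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def has_targets(self) -> bool:
        return self.targets is not None


@dataclass
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record with empty id")
        self.sequence = validate_peptide(self.sequence, context=f"sequence {self.id!r}")


def _as_text_stream(source: Union[str, IO[str]]) -> IO[str]:
    if isinstance(source, str):
        return open(source, "r")
    return source


def read_peptide_table(source: Union[str, IO[str]]) -> QuantPeptideDataset:
    """Parse a peptide table: one ``PEPTIDE [value]`` pair per line.

    Mixing lines with and without a value is rejected (the first offending
    line is named); a non-numeric second column or an illegal residue is
    an error.  Trailing whitespace and Windows line endings are tolerated.
    """
    stream = _as_text_stream(source)
    peptides: list[str] = []
    values: list[float] = []
    mode: Optional[bool] = None  # True: with values, False: without
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        has_value = len(fields) >= 2
        if has_value:
            try:
                value = float(fields[1])
            except ValueError:
                raise FormatError(
                    f"line {lineno}: second column {fields[1]!r} is not numeric"
                ) from None
        if mode is None:
            mode = has_value
        elif mode != has_value:
            raise FormatError(
                f"line {lineno}: mixed format — every line must either carry "
                "a value or none may"
            )
        peptides.append(fields[0])
        if has_value:
            values.append(value)
    if not peptides:
        raise FormatError("no peptide lines found")
    return QuantPeptideDataset(peptides=peptides, targets=values if mode else None)


def write_peptide_table(dataset: QuantPeptideDataset, dest: Union[str, IO[str]]) -> None:
    close = isinstance(dest, str)
    stream = open(dest, "w") if close else dest
    try:
        for i, pep in enumerate(dataset.peptides):
            if dataset.has_targets:
                stream.write(f"{pep} {dataset.targets[i]:.6f}\n")
            else:
                stream.write(f"{pep}\n")
    finally:
        if close:
            stream.close()


def read_fasta(source: Union[str, IO[str]]) -> list[ProteinRecord]:
    """Read FASTA protein records in file order, uppercased."""
    stream = _as_text_stream(source)
    text = stream.read()
    stripped = text.lstrip()
    if not stripped:
        raise FormatError("empty FASTA input")
    if not stripped.startswith(">"):
        raise FormatError("FASTA input does not start with a '>' header line")
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).replace(" ", "").upper()
        if not seq:
            raise FormatError(f"FASTA record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError("no FASTA records found")
    return records


# ---------------------------------------------------------------------------
# model serialization


def save_model(ensemble, path: Union[str, IO[str]]) -> None:
    """Serialize a trained ensemble to a versioned JSON container.

    Floats are written with full ``repr`` precision, so the round trip is
    the identity on every weight.
    """
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        **ensemble.to_dict(),
    }
    close = isinstance(path, str)
    stream = open(path, "w") if close else path
    try:
        json.dump(payload, stream)
        stream.write("\n")
    finally:
        if close:
            stream.close()


def load_model(path: Union[str, IO[str]]):
    """Load an ensemble saved by :func:`save_model`."""
    from .ensemble import Ensemble  # local import to avoid a cycle

    close = isinstance(path, str)
    stream = open(path, "r") if close else path
    try:
        try:
            payload = json.load(stream)
        except json.JSONDecodeError as exc:
            raise FormatError(f"model file is not valid JSON: {exc}") from None
    finally:
        if close:
            stream.close()
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise FormatError("not a recognised model file (missing format header)")
    if payload.get("version") != MODEL_VERSION:
        raise FormatError(
            f"unsupported model file version {payload.get('version')!r} "
            f"(this build reads version {MODEL_VERSION})"
        )
    return Ensemble.from_dict(payload)


# ---------------------------------------------------------------------------
# PSSM text


def write_pssm_text(matrix: np.ndarray, header: str = "") -> str:
    """Format a position × amino-acid score matrix as text.

    One row per motif position (1-based index in the first column), one
    column per residue in alphabetical order, 4 decimals.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != 20:
        raise ValueError("PSSM matrix must have shape (motif_len, 20)")
    lines = []
    if header:
        for hline in header.splitlines():
            lines.append(f"# {hline}")
    lines.append("pos " + " ".join(f"{aa:>8s}" for aa in AA_ORDER))
    for i, row in enumerate(matrix, start=1):
        lines.append(f"{i:3d} " + " ".join(f"{v:8.4f}" for v in row))
    return "\n".join(lines) + "\n"


def parse_pssm_text(text: str) -> np.ndarray:
    """Parse text produced by :func:`write_pssm_text` back to a matrix."""
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("pos"):
            continue
        fields = line.split()
        if len(fields) != 21:
            raise FormatError(f"malformed PSSM row: {line!r}")
        rows.append([float(v) for v in fields[1:]])
    if not rows:
        raise FormatError("no PSSM rows found")
    return np.array(rows, dtype=float)
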