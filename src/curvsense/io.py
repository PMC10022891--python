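"""File I/O: FASTA, dataset CSV, hydrophobicity scales, constants files.

Datasets are plain CSV with a ``sequence,ddf`` header (an optional
``length`` column is derived, never trusted).  FASTA description lines
may carry a ``ddf=<value>`` key to attach labels to records.  Constants
and configuration files are flat YAML whose keys mirror the dataclass
fields they override.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .peptides import Alphabet, HydrophobicityScale, Peptide, MIN_MODEL_LENGTH
from .surrogate import LabeledSequence
from .thermo import ThermoConstants

log = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_dataset",
    "write_dataset",
    "read_scale",
    "read_constants",
]


def _parse_ddf(description: str) -> float | None:
    for token in description.split():
        if token.startswith("ddf="):
            try:
                return float(token[4:])
            except ValueError:
                raise ValueError(f"malformed ddf key in description: {token!r}") from None
    return None


def read_fasta(
    path: "str | Path", alphabet: Alphabet = Alphabet.full20
) -> list[tuple[str, Peptide, float | None]]:
    """Read peptides from FASTA, order preserving.

    Returns (record id, peptide, optional ddf label) triples; a label is
    attached when the description carries a ``ddf=<float>`` key.
    """
    out = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        try:
            pep = Peptide(str(rec.seq).upper(), alphabet)
        except ValueError as exc:
            raise ValueError(f"record {i + 1} ({rec.id}): {exc}") from exc
        out.append((rec.id, pep, _parse_ddf(rec.description)))
    if not out:
        log.warning("no FASTA records found in %s", path)
    return out


def write_fasta(
    path: "str | Path",
    peptides: Sequence[Peptide],
    ids: Sequence[str] | None = None,
    ddfs: Sequence[float] | None = None,
) -> None:
    records = []
    for i, pep in enumerate(peptides):
        name = ids[i] if ids is not None else f"pep{i + 1}"
        desc = f"ddf={ddfs[i]:.4f}" if ddfs is not None else ""
        records.append(SeqRecord(Seq(pep.sequence), id=name, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_dataset(
    path: "str | Path", alphabet: Alphabet = Alphabet.full20
) -> list[LabeledSequence]:
    """Read a ``sequence,ddf`` CSV into labeled records.

    Sequences must be 7-24 residues (the validity range of the model
    chain); offending rows are reported with their row numbers.
    Duplicate sequences are kept but reported.
    """
    df = pd.read_csv(path, comment="#")
    missing = {"sequence", "ddf"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if not pd.api.types.is_numeric_dtype(df["ddf"]):
        bad = df[pd.to_numeric(df["ddf"], errors="coerce").isna()]
        raise ValueError(f"{path}: non-numeric ddf in row(s) {list(bad.index + 2)}")
    bad_rows = [
        i + 2  # header is line 1
        for i, s in enumerate(df["sequence"])
        if not MIN_MODEL_LENGTH <= len(str(s)) <= 24
    ]
    if bad_rows:
        raise ValueError(
            f"{path}: sequence length outside [7, 24] in row(s) {bad_rows}"
        )
    dupes = df["sequence"][df["sequence"].duplicated()].unique()
    if len(dupes):
        log.warning("%s: %d duplicate sequence(s), e.g. %s", path, len(dupes), dupes[0])
    return [
        LabeledSequence(Peptide(str(row.sequence), alphabet), float(row.ddf))
        for row in df.itertuples()
    ]


def write_dataset(path: "str | Path", records: Sequence[LabeledSequence]) -> None:
    from .surrogate import dataset_to_frame

    dataset_to_frame(list(records)).to_csv(path, index=False)


def read_scale(path: "str | Path", name: str | None = None) -> HydrophobicityScale:
    """Load a residue,value two-column delimited text hydrophobicity scale."""
    path = Path(path)
    values: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'residue value', got {line!r}")
        values[parts[0].upper()] = float(parts[1])
    return HydrophobicityScale(values, name=name or path.stem)


def read_constants(path: "str | Path") -> ThermoConstants:
    """Load thermodynamic constants from a flat YAML key-value file.

    Keys mirror :class:`curvsense.thermo.ThermoConstants` fields; unknown
    keys are rejected.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat mapping")
    fields = {f.name for f in dataclasses.fields(ThermoConstants)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"{path}: unknown constant(s) {sorted(unknown)}")
    return ThermoConstants(**raw)
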