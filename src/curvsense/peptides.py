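"""Peptide sequences, alphabets, and physicochemical descriptors.

Amphipathic helices are commonly summarized by three sequence-derived
descriptors: net charge ``z``, mean hydrophobicity ``<H>``, and the
hydrophobic moment ``mu_H`` (the magnitude of the vector sum of residue
hydrophobicities around the helical wheel, 100 deg per residue for an
alpha-helix).  These descriptors are provided here both as features in
their own right and as inputs to the thermodynamic classification chain.

The module also holds the two alphabets used throughout the package: the
full 20-letter amino-acid alphabet and a reduced 10-letter alphabet of
helix-prone residues {A, L, M, K, Q, E, W, S, Y, F} used for de novo
design runs, plus position-frequency matrices for consensus analysis of
evolved populations.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Alphabet",
    "Peptide",
    "HydrophobicityScale",
    "EISENBERG",
    "PositionFrequencyMatrix",
    "net_charge",
    "mean_hydrophobicity",
    "hydrophobic_moment",
    "position_frequency_matrix",
]

#: Canonical one-letter codes, alphabetical.  This ordering is also the
#: channel order of the one-hot encoding used by the regressor.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Helix-prone reduced alphabet used for design runs: one representative of
#: every chemical subtype, residues with low alpha-helix propensity removed.
AA10 = "ALMKQEWSYF"

MAX_LENGTH = 24
MIN_MODEL_LENGTH = 7  # prediction / classification validity floor


class Alphabet(str, enum.Enum):
    """Residue alphabets supported for peptide construction."""

    full20 = "full20"
    reduced10 = "reduced10"

    @property
    def letters(self) -> str:
        return AA20 if self is Alphabet.full20 else AA10


class AlphabetError(ValueError):
    """Sequence contains a residue outside its declared alphabet."""


@dataclass(frozen=True)
class Peptide:
    """A validated peptide sequence.

    Parameters
    ----------
    sequence
        One-letter amino-acid codes, upper case, 1-24 residues.
    alphabet
        The alphabet the sequence is declared over.  Construction checks
        every residue against it.
    """

    sequence: str
    alphabet: Alphabet = Alphabet.full20

    def __post_init__(self) -> None:
        if not 1 <= len(self.sequence) <= MAX_LENGTH:
            raise ValueError(
                f"peptide length must be in [1, {MAX_LENGTH}], got {len(self.sequence)}"
            )
        allowed = set(self.alphabet.letters)
        bad = [c for c in self.sequence if c not in allowed]
        if bad:
            raise AlphabetError(
                f"residue(s) {sorted(set(bad))} not in alphabet {self.alphabet.value}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence


def as_peptide(seq: "Peptide | str", alphabet: Alphabet = Alphabet.full20) -> Peptide:
    return seq if isinstance(seq, Peptide) else Peptide(seq, alphabet)


@dataclass(frozen=True)
class HydrophobicityScale:
    """A residue -> hydrophobicity mapping (dimensionless).

    Must be defined for all 20 standard residues so that any valid peptide
    can be scored.  Custom scales can be loaded from two-column delimited
    text via :func:`curvsense.io.read_scale`.
    """

    values: Mapping[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = [a for a in AA20 if a not in self.values]
        if missing:
            raise ValueError(f"scale '{self.name}' missing residues {missing}")

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise AlphabetError(f"unknown residue {residue!r}") from None

    def of(self, p: "Peptide | str") -> np.ndarray:
        """Per-residue hydrophobicity values as an array."""
        return np.array([self[r] for r in str(p)], dtype=float)


#: Eisenberg consensus hydrophobicity scale (normalized, dimensionless).
EISENBERG = HydrophobicityScale(
    {
        "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
        "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
        "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
        "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
    },
    name="eisenberg",
)

_POSITIVE = frozenset("KR")
_NEGATIVE = frozenset("DE")


def net_charge(p: "Peptide | str", include_termini: bool = False) -> int:
    """Side-chain net charge at neutral pH.

    z = (#K + #R) - (#D + #E); histidine counts as neutral.  The peptide
    termini are treated as a zwitterionic pair (+1 amino, -1 carboxyl)
    whose net contribution is zero, so ``include_termini`` never changes
    the result -- the flag only documents the convention.
    """
    p = as_peptide(p)
    z = sum(1 for r in p.sequence if r in _POSITIVE) - sum(
        1 for r in p.sequence if r in _NEGATIVE
    )
    if include_termini:
        z += 1 - 1
    return z


def mean_hydrophobicity(
    p: "Peptide | str", scale: HydrophobicityScale = EISENBERG
) -> float:
    """Arithmetic mean of per-residue hydrophobicities, <H>."""
    return float(np.mean(scale.of(p)))


def hydrophobic_moment(
    p: "Peptide | str",
    scale: HydrophobicityScale = EISENBERG,
    delta_deg: float = 100.0,
    normalized: bool = True,
) -> float:
    """Hydrophobic moment mu_H of an idealized helix.

    mu_H = |sum_n H_n * exp(i * n * delta)| with delta the per-residue
    rotation (100 deg for an alpha-helix; configurable for 3_10 or pi
    helices).  By default the total moment is divided by the length so
    peptides of different lengths are comparable; pass
    ``normalized=False`` for the raw vector-sum magnitude.
    """
    h = scale.of(p)
    delta = math.radians(delta_deg)
    phases = np.exp(1j * delta * np.arange(h.size))
    total = abs(np.sum(h * phases))
    return float(total / h.size) if normalized else float(total)


@dataclass
class PositionFrequencyMatrix:
    """Per-position residue counts/probabilities for equal-length peptides.

    Rows are residues (in ``letters`` order), columns are positions.
    Suitable as input to sequence-logo tools.
    """

    letters: str
    counts: np.ndarray  # (len(letters), L) non-negative ints
    n_sequences: int = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        col_sums = self.counts.sum(axis=0)
        if col_sums.size and not (col_sums == col_sums[0]).all():
            raise ValueError("every column must contain the same number of residues")
        self.n_sequences = int(col_sums[0]) if col_sums.size else 0

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    def consensus(self) -> str:
        """Most frequent residue per position (ties -> alphabetical first)."""
        return "".join(self.letters[i] for i in self.counts.argmax(axis=0))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.probabilities.T, columns=list(self.letters),
            index=pd.RangeIndex(self.length, name="position"),
        )


def position_frequency_matrix(
    seqs: Sequence["Peptide | str"], letters: str = AA20
) -> PositionFrequencyMatrix:
    """Count residues per position over a set of equal-length peptides."""
    seqs = [str(s) for s in seqs]
    if not seqs:
        raise ValueError("need at least one sequence")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("all sequences must have equal length")
    index = {a: i for i, a in enumerate(letters)}
    counts = np.zeros((len(letters), L), dtype=int)
    for s in seqs:
        for pos, r in enumerate(s):
            try:
                counts[index[r], pos] += 1
            except KeyError:
                raise AlphabetError(f"residue {r!r} not in PFM alphabet") from None
    return PositionFrequencyMatrix(letters, counts)
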