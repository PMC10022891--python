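"""Deterministic surrogate fitness oracle and synthetic dataset generator.

The real design loop scores peptides by ensemble-averaged free energy
calculations from coarse-grained simulations; that stage is expensive
and external.  This module provides a cheap, pure, seeded stand-in with
the same interface so the genetic algorithm and the regressor are
testable end-to-end at desk scale.

The toy score captures the two qualitative drivers of curvature sensing
-- it rewards hydrophobic content and penalizes net charge --

    ddF_toy = -kappa * sum_i max(0, H_i) + lam * |z|,  clipped to [-40, 0],

with H_i the Eisenberg hydrophobicity of residue i.  The toy insertion
depth makes the surface constraint of the fitness scaling meaningful:
with f the hydrophobic residue fraction, d = 2b(1 - f), so an all-polar
peptide floats in solution (d = 2b, factor 0), an all-hydrophobic one
sits transmembrane (d = 0, factor 0), and a balanced f = 0.5 peptide
sits at the surface optimum (d = b, factor 1).  This reproduces, on a
toy landscape, the amphipathicity trade-off the design loop must
negotiate.  It is explicitly *not* a physical model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .peptides import Alphabet, EISENBERG, Peptide, as_peptide, net_charge

if TYPE_CHECKING:
    from .evolve import GAConfig

__all__ = [
    "SurrogateParams",
    "SurrogateBackend",
    "toy_ddf",
    "toy_dmem",
    "generate_dataset",
    "LabeledSequence",
]

DDF_FLOOR = -40.0  # kJ/mol clip keeping toy scores on the physical scale


@dataclass(frozen=True)
class LabeledSequence:
    """A (sequence, ddF) training or evaluation record (kJ/mol)."""

    peptide: Peptide
    ddf: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.ddf):
            raise ValueError("ddf must be finite")

    @property
    def sequence(self) -> str:
        return self.peptide.sequence


@dataclass(frozen=True)
class SurrogateParams:
    """Toy-oracle coefficients.

    kappa (kJ/mol per hydrophobicity unit) scales the hydrophobic reward,
    lam (kJ/mol per unit |charge|) the charge penalty, and noise_sd the
    Gaussian label noise of generated datasets.  Defaults put the label
    range on the realistic [-35, 0] kJ/mol sensing scale.
    """

    kappa: float = 1.5
    lam: float = 1.0
    noise_sd: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kappa < 0 or self.lam < 0 or self.noise_sd < 0:
            raise ValueError("kappa, lam and noise_sd must be non-negative")


def toy_ddf(seq: "Peptide | str", params: SurrogateParams = SurrogateParams()) -> float:
    """Deterministic toy sensing free energy in kJ/mol (noise-free)."""
    p = as_peptide(seq)
    h = EISENBERG.of(p)
    raw = -params.kappa * float(np.clip(h, 0.0, None).sum())
    raw += params.lam * abs(net_charge(p))
    return float(np.clip(raw, DDF_FLOOR, 0.0))


def hydrophobic_fraction(seq: "Peptide | str") -> float:
    """Fraction of residues with positive Eisenberg hydrophobicity."""
    h = EISENBERG.of(as_peptide(seq))
    return float((h > 0).mean())


def toy_dmem(seq: "Peptide | str", config: "GAConfig | None" = None) -> tuple[float, float]:
    """Toy insertion depths (tensionless, stretched) in nm: d = 2b(1 - f)."""
    from .evolve import GAConfig

    config = config or GAConfig()
    f = hydrophobic_fraction(seq)
    return (
        2.0 * config.b_tensionless * (1.0 - f),
        2.0 * config.b_stretched * (1.0 - f),
    )


class SurrogateBackend:
    """Drop-in fitness backend over the toy oracle (pure and seed-free)."""

    def __init__(
        self,
        params: SurrogateParams = SurrogateParams(),
        config: "GAConfig | None" = None,
    ):
        from .evolve import GAConfig

        self.params = params
        self.config = config or GAConfig()

    def evaluate(self, sequence: str) -> tuple[float, float, float]:
        d_t, d_s = toy_dmem(sequence, self.config)
        return toy_ddf(sequence, self.params), d_t, d_s


def generate_dataset(
    n: int,
    length_range: tuple[int, int] = (7, 24),
    params: SurrogateParams = SurrogateParams(),
    rng: np.random.Generator | int | None = None,
    alphabet: Alphabet = Alphabet.full20,
) -> list[LabeledSequence]:
    """Draw n unique random peptides labeled with noisy toy scores.

    Sequences are uniform over the alphabet with lengths uniform over
    ``length_range``; labels are toy_ddf plus Gaussian noise of sd
    ``params.noise_sd``.  Reproducible given a seed (``rng`` accepts an
    int, a Generator, or falls back to ``params.seed``).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    lo, hi = length_range
    if not 1 <= lo <= hi <= 24:
        raise ValueError("length_range must satisfy 1 <= lo <= hi <= 24")
    letters = list(alphabet.letters)
    space = sum(len(letters) ** L for L in range(lo, hi + 1))
    if n > space:
        raise ValueError(f"cannot draw {n} unique sequences from a space of {space}")
    if rng is None:
        rng = params.seed
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    seen: set[str] = set()
    records: list[LabeledSequence] = []
    while len(records) < n:
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=L))
        if seq in seen:
            continue
        seen.add(seq)
        label = toy_ddf(seq, params) + float(rng.normal(0.0, params.noise_sd))
        records.append(LabeledSequence(Peptide(seq, alphabet), label))
    return records


def dataset_to_frame(records: list[LabeledSequence]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence": [r.sequence for r in records],
            "ddf": [r.ddf for r in records],
            "length": [len(r.peptide) for r in records],
        }
    )
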