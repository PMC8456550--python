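"""Expected mutation load of error-prone PCR.

A mutagenic PCR round that turns I units of double-stranded template into O
units performs D = ln(O/I) / ln 2 template duplications; with a polymerase
error rate mu per nucleotide per duplication and an amplicon of L bp the
expected number of mutations per amplicon is Nmut = mu * D * L, summed over
rounds.  Values are returned at full precision; ``round1`` mimics the
one-decimal reporting convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DataError


@dataclass
class PcrRound:
    """dsDNA quantity before (input) and after (output) one mutagenic PCR,
    in any common unit (only the ratio enters)."""

    input_mass: float
    output_mass: float

    def __post_init__(self) -> None:
        if self.input_mass <= 0 or self.output_mass <= 0:
            raise DataError("masses must be positive")
        if self.output_mass < self.input_mass:
            raise DataError("output mass below input mass")


@dataclass
class MutagenesisModel:
    mu: float  # polymerase error rate per nucleotide per duplication
    L: int  # amplicon length in bp
    rounds: list[PcrRound] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mu < 0 or self.L <= 0:
            raise DataError("mu must be >= 0 and L positive")


def duplications(pcr_round: PcrRound) -> float:
    """D = ln(output/input) / ln 2."""
    return math.log(pcr_round.output_mass / pcr_round.input_mass) / math.log(2)


def expected_mutations(model: MutagenesisModel) -> float:
    """Nmut = mu * (sum of D over rounds) * L."""
    return model.mu * sum(duplications(r) for r in model.rounds) * model.L


def round1(value: float) -> float:
    """Round to one decimal, the reporting precision for D and Nmut."""
    return round(value, 1)
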