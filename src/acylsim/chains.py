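"""Acyl-chain and thioester nomenclature.

Chains use the standard ``Cn:m`` notation (n carbons, m double bonds),
e.g. ``C16:0`` (palmitoyl) or ``C18:1`` (cis-vaccenoyl).  Intermediates are
carried either on acyl carrier protein (ACP) or on coenzyme A (CoA).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

__all__ = ["AcylChain", "Carrier", "Thioester", "COA_CHAINS"]

_CHAIN_RE = re.compile(r"^C(\d+):(\d)$")

#: acyl-CoA species that occur in the model: the three fed fatty acids
#: (palmitate, palmitoleate, cis-vaccenate) after activation by FadD.
COA_CHAINS = ("C16:0", "C16:1", "C18:1")


@dataclass(frozen=True, order=True)
class AcylChain:
    """An acyl chain with an even carbon count and 0 or 1 double bonds."""

    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.carbons % 2 != 0 or not (4 <= self.carbons <= 18):
            raise ValueError(f"carbons must be even and in 4..18, got {self.carbons}")
        if self.double_bonds not in (0, 1):
            raise ValueError(f"double_bonds must be 0 or 1, got {self.double_bonds}")
        if self.double_bonds == 1 and self.carbons < 10:
            raise ValueError("unsaturated chains only exist for carbons >= 10")

    @property
    def label(self) -> str:
        return f"C{self.carbons}:{self.double_bonds}"

    @classmethod
    def parse(cls, label: str) -> "AcylChain":
        m = _CHAIN_RE.match(label)
        if m is None:
            raise ValueError(f"not a valid chain label: {label!r}")
        return cls(int(m.group(1)), int(m.group(2)))

    def __str__(self) -> str:
        return self.label


class Carrier(str, Enum):
    ACP = "ACP"
    CoA = "CoA"


@dataclass(frozen=True)
class Thioester:
    """An acyl chain esterified to a carrier (acyl-ACP or acyl-CoA)."""

    chain: AcylChain
    carrier: Carrier

    def __post_init__(self) -> None:
        if self.carrier is Carrier.CoA and self.chain.label not in COA_CHAINS:
            raise ValueError(
                f"acyl-CoA restricted to {COA_CHAINS}, got {self.chain.label}"
            )

    @property
    def species_id(self) -> str:
        return f"{self.chain.label}-{self.carrier.value}"

    @classmethod
    def parse(cls, species_id: str) -> "Thioester":
        try:
            chain_label, carrier = species_id.rsplit("-", 1)
            return cls(AcylChain.parse(chain_label), Carrier(carrier))
        except ValueError as exc:
            raise ValueError(f"not a thioester species id: {species_id!r}") from exc

    def __str__(self) -> str:
        return self.species_id
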