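"""Core record types shared across the toolkit.

Sequences are plain uppercase DNA strings. Aligned profiles project an
element onto the coordinate system of a reference consensus; every
reported position is 1-based inclusive, matching the convention used in
the retrotransposon literature ("position 228", "pos. 6").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

# per-position call states, encoded as uint8 in call vectors
A, C, G, T = 0, 1, 2, 3
DELETED = 4  # reference position absent from the element (internal gap)
MISSING = 5  # position not covered (truncation / N / IUPAC ambiguity)

BASES = "ACGT"
_STATE_CHARS = "ACGT-."
_CODE = {b: i for i, b in enumerate(_STATE_CHARS)}


def encode_states(s: str) -> np.ndarray:
    """Encode a call string (ACGT, '-' deleted, '.' missing) as uint8."""
    out = np.empty(len(s), dtype=np.uint8)
    for i, ch in enumerate(s.upper()):
        out[i] = _CODE.get(ch, MISSING)
    return out


def decode_states(v: np.ndarray) -> str:
    return "".join(_STATE_CHARS[int(x)] for x in v)


@dataclass(frozen=True)
class ElementRecord:
    """One genomic copy of a retrotransposon.

    ``species`` is a short tag (gg/pt/hs by default). Flanks, when
    present, are the genomic sequence immediately 5' and 3' of the
    element (including any target-site duplication).
    """

    id: str
    species: str
    sequence: str
    flank5: Optional[str] = None
    flank3: Optional[str] = None
    locus_label: Optional[str] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"element {self.id!r} has an empty sequence")


@dataclass
class ReferenceSet:
    """Named consensus/reference sequences (coordinates 1-based inclusive)."""

    references: dict[str, str]

    def __post_init__(self):
        for name, seq in self.references.items():
            if not seq:
                raise ValueError(f"reference {name!r} is empty")

    def __getitem__(self, name: str) -> str:
        return self.references[name]

    def __contains__(self, name: str) -> bool:
        return name in self.references


@dataclass(frozen=True)
class Substitution:
    position: int  # 1-based reference position
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.position}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class Deletion:
    start: int  # 1-based first deleted reference position
    length: int

    def __str__(self) -> str:
        return f"{self.start}:del{self.length}"


@dataclass(frozen=True)
class Insertion:
    anchor: int  # 1-based reference position after which the insert sits (0 = before position 1)
    sequence: str

    def __str__(self) -> str:
        return f"{self.anchor}:ins{self.sequence}"


VariantEvent = Substitution | Deletion | Insertion


@dataclass
class AlignedProfile:
    """An element expressed in reference coordinates.

    ``calls`` holds one state per reference position (A/C/G/T, deleted,
    missing). Insertions cannot be represented positionally and are kept
    in ``insertions``. Leading/trailing reference positions outside the
    aligned span are *missing*, never deleted.
    """

    element_id: str
    calls: np.ndarray  # uint8, length == len(reference)
    insertions: list[Insertion] = field(default_factory=list)
    identity: float = 1.0
    score: float = 0.0
    unalignable: bool = False
    reverse_complemented: bool = False

    @property
    def covered_fraction(self) -> float:
        return float(np.mean(self.calls != MISSING))

    def call_string(self) -> str:
        return decode_states(self.calls)
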