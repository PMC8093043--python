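"""881-bit substructure fingerprints for drug molecules.

Each drug is described by a binary vector whose bits flag the presence of
predefined chemical fragments (the PubChem substructure dictionary has 881
keys).  The toolkit consumes precomputed bit strings; matching fragments
against chemical structures is a separate concern — users who compute
fingerprints externally (e.g. from the PubChem system) only need to emit the
two-column TSV read here: ``drug_id<TAB><881-character 0/1 string>``, with
``#`` comment lines allowed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

FINGERPRINT_LENGTH = 881


class FingerprintParseError(ValueError):
    """Raised when a fingerprint table cannot be parsed."""


@dataclass
class Fingerprint:
    """A drug's binary substructure vector (length 881, entries in {0, 1})."""

    drug_id: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (FINGERPRINT_LENGTH,):
            raise ValueError(
                f"fingerprint must have exactly {FINGERPRINT_LENGTH} bits, "
                f"got shape {self.bits.shape}"
            )
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint entries must be 0 or 1")

    def to_bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)


def parse_fingerprint_table(text: str) -> dict[str, Fingerprint]:
    """Parse a fingerprint TSV into a ``drug_id -> Fingerprint`` map.

    Errors name the offending row: wrong bit-string length, characters
    outside {0, 1}, or duplicate drug ids.  An empty file gives an empty map.
    """
    table: dict[str, Fingerprint] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FingerprintParseError(
                f"line {lineno}: expected 'drug_id<TAB>bits', "
                f"got {len(parts)} fields"
            )
        drug_id, bitstring = parts
        if len(bitstring) != FINGERPRINT_LENGTH:
            raise FingerprintParseError(
                f"line {lineno} ({drug_id}): bit string has length "
                f"{len(bitstring)}, expected {FINGERPRINT_LENGTH}"
            )
        bad = set(bitstring) - {"0", "1"}
        if bad:
            raise FingerprintParseError(
                f"line {lineno} ({drug_id}): characters outside 0/1: "
                f"{sorted(bad)}"
            )
        if drug_id in table:
            raise FingerprintParseError(
                f"line {lineno}: duplicate drug id {drug_id!r}"
            )
        table[drug_id] = Fingerprint(
            drug_id=drug_id,
            bits=np.frombuffer(bitstring.encode(), dtype=np.uint8) - ord("0"),
        )
    return table


def serialize_fingerprint_table(table: Mapping[str, Fingerprint]) -> str:
    return "".join(
        f"{drug_id}\t{fp.to_bitstring()}\n" for drug_id, fp in table.items()
    )


def read_fingerprint_table(path: str | Path) -> dict[str, Fingerprint]:
    return parse_fingerprint_table(Path(path).read_text())


def write_fingerprint_table(
    table: Mapping[str, Fingerprint], path: str | Path
) -> None:
    Path(path).write_text(serialize_fingerprint_table(table))


def synthetic_fingerprint(
    seed: int, density: float = 0.1, drug_id: str = "synthetic"
) -> Fingerprint:
    """Random fingerprint with an expected set-bit fraction of ``density``.

    Deterministic for a fixed seed; each bit is an independent Bernoulli
    draw, so the realised density concentrates around ``density`` at the
    881-bit length.
    """
    if not 0 < density < 1:
        raise ValueError(f"density must be in (0, 1), got {density}")
    rng = np.random.default_rng(seed)
    bits = (rng.random(FINGERPRINT_LENGTH) < density).astype(np.uint8)
    return Fingerprint(drug_id=drug_id, bits=bits)
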