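"""Reading, writing and synthesising Position-Specific Scoring Matrices.

A PSSM is the per-position amino-acid substitution profile produced by
iterative database search (PSI-BLAST, ``-out_ascii_pssm``).  For a protein of
length L it is an L x 20 matrix whose entry (i, j) scores the mutation of
residue i into the j-th amino acid of a fixed 20-letter alphabet.  Only the
first 20 numeric columns of the ASCII file (the log-odds block) are kept; the
weighted-percentage block and trailing statistics are ignored.

Real profiles come from PSI-BLAST run against a sequence database (typical
settings: e-value 0.001, 3 iterations); this module only parses that output
and can fabricate statistically similar matrices for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

#: Amino-acid column order of the PSI-BLAST ASCII header, assumed when a file
#: carries no header line of its own.
PSIBLAST_ALPHABET: tuple[str, ...] = tuple("ARNDCQEGHILKMFPSTWYV")

#: Integer score range typical of log-odds PSSM entries, used by the
#: synthetic generator (inclusive bounds).
SYNTHETIC_SCORE_RANGE: tuple[int, int] = (-10, 12)


class PssmParseError(ValueError):
    """Raised when an ASCII PSSM file cannot be parsed."""


@dataclass
class Pssm:
    """An L x 20 evolutionary scoring profile for one protein.

    Parameters
    ----------
    protein_id
        Identifier of the protein (by convention the file stem).
    sequence
        Amino-acid string of length L, reconstructed from the residue column.
    scores
        ``(L, 20)`` float array of log-odds substitution scores.
    alphabet
        The 20-letter column order, taken from the file header when present.
    """

    protein_id: str
    sequence: str
    scores: np.ndarray
    alphabet: tuple[str, ...] = field(default=PSIBLAST_ALPHABET)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"scores must be L x 20, got shape {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValueError("PSSM must have at least one row")
        if len(self.sequence) != self.scores.shape[0]:
            raise ValueError(
                f"sequence length {len(self.sequence)} != "
                f"score rows {self.scores.shape[0]}"
            )
        if len(self.alphabet) != 20:
            raise ValueError("alphabet must contain exactly 20 letters")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


def _is_alphabet_header(tokens: list[str]) -> bool:
    return len(tokens) >= 20 and all(len(t) == 1 and t.isalpha() for t in tokens)


def parse_pssm(text: str, protein_id: str = "") -> Pssm:
    """Parse PSI-BLAST ``-out_ascii_pssm`` content into a :class:`Pssm`.

    Body rows look like ``<idx> <residue> <40 ints> <2 floats>``; only the
    first 20 numeric fields (log-odds) are retained.  Rows with fewer than 20
    numeric fields, or non-numeric score cells, raise :class:`PssmParseError`
    naming the offending line.
    """
    alphabet: tuple[str, ...] | None = None
    residues: list[str] = []
    rows: list[list[float]] = []

    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        # header with the amino-acid column order (20 letters, printed twice
        # in real files); keep the first 20
        if alphabet is None and not rows and _is_alphabet_header(tokens):
            alphabet = tuple(tokens[:20])
            continue
        # body rows start with the 1-based residue index
        try:
            idx = int(tokens[0])
        except ValueError:
            continue  # statistics / footer lines
        if len(tokens) < 2 or not (len(tokens[1]) == 1 and tokens[1].isalpha()):
            raise PssmParseError(
                f"line {lineno}: expected '<index> <residue> <scores...>', "
                f"got {line!r}"
            )
        fields = tokens[2:]
        if len(fields) < 20:
            raise PssmParseError(
                f"line {lineno}: row has {len(fields)} score fields, "
                f"expected at least 20: {line!r}"
            )
        try:
            scores = [float(f) for f in fields[:20]]
        except ValueError as exc:
            raise PssmParseError(
                f"line {lineno}: non-numeric score cell ({exc}): {line!r}"
            ) from None
        if idx != len(rows) + 1:
            raise PssmParseError(
                f"line {lineno}: residue index {idx} out of order "
                f"(expected {len(rows) + 1})"
            )
        residues.append(tokens[1].upper())
        rows.append(scores)

    if not rows:
        raise PssmParseError("no PSSM body rows found (empty body)")

    return Pssm(
        protein_id=protein_id,
        sequence="".join(residues),
        scores=np.asarray(rows, dtype=float),
        alphabet=alphabet if alphabet is not None else PSIBLAST_ALPHABET,
    )


def serialize_pssm(pssm: Pssm) -> str:
    """Render a :class:`Pssm` in the PSI-BLAST ASCII dialect.

    The log-odds block holds the real scores; the weighted-percentage block
    and the per-row information/weight columns are zero-filled, as they play
    no role downstream.  ``parse_pssm(serialize_pssm(p))`` recovers the
    sequence and scores exactly.
    """
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "   ".join(pssm.alphabet) + "   "
        + "   ".join(pssm.alphabet),
    ]
    integral = np.allclose(pssm.scores, np.round(pssm.scores))
    for i, (aa, row) in enumerate(zip(pssm.sequence, pssm.scores), start=1):
        if integral:
            cells = " ".join(f"{int(round(v)):>3d}" for v in row)
        else:
            cells = " ".join(f"{v:>6.2f}" for v in row)
        zeros = " ".join("  0" for _ in range(20))
        lines.append(f"{i:>5d} {aa}  {cells}  {zeros}  0.00 0.00")
    lines += ["", "                      K         Lambda",
              "Standard Ungapped    0.0000     0.0000",
              "Standard Gapped      0.0000     0.0000",
              "PSI Ungapped         0.0000     0.0000",
              "PSI Gapped           0.0000     0.0000", ""]
    return "\n".join(lines)


def read_pssm_file(path: str | Path) -> Pssm:
    """Read ``<protein_id>.pssm``; the file stem becomes the protein id."""
    path = Path(path)
    return parse_pssm(path.read_text(), protein_id=path.stem)


def read_pssm_dir(directory: str | Path) -> dict[str, Pssm]:
    """Read every ``*.pssm`` file in a directory, keyed by protein id."""
    directory = Path(directory)
    out: dict[str, Pssm] = {}
    for path in sorted(directory.glob("*.pssm")):
        out[path.stem] = read_pssm_file(path)
    return out


def write_pssm_dir(pssms: Mapping[str, Pssm], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for pid, pssm in pssms.items():
        (directory / f"{pid}.pssm").write_text(serialize_pssm(pssm))


def synthetic_pssm(
    length: int, seed: int, protein_id: str = "synthetic"
) -> Pssm:
    """Generate a deterministic random PSSM (test stand-in for PSI-BLAST).

    Scores are integers drawn uniformly from ``SYNTHETIC_SCORE_RANGE``; the
    sequence is a uniform random 20-letter amino-acid string.  Identical
    (length, seed) pairs give bit-identical matrices.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    lo, hi = SYNTHETIC_SCORE_RANGE
    scores = rng.integers(lo, hi + 1, size=(length, 20)).astype(float)
    sequence = "".join(rng.choice(list(PSIBLAST_ALPHABET), size=length))
    return Pssm(protein_id=protein_id, sequence=sequence, scores=scores)
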