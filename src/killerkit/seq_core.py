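"""Protein sequence records, FASTA I/O, and peptide mass arithmetic.

Everything downstream of this module (maturation annotation, mature-product
masses, homolog filtering) operates on :class:`ProteinRecord` objects.
Masses are *average* (not monoisotopic) masses, because the kilodalton
figures quoted for secreted killer toxins are on the average-mass scale:

    mass(seq) = sum of residue masses + 18.015 Da (one water)
                - 2.016 Da per disulfide bond (two hydrogens)
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, TextIO

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: mass assigned to 'X' under the lenient alphabet policy (mean residue mass)
MEAN_RESIDUE_MASS = 110.0


class FastaParseError(ValueError):
    """Malformed FASTA input; carries the offending 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class AlphabetError(ValueError):
    """A sequence letter outside the active alphabet policy."""


@dataclass(frozen=True)
class AlphabetPolicy:
    """How non-canonical letters (X/B/Z/U, digits, ...) are handled.

    ``strict`` (default) rejects anything outside the 20 canonical letters.
    The lenient policy accepts the letters in ``substitution_masses`` and
    assigns them the configured mass, with a logged warning.
    """

    strict: bool = True
    substitution_masses: dict[str, float] = field(
        default_factory=lambda: {"X": MEAN_RESIDUE_MASS}
    )

    def check(self, sequence: str, record_id: str = "<sequence>") -> None:
        for i, letter in enumerate(sequence, start=1):
            if letter in CANONICAL_RESIDUES:
                continue
            if not self.strict and letter in self.substitution_masses:
                continue
            raise AlphabetError(
                f"record {record_id!r}: disallowed character {letter!r} "
                f"at position {i}"
            )


STRICT = AlphabetPolicy(strict=True)
LENIENT = AlphabetPolicy(strict=False)


@dataclass
class ProteinRecord:
    """One identified amino-acid sequence.

    ``id`` is the first whitespace-delimited word of the FASTA header,
    ``description`` the remainder. The sequence is stored uppercase.
    """

    id: str
    description: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)

    def subsequence(self, start: int, end: int) -> str:
        """1-based inclusive slice, the coordinate convention used throughout."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise ValueError(
                f"span {start}-{end} outside sequence of length {len(self.sequence)}"
            )
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class ResidueMassTable:
    """Average residue masses (Da), shipped as versioned package data."""

    masses: dict[str, float]
    water: float = 18.015
    disulfide: float = 2.016
    version: str = "1.0"

    def __post_init__(self):
        missing = set(CANONICAL_RESIDUES) - set(self.masses)
        if missing:
            raise ValueError(f"mass table missing residues: {sorted(missing)}")
        if any(m <= 0 for m in self.masses.values()):
            raise ValueError("all residue masses must be positive")

    @classmethod
    def default(cls) -> "ResidueMassTable":
        payload = json.loads(
            resources.files("killerkit.data").joinpath("residue_masses.json").read_text()
        )
        return cls(
            masses=payload["masses"],
            water=payload["water"],
            disulfide=payload["disulfide"],
            version=payload["version"],
        )


_DEFAULT_TABLE: ResidueMassTable | None = None


def default_mass_table() -> ResidueMassTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = ResidueMassTable.default()
    return _DEFAULT_TABLE


def read_fasta(
    source: str | Path | TextIO,
    policy: AlphabetPolicy = STRICT,
) -> list[ProteinRecord]:
    """Parse FASTA text into :class:`ProteinRecord` objects.

    Sequences are uppercased and joined across lines; blank lines are
    ignored; terminal ``*`` stop characters are stripped with a warning.
    Sequence data before the first ``>`` header raises
    :class:`FastaParseError` with the line number.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()

    seen_header = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            seen_header = True
            break
        raise FastaParseError(
            "sequence data before the first '>' header", line_number=lineno
        )
    if not seen_header:
        raise FastaParseError("no '>' header found in input")

    records: list[ProteinRecord] = []
    for title, seq in SimpleFastaParser(io.StringIO(text)):
        parts = title.split(None, 1)
        rec_id = parts[0] if parts else ""
        desc = parts[1] if len(parts) > 1 else ""
        if not rec_id:
            raise FastaParseError("empty FASTA header")
        seq = seq.upper().strip()
        if seq.endswith("*"):
            logger.warning("record %r: stripping terminal stop character(s)", rec_id)
            seq = seq.rstrip("*")
        if not seq:
            raise FastaParseError(f"record {rec_id!r} has an empty sequence")
        policy.check(seq, rec_id)
        records.append(ProteinRecord(id=rec_id, description=desc, sequence=seq))
    return records


def write_fasta(
    records: Iterable[ProteinRecord],
    dest: str | Path | TextIO,
    width: int = 60,
) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""

    def _emit(handle: TextIO) -> None:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")

    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            _emit(fh)
    else:
        _emit(dest)


def molecular_mass(
    sequence: str,
    disulfide_count: int = 0,
    table: ResidueMassTable | None = None,
    policy: AlphabetPolicy = STRICT,
) -> float:
    """Average molecular mass of a peptide, in daltons.

    ``disulfide_count`` bonds each subtract 2.016 Da (loss of two hydrogens);
    at the 0.1 kDa precision used for printed toxin masses this correction
    is invisible, but it is applied exactly.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if disulfide_count < 0:
        raise ValueError("disulfide_count must be non-negative")
    table = table or default_mass_table()
    sequence = sequence.upper()
    policy.check(sequence)
    total = table.water - disulfide_count * table.disulfide
    for letter in sequence:
        if letter in table.masses:
            total += table.masses[letter]
        else:
            sub = policy.substitution_masses[letter]
            warnings.warn(
                f"non-canonical residue {letter!r}: using substitution mass {sub} Da",
                stacklevel=2,
            )
            total += sub
    return total


def combine_chain_masses(chain_masses: Iterable[float], disulfide_count: int = 0,
                         table: ResidueMassTable | None = None) -> float:
    """Total mass of a disulfide-linked multimer from per-chain masses (Da)."""
    table = table or default_mass_table()
    masses = list(chain_masses)
    if not masses:
        raise ValueError("no chain masses given")
    if disulfide_count < 0:
        raise ValueError("disulfide_count must be non-negative")
    return sum(masses) - disulfide_count * table.disulfide


def residue_composition(sequence: str) -> tuple[dict[str, int], dict[str, float]]:
    """Counts and fractions per residue letter; fractions sum to 1."""
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    counts: dict[str, int] = {}
    for letter in sequence:
        counts[letter] = counts.get(letter, 0) + 1
    n = len(sequence)
    fractions = {letter: c / n for letter, c in counts.items()}
    return counts, fractions
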