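"""Complete combinatorial peptide library enumeration and sequence I/O.

A combinatorial library over an alphabet ``A`` at length ``L`` is the full set
of ``|A|**L`` sequences, streamed in lexicographic order of the alphabet as
given.  The canonical 20-letter alphabet is ``ACDEFGHIKLMNPQRSTVWY``; the
complete tetrapeptide library over it has 160,000 members.  Positions are
1-based, N-terminus to C-terminus.
"""

from __future__ import annotations

import csv
import itertools
from collections.abc import Iterable, Iterator
from pathlib import Path

from .errors import InvalidSequenceError

CANONICAL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

SEQUENCE_FORMATS = ("fasta", "plain", "csv")


def validate_alphabet(letters: str) -> str:
    """Validate an alphabet string: non-empty, unique, canonical letters only."""
    if not letters:
        raise ValueError("alphabet must be non-empty")
    seen = set()
    for ch in letters:
        if ch not in CANONICAL_ALPHABET:
            raise ValueError(
                f"letter {ch!r} is not one of the 20 canonical residues "
                f"{CANONICAL_ALPHABET}"
            )
        if ch in seen:
            raise ValueError(f"duplicate letter {ch!r} in alphabet")
        seen.add(ch)
    return letters


def validate_sequence(sequence: str, alphabet: str = CANONICAL_ALPHABET) -> str:
    """Validate a peptide sequence, naming the offending letter and 1-based position."""
    if not sequence:
        raise ValueError("sequence must have length >= 1")
    for i, ch in enumerate(sequence, start=1):
        if ch not in alphabet:
            raise InvalidSequenceError(sequence, i, ch)
    return sequence


class PeptideLibrary:
    """A complete combinatorial peptide library, streamed lazily.

    Iterating a :class:`PeptideLibrary` yields each member sequence as a plain
    string, in lexicographic order of the alphabet's letter ordering.  Two
    enumerations produce byte-identical streams.

    Parameters
    ----------
    alphabet:
        Ordered string of unique one-letter residue codes.
    length:
        Peptide length (>= 1).
    """

    def __init__(self, alphabet: str = CANONICAL_ALPHABET, length: int = 4):
        self.alphabet = validate_alphabet(alphabet)
        if not isinstance(length, int) or length < 1:
            raise ValueError(f"length must be a positive integer, got {length!r}")
        self.length = length

    def __len__(self) -> int:
        return len(self.alphabet) ** self.length

    def __iter__(self) -> Iterator[str]:
        for combo in itertools.product(self.alphabet, repeat=self.length):
            yield "".join(combo)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PeptideLibrary(alphabet={self.alphabet!r}, length={self.length}, "
            f"size={len(self)})"
        )


def enumerate_library(alphabet: str = CANONICAL_ALPHABET, length: int = 4) -> PeptideLibrary:
    """Enumerate the complete combinatorial library over ``alphabet`` at ``length``."""
    return PeptideLibrary(alphabet, length)


def write_sequences(
    sequences: Iterable[str], path: str | Path, fmt: str = "fasta"
) -> int:
    """Write a sequence stream to ``path`` in one of the supported formats.

    FASTA records use the sequence itself as header id, so a round-trip read
    reproduces the stream exactly.  Returns the number of records written;
    writing an empty stream is an error.
    """
    if fmt not in SEQUENCE_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {SEQUENCE_FORMATS}")
    path = Path(path)
    n = 0
    with open(path, "w", newline="") as handle:
        if fmt == "csv":
            writer = csv.writer(handle)
            writer.writerow(["id", "sequence"])
        for seq in sequences:
            if fmt == "fasta":
                handle.write(f">{seq}\n{seq}\n")
            elif fmt == "plain":
                handle.write(f"{seq}\n")
            else:
                writer.writerow([seq, seq])
            n += 1
    if n == 0:
        path.unlink(missing_ok=True)
        raise ValueError("refusing to write an empty sequence stream")
    return n


def read_sequences(path: str | Path, fmt: str | None = None) -> list[str]:
    """Read sequences back from any format written by :func:`write_sequences`.

    When ``fmt`` is None it is inferred from the file suffix
    (``.fasta``/``.fa`` -> fasta, ``.csv`` -> csv, otherwise plain).
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".fasta": "fasta", ".fa": "fasta", ".csv": "csv"}.get(suffix, "plain")
    if fmt == "fasta":
        from Bio.SeqIO.FastaIO import SimpleFastaParser

        with open(path) as handle:
            return [seq for _title, seq in SimpleFastaParser(handle)]
    if fmt == "csv":
        with open(path, newline="") as handle:
            reader = csv.DictReader(handle)
            return [row["sequence"] for row in reader]
    with open(path) as handle:
        return [line.strip() for line in handle if line.strip()]


def residue_frequency(
    library: Iterable[str], position: int, length: int | None = None
) -> dict[str, float]:
    """Frequency of each residue at a 1-based ``position`` over a sequence stream.

    Frequencies sum to 1; for a complete combinatorial library every residue
    in the alphabet has frequency ``1/|alphabet|`` at every position.
    """
    if isinstance(library, PeptideLibrary):
        length = library.length
    if length is not None and not (1 <= position <= length):
        raise ValueError(f"position {position} out of range 1..{length}")
    counts: dict[str, int] = {}
    n = 0
    for seq in library:
        if not (1 <= position <= len(seq)):
            raise ValueError(
                f"position {position} out of range 1..{len(seq)} for {seq!r}"
            )
        ch = seq[position - 1]
        counts[ch] = counts.get(ch, 0) + 1
        n += 1
    if n == 0:
        raise ValueError("empty sequence stream")
    return {ch: c / n for ch, c in sorted(counts.items())}
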