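"""Reading, validating and writing protein sequences in FASTA format.

Sequences are normalised onto a closed 21-letter alphabet (the 20 standard
amino acids plus the ambiguity code ``X``): lowercase is upcased, the
ambiguity codes B, Z, J, U and O are mapped to ``X``, and gap characters
(``-``, ``.``) are deleted.  Downstream alignment and tokenisation rely on
this closed alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

logger = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(STANDARD_AA + "X")

#: non-standard one-letter codes collapsed onto the ambiguity symbol
_AMBIGUOUS_TO_X = str.maketrans({c: "X" for c in "BZJUO"})
_GAP_CHARS = "-."


class FastaParseError(ValueError):
    """Malformed FASTA input; message carries the offending line number."""


@dataclass(frozen=True)
class ProteinSequence:
    """An identified amino-acid sequence over the 21-letter alphabet.

    Parameters
    ----------
    id : str
        Non-empty identifier (first whitespace-delimited header token).
    residues : str
        Uppercase residues; every character in ``ACDEFGHIKLMNPQRSTVWY`` + ``X``.
    description : str, optional
        Full FASTA header (without ``>``), retained for provenance.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be non-empty")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: invalid residue(s) {sorted(bad)}; "
                f"allowed alphabet is {STANDARD_AA}X"
            )

    def __len__(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str) -> str:
    """Map raw sequence text onto the closed alphabet.

    Upcases, deletes gap characters ('-', '.'), and maps the non-standard
    codes B, Z, J, U, O to X.  Characters outside the alphabet after this
    treatment raise ``ValueError`` at ``ProteinSequence`` construction.
    """
    s = raw.upper()
    for g in _GAP_CHARS:
        s = s.replace(g, "")
    return s.translate(_AMBIGUOUS_TO_X)


@dataclass
class SequenceSet:
    """Ordered collection of :class:`ProteinSequence` with unique ids.

    Input order is preserved: the greedy redundancy-reduction step downstream
    is deterministic only because of it.
    """

    sequences: list[ProteinSequence] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.sequences:
            if s.id in seen:
                raise ValueError(f"duplicate sequence id {s.id!r}")
            seen.add(s.id)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[ProteinSequence]:
        return iter(self.sequences)

    def __getitem__(self, key: int | str) -> ProteinSequence:
        if isinstance(key, str):
            for s in self.sequences:
                if s.id == key:
                    return s
            raise KeyError(key)
        return self.sequences[key]

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]


def read_fasta(path: str | Path) -> SequenceSet:
    """Parse a FASTA file into a normalised :class:`SequenceSet`.

    Headers are split on whitespace; the first token becomes the id and the
    full header is kept as the description.  Bodies are normalised with
    :func:`normalize_residues`.  CRLF and LF line endings are both accepted.

    Raises
    ------
    FastaParseError
        If a sequence line precedes any header (the message names the line
        number), if a record has an empty body, or if two records share an id.
    """
    path = Path(path)
    records: list[ProteinSequence] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    seen: set[str] = set()

    def flush() -> None:
        if header is None:
            return
        residues = normalize_residues("".join(chunks))
        if not residues:
            raise FastaParseError(
                f"{path}: record {header.split()[0]!r} starting at line "
                f"{header_line} has an empty body"
            )
        sid = header.split()[0]
        if sid in seen:
            raise FastaParseError(f"{path}: duplicate sequence id {sid!r}")
        seen.add(sid)
        records.append(ProteinSequence(sid, residues, description=header))

    with open(path, encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"{path}: empty header at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}: sequence data before any '>' header at line {lineno}"
                    )
                chunks.append(line.strip())
    flush()

    if not records:
        logger.warning("FASTA file %s contained no records", path)
    return SequenceSet(records, source=str(path))


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 60) -> None:
    """Write sequences in FASTA, bodies wrapped at ``width`` columns.

    Round-trip contract: ``read_fasta(write_fasta(S)) == S`` for any
    already-normalised set ``S`` (ids and residues; descriptions are written
    back as-is when present).
    """
    if width < 1:
        raise ValueError("width must be positive")
    path = Path(path)
    with open(path, "w", encoding="ascii") as fh:
        for s in seqs:
            header = s.description if s.description else s.id
            if not header.split() or header.split()[0] != s.id:
                header = s.id
            fh.write(f">{header}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")
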