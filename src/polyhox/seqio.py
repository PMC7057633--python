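"""Sequence records, FASTA I/O and nucleotide utilities.

Every sequence in the package is stored uppercase over the IUPAC alphabet;
coordinates are 1-based inclusive throughout (the convention used when a
recombinant is reported as "positions 1-1026").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import ambiguous_dna_complement, ambiguous_dna_values

#: IUPAC nucleotide code -> set of concrete bases it denotes.
IUPAC_DNA: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}
DNA_ALPHABET = frozenset(IUPAC_DNA) | {"-"}
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO*-")

_COMPLEMENT = {k.upper(): v.upper() for k, v in ambiguous_dna_complement.items()}

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


class SequenceError(ValueError):
    """Raised for malformed sequences or illegal alphabet characters."""


class FastaParseError(SequenceError):
    """Raised when a FASTA file cannot be parsed; carries the line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _check_alphabet(sequence: str, moltype: str) -> str:
    seq = sequence.upper().replace(" ", "")
    if not seq:
        raise SequenceError("empty sequence")
    alphabet = DNA_ALPHABET if moltype == "dna" else PROTEIN_ALPHABET
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise SequenceError(f"illegal {moltype} character {ch!r} at position {i + 1}")
    return seq


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence (DNA by default), stored uppercase.

    ``id`` must be whitespace-free; ``description`` is free text.
    """

    id: str
    sequence: str
    description: str = ""
    moltype: str = "dna"

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceError(f"record id {self.id!r} empty or contains whitespace")
        if self.moltype not in ("dna", "protein"):
            raise SequenceError(f"unknown moltype {self.moltype!r}")
        object.__setattr__(self, "sequence", _check_alphabet(self.sequence, self.moltype))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CloneRecord:
    """One sequenced PCR clone from a species' library."""

    clone_id: str
    species_label: str
    sequence: str
    primer_set: str = ""

    MIN_LENGTH = 50  # shorter inserts are not credible homeobox fragments

    def __post_init__(self):
        seq = _check_alphabet(self.sequence, "dna")
        if len(seq) < self.MIN_LENGTH:
            raise SequenceError(
                f"clone {self.clone_id!r}: length {len(seq)} < {self.MIN_LENGTH}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class Primer:
    """A (possibly degenerate) PCR primer; whitespace in the input is stripped."""

    name: str
    iupac_sequence: str
    orientation: str  # "forward" | "reverse"

    def __post_init__(self):
        seq = _check_alphabet(self.iupac_sequence, "dna")
        if len(seq) < 15:
            raise SequenceError(f"primer {self.name!r}: length {len(seq)} < 15")
        if self.orientation not in ("forward", "reverse"):
            raise SequenceError(f"primer orientation {self.orientation!r} invalid")
        object.__setattr__(self, "iupac_sequence", seq)

    def __len__(self) -> int:
        return len(self.iupac_sequence)


def read_fasta(path: str | Path, moltype: str = "dna") -> list[SeqRecord]:
    """Parse a (possibly line-wrapped) FASTA file into `SeqRecord`s.

    Raises `FastaParseError` naming the offending line on malformed headers
    or illegal sequence characters.
    """
    records: list[SeqRecord] = []
    header: tuple[str, str] | None = None
    chunks: list[str] = []
    header_line = 0

    def flush():
        if header is None:
            return
        rid, desc = header
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"record {rid!r} has no sequence", header_line)
        try:
            records.append(SeqRecord(rid, seq, description=desc, moltype=moltype))
        except SequenceError as exc:
            raise FastaParseError(str(exc), header_line) from exc

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                body = line[1:].strip()
                if not body:
                    raise FastaParseError("empty FASTA header", lineno)
                parts = body.split(None, 1)
                header = (parts[0], parts[1] if len(parts) > 1 else "")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError("sequence data before first header", lineno)
                stripped = line.strip()
                alphabet = DNA_ALPHABET if moltype == "dna" else PROTEIN_ALPHABET
                for ch in stripped.upper():
                    if ch not in alphabet:
                        raise FastaParseError(
                            f"illegal {moltype} character {ch!r}", lineno
                        )
                chunks.append(stripped.upper())
        flush()
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA; inverse of `read_fasta`."""
    if width <= 0:
        raise ValueError("width must be positive")
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_clone_table(path: str | Path) -> list[CloneRecord]:
    """Read a clone TSV (columns clone_id, species_label, primer_set, sequence)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"clone_id", "species_label", "primer_set", "sequence"}
    missing = required - set(df.columns)
    if missing:
        raise SequenceError(f"clone table missing columns: {sorted(missing)}")
    return [
        CloneRecord(r.clone_id, r.species_label, r.sequence, primer_set=r.primer_set)
        for r in df.itertuples()
    ]


def write_clone_table(clones: Iterable[CloneRecord], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {"clone_id": c.clone_id, "species_label": c.species_label,
             "primer_set": c.primer_set, "sequence": c.sequence}
            for c in clones
        ]
    ).to_csv(path, sep="\t", index=False)


def iupac_match(pattern_base: str, concrete_base: str) -> bool:
    """True iff ``concrete_base`` (A/C/G/T) is in the set that the IUPAC
    code ``pattern_base`` denotes (e.g. M = {A,C})."""
    try:
        allowed = IUPAC_DNA[pattern_base.upper()]
    except KeyError:
        raise SequenceError(f"illegal IUPAC code {pattern_base!r}") from None
    cb = concrete_base.upper()
    if cb not in "ACGT":
        raise SequenceError(f"concrete base must be A/C/G/T, got {concrete_base!r}")
    return cb in allowed


def reverse_complement(sequence: str) -> str:
    """Reverse complement, degenerate codes included (R<->Y, M<->K, ...)."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(sequence.upper()))
    except KeyError as exc:
        raise SequenceError(f"illegal character {exc.args[0]!r}") from None


def translate(sequence: str, frame: int = 0) -> str:
    """Translate under the standard nuclear code.

    Stops render as ``*``; any codon containing a non-ACGT character
    translates to ``X``; a trailing partial codon is dropped.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    seq = sequence.upper()
    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append(_CODON_TABLE.get(codon, "X"))
    return "".join(out)
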