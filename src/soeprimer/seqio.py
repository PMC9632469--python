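"""FASTA input/output and elementary nucleotide-sequence operations.

Sequences are plain Python strings over the alphabet {A, C, G, T}, always
written 5'->3' on the strand they describe.  All coordinates in the package
are 0-based, half-open, and expressed on the sense strand of the chimera
(fragment 1 followed by fragment 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import SequenceError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: smallest fragment the designer accepts: a 30-nt end primer plus a 15-nt
#: junction part must never be forced to overlap ambiguously.
MIN_FRAGMENT_LEN = 45

#: below this length gel extraction of the intermediate band becomes
#: inefficient in practice; logged as a warning, never an error.
RECOMMENDED_MIN_LEN = 200


def clean_sequence(raw: str) -> str:
    """Uppercase ``raw`` and validate it as a plain A/C/G/T sequence.

    Ambiguity codes (N, IUPAC degenerate bases) are rejected: the
    nearest-neighbor Tm model and the primer enumeration are undefined on
    them.  The error names the first offending position (1-based, as primer
    positions are conventionally counted).
    """
    seq = raw.upper()
    if not seq:
        raise SequenceError("empty sequence")
    for pos, base in enumerate(seq):
        if base not in VALID_BASES:
            raise SequenceError(f"invalid base {base} at position {pos + 1}")
    return seq


def reverse_complement(s: str) -> str:
    """Watson-Crick complement of ``s``, reversed (5'->3' of the other strand)."""
    return str(Seq(s).reverse_complement())


def gc_percent(s: str) -> float:
    """G+C content as a percentage, rounded half-up to one decimal."""
    frac = 100 * (s.count("G") + s.count("C")) / len(s)
    return float(Decimal(frac).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FragmentRecord:
    """One input DNA fragment: FASTA identifier plus validated sequence."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise SequenceError("fragment name must be non-empty")
        object.__setattr__(self, "sequence", clean_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentPair:
    """The two fragments to be ligated, plus the derived chimera.

    ``chimera`` is fragment 1 followed by fragment 2 on the sense strand;
    ``junction`` is the 0-based index J of the first base of fragment 2,
    i.e. ``chimera[:J] == first.sequence`` and ``chimera[J:] == second.sequence``.
    """

    first: FragmentRecord
    second: FragmentRecord
    chimera: str = field(init=False)
    junction: int = field(init=False)

    def __post_init__(self) -> None:
        for frag, label in ((self.first, "first"), (self.second, "second")):
            if len(frag) < MIN_FRAGMENT_LEN:
                raise SequenceError(
                    f"{label} fragment {frag.name!r} is {len(frag)} nt; "
                    f"at least {MIN_FRAGMENT_LEN} nt are required for primer design"
                )
            if len(frag) < RECOMMENDED_MIN_LEN:
                logger.warning(
                    "fragment %s is %d nt (< %d nt); gel extraction of the "
                    "intermediate band may be inefficient",
                    frag.name, len(frag), RECOMMENDED_MIN_LEN,
                )
        object.__setattr__(self, "chimera", self.first.sequence + self.second.sequence)
        object.__setattr__(self, "junction", len(self.first.sequence))


def read_fragment(path: str | Path) -> FragmentRecord:
    """Read the first record of a FASTA file as a :class:`FragmentRecord`.

    The record name is the header token before the first whitespace.  If the
    file holds more than one record, the extras are ignored with a warning
    (the designer works on exactly one fragment per file).
    """
    path = Path(path)
    if not path.exists():
        raise SequenceError(f"FASTA file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    if len(records) > 1:
        logger.warning(
            "%s holds %d records; using the first (%s) and ignoring the rest",
            path, len(records), records[0].id,
        )
    rec = records[0]
    try:
        return FragmentRecord(name=rec.id, sequence=str(rec.seq))
    except SequenceError as exc:
        raise SequenceError(f"{path}: {exc}") from exc


def read_pair(path1: str | Path, path2: str | Path) -> FragmentPair:
    """Read two single-fragment FASTA files into a :class:`FragmentPair`."""
    return FragmentPair(first=read_fragment(path1), second=read_fragment(path2))


def write_fragment(record: FragmentRecord, path: str | Path) -> Path:
    """Write one fragment as FASTA, wrapped at 60 columns."""
    path = Path(path)
    seqrec = SeqRecord(Seq(record.sequence), id=record.name, description="")
    with open(path, "w") as handle:
        SeqIO.write([seqrec], handle, "fasta")
    return path
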