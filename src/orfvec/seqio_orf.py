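"""Transcript I/O and longest-ORF extraction.

Transcripts are spliced, single-stranded RNA given as DNA-alphabet FASTA.
Sequences are normalized at ingest to uppercase {A,C,G,T,N}: U becomes T and
every other IUPAC ambiguity code becomes N.  ORF search runs on the three
forward frames only; the longest complete ORF (ATG through the first in-frame
stop, stop included) is the presumed coding region.  When no complete ORF
exists a fallback ladder keeps every transcript featurizable: the longest
stop-free ATG-to-end stretch, else the whole sequence in frame 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
_CODON_TO_AA = dict(standard_dna_table.forward_table)

# U->T plus every IUPAC nucleotide ambiguity code -> N
_NORMALIZE = str.maketrans(
    {"U": "T", **{c: "N" for c in "RYSWKMBDHV"}}
)
_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class TranscriptRecord:
    """One input transcript: FASTA header token plus normalized DNA sequence."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class OrfResult:
    """The longest ORF of a transcript.

    Coordinates are 0-based half-open on the transcript.  ``has_start`` /
    ``has_stop`` encode ORF integrity; for a complete ORF the stop codon is
    included in ``nt_seq`` but excluded from ``protein``.
    """

    start: int
    end: int
    frame: int
    nt_seq: str
    has_start: bool
    has_stop: bool
    protein: str

    @property
    def length(self) -> int:
        return self.end - self.start


def normalize_sequence(raw: str, record_id: str = "<anonymous>") -> str:
    """Uppercase, map U->T and ambiguity codes->N; reject non-nucleotide chars."""
    seq = raw.upper().translate(_NORMALIZE)
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(
            f"record {record_id!r}: characters outside the IUPAC nucleotide "
            f"alphabet: {sorted(bad)}"
        )
    return seq


def as_records(transcripts) -> list[TranscriptRecord]:
    """Coerce strings / (id, seq) pairs / TranscriptRecords to records."""
    out = []
    for i, item in enumerate(transcripts):
        if isinstance(item, TranscriptRecord):
            out.append(item)
        elif isinstance(item, str):
            out.append(TranscriptRecord(f"seq_{i}", normalize_sequence(item)))
        else:
            ident, seq = item
            out.append(TranscriptRecord(str(ident), normalize_sequence(seq, ident)))
    return out


def read_fasta(path) -> list[TranscriptRecord]:
    """Read a multi-record FASTA into normalized transcript records.

    Records appear in file order.  Duplicate identifiers and empty sequences
    are rejected; an empty file yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    with path.open() as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA identifier: {rec.id!r}")
            seen.add(rec.id)
            seq = normalize_sequence(str(rec.seq), rec.id)
            if not seq:
                raise ValueError(f"record {rec.id!r}: empty sequence")
            records.append(TranscriptRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[TranscriptRecord], path, width: int = 60) -> None:
    """Write records as FASTA with 60-column wrapped sequence lines."""
    with Path(path).open("w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i : i + width] + "\n")


def translate(nt_seq: str) -> str:
    """Translate from position 0 with the standard genetic code.

    Stops at (and excludes) the first stop codon; any codon containing N
    becomes 'X'; a trailing partial codon is ignored.  Shorter than one codon
    translates to the empty protein.
    """
    aas = []
    for i in range(0, len(nt_seq) - 2, 3):
        codon = nt_seq[i : i + 3]
        if "N" in codon:
            aas.append("X")
        elif codon in STOP_CODONS:
            break
        else:
            aas.append(_CODON_TO_AA[codon])
    return "".join(aas)


def _frame_scan(seq: str, frame: int):
    """Yield complete ORFs (start, end) in one frame plus the open fallback.

    Complete ORF: first ATG after the previous stop, through that stop.  The
    fallback is the first ATG after the last stop with no stop before the end
    of the frame (trimmed to a whole number of codons), or None.
    """
    complete: list[tuple[int, int]] = []
    open_start = -1
    n = len(seq)
    for pos in range(frame, n - 2, 3):
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            if open_start >= 0:
                complete.append((open_start, pos + 3))
                open_start = -1
        elif open_start < 0 and codon == "ATG":
            open_start = pos
    fallback = None
    if open_start >= 0:
        end = open_start + 3 * ((n - open_start) // 3)
        fallback = (open_start, end)
    return complete, fallback


def find_longest_orf(seq: str) -> OrfResult:
    """Locate the longest forward-strand ORF of a normalized transcript.

    Among complete ORFs in the three forward frames, the longest wins; ties
    break on smaller start, then smaller frame.  With no complete ORF, the
    longest stop-free ATG-to-end stretch is returned (``has_stop=False``);
    with no ATG at all, the whole sequence in frame 0 (``has_start=False``).
    """
    if not seq:
        raise ValueError("cannot locate an ORF in an empty sequence")
    complete_all: list[tuple[int, int, int]] = []
    fallbacks: list[tuple[int, int, int]] = []
    for frame in range(3):
        complete, fallback = _frame_scan(seq, frame)
        complete_all.extend((s, e, frame) for s, e in complete)
        if fallback is not None:
            fallbacks.append((*fallback, frame))

    def key(span):
        s, e, f = span
        return (-(e - s), s, f)

    if complete_all:
        s, e, f = min(complete_all, key=key)
        nt = seq[s:e]
        return OrfResult(s, e, f, nt, True, True, translate(nt))
    if fallbacks:
        s, e, f = min(fallbacks, key=key)
        nt = seq[s:e]
        return OrfResult(s, e, f, nt, True, False, translate(nt))
    return OrfResult(0, len(seq), 0, seq, False, False, translate(seq))
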