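"""FASTA/BED input-output, window validation and 41-bp promoter fragmentation.

The prediction unit throughout the package is a 41-bp window.  Promoters are
tiled into consecutive, non-overlapping 41-bp windows starting at base 1, so
window *w* covers bases ``(w-1)*41 + 1 .. w*41`` (1-based, inclusive).  This
tiling is what makes printed promoter site ranges such as 165-205, 1026-1066
and 1313-1353 (windows 5, 26 and 33 of a 1.5-kb upstream region) reproducible.
BED output converts to the usual 0-based half-open convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from .promoscan import SiteMap

WINDOW_WIDTH = 41
UNAMBIGUOUS = frozenset("ACGT")
#: IUPAC ambiguity codes; normalised to N on read (all are "ambiguous bases").
IUPAC_AMBIGUOUS = frozenset("NRYSWKMBDHV")


class FastaFormatError(ValueError):
    """Raised for malformed multi-FASTA input (duplicates, bad alphabet...)."""


class WindowValidationError(ValueError):
    """Raised when a record violates the 41-nt / unambiguous-base contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}, as read from FASTA.

    ``description`` keeps the remainder of the header line; the promoter
    scanner looks for a ``species=<tag>`` token there.
    """

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise FastaFormatError("record with empty accession")
        bad = set(self.sequence) - UNAMBIGUOUS - {"N"}
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise FastaFormatError(
                f"{self.accession}: invalid character {self.sequence[pos]!r} "
                f"at position {pos + 1}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SequenceWindow:
    """A 41-bp fragment with provenance coordinates in its parent sequence.

    Coordinates are 1-based inclusive and follow the consecutive tiling
    ``start = (window_index - 1) * 41 + 1``.
    """

    accession: str
    window_index: int
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        width = len(self.sequence)
        if self.end - self.start + 1 != width:
            raise WindowValidationError(
                f"{self.accession}: span {self.start}-{self.end} does not "
                f"match sequence length {width}"
            )
        if self.window_index < 1:
            raise WindowValidationError("window_index must be >= 1")
        if self.start != (self.window_index - 1) * width + 1:
            raise WindowValidationError(
                f"{self.accession}: start {self.start} inconsistent with "
                f"window_index {self.window_index}"
            )
        bad = set(self.sequence) - UNAMBIGUOUS - {"N"}
        if bad:
            raise WindowValidationError(
                f"{self.accession}: invalid character in window: {sorted(bad)}"
            )


def _normalise(seq: str, accession: str) -> str:
    """Uppercase and map IUPAC ambiguity codes to N; reject U / non-IUPAC."""
    seq = seq.upper()
    out = []
    for i, c in enumerate(seq):
        if c in UNAMBIGUOUS:
            out.append(c)
        elif c in IUPAC_AMBIGUOUS:
            out.append("N")
        else:
            kind = "RNA base" if c == "U" else "non-IUPAC character"
            raise FastaFormatError(
                f"{accession}: {kind} {c!r} at position {i + 1}"
            )
    return "".join(out)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into validated records.

    Sequences are uppercased; IUPAC ambiguity codes become N.  Duplicate
    accessions, empty files and non-IUPAC characters are hard errors: the
    downstream predictor requires every accession to be unique.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate accession {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(rec.id, _normalise(str(rec.seq), rec.id), desc)
        )
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    """Write records back to multi-FASTA, preserving order and headers."""
    out = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    ]
    SeqIO.write(out, str(path), "fasta")


def validate_window(record: SequenceRecord | SequenceWindow | str,
                    accession: str = "window") -> SequenceWindow:
    """Enforce the predictor's input contract: exactly 41 nt, no ambiguity.

    Returns a :class:`SequenceWindow` spanning 1-41 (window_index 1) so that
    ad-hoc 41-mers can be fed straight to the encoder.
    """
    if isinstance(record, SequenceWindow):
        seq, acc = record.sequence, record.accession
    elif isinstance(record, SequenceRecord):
        seq, acc = record.sequence, record.accession
    else:
        seq, acc = str(record).upper(), accession
    if len(seq) != WINDOW_WIDTH:
        raise WindowValidationError(
            f"{acc}: sequence length must be exactly {WINDOW_WIDTH} nt, "
            f"got {len(seq)}"
        )
    for i, c in enumerate(seq):
        if c not in UNAMBIGUOUS:
            raise WindowValidationError(
                f"{acc}: ambiguous base {c!r} at position {i + 1}"
            )
    if isinstance(record, SequenceWindow):
        return record
    return SequenceWindow(acc, 1, 1, WINDOW_WIDTH, seq)


def split_windows(record: SequenceRecord, drop_ambiguous: bool = True,
                  excise: bool = False,
                  width: int = WINDOW_WIDTH) -> list[SequenceWindow]:
    """Fragment a sequence into consecutive non-overlapping windows.

    Tiling starts at base 1; a trailing remainder shorter than ``width`` is
    discarded (the encoders are defined only for full windows).  With
    ``drop_ambiguous`` (default), windows containing N are removed but the
    coordinates of the surviving windows are untouched, which is what site
    mapping needs.  ``excise`` instead deletes N characters *before* tiling
    (mirroring a trim-then-split pre-processing pipeline) at the cost of
    coordinate fidelity; the two options are mutually exclusive.

    A record shorter than ``width`` yields an empty list with a warning.
    """
    seq = record.sequence
    if excise:
        if drop_ambiguous:
            raise ValueError("drop_ambiguous and excise are mutually exclusive")
        seq = seq.replace("N", "")
    if len(seq) < width:
        warnings.warn(
            f"{record.accession}: length {len(seq)} < window width {width}; "
            "no windows produced",
            stacklevel=2,
        )
        return []
    windows = []
    for w in range(len(seq) // width):
        sub = seq[w * width:(w + 1) * width]
        if drop_ambiguous and "N" in sub:
            continue
        windows.append(
            SequenceWindow(record.accession, w + 1, w * width + 1,
                           (w + 1) * width, sub)
        )
    return windows


def write_bed(sites: "SiteMap", path) -> None:
    """Write a site map as BED6 (0-based half-open), sorted by (chrom, start).

    ``name`` is ``accession:window_index`` and ``score`` is the ensemble vote
    score scaled to the BED 0-1000 range.
    """
    entries = sorted(sites.entries, key=lambda e: (e.accession, e.start))
    with open(path, "w") as fh:
        fh.write("# BED6: predicted 6mA windows, promoter-relative\n")
        for e in entries:
            fh.write(
                f"{e.accession}\t{e.start - 1}\t{e.end}\t"
                f"{e.accession}:{e.window_index}\t"
                f"{int(round(1000 * e.score))}\t+\n"
            )
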