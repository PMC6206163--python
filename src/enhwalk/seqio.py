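"""Sequence input/output and normalization.

Reads multi-record FASTA, extracts genomic intervals from an indexed
reference, and enforces the length/ambiguity policy used throughout the
pipeline: sequences are uppercased, truncated to a maximum length
(keeping the 5' prefix), stripped of ambiguous bases up to a cap, and
rejected when too short for the walk statistics to be defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional

from pyfaidx import Fasta

from .errors import FastaParseError, IntervalBoundsError, SequenceRejectedError

logger = logging.getLogger(__name__)

#: Default maximum sequence length; longer sequences keep their 5' prefix.
MAX_LEN = 1500

#: Below this length the lag-300 autocorrelation is undefined (needs lag + 2
#: points), so sequences are rejected outright.
MIN_LEN = 302

#: Sequences shorter than this are accepted but flagged: long-lag statistics
#: on them are dominated by edge effects.
WARN_LEN = 400

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class GenomeInterval:
    """A BED-convention region: 0-based, half-open, optional strand."""

    chrom: str
    start: int
    end: int
    strand: Optional[str] = None

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SequenceRecord:
    """An identified DNA sequence with optional genomic provenance and label."""

    id: str
    bases: str
    source: Optional[GenomeInterval] = None
    label: Optional[str] = None  # "positive" | "negative" | None

    def __len__(self) -> int:
        return len(self.bases)


def reverse_complement(bases: str) -> str:
    return bases.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a (possibly wrapped) multi-record FASTA file.

    Sequences are uppercased; record order is preserved. Malformed headers
    and empty records raise :class:`FastaParseError` naming the line.
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"record {header!r} has an empty sequence", header_line)
        records.append(SequenceRecord(id=header, bases=seq.upper()))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FastaParseError("empty FASTA header", lineno)
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError("sequence data before first header", lineno)
                chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (60 columns by default)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")


def extract_intervals(genome: str | Path, intervals: Iterable[GenomeInterval]) -> list[SequenceRecord]:
    """Extract interval sequences from an indexed reference FASTA.

    Minus-strand intervals are reverse-complemented. Out-of-bounds
    intervals and unknown chromosomes raise :class:`IntervalBoundsError`.
    """
    fa = Fasta(str(genome), as_raw=True, sequence_always_upper=True)
    out: list[SequenceRecord] = []
    for iv in intervals:
        if iv.chrom not in fa:
            raise IntervalBoundsError(f"chromosome {iv.chrom!r} absent from {genome}")
        chrom_len = len(fa[iv.chrom])
        if iv.end > chrom_len:
            raise IntervalBoundsError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length {chrom_len}"
            )
        seq = str(fa[iv.chrom][iv.start : iv.end])
        if iv.strand == "-":
            seq = reverse_complement(seq)
        rec_id = f"{iv.chrom}:{iv.start}-{iv.end}" + (f"({iv.strand})" if iv.strand else "")
        out.append(SequenceRecord(id=rec_id, bases=seq, source=iv))
    return out


def read_bed(path: str | Path) -> list[GenomeInterval]:
    """Read BED3/BED6 into intervals (columns beyond strand are ignored)."""
    intervals: list[GenomeInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FastaParseError("BED line has fewer than 3 columns", lineno)
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else None
            intervals.append(GenomeInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return intervals


def write_bed(intervals: Iterable[GenomeInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.strand:
                cols += [".", "0", iv.strand]
            fh.write("\t".join(cols) + "\n")


def prepare_sequence(
    rec: SequenceRecord,
    max_len: int = MAX_LEN,
    ambiguous_policy: str = "strip",
    max_ambiguous_frac: float = 0.05,
    min_len: int = MIN_LEN,
) -> SequenceRecord:
    """Normalize a record for feature extraction.

    Uppercases; truncates to ``max_len`` keeping the 5' prefix; removes
    ambiguous (non-ACGT) characters under the ``strip`` policy as long as
    their fraction is at most ``max_ambiguous_frac``, otherwise rejects.
    Idempotent: preparing a prepared record is the identity.
    """
    if not rec.bases:
        raise SequenceRejectedError("empty sequence", rec.id)
    bases = rec.bases.upper()[:max_len]
    n_ambig = sum(1 for b in bases if b not in _VALID)
    if n_ambig:
        frac = n_ambig / len(bases)
        if ambiguous_policy == "reject" or frac > max_ambiguous_frac:
            raise SequenceRejectedError(
                f"{n_ambig}/{len(bases)} ambiguous bases (fraction {frac:.3f} "
                f"> {max_ambiguous_frac} or policy=reject)",
                rec.id,
            )
        bases = "".join(b for b in bases if b in _VALID)
    if len(bases) < min_len:
        raise SequenceRejectedError(
            f"length {len(bases)} below minimum {min_len} (long-lag statistics undefined)",
            rec.id,
        )
    if len(bases) < WARN_LEN:
        logger.warning(
            "sequence %s has length %d < %d; long-lag autocorrelations will be noisy",
            rec.id, len(bases), WARN_LEN,
        )
    return replace(rec, bases=bases)
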