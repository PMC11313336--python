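"""Sequence and interval I/O: FASTA parsing, N-gap detection, flank extraction.

Scaffold gaps are maximal runs of N/n characters; all coordinates are
0-based half-open (BED convention). Flanks are the gap-adjacent sequence
used downstream as decoding context and as evaluation anchors; they are
truncated at sequence ends and at the first interior N so that they never
span a neighbouring gap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence, Union

from Bio import SeqIO

PathLike = Union[str, Path]

_VALID = set("ACGTN")
_GAP_RE = re.compile(r"N+")

DEFAULT_FLANK_LEN = 500  # bases of context kept on each side of a gap


class FastaParseError(ValueError):
    """Raised when a FASTA file violates the {A,C,G,T,N} alphabet contract."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence over {A,C,G,T,N}, upper-case."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - _VALID
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class GapRecord:
    """One maximal N-run on one scaffold, half-open coordinates."""

    scaffold_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid gap interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FlankPair:
    """Gap-adjacent sequence on each side, N-free, possibly truncated."""

    gap: GapRecord
    left: str
    right: str


def read_fasta(path: PathLike) -> List[GenomeSequence]:
    """Read a (multi-)FASTA file, normalising to upper case.

    Rejects empty files and any character outside {A,C,G,T,N}; the error
    names the offending record and line.
    """
    path = Path(path)
    records: List[GenomeSequence] = []
    # SeqIO tolerates arbitrary letters, so alphabet checking is done here
    # with line bookkeeping for a useful error message.
    line_no = 0
    header_line = 0
    with open(path) as fh:
        current_id = None
        chunks: List[str] = []
        for raw in fh:
            line_no += 1
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current_id is not None:
                    records.append(_finish_record(current_id, chunks, header_line))
                current_id = line[1:].split()[0] if len(line) > 1 else ""
                if not current_id:
                    raise FastaParseError(f"{path}:{line_no}: empty FASTA header")
                header_line = line_no
                chunks = []
            else:
                if current_id is None:
                    raise FastaParseError(
                        f"{path}:{line_no}: sequence data before first header"
                    )
                up = line.upper()
                bad = set(up) - _VALID
                if bad:
                    raise FastaParseError(
                        f"{path}:{line_no}: invalid character(s) {sorted(bad)} "
                        f"in record {current_id!r}"
                    )
                chunks.append(up)
        if current_id is None:
            raise FastaParseError(f"{path}: empty FASTA file")
        records.append(_finish_record(current_id, chunks, header_line))
    return records


def _finish_record(rec_id: str, chunks: List[str], header_line: int) -> GenomeSequence:
    seq = "".join(chunks)
    if not seq:
        raise FastaParseError(f"record {rec_id!r} (header at line {header_line}) has no sequence")
    return GenomeSequence(id=rec_id, seq=seq)


def write_fasta(records: Iterable[GenomeSequence], path: PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_reads(path: PathLike) -> List[str]:
    """Read sequences from FASTA or FASTQ (auto-detected; qualities ignored)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)]


def find_gaps(scaffold: GenomeSequence, min_len: int = 1) -> List[GapRecord]:
    """Locate maximal N-runs of length >= min_len, sorted by start."""
    return [
        GapRecord(scaffold.id, m.start(), m.end())
        for m in _GAP_RE.finditer(scaffold.seq)
        if m.end() - m.start() >= min_len
    ]


def write_bed(gaps: Sequence[GapRecord], path: PathLike) -> None:
    """Write gaps as 3-column BED (0-based half-open), input order."""
    with open(path, "w") as fh:
        for g in gaps:
            fh.write(f"{g.scaffold_id}\t{g.start}\t{g.end}\n")


def read_bed(path: PathLike) -> List[GapRecord]:
    gaps: List[GapRecord] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: expected >= 3 BED columns")
            gaps.append(GapRecord(fields[0], int(fields[1]), int(fields[2])))
    return gaps


def extract_flanks(scaffold: GenomeSequence, gap: GapRecord, flank_len: int = DEFAULT_FLANK_LEN) -> FlankPair:
    """Extract up to flank_len N-free bases on each side of the gap.

    The left flank ends at gap.start, the right flank begins at gap.end.
    Both are truncated at the sequence boundary and at the first interior N
    (so a flank never reaches across a neighbouring gap).
    """
    if flank_len < 1:
        raise ValueError("flank_len must be >= 1")
    if scaffold.id != gap.scaffold_id or gap.end > len(scaffold):
        raise ValueError(f"gap {gap} does not lie on scaffold {scaffold.id!r}")
    seq = scaffold.seq
    left_region = seq[max(0, gap.start - flank_len) : gap.start]
    n_pos = left_region.rfind("N")
    left = left_region[n_pos + 1 :] if n_pos != -1 else left_region
    right_region = seq[gap.end : gap.end + flank_len]
    n_pos = right_region.find("N")
    right = right_region[:n_pos] if n_pos != -1 else right_region
    return FlankPair(gap=gap, left=left, right=right)
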