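"""Annotated mRNA transcripts and coordinate/region conventions.

All coordinates at module interfaces are 1-based and inclusive, measured
from the transcript 5' end.  Sequences are stored as uppercase DNA
(``U`` is normalized to ``T`` on read); guide strands are converted back
to RNA only when reports are written.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class Region(str, enum.Enum):
    """Functional region of an mRNA: 5' UTR, coding sequence, or 3' UTR."""

    FIVE_UTR = "FIVE_UTR"
    CDS = "CDS"
    THREE_UTR = "THREE_UTR"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and convert RNA ``U`` to DNA ``T``."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a DNA string (alphabet ACGT)."""
    seq = normalize_sequence(seq)
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"non-ACGT symbols in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """DNA -> RNA representation (T -> U) for report output."""
    return seq.upper().replace("T", "U")


@dataclass
class Transcript:
    """An mRNA with CDS boundaries and optional exon structure.

    ``cds_start``/``cds_end`` are 1-based inclusive: the first base of the
    start codon and the last base of the stop codon.  ``exon_lengths``
    partitions the transcript in 5'->3' order when provided.
    """

    id: str
    symbol: str
    sequence: str
    cds_start: int
    cds_end: int
    exon_lengths: list[int] | None = field(default=None)

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        bad = set(self.sequence) - _DNA
        if bad:
            raise ValueError(
                f"transcript {self.id}: non-ACGT symbols {sorted(bad)}"
            )
        n = len(self.sequence)
        if not (1 <= self.cds_start < self.cds_end <= n):
            raise ValueError(
                f"transcript {self.id}: CDS [{self.cds_start}, {self.cds_end}] "
                f"violates 1 <= start < end <= {n}"
            )
        if self.exon_lengths is not None:
            if any(e <= 0 for e in self.exon_lengths):
                raise ValueError(f"transcript {self.id}: non-positive exon length")
            if sum(self.exon_lengths) != n:
                raise ValueError(
                    f"transcript {self.id}: exon lengths sum to "
                    f"{sum(self.exon_lengths)}, sequence length is {n}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    def window(self, start: int, length: int) -> str:
        """Subsequence at 1-based inclusive ``start`` of given ``length``."""
        if start < 1 or start + length - 1 > len(self):
            raise ValueError(
                f"window [{start}, {start + length - 1}] out of bounds for "
                f"transcript {self.id} of length {len(self)}"
            )
        return self.sequence[start - 1 : start - 1 + length]


def read_transcripts(fasta_path: str | Path, annotation_path: str | Path) -> list[Transcript]:
    """Read a multi-FASTA plus a TSV annotation table into Transcripts.

    The annotation table must have columns ``id``, ``symbol``, ``cds_start``,
    ``cds_end`` and optionally ``exon_lengths`` (comma-separated).  Every
    FASTA record must have a matching annotation row; validation errors are
    hard failures naming the offending record.
    """
    annot = pd.read_csv(annotation_path, sep="\t", comment="#", dtype={"id": str})
    required = {"id", "symbol", "cds_start", "cds_end"}
    missing_cols = required - set(annot.columns)
    if missing_cols:
        raise ValueError(f"annotation table missing columns: {sorted(missing_cols)}")
    rows = annot.set_index("id")

    transcripts: list[Transcript] = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id not in rows.index:
            raise ValueError(f"no annotation for FASTA record {record.id!r}")
        row = rows.loc[record.id]
        exons = None
        if "exon_lengths" in rows.columns and pd.notna(row["exon_lengths"]):
            exons = [int(x) for x in str(row["exon_lengths"]).split(",") if x]
        transcripts.append(
            Transcript(
                id=record.id,
                symbol=str(row["symbol"]),
                sequence=str(record.seq),
                cds_start=int(row["cds_start"]),
                cds_end=int(row["cds_end"]),
                exon_lengths=exons,
            )
        )
    return transcripts


def region_of(transcript: Transcript, start: int, site_len: int) -> Region:
    """Region label for a target site: the region holding the majority of
    its bases, ties broken toward the more 3' region.

    The regions partition the transcript: 5'UTR = [1, cds_start-1],
    CDS = [cds_start, cds_end], 3'UTR = [cds_end+1, length].
    """
    end = start + site_len - 1
    if start < 1 or end > len(transcript):
        raise ValueError(
            f"site [{start}, {end}] out of bounds for transcript "
            f"{transcript.id} of length {len(transcript)}"
        )

    def overlap(lo: int, hi: int) -> int:
        return max(0, min(end, hi) - max(start, lo) + 1)

    counts = [
        (Region.FIVE_UTR, overlap(1, transcript.cds_start - 1)),
        (Region.CDS, overlap(transcript.cds_start, transcript.cds_end)),
        (Region.THREE_UTR, overlap(transcript.cds_end + 1, len(transcript))),
    ]
    # max() keeps the last of tied items only with a tweak; scan explicitly,
    # preferring the later (more 3') region on ties.
    best_region, best_n = counts[0]
    for region, n in counts[1:]:
        if n >= best_n:
            best_region, best_n = region, n
    return best_region


def exon_context(
    transcript: Transcript, start: int, site_len: int
) -> tuple[int | None, int | None]:
    """Length of the exon containing the site's first base, and whether the
    site crosses an exon-exon junction (1) or not (0).

    Returns ``(None, None)`` when the transcript has no exon annotation.
    """
    if transcript.exon_lengths is None:
        logger.info("transcript %s has no exon annotation; exon context missing",
                    transcript.id)
        return (None, None)
    end = start + site_len - 1
    if start < 1 or end > len(transcript):
        raise ValueError(f"site [{start}, {end}] out of bounds")
    boundaries = []  # cumulative 1-based end of each exon
    acc = 0
    for length in transcript.exon_lengths:
        acc += length
        boundaries.append(acc)
    exon_idx = next(i for i, b in enumerate(boundaries) if start <= b)
    target_exon_length = transcript.exon_lengths[exon_idx]
    spans = int(end > boundaries[exon_idx])
    return (target_exon_length, spans)


def write_transcripts(
    transcripts: list[Transcript], fasta_path: str | Path, annotation_path: str | Path
) -> None:
    """Write transcripts as multi-FASTA plus companion TSV annotation."""
    with open(fasta_path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id} {t.symbol}\n")
            for i in range(0, len(t.sequence), 70):
                fh.write(t.sequence[i : i + 70] + "\n")
    rows = []
    for t in transcripts:
        rows.append(
            {
                "id": t.id,
                "symbol": t.symbol,
                "cds_start": t.cds_start,
                "cds_end": t.cds_end,
                "exon_lengths": ",".join(map(str, t.exon_lengths))
                if t.exon_lengths
                else "",
            }
        )
    pd.DataFrame(rows).to_csv(annotation_path, sep="\t", index=False)
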