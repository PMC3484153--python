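"""Approximate matching of siRNA sequences against a transcript databank,
and miRNA-style seed-complement profiling of 3' UTRs.

The core matcher is a bit-parallel shift-add search (Baeza-Yates/Gonnet
counting variant, as used in agrep-style tools): one saturating mismatch
counter per pattern position, packed side by side in a single integer, all
updated per text character with one shift and one add.  Every alignment
with Hamming distance <= k is reported with its exact mismatch positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .design import GUIDE_LEN
from .transcripts import Transcript, normalize_sequence, reverse_complement

MAX_PATTERN_LEN = 32

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class MismatchHit:
    """One alignment of a pattern inside a subject sequence.

    ``subject_start`` is 1-based; ``mismatch_positions`` are 1-based
    positions on the pattern (5'->3')."""

    pattern_id: str
    subject_id: str
    subject_start: int
    mismatch_count: int
    mismatch_positions: tuple[int, ...]


def shift_add_search(
    pattern: str,
    text: str,
    k: int,
    pattern_id: str = "pattern",
    subject_id: str = "subject",
) -> list[MismatchHit]:
    """All alignments of ``pattern`` in ``text`` with <= ``k`` mismatches.

    Counters use B = ceil(log2(k+1)) + 1 bits each; a counter whose high
    (saturation) bit fires is zeroed and remembered in a sticky overflow
    register, so counts never carry into the neighbouring counter.  An
    alignment ending at text position j is a hit iff the full-pattern
    counter never saturated on that diagonal and its final value is <= k.
    """
    pattern = normalize_sequence(pattern)
    text = normalize_sequence(text)
    m = len(pattern)
    if not 1 <= m <= MAX_PATTERN_LEN:
        raise ValueError(
            f"pattern length {m} outside [1, {MAX_PATTERN_LEN}]; split the "
            "pattern and combine chunked searches for longer queries"
        )
    if k < 0:
        raise ValueError("k must be >= 0")
    n = len(text)
    if n < m:
        return []

    b = max(k + 1, 1).bit_length() + 1  # counter width incl. saturation bit
    ones = sum(1 << (b * i) for i in range(m))  # bit 0 of every counter
    high = ones << (b - 1)  # saturation bit of every counter
    mask = (1 << (b * m)) - 1
    full = (1 << b) - 1

    # T[c]: counter-aligned mask with 1 where pattern position != c.
    table = {}
    for c in "ACGT":
        t = 0
        for i, p in enumerate(pattern):
            if p != c:
                t |= 1 << (b * i)
        table[c] = t
    miss_all = ones  # unknown text symbol mismatches everywhere

    hits = []
    state = 0
    sticky = 0
    top_shift = b * (m - 1)
    for j, c in enumerate(text):
        state = ((state << b) + table.get(c, miss_all)) & mask
        sticky = (sticky << b) & mask
        over = state & high
        if over:
            sticky |= over
            # zero saturated counters: spread their saturation bit over the
            # whole counter and clear
            sat_blocks = ((over >> (b - 1)) * full) & mask
            state &= ~sat_blocks
        if j >= m - 1:
            if not (sticky >> top_shift) & full:
                count = (state >> top_shift) & full
                if count <= k:
                    start = j - m + 2  # 1-based
                    positions = tuple(
                        i + 1
                        for i in range(m)
                        if pattern[i] != text[start - 1 + i]
                    )
                    hits.append(
                        MismatchHit(
                            pattern_id=pattern_id,
                            subject_id=subject_id,
                            subject_start=start,
                            mismatch_count=len(positions),
                            mismatch_positions=positions,
                        )
                    )
    return hits


def scan_offtargets(
    candidate,
    databank: Sequence[Transcript],
    k: int = 3,
    exclude_ids: Iterable[str] = (),
) -> tuple[int, list[MismatchHit]]:
    """Scan a candidate's 21-nt sense sequence against every non-excluded
    transcript, allowing up to ``k`` mismatches (default 3).

    Returns the number of distinct transcripts with at least one hit —
    the per-transcript off-target count — plus all hits.  ``exclude_ids``
    must contain the intended target's transcript id(s).
    """
    exclude = set(exclude_ids)
    all_hits: list[MismatchHit] = []
    n_transcripts = 0
    for t in databank:
        if t.id in exclude:
            continue
        hits = shift_add_search(
            candidate.sense, t.sequence, k,
            pattern_id=candidate.sirna_id, subject_id=t.id,
        )
        if hits:
            n_transcripts += 1
            all_hits.extend(hits)
    return n_transcripts, all_hits


def seed_site(guide: str) -> str:
    """mRNA-side seed match site: reverse complement of guide positions 2-8.

    Guide positions 2-8 (5'->3') form the seed; a 3'UTR carrying the
    reverse complement of that heptamer can be repressed miRNA-style.
    """
    guide = normalize_sequence(guide)
    if len(guide) != GUIDE_LEN:
        raise ValueError(f"guide must be {GUIDE_LEN} nt, got {len(guide)}")
    return reverse_complement(guide[1:8])


@dataclass(frozen=True)
class SeedMatchProfile:
    """Per-guide summary of seed sites found in a 3'UTR databank:
    UTR counts with exactly one, exactly two, and three or more sites."""

    n_seqs: int
    hit1: int
    hit2: int
    hit3plus: int


def seed_match_profile(
    guide: str,
    utr3_databank: Sequence[tuple[str, str]],
    strict_identity: bool = False,
) -> SeedMatchProfile:
    """Count exact (k=0) occurrences of the guide's seed site in each 3'UTR.

    Overlapping occurrences count separately.  ``strict_identity`` matches
    the seed heptamer itself instead of its reverse complement.
    """
    guide = normalize_sequence(guide)
    if len(guide) != GUIDE_LEN:
        raise ValueError(f"guide must be {GUIDE_LEN} nt, got {len(guide)}")
    site = guide[1:8] if strict_identity else seed_site(guide)
    hit1 = hit2 = hit3plus = 0
    for _utr_id, utr_seq in utr3_databank:
        n = len(shift_add_search(site, utr_seq, 0))
        if n == 1:
            hit1 += 1
        elif n == 2:
            hit2 += 1
        elif n >= 3:
            hit3plus += 1
    return SeedMatchProfile(
        n_seqs=hit1 + hit2 + hit3plus, hit1=hit1, hit2=hit2, hit3plus=hit3plus
    )


def mismatch_positions(guide: str, mrna_window: str) -> list[int]:
    """Guide positions (1-based, 5'->3') not Watson-Crick paired with the
    mRNA window they face: guide position p pairs with window position 22-p."""
    guide = normalize_sequence(guide)
    window = normalize_sequence(mrna_window)
    if len(guide) != GUIDE_LEN or len(window) != GUIDE_LEN:
        raise ValueError(f"guide and window must both be {GUIDE_LEN} nt")
    out = []
    for p in range(1, GUIDE_LEN + 1):
        paired = window[(GUIDE_LEN + 1 - p) - 1]
        if _COMP[guide[p - 1]] != paired:
            out.append(p)
    return out
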