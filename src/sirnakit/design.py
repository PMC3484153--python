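"""Candidate enumeration, efficacy scoring and selection.

The scorer is a linear model over the 21-nt guide strand (2-nt 3'
overhangs included): position-specific nucleotide indicators plus k-mer
motif counts, fit by ridge regression on (guide, measured efficacy)
training pairs.  A positional correction then adjusts the predicted
extinction percentage for where the target site sits on the transcript:
sites in the UTRs and sites far from the 5' end silence less well.
"""

from __future__ import annotations

import enum
import itertools
import logging
import re
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso, Ridge

from .transcripts import Region, Transcript, normalize_sequence, region_of, reverse_complement

logger = logging.getLogger(__name__)

GUIDE_LEN = 21

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

# Fixed feature order: 84 position x nucleotide indicators (position-major,
# bases in ACGT order), then counts of every 1-, 2- and 3-mer in
# lexicographic order (4 + 16 + 64 = 84).  168 features total.
KMERS: list[str] = [
    "".join(p)
    for k in (1, 2, 3)
    for p in itertools.product(_BASES, repeat=k)
]
_KMER_INDEX = {kmer: i for i, kmer in enumerate(KMERS)}
N_FEATURES = GUIDE_LEN * 4 + len(KMERS)

FEATURE_NAMES: list[str] = [
    f"pos{p + 1}_{b}" for p in range(GUIDE_LEN) for b in _BASES
] + [f"kmer_{k}" for k in KMERS]


class Grade(str, enum.Enum):
    """Knockdown grade: >=70% HIGH, [50, 70) MODERATE, <50 INEFFICIENT."""

    HIGH = "HIGH"
    MODERATE = "MODERATE"
    INEFFICIENT = "INEFFICIENT"

    def __str__(self) -> str:
        return self.value


def grade_efficacy(knockdown_pct: float) -> Grade:
    """Grade a measured knockdown percentage."""
    if knockdown_pct >= 70:
        return Grade.HIGH
    if knockdown_pct >= 50:
        return Grade.MODERATE
    return Grade.INEFFICIENT


@dataclass
class SiRNACandidate:
    """A 21-nt target window with its sense/guide strands and scores.

    ``start`` is the 1-based first base of the target window on the
    transcript; ``sense`` equals the window; ``guide`` is its reverse
    complement (the RISC-loaded antisense strand, written 5'->3').
    """

    target_id: str
    symbol: str
    start: int
    sense: str
    guide: str
    location: Region
    base_score: float | None = None
    corrected_score: float | None = None
    n_offtargets: int | None = None
    flags: set[str] = field(default_factory=set)

    @property
    def sirna_id(self) -> str:
        return f"{self.target_id}:{self.start}"


def enumerate_candidates(transcript: Transcript) -> list[SiRNACandidate]:
    """Every 21-nt window of the transcript as a candidate, ordered by start."""
    n = len(transcript)
    if n < GUIDE_LEN:
        logger.warning("transcript %s shorter than %d nt; no candidates",
                       transcript.id, GUIDE_LEN)
        return []
    out = []
    for start in range(1, n - GUIDE_LEN + 2):
        sense = transcript.window(start, GUIDE_LEN)
        out.append(
            SiRNACandidate(
                target_id=transcript.id,
                symbol=transcript.symbol,
                start=start,
                sense=sense,
                guide=reverse_complement(sense),
                location=region_of(transcript, start, GUIDE_LEN),
            )
        )
    return out


def encode_features(guide: str) -> np.ndarray:
    """Encode a 21-nt guide as 84 position-nucleotide indicators followed by
    84 k-mer counts (k = 1, 2, 3), in the fixed order of ``FEATURE_NAMES``."""
    guide = normalize_sequence(guide)
    if len(guide) != GUIDE_LEN:
        raise ValueError(f"guide must be {GUIDE_LEN} nt, got {len(guide)}")
    if set(guide) - set(_BASES):
        raise ValueError("guide contains non-ACGU/T symbols")
    x = np.zeros(N_FEATURES)
    for p, b in enumerate(guide):
        x[p * 4 + _BASE_INDEX[b]] = 1.0
    off = GUIDE_LEN * 4
    for k in (1, 2, 3):
        for i in range(GUIDE_LEN - k + 1):
            x[off + _KMER_INDEX[guide[i : i + k]]] += 1.0
    return x


@dataclass
class ScoringModel:
    """Linear efficacy model over guide-strand features.

    ``position_weights`` is the 21x4 slice of the coefficient vector
    (nucleotide b at guide position p); ``motif_weights`` maps each k-mer
    to its count weight.  Prediction is affine in ``encode_features`` and
    clipped to [0, 100] (a predicted extinction percentage).
    """

    intercept: float = 0.0
    coef: np.ndarray | None = None
    regularization: float = 1.0
    trained: bool = False

    @property
    def position_weights(self) -> np.ndarray:
        self._require_trained()
        return self.coef[: GUIDE_LEN * 4].reshape(GUIDE_LEN, 4)

    @property
    def motif_weights(self) -> dict[str, float]:
        self._require_trained()
        tail = self.coef[GUIDE_LEN * 4 :]
        return {kmer: float(w) for kmer, w in zip(KMERS, tail)}

    def _require_trained(self) -> None:
        if not self.trained or self.coef is None:
            raise RuntimeError("scoring model is untrained; fit it first")

    def linear_predictor(self, guide: str) -> float:
        """Affine prediction before clipping."""
        self._require_trained()
        return float(self.intercept + encode_features(guide) @ self.coef)


def train_model(
    pairs: list[tuple[str, float]],
    regularization: float = 1.0,
    seed: int = 0,
    method: str = "ridge",
) -> ScoringModel:
    """Fit the guide-strand linear model on (guide, efficacy%) pairs.

    Ridge regression (closed-form, deterministic) is the default; lasso is
    available via ``method="lasso"``.  Efficacies must lie in [0, 100] and
    at least two distinct guides are required.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 training pairs")
    guides = [normalize_sequence(g) for g, _ in pairs]
    y = np.array([e for _, e in pairs], dtype=float)
    if np.any((y < 0) | (y > 100)):
        raise ValueError("training efficacies must lie in [0, 100]")
    if len(set(guides)) < 2:
        raise ValueError("degenerate training set: all guides identical")
    X = np.vstack([encode_features(g) for g in guides])
    if method == "ridge":
        est = Ridge(alpha=regularization, solver="svd")
    elif method == "lasso":
        est = Lasso(alpha=max(regularization, 1e-12), random_state=seed, max_iter=50_000)
    else:
        raise ValueError(f"unknown method {method!r}")
    est.fit(X, y)
    return ScoringModel(
        intercept=float(est.intercept_),
        coef=np.asarray(est.coef_, dtype=float),
        regularization=regularization,
        trained=True,
    )


def predict_efficacy(model: ScoringModel, guide: str) -> float:
    """Predicted extinction percentage for a guide, clipped to [0, 100]."""
    return float(np.clip(model.linear_predictor(guide), 0.0, 100.0))


@dataclass
class CorrectionParams:
    """Positional/location correction for a predicted efficacy.

    The CDS at transcript position 1 is the reference (offset 0).  Sites in
    the 5'UTR are penalised ~39 points and 3'UTR sites ~26 points relative
    to the CDS, and efficacy decays ``slope_per_100bp`` points per 100 bp of
    distance from the transcript 5' end.
    """

    slope_per_100bp: float = -1.0
    location_offset: dict[Region, float] = field(
        default_factory=lambda: {
            Region.FIVE_UTR: -39.0,
            Region.CDS: 0.0,
            Region.THREE_UTR: -26.0,
        }
    )


def apply_positional_correction(
    base_score: float,
    location: Region,
    start: int,
    params: CorrectionParams | None = None,
) -> float:
    """Corrected score = clip(base + location offset + slope x (start-1)/100)."""
    params = params or CorrectionParams()
    if start < 1:
        raise ValueError("start must be >= 1")
    if location not in params.location_offset:
        raise ValueError(f"unknown location label {location!r}")
    corrected = (
        base_score
        + params.location_offset[location]
        + params.slope_per_100bp * (start - 1) / 100.0
    )
    return float(np.clip(corrected, 0.0, 100.0))


_POLYN_CACHE: dict[int, re.Pattern] = {}


def has_polyn_tract(seq: str, min_run: int = 4) -> bool:
    """True iff the sequence holds >= ``min_run`` identical consecutive bases."""
    if not seq:
        raise ValueError("empty sequence")
    pat = _POLYN_CACHE.get(min_run)
    if pat is None:
        pat = re.compile(r"(.)\1{%d,}" % (min_run - 1))
        _POLYN_CACHE[min_run] = pat
    return pat.search(normalize_sequence(seq)) is not None


@dataclass
class FilterRules:
    """Active selection rules.  ``None`` disables a rule.

    ``min_score`` is a strict lower bound on the base score (default >80%);
    ``cds_only`` restricts to CDS sites; ``no_polyn`` drops candidates with
    polynucleotide tracts; ``max_offtargets`` caps the per-transcript
    off-target count (counts must be attached beforehand).
    """

    min_score: float | None = 80.0
    cds_only: bool = False
    no_polyn: bool = False
    max_offtargets: int | None = None


# Filter-failure flags
LOW_SCORE = "LOW_SCORE"
NOT_CDS = "NOT_CDS"
POLYN_TRACT = "POLYN_TRACT"
OFFTARGETS = "OFFTARGETS"


def filter_candidates(
    candidates: list[SiRNACandidate], rules: FilterRules
) -> tuple[list[SiRNACandidate], list[SiRNACandidate]]:
    """Partition candidates into (retained, rejected); every rejected
    candidate carries the full set of failed-rule flags."""
    retained, rejected = [], []
    for c in candidates:
        flags = set()
        if rules.min_score is not None:
            if c.base_score is None or not (c.base_score > rules.min_score):
                flags.add(LOW_SCORE)
        if rules.cds_only and c.location is not Region.CDS:
            flags.add(NOT_CDS)
        if rules.no_polyn and has_polyn_tract(c.sense):
            flags.add(POLYN_TRACT)
        if rules.max_offtargets is not None:
            if c.n_offtargets is None:
                raise ValueError(
                    f"candidate {c.sirna_id} has no off-target count; "
                    "run the off-target scan before filtering on it"
                )
            if c.n_offtargets > rules.max_offtargets:
                flags.add(OFFTARGETS)
        c.flags = flags
        (rejected if flags else retained).append(c)
    return retained, rejected


def select_spaced(
    candidates: list[SiRNACandidate], k: int, min_gap: int
) -> list[SiRNACandidate]:
    """Greedy pick of up to ``k`` candidates by descending corrected score,
    skipping starts within ``min_gap`` of a pick on the same transcript.
    Ties break toward the smaller start."""

    def score(c: SiRNACandidate) -> float:
        s = c.corrected_score if c.corrected_score is not None else c.base_score
        if s is None:
            raise ValueError(f"candidate {c.sirna_id} is unscored")
        return s

    ranked = sorted(candidates, key=lambda c: (-score(c), c.start))
    picked: list[SiRNACandidate] = []
    for c in ranked:
        if len(picked) >= k:
            break
        if any(
            p.target_id == c.target_id and abs(p.start - c.start) < min_gap
            for p in picked
        ):
            continue
        picked.append(c)
    return picked
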