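"""Synthetic fixtures for every pipeline stage.

Generates random transcriptomes with UTR/CDS/exon structure, plants
near-match off-target sites with a ground-truth manifest, simulates qPCR
cycle-threshold tables with replicate noise, and draws per-siRNA
efficacies from an additive generating model (gene offsets + location
offsets + a linear positional decay + Gaussian noise).

The default parameters reproduce the conditions of an eight-gene,
88-siRNA endogenous knockdown screen: transcript lengths and CDS sizes of
the eight cancer-related targets, per-gene siRNA counts, gene effects
spanning -22 to +10 percentage points around the BCL2L1 reference, CDS
and 3'UTR sites more potent than 5'UTR sites by 39 and 13 points, a decay
of 1 point per 100 bp, and replicate noise of 10 points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import GUIDE_LEN, SiRNACandidate, enumerate_candidates
from .qpcr import CtRecord, Role
from .transcripts import Region, Transcript, region_of, reverse_complement

_BASES = np.array(list("ACGT"))

# The eight first-round target genes: (symbol, total length, CDS length,
# number of exons, number of siRNAs tested in the first round).
STUDY_GENES: list[tuple[str, int, int, int, int]] = [
    ("BCL2L1", 2575, 702, 3, 12),
    ("CSNK2A1", 2732, 1176, 13, 10),
    ("CSNK2A2", 1674, 1053, 12, 10),
    ("CSNK2B", 1128, 648, 7, 10),
    ("ERCC1", 3400, 894, 10, 9),
    ("ERCC2", 2568, 2283, 23, 15),
    ("HIF1A", 4082, 2481, 15, 9),
    ("HDAC6", 4099, 3648, 29, 13),
]

# Share of the non-coding length assigned to the 5' UTR: mRNA 5' UTRs are
# typically several-fold shorter than 3' UTRs.
FIVE_UTR_SHARE = 0.25


@dataclass
class EfficacyGenParams:
    """Parameters of the additive efficacy-generating model.

    efficacy = baseline + gene_offset + location_offset
               + slope_per_100bp x (position - 1)/100 + N(0, noise_sd),
    clipped to [-50, 100].  Defaults are the fitted effects of the
    eight-gene screen (offsets relative to BCL2L1 and to the 5' UTR).
    """

    gene_offsets: dict[str, float] = field(
        default_factory=lambda: {
            "BCL2L1": 0.0,
            "HDAC6": -22.0,
            "ERCC2": -11.0,
            "ERCC1": 7.0,
            "CSNK2A1": 9.0,
            "CSNK2A2": 10.0,
            "CSNK2B": 8.0,
            "HIF1A": 0.0,
        }
    )
    location_offsets: dict[Region, float] = field(
        default_factory=lambda: {
            Region.FIVE_UTR: 0.0,
            Region.CDS: 39.0,
            Region.THREE_UTR: 13.0,
        }
    )
    slope_per_100bp: float = -1.0
    noise_sd: float = 10.0
    baseline: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _random_exon_partition(rng: np.random.Generator, length: int, n_exons: int) -> list[int]:
    """Split ``length`` into ``n_exons`` positive parts."""
    n_exons = min(n_exons, length)
    cuts = rng.choice(np.arange(1, length), size=n_exons - 1, replace=False)
    cuts.sort()
    edges = np.concatenate([[0], cuts, [length]])
    return list(np.diff(edges).astype(int))


def make_transcriptome(
    n_genes: int = 8,
    length_range: tuple[int, int] = (1128, 4099),
    utr_fractions: tuple[float, float] = (0.1, 0.3),
    seed: int = 0,
    gene_specs: list[tuple[str, int, int, int]] | None = None,
) -> list[Transcript]:
    """Random transcripts with CDS boundaries and exon partitions.

    ``utr_fractions`` = (5'UTR, 3'UTR) fractions of total length when
    ``gene_specs`` is not given; otherwise each spec is (symbol, total
    length, CDS length, n_exons) and the non-coding length is split
    ``FIVE_UTR_SHARE`` / (1 - ``FIVE_UTR_SHARE``) between the UTRs.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    out: list[Transcript] = []
    specs: list[tuple[str, int, int, int, int | None]]
    if gene_specs is None:
        f5, f3 = utr_fractions
        if f5 + f3 >= 1.0:
            raise ValueError("UTR fractions must sum to < 1")
        specs = []
        for i in range(n_genes):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            utr5 = max(1, int(f5 * length))
            cds_len = length - utr5 - int(f3 * length)
            specs.append((f"GENE{i + 1:02d}", length, cds_len,
                          int(rng.integers(3, 25)), utr5))
    else:
        specs = [(*spec, None) for spec in gene_specs]
    for symbol, length, cds_len, n_exons, utr5 in specs:
        if length < 200:
            raise ValueError(f"{symbol}: transcript length must be >= 200")
        if cds_len >= length:
            raise ValueError(f"{symbol}: CDS length must be < total length")
        noncoding = length - cds_len
        if utr5 is None:
            utr5 = max(1, int(round(FIVE_UTR_SHARE * noncoding)))
        out.append(
            Transcript(
                id=f"SYN_{symbol}",
                symbol=symbol,
                sequence=_random_sequence(rng, length),
                cds_start=utr5 + 1,
                cds_end=utr5 + cds_len,
                exon_lengths=_random_exon_partition(rng, length, n_exons),
            )
        )
    return out


def make_study_transcriptome(seed: int = 0) -> list[Transcript]:
    """The eight-gene screen transcriptome: real lengths/CDS sizes/exon
    counts, random sequence content."""
    specs = [(sym, length, cds, exons) for sym, length, cds, exons, _ in STUDY_GENES]
    return make_transcriptome(seed=seed, gene_specs=specs)


def sample_study_candidates(
    seed: int = 0,
    transcriptome: list[Transcript] | None = None,
    n_per_gene: dict[str, int] | None = None,
) -> list[SiRNACandidate]:
    """Draw the screen's per-gene numbers of 21-nt target sites (88 in
    total by default) uniformly over each transcript."""
    rng = np.random.default_rng(seed)
    transcriptome = transcriptome or make_study_transcriptome(seed=seed)
    counts = n_per_gene or {sym: n for sym, _, _, _, n in STUDY_GENES}
    candidates: list[SiRNACandidate] = []
    for t in transcriptome:
        n = counts.get(t.symbol, 0)
        if n == 0:
            continue
        starts = rng.choice(np.arange(1, len(t) - GUIDE_LEN + 2), size=n, replace=False)
        for start in sorted(int(s) for s in starts):
            sense = t.window(start, GUIDE_LEN)
            candidates.append(
                SiRNACandidate(
                    target_id=t.id,
                    symbol=t.symbol,
                    start=start,
                    sense=sense,
                    guide=reverse_complement(sense),
                    location=region_of(t, start, GUIDE_LEN),
                )
            )
    return candidates


def simulate_efficacies(
    candidates: list[SiRNACandidate], params: EfficacyGenParams
) -> dict[str, float]:
    """Efficacy percentage per siRNA from the additive generating model,
    clipped to [-50, 100]; deterministic per ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    out: dict[str, float] = {}
    for c in candidates:
        if c.symbol not in params.gene_offsets:
            raise ValueError(f"no gene offset for {c.symbol!r}")
        mean = (
            params.baseline
            + params.gene_offsets[c.symbol]
            + params.location_offsets[c.location]
            + params.slope_per_100bp * (c.start - 1) / 100.0
        )
        eff = mean + (rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0)
        out[c.sirna_id] = float(np.clip(eff, -50.0, 100.0))
    return out


def plant_offtarget(
    transcriptome: list[Transcript],
    sense_21mer: str,
    n_sites: int,
    n_mismatches: int,
    seed: int = 0,
) -> tuple[list[Transcript], list[dict]]:
    """Insert mutated copies of a sense sequence into random transcripts.

    Each planted copy carries exactly ``n_mismatches`` substitutions at
    recorded pattern positions.  Returns the modified transcriptome and a
    manifest of ground-truth sites for oracle tests.
    """
    if not 0 <= n_mismatches <= 3:
        raise ValueError("n_mismatches must be in [0, 3]")
    m = len(sense_21mer)
    rng = np.random.default_rng(seed)
    seqs = {t.id: list(t.sequence) for t in transcriptome}
    manifest: list[dict] = []
    eligible = [t for t in transcriptome if len(t) >= m]
    if not eligible:
        raise ValueError("no transcript long enough to host the site")
    for _ in range(n_sites):
        host = eligible[int(rng.integers(len(eligible)))]
        start = int(rng.integers(1, len(host) - m + 2))
        copy = list(sense_21mer)
        positions = sorted(
            int(p) + 1 for p in rng.choice(m, size=n_mismatches, replace=False)
        )
        for p in positions:
            alternatives = [b for b in "ACGT" if b != copy[p - 1]]
            copy[p - 1] = alternatives[int(rng.integers(3))]
        seqs[host.id][start - 1 : start - 1 + m] = copy
        manifest.append(
            {
                "transcript_id": host.id,
                "start": start,
                "n_mismatches": n_mismatches,
                "mismatch_positions": positions,
            }
        )
    modified = [
        Transcript(
            id=t.id,
            symbol=t.symbol,
            sequence="".join(seqs[t.id]),
            cds_start=t.cds_start,
            cds_end=t.cds_end,
            exon_lengths=t.exon_lengths,
        )
        for t in transcriptome
    ]
    return modified, manifest


def simulate_ct(
    true_q_map: dict[str, float],
    target_gene: str,
    efficiencies: dict[str, float] | None = None,
    replicate_sd: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
    normalizer_genes: tuple[str, str] = ("36B4", "HPRT"),
    calibrator: str = "mock",
    run_id: str = "run1",
) -> list[CtRecord]:
    """Ct records consistent with the efficiency-corrected ratio model.

    Each sample in ``true_q_map`` gets ``n_replicates`` target and
    normalizer readings; the calibrator sample is included.  Target Ct is
    shifted by -log_e(q) cycles relative to the calibrator; Gaussian noise
    of ``replicate_sd`` cycles is added to every reading.
    """
    rng = np.random.default_rng(seed)
    eff = dict(efficiencies or {})
    base_ct = {target_gene: 24.0}
    for i, g in enumerate(normalizer_genes):
        base_ct[g] = 18.0 + 1.5 * i
    records: list[CtRecord] = []

    def noise() -> float:
        return float(rng.normal(0.0, replicate_sd)) if replicate_sd > 0 else 0.0

    samples = {calibrator: 1.0, **true_q_map}
    for sample, q in samples.items():
        if q <= 0:
            raise ValueError(f"true q must be positive, got {q} for {sample!r}")
        for gene in (target_gene, *normalizer_genes):
            e = eff.get(gene, 2.0)
            ct0 = base_ct[gene]
            shift = -np.log(q) / np.log(e) if gene == target_gene else 0.0
            for rep in range(1, n_replicates + 1):
                records.append(
                    CtRecord(
                        run_id=run_id,
                        sample=sample,
                        gene=gene,
                        role=Role.TARGET if gene == target_gene else Role.NORMALIZER,
                        replicate=rep,
                        ct=ct0 + shift + noise(),
                        efficiency=e,
                    )
                )
    return records


def simulate_covariate_table(
    seed: int,
    params: EfficacyGenParams | None = None,
    pure_noise: bool = False,
    noise_sd: float | None = None,
):
    """One full 13-covariate table for the 88-siRNA screen layout.

    Informative covariates (gene, location, position) and the response come
    from the generating model; the remaining covariates are drawn from
    simple null distributions so they carry no signal.  ``pure_noise``
    replaces the response with pure Gaussian noise (for null calibration).
    """
    from .analysis import build_covariate_table
    from .offtarget import SeedMatchProfile
    from .transcripts import exon_context

    rng = np.random.default_rng(seed)
    transcriptome = make_study_transcriptome(seed=seed)
    by_id = {t.id: t for t in transcriptome}
    candidates = sample_study_candidates(seed=seed, transcriptome=transcriptome)
    if params is None:
        params = EfficacyGenParams(seed=seed)
    if pure_noise:
        sd = params.noise_sd if noise_sd is None else noise_sd
        efficacies = {
            c.sirna_id: float(np.clip(rng.normal(50.0, sd), -50.0, 100.0))
            for c in candidates
        }
    else:
        efficacies = simulate_efficacies(candidates, params)

    offtarget_results = {}
    seed_profiles = {}
    exon_contexts = {}
    accessibility = {}
    for c in candidates:
        c.base_score = float(rng.uniform(80.1, 99.9))  # every screened siRNA scored >80%
        n_ot = int(rng.poisson(1.0))
        offtarget_results[c.sirna_id] = (n_ot, [None] * int(rng.poisson(2.0)))
        h1, h2, h3 = (int(rng.poisson(l)) for l in (3.0, 1.0, 0.5))
        seed_profiles[c.sirna_id] = SeedMatchProfile(h1 + h2 + h3, h1, h2, h3)
        exon_contexts[c.sirna_id] = exon_context(by_id[c.target_id], c.start, GUIDE_LEN)
        accessibility[c.sirna_id] = float(rng.uniform(0.0, 1.0))
    return build_covariate_table(
        candidates, offtarget_results, seed_profiles, exon_contexts,
        accessibility, efficacies,
    )
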